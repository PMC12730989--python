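"""Cohort configuration and the seeded substream scheme.

All randomness in the package flows from one integer seed through named
substreams (:func:`substream`), so adding a new stochastic operation never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

#: Fixed codes for per-operation random substreams.  Never renumber; append.
SUBSTREAMS: dict[str, int] = {
    "baseline_reference": 1,
    "morphometry": 2,
    "timeseries": 3,
    "outcomes": 4,
    "null_model": 5,
    "sweep": 6,
}

GROUPS = ("sci_only", "treatment")


def substream(seed: int, name: str, extra: tuple[int, ...] = ()) -> np.random.Generator:
    """Return the dedicated :class:`numpy.random.Generator` for one operation.

    Parameters
    ----------
    seed
        The global cohort seed.
    name
        One of the keys of :data:`SUBSTREAMS`.
    extra
        Optional further indices (e.g. per-subject, per-threshold) appended to
        the spawn key so nested loops get independent, reproducible streams.
    """
    if name not in SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(SUBSTREAMS)}")
    key = (SUBSTREAMS[name],) + tuple(int(e) for e in extra)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass(frozen=True)
class CohortConfig:
    """Design and effect-size parameters of a synthetic longitudinal cohort.

    Defaults emulate the study design the package targets: two groups of four
    animals (injury-only vs. injury plus regenerative treatment), scanned at a
    healthy baseline and 1, 2, 3, 6 and 12 months post-injury, with 110 usable
    fMRI samples per session and a modular inter-regional covariance structure
    at baseline.  ``n_roi`` defaults to 60 (the full atlas has 470 regions;
    the reduced default keeps simulations fast without changing the topology
    regime being emulated).
    """

    n_per_group: int = 4
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 6.0, 12.0)
    n_roi: int = 60
    n_timepoints_ts: int = 110
    n_modules: int = 4
    within_r: float = 0.6
    between_r: float = 0.1

    # morphometry scales (arbitrary volume units)
    gmv_mean: float = 100.0
    gmv_sd: float = 10.0
    tiv_mean: float = 95.0
    tiv_sd: float = 8.0
    tiv_coupling: float = 0.3          # GMV units per TIV unit
    subject_frac: float = 0.5          # share of GMV covariance that is a stable per-subject deviation

    #: per-group mean GMV shift (volume units) at each timepoint, baseline first
    injury_effect: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "sci_only": (0.0, -6.0, -8.0, -9.0, -10.0, -10.0),
            "treatment": (0.0, -6.0, -7.0, -6.0, -4.0, -2.0),
        }
    )
    perturb_covariance: bool = False
    covariance_shrink: float = 0.0     # post-injury shrink of off-diagonal correlation, used only if perturb_covariance

    # outcome model (locomotor parameters, arbitrary gait units)
    outcome_intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"path_length": 30.0, "step_height": 5.0, "stride_length": 40.0}
    )
    #: slope of the network metric in the reference (injury-only) group
    metric_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"path_length": -6.137, "step_height": 0.0, "stride_length": 2.669}
    )
    #: planted metric-by-group interaction coefficients
    interaction_effects: Mapping[str, float] = field(
        default_factory=lambda: {"path_length": 9.087, "step_height": 0.0, "stride_length": -4.553}
    )
    group_effects: Mapping[str, float] = field(
        default_factory=lambda: {"path_length": 2.0, "step_height": 0.3, "stride_length": 1.0}
    )
    time_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"path_length": 0.5, "step_height": 0.0, "stride_length": 0.0}
    )
    noise_sd: float = 1.0              # residual sd of locomotor outcomes
    subject_sd: float = 0.5            # sd of the per-subject random intercept

    # spinal-cord DTI scalars
    fa_effect: float = 0.549           # planted main-effect slope of FA on the Eg-like latent
    fa_intercept: float = 0.6
    fa_noise_sd: float = 0.02
    diffusivity_base: Mapping[str, float] = field(
        default_factory=lambda: {"md": 1.0, "rd": 0.6, "ad": 1.6}
    )
    diffusivity_noise_sd: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_roi < 3 * self.n_modules:
            raise ValueError("n_roi must be >= 3 * n_modules")
        tps = tuple(float(t) for t in self.timepoints)
        if tps[0] != 0.0:
            raise ValueError("first timepoint must be 0 (healthy baseline)")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("gmv_sd", "tiv_sd", "noise_sd", "fa_noise_sd", "diffusivity_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if not 0.0 <= self.subject_frac <= 1.0:
            raise ValueError("subject_frac must be in [0, 1]")
        for g in GROUPS:
            eff = self.injury_effect.get(g)
            if eff is None or len(eff) != len(tps):
                raise ValueError(
                    f"injury_effect[{g!r}] must list one shift per timepoint ({len(tps)})"
                )
        object.__setattr__(self, "timepoints", tps)

    # -- derived design facts -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"M{i + 1:02d}" for i in range(self.n_subjects))

    def group_of(self, subject_id: str) -> str:
        idx = self.subject_ids.index(subject_id)
        return GROUPS[0] if idx < self.n_per_group else GROUPS[1]

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["injury_effect"] = {k: list(v) for k, v in self.injury_effect.items()}
        for key in (
            "outcome_intercepts",
            "metric_slopes",
            "interaction_effects",
            "group_effects",
            "time_slopes",
            "diffusivity_base",
        ):
            d[key] = dict(getattr(self, key))
        d["timepoints"] = list(self.timepoints)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if "injury_effect" in d:
            d["injury_effect"] = {k: tuple(v) for k, v in d["injury_effect"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def config_hash(self) -> str:
        """Stable content hash of the configuration (used in run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
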