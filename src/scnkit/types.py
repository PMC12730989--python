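"""Shared in-memory containers for networks, records and metric curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SYM_TOL = 1e-8


def _check_symmetric(a: np.ndarray, name: str) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{name} must be symmetric (tolerance {_SYM_TOL})")


@dataclass(frozen=True)
class BaselineReference:
    """Healthy-period reference: per-ROI GMV mean/SD and the group-level
    structural covariance (correlation) matrix.

    ``mean[i]`` and ``sd[i]`` are the mean and standard deviation of region
    *i*'s gray-matter volume across healthy-period subjects; ``scn_hc[i, j]``
    is the Pearson correlation of TIV-adjusted GMV residuals between regions
    *i* and *j*.
    """

    mean: np.ndarray
    sd: np.ndarray
    scn_hc: np.ndarray
    roi_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        scn = np.asarray(self.scn_hc, dtype=float)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean and sd must be equal-length 1-D arrays")
        if np.any(sd <= 0):
            raise ValueError("all reference SDs must be strictly positive")
        _check_symmetric(scn, "scn_hc")
        if scn.shape[0] != mean.shape[0]:
            raise ValueError("scn_hc size must match mean/sd length")
        if not np.allclose(np.diag(scn), 1.0, atol=1e-8):
            raise ValueError("scn_hc must have unit diagonal")
        if np.any(np.abs(scn) > 1 + 1e-10):
            raise ValueError("scn_hc entries must lie in [-1, 1]")
        labels = tuple(self.roi_labels) or tuple(f"roi_{i + 1}" for i in range(mean.size))
        if len(labels) != mean.size:
            raise ValueError("roi_labels length must match n_roi")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "scn_hc", scn)
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n_roi(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI-by-ROI weighted network with zero diagonal.

    ``kind`` records how the matrix was built: ``functional_z`` (positive
    Pearson correlations, Fisher-z transformed), ``individual_scn`` (the
    subject weighting matrix times the group covariance) or ``group_scn``.
    """

    values: np.ndarray
    kind: str
    roi_labels: tuple[str, ...] = ()
    subject_id: str | None = None
    timepoint: float | None = None

    KINDS = ("functional_z", "individual_scn", "group_scn")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        _check_symmetric(v, "connectivity values")
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("connectivity matrix must have zero diagonal")
        if self.kind == "functional_z" and np.any(v < 0):
            raise ValueError("functional_z entries must be nonnegative (negatives are masked)")
        labels = tuple(self.roi_labels) or tuple(f"roi_{i + 1}" for i in range(v.shape[0]))
        if len(labels) != v.shape[0]:
            raise ValueError("roi_labels length must match matrix size")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightMatrix:
    """Subject-specific weighting derived from deviations from healthy means.

    ``esd`` is the inter-regional effect-size difference, ``r = tanh(esd)``
    and ``w = 1 - r``; all symmetric, ``w`` in (0, 1].
    """

    esd: np.ndarray
    r: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        esd = np.asarray(self.esd, dtype=float)
        r = np.asarray(self.r, dtype=float)
        w = np.asarray(self.w, dtype=float)
        for name, a in (("esd", esd), ("r", r), ("w", w)):
            _check_symmetric(a, name)
        if np.any(esd < 0):
            raise ValueError("esd must be nonnegative")
        if np.any((r < 0) | (r >= 1)):
            raise ValueError("r must lie in [0, 1)")
        if np.any((w <= 0) | (w > 1)):
            raise ValueError("w must lie in (0, 1]")
        object.__setattr__(self, "esd", esd)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class MorphometryRecord:
    """Regional gray-matter volumes for one subject at one timepoint."""

    subject_id: str
    group: str
    timepoint: float
    gmv: np.ndarray
    tiv: float

    def __post_init__(self) -> None:
        gmv = np.asarray(self.gmv, dtype=float)
        if gmv.ndim != 1 or not np.all(np.isfinite(gmv)):
            raise ValueError("gmv must be a finite 1-D array")
        if not self.tiv > 0:
            raise ValueError("tiv must be positive")
        object.__setattr__(self, "gmv", gmv)


@dataclass(frozen=True)
class TimeSeriesRecord:
    """ROI time series (time by ROI) for one subject at one timepoint."""

    subject_id: str
    timepoint: float
    series: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2:
            raise ValueError("series must be 2-D (time x ROI)")
        object.__setattr__(self, "series", s)


@dataclass(frozen=True)
class OutcomeRecord:
    """Locomotor parameters and spinal-cord DTI scalars for one assessment."""

    subject_id: str
    group: str
    timepoint: float
    path_length: float
    step_height: float
    stride_length: float
    fa: float
    md: float
    rd: float
    ad: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError("fa must lie in [0, 1]")
        for name in ("md", "rd", "ad"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ThresholdGrid:
    """Proportional-threshold (sparsity) grid."""

    s_min: float = 0.05
    s_max: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max <= 1):
            raise ValueError("need 0 < s_min <= s_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        grid = self.s_min + self.step * np.arange(n)
        return np.round(grid[grid <= self.s_max + 1e-12], 10)


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected binary graph as a 0/1 adjacency matrix without self-loops."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        _check_symmetric(a.astype(float), "adjacency")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency must be 0/1")
        if np.any(np.diag(a) != 0):
            raise ValueError("no self-loops allowed")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class GlobalMetricSet:
    """The seven global binary-graph metrics at one sparsity threshold."""

    eg: float
    eloc: float
    lp: float
    cp: float
    gamma: float
    lambda_: float
    sigma: float
    sparsity: float
    notes: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "Eg": self.eg,
            "Eloc": self.eloc,
            "Lp": self.lp,
            "Cp": self.cp,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


@dataclass(frozen=True)
class MetricCurve:
    """One metric traced across the sparsity grid, with its AUC."""

    metric_name: str
    sparsities: np.ndarray
    values: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        s = np.asarray(self.sparsities, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("sparsities and values must be equal-length 1-D arrays")
        object.__setattr__(self, "sparsities", s)
        object.__setattr__(self, "values", v)
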