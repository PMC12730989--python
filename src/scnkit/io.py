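"""Plain-text I/O: square matrix TSVs with label headers, tables, manifests.

Matrices are written as TSV with ROI labels as both header row and first
column, plus a JSON sidecar recording the kind, subject, timepoint and
construction parameters.  Reading verifies squareness, symmetry (1e-8) and
label consistency, and can permute to a requested label order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ConnectivityMatrix

__all__ = ["write_matrix", "read_matrix", "sha256_of", "write_manifest", "read_manifest"]

_SYM_TOL = 1e-8


def write_matrix(path: str | Path, matrix: ConnectivityMatrix) -> Path:
    """Write a connectivity matrix as labeled TSV + JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(matrix.values, index=matrix.roi_labels, columns=matrix.roi_labels)
    frame.to_csv(path, sep="\t", float_format="%.17g")
    sidecar = {
        "kind": matrix.kind,
        "subject_id": matrix.subject_id,
        "timepoint": matrix.timepoint,
        "n_roi": matrix.n_roi,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_matrix(
    path: str | Path, roi_labels: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Read a labeled square matrix TSV back into a :class:`ConnectivityMatrix`.

    Verifies the matrix is square, symmetric (within 1e-8) and that row and
    column labels agree.  If ``roi_labels`` is given, rows and columns are
    permuted consistently to that order (a missing label is an error).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({frame.shape})")
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise ValueError(f"{path}: row labels do not match column labels")
    values = frame.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{path}: matrix is asymmetric beyond {_SYM_TOL}")
    labels = tuple(str(c) for c in frame.columns)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if roi_labels is not None:
        want = [str(l) for l in roi_labels]
        missing = set(want) - set(labels)
        if missing:
            raise ValueError(f"{path}: requested labels not present: {sorted(missing)}")
        perm = [labels.index(l) for l in want]
        values = values[np.ix_(perm, perm)]
        labels = tuple(want)
    return ConnectivityMatrix(
        values=values,
        kind=meta.get("kind", "group_scn"),
        roi_labels=labels,
        subject_id=meta.get("subject_id"),
        timepoint=meta.get("timepoint"),
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
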