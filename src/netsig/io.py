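"""Readers and writers: labelled TSV matrices, JSON partitions and provenance.

Matrices travel as tab-separated text with the ROI labels as the header row
and first column — human-diffable and adequate at 43 x 43 scale. Values are
serialized with 17 significant digits so a read-back reproduces the floats
bit-for-bit. Partitions and result summaries are plain JSON.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .roi import RoiSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_json",
    "provenance_block",
    "load_reference_partitions",
]

logger = logging.getLogger("netsig")


def write_matrix(matrix: np.ndarray, roi_set: RoiSet, path: str | Path) -> Path:
    """Write a labelled square matrix as TSV (full float precision)."""
    matrix = np.asarray(matrix)
    n = len(roi_set)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} ROI labels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(matrix, index=list(roi_set), columns=list(roi_set))
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="roi")
    return path


def read_matrix(
    path: str | Path, roi_set: RoiSet | None = None
) -> tuple[np.ndarray, RoiSet]:
    """Read a labelled square TSV matrix, canonicalizing ROI order.

    If ``roi_set`` is given, rows/columns are reordered to its canonical
    order (a reordering is logged); unknown or missing labels are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(rows) != len(cols):
        raise ValueError(f"{path}: matrix is {len(rows)}x{len(cols)}, not square")
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise ValueError(f"{path}: duplicate ROI labels")
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels")
    found = RoiSet.from_labels(rows)
    if roi_set is None or found == roi_set:
        return df.to_numpy(dtype=float), found
    if set(rows) != set(roi_set.labels):
        missing = sorted(set(roi_set.labels) - set(rows))
        extra = sorted(set(rows) - set(roi_set.labels))
        raise ValueError(
            f"{path}: labels do not match the canonical RoiSet "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    logger.info("%s: reordering rows/columns to canonical ROI order", path)
    order = [rows.index(l) for l in roi_set]
    values = df.to_numpy(dtype=float)[np.ix_(order, order)]
    return values, roi_set


def write_partition(assignment: Mapping[str, int], q: float, path: str | Path,
                    extra: Mapping | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"assignment": {k: int(v) for k, v in assignment.items()},
               "q": float(q)}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_partition(path: str | Path) -> tuple[dict[str, int], float]:
    payload = json.loads(Path(path).read_text())
    return {k: int(v) for k, v in payload["assignment"].items()}, float(payload["q"])


def write_json(payload: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def provenance_block(config: Mapping) -> dict:
    """Config echo embedded into every output artifact."""
    import netsig

    return {
        "config": {k: _plain(v) for k, v in dict(config).items()},
        "netsig_version": netsig.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (tuple, list)):
        return [_plain(x) for x in v]
    if isinstance(v, Path):
        return str(v)
    return v


def load_reference_partitions(path: str | Path) -> dict[str, dict[str, int]]:
    """Load published ROI -> module assignment tables for both modalities.

    Expects a JSON object ``{"rsfmri": {label: module, ...},
    "tractography": {...}}`` transcribed from a published parcellation
    (such tables ship in article supplements, not with this package).
    Raises ``FileNotFoundError`` with guidance when the file is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: reference module-assignment tables not found. These are "
            "published as article supplementary material and must be "
            "transcribed to JSON ({'rsfmri': {roi: module}, 'tractography': "
            "{roi: module}}) by the user; they are not distributed here."
        )
    payload = json.loads(path.read_text())
    for key in ("rsfmri", "tractography"):
        if key not in payload:
            raise ValueError(f"{path}: missing {key!r} assignment table")
    return {k: {str(r): int(m) for r, m in payload[k].items()}
            for k in ("rsfmri", "tractography")}
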