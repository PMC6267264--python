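"""Group connectome construction.

Two branches, mirroring how task-independent connectivity is usually built
from a cohort:

* **Structural** — per-subject directional streamline-count matrices are
  symmetrised (the two tracking directions combined into one probability
  estimate per region pair), double-thresholded (a per-subject Poisson
  threshold at ``p = 0.05`` on the streamline-hit noise floor, then a group
  consistency criterion of at least half the subjects), yielding one binary
  group adjacency matrix.
* **Functional** — per-subject ROI-to-ROI Pearson correlation matrices are
  Fisher z-transformed, averaged across subjects, transformed back, and
  negative group correlations are zeroed, yielding one weighted group
  matrix. Subjects exceeding motion limits (3 mm translation or 1 degree
  rotation) are censored before averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .roi import RoiSet

__all__ = [
    "SubjectStructuralMatrix",
    "SubjectTimeSeries",
    "GroupBinaryConnectome",
    "GroupWeightedConnectome",
    "PoissonThresholdConfig",
    "combine_directional",
    "poisson_threshold",
    "poisson_threshold_value",
    "group_consistency",
    "censor_subjects",
    "subject_functional_matrix",
    "group_functional_matrix",
    "build_structural_connectome",
    "build_functional_connectome",
]

#: Monte-Carlo streamlines initiated per seed voxel; matrix entries are hits
#: out of this many samples.
N_STREAMLINES_DEFAULT = 20_000

_R_CLIP = 1.0 - 1e-6  # keeps atanh finite for perfectly correlated series


def _check_square(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{what} must be square, got shape {values.shape}")
    return values


def _assert_symmetric_zero_diag(m: np.ndarray, what: str) -> None:
    if not np.allclose(m, m.T, atol=1e-12):
        raise AssertionError(f"{what} is not symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise AssertionError(f"{what} has a nonzero diagonal")


@dataclass
class SubjectStructuralMatrix:
    """Directional streamline-hit counts (source row -> target column)."""

    values: np.ndarray
    roi_set: RoiSet
    subject_id: str = ""
    n_streamlines: int = N_STREAMLINES_DEFAULT

    def __post_init__(self) -> None:
        self.values = _check_square(np.asarray(self.values), "structural matrix")
        if len(self.roi_set) != self.values.shape[0]:
            raise ValueError(
                f"matrix is {self.values.shape[0]}x{self.values.shape[0]} but "
                f"roi_set has {len(self.roi_set)} labels"
            )
        if np.any(self.values < 0):
            raise ValueError("streamline counts must be nonnegative")
        if np.any(self.values > self.n_streamlines):
            raise ValueError(f"streamline counts exceed n_streamlines={self.n_streamlines}")


@dataclass
class SubjectTimeSeries:
    """ROI x time BOLD-like series with head-motion summary scalars."""

    series: np.ndarray
    roi_set: RoiSet
    subject_id: str = ""
    motion_translation_mm: float | None = 0.0
    motion_rotation_deg: float | None = 0.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be ROI x time")
        if self.series.shape[0] != len(self.roi_set):
            raise ValueError("series row count must match roi_set")
        if self.series.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if np.any(~np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")


@dataclass
class GroupBinaryConnectome:
    """Symmetric 0/1 group structural adjacency with threshold provenance."""

    adjacency: np.ndarray
    roi_set: RoiSet
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = _check_square(np.asarray(self.adjacency), "adjacency")
        _assert_symmetric_zero_diag(self.adjacency, "group adjacency")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class GroupWeightedConnectome:
    """Symmetric nonnegative group functional connectivity (correlations)."""

    weights: np.ndarray
    roi_set: RoiSet
    n_subjects_included: int = 0

    def __post_init__(self) -> None:
        self.weights = _check_square(np.asarray(self.weights, dtype=float), "weights")
        _assert_symmetric_zero_diag(self.weights, "group weights")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("group weights must lie in [0, 1]")


@dataclass(frozen=True)
class PoissonThresholdConfig:
    """Per-subject streamline threshold: Poisson noise model at level alpha.

    ``lambda_estimator`` chooses how the Poisson rate is fit to a subject's
    combined matrix: ``"nonzero_mean"`` (default) averages the nonzero
    off-diagonal entries — zero entries dominate sparse connectomes and
    would collapse the rate — while ``"all_mean"`` averages every
    off-diagonal entry.
    """

    alpha: float = 0.05
    lambda_estimator: Literal["nonzero_mean", "all_mean"] = "nonzero_mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lambda_estimator not in ("nonzero_mean", "all_mean"):
            raise ValueError(f"unknown lambda_estimator {self.lambda_estimator!r}")


def combine_directional(
    m: SubjectStructuralMatrix, rule: Literal["mean", "max"] = "mean"
) -> np.ndarray:
    """Collapse the two tracking directions into one symmetric estimate.

    Tractography tracks A->B and B->A separately; the two hit counts are
    combined into a single per-pair probability estimate. ``mean`` is the
    default symmetric combination; ``max`` is available because the choice
    of combination rule is a modelling decision, not a mathematical one.
    """
    v = np.asarray(m.values, dtype=float)
    if rule == "mean":
        combined = (v + v.T) / 2.0
    elif rule == "max":
        combined = np.maximum(v, v.T)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    np.fill_diagonal(combined, 0.0)
    return combined


def poisson_threshold_value(lam: float, alpha: float = 0.05) -> int:
    """Smallest integer v with ``P(X >= v | Poisson(lam)) < alpha``.

    Computed with scipy's Poisson survival function (numerically stable at
    any rate); a short scan around the quantile guards the strict-inequality
    boundary.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        return 1  # any positive count is already beyond a zero-rate noise floor
    # sf(v - 1) = P(X >= v); start near the (1 - alpha) quantile and scan.
    v = int(stats.poisson.ppf(1.0 - alpha, lam))
    v = max(v - 2, 1)
    while stats.poisson.sf(v - 1, lam) >= alpha:
        v += 1
    return v


def poisson_threshold(
    combined: np.ndarray, cfg: PoissonThresholdConfig = PoissonThresholdConfig()
) -> np.ndarray:
    """Binarize one subject's combined matrix against its Poisson noise floor.

    The rate λ is fit to the subject's off-diagonal entries per
    ``cfg.lambda_estimator``; entries at or above the critical value
    ``v* = min{v : P(X >= v) < alpha}`` are kept as edges.
    """
    combined = _check_square(np.asarray(combined, dtype=float), "combined matrix")
    if np.any(combined < 0):
        raise ValueError("combined matrix entries must be nonnegative")
    off = combined[~np.eye(combined.shape[0], dtype=bool)]
    if cfg.lambda_estimator == "nonzero_mean":
        nonzero = off[off > 0]
        if nonzero.size == 0:
            warnings.warn(
                "all-zero matrix: Poisson rate undefined under nonzero_mean; "
                "returning an all-zero adjacency",
                stacklevel=2,
            )
            return np.zeros_like(combined, dtype=int)
        lam = float(nonzero.mean())
    else:
        lam = float(off.mean())
        if lam == 0.0:
            warnings.warn("all-zero matrix: returning an all-zero adjacency", stacklevel=2)
            return np.zeros_like(combined, dtype=int)
    v_star = poisson_threshold_value(lam, cfg.alpha)
    binary = (combined >= v_star).astype(int)
    np.fill_diagonal(binary, 0)
    return binary


def group_consistency(
    binary_matrices: Sequence[np.ndarray],
    roi_set: RoiSet,
    min_fraction: float = 0.5,
    provenance: dict | None = None,
) -> GroupBinaryConnectome:
    """Keep edges present in at least ``ceil(min_fraction * n)`` subjects.

    The boundary is inclusive: with 24 subjects and the default fraction of
    one half, an edge present in exactly 12 subjects is kept.
    """
    if len(binary_matrices) == 0:
        raise ValueError("need at least one subject matrix")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    stack = np.stack([np.asarray(b) for b in binary_matrices])
    if stack.shape[1] != len(roi_set) or stack.shape[2] != len(roi_set):
        raise ValueError("subject matrices must match the roi_set size")
    n = stack.shape[0]
    need = math.ceil(min_fraction * n)
    counts = stack.sum(axis=0)
    adjacency = (counts >= need).astype(int)
    adjacency = np.maximum(adjacency, adjacency.T)  # guards asymmetric inputs
    np.fill_diagonal(adjacency, 0)
    prov = {"min_fraction": min_fraction, "n_subjects": n, "min_subjects": need}
    if provenance:
        prov.update(provenance)
    return GroupBinaryConnectome(adjacency=adjacency, roi_set=roi_set, provenance=prov)


def censor_subjects(
    cohort: Sequence[SubjectTimeSeries],
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 1.0,
) -> tuple[list[SubjectTimeSeries], list[dict]]:
    """Drop subjects whose head motion exceeds either limit.

    Returns the retained subjects and an exclusion report (one entry per
    excluded subject, with the offending measurements). Subjects with
    missing motion scalars pass with a warning — absence of evidence of
    motion is not treated as motion.
    """
    included: list[SubjectTimeSeries] = []
    report: list[dict] = []
    for s in cohort:
        t, r = s.motion_translation_mm, s.motion_rotation_deg
        if t is None or r is None:
            warnings.warn(
                f"subject {s.subject_id!r}: missing motion scalars, treating as pass",
                stacklevel=2,
            )
            included.append(s)
            continue
        reasons = []
        if t > max_translation_mm:
            reasons.append(f"translation {t:g} mm > {max_translation_mm:g} mm")
        if r > max_rotation_deg:
            reasons.append(f"rotation {r:g} deg > {max_rotation_deg:g} deg")
        if reasons:
            report.append({"subject_id": s.subject_id, "reasons": reasons})
        else:
            included.append(s)
    return included, report


def subject_functional_matrix(ts: SubjectTimeSeries) -> np.ndarray:
    """ROI-to-ROI Pearson correlation of one subject's series (diagonal 0)."""
    sd = ts.series.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [ts.roi_set[int(i)] for i in flat]
        raise ValueError(f"constant time series for ROI(s) {names}: correlation undefined")
    r = np.corrcoef(ts.series)
    np.fill_diagonal(r, 0.0)
    return r


def group_functional_matrix(
    subject_matrices: Sequence[np.ndarray], roi_set: RoiSet
) -> GroupWeightedConnectome:
    """Fisher-z average subject correlation matrices; zero negative weights.

    Each subject correlation r is clipped to ±(1 − 1e−6) before atanh so a
    perfectly correlated pair stays finite; the group value is
    tanh(mean z), and edges whose group correlation is negative are set to
    zero rather than the ROI being removed.
    """
    if len(subject_matrices) == 0:
        raise ValueError("need at least one subject matrix")
    n = len(roi_set)
    stack = np.stack([np.asarray(m, dtype=float) for m in subject_matrices])
    if stack.shape[1:] != (n, n):
        raise ValueError("subject matrices must match roi_set size")
    if stack.shape[0] == 1:
        # mean of one z-score is that z-score: skip the transform entirely so
        # the single-subject round trip is exact to the last bit
        group_r = stack[0].copy()
    else:
        z = np.arctanh(np.clip(stack, -_R_CLIP, _R_CLIP))
        group_r = np.tanh(z.mean(axis=0))
    group_r = (group_r + group_r.transpose()) / 2.0  # symmetrize numeric noise
    weights = np.where(group_r > 0, group_r, 0.0)
    np.fill_diagonal(weights, 0.0)
    return GroupWeightedConnectome(
        weights=weights, roi_set=roi_set, n_subjects_included=stack.shape[0]
    )


def build_structural_connectome(
    cohort: Sequence[SubjectStructuralMatrix],
    cfg: PoissonThresholdConfig = PoissonThresholdConfig(),
    min_fraction: float = 0.5,
    combine: Literal["mean", "max"] = "mean",
) -> GroupBinaryConnectome:
    """Full structural branch: combine directions, double-threshold, group."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    roi_set = cohort[0].roi_set
    binaries = []
    for subj in cohort:
        if subj.roi_set != roi_set:
            raise ValueError("all subjects must share one roi_set")
        binaries.append(poisson_threshold(combine_directional(subj, combine), cfg))
    return group_consistency(
        binaries,
        roi_set,
        min_fraction,
        provenance={"alpha": cfg.alpha, "lambda_estimator": cfg.lambda_estimator,
                    "combine": combine},
    )


def build_functional_connectome(
    cohort: Sequence[SubjectTimeSeries],
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 1.0,
) -> tuple[GroupWeightedConnectome, list[dict]]:
    """Full functional branch: censor, correlate per subject, Fisher-average."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    included, report = censor_subjects(cohort, max_translation_mm, max_rotation_deg)
    if len(included) == 0:
        raise ValueError("every subject was censored for motion")
    roi_set = included[0].roi_set
    mats = [subject_functional_matrix(s) for s in included]
    return group_functional_matrix(mats, roi_set), report
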