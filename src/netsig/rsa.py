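"""Network-level representational similarity analysis.

The cognitive signature of a network partition is tested formally by
comparing two kinds of representational dissimilarity matrices (RDMs) over
the ROI set:

* **activation RDMs** — per subject, ``d(i, j) = 1 - Pearson(b_i, b_j)``
  where ``b_i`` is ROI *i*'s activity profile across the task contrasts;
* **model RDMs** — the partition's hypothesis: dissimilarity 0 for ROI
  pairs in the same module, 1 for pairs in different modules.

The second-order statistic is Spearman's rank correlation between the
strict upper triangles of two RDMs (n(n-1)/2 pairs; 903 for 43 ROIs),
with average-rank tie handling — consequential because model RDMs are
binary and massively tied. Group inference is a two-tailed one-sample
t-test over Fisher-transformed subject correlations, Bonferroni-corrected
over the model x study comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .roi import RoiSet
from .signature import ContrastBetas

__all__ = [
    "RDM",
    "RsaResult",
    "ModelComparison",
    "activation_rdm",
    "activation_rdms",
    "model_rdm",
    "rdm_correlation",
    "group_rsa",
    "compare_model_rdms",
]


@dataclass
class RDM:
    """Symmetric zero-diagonal dissimilarity matrix over the ROI set."""

    dissimilarity: np.ndarray
    roi_set: RoiSet
    kind: Literal["activation", "model"] = "activation"

    def __post_init__(self) -> None:
        d = np.asarray(self.dissimilarity, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"RDM must be square, got {d.shape}")
        if d.shape[0] != len(self.roi_set):
            raise ValueError("RDM size must match roi_set")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("RDM diagonal must be zero")
        if self.kind == "activation" and (d.min() < -1e-10 or d.max() > 2.0 + 1e-10):
            raise ValueError("activation RDM entries must lie in [0, 2]")
        if self.kind == "model" and not np.isin(d, (0.0, 1.0)).all():
            raise ValueError("model RDM entries must be 0 or 1")
        self.dissimilarity = d

    def upper(self) -> np.ndarray:
        """Strict upper-triangle entries in row-major (lexicographic pair) order."""
        iu, ju = np.triu_indices(len(self.roi_set), k=1)
        return self.dissimilarity[iu, ju]


@dataclass
class RsaResult:
    """Group-level second-order correlation of subject RDMs with a model."""

    subject_rhos: np.ndarray
    mean_rho: float
    t: float
    p_uncorrected: float
    p_corrected: float
    n_comparisons: int
    n_subjects_dropped: int = 0


@dataclass
class ModelComparison:
    """Model-to-model RDM correlation with parametric and permutation p."""

    rho: float
    p_parametric: float
    p_permutation: float | None
    n_pairs: int
    n_perm: int


def activation_rdm(betas_one_subject: np.ndarray, roi_set: RoiSet) -> RDM:
    """RDM of one subject's ROI x contrast activity: 1 - Pearson across contrasts."""
    b = np.asarray(betas_one_subject, dtype=float)
    if b.ndim != 2 or b.shape[0] != len(roi_set):
        raise ValueError("expected an ROI x contrast matrix matching roi_set")
    if b.shape[1] < 3:
        raise ValueError("need at least 3 contrasts for a correlation-based RDM")
    sd = b.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [roi_set[int(i)] for i in flat]
        raise ValueError(
            f"constant activity profile for ROI(s) {names}: dissimilarity undefined"
        )
    r = np.corrcoef(b)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)  # guards tiny float excursions past the bounds
    return RDM(dissimilarity=d, roi_set=roi_set, kind="activation")


def activation_rdms(betas: ContrastBetas) -> list[RDM]:
    """Per-subject activation RDMs for one study."""
    return [activation_rdm(betas.values[s], betas.roi_set)
            for s in range(betas.n_subjects)]


def model_rdm(partition) -> RDM:
    """Partition hypothesis RDM: 0 within a module, 1 between modules."""
    labels = partition.labels_array()
    d = (labels[:, None] != labels[None, :]).astype(float)
    np.fill_diagonal(d, 0.0)
    return RDM(dissimilarity=d, roi_set=partition.roi_set, kind="model")


def rdm_correlation(x: RDM, y: RDM) -> float:
    """Spearman rank correlation between two RDMs' strict upper triangles."""
    if x.roi_set != y.roi_set:
        raise ValueError("RDMs must share one roi_set")
    if len(x.roi_set) < 3:
        raise ValueError("need at least 3 ROIs for a second-order correlation")
    ux, uy = x.upper(), y.upper()
    if np.all(ux == ux[0]) or np.all(uy == uy[0]):
        raise ValueError(
            "an RDM with constant off-diagonal entries (e.g. a single-module "
            "model) has no rank variance; correlation undefined"
        )
    rho, _ = stats.spearmanr(ux, uy)
    return float(rho)


def group_rsa(
    individual_rdms: Sequence[RDM], model: RDM, n_comparisons: int = 6
) -> RsaResult:
    """Second-order correlation of each subject's RDM with a model RDM.

    Group inference is a two-tailed one-sample t-test of atanh(rho) against
    zero (random effects over subjects); the reported summary ``mean_rho``
    is the mean of the raw subject correlations. Bonferroni correction
    multiplies by ``n_comparisons`` (default 6: two models x three
    studies). Subjects whose correlation is undefined are dropped with a
    warning and counted.
    """
    if len(individual_rdms) < 2:
        raise ValueError("need at least two subject RDMs")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be positive")
    rhos = []
    dropped = 0
    for rdm in individual_rdms:
        try:
            rhos.append(rdm_correlation(rdm, model))
        except ValueError:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} subject(s) with undefined correlation",
                      stacklevel=2)
    if len(rhos) < 2:
        raise ValueError("fewer than two subjects with a defined correlation")
    rhos_arr = np.asarray(rhos)
    z = np.arctanh(np.clip(rhos_arr, -1 + 1e-12, 1 - 1e-12))
    if z.std() == 0:
        # identical correlations across subjects: t degenerates
        t = math.inf if z.mean() > 0 else (-math.inf if z.mean() < 0 else 0.0)
        p = math.nan if z.mean() != 0 else 1.0
    else:
        t_res = stats.ttest_1samp(z, 0.0)
        t, p = float(t_res.statistic), float(t_res.pvalue)
    return RsaResult(
        subject_rhos=rhos_arr,
        mean_rho=float(rhos_arr.mean()),
        t=t,
        p_uncorrected=p,
        p_corrected=min(1.0, p * n_comparisons) if not math.isnan(p) else math.nan,
        n_comparisons=n_comparisons,
        n_subjects_dropped=dropped,
    )


def _spearman_binary_fast(rank_x: np.ndarray, y_binary: np.ndarray) -> float:
    """Spearman of a fixed vector (pre-ranked) against a binary vector.

    With only two distinct values in y, average ranks are an affine
    function of y, so Spearman(x, y) equals the Pearson correlation of
    rank(x) with y itself. Used by the Mantel permutation loop.
    """
    y = y_binary - y_binary.mean()
    denom = math.sqrt((rank_x - rank_x.mean()) @ (rank_x - rank_x.mean()) * (y @ y))
    if denom == 0:
        return math.nan
    return float((rank_x - rank_x.mean()) @ y / denom)


def compare_model_rdms(
    m1: RDM, m2: RDM, n_perm: int = 100_000, seed: int = 0
) -> ModelComparison:
    """Correlate two partition model RDMs, with two kinds of p-value.

    * parametric: the t approximation on n(n-1)/2 pairs
      (``t = rho * sqrt((n_pairs - 2) / (1 - rho^2))``, df = n_pairs - 2);
      anticonservative because RDM entries sharing an ROI are not
      independent, which is why the permutation p is also reported;
    * permutation (Mantel-style): ROI labels of the second partition are
      permuted ``n_perm`` times and the correlation recomputed;
      ``p = (1 + #{|rho_perm| >= |rho|}) / (n_perm + 1)``.
    """
    if m1.kind != "model" or m2.kind != "model":
        raise ValueError("compare_model_rdms expects two model RDMs")
    rho = rdm_correlation(m1, m2)
    n_pairs = len(m1.upper())
    if abs(rho) >= 1.0:
        p_param = 0.0
    else:
        t = rho * math.sqrt((n_pairs - 2) / (1.0 - rho * rho))
        p_param = 2.0 * float(stats.t.sf(abs(t), df=n_pairs - 2))
    p_perm = None
    if n_perm > 0:
        n = len(m1.roi_set)
        rank_x = stats.rankdata(m1.upper())
        d2 = m2.dissimilarity
        iu, ju = np.triu_indices(n, k=1)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            y = d2[perm[iu], perm[ju]]
            r = _spearman_binary_fast(rank_x, y)
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p_perm = (1.0 + hits) / (n_perm + 1.0)
    return ModelComparison(
        rho=rho, p_parametric=p_param, p_permutation=p_perm,
        n_pairs=n_pairs, n_perm=n_perm,
    )
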