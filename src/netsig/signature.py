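"""Cognitive signatures of networks: module-averaged task activity.

Given per-subject ROI x contrast activity (betas for e.g. semantic > control,
rest > semantic, control > rest) and a network partition of the ROIs, the
signature of each network is its module-averaged activity per contrast,
presented as z-scores, with a two-tailed one-sample t-test of the
subject-level module means against zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .roi import RoiSet

__all__ = ["ContrastBetas", "NetworkSignature", "network_activity", "network_ttest",
           "DEFAULT_CONTRASTS"]

DEFAULT_CONTRASTS = ("semantic>control", "rest>semantic", "control>rest")

ZScope = Literal["study", "contrast"]


@dataclass
class ContrastBetas:
    """Subject x ROI x contrast activity values for one task-fMRI study."""

    values: np.ndarray
    roi_set: RoiSet
    contrast_names: tuple[str, ...] = DEFAULT_CONTRASTS
    study_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be subject x ROI x contrast")
        if self.values.shape[1] != len(self.roi_set):
            raise ValueError("ROI axis must match roi_set")
        if self.values.shape[2] != len(self.contrast_names):
            raise ValueError("contrast axis must match contrast_names")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.values.shape[2]


@dataclass
class NetworkSignature:
    """Module x contrast activity summary for one study and partition."""

    mean_activity: np.ndarray          # module x contrast, group mean
    z_activity: np.ndarray             # module x contrast, z-scored
    t_stats: np.ndarray                # module x contrast
    p_values: np.ndarray               # module x contrast (nan where undefined)
    subject_activity: np.ndarray       # subject x module x contrast
    contrast_names: tuple[str, ...]
    study_id: str = ""
    zscore_scope: ZScope = "study"


def _module_means(betas: ContrastBetas, module_ids: np.ndarray) -> np.ndarray:
    """Subject x module x contrast means over each module's ROIs."""
    n_modules = int(module_ids.max())
    out = np.empty((betas.n_subjects, n_modules, betas.n_contrasts))
    for m in range(1, n_modules + 1):
        mask = module_ids == m
        if not mask.any():
            raise ValueError(f"module {m} contains no ROI")
        out[:, m - 1, :] = betas.values[:, mask, :].mean(axis=1)
    return out


def network_activity(
    betas: ContrastBetas, partition, zscore_scope: ZScope = "study"
) -> NetworkSignature:
    """Module-averaged activity per contrast, z-scored, with t-tests.

    Per subject, each module's activity is the mean over its ROIs for each
    contrast; the group signature is the mean over subjects. Z-scoring is
    applied across all module x contrast cells of the study by default
    (``zscore_scope="study"``) or within each contrast column
    (``"contrast"``). The one-sample t-test operates on the subject-level
    module means (random-effects inference).
    """
    module_ids = np.asarray(partition.labels_array() if hasattr(partition, "labels_array")
                            else partition, dtype=int)
    if module_ids.shape != (len(betas.roi_set),):
        raise ValueError("partition must cover every ROI in betas")
    subject_activity = _module_means(betas, module_ids)
    mean_activity = subject_activity.mean(axis=0)

    if zscore_scope == "study":
        sd = mean_activity.std()
        if sd == 0:
            warnings.warn("constant activity across all cells: z-scores set to 0", stacklevel=2)
            z = np.zeros_like(mean_activity)
        else:
            z = (mean_activity - mean_activity.mean()) / sd
    elif zscore_scope == "contrast":
        sd = mean_activity.std(axis=0, keepdims=True)
        mu = mean_activity.mean(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (mean_activity - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        if np.any(sd == 0):
            warnings.warn("constant activity in a contrast column: z set to 0", stacklevel=2)
    else:
        raise ValueError(f"unknown zscore_scope {zscore_scope!r}")

    t, p = network_ttest(subject_activity)
    return NetworkSignature(
        mean_activity=mean_activity,
        z_activity=z,
        t_stats=t,
        p_values=p,
        subject_activity=subject_activity,
        contrast_names=betas.contrast_names,
        study_id=betas.study_id,
        zscore_scope=zscore_scope,
    )


def network_ttest(subject_activity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed one-sample t-test against zero per module x contrast cell.

    Cells with zero variance across subjects get ``t = +-inf`` (the sign of
    the mean; 0 if the mean is 0) and ``p = nan`` — a p-value is never
    fabricated for a degenerate sample.
    """
    subject_activity = np.asarray(subject_activity, dtype=float)
    if subject_activity.ndim != 3:
        raise ValueError("expected subject x module x contrast activity")
    if subject_activity.shape[0] < 2:
        raise ValueError("need at least two subjects for a t-test")
    t, p = stats.ttest_1samp(subject_activity, 0.0, axis=0)
    sd = subject_activity.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("zero-variance cells: t set to signed infinity, p undefined",
                      stacklevel=2)
        mean = subject_activity.mean(axis=0)
        t = np.where(degenerate, np.sign(mean) * np.inf, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
        p = np.where(degenerate, np.nan, p)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)
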