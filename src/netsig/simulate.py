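"""Synthetic cohorts with a planted module structure.

Every downstream stage of the pipeline is tested against data whose module
partition is known by construction. Three generators share one
:class:`PlantedDesign`:

* ``generate_structural_cohort`` — directional streamline-count matrices.
  An edge between two ROIs is present in a given subject with probability
  ``within_edge_prob`` (same planted module) or ``between_edge_prob``
  (different modules), independently per tracking direction. A present
  direction carries exactly ``streamline_scale`` hits; an absent one
  carries a Poisson(``noise_lambda``) noise floor. This bimodal
  "high-probability hit versus noise floor" structure is what the
  per-subject Poisson threshold and group-consistency criterion assume.
* ``generate_functional_cohort`` — ROI x time series built from shared
  latent module signals: ``x_i(t) = sqrt(rho) * s_m(i)(t) +
  sqrt(1 - rho) * eps_i(t)`` with unit-variance Gaussian ``s`` and
  ``eps``, the standard generative model for block-structured correlation
  matrices. Expected within-module correlation is ``rho = within_corr``;
  expected between-module correlation is 0.
* ``generate_task_betas`` — ROI x contrast activity per subject and study:
  the ROI's module profile plus Gaussian noise, so condition profiles are
  shared within modules and distinct between modules.

All generators are deterministic in ``(design, seed)``: per-subject
substreams are spawned from one master ``numpy`` SeedSequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .connectome import SubjectStructuralMatrix, SubjectTimeSeries
from .roi import RoiSet
from .signature import ContrastBetas

__all__ = ["PlantedDesign", "demo_design", "generate_structural_cohort",
           "generate_functional_cohort", "generate_task_betas"]

#: Mean of the Poisson streamline-hit noise floor on absent edges.
NOISE_LAMBDA_DEFAULT = 2.0

#: Default contrast profiles for up to six planted modules. Rows are module
#: mean activity across (semantic>control, rest>semantic, control>rest);
#: chosen mutually distinct so modules are separable in activity space.
DEFAULT_PROFILES = (
    (1.5, -1.0, 0.5),
    (-1.0, 1.5, 0.5),
    (0.5, 0.5, -1.5),
    (1.5, 0.5, -1.0),
    (-1.0, -0.5, 1.5),
    (0.5, -1.5, 1.0),
)


@dataclass(frozen=True)
class PlantedDesign:
    """Ground-truth design shared by all three synthetic generators.

    ``true_partition`` maps each ROI label to a module id; ids must be the
    contiguous integers 1..K and every ROI must appear exactly once.
    """

    roi_set: RoiSet
    true_partition: Mapping[str, int]
    n_subjects: int = 24
    seed: int = 0
    within_edge_prob: float = 0.9
    between_edge_prob: float = 0.05
    streamline_scale: int = 20_000
    noise_lambda: float = NOISE_LAMBDA_DEFAULT
    ts_length: int = 128
    within_corr: float = 0.5
    contrast_profiles: Mapping[int, Sequence[float]] | None = None
    beta_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        part = dict(self.true_partition)
        if set(part) != set(self.roi_set.labels):
            raise ValueError("true_partition must assign every ROI exactly once")
        ids = sorted(set(part.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"module ids must be contiguous from 1, got {ids}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for name in ("within_edge_prob", "between_edge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.streamline_scale < 1:
            raise ValueError("streamline_scale must be a positive integer")
        if self.noise_lambda < 0:
            raise ValueError("noise_lambda must be nonnegative")
        if not 0.0 <= self.within_corr < 1.0:
            raise ValueError("within_corr must lie in [0, 1)")
        if self.contrast_profiles is not None:
            lengths = {len(v) for v in self.contrast_profiles.values()}
            if len(lengths) > 1:
                raise ValueError("contrast profile vectors must share one length")
            if set(self.contrast_profiles) != set(ids):
                raise ValueError("contrast_profiles must cover every module id")
        if self.beta_noise_sd < 0:
            raise ValueError("beta_noise_sd must be nonnegative")

    @property
    def n_modules(self) -> int:
        return max(self.true_partition.values())

    @property
    def module_ids(self) -> np.ndarray:
        """Module id per ROI, in canonical roi_set order."""
        return np.array([self.true_partition[l] for l in self.roi_set], dtype=int)

    def profiles(self) -> dict[int, np.ndarray]:
        if self.contrast_profiles is not None:
            return {m: np.asarray(v, dtype=float) for m, v in self.contrast_profiles.items()}
        if self.n_modules > len(DEFAULT_PROFILES):
            raise ValueError(
                f"no default profiles for {self.n_modules} modules; pass contrast_profiles"
            )
        return {m: np.asarray(DEFAULT_PROFILES[m - 1], dtype=float)
                for m in range(1, self.n_modules + 1)}

    def _rng(self, stream: str, replicate: int = 0) -> np.random.Generator:
        # crc32 (not hash()) so substreams are stable across processes
        ss = np.random.SeedSequence(
            entropy=self.seed,
            spawn_key=(zlib.crc32(stream.encode()) % (2**31), replicate),
        )
        return np.random.default_rng(ss)


def demo_design(seed: int = 0, n_rois: int = 43, n_subjects: int = 24) -> PlantedDesign:
    """The default demonstration design: 5 planted modules over 43 ROIs.

    Module sizes 9, 9, 9, 8, 8 — the 5–6 module range typical of
    associative-cortex parcellations of this size — with strong modular
    structure (within-module edge probability 0.9 vs 0.05 between).
    """
    roi_set = RoiSet.default(n_rois)
    n_modules = 5
    base, extra = divmod(n_rois, n_modules)
    sizes = [base + (1 if i < extra else 0) for i in range(n_modules)]
    partition: dict[str, int] = {}
    idx = 0
    for m, size in enumerate(sizes, start=1):
        for _ in range(size):
            partition[roi_set[idx]] = m
            idx += 1
    return PlantedDesign(roi_set=roi_set, true_partition=partition,
                         n_subjects=n_subjects, seed=seed)


def generate_structural_cohort(design: PlantedDesign) -> list[SubjectStructuralMatrix]:
    """Directional streamline-count matrices with planted modules.

    Entries are integers in ``[0, streamline_scale]``; the diagonal is zero.
    """
    n = len(design.roi_set)
    modules = design.module_ids
    same_module = modules[:, None] == modules[None, :]
    p_edge = np.where(same_module, design.within_edge_prob, design.between_edge_prob)
    np.fill_diagonal(p_edge, 0.0)
    cohort = []
    for s in range(design.n_subjects):
        rng = design._rng("structural", s)
        present = rng.random((n, n)) < p_edge  # independent per direction
        noise = rng.poisson(design.noise_lambda, size=(n, n))
        values = np.where(present, design.streamline_scale, noise)
        values = np.minimum(values, design.streamline_scale)
        np.fill_diagonal(values, 0)
        cohort.append(
            SubjectStructuralMatrix(
                values=values.astype(int),
                roi_set=design.roi_set,
                subject_id=f"sub-{s + 1:02d}",
                n_streamlines=design.streamline_scale,
            )
        )
    return cohort


def generate_functional_cohort(
    design: PlantedDesign,
    motion_translation_mm: Sequence[float] | None = None,
    motion_rotation_deg: Sequence[float] | None = None,
) -> list[SubjectTimeSeries]:
    """ROI x time series whose correlations follow the planted modules.

    Optional per-subject motion scalars (defaults: zero motion) feed the
    censoring stage in tests of the functional branch.
    """
    if design.ts_length < 20:
        raise ValueError("ts_length must be at least 20")
    n = len(design.roi_set)
    modules = design.module_ids
    rho = design.within_corr
    cohort = []
    for s in range(design.n_subjects):
        rng = design._rng("functional", s)
        latent = rng.standard_normal((design.n_modules, design.ts_length))
        noise = rng.standard_normal((n, design.ts_length))
        series = np.sqrt(rho) * latent[modules - 1] + np.sqrt(1.0 - rho) * noise
        cohort.append(
            SubjectTimeSeries(
                series=series,
                roi_set=design.roi_set,
                subject_id=f"sub-{s + 1:02d}",
                motion_translation_mm=(
                    motion_translation_mm[s] if motion_translation_mm is not None else 0.0
                ),
                motion_rotation_deg=(
                    motion_rotation_deg[s] if motion_rotation_deg is not None else 0.0
                ),
            )
        )
    return cohort


def generate_task_betas(design: PlantedDesign, n_studies: int = 3) -> list[ContrastBetas]:
    """Per-study subject x ROI x contrast activity driven by module profiles."""
    if n_studies < 1:
        raise ValueError("n_studies must be positive")
    profiles = design.profiles()
    n_contrasts = len(next(iter(profiles.values())))
    modules = design.module_ids
    mean = np.stack([profiles[m] for m in modules])  # ROI x contrast
    studies = []
    for k in range(n_studies):
        rng = design._rng("betas", k)
        values = mean[None, :, :] + rng.normal(
            0.0, design.beta_noise_sd, size=(design.n_subjects, len(modules), n_contrasts)
        )
        studies.append(
            ContrastBetas(
                values=values,
                roi_set=design.roi_set,
                study_id=f"study-{k + 1}",
            )
        )
    return studies
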