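"""Synthetic multi-subject voxel-pattern cohorts.

Emulates the statistical structure the downstream analyses assume: each
condition-pair contrast carries a fixed ground-truth spatial pattern built
from orthogonal components (a negative-experience pattern, a regulation
component shared by both strategies, and acceptance-/reappraisal-specific
components), expressed per subject with multiplicative amplitude jitter and
corrupted by i.i.d. plus spatially smooth Gaussian noise.  Trial-level maps
carry a latent per-trial score driving the same pattern, which is what the
encoding-model reconstruction consumes.

Component amplitudes and noise are chosen so that within-subject pattern
expression differences have effect sizes of roughly d = 1.5-3, the range a
well-powered task-fMRI contrast exhibits.  All randomness flows from a single
seed through per-subject ``numpy`` SeedSequence substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from neurosig.volume_core import (
    BrainMask,
    ContrastImage,
    Parcellation,
    SubjectTrialData,
    ValidationError,
    VolumeGrid,
)

#: condition-pair vocabulary: contrast -> (amplitude per component)
DEFAULT_AMPLITUDES: dict[str, dict[str, float]] = {
    "NV_vs_NeutV": {"negative_experience": 8.0},
    "NA_vs_NV": {"shared_regulation": 4.0, "acceptance_specific": 6.0},
    "NR_vs_NV": {"shared_regulation": 4.0, "reappraisal_specific": 6.0},
}

COMPONENT_NAMES = (
    "negative_experience",
    "shared_regulation",
    "acceptance_specific",
    "reappraisal_specific",
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for one synthetic cohort.

    ``noise_sd`` is the i.i.d. voxel noise SD of a *contrast* (condition
    difference) image; ``smooth_noise_sd`` adds a spatially smooth component
    (Gaussian kernel of ``noise_fwhm_vox`` voxels FWHM).  ``amplitude_jitter``
    is the SD of the per-subject multiplicative Normal(1, sd^2) amplitude
    factor applied to each component.
    """

    n_subjects: int = 40
    grid: VolumeGrid = VolumeGrid((16, 16, 16))
    mask_fraction: float = 0.5
    amplitudes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AMPLITUDES.items()}
    )
    noise_sd: float = 1.0
    smooth_noise_sd: float = 0.5
    noise_fwhm_vox: float = 2.0
    amplitude_jitter: float = 0.2
    background_sd: float = 0.5
    n_trials_per_condition: int = 12
    trial_latent_sd: float = 0.3
    seed: int = 0
    #: when set, the mask/pattern geometry derives from this seed instead of
    #: ``seed``, letting two cohorts share one ground truth (clinical use)
    structure_seed: int | None = None
    experience_contrasts: tuple[str, ...] = ("NV_vs_NeutV",)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValidationError("mask_fraction must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.n_trials_per_condition < 1:
            raise ValidationError("n_trials_per_condition must be positive")
        for contrast, comps in self.amplitudes.items():
            for name, a in comps.items():
                if not np.isfinite(a):
                    raise ValidationError(f"amplitude {name}@{contrast} not finite")

    @property
    def contrasts(self) -> list[str]:
        return list(self.amplitudes)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth that produced it."""

    spec: CohortSpec
    mask: BrainMask
    #: contrast -> subject_id -> (target ContrastImage, control ContrastImage)
    condition_pairs: dict[str, dict[str, tuple[ContrastImage, ContrastImage]]]
    #: contrast -> subject_id -> SubjectTrialData (conditions "target"/"control")
    trials: dict[str, dict[str, SubjectTrialData]]
    #: component name -> unit-norm in-mask pattern vector
    components: dict[str, np.ndarray]
    #: contrast -> amplitude-weighted generating pattern (in-mask vector)
    ground_truth: dict[str, np.ndarray]

    @property
    def subject_ids(self) -> list[str]:
        first = next(iter(self.condition_pairs.values()))
        return list(first)

    def paired(self, contrast: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """subject -> (target values, control values) for one condition pair."""
        return {
            sid: (tgt.values, ctl.values)
            for sid, (tgt, ctl) in self.condition_pairs[contrast].items()
        }

    def contrast_images(self, contrast: str) -> dict[str, np.ndarray]:
        """subject -> target-minus-control difference vector."""
        return {
            sid: tgt.values - ctl.values
            for sid, (tgt, ctl) in self.condition_pairs[contrast].items()
        }


# ---------------------------------------------------------------------------
# building blocks


def _ellipsoid_mask(grid: VolumeGrid, fraction: float) -> BrainMask:
    """Centered ball capturing the requested fraction of grid voxels."""
    coords = np.indices(grid.dims, dtype=float)
    center = (np.asarray(grid.dims, dtype=float) - 1.0) / 2.0
    scale = np.asarray(grid.dims, dtype=float) / 2.0
    d2 = sum(
        ((coords[i] - center[i]) / scale[i]) ** 2 for i in range(3)
    )
    cutoff = np.quantile(d2.ravel(), fraction)
    inclusion = d2 <= cutoff
    return BrainMask(grid, inclusion)


def _smooth_field(rng: np.random.Generator, mask: BrainMask, fwhm_vox: float) -> np.ndarray:
    """Unit-SD spatially smooth Gaussian field, returned as in-mask vector."""
    vol = rng.standard_normal(mask.grid.dims)
    sigma = max(fwhm_vox, 1e-6) * _FWHM_TO_SIGMA
    smooth = gaussian_filter(vol, sigma=sigma, mode="constant")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return mask.vectorize(smooth)


def _component_patterns(
    mask: BrainMask, rng: np.random.Generator, blob_radius: float = 2.5
) -> dict[str, np.ndarray]:
    """Compact disjoint Gaussian blobs, one per component, orthogonalized.

    Blob centers are drawn far apart inside the mask so the raw patterns are
    near-disjoint; Gram-Schmidt then enforces exact orthogonality and unit
    norm, keeping "common" vs "specific" voxel classes well-defined in truth.
    """
    coords = mask.coordinates().astype(float)
    n = coords.shape[0]
    centers: list[np.ndarray] = []
    # greedy farthest-point placement from a random start
    first = coords[rng.integers(n)]
    centers.append(first)
    for _ in range(len(COMPONENT_NAMES) - 1):
        d2 = np.min(
            np.stack([np.sum((coords - c) ** 2, axis=1) for c in centers]), axis=0
        )
        centers.append(coords[int(np.argmax(d2))])
    patterns: dict[str, np.ndarray] = {}
    basis: list[np.ndarray] = []
    for name, c in zip(COMPONENT_NAMES, centers):
        d2 = np.sum((coords - c) ** 2, axis=1)
        raw = np.exp(-d2 / (2.0 * blob_radius**2))
        for b in basis:
            raw = raw - (raw @ b) * b
        norm = np.linalg.norm(raw)
        if norm <= 0:
            raise ValidationError("degenerate pattern geometry; enlarge the mask")
        raw = raw / norm
        basis.append(raw)
        patterns[name] = raw
    return patterns


# ---------------------------------------------------------------------------
# generators


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full cohort (condition-pair images + trial maps) from ``spec``.

    Deterministic given ``(spec, spec.seed)``: structure (mask, patterns) and
    each subject use dedicated SeedSequence substreams.
    """
    root = np.random.SeedSequence(spec.seed)
    structure_ss, subjects_ss = root.spawn(2)
    if spec.structure_seed is not None:
        structure_ss = np.random.SeedSequence(spec.structure_seed).spawn(2)[0]
    structure_rng = np.random.default_rng(structure_ss)

    mask = _ellipsoid_mask(spec.grid, spec.mask_fraction)
    components = _component_patterns(mask, structure_rng)

    ground_truth = {
        contrast: sum(
            a * components[name] for name, a in comps.items()
        )
        for contrast, comps in spec.amplitudes.items()
    }

    n_vox = mask.n_voxels
    # condition-image noise so that the *difference* has sd = noise_sd
    cond_iid_sd = spec.noise_sd / np.sqrt(2.0)
    cond_smooth_sd = spec.smooth_noise_sd / np.sqrt(2.0)

    condition_pairs: dict[str, dict[str, tuple[ContrastImage, ContrastImage]]] = {
        c: {} for c in spec.contrasts
    }
    trials: dict[str, dict[str, SubjectTrialData]] = {c: {} for c in spec.contrasts}

    subject_streams = subjects_ss.spawn(spec.n_subjects)
    for i, sub_ss in enumerate(subject_streams):
        sid = f"sub-{i + 1:03d}"
        rng = np.random.default_rng(sub_ss)
        for contrast, comps in spec.amplitudes.items():
            jitter = {
                name: 1.0 + spec.amplitude_jitter * rng.standard_normal()
                for name in comps
            }
            effect = np.zeros(n_vox)
            for name, a in comps.items():
                effect = effect + jitter[name] * a * components[name]

            background = spec.background_sd * _smooth_field(
                rng, mask, spec.noise_fwhm_vox
            )

            def cond_noise() -> np.ndarray:
                noise = cond_iid_sd * rng.standard_normal(n_vox)
                if cond_smooth_sd > 0:
                    noise = noise + cond_smooth_sd * _smooth_field(
                        rng, mask, spec.noise_fwhm_vox
                    )
                return noise

            target = background + 0.5 * effect + cond_noise()
            control = background - 0.5 * effect + cond_noise()
            condition_pairs[contrast][sid] = (
                ContrastImage(sid, contrast, target),
                ContrastImage(sid, contrast, control),
            )

            n_t = spec.n_trials_per_condition
            latent = np.concatenate(
                [
                    1.0 + spec.trial_latent_sd * rng.standard_normal(n_t),
                    -1.0 + spec.trial_latent_sd * rng.standard_normal(n_t),
                ]
            )
            trial_noise = spec.noise_sd * rng.standard_normal((2 * n_t, n_vox))
            if spec.smooth_noise_sd > 0:
                trial_noise = trial_noise + spec.smooth_noise_sd * np.stack(
                    [_smooth_field(rng, mask, spec.noise_fwhm_vox) for _ in range(2 * n_t)]
                )
            trial_maps = 0.5 * latent[:, None] * effect[None, :] + trial_noise
            conditions = ["target"] * n_t + ["control"] * n_t
            trials[contrast][sid] = SubjectTrialData(sid, conditions, trial_maps)

    return SyntheticCohort(
        spec=spec,
        mask=mask,
        condition_pairs=condition_pairs,
        trials=trials,
        components=components,
        ground_truth=ground_truth,
    )


def generate_clinical_cohorts(
    spec: CohortSpec, attenuation: float
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two cohorts; the second's regulation effects are scaled by ``attenuation``.

    Emulates a patient group with an emotion-regulation deficit: amplitudes of
    every non-experience contrast are multiplied by ``attenuation`` in the
    second cohort, while the experience contrast is untouched.  The cohorts
    use distinct sub-seeds of ``spec.seed``.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValidationError("attenuation must lie in [0, 1]")
    seed_a, seed_b = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31)
    spec_a = replace(spec, seed=int(seed_a), structure_seed=spec.seed)
    att_amplitudes = {
        contrast: {
            name: (a if contrast in spec.experience_contrasts else a * attenuation)
            for name, a in comps.items()
        }
        for contrast, comps in spec.amplitudes.items()
    }
    spec_b = replace(
        spec, seed=int(seed_b), structure_seed=spec.seed, amplitudes=att_amplitudes
    )
    return generate_cohort(spec_a), generate_cohort(spec_b)


def generate_parcellation(
    grid: VolumeGrid,
    n_regions: int,
    seed: int,
    mask: BrainMask | None = None,
) -> Parcellation:
    """Nearest-seed partition of the (default ellipsoid) mask into regions."""
    if mask is None:
        mask = _ellipsoid_mask(grid, 0.5)
    if n_regions < 1 or n_regions > mask.n_voxels:
        raise ValidationError(
            f"n_regions must lie in [1, {mask.n_voxels}], got {n_regions}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coords = mask.coordinates().astype(float)
    seed_idx = rng.choice(coords.shape[0], size=n_regions, replace=False)
    tree = cKDTree(coords[seed_idx])
    _, assignment = tree.query(coords)
    labels_vec = assignment.astype(np.int64) + 1
    labels = mask.unvectorize(labels_vec.astype(float)).astype(np.int64)
    table = {int(k): f"region-{k:02d}" for k in range(1, n_regions + 1)}
    return Parcellation(grid, labels, table)
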