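"""Bootstrap thresholding of decoder weights and encoding-model reconstruction.

Decoder weights are made interpretable in two steps.  First, subject-level
bootstrap resampling of the training cohort yields per-voxel z/p/q maps that
threshold the weight map.  Second, the weights are transformed into an
encoding ("activation") pattern: with a single latent score s_t = w.x_t per
trial, the transform A = cov(X) W cov(S)^-1 reduces to the per-voxel
regression slope A_j = cov(x_j, s) / var(s), computed within subject on
trial-level maps and then tested across subjects with a one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neurosig.decoding import SignatureModel, train_signature
from neurosig.volume_core import SubjectTrialData, ValidationError


@dataclass
class BootstrapResult:
    n_boot: int
    mean: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    threshold_mask: np.ndarray  # q < q_level on the trained weight support
    q_level: float
    n_redrawn: int


@dataclass
class EncodingMap:
    """Per-subject activation vectors with group-level t/p/q maps."""

    subject_maps: np.ndarray  # (n_subjects, n_voxels)
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    source_model: str


def fdr_bh(p_values: np.ndarray, q_level: float = 0.05):
    """Benjamini-Hochberg step-up: per-item q-values and the rejection set."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValidationError("empty p-value array")
    if np.any(p_values <= 0) or np.any(p_values > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p_values, alpha=q_level, method="fdr_bh")
    return q, reject


def bootstrap_weights(
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    pair: str,
    n_boot: int = 1000,
    seed: int = 0,
    regularization: float = 1.0,
    q_level: float = 0.05,
) -> BootstrapResult:
    """Subject-level bootstrap of the decoder: per-voxel z, normal p, BH q.

    Subjects are resampled with replacement ``n_boot`` times and the decoder
    retrained per resample.  z = bootstrap mean / bootstrap SE; two-tailed p
    from the normal reference, floored at 1/(n_boot+1); q by BH.  Resamples
    that collapse below two distinct subjects are redrawn (counted).
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    sids = list(paired)
    rng = np.random.default_rng(seed)
    n_vox = next(iter(paired.values()))[0].size
    weights = np.empty((n_boot, n_vox))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            draw = rng.choice(len(sids), size=len(sids), replace=True)
            if len(set(draw)) >= 2:
                break
            n_redrawn += 1
        resample = {
            f"{sids[j]}#{k}": paired[sids[j]] for k, j in enumerate(draw)
        }
        model = train_signature(resample, pair, regularization)
        weights[b] = model.weights
    mean = weights.mean(axis=0)
    se = weights.std(axis=0, ddof=1)
    p_floor = 1.0 / (n_boot + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / se, np.where(mean != 0, np.inf, 0.0))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, p_floor, 1.0)
    q, reject = fdr_bh(p, q_level)
    return BootstrapResult(
        n_boot=n_boot,
        mean=mean,
        se=se,
        z=z,
        p=p,
        q=q,
        threshold_mask=reject,
        q_level=q_level,
        n_redrawn=n_redrawn,
    )


def haufe_transform(trials: SubjectTrialData, model: SignatureModel) -> np.ndarray:
    """Within-subject encoding reconstruction from trial maps.

    Computes the latent score s_t = w.x_t per trial and returns the per-voxel
    slope A_j = cov(x_j, s)/var(s) — the single-latent specialization of
    A = cov(X) W cov(S)^-1, avoiding the voxel-by-voxel covariance matrix.
    Sample covariances use 1/(n-1) after trial-wise mean centering.
    """
    X = trials.trial_maps
    if X.shape[1] != model.weights.size:
        raise ValidationError("trial maps and model weights differ in voxel count")
    s = X @ model.weights
    s_c = s - s.mean()
    var_s = float(s_c @ s_c) / (len(s) - 1)
    if var_s <= 0:
        raise ValidationError("zero latent variance: encoding map undefined")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov_xs = (Xc.T @ s_c) / (len(s) - 1)
    return cov_xs / var_s


def group_encoding_test(
    subject_maps: np.ndarray, source_model: str = "", q_level: float = 0.05
) -> EncodingMap:
    """Voxel-wise one-sample t-test of per-subject activation maps against 0.

    Two-sided p with BH q; voxels with zero across-subject variance get
    t = 0, p = 1 (flagged by that convention rather than NaN).
    """
    subject_maps = np.asarray(subject_maps, dtype=float)
    if subject_maps.ndim != 2 or subject_maps.shape[0] < 3:
        raise ValidationError("group test needs >= 3 subject maps")
    n = subject_maps.shape[0]
    mean = subject_maps.mean(axis=0)
    sd = subject_maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = np.where(sd > 0, 2.0 * stats.t.sf(np.abs(t), df=n - 1), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q, _ = fdr_bh(p, q_level)
    return EncodingMap(subject_maps=subject_maps, t=t, p=p, q=q, source_model=source_model)


def map_similarity(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and cosine similarity of two voxel maps."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("maps must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cosine = float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        # correlation undefined; cosine is still meaningful and returned
        import warnings

        warnings.warn("correlation undefined for constant input", RuntimeWarning)
        return float("nan"), cosine
    corr = float(np.corrcoef(a, b)[0, 1])
    return corr, cosine
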