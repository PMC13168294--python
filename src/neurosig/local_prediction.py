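"""Local versus whole-brain predictive performance.

Random-voxel-sampling curves measure cross-validated accuracy as a function
of the number of voxels drawn uniformly (without replacement) from a region,
with a saturating parametric fit acc(k) = a - b exp(-k/c) whose plateau a is
the region's asymptotic performance.  Searchlight mapping trains a decoder
in a sphere (voxel-unit radius, clipped to the mask) around every in-mask
center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from neurosig.decoding import loso_cv, threshold_report
from neurosig.volume_core import BrainMask, ValidationError


@dataclass
class SamplingCurve:
    roi_name: str
    k_grid: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    n_rep: int
    seed: int
    fit_params: tuple[float, float, float] | None = None  # (a, b, c)
    fit_ok: bool = False


def _loso_accuracy(
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    pair: str,
    voxel_idx: np.ndarray | None = None,
    regularization: float = 1.0,
) -> float:
    if voxel_idx is not None:
        paired = {
            sid: (tgt[voxel_idx], ctl[voxel_idx]) for sid, (tgt, ctl) in paired.items()
        }
    cv = loso_cv(paired, pair, regularization)
    correct = sum(
        int(d_t > 0.0) + int(d_c <= 0.0) for d_t, d_c in cv.decisions.values()
    )
    return correct / (2 * len(cv.decisions))


def sampling_curve(
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    pair: str,
    roi: np.ndarray,
    k_grid,
    n_rep: int = 100,
    seed: int = 0,
    roi_name: str = "roi",
    regularization: float = 1.0,
) -> SamplingCurve:
    """Accuracy vs number of uniformly sampled roi voxels.

    ``roi`` is a boolean vector over the data's voxels.  Per repetition, k
    voxels are drawn without replacement from the roi and a fresh LOSO
    decoder is trained on them; repetitions use independent substreams.
    When k equals the roi size the draw is exhaustive, so every repetition
    reproduces the roi-restricted LOSO accuracy exactly.
    """
    roi = np.asarray(roi, dtype=bool)
    roi_idx = np.flatnonzero(roi)
    k_grid = np.asarray(sorted(set(int(k) for k in k_grid)))
    if n_rep < 2:
        raise ValidationError("n_rep must be >= 2")
    if k_grid.max() > roi_idx.size:
        raise ValidationError(
            f"max k {k_grid.max()} exceeds roi size {roi_idx.size}"
        )
    rngs = [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(n_rep)]
    means, sds = [], []
    for k in k_grid:
        accs = np.empty(n_rep)
        for r, rng in enumerate(rngs):
            idx = rng.choice(roi_idx, size=int(k), replace=False)
            accs[r] = _loso_accuracy(paired, pair, idx, regularization)
        means.append(accs.mean())
        sds.append(accs.std(ddof=1))
    return SamplingCurve(
        roi_name=roi_name,
        k_grid=k_grid,
        mean_accuracy=np.asarray(means),
        sd_accuracy=np.asarray(sds),
        n_rep=n_rep,
        seed=seed,
    )


def fit_asymptote(curve: SamplingCurve) -> SamplingCurve:
    """Least-squares saturating fit acc(k) = a - b exp(-k/c), a in [0, 1].

    On failure the raw means are kept and ``fit_ok`` stays False.
    """
    if curve.k_grid.size < 3:
        raise ValidationError("need >= 3 distinct k values to fit")
    f = lambda k, a, b, c: a - b * np.exp(-k / c)
    y = curve.mean_accuracy
    k = curve.k_grid.astype(float)
    a0 = float(y[-1])
    b0 = max(float(y[-1] - y[0]), 1e-3)
    c0 = max(float(k[len(k) // 2]), 1.0)
    try:
        popt, _ = curve_fit(
            f,
            k,
            y,
            p0=(a0, b0, c0),
            bounds=([0.0, -1.0, 1e-6], [1.0, 1.0, 1e9]),
            maxfev=20000,
        )
        curve.fit_params = tuple(float(x) for x in popt)
        curve.fit_ok = True
    except (RuntimeError, ValueError):
        curve.fit_params = None
        curve.fit_ok = False
    return curve


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets with squared norm <= radius^2 (center included)."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r * r
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def searchlight(
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    pair: str,
    mask: BrainMask,
    radius_voxels: int = 3,
    regularization: float = 1.0,
    centers: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel LOSO accuracy of decoders trained in spheres around centers.

    Spheres use Euclidean voxel distance, include the center, and are clipped
    to the mask.  ``centers`` (indices into the mask's voxel order) defaults
    to every in-mask voxel; the returned map is NaN at non-center voxels.
    """
    offsets = sphere_offsets(radius_voxels)
    coords = mask.coordinates()
    # voxel coordinate -> position in mask order
    index_vol = np.full(mask.grid.dims, -1, dtype=np.int64)
    index_vol[tuple(coords.T)] = np.arange(coords.shape[0])
    if centers is None:
        centers = np.arange(coords.shape[0])
    acc_map = np.full(mask.n_voxels, np.nan)
    dims = np.asarray(mask.grid.dims)
    for ci in centers:
        neigh = coords[ci][None, :] + offsets
        ok = np.all((neigh >= 0) & (neigh < dims[None, :]), axis=1)
        idx = index_vol[tuple(neigh[ok].T)]
        idx = idx[idx >= 0]
        acc_map[ci] = _loso_accuracy(paired, pair, idx, regularization)
    return acc_map
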