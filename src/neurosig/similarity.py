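"""Spatial-similarity interpretation of thresholded encoding maps.

Two complementary views: (i) region-level contribution analysis — cosine
similarity and occupancy of each thresholded, positive encoding map within
each parcellation region, normalized into relative contributions across
models; (ii) voxel-level octant analysis — the joint distribution of two
z-scored maps partitioned into eight 45-degree sectors separating shared,
selective, and opposing voxel weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neurosig.volume_core import BrainMask, Parcellation, ValidationError, region_mask

#: octant index by sector center: +y -> 1 (selective A+), diagonal -> 2
#: (shared +), +x -> 3 (selective R+), lower-right anti-diagonal -> 4
#: (opposite), -y -> 5 (selective A-), lower diagonal -> 6 (shared -),
#: -x -> 7 (selective R-), upper-left anti-diagonal -> 8 (opposite)
OCTANT_SEMANTICS = {
    1: "selective_acceptance_positive",
    2: "shared_positive",
    3: "selective_reappraisal_positive",
    4: "opposite_r_pos_a_neg",
    5: "selective_acceptance_negative",
    6: "shared_negative",
    7: "selective_reappraisal_negative",
    8: "opposite_r_neg_a_pos",
}

# sector centers in degrees (angle of (x=z_r, y=z_a)) per octant index
_OCTANT_BY_SECTOR = {0: 3, 45: 2, 90: 1, 135: 8, 180: 7, 225: 6, 270: 5, 315: 4}


@dataclass
class OctantSummary:
    counts: dict[int, int]
    ssd: dict[int, float]
    n_origin: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "octant": list(range(1, 9)),
                "semantics": [OCTANT_SEMANTICS[k] for k in range(1, 9)],
                "n_voxels": [self.counts[k] for k in range(1, 9)],
                "sum_squared_distance": [self.ssd[k] for k in range(1, 9)],
            }
        )


def cosine_with_region(map_values: np.ndarray, region: BrainMask | np.ndarray) -> float:
    """Cosine between a (thresholded, positive-part) map and a region indicator.

    ``region`` may be a BrainMask or a boolean vector over the same voxels as
    ``map_values``.  A zero-norm map yields 0 with a warning.
    """
    indicator = (
        region.inclusion.ravel(order="F")[region._flat_order]
        if isinstance(region, BrainMask)
        else np.asarray(region, dtype=bool)
    )
    indicator = np.asarray(indicator, dtype=float)
    map_values = np.asarray(map_values, dtype=float)
    if map_values.shape != indicator.shape:
        raise ValidationError("map and region must have equal voxel counts")
    if indicator.sum() == 0:
        raise ValidationError("region is empty")
    nm = np.linalg.norm(map_values)
    if nm == 0:
        import warnings

        warnings.warn("zero-norm map: cosine defined as 0", RuntimeWarning)
        return 0.0
    return float(map_values @ indicator / (nm * np.linalg.norm(indicator)))


def threshold_positive(values: np.ndarray, surviving: np.ndarray) -> np.ndarray:
    """Positive part of a map restricted to its surviving (q<level) voxels."""
    values = np.asarray(values, dtype=float)
    out = np.where(np.asarray(surviving, dtype=bool) & (values > 0), values, 0.0)
    return out


def contribution_table(
    maps: dict[str, np.ndarray],
    parcellation: Parcellation,
    mask: BrainMask,
) -> pd.DataFrame:
    """Per region x model: cosine, percent occupied, relative contribution.

    ``maps`` are thresholded positive in-mask vectors (zeros where a voxel
    did not survive).  occupied% = 100 * |surviving voxels in region| /
    |region|; relative contribution renormalizes occupied% across models
    within each region (summing to 1 where any model overlaps the region).
    """
    region_labels = parcellation.region_labels()
    parc_vec = mask.vectorize(parcellation.labels.astype(float)).astype(int)
    rows = []
    for label in region_labels:
        in_region = parc_vec == label
        size = int(in_region.sum())
        if size == 0:
            raise ValidationError(f"region {label} has no in-mask voxels")
        occ = {}
        for name, values in maps.items():
            values = np.asarray(values, dtype=float)
            surviving = (values != 0) & in_region
            occ[name] = 100.0 * surviving.sum() / size
            rows.append(
                {
                    "region": parcellation.label_table[label],
                    "label": label,
                    "model": name,
                    "cosine": cosine_with_region(
                        np.where(in_region, values, 0.0), in_region
                    ),
                    "occupied_pct": occ[name],
                }
            )
        total = sum(occ.values())
        for row in rows[-len(maps):]:
            row["relative_contribution"] = (
                row["occupied_pct"] / total if total > 0 else 0.0
            )
    return pd.DataFrame(rows)


def octant_analysis(z_r: np.ndarray, z_a: np.ndarray) -> OctantSummary:
    """Assign voxels of two z-scored maps to eight 45-degree sectors.

    Axes: x = reappraisal map, y = acceptance map.  Sector centers lie on the
    axes and diagonals; boundaries at 22.5 + k*45 degrees go to the
    lower-indexed adjacent octant; exact-origin voxels are excluded from the
    counts.  Returns per-octant voxel counts and sums of squared distances
    from the origin, which together conserve total squared mass.
    """
    z_r = np.asarray(z_r, dtype=float)
    z_a = np.asarray(z_a, dtype=float)
    if z_r.shape != z_a.shape:
        raise ValidationError("maps must have equal length")
    if np.ptp(z_r) == 0 or np.ptp(z_a) == 0:
        raise ValidationError("zero-variance input map")
    r2 = z_r**2 + z_a**2
    off = r2 > 0
    theta = np.degrees(np.arctan2(z_a[off], z_r[off])) % 360.0
    # nearest sector center; boundary (exact .5) resolves toward the sector
    # whose octant index is lower
    sector_f = theta / 45.0
    nearest = np.rint(sector_f).astype(int) % 8
    on_boundary = np.isclose((sector_f + 0.5) % 1.0, 0.0, atol=1e-12)
    if np.any(on_boundary):
        lower = (np.floor(sector_f[on_boundary]).astype(int)) % 8
        upper = (lower + 1) % 8
        lo_oct = np.array([_OCTANT_BY_SECTOR[45 * k] for k in lower])
        hi_oct = np.array([_OCTANT_BY_SECTOR[45 * k] for k in upper])
        pick = np.where(lo_oct < hi_oct, lower, upper)
        nearest[on_boundary] = pick
    octants = np.array([_OCTANT_BY_SECTOR[45 * k] for k in nearest])
    counts = {k: int(np.sum(octants == k)) for k in range(1, 9)}
    ssd = {k: float(r2[off][octants == k].sum()) for k in range(1, 9)}
    return OctantSummary(counts=counts, ssd=ssd, n_origin=int(np.sum(~off)))


def zscore_map(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValidationError("cannot z-score a constant map")
    return (values - values.mean()) / sd
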