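"""JZS Bayes factors for one-sample t statistics and voxel classification.

The Jeffreys-Zellner-Siow default Bayes factor compares H1 (standardized
effect delta ~ Cauchy(0, r)) against H0 (delta = 0) given a one-sample t
statistic with v = N - 1 degrees of freedom:

    B01 = (1 + t^2/v)^(-(v+1)/2)
          / int_0^inf (1 + N g r^2)^(-1/2)
                      (1 + t^2 / ((1 + N g r^2) v))^(-(v+1)/2)
                      (2 pi)^(-1/2) g^(-3/2) exp(-1/(2g)) dg

with BF10 = 1/B01.  BF10 is symmetric and strictly increasing in |t|, and is
bounded below by its value at t = 0 (about 0.14 for N = 59, r = 0.707), so a
BF10 threshold inverts to a unique two-sided p-value threshold.

Voxels are classified as strategy-specific or common by conjunctions of BF
evidence for each strategy's encoding map: "acceptance only" needs positive
activation with BF10 > bf_alt (and p below the map's own FDR bound) for
acceptance together with BF10 < bf_null for reappraisal; "common" needs
supra-threshold evidence for both; symmetrically for "reappraisal only".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from neurosig.volume_core import BrainMask, ValidationError

LABEL_NONE = 0
LABEL_ACCEPTANCE_ONLY = 1
LABEL_COMMON = 2
LABEL_REAPPRAISAL_ONLY = 3

LABEL_NAMES = {
    LABEL_NONE: "none",
    LABEL_ACCEPTANCE_ONLY: "acceptance_only",
    LABEL_COMMON: "common",
    LABEL_REAPPRAISAL_ONLY: "reappraisal_only",
}


@dataclass(frozen=True)
class BFParams:
    """Sample size, degrees of freedom, and Cauchy prior scale."""

    N: int
    r: float = 0.707

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValidationError("N must be >= 2")
        if self.r <= 0:
            raise ValidationError("prior scale r must be positive")

    @property
    def v(self) -> int:
        return self.N - 1


@dataclass
class BFMap:
    """Per-voxel t statistics with their BF10 and two-sided p values."""

    t: np.ndarray
    bf10: np.ndarray
    p: np.ndarray
    params: BFParams


@dataclass
class StrategyLabelMap:
    labels: np.ndarray  # integer codes per voxel (LABEL_* constants)

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == code))
            for code, name in LABEL_NAMES.items()
        }


def _b01_denominator(t: float, params: BFParams) -> float:
    """The improper prior integral over g, via the compactifying map
    g = u/(1-u) so the heavy tail is integrated on (0, 1)."""
    N, v, r2 = params.N, params.v, params.r**2
    t2 = t * t

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        jac = 1.0 / (1.0 - u) ** 2
        a = 1.0 + N * g * r2
        # log-space for the t-dependent power to avoid underflow at large |t|
        log_term = -0.5 * np.log(a) - (v + 1) / 2.0 * np.log1p(t2 / (a * v))
        log_prior = -0.5 * np.log(2.0 * np.pi) - 1.5 * np.log(g) - 1.0 / (2.0 * g)
        return float(np.exp(log_term + log_prior)) * jac

    val, err = integrate.quad(
        integrand, 0.0, 1.0, epsabs=0.0, epsrel=1e-10, limit=500
    )
    if not np.isfinite(val) or val <= 0 or (err > 0 and err / val > 1e-8):
        raise ArithmeticError(
            f"JZS integral failed to converge: value={val}, abs err={err}"
        )
    return val


def jzs_bf10(t: float, params: BFParams) -> float:
    """BF10 = 1/B01 for a one-sample t statistic; symmetric in t <-> -t."""
    if not np.isfinite(t):
        raise ValidationError("t must be finite")
    v = params.v
    log_num = -(v + 1) / 2.0 * np.log1p(t * t / v)
    den = _b01_denominator(float(t), params)
    b01 = float(np.exp(log_num)) / den
    return 1.0 / b01


def jzs_bf10_vector(t: np.ndarray, params: BFParams) -> np.ndarray:
    return np.array([jzs_bf10(float(ti), params) for ti in np.asarray(t, float)])


def min_bf10(params: BFParams) -> float:
    """Lower bound of BF10, attained at t = 0 (BF10 increases in |t|)."""
    return jzs_bf10(0.0, params)


def bf_to_p_threshold(bf_target: float, params: BFParams) -> float:
    """Two-sided p at which BF10 equals ``bf_target`` (monotone inversion).

    Root-finds t* >= 0 with BF10(t*) = bf_target and converts it to the
    two-sided tail of the t distribution with v degrees of freedom.
    """
    floor = min_bf10(params)
    if bf_target <= floor:
        raise ValidationError(
            f"BF10 target {bf_target} not attainable (minimum {floor:.4g})"
        )
    f = lambda t: jzs_bf10(t, params) - bf_target
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ArithmeticError("failed to bracket the BF10 target")
    t_star = optimize.brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12)
    return float(2.0 * stats.t.sf(t_star, df=params.v))


def bf_map_from_t(t: np.ndarray, params: BFParams) -> BFMap:
    t = np.asarray(t, dtype=float)
    p = 2.0 * stats.t.sf(np.abs(t), df=params.v)
    return BFMap(t=t, bf10=jzs_bf10_vector(t, params), p=p, params=params)


def classify_strategy_voxels(
    acc: BFMap,
    reapp: BFMap,
    bf_alt: float = 5.0,
    bf_null: float = 0.2,
    p_acc: float = 0.05,
    p_reapp: float = 0.05,
    sign_acc: np.ndarray | None = None,
    sign_reapp: np.ndarray | None = None,
) -> StrategyLabelMap:
    """Classify voxels as acceptance-only / reappraisal-only / common / none.

    The evidence bounds ``p_acc``/``p_reapp`` are each map's own FDR-derived
    p thresholds (data-dependent inputs, not constants).  "Positive
    activation" requires the voxel's encoding sign (default: sign of the
    map's own t) to be positive for the implicated strategy.
    """
    if acc.t.shape != reapp.t.shape:
        raise ValidationError("acceptance and reappraisal maps are misaligned")
    if not (bf_alt > 1.0 > bf_null > 0.0):
        raise ValidationError("need bf_alt > 1 > bf_null > 0")
    pos_a = (acc.t if sign_acc is None else np.asarray(sign_acc)) > 0
    pos_r = (reapp.t if sign_reapp is None else np.asarray(sign_reapp)) > 0

    evid_a = pos_a & (acc.bf10 > bf_alt) & (acc.p < p_acc)
    evid_r = pos_r & (reapp.bf10 > bf_alt) & (reapp.p < p_reapp)
    null_a = acc.bf10 < bf_null
    null_r = reapp.bf10 < bf_null

    labels = np.full(acc.t.shape, LABEL_NONE, dtype=np.int64)
    labels[evid_a & null_r] = LABEL_ACCEPTANCE_ONLY
    labels[evid_r & null_a] = LABEL_REAPPRAISAL_ONLY
    labels[evid_a & evid_r] = LABEL_COMMON
    return StrategyLabelMap(labels)


def conjunction(mask_a: BrainMask, mask_b: BrainMask) -> BrainMask:
    """Voxel-wise AND of two aligned masks."""
    return mask_a & mask_b
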