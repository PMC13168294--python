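"""Applying trained signatures to two cohorts and testing group differences.

Per subject the unit of comparison is the pattern-expression delta
(expression of the regulation image minus the experience image).  Group
differences are tested by permutation: subjects are reassigned to groups of
the original sizes, pooled deltas are z-normalized, and the difference of
group means recomputed per permutation; two-sided p by absolute value with
add-one smoothing.  A forced-choice-accuracy-difference statistic is
available as a variant, mirroring the alternative framing of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neurosig.decoding import ClassificationReport, SignatureModel, forced_choice
from neurosig.volume_core import ValidationError


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int
    statistic: str
    null_distribution: np.ndarray | None = None


def expression_delta(
    model: SignatureModel,
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    mask_fingerprint: str | None = None,
) -> np.ndarray:
    """Per-subject expression(target) - expression(control); intercept-free."""
    model._check_mask(mask_fingerprint)
    return np.array(
        [model.expression(t) - model.expression(c) for t, c in paired.values()]
    )


def group_forced_choice(
    model: SignatureModel,
    paired: dict[str, tuple[np.ndarray, np.ndarray]],
    **kwargs,
) -> ClassificationReport:
    """Forced-choice report for one group (delegates to decoding)."""
    return forced_choice(model, paired, **kwargs)


def _mean_diff_stat(z: np.ndarray, is_a: np.ndarray) -> float:
    return float(z[is_a].mean() - z[~is_a].mean())


def _fc_acc_diff_stat(z: np.ndarray, is_a: np.ndarray) -> float:
    return float((z[is_a] > 0).mean() - (z[~is_a] > 0).mean())


def permutation_group_test(
    deltas_a: np.ndarray,
    deltas_b: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    statistic: str = "mean_diff",
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation test for a group difference in pattern-expression deltas.

    ``statistic``: "mean_diff" (difference of group means of pooled
    z-normalized deltas; primary) or "fc_acc_diff" (difference of the groups'
    forced-choice accuracies, i.e. fractions of positive deltas).  The null
    reassigns subjects to groups of the original sizes; p = (1 + #{|null| >=
    |observed|}) / (n_perm + 1).
    """
    deltas_a = np.asarray(deltas_a, dtype=float)
    deltas_b = np.asarray(deltas_b, dtype=float)
    if deltas_a.size < 2 or deltas_b.size < 2:
        raise ValidationError("both groups need >= 2 subjects")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p-value", RuntimeWarning)
    pooled = np.concatenate([deltas_a, deltas_b])
    if np.ptp(pooled) == 0:
        raise ValidationError("all deltas identical: test degenerate")
    z = (pooled - pooled.mean()) / pooled.std(ddof=1)
    n_a = deltas_a.size
    n = pooled.size
    stat_fn = {"mean_diff": _mean_diff_stat, "fc_acc_diff": _fc_acc_diff_stat}[
        statistic
    ]
    is_a = np.zeros(n, dtype=bool)
    is_a[:n_a] = True
    observed = stat_fn(z, is_a)
    rng = np.random.default_rng(seed)
    # vectorized null: each row of perm_idx is a permutation of subjects
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = stat_fn(z[perm], is_a)
    p = (1.0 + np.sum(np.abs(null) >= np.abs(observed))) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        statistic=statistic,
        null_distribution=null if keep_null else None,
    )


def cohens_d(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both groups need >= 2 values")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise ValidationError("zero pooled SD: d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
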