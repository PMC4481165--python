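"""Paired percentile-bootstrap comparison of association estimates.

To ask whether two compendia estimate the same underlying association for
a gene pair, resample each compendium's samples with replacement, compute
the metric on the z-th resample of each (z = 1..reps), form the replicate
differences ``d_z = r_k,z - r_l,z``, and take the 2.5/97.5 percentiles of
d as a 95% CI on the difference. When both compendia estimate the same
parameter, about 5% of such intervals exclude zero; a much larger
exclusion rate indicates the compendia disagree beyond sampling noise.

One resampling plan is drawn per compendium and shared across all pairs of
a call: this preserves each pair's marginal bootstrap distribution while
keeping all-pairs runs cheap and exactly reproducible under one seed.

Replicates on which either resampled vector is constant leave the metric
undefined; they are dropped (never redrawn, which would distort the
resampling distribution) and counted in ``n_valid_reps``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .assoc import METRICS, mutual_information
from .errors import ConstantInputError, DegeneratePairError, ValidationError
from .io import ExpressionCompendium, FlagPolicy, canonical_pairs

__all__ = [
    "BootstrapComparison",
    "bootstrap_resample_plan",
    "diff_ci",
    "diff_ci_pairs",
    "exclusion_rate",
    "naive_vs_uninformative",
]


@dataclass(frozen=True)
class BootstrapComparison:
    """Percentile-bootstrap CI on one pair's between-compendium difference."""

    gene_a: str
    gene_b: str
    compendium_k: str
    compendium_l: str
    metric: str
    r_k: float
    r_l: float
    ci_low: float
    ci_high: float
    excludes_zero: bool
    n_valid_reps: int


def bootstrap_resample_plan(n_samples: int, reps: int, seed: int) -> np.ndarray:
    """Matrix of resample indices, shape (reps, n_samples), uniform with replacement."""
    if n_samples < 3:
        raise ValidationError("bootstrap needs at least 3 samples")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_samples, size=(reps, n_samples))


def _rowwise_pearson(x_rows: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with the same row of y.

    Rows where either vector is constant yield NaN.
    """
    xc = x_rows - x_rows.mean(axis=1, keepdims=True)
    yc = y_rows - y_rows.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _replicate_metric(
    x: np.ndarray, y: np.ndarray, plan: np.ndarray, metric: str, n_bins: int = 10
) -> np.ndarray:
    """Metric value on every resample of (x, y) prescribed by ``plan``."""
    xr = x[plan]
    yr = y[plan]
    if metric == "pearson":
        return _rowwise_pearson(xr, yr)
    if metric == "spearman":
        const = (np.ptp(xr, axis=1) == 0) | (np.ptp(yr, axis=1) == 0)
        r = _rowwise_pearson(
            stats.rankdata(xr, axis=1).astype(float),
            stats.rankdata(yr, axis=1).astype(float),
        )
        r[const] = np.nan
        return r
    # mutual information: no useful vectorization across replicates
    return np.array(
        [mutual_information(xr[z], yr[z], n_bins=n_bins) for z in range(plan.shape[0])]
    )


def _point_estimate(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    try:
        return float(METRICS[metric](x, y))
    except ConstantInputError:
        return float("nan")


def diff_ci_pairs(
    comp_k: ExpressionCompendium,
    comp_l: ExpressionCompendium,
    pairs: Iterable[tuple[str, str]],
    metric: str = "pearson",
    policy: FlagPolicy | None = None,
    seed: int = 0,
) -> list[BootstrapComparison]:
    """Bootstrap difference CIs for many pairs, sharing one plan per compendium."""
    policy = policy or FlagPolicy()
    if metric == "mi":
        metric = "mutual_information"
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    pair_list = canonical_pairs(pairs)
    reps = policy.bootstrap_reps
    alpha = 1.0 - policy.ci_level

    seed_k, seed_l = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(int(seed)).spawn(2)
    )
    plan_k = bootstrap_resample_plan(comp_k.n_samples, reps, seed_k)
    plan_l = bootstrap_resample_plan(comp_l.n_samples, reps, seed_l)

    out = []
    for a, b in pair_list:
        xk, yk = comp_k.row(a), comp_k.row(b)
        xl, yl = comp_l.row(a), comp_l.row(b)
        d = _replicate_metric(xk, yk, plan_k, metric) - _replicate_metric(
            xl, yl, plan_l, metric
        )
        valid = d[np.isfinite(d)]
        if valid.size < 0.5 * reps:
            raise DegeneratePairError(
                f"pair ({a}, {b}): only {valid.size}/{reps} valid bootstrap "
                "replicates (near-constant gene?)"
            )
        ci_low, ci_high = np.percentile(
            valid, [100 * alpha / 2, 100 * (1 - alpha / 2)]
        )
        out.append(
            BootstrapComparison(
                gene_a=a,
                gene_b=b,
                compendium_k=comp_k.name,
                compendium_l=comp_l.name,
                metric=metric,
                r_k=_point_estimate(xk, yk, metric),
                r_l=_point_estimate(xl, yl, metric),
                ci_low=float(ci_low),
                ci_high=float(ci_high),
                excludes_zero=bool(ci_low > 0 or ci_high < 0),
                n_valid_reps=int(valid.size),
            )
        )
    return out


def diff_ci(
    comp_k: ExpressionCompendium,
    comp_l: ExpressionCompendium,
    pair: tuple[str, str],
    metric: str = "pearson",
    policy: FlagPolicy | None = None,
    seed: int = 0,
) -> BootstrapComparison:
    """Bootstrap CI on the between-compendium association difference of one pair."""
    return diff_ci_pairs(comp_k, comp_l, [pair], metric, policy, seed)[0]


def exclusion_rate(comparisons: Sequence[BootstrapComparison]) -> float:
    """Fraction of comparisons whose CI excludes zero."""
    if not comparisons:
        raise ValidationError("empty comparison list")
    return float(np.mean([c.excludes_zero for c in comparisons]))


def naive_vs_uninformative(
    comp_k: ExpressionCompendium,
    comp_l: ExpressionCompendium,
    pairs: Iterable[tuple[str, str]],
    metric: str = "pearson",
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """How often a random other pair predicts r_k better than the same pair.

    The *naive* prediction of a pair's association in compendium k is the
    same pair's value in compendium l; the *uninformative* prediction is a
    randomly chosen different pair's value in l. Each of ``n_draws`` draws
    samples an evaluated pair (i, j) and a distinct random pair (y, z) and
    scores a win for the uninformative approach iff
    ``|r_k[i,j] - r_l[y,z]| < |r_k[i,j] - r_l[i,j]|`` (ties count for the
    naive approach). Returns the uninformative win fraction; near 0 means
    compendia agree, near or above 0.5 means the same pair's value in the
    other compendium carries almost no information.
    """
    if metric == "mi":
        metric = "mutual_information"
    pair_list = canonical_pairs(pairs)
    if len(pair_list) < 2:
        raise ValidationError("need at least 2 pairs so a distinct (y,z) exists")
    r_k = np.array(
        [_point_estimate(comp_k.row(a), comp_k.row(b), metric) for a, b in pair_list]
    )
    r_l = np.array(
        [_point_estimate(comp_l.row(a), comp_l.row(b), metric) for a, b in pair_list]
    )
    usable = np.isfinite(r_k) & np.isfinite(r_l)
    if usable.sum() < 2:
        raise DegeneratePairError("fewer than 2 pairs with defined correlations")

    rng = np.random.default_rng(seed)
    idx_usable = np.flatnonzero(usable)
    wins = 0
    total = 0
    for _ in range(n_draws):
        i = rng.choice(idx_usable)
        j = rng.choice(idx_usable)
        while j == i:
            j = rng.choice(idx_usable)
        total += 1
        if abs(r_k[i] - r_l[j]) < abs(r_k[i] - r_l[i]):
            wins += 1
    return wins / total
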