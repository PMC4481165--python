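"""Pairwise association metrics and per-gene dispersion.

Three symmetric association measures are supported: Pearson correlation,
Spearman rank correlation (midranks for ties), and mutual information
estimated by the plug-in (maximum-likelihood) method on equal-width bins.
Correlations on a constant vector are undefined and raise
:class:`~corrflag.errors.ConstantInputError`; all-pairs scans convert that
into an NA result with reason code ``constant_gene`` so degenerate genes
are visible rather than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ConstantInputError, ValidationError
from .io import ExpressionCompendium, canonical_pairs

__all__ = [
    "AssociationResult",
    "pearson",
    "spearman",
    "mutual_information",
    "gene_sd",
    "all_pairs_association",
    "METRICS",
]


def _check_xy(x, y, min_len: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors")
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_len:
        raise ValidationError(f"need at least {min_len} observations, got {x.size}")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Pearson correlation undefined for a constant vector")
    r = stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation: Pearson applied to midranks (average ranks on ties)."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman correlation undefined for a constant vector")
    r = stats.spearmanr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def mutual_information(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int = 10,
    base: float = 2.0,
) -> float:
    """Plug-in mutual information on an equal-width binned joint histogram.

    Each vector is discretized into ``n_bins`` equal-width bins spanning its
    own observed range (a constant vector puts all mass in one bin, hence
    zero entropy and zero MI). The empirical joint distribution's MI is
    returned in ``log base`` units (bits by default); it is never negative.
    """
    x, y = _check_xy(x, y)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    counts, _, _ = np.histogram2d(x, y, bins=n_bins)
    p_xy = counts / counts.sum()
    p_x = p_xy.sum(axis=1, keepdims=True)
    p_y = p_xy.sum(axis=0, keepdims=True)
    mask = p_xy > 0
    mi = float(np.sum(p_xy[mask] * np.log(p_xy[mask] / (p_x @ p_y)[mask])))
    return max(mi / np.log(base), 0.0)


METRICS = {
    "pearson": pearson,
    "spearman": spearman,
    "mutual_information": mutual_information,
    "mi": mutual_information,
}


def gene_sd(comp: ExpressionCompendium, gene_id: str) -> float:
    """Sample standard deviation (n-1 denominator) of a gene's expression row."""
    row = comp.row(gene_id)
    if row.size < 2:
        raise ValidationError("standard deviation needs at least 2 samples")
    return float(np.std(row, ddof=1))


@dataclass(frozen=True)
class AssociationResult:
    """One pair's association value in one compendium.

    ``value`` is NaN (with ``reason='constant_gene'``) when either gene is
    constant, where correlation is undefined.
    """

    gene_a: str
    gene_b: str
    metric: str
    value: float
    n_samples: int
    compendium_id: str
    reason: str | None = None


def all_pairs_association(
    comp: ExpressionCompendium,
    metric: str = "pearson",
    pairs: Iterable[tuple[str, str]] | None = None,
    n_bins: int = 10,
) -> list[AssociationResult]:
    """Association of every requested pair (default: all C(G,2) pairs).

    Pairs are canonicalized and de-duplicated. Pairs involving a constant
    gene get an NA value with reason ``constant_gene``.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    fn = METRICS[metric]
    metric_name = "mutual_information" if metric == "mi" else metric
    if pairs is None:
        pair_list = canonical_pairs(combinations(comp.gene_ids, 2))
    else:
        pair_list = canonical_pairs(pairs)

    rows = {g: comp.row(g) for g in {g for p in pair_list for g in p}}
    out = []
    for a, b in pair_list:
        try:
            if metric_name == "mutual_information":
                value, reason = fn(rows[a], rows[b], n_bins=n_bins), None
            else:
                value, reason = fn(rows[a], rows[b]), None
        except ConstantInputError:
            value, reason = float("nan"), "constant_gene"
        out.append(
            AssociationResult(
                gene_a=a,
                gene_b=b,
                metric=metric_name,
                value=value,
                n_samples=comp.n_samples,
                compendium_id=comp.name,
                reason=reason,
            )
        )
    return out
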