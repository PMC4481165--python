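"""Calibration of flagging cutoffs against gold-standard pairs, and
partial-compendium construction.

Calibration semantics: within a set of gold-positive pairs (e.g. likely
operons, which *should* correlate), a pair whose observed correlation falls
below a meaningful-correlation threshold (default 0.6) is presumed biased
and ought to be flagged. Sensitivity is the fraction of those low-
correlation pairs a cutoff flags; specificity is the fraction of high-
correlation pairs it leaves unflagged. Sweeping cutoffs and maximizing
sensitivity + specificity is how the 0.5-SD and 10%-state rules of thumb
are chosen.

Boundary conventions: "below the correlation threshold" is strict ``<``;
a statistic triggers the flag when strictly ``<`` its cutoff.

Partial compendia emulate independently assembled repositories: whole
series (never split) are randomly ordered and greedily merged until each
partition reaches a minimum sample count (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionCompendium, subset_samples

__all__ = [
    "ConfusionRates",
    "CalibrationTable",
    "sensitivity_specificity",
    "calibration_sweep",
    "binned_mean_correlation",
    "partition_compendium",
    "DEFAULT_STATE_BIN_EDGES",
]

DEFAULT_STATE_BIN_EDGES: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass(frozen=True)
class ConfusionRates:
    """Sensitivity/specificity of one cutoff with its confusion counts."""

    cutoff: float
    flagged_low: int
    total_low: int
    unflagged_high: int
    total_high: int

    @property
    def sensitivity(self) -> float:
        """Fraction of low-correlation pairs flagged; NaN if none exist."""
        return self.flagged_low / self.total_low if self.total_low else float("nan")

    @property
    def specificity(self) -> float:
        """Fraction of high-correlation pairs left unflagged; NaN if none exist."""
        return (
            self.unflagged_high / self.total_high if self.total_high else float("nan")
        )

    @property
    def youden_sum(self) -> float:
        return self.sensitivity + self.specificity


def sensitivity_specificity(
    correlations: Sequence[float],
    flag_stat: Sequence[float],
    cutoff: float,
    corr_threshold: float = 0.6,
) -> ConfusionRates:
    """Confusion counts of the rule "flag when ``flag_stat < cutoff``".

    ``correlations`` and ``flag_stat`` are aligned per-pair arrays; the
    caller restricts them to the gold-positive class. ``flag_stat`` is
    typically the pair's minimum SD or its pair-level minimum state
    percent. Pairs with correlation strictly below ``corr_threshold`` form
    the "should flag" class.
    """
    corr = np.asarray(correlations, dtype=float)
    stat = np.asarray(flag_stat, dtype=float)
    if corr.shape != stat.shape:
        raise ValidationError("correlations and flag_stat must align")
    keep = np.isfinite(corr) & np.isfinite(stat)
    corr, stat = corr[keep], stat[keep]
    low = corr < corr_threshold
    flagged = stat < cutoff
    return ConfusionRates(
        cutoff=float(cutoff),
        flagged_low=int((flagged & low).sum()),
        total_low=int(low.sum()),
        unflagged_high=int((~flagged & ~low).sum()),
        total_high=int((~low).sum()),
    )


@dataclass
class CalibrationTable:
    """Sensitivity/specificity across a sweep of cutoffs."""

    rows: list[ConfusionRates]

    @classmethod
    def from_counts(
        cls,
        cutoffs: Sequence[float],
        flagged_low: Sequence[int],
        total_low: Sequence[int],
        unflagged_high: Sequence[int],
        total_high: Sequence[int],
    ) -> "CalibrationTable":
        """Build a table directly from published/known confusion counts."""
        return cls(
            rows=[
                ConfusionRates(float(c), int(fl), int(tl), int(uh), int(th))
                for c, fl, tl, uh, th in zip(
                    cutoffs, flagged_low, total_low, unflagged_high, total_high
                )
            ]
        )

    @property
    def cutoffs(self) -> list[float]:
        return [r.cutoff for r in self.rows]

    @property
    def sums(self) -> list[float]:
        return [r.youden_sum for r in self.rows]

    @property
    def best_cutoff(self) -> float:
        """Cutoff maximizing sensitivity + specificity (ties: smallest cutoff)."""
        finite = [r for r in self.rows if np.isfinite(r.youden_sum)]
        if not finite:
            raise ValidationError("no cutoff has defined sensitivity and specificity")
        best = max(r.youden_sum for r in finite)
        return min(r.cutoff for r in finite if r.youden_sum == best)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": [r.sensitivity for r in self.rows],
                "specificity": [r.specificity for r in self.rows],
                "sens_plus_spec": self.sums,
                "flagged_low": [r.flagged_low for r in self.rows],
                "total_low": [r.total_low for r in self.rows],
                "unflagged_high": [r.unflagged_high for r in self.rows],
                "total_high": [r.total_high for r in self.rows],
            }
        )


def calibration_sweep(
    correlations: Sequence[float],
    flag_stat: Sequence[float],
    cutoffs: Sequence[float],
    corr_threshold: float = 0.6,
) -> CalibrationTable:
    """Sensitivity/specificity of "flag when stat < cutoff" at each cutoff."""
    if len(cutoffs) < 1:
        raise ValidationError("need at least one cutoff")
    return CalibrationTable(
        rows=[
            sensitivity_specificity(correlations, flag_stat, c, corr_threshold)
            for c in cutoffs
        ]
    )


def binned_mean_correlation(
    labels: Sequence[str],
    pair_min_state_pct: Sequence[float],
    correlations: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_STATE_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean correlation per (label, state-percent bin), with pair counts.

    Bins are half-open ``[lo, hi)`` except the last, which is closed at
    0.5 (a minority state can occupy at most half the samples). Pairs with
    undefined state percent (either gene not two-state) are excluded.
    Returns ``(means, counts)`` DataFrames indexed by label.
    """
    labels = np.asarray(labels, dtype=object)
    pct = np.asarray(pair_min_state_pct, dtype=float)
    corr = np.asarray(correlations, dtype=float)
    if not (labels.shape == pct.shape == corr.shape):
        raise ValidationError("labels, state percents and correlations must align")
    edges = np.asarray(bin_edges, dtype=float)
    keep = np.isfinite(pct) & np.isfinite(corr)
    labels, pct, corr = labels[keep], pct[keep], corr[keep]

    bin_idx = np.digitize(pct, edges[1:-1], right=False)
    bin_idx[pct == edges[-1]] = len(edges) - 2  # closed top of last bin
    bin_names = [
        f"[{lo:g},{hi:g})" if i < len(edges) - 2 else f"[{lo:g},{hi:g}]"
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
    ]

    label_order = list(dict.fromkeys(labels))
    means = pd.DataFrame(np.nan, index=label_order, columns=bin_names)
    counts = pd.DataFrame(0, index=label_order, columns=bin_names, dtype=int)
    for lab in label_order:
        sel = labels == lab
        for i, name in enumerate(bin_names):
            cell = corr[sel & (bin_idx == i)]
            counts.loc[lab, name] = cell.size
            if cell.size:
                means.loc[lab, name] = cell.mean()
    return means, counts


def partition_compendium(
    comp: ExpressionCompendium,
    min_size: int = 50,
    seed: int = 0,
) -> list[ExpressionCompendium]:
    """Split a compendium into partial compendia of whole series.

    Series are shuffled (seeded) then greedily accumulated; a partition
    closes once it holds at least ``min_size`` samples. A trailing
    remainder smaller than ``min_size`` is merged into the last closed
    partition. Partitions are named A, B, C, ... by decreasing sample
    count. Every sample lands in exactly one partition and no series is
    ever split.
    """
    series = comp.series_labels
    if len(series) < 2:
        raise ValidationError("partitioning needs at least 2 series")
    if comp.n_samples < min_size:
        raise ValidationError(
            f"total samples ({comp.n_samples}) below min_size ({min_size})"
        )
    rng = np.random.default_rng(seed)
    order = [series[i] for i in rng.permutation(len(series))]

    groups: list[list[str]] = []
    current: list[str] = []
    count = 0
    for s in order:
        members = comp.samples_of_series(s)
        current.extend(members)
        count += len(members)
        if count >= min_size:
            groups.append(current)
            current, count = [], 0
    if current:
        if groups:
            groups[-1].extend(current)  # remainder merged, never dropped
        else:
            groups.append(current)

    groups.sort(key=len, reverse=True)
    letters = [chr(ord("A") + i) for i in range(len(groups))]
    return [
        subset_samples(comp, sorted(g, key=comp.sample_ids.index), name=letter)
        for g, letter in zip(groups, letters)
    ]
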