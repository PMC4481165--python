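"""Data model and TSV input/output for expression compendia.

A *compendium* is a genes-by-samples matrix of log2, RMA-normalized
expression values together with a sample -> series mapping ("series" in the
sense of a GEO Series: a batch of related samples deposited together).
Everything downstream — association metrics, on/off state calling, bias
flagging, bootstrap comparisons — consumes this container.

File conventions (all TSV; gene annotations commonly contain commas, so CSV
is deliberately not used):

* expression matrix: header ``gene_id<TAB>sample1<TAB>...``, one row per gene;
* series metadata: headers ``sample_id``, ``series``;
* pair labels: headers ``gene_a``, ``gene_b``, ``label`` with label in
  {likely_operon, likely_non_operon, same_pathway};
* flag report: see :func:`write_flag_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionCompendium",
    "GenePairLabels",
    "FlagPolicy",
    "PAIR_LABELS",
    "canonical_pair",
    "canonical_pairs",
    "read_compendium",
    "write_compendium",
    "subset_samples",
    "read_pair_labels",
    "write_pair_labels",
    "write_flag_report",
    "read_flag_report",
]

#: Recognised gold-standard pair label classes.
PAIR_LABELS = ("likely_operon", "likely_non_operon", "same_pathway")

#: Series label assigned to samples absent from the metadata table.
DEFAULT_SERIES = "S0"


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the pair ordered lexicographically; reject self-pairs.

    Association metrics are symmetric, so (a, b) and (b, a) denote the same
    pair; canonicalization guarantees each pair has a single spelling.
    """
    if gene_a == gene_b:
        raise ValidationError(f"self-pair not allowed: {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def canonical_pairs(pairs: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Canonicalize and de-duplicate a pair list, preserving first-seen order."""
    seen: dict[tuple[str, str], None] = {}
    for a, b in pairs:
        seen.setdefault(canonical_pair(a, b), None)
    return list(seen)


@dataclass
class ExpressionCompendium:
    """Genes-by-samples matrix of log2 expression with series labels.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, duplicate-free identifiers for rows and columns.
    values
        ``(len(gene_ids), len(sample_ids))`` float array; finite, no missing.
    series_of_sample
        Mapping of every sample id to its series label.
    name
        Label used to identify this compendium in reports ("full", "A", ...).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    series_of_sample: dict[str, str] = field(default_factory=dict)
    name: str = "full"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValidationError(f"duplicate {kind} id: {dupes[0]!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        unknown = set(self.series_of_sample) - set(self.sample_ids)
        if unknown:
            raise ValidationError(
                f"series metadata references unknown sample: {sorted(unknown)[0]!r}"
            )
        # every sample gets exactly one series label; absentees fall into S0
        self.series_of_sample = {
            s: self.series_of_sample.get(s, DEFAULT_SERIES) for s in self.sample_ids
        }

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def series_labels(self) -> list[str]:
        """Distinct series labels in first-appearance order."""
        out: dict[str, None] = {}
        for s in self.sample_ids:
            out.setdefault(self.series_of_sample[s], None)
        return list(out)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise ValidationError(f"unknown gene id: {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        return self.values[self.gene_index(gene_id)]

    def samples_of_series(self, series: str) -> list[str]:
        return [s for s in self.sample_ids if self.series_of_sample[s] == series]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )


def subset_samples(
    comp: ExpressionCompendium, sample_ids: Sequence[str], name: str | None = None
) -> ExpressionCompendium:
    """Column-subset a compendium, preserving gene order and series labels."""
    pos = {s: i for i, s in enumerate(comp.sample_ids)}
    missing = [s for s in sample_ids if s not in pos]
    if missing:
        raise ValidationError(f"unknown sample id: {missing[0]!r}")
    idx = [pos[s] for s in sample_ids]
    return ExpressionCompendium(
        gene_ids=comp.gene_ids,
        sample_ids=list(sample_ids),
        values=comp.values[:, idx],
        series_of_sample={s: comp.series_of_sample[s] for s in sample_ids},
        name=name if name is not None else comp.name,
    )


def read_compendium(
    matrix_path: str | Path,
    series_path: str | Path | None = None,
    *,
    transpose: bool = False,
    name: str | None = None,
) -> ExpressionCompendium:
    """Read an expression matrix TSV (and optional series metadata TSV).

    The matrix file has a header row (first field ``gene_id``, remaining
    fields sample ids) and one row per gene. ``transpose=True`` accepts the
    samples-in-rows orientation instead.
    """
    matrix_path = Path(matrix_path)
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dupes = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate sample id in header: {dupes[0]!r}")

    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id: {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        bad |= df[col].isna()
        if bad.any():
            row_label = df.index[bad.to_numpy()][0]
            raise ParseError(
                f"non-numeric or missing value at row {row_label!r}, "
                f"column {col!r} of {matrix_path}"
            )
        values[:, j] = converted.to_numpy()
    gene_ids = list(df.index.astype(str))
    if transpose:
        gene_ids, sample_ids = sample_ids, gene_ids
        values = values.T

    series: dict[str, str] = {}
    if series_path is not None:
        meta = pd.read_csv(series_path, sep="\t", dtype=str)
        if not {"sample_id", "series"}.issubset(meta.columns):
            raise ParseError(
                f"series file {series_path} must have headers sample_id, series"
            )
        unknown = set(meta["sample_id"]) - set(sample_ids)
        if unknown:
            raise ValidationError(
                f"series metadata references unknown sample: {sorted(unknown)[0]!r}"
            )
        series = dict(zip(meta["sample_id"], meta["series"]))

    return ExpressionCompendium(
        gene_ids=gene_ids,
        sample_ids=list(sample_ids),
        values=values,
        series_of_sample=series,
        name=name if name is not None else matrix_path.stem,
    )


def write_compendium(
    comp: ExpressionCompendium,
    matrix_path: str | Path,
    series_path: str | Path | None = None,
) -> None:
    """Write a compendium back to TSV; values round-trip at full precision."""
    df = comp.to_frame()
    # repr() of a Python float is shortest-round-trip, so read->write->read
    # reproduces the array bit-for-bit
    df.to_csv(matrix_path, sep="\t", float_format=lambda v: repr(float(v)))
    if series_path is not None:
        pd.DataFrame(
            {
                "sample_id": comp.sample_ids,
                "series": [comp.series_of_sample[s] for s in comp.sample_ids],
            }
        ).to_csv(series_path, sep="\t", index=False)


@dataclass
class GenePairLabels:
    """A set of gene pairs sharing one gold-standard label.

    Labels come from external evidence (operon predictions, pathway
    membership) and are consumed as-is; corrflag never computes them.
    """

    label: str
    pairs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in PAIR_LABELS:
            raise ValidationError(
                f"label {self.label!r} not in {PAIR_LABELS}"
            )
        self.pairs = canonical_pairs(self.pairs)


def read_pair_labels(path: str | Path) -> pd.DataFrame:
    """Read a pair-label TSV into a canonicalized, validated DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"pair-label file {path} must have headers {sorted(required)}")
    bad = ~df["label"].isin(PAIR_LABELS)
    if bad.any():
        raise ValidationError(f"unknown pair label: {df['label'][bad].iloc[0]!r}")
    canon = [canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
    out = pd.DataFrame(
        {
            "gene_a": [p[0] for p in canon],
            "gene_b": [p[1] for p in canon],
            "label": df["label"].to_numpy(),
        }
    )
    return out.drop_duplicates(subset=["gene_a", "gene_b", "label"]).reset_index(
        drop=True
    )


def write_pair_labels(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


_FLAG_COLUMNS = [
    "gene_a",
    "gene_b",
    "sd_a",
    "sd_b",
    "min_sd",
    "two_state_valid_a",
    "two_state_valid_b",
    "min_state_pct_a",
    "min_state_pct_b",
    "pair_min_state_pct",
    "flagged",
    "reasons",
]


def _fmt_pct(value: float | None) -> str:
    return "NA" if value is None else repr(float(value))


def write_flag_report(report: Sequence, path: str | Path) -> None:
    """Write pair flag decisions as TSV.

    One row per pair: ids, per-gene SDs, two-state validity, per-gene and
    pair-level minimum state percents (``NA`` when the gene is not
    two-state), the flag boolean and semicolon-joined reason codes. The file
    round-trips losslessly through :func:`read_flag_report`.
    """
    rows = []
    for r in report:
        rows.append(
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "sd_a": repr(float(r.sd_a)),
                "sd_b": repr(float(r.sd_b)),
                "min_sd": repr(float(r.min_sd)),
                "two_state_valid_a": r.two_state_valid_a,
                "two_state_valid_b": r.two_state_valid_b,
                "min_state_pct_a": _fmt_pct(r.min_state_pct_a),
                "min_state_pct_b": _fmt_pct(r.min_state_pct_b),
                "pair_min_state_pct": _fmt_pct(r.pair_min_state_pct),
                "flagged": r.flagged,
                "reasons": ";".join(r.reasons),
            }
        )
    pd.DataFrame(rows, columns=_FLAG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_flag_report(path: str | Path) -> list:
    """Read a flag-report TSV back into :class:`~corrflag.flagging.PairFlagReport`."""
    from .flagging import PairFlagReport  # local import: flagging imports io

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def _pct(cell: str) -> float | None:
        return None if cell == "NA" else float(cell)

    out = []
    for _, r in df.iterrows():
        out.append(
            PairFlagReport(
                gene_a=r["gene_a"],
                gene_b=r["gene_b"],
                sd_a=float(r["sd_a"]),
                sd_b=float(r["sd_b"]),
                two_state_valid_a=r["two_state_valid_a"] == "True",
                two_state_valid_b=r["two_state_valid_b"] == "True",
                min_state_pct_a=_pct(r["min_state_pct_a"]),
                min_state_pct_b=_pct(r["min_state_pct_b"]),
                flagged=r["flagged"] == "True",
                reasons=tuple(r["reasons"].split(";")) if r["reasons"] else (),
            )
        )
    return out


@dataclass
class FlagPolicy:
    """Thresholds governing state calling, flagging and bootstrap CIs.

    Attributes
    ----------
    sd_threshold
        Minimum per-gene standard deviation (log2 units) below which a
        pair's correlation is flagged; default 0.5, the RMA rule of thumb.
    state_pct_threshold
        Minimum representation required of the minority expression state,
        as a proportion of samples; default 0.10.
    bic_margin
        BIC units (higher-is-better convention) by which an alternative
        component count must beat the two-state model to displace it;
        default 10.
    operon_corr_threshold
        Correlation deemed "meaningful" for a true operon pair when
        calibrating flag cutoffs; default 0.6.
    bootstrap_reps
        Bootstrap replicates for between-compendium CIs; default 1000.
    ci_level
        Two-sided confidence level of the percentile interval; default 0.95.
    """

    sd_threshold: float = 0.5
    state_pct_threshold: float = 0.10
    bic_margin: float = 10.0
    operon_corr_threshold: float = 0.6
    bootstrap_reps: int = 1000
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        for attr in (
            "sd_threshold",
            "state_pct_threshold",
            "bic_margin",
            "operon_corr_threshold",
            "bootstrap_reps",
            "ci_level",
        ):
            if not getattr(self, attr) > 0:
                raise ValidationError(f"{attr} must be positive")
        if not self.state_pct_threshold < 0.5:
            raise ValidationError("state_pct_threshold must be < 0.5")
        if not self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if not math.isfinite(self.sd_threshold):
            raise ValidationError("sd_threshold must be finite")
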