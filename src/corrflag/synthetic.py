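"""Synthetic expression compendia with known regulon/operon structure.

The generator realizes the on/off abstraction behind the bias diagnostics:
each *regulon* is a binary switch that is "on" in a sample with a
series-specific probability; all genes of the regulon follow the switch
(operon-like co-transcription), genes of pathway-coupled regulons follow
correlated switches, and independent genes each carry a private switch.
A gene's log2 expression is ``mu_off + state * delta_on + N(0, noise_sd^2)``
— within-state spread is pure noise, the state change is the signal.

With the defaults (off mean 6, on shift +4, noise SD 0.4) the values live
on the 2–15 log2 scale typical of RMA-normalized microarrays, and an
operon pair's expected Pearson correlation has the closed form
``rho = s / (s + noise_sd^2)`` with ``s = p(1-p) * delta_on^2``: ~0.96 at
p_on = 0.4, collapsing to 0 when a compendium samples only one state —
exactly the sampling-bias phenomenology the flagging rules target.

Series-specific on-probabilities are the bias knob:
:func:`make_bias_scenario` starves a chosen fraction of series of the "on"
state so that partial compendia built from them misestimate associations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionCompendium

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "make_bias_scenario"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic compendium.

    Attributes
    ----------
    n_regulons, genes_per_regulon
        Co-switching gene groups; adjacent genes within a regulon are the
        ground-truth operon pairs.
    n_independent_genes
        Genes with private, independent switches.
    n_series, samples_per_series
        Series emulate deposition batches (a compendium of 10 x 50 = 500
        samples by default, within the 50–900 range typical of bacterial
        compendia).
    p_on
        Probability a regulon is "on" in a sample: one global value or one
        value per series. Per-series values are the sampling-bias knob.
    mu_off, delta_on, noise_sd
        Log2-scale off mean, on shift, and within-state noise SD.
    pathway_coupling
        Probability that the second regulon of a pathway group copies the
        first's switch instead of drawing its own; equals the correlation
        between the member regulons' states. Weaker than operon coupling
        (1.0) by construction.
    n_pathway_groups
        Number of leading regulon pairs (0-1, 2-3, ...) that are coupled;
        cross-regulon pairs within a group are the ground-truth pathway
        pairs.
    """

    n_regulons: int = 12
    genes_per_regulon: int = 3
    n_independent_genes: int = 12
    n_series: int = 10
    samples_per_series: int = 50
    p_on: float | tuple[float, ...] = 0.4
    mu_off: float = 6.0
    delta_on: float = 4.0
    noise_sd: float = 0.4
    pathway_coupling: float = 0.3
    n_pathway_groups: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("n_regulons", "genes_per_regulon", "n_series", "samples_per_series"):
            if getattr(self, attr) < 1:
                raise ValidationError(f"{attr} must be positive")
        if self.n_independent_genes < 0 or self.n_pathway_groups < 0:
            raise ValidationError("counts must be non-negative")
        if self.delta_on <= 0:
            raise ValidationError("delta_on must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.pathway_coupling < 1:
            raise ValidationError("pathway_coupling must be in [0, 1)")
        if 2 * self.n_pathway_groups > self.n_regulons:
            raise ValidationError("not enough regulons for the pathway groups")
        for p in self.p_on_per_series():
            if not 0 <= p <= 1:
                raise ValidationError("p_on values must be proportions")

    def p_on_per_series(self) -> tuple[float, ...]:
        if isinstance(self.p_on, (int, float)):
            return (float(self.p_on),) * self.n_series
        if len(self.p_on) != self.n_series:
            raise ValidationError(
                f"p_on has {len(self.p_on)} entries for {self.n_series} series"
            )
        return tuple(float(p) for p in self.p_on)

    @property
    def n_samples(self) -> int:
        return self.n_series * self.samples_per_series


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated compendium."""

    regulon_of_gene: dict[str, int]
    state_matrix: np.ndarray  # (n_switches, n_samples) binary
    operon_pairs: list[tuple[str, str]]
    non_operon_pairs: list[tuple[str, str]]
    pathway_pairs: list[tuple[str, str]]

    def pair_labels_frame(self) -> pd.DataFrame:
        """Ground-truth labels in the gold-standard pair-label TSV layout."""
        rows = (
            [(a, b, "likely_operon") for a, b in self.operon_pairs]
            + [(a, b, "likely_non_operon") for a, b in self.non_operon_pairs]
            + [(a, b, "same_pathway") for a, b in self.pathway_pairs]
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"])


def _draw_states(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary state matrix for all switches (regulons, then independent genes)."""
    n_switch = spec.n_regulons + spec.n_independent_genes
    p_series = spec.p_on_per_series()
    states = np.empty((n_switch, spec.n_samples), dtype=int)
    col = 0
    for p in p_series:
        n = spec.samples_per_series
        block = (rng.random((n_switch, n)) < p).astype(int)
        # pathway groups: the second member copies the first's switch with
        # prob c, which makes corr(state_a, state_b) = c exactly
        for g in range(spec.n_pathway_groups):
            copy = rng.random(n) < spec.pathway_coupling
            block[2 * g + 1, copy] = block[2 * g, copy]
        states[:, col : col + n] = block
        col += n
    return states


def generate(spec: SyntheticSpec) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Generate a compendium and its ground truth, deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    states = _draw_states(spec, rng)

    gene_ids: list[str] = []
    regulon_of_gene: dict[str, int] = {}
    switch_of_gene: list[int] = []
    for r in range(spec.n_regulons):
        for g in range(spec.genes_per_regulon):
            gid = f"op{r:02d}g{g}"
            gene_ids.append(gid)
            regulon_of_gene[gid] = r
            switch_of_gene.append(r)
    for j in range(spec.n_independent_genes):
        gid = f"ind{j:02d}"
        gene_ids.append(gid)
        regulon_of_gene[gid] = spec.n_regulons + j
        switch_of_gene.append(spec.n_regulons + j)

    signal = states[switch_of_gene] * spec.delta_on
    values = spec.mu_off + signal + rng.normal(
        0.0, spec.noise_sd, size=(len(gene_ids), spec.n_samples)
    )

    sample_ids = [f"s{i:04d}" for i in range(spec.n_samples)]
    series_of_sample = {
        sample_ids[i]: f"GSE{i // spec.samples_per_series:02d}"
        for i in range(spec.n_samples)
    }
    comp = ExpressionCompendium(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        series_of_sample=series_of_sample,
        name="synthetic",
    )

    operon_pairs = [
        (f"op{r:02d}g{g}", f"op{r:02d}g{g + 1}")
        for r in range(spec.n_regulons)
        for g in range(spec.genes_per_regulon - 1)
    ]
    pathway_pairs = [
        (f"op{2 * g:02d}g{i}", f"op{2 * g + 1:02d}g{j}")
        for g in range(spec.n_pathway_groups)
        for i in range(spec.genes_per_regulon)
        for j in range(spec.genes_per_regulon)
    ]
    # uncoupled structure: independent-gene pairs, plus first genes of
    # regulons outside any pathway group
    non_operon_pairs = [
        (f"ind{i:02d}", f"ind{j:02d}")
        for i in range(spec.n_independent_genes)
        for j in range(i + 1, spec.n_independent_genes)
    ]
    free = range(2 * spec.n_pathway_groups, spec.n_regulons)
    non_operon_pairs += [
        (f"op{a:02d}g0", f"op{b:02d}g0") for a in free for b in free if a < b
    ]

    truth = SyntheticTruth(
        regulon_of_gene=regulon_of_gene,
        state_matrix=states,
        operon_pairs=operon_pairs,
        non_operon_pairs=non_operon_pairs,
        pathway_pairs=pathway_pairs,
    )
    return comp, truth


def make_bias_scenario(
    spec: SyntheticSpec, starved_series_fraction: float
) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Generate a compendium in which some series never leave the off state.

    The first ``round(fraction * n_series)`` series get on-probability 0 —
    every regulon stays off, so those series contribute pure within-state
    noise. The remaining series keep the spec's (global) on-probability.
    Partial compendia assembled from starved series reproduce the biased-
    correlation phenomenology end to end.
    """
    if not 0 <= starved_series_fraction <= 1:
        raise ValidationError("starved_series_fraction must be in [0, 1]")
    if not isinstance(spec.p_on, (int, float)):
        raise ValidationError("make_bias_scenario needs a spec with a global p_on")
    n_starved = round(starved_series_fraction * spec.n_series)
    p_on = (0.0,) * n_starved + (float(spec.p_on),) * (spec.n_series - n_starved)
    return generate(replace(spec, p_on=p_on))
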