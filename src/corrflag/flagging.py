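"""Flag gene pairs whose association estimates are prone to sampling bias.

Two rules, applied per pair:

* **SD rule** (always applies): if either gene's sample standard deviation
  of log2 expression is below the policy threshold (default 0.5), the pair
  is flagged ``low_sd`` — little spread means the compendium mostly sampled
  noise within a single expression state, not signal between states.
* **State rule** (applies only when both genes are validly two-state): if
  the minority expression state of either gene occupies less than the
  policy threshold (default 10%) of samples, the pair is flagged
  ``state_underrepresented``. An optional joint variant instead requires
  both the both-on and both-off co-occupancy fractions to reach the
  threshold.

Constant genes (zero SD, correlation undefined) always flag with
``constant_gene``; so do genes whose state fit failed outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from . import mixture as mx
from .assoc import gene_sd
from .errors import ValidationError
from .io import ExpressionCompendium, FlagPolicy, canonical_pairs

__all__ = ["PairFlagReport", "flag_pair", "flag_compendium"]

REASON_LOW_SD = "low_sd"
REASON_STATE = "state_underrepresented"
REASON_CONSTANT = "constant_gene"


@dataclass(frozen=True)
class PairFlagReport:
    """Flag decision for one gene pair with the statistics behind it."""

    gene_a: str
    gene_b: str
    sd_a: float
    sd_b: float
    two_state_valid_a: bool
    two_state_valid_b: bool
    min_state_pct_a: float | None
    min_state_pct_b: float | None
    flagged: bool
    reasons: tuple[str, ...]

    @property
    def min_sd(self) -> float:
        return min(self.sd_a, self.sd_b)

    @property
    def pair_min_state_pct(self) -> float | None:
        """Minimum across the pair of each gene's minority-state share.

        None unless both genes are validly two-state.
        """
        if self.min_state_pct_a is None or self.min_state_pct_b is None:
            return None
        return min(self.min_state_pct_a, self.min_state_pct_b)


def _joint_min_state_pct(state_a: "mx.MixtureFit", state_b: "mx.MixtureFit") -> float:
    """min(fraction both on, fraction both off) from MAP assignments."""
    on_a = state_a.assignment.astype(bool)
    on_b = state_b.assignment.astype(bool)
    both_on = float(np.mean(on_a & on_b))
    both_off = float(np.mean(~on_a & ~on_b))
    return min(both_on, both_off)


def flag_pair(
    gene_a: str,
    gene_b: str,
    sd_a: float,
    sd_b: float,
    state_a: "mx.MixtureFit | None",
    state_b: "mx.MixtureFit | None",
    policy: FlagPolicy | None = None,
    *,
    joint_state: bool = False,
) -> PairFlagReport:
    """Apply the SD and state-representation rules to one pair.

    ``state_a``/``state_b`` are per-gene mixture fits, or None when the
    gene's fit failed (the SD rule still applies; such genes additionally
    carry the ``constant_gene`` reason). With ``joint_state=True`` the 10%
    rule tests the fraction of samples in which the two genes are
    simultaneously on (and simultaneously off) rather than each gene's
    marginal minority-state share.
    """
    policy = policy or FlagPolicy()
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be non-negative")

    reasons: list[str] = []
    if min(sd_a, sd_b) < policy.sd_threshold:
        reasons.append(REASON_LOW_SD)

    valid_a = state_a is not None and state_a.two_state_valid
    valid_b = state_b is not None and state_b.two_state_valid
    if valid_a and valid_b:
        if joint_state:
            pair_stat = _joint_min_state_pct(state_a, state_b)
        else:
            pair_stat = min(state_a.min_state_pct, state_b.min_state_pct)
        if pair_stat < policy.state_pct_threshold:
            reasons.append(REASON_STATE)

    if sd_a == 0 or sd_b == 0 or state_a is None or state_b is None:
        reasons.append(REASON_CONSTANT)

    return PairFlagReport(
        gene_a=gene_a,
        gene_b=gene_b,
        sd_a=float(sd_a),
        sd_b=float(sd_b),
        two_state_valid_a=valid_a,
        two_state_valid_b=valid_b,
        min_state_pct_a=state_a.min_state_pct if valid_a else None,
        min_state_pct_b=state_b.min_state_pct if valid_b else None,
        flagged=bool(reasons),
        reasons=tuple(reasons),
    )


def flag_compendium(
    comp: ExpressionCompendium,
    policy: FlagPolicy | None = None,
    pairs: Iterable[tuple[str, str]] | None = None,
    seed: int = 0,
    *,
    joint_state: bool = False,
    states: "dict[str, mx.MixtureFit | None] | None" = None,
) -> list[PairFlagReport]:
    """Flag every requested pair (default: all pairs) of a compendium.

    State fits and SDs are computed once per gene and shared across pairs.
    Precomputed fits can be supplied via ``states`` to avoid refitting.
    Genes whose fit failed are reported (flagged), never dropped.
    """
    if comp.n_genes < 2:
        raise ValidationError("need at least 2 genes to flag pairs")
    policy = policy or FlagPolicy()
    if pairs is None:
        pair_list = canonical_pairs(combinations(comp.gene_ids, 2))
    else:
        pair_list = canonical_pairs(pairs)

    needed = {g for p in pair_list for g in p}
    sds = {g: gene_sd(comp, g) for g in needed}
    if states is None:
        states = mx.fit_all_genes(comp, policy, seed=seed)

    return [
        flag_pair(
            a,
            b,
            sds[a],
            sds[b],
            states.get(a),
            states.get(b),
            policy,
            joint_state=joint_state,
        )
        for a, b in pair_list
    ]
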