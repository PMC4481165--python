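"""Per-gene on/off state calling via univariate Gaussian mixtures.

Many bacterial genes are well described as switching between an "off"
baseline and an "on" induced expression level; across a compendium such a
gene's log2 expression distribution is a two-component Gaussian mixture.
This module fits unequal-variance univariate mixtures by EM for a range of
component counts m, scores each with BIC (higher-is-better convention,
``2*logLik - k*log(n)`` with ``k = 3m - 1`` free parameters) and keeps the
two-state model unless some other m beats it by more than a configurable
BIC margin (default 10) — strong-evidence model selection biased toward the
biologically motivated two-state abstraction.

For a two-state gene the "on" component is the one with the larger mean;
``p_on`` is the fraction of samples MAP-assigned to it and
``min_state_pct = min(p_on, 1 - p_on)`` measures how well the minority
state is represented — the quantity the 10% flagging rule tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FitError, ValidationError
from .io import ExpressionCompendium, FlagPolicy

__all__ = [
    "GMMFit",
    "MixtureFit",
    "fit_gmm",
    "select_m",
    "classify_states",
    "classify_by_threshold",
    "joint_on_fraction",
    "fit_gene_states",
    "fit_all_genes",
    "DEFAULT_CANDIDATE_SIZES",
]

#: Candidate component counts tried per gene.
DEFAULT_CANDIDATE_SIZES: tuple[int, ...] = tuple(range(1, 10))

#: A candidate m is fitted only when n >= MIN_SAMPLES_PER_COMPONENT * m.
MIN_SAMPLES_PER_COMPONENT = 5

#: Component variances are floored at this fraction of the data variance;
#: a component pinned at the floor indicates EM collapse and fails the fit.
VAR_FLOOR_FRACTION = 1e-6

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GMMFit:
    """Parameters and fit statistics of one univariate Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float

    @property
    def m(self) -> int:
        return self.means.size


def _log_resp(x: np.ndarray, w: np.ndarray, mu: np.ndarray, var: np.ndarray):
    """Log joint densities (n, m) and per-sample log-likelihood (n,)."""
    d = x[:, None] - mu[None, :]
    logp = -0.5 * (_LOG_2PI + np.log(var)[None, :] + d * d / var[None, :])
    logp += np.log(w)[None, :]
    mx = logp.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
    return logp, lse


def _em(
    x: np.ndarray,
    mu0: np.ndarray,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Run EM to convergence from one initialization; returns (w, mu, var, ll)."""
    m = mu0.size
    n = x.size
    w = np.full(m, 1.0 / m)
    mu = mu0.astype(float).copy()
    var = np.full(m, max(x.var(), var_floor))
    ll_old = -np.inf
    for _ in range(max_iter):
        logp, lse = _log_resp(x, w, mu, var)
        ll = float(lse.sum())
        r = np.exp(logp - lse[:, None])
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk + var_floor
        if ll - ll_old < tol:
            break
        ll_old = ll
    return w, mu, var, ll


def fit_gmm(
    values: Sequence[float],
    m: int,
    seed: int,
    *,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> GMMFit:
    """Fit an m-component unequal-variance Gaussian mixture by EM.

    The first restart initializes component means at the m interior
    quantiles of the data; the remaining restarts jitter those quantiles
    with noise drawn from a generator seeded by ``seed``, so the whole fit
    is deterministic. ``m = 1`` has a closed form and needs no EM. BIC uses
    the higher-is-better convention ``2*logLik - (3m - 1)*log(n)``.

    Raises
    ------
    FitError
        If every restart collapses a component onto the variance floor
        (fewer distinct values than components, typically).
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if m < 1:
        raise ValidationError("m must be >= 1")
    if n < MIN_SAMPLES_PER_COMPONENT * m:
        raise ValidationError(
            f"need at least {MIN_SAMPLES_PER_COMPONENT * m} samples for m={m}"
        )
    k_free = 3 * m - 1

    if m == 1:
        mu = float(x.mean())
        var = float(x.var())  # MLE variance
        if var <= 0:
            raise FitError("constant vector: single-Gaussian variance is zero")
        ll = -0.5 * n * (_LOG_2PI + np.log(var) + 1.0)
        return GMMFit(
            weights=np.array([1.0]),
            means=np.array([mu]),
            variances=np.array([var]),
            log_likelihood=float(ll),
            bic=float(2.0 * ll - k_free * np.log(n)),
        )

    data_var = x.var()
    if data_var <= 0:
        raise FitError("constant vector: mixture fit undefined")
    var_floor = VAR_FLOOR_FRACTION * data_var
    quantile_means = np.quantile(x, (np.arange(m) + 0.5) / m)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), m]))

    best: GMMFit | None = None
    for restart in range(n_restarts):
        mu0 = quantile_means.copy()
        if restart > 0:
            mu0 = mu0 + rng.normal(0.0, 0.25 * x.std(), size=m)
        w, mu, var, ll = _em(x, mu0, var_floor, tol, max_iter)
        if np.any(var <= var_floor * (1.0 + 1e-9)) or not np.isfinite(ll):
            continue  # collapsed component: this restart failed
        if best is None or ll > best.log_likelihood:
            order = np.argsort(mu)
            best = GMMFit(
                weights=w[order],
                means=mu[order],
                variances=var[order],
                log_likelihood=ll,
                bic=float(2.0 * ll - k_free * np.log(n)),
            )
    if best is None:
        raise FitError(f"EM degenerate for m={m}: variance collapse in every restart")
    return best


def select_m(bic: Mapping[int, float], margin: float = 10.0) -> int:
    """Choose the component count, favouring the two-state model.

    Returns 2 whenever ``BIC_2 > BIC_i - margin`` for every other candidate
    i — i.e. the two-state model is kept unless some alternative beats it
    by more than ``margin`` BIC units (higher is better). Otherwise returns
    the candidate with maximal BIC, breaking ties toward the smallest m.
    If m=2 is absent (its fit failed), falls through to the argmax rule.
    """
    if not bic:
        raise ValidationError("empty BIC mapping")
    if 2 in bic and all(bic[2] > b - margin for m, b in bic.items() if m != 2):
        return 2
    best_bic = max(bic.values())
    return min(m for m, b in bic.items() if b == best_bic)


def classify_states(fit: GMMFit, values: Sequence[float]):
    """MAP on/off assignment under a two-component fit.

    Returns ``(assignment, p_on, min_state_pct)`` where assignment is 0/1
    per sample, 1 marking the larger-mean ("on") component. Defined only
    for two-component fits.
    """
    if fit.m != 2:
        raise ValidationError(f"state classification requires m=2, got m={fit.m}")
    x = np.asarray(values, dtype=float).ravel()
    logp, _ = _log_resp(x, fit.weights, fit.means, fit.variances)
    comp = logp.argmax(axis=1)
    on_component = int(np.argmax(fit.means))
    assignment = (comp == on_component).astype(int)
    p_on = float(assignment.mean())
    return assignment, p_on, min(p_on, 1.0 - p_on)


def classify_by_threshold(values: Sequence[float], threshold: float):
    """Fixed-threshold state call: on iff the value is strictly above it.

    Supports threshold-style accounting of on/off occupancy (e.g. marking a
    gene "on" above a visually chosen expression level) without a mixture
    fit. Returns ``(assignment, p_on)``.
    """
    x = np.asarray(values, dtype=float).ravel()
    assignment = (x > threshold).astype(int)
    return assignment, float(assignment.mean())


def joint_on_fraction(
    values_a: Sequence[float],
    threshold_a: float,
    values_b: Sequence[float],
    threshold_b: float,
) -> float:
    """Fraction of samples in which both genes are simultaneously on."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValidationError("vectors must be the same length")
    return float(np.mean((a > threshold_a) & (b > threshold_b)))


@dataclass
class MixtureFit:
    """Complete per-gene state-calling result.

    ``two_state_valid`` is true exactly when the BIC-margin rule selected
    m=2; only then are ``on_component``, ``p_on`` and ``min_state_pct``
    defined (otherwise None).
    """

    gene_id: str
    candidate_sizes: tuple[int, ...]
    bic: dict[int, float]
    m_selected: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    assignment: np.ndarray
    on_component: int | None = None
    p_on: float | None = None
    min_state_pct: float | None = None
    failed_sizes: tuple[int, ...] = field(default_factory=tuple)

    @property
    def two_state_valid(self) -> bool:
        return self.m_selected == 2


def fit_gene_states(
    comp: ExpressionCompendium,
    gene_id: str,
    policy: FlagPolicy | None = None,
    seed: int = 0,
    candidate_sizes: Sequence[int] | None = None,
) -> MixtureFit:
    """Fit candidate mixtures for one gene and call its expression states.

    Candidates needing more than n/5 components are skipped; candidates
    whose EM degenerates are recorded in ``failed_sizes`` and excluded from
    selection. All candidates failing raises :class:`FitError`.
    """
    policy = policy or FlagPolicy()
    sizes = tuple(candidate_sizes) if candidate_sizes else DEFAULT_CANDIDATE_SIZES
    x = comp.row(gene_id)

    fits: dict[int, GMMFit] = {}
    failed: list[int] = []
    for m in sizes:
        if x.size < MIN_SAMPLES_PER_COMPONENT * m:
            continue
        try:
            fits[m] = fit_gmm(x, m, seed)
        except FitError:
            failed.append(m)
    if not fits:
        raise FitError(f"all candidate mixture sizes failed for gene {gene_id!r}")

    bic = {m: f.bic for m, f in fits.items()}
    m_sel = select_m(bic, margin=policy.bic_margin)
    sel = fits[m_sel]

    if m_sel == 2:
        assignment, p_on, min_state_pct = classify_states(sel, x)
        on_component = int(np.argmax(sel.means))
    else:
        logp, _ = _log_resp(x, sel.weights, sel.means, sel.variances)
        assignment = logp.argmax(axis=1)
        on_component, p_on, min_state_pct = None, None, None

    return MixtureFit(
        gene_id=gene_id,
        candidate_sizes=sizes,
        bic=bic,
        m_selected=m_sel,
        weights=sel.weights,
        means=sel.means,
        variances=sel.variances,
        assignment=np.asarray(assignment),
        on_component=on_component,
        p_on=p_on,
        min_state_pct=min_state_pct,
        failed_sizes=tuple(failed),
    )


def fit_all_genes(
    comp: ExpressionCompendium,
    policy: FlagPolicy | None = None,
    seed: int = 0,
    candidate_sizes: Sequence[int] | None = None,
) -> dict[str, MixtureFit | None]:
    """State fits for every gene; genes whose fit fails entirely map to None.

    Each gene receives a sub-seed derived from ``seed`` and a CRC of its
    id, so results are deterministic and independent of which other genes
    are present.
    """
    out: dict[str, MixtureFit | None] = {}
    for gene in comp.gene_ids:
        sub_seed = int(
            np.random.SeedSequence([int(seed), zlib.crc32(gene.encode())])
            .generate_state(1)[0]
            % (2**31)
        )
        try:
            out[gene] = fit_gene_states(
                comp, gene, policy, seed=sub_seed, candidate_sizes=candidate_sizes
            )
        except FitError:
            out[gene] = None
    return out
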