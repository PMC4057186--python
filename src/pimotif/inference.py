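"""Model estimation: PWMs with pseudo-counts, gauge fixing, marginal-matching
gradient descent for the pairwise model, and BIC-controlled greedy coupling
addition.

The fitting problem is convex: the maximum-entropy model matching a set of
single and pairwise marginals is unique, and plain gradient descent on the
fields/couplings (steps proportional to the marginal residuals) converges to
it.  Couplings are added one at a time, each time picking the inactive pair
whose model-predicted dinucleotide distribution deviates most from the data
under an exact binomial test; the Bayesian Information Criterion decides when
to stop.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    PWM,
    PairFrequencies,
    PIMParams,
    SiteSet,
    _marginals,
    energy,
    log_partition,
)

#: Default pseudo-counts: 1 per single-nucleotide cell, 1/16 per dinucleotide
#: cell (so each pair distribution also receives one prior observation).
BETA_SINGLE = 1.0
BETA_PAIR = 1.0 / 16.0


def estimate_pwm(sites: SiteSet, beta: float | np.ndarray = BETA_SINGLE) -> PWM:
    """Pseudo-counted PWM: p_i(a) = (n_i(a) + beta) / (N + sum_a beta).

    ``beta`` may be a scalar or an (L, 4) array of per-cell pseudo-counts.
    """
    counts = sites.counts_single().astype(np.float64)
    b = np.broadcast_to(np.asarray(beta, dtype=np.float64), counts.shape)
    num = counts + b
    probs = num / num.sum(axis=1, keepdims=True)
    return PWM(probs, beta=float(np.mean(b)))


def empirical_frequencies(
    sites: SiteSet,
    beta_single: float = BETA_SINGLE,
    beta_pair: float = BETA_PAIR,
) -> PairFrequencies:
    """Pseudo-counted single and pairwise frequencies for all i < j."""
    L = sites.L
    counts = sites.counts_single().astype(np.float64) + beta_single
    singles = counts / counts.sum(axis=1, keepdims=True)
    pairs = np.zeros((L, L, 4, 4))
    for i in range(L):
        for j in range(i + 1, L):
            c = sites.counts_pair(i, j).astype(np.float64) + beta_pair
            f = c / c.sum()
            # Different single/pair pseudo-counts leave the pair tables
            # marginally inconsistent with the singles at O(beta/N); rebalance
            # each table (iterative proportional fitting) so a model matching
            # the pair constraints also matches the single constraints.
            if beta_single != 4 * beta_pair:
                for _ in range(200):
                    f *= (singles[i] / f.sum(axis=1))[:, None]
                    f *= (singles[j] / f.sum(axis=0))[None, :]
                    if max(np.abs(f.sum(axis=1) - singles[i]).max(),
                           np.abs(f.sum(axis=0) - singles[j]).max()) < 1e-13:
                        break
            pairs[i, j] = f
            pairs[j, i] = f.T
    return PairFrequencies(singles=singles, pairs=pairs)


def fix_gauge(params: PIMParams) -> PIMParams:
    """Zero-sum (minimum-norm) gauge.

    Each coupling block is decomposed into a double-centered part plus row and
    column means; the means are absorbed into the fields, the fields are then
    centered per position.  The distribution is unchanged (all shifts are
    per-position or global constants).
    """
    h = params.h.copy()
    new_c = {}
    for (i, j), J in params.couplings.items():
        t = J.mean()
        r = J.mean(axis=1) - t
        c = J.mean(axis=0) - t
        new_c[(i, j)] = J - r[:, None] - c[None, :] - t
        h[i] += r
        h[j] += c
    h -= h.mean(axis=1, keepdims=True)
    return PIMParams(h, new_c, gauge_fixed=True)


@dataclass
class FitRecord:
    step: int
    pair: tuple[int, int] | None
    nll: float
    bic: float
    residual: float
    iterations: int
    converged: bool


@dataclass
class FitTrace:
    """Greedy-addition history: one record per model size, starting at zero
    couplings, plus the index of the BIC-minimal step."""

    records: list[FitRecord] = field(default_factory=list)
    best_step: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [r.step for r in self.records],
                "pair_i": [(-1 if r.pair is None else r.pair[0] + 1)
                           for r in self.records],
                "pair_j": [(-1 if r.pair is None else r.pair[1] + 1)
                           for r in self.records],
                "nll": [r.nll for r in self.records],
                "bic": [r.bic for r in self.records],
                "residual": [r.residual for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _target_from(sites_or_freqs, beta_single, beta_pair) -> PairFrequencies:
    if isinstance(sites_or_freqs, PairFrequencies):
        return sites_or_freqs
    return empirical_frequencies(sites_or_freqs, beta_single, beta_pair)


def fit_pim(
    sites_or_freqs,
    active_pairs,
    init: PIMParams | None = None,
    eta: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 20000,
    beta_single: float = BETA_SINGLE,
    beta_pair: float = BETA_PAIR,
) -> tuple[PIMParams, dict]:
    """Fit fields and the active couplings by marginal matching.

    Gradient steps move each parameter opposite to its marginal residual
    (h down where the data marginal exceeds the model's, since P ~ exp(-E)),
    until the largest absolute residual over all single marginals and the
    active pairwise marginals is <= ``tol``.  Returns the gauge-fixed model
    and a diagnostics dict (iterations, residual, converged).
    """
    target = _target_from(sites_or_freqs, beta_single, beta_pair)
    L = target.L
    active = sorted({(min(i, j), max(i, j)) for (i, j) in active_pairs})
    for (i, j) in active:
        if not 0 <= i < j < L:
            raise ValueError(f"invalid pair ({i}, {j})")

    if init is None:
        params = PIMParams(-np.log(target.singles),
                           {p: np.zeros((4, 4)) for p in active})
    else:
        params = init.copy()
        for p in active:
            params.couplings.setdefault(p, np.zeros((4, 4)))
        for p in list(params.couplings):
            if p not in active:
                del params.couplings[p]

    # Adaptive step: the stability region shrinks as strong couplings merge
    # positions into larger components, so on divergence (residual well above
    # the best seen) restore the best parameters and halve the step.
    eta_cur = eta
    resid = np.inf
    best_resid = np.inf
    best_params = params.copy()
    it = 0
    for it in range(1, max_iter + 1):
        singles, pair_marg = _marginals(params, active)
        r_h = target.singles - singles
        resid = np.abs(r_h).max() if r_h.size else 0.0
        r_J = {}
        for p in active:
            r = target.pair(*p) - pair_marg[p]
            r_J[p] = r
            resid = max(resid, np.abs(r).max())
        if resid <= tol:
            break
        if resid < best_resid:
            best_resid = resid
            best_params = params.copy()
        elif resid > 3.0 * best_resid and eta_cur > 1e-3:
            params = best_params.copy()
            eta_cur *= 0.5
            continue
        params.h -= eta_cur * r_h
        for p in active:
            params.couplings[p] -= eta_cur * r_J[p]
        params.logZ_cache = None

    converged = resid <= tol
    if not converged and best_resid < resid:
        params, resid = best_params, best_resid
        converged = resid <= tol
    out = fix_gauge(params)
    return out, {"iterations": it, "residual": float(resid),
                 "converged": bool(converged)}


def _binom_two_sided(counts: np.ndarray, N: int, probs: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial tail for each cell.

    The p-value of an observed count n under Binom(N, p) is the total
    probability of outcomes no more likely than n.
    """
    counts = np.asarray(counts).ravel()
    probs = np.clip(np.asarray(probs, dtype=np.float64).ravel(), 0.0, 1.0)
    k = np.arange(N + 1)
    pmf = stats.binom.pmf(k[None, :], N, probs[:, None])  # (cells, N+1)
    obs = pmf[np.arange(counts.size), counts]
    mask = pmf <= obs[:, None] * (1 + 1e-9)
    return np.minimum((pmf * mask).sum(axis=1), 1.0)


def select_next_pair(
    params: PIMParams,
    sites: SiteSet,
    excluded=(),
    universe=None,
) -> tuple[int, int] | None:
    """The inactive pair whose dinucleotide statistics deviate most from data.

    For every candidate pair and each of the 16 dinucleotide cells, the exact
    two-sided binomial tail probability of the observed count under the model
    probability is computed; a pair's score is its smallest cell p-value and
    the smallest-scoring pair wins (lexicographic tie-break).  Returns None
    when no candidate remains.
    """
    L, N = params.L, sites.N
    excl = set(excluded) | set(params.couplings)
    cand = sorted(
        (p for p in (universe if universe is not None
                     else ((i, j) for i in range(L) for j in range(i + 1, L)))
         if p not in excl)
    )
    if not cand:
        return None
    _, model_pairs = _marginals(params, cand)
    best, best_score = None, np.inf
    for p in cand:
        obs = sites.counts_pair(*p)
        score = _binom_two_sided(obs, N, model_pairs[p]).min()
        if score < best_score:
            best, best_score = p, score
    return best


def bic(neg_log_likelihood: float, k: int, N: int) -> float:
    """-log L-hat + (k/2) log N  (natural logs)."""
    return float(neg_log_likelihood) + 0.5 * k * np.log(N)


def pim_param_count(L: int, n_couplings: int) -> int:
    """Gauge-independent parameter count: 3 per position, 9 per coupling."""
    return 3 * L + 9 * n_couplings


def negative_log_likelihood(params: PIMParams, sites: SiteSet) -> float:
    """-sum_n log P(s_n) = sum_n E(s_n) + N log Z."""
    lz = log_partition(params)
    return float(energy(params, sites.seqs).sum() + sites.N * lz)


def build_pim(
    sites: SiteSet,
    pair_universe: str = "all",
    patience: int = 3,
    max_couplings: int | None = None,
    eta: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 20000,
    beta_single: float = BETA_SINGLE,
    beta_pair: float = BETA_PAIR,
) -> tuple[PIMParams, FitTrace]:
    """Greedy BIC-controlled model growth.

    Starting from the coupling-free fit, repeatedly add the most deviant pair
    (restricted to adjacent positions when ``pair_universe`` is
    ``"nearest_neighbor"``), refit, and score the BIC.  Stops once the BIC has
    failed to improve for ``patience`` consecutive additions (or the universe
    is exhausted) and returns the BIC-minimal model with the full trace.
    """
    if sites.N < 2:
        raise ValueError("need at least 2 sites to select couplings")
    if pair_universe not in ("all", "nearest_neighbor"):
        raise ValueError("pair_universe must be 'all' or 'nearest_neighbor'")
    L = sites.L
    universe = (
        [(i, i + 1) for i in range(L - 1)]
        if pair_universe == "nearest_neighbor"
        else [(i, j) for i in range(L) for j in range(i + 1, L)]
    )
    target = empirical_frequencies(sites, beta_single, beta_pair)
    fit_kw = dict(eta=eta, tol=tol, max_iter=max_iter)

    params, info = fit_pim(target, [], **fit_kw)
    nll = negative_log_likelihood(params, sites)
    trace = FitTrace()
    trace.records.append(FitRecord(0, None, nll,
                                   bic(nll, pim_param_count(L, 0), sites.N),
                                   info["residual"], info["iterations"],
                                   info["converged"]))
    best_bic = trace.records[0].bic
    best_params = params.copy()
    since_best = 0
    active: list[tuple[int, int]] = []
    limit = len(universe) if max_couplings is None else min(len(universe),
                                                           max_couplings)

    while len(active) < limit and since_best < patience:
        pair = select_next_pair(params, sites, excluded=active,
                                universe=universe)
        if pair is None:
            break
        active.append(pair)
        params, info = fit_pim(target, active, init=params, **fit_kw)
        nll = negative_log_likelihood(params, sites)
        b = bic(nll, pim_param_count(L, len(active)), sites.N)
        trace.records.append(FitRecord(len(active), pair, nll, b,
                                       info["residual"], info["iterations"],
                                       info["converged"]))
        if b < best_bic:
            best_bic = b
            best_params = params.copy()
            trace.best_step = len(active)
            since_best = 0
        else:
            since_best += 1

    return best_params, trace
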