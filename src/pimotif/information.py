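"""Information-theoretic analysis of fitted models.

Covers Kullback-Leibler divergences (with a finite-sampling "self" control),
Direct Information computed from the two-site direct distribution, Mutual
Information, their entropy-normalized versions, participation ratios of the
interaction weights, and the interaction-vs-distance profile.  All entropies
and divergences are reported in bits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import (
    LN2,
    PIMParams,
    SiteSet,
    log2_probability,
    model_marginals,
)

#: Anchor letter for the direct-field solution (T, last in alphabet order).
ANCHOR = 3


def dkl(P, Q) -> float:
    """KL divergence sum P log2(P/Q) in bits; +inf on support violation."""
    P = np.asarray(P, dtype=np.float64).ravel()
    Q = np.asarray(Q, dtype=np.float64).ravel()
    if P.shape != Q.shape:
        raise ValueError("distributions must have the same shape")
    pos = P > 0
    if np.any(Q[pos] <= 0):
        return float("inf")
    return float((P[pos] * np.log2(P[pos] / Q[pos])).sum())


def entropy_bits(p) -> float:
    p = np.asarray(p, dtype=np.float64).ravel()
    pos = p > 0
    return float(-(p[pos] * np.log2(p[pos])).sum())


def dkl_sample_to_model(sites: SiteSet, model) -> float:
    """DKL(empirical site frequencies || model distribution), in bits.

    ``model`` is anything exposing probabilities of encoded sites: a
    PIMParams, a PWM, or a MixtureModel.
    """
    uniq, counts = sites.unique()
    q = counts / counts.sum()
    lp = _model_log2(model, uniq)
    return float((q * (np.log2(q) - lp)).sum())


def _model_log2(model, sites) -> np.ndarray:
    from .core import PWM, pwm_log2_probability
    from .mixture import MixtureModel

    if isinstance(model, PIMParams):
        return np.atleast_1d(log2_probability(model, sites))
    if isinstance(model, PWM):
        return np.atleast_1d(pwm_log2_probability(model, sites))
    if isinstance(model, MixtureModel):
        return np.atleast_1d(model.log2_probability(sites))
    raise TypeError(f"unsupported model type {type(model)!r}")


def self_dkl(model_probs, N: int, reps: int, seed: int) -> tuple[float, float]:
    """Finite-sampling control: DKL between model samples and the model.

    Draws ``reps`` independent samples of size N from the categorical
    distribution ``model_probs`` (a probability vector over states) and
    returns the mean and standard deviation of DKL(sample || model).  An
    observed DKL exceeding mean + 2 sd flags a genuinely inadequate model.
    """
    p = np.asarray(model_probs, dtype=np.float64).ravel()
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("model_probs must be a probability vector")
    rng = np.random.default_rng(seed)
    vals = np.empty(reps)
    for r in range(reps):
        counts = rng.multinomial(N, p)
        vals[r] = dkl(counts / N, p)
    return float(vals.mean()), float(vals.std(ddof=1))


def state_probabilities(params: PIMParams) -> np.ndarray:
    """The full 4^L probability vector of a model (for self-DKL controls)."""
    from .core import _block_digits, _block_energies, _check_enum

    L = params.L
    _check_enum(L)
    comp = tuple(range(L))
    digits = _block_digits(comp, 0, 4 ** L)
    e = _block_energies(params, comp, digits)
    p = np.exp(-(e - e.min()))
    return p / p.sum()


@dataclass(frozen=True)
class DirectPairSolution:
    """Two-site direct distribution for a pair, with its constraint fields.

    P_dir(a, b) ~ exp(-J(a,b) - hi(a) - hj(b)) with marginals matching the
    supplied single-site frequencies; the fields are anchored to vanish for
    the last alphabet letter (T).
    """

    pair: tuple[int, int]
    h_i: np.ndarray
    h_j: np.ndarray
    p_dir: np.ndarray
    residual: float
    converged: bool


def solve_direct_fields(
    J_block: np.ndarray,
    f_i: np.ndarray,
    f_j: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
    pair: tuple[int, int] = (0, 1),
) -> DirectPairSolution:
    """Solve for the direct-distribution fields by Levenberg-Marquardt.

    The six free field values (three per position after anchoring T to zero)
    are determined by the six independent marginal constraints.
    """
    J = np.asarray(J_block, dtype=np.float64)
    f_i = np.asarray(f_i, dtype=np.float64)
    f_j = np.asarray(f_j, dtype=np.float64)
    if np.any(f_i <= 0) or np.any(f_j <= 0):
        raise ValueError("marginals must be strictly positive (pseudo-counted)")

    def unpack(x):
        hi = np.zeros(4)
        hj = np.zeros(4)
        hi[:ANCHOR] = x[:3]
        hj[:ANCHOR] = x[3:]
        return hi, hj

    def pdir(hi, hj):
        w = np.exp(-(J + hi[:, None] + hj[None, :]))
        return w / w.sum()

    def residuals(x):
        P = pdir(*unpack(x))
        return np.concatenate(
            [(P.sum(axis=1) - f_i)[:3], (P.sum(axis=0) - f_j)[:3]]
        )

    x0 = np.concatenate([
        -np.log(f_i[:ANCHOR] / f_i[ANCHOR]),
        -np.log(f_j[:ANCHOR] / f_j[ANCHOR]),
    ])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=max_iter * 7)
    hi, hj = unpack(sol.x)
    P = pdir(hi, hj)
    resid = float(max(np.abs(P.sum(axis=1) - f_i).max(),
                      np.abs(P.sum(axis=0) - f_j).max()))
    return DirectPairSolution(pair, hi, hj, P, resid, resid <= tol)


def direct_information(solution: DirectPairSolution,
                       f_i: np.ndarray, f_j: np.ndarray) -> float:
    """DI = sum_ab P_dir log2[P_dir / (f_i f_j)] >= 0, in bits."""
    P = solution.p_dir
    indep = np.outer(f_i, f_j)
    pos = P > 0
    return max(float((P[pos] * np.log2(P[pos] / indep[pos])).sum()), 0.0)


def mutual_information(f_ij: np.ndarray, f_i: np.ndarray,
                       f_j: np.ndarray) -> float:
    """MI = sum_ab f_ij log2[f_ij / (f_i f_j)] in bits."""
    f_ij = np.asarray(f_ij, dtype=np.float64)
    indep = np.outer(f_i, f_j)
    pos = f_ij > 0
    return max(float((f_ij[pos] * np.log2(f_ij[pos] / indep[pos])).sum()), 0.0)


def normalized(value: float, H_i: float, H_j: float) -> float:
    """Entropy normalization: value / min(H_i, H_j); 0 when both vanish.

    MI is bounded by the smaller marginal entropy, so the normalized MI lies
    in [0, 1] and reaches 1 for a deterministic copy of equal-entropy
    positions; the same denominator is applied to DI.
    """
    m = min(H_i, H_j)
    if m <= 0:
        return 0.0
    return value / m


@dataclass(frozen=True)
class InfoMatrices:
    """Symmetric L x L matrices (zero diagonal): DI, NDI, MI, NMI, in bits."""

    di: np.ndarray
    ndi: np.ndarray
    mi: np.ndarray
    nmi: np.ndarray

    @property
    def L(self) -> int:
        return self.di.shape[0]


def interaction_matrices(params: PIMParams, freqs=None,
                         tol: float = 1e-10) -> InfoMatrices:
    """DI/NDI/MI/NMI matrices of a fitted model.

    DI uses the model couplings with single-site marginals from ``freqs``
    (default: the model's own exact marginals); pairs without a coupling have
    DI exactly 0 and are not solved.  MI uses the pairwise marginals of
    ``freqs``.
    """
    L = params.L
    f = model_marginals(params) if freqs is None else freqs
    H = np.array([entropy_bits(f.singles[i]) for i in range(L)])
    di = np.zeros((L, L))
    mi = np.zeros((L, L))
    ndi = np.zeros((L, L))
    nmi = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            m = mutual_information(f.pair(i, j), f.singles[i], f.singles[j])
            mi[i, j] = mi[j, i] = m
            nmi[i, j] = nmi[j, i] = normalized(m, H[i], H[j])
            J = params.couplings.get((i, j))
            if J is not None and np.abs(J).max() > 0:
                sol = solve_direct_fields(J, f.singles[i], f.singles[j],
                                          tol=tol, pair=(i, j))
                d = direct_information(sol, f.singles[i], f.singles[j])
                di[i, j] = di[j, i] = d
                ndi[i, j] = ndi[j, i] = normalized(d, H[i], H[j])
    return InfoMatrices(di=di, ndi=ndi, mi=mi, nmi=nmi)


def weight_matrix(info: np.ndarray, kind: str = "squared") -> np.ndarray:
    """Interaction weights per pair from an NDI (or NMI) matrix.

    ``squared`` (default) emphasizes the strong links; ``linear`` uses the
    matrix as-is.  The diagonal is zeroed (self-interactions are meaningless).
    """
    w = np.asarray(info, dtype=np.float64) ** (2 if kind == "squared" else 1)
    if kind not in ("squared", "linear"):
        raise ValueError("kind must be 'squared' or 'linear'")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def participation_ratio(w: np.ndarray) -> float:
    """R = (sum w)^2 / (N_pairs sum w^2), both orientations counted.

    1 for uniform weights over all L(L-1) ordered pairs; 1/N_pairs when a
    single ordered entry carries all the weight.
    """
    w = np.asarray(w, dtype=np.float64)
    L = w.shape[0]
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diagonal(w) != 0):
        raise ValueError("self-interactions must be zero")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weight matrix: participation ratio undefined")
    n_pairs = L * (L - 1)
    return float(total**2 / (n_pairs * (w**2).sum()))


def distance_profile(w: np.ndarray, L: int | None = None) -> np.ndarray:
    """Weight per inter-position distance d = 1..L-1, corrected for the
    number of pairs at each distance ((L - d) of them) and normalized to 1."""
    w = np.asarray(w, dtype=np.float64)
    L = w.shape[0] if L is None else L
    prof = np.array([
        sum(w[i, i + d] for i in range(L - d)) / (L - d)
        for d in range(1, L)
    ])
    s = prof.sum()
    return prof / s if s > 0 else prof


def positional_interaction_sum(ndi: np.ndarray,
                               orientation_average: bool = False) -> np.ndarray:
    """Total interaction carried by each position: sum_j NDI_ij.

    With ``orientation_average`` the profile is averaged with its reverse
    (i <-> L+1-i), matching the convention of strand-symmetric reporting.
    """
    totals = np.asarray(ndi, dtype=np.float64).sum(axis=1)
    if orientation_average:
        totals = 0.5 * (totals + totals[::-1])
    return totals


def chi2_expected_self_dkl(n_states: int, N: int) -> float:
    """Asymptotic mean self-DKL: (k-1) / (2 N ln 2) bits for k categories."""
    return (n_states - 1) / (2 * N * LN2)
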