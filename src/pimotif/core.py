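"""Core containers and exact computations for pairwise-interaction site models.

A binding-site model assigns to every L-mer ``s`` over {A,C,G,T} an energy

    E(s) = sum_i h_i(s_i) + sum_{i<j active} J_ij(s_i, s_j)

and a probability P(s) = exp(-E(s)) / Z.  Lower energy means a more probable
(better-bound) sequence.  The position weight matrix (PWM) is the special
case with all couplings zero.

All exact quantities (partition function, model marginals, exact sampling)
are computed by full enumeration.  Because positions not linked by any
coupling are statistically independent, enumeration factorizes over the
connected components of the coupling graph; within a component all 4^m
states are enumerated (streamed in blocks for large components).  This is
exact — no mean-field or pseudo-likelihood approximation anywhere.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

ALPHABET = "ACGT"
#: Hard bound on the number of positions enumerated jointly (4^14 states).
ENUM_MAX_L = 14
#: States per enumeration block when streaming large components.
_BLOCK = 4 ** 12

LN2 = float(np.log(2.0))

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i
_LUT_N = _LUT.copy()
_LUT_N[ord("N")] = -1
_LUT_N[ord("n")] = -1


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as integer indices (A=0, C=1, G=2, T=3).

    Case-insensitive.  Raises ``ValueError`` naming the (1-based) position of
    the first non-ACGT character, including N.
    """
    arr = _LUT[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    bad = np.nonzero(arr < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-ACGT character {seq[pos]!r} at position {pos + 1}"
        )
    return arr


def encode_masked(seq: str) -> np.ndarray:
    """Encode allowing N/n as the mask value -1; other letters must be ACGT."""
    arr = _LUT_N[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    bad = np.nonzero((arr < 0) & (np.frombuffer(
        seq.upper().encode("ascii", "replace"), dtype=np.uint8) != ord("N")))[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-ACGTN character {seq[pos]!r} at position {pos + 1}"
        )
    return arr


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    arr = np.asarray(indices)
    return "".join(ALPHABET[int(a)] for a in arr)


def reverse_complement(indices: np.ndarray) -> np.ndarray:
    """Reverse complement of encoded sequence(s); A<->T, C<->G is ``3 - a``.

    Works on a 1-D site or a 2-D (n, L) batch (reversal along the last axis).
    Mask values (-1) would not map correctly and must be filtered upstream.
    """
    arr = np.asarray(indices)
    return (3 - arr)[..., ::-1]


@dataclass(frozen=True)
class Fragment:
    """A named DNA fragment (upper-case ACGTN string); N marks masked bases."""

    id: str
    sequence: str


@dataclass(frozen=True)
class SiteSet:
    """A sample of N fixed-length binding sites, stored as an (N, L) array.

    Duplicates are kept (multiplicities matter for every estimator).
    """

    seqs: np.ndarray

    def __post_init__(self):
        arr = np.ascontiguousarray(np.asarray(self.seqs, dtype=np.int8))
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("SiteSet requires a non-empty (N, L) array")
        if arr.min() < 0 or arr.max() > 3:
            raise ValueError("site symbols must be in 0..3")
        object.__setattr__(self, "seqs", arr)

    @classmethod
    def from_strings(cls, strings) -> "SiteSet":
        rows = [encode(s) for s in strings]
        if not rows:
            raise ValueError("empty site list")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("sites have unequal lengths")
        return cls(np.vstack(rows))

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    @property
    def N(self) -> int:
        return self.seqs.shape[0]

    def to_strings(self) -> list[str]:
        return [decode(row) for row in self.seqs]

    def unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct sites and their multiplicities."""
        return np.unique(self.seqs, axis=0, return_counts=True)

    def counts_single(self) -> np.ndarray:
        """Per-position nucleotide counts, shape (L, 4)."""
        L = self.L
        out = np.empty((L, 4), dtype=np.int64)
        for i in range(L):
            out[i] = np.bincount(self.seqs[:, i], minlength=4)
        return out

    def counts_pair(self, i: int, j: int) -> np.ndarray:
        """Joint nucleotide counts for positions (i, j), shape (4, 4)."""
        code = self.seqs[:, i].astype(np.int64) * 4 + self.seqs[:, j]
        return np.bincount(code, minlength=16).reshape(4, 4)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position nucleotide probabilities (L, 4).

    ``beta`` records the pseudo-count used during estimation (provenance
    only; the probabilities already include it).
    """

    probs: np.ndarray
    beta: float = 0.0

    def __post_init__(self):
        arr = np.ascontiguousarray(np.asarray(self.probs, dtype=np.float64))
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PWM requires an (L, 4) matrix")
        if arr.min() < 0:
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        object.__setattr__(self, "probs", arr)

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    def log2_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs)

    def consensus(self) -> str:
        return decode(np.argmax(self.probs, axis=1))

    def information_content(self, background: np.ndarray | None = None) -> np.ndarray:
        """Per-column information in bits, relative to ``background`` (or uniform)."""
        q = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / q[None, :]), 0.0)
        return terms.sum(axis=1)


@dataclass(frozen=True)
class PairFrequencies:
    """Single-site marginals f_i(a) and pairwise marginals f_ij(a,b).

    ``pairs`` has shape (L, L, 4, 4); entry [i, j] holds f_ij for i < j and
    its transpose for i > j.  The diagonal is unused (zeros).
    """

    singles: np.ndarray
    pairs: np.ndarray

    @property
    def L(self) -> int:
        return self.singles.shape[0]

    def pair(self, i: int, j: int) -> np.ndarray:
        return self.pairs[i, j]


@dataclass
class PIMParams:
    """Parameters of the pairwise interaction model.

    ``h`` is (L, 4); ``couplings`` maps ordered pairs (i, j), i < j, to
    4x4 blocks J_ij(a, b).  Energies are in natural-log units.
    """

    h: np.ndarray
    couplings: dict = field(default_factory=dict)
    gauge_fixed: bool = False
    logZ_cache: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.h = np.ascontiguousarray(np.asarray(self.h, dtype=np.float64))
        if self.h.ndim != 2 or self.h.shape[1] != 4:
            raise ValueError("h must be an (L, 4) matrix")
        L = self.h.shape[0]
        clean = {}
        for (i, j), block in self.couplings.items():
            if not (0 <= i < j < L):
                raise ValueError(f"coupling pair ({i}, {j}) must satisfy 0 <= i < j < L")
            b = np.ascontiguousarray(np.asarray(block, dtype=np.float64))
            if b.shape != (4, 4):
                raise ValueError("coupling blocks must be 4x4")
            clean[(i, j)] = b
        self.couplings = clean

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def active_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.couplings)

    def partners(self) -> dict[int, list[tuple[int, np.ndarray, bool]]]:
        """Adjacency: position -> [(other, block, is_first_index)]."""
        adj: dict[int, list] = {i: [] for i in range(self.L)}
        for (i, j), block in self.couplings.items():
            adj[i].append((j, block, True))
            adj[j].append((i, block, False))
        return adj

    def copy(self) -> "PIMParams":
        return PIMParams(
            self.h.copy(),
            {p: b.copy() for p, b in self.couplings.items()},
            gauge_fixed=self.gauge_fixed,
        )

    # -- serialization (single JSON document, 1-based positions) ------------

    def to_json(self, meta: dict | None = None) -> str:
        doc = {
            "L": self.L,
            "h": self.h.tolist(),
            "couplings": [
                {"i": i + 1, "j": j + 1, "block": self.couplings[(i, j)].tolist()}
                for (i, j) in self.active_pairs
            ],
            "gauge_fixed": self.gauge_fixed,
            "meta": meta or {},
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PIMParams":
        doc = json.loads(text)
        couplings = {
            (c["i"] - 1, c["j"] - 1): np.array(c["block"], dtype=np.float64)
            for c in doc["couplings"]
        }
        return cls(np.array(doc["h"], dtype=np.float64), couplings,
                   gauge_fixed=bool(doc["gauge_fixed"]))


# ---------------------------------------------------------------------------
# energies and probabilities


def _as_batch(params: PIMParams, sites) -> tuple[np.ndarray, bool]:
    s = np.asarray(sites)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    if S.shape[1] != params.L:
        raise ValueError(
            f"site length {S.shape[1]} does not match model length {params.L}"
        )
    return S, single


def energy(params: PIMParams, sites) -> float | np.ndarray:
    """E(s) for one site (1-D) or a batch (n, L); lower = more probable."""
    S, single = _as_batch(params, sites)
    e = params.h[np.arange(params.L)[None, :], S].sum(axis=1)
    for (i, j), block in params.couplings.items():
        e = e + block[S[:, i], S[:, j]]
    return float(e[0]) if single else e


def components(params: PIMParams) -> list[tuple[int, ...]]:
    """Connected components of the coupling graph, as sorted position tuples."""
    L = params.L
    parent = list(range(L))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in params.couplings:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(L):
        groups.setdefault(find(i), []).append(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


def _comp_pairs(params: PIMParams, comp: tuple[int, ...]):
    cset = set(comp)
    return [((i, j), b) for (i, j), b in params.couplings.items()
            if i in cset and j in cset]


_DIGIT_CACHE: dict[int, np.ndarray] = {}


def _block_digits(comp: tuple[int, ...], start: int, stop: int) -> np.ndarray:
    """Digit matrix (stop-start, m) for states start..stop-1 of a component."""
    m = len(comp)
    if start == 0 and stop == 4 ** m and m <= 10:
        if m not in _DIGIT_CACHE:
            idx = np.arange(4 ** m, dtype=np.int64)
            digits = np.empty((idx.size, m), dtype=np.int8)
            for k in range(m):
                digits[:, k] = (idx >> (2 * (m - 1 - k))) & 3
            _DIGIT_CACHE[m] = digits
        return _DIGIT_CACHE[m]
    idx = np.arange(start, stop, dtype=np.int64)
    digits = np.empty((idx.size, m), dtype=np.int8)
    for k in range(m):
        digits[:, k] = (idx >> (2 * (m - 1 - k))) & 3
    return digits


def _block_energies(params: PIMParams, comp: tuple[int, ...],
                    digits: np.ndarray) -> np.ndarray:
    e = np.zeros(digits.shape[0], dtype=np.float64)
    pos_index = {p: k for k, p in enumerate(comp)}
    for k, p in enumerate(comp):
        e += params.h[p, digits[:, k]]
    for (i, j), block in _comp_pairs(params, comp):
        e += block[digits[:, pos_index[i]], digits[:, pos_index[j]]]
    return e


def _check_enum(m: int):
    if m > ENUM_MAX_L:
        raise ValueError(
            f"enumeration over {m} coupled positions exceeds the bound "
            f"L <= {ENUM_MAX_L}"
        )


def _comp_logZ(params: PIMParams, comp: tuple[int, ...], block: int = _BLOCK) -> float:
    m = len(comp)
    _check_enum(m)
    if m == 1:
        return float(logsumexp(-params.h[comp[0]]))
    n = 4 ** m
    parts = []
    for start in range(0, n, block):
        digits = _block_digits(comp, start, min(start + block, n))
        parts.append(logsumexp(-_block_energies(params, comp, digits)))
    return float(logsumexp(parts))


def log_partition(params: PIMParams, block: int = _BLOCK) -> float:
    """log Z = log sum_s exp(-E(s)) over all 4^L sites (overflow-safe)."""
    _check_enum(params.L)
    lz = sum(_comp_logZ(params, comp, block) for comp in components(params))
    params.logZ_cache = lz
    return lz


def probability(params: PIMParams, sites) -> float | np.ndarray:
    """exp(-E(s)) / Z for one site or a batch."""
    if params.logZ_cache is None:
        log_partition(params)
    e = energy(params, sites)
    return np.exp(-e - params.logZ_cache)


def log2_probability(params: PIMParams, sites) -> float | np.ndarray:
    if params.logZ_cache is None:
        log_partition(params)
    e = energy(params, sites)
    return (-e - params.logZ_cache) / LN2


def _marginals(params: PIMParams, pairs, block: int = _BLOCK):
    """Exact singles (L, 4) and pairwise marginals for the requested pairs.

    ``pairs`` is an iterable of (i, j) with i < j, or None for all pairs.
    """
    L = params.L
    comps = components(params)
    comp_of = {}
    for ci, comp in enumerate(comps):
        for p in comp:
            comp_of[p] = ci
    want = (
        [(i, j) for i in range(L) for j in range(i + 1, L)]
        if pairs is None else sorted(set(pairs))
    )

    singles = np.zeros((L, 4))
    within: dict[tuple[int, int], np.ndarray] = {}
    for ci, comp in enumerate(comps):
        m = len(comp)
        _check_enum(m)
        if m == 1:
            w = np.exp(-params.h[comp[0]])
            singles[comp[0]] = w / w.sum()
            continue
        n = 4 ** m
        pos_index = {p: k for k, p in enumerate(comp)}
        comp_want = [(i, j) for (i, j) in want
                     if comp_of[i] == ci and comp_of[j] == ci]
        lz = _comp_logZ(params, comp, block)
        acc_s = np.zeros((m, 4))
        acc_p = {pr: np.zeros(16) for pr in comp_want}
        for start in range(0, n, block):
            digits = _block_digits(comp, start, min(start + block, n))
            p = np.exp(-_block_energies(params, comp, digits) - lz)
            for k in range(m):
                acc_s[k] += np.bincount(digits[:, k], weights=p, minlength=4)
            for (i, j) in comp_want:
                code = digits[:, pos_index[i]].astype(np.int64) * 4 \
                    + digits[:, pos_index[j]]
                acc_p[(i, j)] += np.bincount(code, weights=p, minlength=16)
        for k, p_ in enumerate(comp):
            singles[p_] = acc_s[k]
        for pr, v in acc_p.items():
            within[pr] = v.reshape(4, 4)

    out: dict[tuple[int, int], np.ndarray] = {}
    for (i, j) in want:
        if (i, j) in within:
            out[(i, j)] = within[(i, j)]
        else:
            out[(i, j)] = np.outer(singles[i], singles[j])
    return singles, out


def model_marginals(params: PIMParams, block: int = _BLOCK) -> PairFrequencies:
    """Exact single and pairwise marginals of the model distribution."""
    L = params.L
    singles, pair_dict = _marginals(params, None, block)
    pairs = np.zeros((L, L, 4, 4))
    for (i, j), f in pair_dict.items():
        pairs[i, j] = f
        pairs[j, i] = f.T
    return PairFrequencies(singles=singles, pairs=pairs)


def pwm_probability(pwm: PWM, sites) -> float | np.ndarray:
    """Independent-positions likelihood: prod_i p_i(s_i)."""
    s = np.asarray(sites)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    if S.shape[1] != pwm.L:
        raise ValueError(
            f"site length {S.shape[1]} does not match PWM length {pwm.L}"
        )
    p = pwm.probs[np.arange(pwm.L)[None, :], S].prod(axis=1)
    return float(p[0]) if single else p


def pwm_log2_probability(pwm: PWM, sites) -> float | np.ndarray:
    s = np.asarray(sites)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    if S.shape[1] != pwm.L:
        raise ValueError("site length does not match PWM length")
    lp = pwm.log2_probs()[np.arange(pwm.L)[None, :], S].sum(axis=1)
    return float(lp[0]) if single else lp


def pwm_to_pim(pwm: PWM) -> PIMParams:
    """The coupling-free model with the same distribution: h_i = -ln p_i."""
    with np.errstate(divide="ignore"):
        h = -np.log(pwm.probs)
    return PIMParams(h)
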