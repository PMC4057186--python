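"""Synthetic data: exact model sampling, Markov backgrounds with CpG
depletion, and planted-site fragment construction.

These generators emulate the structure of ChIP peak data — fragments of a
few hundred base pairs with nucleotide-biased, dinucleotide-correlated
background and one or a few genuine binding sites each — so the whole
inference workflow can be exercised with a known ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ALPHABET,
    PWM,
    Fragment,
    PIMParams,
    SiteSet,
    _block_digits,
    _block_energies,
    _check_enum,
    components,
    decode,
    reverse_complement,
)

#: Default background composition: mildly AT-rich, as in mammalian peaks.
DEFAULT_BASE_FREQS = np.array([0.3, 0.2, 0.2, 0.3])


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic dataset.

    Defaults mirror the real-data setting the package targets: sites of
    length 12 planted once per fragment in 300-bp CpG-depleted fragments,
    1000 fragments per factor.
    """

    L: int = 12
    fragment_length: int = 300
    n_fragments: int = 1000
    base_freqs: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASE_FREQS.copy())
    cpg_bias: float = 0.5
    sites_per_fragment: int = 1
    seed: int = 0


def sample_sites(model, n: int, seed: int) -> SiteSet:
    """n i.i.d. draws from the exact model distribution.

    For a pairwise model the draw factorizes over coupling-graph components,
    each sampled from its fully enumerated joint; for a PWM each position is
    an independent categorical draw.  No Markov-chain approximation anywhere.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, PWM):
        L = model.L
        out = np.empty((n, L), dtype=np.int8)
        for i in range(L):
            out[:, i] = rng.choice(4, size=n, p=model.probs[i])
        return SiteSet(out)
    if not isinstance(model, PIMParams):
        raise TypeError("model must be a PWM or PIMParams")
    L = model.L
    out = np.empty((n, L), dtype=np.int8)
    for comp in components(model):
        m = len(comp)
        _check_enum(m)
        digits = _block_digits(comp, 0, 4 ** m)
        e = _block_energies(model, comp, digits)
        p = np.exp(-(e - e.min()))
        p /= p.sum()
        draws = rng.choice(4 ** m, size=n, p=p)
        out[:, list(comp)] = digits[draws]
    return SiteSet(out)


def background_transitions(base_freqs, cpg_bias: float) -> np.ndarray:
    """First-order transition matrix with stationary ``base_freqs`` and the
    C->G transition suppressed by ``1 - cpg_bias``.

    Construction: start from the independent dinucleotide joint, damp the CG
    cell, then rebalance by iterative proportional fitting so both marginals
    equal ``base_freqs`` exactly; the row-normalized joint is the transition
    matrix, and ``base_freqs`` is its stationary distribution by construction.
    """
    pi = np.asarray(base_freqs, dtype=np.float64)
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must be a positive probability 4-vector")
    if not 0 <= cpg_bias < 1:
        raise ValueError("cpg_bias must be in [0, 1)")
    D = np.outer(pi, pi)
    D[1, 2] *= (1.0 - cpg_bias)  # C followed by G
    for _ in range(500):
        D *= (pi / D.sum(axis=1))[:, None]
        D *= (pi / D.sum(axis=0))[None, :]
        if max(np.abs(D.sum(axis=1) - pi).max(),
               np.abs(D.sum(axis=0) - pi).max()) < 1e-14:
            break
    return D / D.sum(axis=1, keepdims=True)


def sample_background(
    length: int,
    n_fragments: int,
    base_freqs=None,
    cpg_bias: float = 0.0,
    seed: int = 0,
    prefix: str = "frag",
) -> list[Fragment]:
    """Fragments from a stationary first-order Markov chain.

    ``cpg_bias = 0`` reduces to i.i.d. letters; positive values deplete the
    CG dinucleotide below the product of its marginals while keeping the
    single-nucleotide composition at ``base_freqs``.
    """
    pi = DEFAULT_BASE_FREQS if base_freqs is None else np.asarray(base_freqs,
                                                                 float)
    T = background_transitions(pi, cpg_bias)
    cumT = T.cumsum(axis=1)
    rng = np.random.default_rng(seed)
    seqs = np.empty((n_fragments, length), dtype=np.int8)
    seqs[:, 0] = rng.choice(4, size=n_fragments, p=pi)
    u = rng.random((n_fragments, length))
    for t in range(1, length):
        rows = cumT[seqs[:, t - 1]]
        seqs[:, t] = (u[:, t, None] >= rows).sum(axis=1)
    letters = np.array(list(ALPHABET))
    return [Fragment(f"{prefix}{k:05d}", "".join(letters[seqs[k]]))
            for k in range(n_fragments)]


def plant_sites(
    fragments: list[Fragment],
    model,
    sites_per_fragment: int = 1,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[list[Fragment], pd.DataFrame]:
    """Write model-sampled sites into fragments at random non-overlapping
    offsets and strands.

    Minus-strand sites are written as their reverse complement; the truth
    table records the site in its scored (matched) orientation, with the
    0-based offset of the fragment slice.  Columns: fragment, offset, strand,
    site.
    """
    L = model.L
    rng = np.random.default_rng(seed)
    n_sites = sites_per_fragment * len(fragments)
    drawn = sample_sites(model, max(n_sites, 1), int(rng.integers(2**31))) \
        if n_sites else None
    rows = []
    out = []
    k = 0
    for frag in fragments:
        seq = np.array(list(frag.sequence))
        flen = len(seq)
        if sites_per_fragment and flen < L:
            raise ValueError(f"fragment {frag.id} shorter than site length")
        offsets: list[int] = []
        for _ in range(sites_per_fragment):
            for attempt in range(max_tries):
                off = int(rng.integers(flen - L + 1))
                if all(abs(off - o) >= L for o in offsets):
                    offsets.append(off)
                    break
            else:
                raise ValueError(
                    f"could not place {sites_per_fragment} non-overlapping "
                    f"sites in fragment {frag.id}"
                )
        for off in offsets:
            site = drawn.seqs[k]
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            written = site if strand == "+" else reverse_complement(site)
            seq[off:off + L] = list(decode(written))
            rows.append({"fragment": frag.id, "offset": off,
                         "strand": strand, "site": decode(site)})
        out.append(Fragment(frag.id, "".join(seq)))
    truth = pd.DataFrame(rows, columns=["fragment", "offset", "strand", "site"])
    return out, truth


def demo_pim(L: int = 12) -> PIMParams:
    """A sharp, non-palindromic two-basin demonstration model.

    Ten positions strongly prefer one consensus letter (field gap 3, about
    0.87 probability each); the central pair carries a strong coupling that
    makes exactly two dinucleotide variants (CA and TG) dominate, so the
    landscape has two basins of comparable weight.  Total information content
    exceeds 8 bits, as for a well-defined in vivo motif.
    """
    if L < 4:
        raise ValueError("demo model needs L >= 4")
    consensus = "ACGGAATGACCT"
    h = np.full((L, 4), 0.75)
    for i in range(L):
        h[i, "ACGT".index(consensus[i % len(consensus)])] = -2.25
    c1, c2 = L // 2 - 1, L // 2
    h[c1] = 0.0
    h[c2] = 0.0
    J = np.zeros((4, 4))
    J[1, 0] = -4.0  # C,A
    J[3, 2] = -4.0  # T,G
    return PIMParams(h, {(c1, c2): J})


def simulate_dataset(config: SynthConfig, model=None):
    """Full synthetic study: background fragments with planted model sites.

    Returns (fragments, truth table, planted model).
    """
    planted = demo_pim(config.L) if model is None else model
    rng = np.random.default_rng(config.seed)
    frags = sample_background(
        config.fragment_length, config.n_fragments,
        base_freqs=config.base_freqs, cpg_bias=config.cpg_bias,
        seed=int(rng.integers(2**31)),
    )
    frags, truth = plant_sites(
        frags, planted, sites_per_fragment=config.sites_per_fragment,
        seed=int(rng.integers(2**31)),
    )
    return frags, truth, planted
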