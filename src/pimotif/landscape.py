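"""Energy-landscape analysis: local minima, basins of attraction, basin PWMs.

With couplings, the energy over sequence space can have several local minima
(probability peaks).  Descending from a site by energy-lowering
single-nucleotide substitutions assigns it to a basin; the sites of a sample
then split into weighted basins, each summarized by its own PWM and matched
to the nearest mixture component by KL divergence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PWM, PIMParams, SiteSet, decode, energy
from .inference import BETA_SINGLE, estimate_pwm
from .mixture import MixtureModel


def _delta_energies(params: PIMParams, site: np.ndarray,
                    adj) -> np.ndarray:
    """(L, 4) matrix of energy changes for substituting each letter at each
    position (zero for the current letter)."""
    L = params.L
    d = params.h[np.arange(L), :] - params.h[np.arange(L), site][:, None]
    for i in range(L):
        for (j, block, first) in adj[i]:
            col = block[:, site[j]] if first else block[site[j], :]
            d[i] += col - col[site[i]]
    return d


def descend(
    params: PIMParams,
    site,
    mode: str = "deterministic",
    seed: int | None = None,
    max_steps: int | None = None,
) -> np.ndarray:
    """Walk downhill by strictly energy-lowering single substitutions.

    ``deterministic`` takes the steepest move (ties: lowest position, then
    alphabet order); ``random`` picks uniformly among all strictly improving
    moves.  Returns the reached local minimum (possibly the input itself).
    """
    if mode not in ("deterministic", "random"):
        raise ValueError("mode must be 'deterministic' or 'random'")
    rng = np.random.default_rng(seed)
    s = np.array(site, dtype=np.int8).copy()
    L = params.L
    adj = params.partners()
    limit = max_steps if max_steps is not None else 3 * L * L
    for _ in range(limit):
        d = _delta_energies(params, s, adj)
        improving = d < 0
        if not improving.any():
            return s
        if mode == "deterministic":
            flat = int(d.argmin())
            i, a = divmod(flat, 4)
        else:
            cand = np.argwhere(improving)
            i, a = cand[rng.integers(cand.shape[0])]
        s[i] = a
    raise RuntimeError("descent did not terminate within the step bound")


@dataclass(frozen=True)
class Basin:
    """A local minimum with the sites that descend into it."""

    minimum: np.ndarray
    energy: float
    members: SiteSet
    weight: float

    @property
    def sequence(self) -> str:
        return decode(self.minimum)


def find_basins(
    params: PIMParams,
    sites: SiteSet,
    mode: str = "deterministic",
    seed: int | None = None,
) -> list[Basin]:
    """Descend every site once and group by terminal minimum.

    Basins are sorted by decreasing weight (member fraction of N); weights
    sum to 1.
    """
    rng = np.random.default_rng(seed)
    uniq, counts = sites.unique()
    groups: dict[tuple, list[int]] = {}
    for u in range(uniq.shape[0]):
        sub_seed = int(rng.integers(2**31)) if mode == "random" else None
        term = descend(params, uniq[u], mode=mode, seed=sub_seed)
        groups.setdefault(tuple(int(x) for x in term), []).append(u)
    basins = []
    for term, idxs in groups.items():
        mask_counts = counts[idxs]
        members = np.repeat(uniq[idxs], mask_counts, axis=0)
        minimum = np.array(term, dtype=np.int8)
        basins.append(Basin(
            minimum=minimum,
            energy=float(energy(params, minimum)),
            members=SiteSet(members),
            weight=float(mask_counts.sum() / sites.N),
        ))
    basins.sort(key=lambda b: (-b.weight, b.sequence))
    return basins


def local_minima(params: PIMParams) -> list[np.ndarray]:
    """All single-substitution-stable states, by exhaustive enumeration.

    Intended for small L (the full 4^L states are checked); a state is a
    minimum when no single substitution strictly lowers its energy.
    """
    from .core import _block_digits, _block_energies, _check_enum

    L = params.L
    if L > 8:
        raise ValueError("exhaustive minima enumeration is limited to L <= 8")
    _check_enum(L)
    comp = tuple(range(L))
    digits = _block_digits(comp, 0, 4 ** L)
    E = _block_energies(params, comp, digits)
    idx = np.arange(4 ** L, dtype=np.int64)
    stable = np.ones(4 ** L, dtype=bool)
    for i in range(L):
        shift = 2 * (L - 1 - i)
        cur = (idx >> shift) & 3
        for b in range(4):
            neighbor = idx + ((b - cur) << shift)
            stable &= ~(E[neighbor] < E)
    return [digits[k].copy() for k in np.nonzero(stable)[0]]


def basin_pwms(basins: list[Basin],
               beta: float = BETA_SINGLE) -> list[tuple[PWM, float]]:
    """One PWM per basin (pseudo-counted), with the basin weight carried over."""
    if not basins:
        raise ValueError("no basins supplied")
    return [(estimate_pwm(b.members, beta=beta), b.weight) for b in basins]


def pwm_dkl(p: PWM, q: PWM) -> float:
    """Position-summed KL divergence between two PWMs, in bits.

    For independent-position models this equals the KL divergence of the full
    sequence distributions.
    """
    if p.L != q.L:
        raise ValueError("PWMs must share L")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p.probs > 0, p.probs * np.log2(p.probs / q.probs), 0.0)
    return float(terms.sum())


def match_basins_to_mixture(
    pwms: list[tuple[PWM, float]],
    mixture: MixtureModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each basin PWM to its nearest mixture component by KL distance.

    Returns (assignment, dkl_matrix) with dkl_matrix[b, k] the divergence of
    basin b from mixture component k.
    """
    D = np.array([
        [pwm_dkl(pwm, comp) for comp in mixture.components]
        for (pwm, _) in pwms
    ])
    return D.argmin(axis=1), D


def basin_report(
    basins: list[Basin],
    mixture: MixtureModel | None = None,
    beta: float = BETA_SINGLE,
) -> pd.DataFrame:
    """Tabular summary: minimum sequence, energy, weight (+ mixture match)."""
    rows = [{
        "minimum": b.sequence,
        "energy": b.energy,
        "weight": b.weight,
    } for b in basins]
    frame = pd.DataFrame(rows)
    if mixture is not None:
        pwms = basin_pwms(basins, beta=beta)
        assign, D = match_basins_to_mixture(pwms, mixture)
        frame["component"] = assign + 1
        frame["dkl_bits"] = D[np.arange(len(basins)), assign]
    return frame
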