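"""Self-consistent site/model refinement on bound fragments.

The workflow alternates two steps until the selected binding-site set is
stable: (1) scan both strands of every fragment with the current model
against a background model, keep fragments whose best window clears a
cutoff chosen so that a set fraction (default 50%) of fragments retain at
least one predicted site; (2) relearn the model on the selected sites.
Scores are log2 probability ratios (bits) between the motif model and the
background.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    PWM,
    Fragment,
    PIMParams,
    SiteSet,
    decode,
    encode_masked,
    log2_probability,
    pwm_log2_probability,
)
from .inference import BETA_SINGLE, build_pim, estimate_pwm


def _model_log2(model, windows: np.ndarray) -> np.ndarray:
    from .mixture import MixtureModel

    if isinstance(model, PIMParams):
        return np.atleast_1d(log2_probability(model, windows))
    if isinstance(model, PWM):
        return np.atleast_1d(pwm_log2_probability(model, windows))
    if isinstance(model, MixtureModel):
        return np.atleast_1d(model.log2_probability(windows))
    raise TypeError(f"unsupported model type {type(model)!r}")


def _model_length(model) -> int:
    return model.L


def collect_windows(fragments: list[Fragment], L: int) -> np.ndarray:
    """All valid L-windows from both strands of all fragments, as (n, L).

    Windows containing masked bases (N) are skipped; each kept window also
    contributes its reverse complement (the minus-strand read of the slice).
    """
    blocks = []
    for frag in fragments:
        enc = encode_masked(frag.sequence)
        if enc.size < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = win[(win >= 0).all(axis=1)]
        if valid.size:
            blocks.append(valid)
            blocks.append((3 - valid)[:, ::-1])
    if not blocks:
        raise ValueError("no valid windows in the supplied fragments")
    return np.ascontiguousarray(np.vstack(blocks))


def learn_background(
    fragments: list[Fragment],
    L: int,
    order: str = "pwm",
    beta: float = BETA_SINGLE,
    max_sites: int | None = 20000,
    seed: int = 0,
):
    """Background model from every L-window on both strands.

    ``order="pwm"`` returns the position-independent nucleotide composition
    (identical rows; both-strand counting makes it exactly strand-symmetric,
    p(A)=p(T) and p(C)=p(G)).  ``order="pim"`` fits a full pairwise model on
    the window set (subsampled to ``max_sites`` windows for tractability).
    """
    windows = collect_windows(fragments, L)
    if order == "pwm":
        counts = np.bincount(windows.ravel(), minlength=4).astype(np.float64)
        freqs = (counts + beta) / (counts.sum() + 4 * beta)
        return PWM(np.tile(freqs, (L, 1)), beta=beta)
    if order == "pim":
        if max_sites is not None and windows.shape[0] > max_sites:
            rng = np.random.default_rng(seed)
            windows = windows[rng.choice(windows.shape[0], max_sites,
                                         replace=False)]
        params, _ = build_pim(SiteSet(windows))
        return params
    raise ValueError("order must be 'pwm' or 'pim'")


def background_freqs(background) -> np.ndarray:
    """Single-nucleotide background composition of a background model."""
    if isinstance(background, PWM):
        return background.probs.mean(axis=0)
    if isinstance(background, PIMParams):
        from .core import model_marginals

        return model_marginals(background).singles.mean(axis=0)
    raise TypeError("background must be a PWM or PIMParams")


def score_site(model, background, site) -> float:
    """log2( P_model(site) / P_background(site) ), in bits."""
    s = np.atleast_2d(np.asarray(site))
    return float(_model_log2(model, s)[0] - _model_log2(background, s)[0])


@dataclass
class ScanResult:
    """Vectorized scan output: one row per scored window.

    ``windows`` holds the matched-orientation L-mer (minus-strand rows are
    already reverse-complemented); ``offsets`` are 0-based starts of the
    fragment slice on the given strand's + coordinates.
    """

    frag_ids: list[str]
    frag_index: np.ndarray
    offsets: np.ndarray
    strands: np.ndarray
    scores: np.ndarray
    windows: np.ndarray

    @property
    def n(self) -> int:
        return self.scores.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fragment": [self.frag_ids[k] for k in self.frag_index],
            "offset": self.offsets,
            "strand": self.strands,
            "score": self.scores,
            "site": [decode(w) for w in self.windows],
        })

    def best_per_fragment(self) -> np.ndarray:
        """Best score per fragment (fragments with no window get -inf)."""
        best = np.full(len(self.frag_ids), -np.inf)
        np.maximum.at(best, self.frag_index, self.scores)
        return best


@dataclass(frozen=True)
class ScoredSite:
    """A single scored window, for external reporting."""

    fragment: str
    offset: int
    strand: str
    site: str
    score: float


def scan(model, background, fragments: list[Fragment]) -> ScanResult:
    """Score every L-window on both strands of every fragment.

    Windows containing masked (N) bases are skipped.  Minus-strand windows
    are the reverse complements of the fragment slices, reported at the
    slice's 0-based offset.
    """
    L = _model_length(model)
    fids, fidx, offs, strands, wins = [], [], [], [], []
    for k, frag in enumerate(fragments):
        fids.append(frag.id)
        enc = encode_masked(frag.sequence)
        if enc.size < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = np.nonzero((win >= 0).all(axis=1))[0]
        if valid.size == 0:
            continue
        fwd = win[valid]
        rev = np.ascontiguousarray((3 - fwd)[:, ::-1])
        wins.append(fwd)
        wins.append(rev)
        offs.append(valid)
        offs.append(valid)
        fidx.append(np.full(2 * valid.size, k, dtype=np.int64))
        strands.append(np.full(valid.size, "+", dtype="<U1"))
        strands.append(np.full(valid.size, "-", dtype="<U1"))
    if not wins:
        return ScanResult(fids, np.empty(0, np.int64), np.empty(0, np.int64),
                          np.empty(0, "<U1"), np.empty(0),
                          np.empty((0, L), np.int8))
    W = np.ascontiguousarray(np.vstack(wins))
    scores = _model_log2(model, W) - _model_log2(background, W)
    return ScanResult(
        frag_ids=fids,
        frag_index=np.concatenate(fidx),
        offsets=np.concatenate(offs).astype(np.int64),
        strands=np.concatenate(strands),
        scores=np.asarray(scores, dtype=np.float64),
        windows=W,
    )


def choose_cutoff(per_fragment_best_scores, tpr: float = 0.5) -> float:
    """The largest threshold keeping >= ceil(tpr * M) fragments.

    Equivalently, the ceil(tpr*M)-th largest per-fragment best score.
    """
    best = np.asarray(per_fragment_best_scores, dtype=np.float64)
    best = best[np.isfinite(best)]
    if best.size == 0:
        raise ValueError("need at least one fragment with a score")
    k = max(1, math.ceil(tpr * best.size))
    return float(np.sort(best)[::-1][k - 1])


def select_training_sites(result: ScanResult, cutoff: float) -> np.ndarray:
    """Indices of the above-cutoff windows kept for model learning.

    Within each fragment, above-cutoff windows are taken greedily by
    descending score with non-overlapping intervals (strand-agnostic;
    overlap means the [offset, offset+L) slices intersect).
    """
    L = result.windows.shape[1]
    keep = []
    above = np.nonzero(result.scores >= cutoff)[0]
    order = above[np.lexsort((
        np.where(result.strands[above] == "+", 0, 1),
        result.offsets[above],
        -result.scores[above],
    ))]
    taken: dict[int, list[int]] = {}
    for idx in order:
        f = int(result.frag_index[idx])
        off = int(result.offsets[idx])
        occupied = taken.setdefault(f, [])
        if all(abs(off - o) >= L for o in occupied):
            occupied.append(off)
            keep.append(idx)
    return np.sort(np.asarray(keep, dtype=np.int64))


def recenter_pwm(pwm: PWM, background_freqs: np.ndarray, L: int = 12) -> PWM:
    """Re-window a PWM of any length to length L around its information
    center of mass.

    Column information is measured against the background composition; the
    center of mass is rounded half-up (midpoint for an uninformative input).
    Columns outside the input's coverage are filled with the background.
    """
    q = np.asarray(background_freqs, dtype=np.float64)
    ic = pwm.information_content(background=q)
    total = ic.sum()
    if total <= 1e-12:
        # no information anywhere: all-background output
        return PWM(np.tile(q, (L, 1)), beta=pwm.beta)
    center = float((np.arange(pwm.L) * ic).sum() / total)
    # integer shift placing the center of mass at the window midpoint
    # ((L-1)/2), rounded half-up
    start = math.floor(center - (L - 1) / 2.0 + 0.5)
    rows = np.empty((L, 4))
    for k in range(L):
        src = start + k
        rows[k] = pwm.probs[src] if 0 <= src < pwm.L else q
    return PWM(rows, beta=pwm.beta)


@dataclass
class RefinementResult:
    model: object
    sites: SiteSet
    selected: pd.DataFrame
    history: list[dict] = field(default_factory=list)
    converged: bool = False
    rounds: int = 0


def _builder(kind: str, sites: SiteSet, bg_freqs: np.ndarray, L: int,
             beta: float, seed: int, mixture_k_max: int):
    if kind == "pwm":
        return recenter_pwm(estimate_pwm(sites, beta=beta), bg_freqs, L)
    if kind == "pim":
        return build_pim(sites, "all")[0]
    if kind == "nnm":
        return build_pim(sites, "nearest_neighbor")[0]
    if kind == "mixture":
        from .mixture import select_mixture

        return select_mixture(sites, mixture_k_max, beta=beta, seed=seed)[0]
    raise ValueError("model_builder must be pwm|pim|nnm|mixture")


def iterate_refinement(
    initial_pwm: PWM,
    fragments: list[Fragment],
    model_builder: str = "pwm",
    L: int = 12,
    tpr: float = 0.5,
    max_rounds: int = 20,
    beta: float = BETA_SINGLE,
    seed: int = 0,
    background=None,
    mixture_k_max: int = 5,
) -> RefinementResult:
    """Alternate site selection and model learning to a fixed point.

    Convergence is exact equality of the selected (fragment, offset, strand)
    multiset between successive rounds; the returned model's own selection
    reproduces the returned site set.  The history records, per round, the
    cutoff, site count, and Jaccard overlap with the previous selection.
    """
    if not fragments:
        raise ValueError("no fragments supplied")
    bg = background if background is not None else learn_background(
        fragments, L, "pwm", beta=beta)
    bg_freqs = background_freqs(bg)
    model = recenter_pwm(initial_pwm, bg_freqs, L)
    history0: list[dict] = []
    if model_builder != "pwm":
        # Establish a stable, centered window frame with the PWM stage first
        # (its per-round re-centering corrects frame drift); then refine with
        # the richer model from that frame.
        pre = iterate_refinement(initial_pwm, fragments, "pwm", L=L, tpr=tpr,
                                 max_rounds=max_rounds, beta=beta, seed=seed,
                                 background=bg)
        model = pre.model
        history0 = [dict(h, stage="pwm") for h in pre.history]
    prev_key: tuple | None = None
    history: list[dict] = history0
    sites = None
    sel_frame = None
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        result = scan(model, bg, fragments)
        cutoff = choose_cutoff(result.best_per_fragment(), tpr=tpr)
        sel = select_training_sites(result, cutoff)
        key = tuple(sorted(
            (result.frag_ids[result.frag_index[i]], int(result.offsets[i]),
             str(result.strands[i]))
            for i in sel
        ))
        jac = None
        if prev_key is not None:
            a, b = set(prev_key), set(key)
            jac = len(a & b) / len(a | b) if (a | b) else 1.0
        history.append({"round": rounds, "cutoff": cutoff,
                        "n_sites": int(sel.size), "jaccard": jac})
        sites = SiteSet(result.windows[sel])
        sel_frame = pd.DataFrame({
            "fragment": [result.frag_ids[result.frag_index[i]] for i in sel],
            "offset": result.offsets[sel],
            "strand": result.strands[sel],
            "score": result.scores[sel],
            "site": [decode(result.windows[i]) for i in sel],
        })
        if key == prev_key:
            converged = True
            break
        prev_key = key
        model = _builder(model_builder, sites, bg_freqs, L, beta, seed,
                         mixture_k_max)
    return RefinementResult(model=model, sites=sites, selected=sel_frame,
                            history=history, converged=converged,
                            rounds=rounds)


def overlap_report(selected_a: pd.DataFrame, selected_b: pd.DataFrame,
                   top_k: int = 1) -> dict:
    """Shared fraction of per-fragment best sites between two predictions.

    Sites are identified by (fragment, offset, strand); each fragment
    contributes its ``top_k`` best-scoring sites.  Returns the shared
    proportion and its complement (the "difference").
    """
    def tops(frame: pd.DataFrame) -> set:
        out = set()
        for fid, grp in frame.groupby("fragment"):
            best = grp.nlargest(top_k, "score")
            out |= {(fid, int(r.offset), r.strand)
                    for r in best.itertuples()}
        return out

    A, B = tops(selected_a), tops(selected_b)
    denom = max(len(A), len(B))
    shared = len(A & B) / denom if denom else 1.0
    return {"shared": shared, "difference": 1.0 - shared}
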