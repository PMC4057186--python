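"""Mixture-of-PWMs baseline, learned by Hamming-distance K-means.

Sites are clustered around consensus sequences (per-position modal
nucleotide); a PWM is estimated on each cluster and weighted by its size.
The number of components is selected by BIC, with the mixture likelihood
computed from the mixture distribution itself (hard clustering is only the
estimation device).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import PWM, SiteSet, pwm_log2_probability, LN2
from .inference import BETA_SINGLE, bic, estimate_pwm


@dataclass(frozen=True)
class MixtureModel:
    """K component PWMs with mixing weights pi_k (summing to 1)."""

    components: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or len(self.components) != w.size:
            raise ValueError("one weight per component required")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        Ls = {c.L for c in self.components}
        if len(Ls) != 1:
            raise ValueError("all components must share L")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def L(self) -> int:
        return self.components[0].L

    def log2_probability(self, sites) -> np.ndarray | float:
        """log2 of the mixture probability sum_k pi_k P_k(s)."""
        s = np.asarray(sites)
        single = s.ndim == 1
        S = np.atleast_2d(s)
        comp = np.stack([pwm_log2_probability(c, S) for c in self.components])
        lp = logsumexp(comp * LN2, axis=0, b=self.weights[:, None]) / LN2
        return float(lp[0]) if single else lp

    def probability(self, sites):
        return 2.0 ** np.asarray(self.log2_probability(sites))

    def to_json(self) -> str:
        doc = {
            "K": self.K,
            "weights": self.weights.tolist(),
            "components": [c.probs.tolist() for c in self.components],
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        doc = json.loads(text)
        return cls(tuple(PWM(np.array(p)) for p in doc["components"]),
                   np.array(doc["weights"]))


def _consensus(seqs: np.ndarray) -> np.ndarray:
    """Per-position modal nucleotide; ties break toward the alphabet order."""
    counts = np.stack([np.bincount(seqs[:, i], minlength=4)
                       for i in range(seqs.shape[1])])
    return counts.argmax(axis=1).astype(np.int8)


def _hamming_to(seqs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return (seqs[:, None, :] != centroids[None, :, :]).sum(axis=2)


def kmeans_hamming(
    sites: SiteSet,
    K: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Hamming K-means with consensus centroids.

    Returns (assignment, centroids, objective_history) for the best of
    ``n_restarts`` runs by total within-cluster Hamming distance.  Empty
    clusters are re-seeded from the farthest points.  Assignment ties go to
    the lowest cluster index.
    """
    seqs = sites.seqs
    uniq = np.unique(seqs, axis=0)
    if not 1 <= K <= uniq.shape[0]:
        raise ValueError(
            f"K={K} must be between 1 and the number of distinct sites "
            f"({uniq.shape[0]})"
        )
    master = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        centroids = uniq[rng.choice(uniq.shape[0], size=K, replace=False)].copy()
        history = []
        assign = None
        for _ in range(max_iter):
            d = _hamming_to(seqs, centroids)
            assign = d.argmin(axis=1)
            # re-seed empty clusters from the points farthest from their centroid
            for k in range(K):
                if not np.any(assign == k):
                    far = d[np.arange(len(assign)), assign].argmax()
                    centroids[k] = seqs[far]
                    assign = _hamming_to(seqs, centroids).argmin(axis=1)
            obj = int(_hamming_to(seqs, centroids)[np.arange(len(assign)),
                                                   assign].sum())
            history.append(obj)
            new_centroids = centroids.copy()
            for k in range(K):
                members = seqs[assign == k]
                if members.size:
                    new_centroids[k] = _consensus(members)
            if np.array_equal(new_centroids, centroids):
                break
            centroids = new_centroids
        obj = int(_hamming_to(seqs, centroids)[np.arange(len(assign)),
                                               assign].sum())
        if best is None or obj < best[0]:
            best = (obj, assign.copy(), centroids.copy(), history)
    _, assign, centroids, history = best
    return assign, centroids, history


def fit_mixture(
    sites: SiteSet,
    K: int,
    beta: float = BETA_SINGLE,
    seed: int = 0,
    n_restarts: int = 10,
) -> MixtureModel:
    """Cluster the sites, estimate a PWM per cluster, weight by cluster size."""
    assign, _, _ = kmeans_hamming(sites, K, seed=seed, n_restarts=n_restarts)
    comps, weights = [], []
    for k in range(K):
        members = sites.seqs[assign == k]
        comps.append(estimate_pwm(SiteSet(members), beta=beta))
        weights.append(members.shape[0] / sites.N)
    return MixtureModel(tuple(comps), np.array(weights))


def mixture_param_count(K: int, L: int) -> int:
    """K PWMs with 3L free entries each, plus K-1 free weights."""
    if K < 1 or L < 1:
        raise ValueError("K and L must be >= 1")
    return K * 3 * L + (K - 1)


def mixture_nll(model: MixtureModel, sites: SiteSet) -> float:
    return float(-(model.log2_probability(sites.seqs) * LN2).sum())


def select_mixture(
    sites: SiteSet,
    K_max: int,
    beta: float = BETA_SINGLE,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit K = 1..K_max and return the BIC-minimal mixture with the trace."""
    rows = []
    best = None
    n_distinct = np.unique(sites.seqs, axis=0).shape[0]
    for K in range(1, K_max + 1):
        if K > n_distinct:
            break
        model = fit_mixture(sites, K, beta=beta, seed=seed + K,
                            n_restarts=n_restarts)
        nll = mixture_nll(model, sites)
        b = bic(nll, mixture_param_count(K, sites.L), sites.N)
        rows.append({"K": K, "nll": nll, "bic": b})
        if best is None or b < best[0]:
            best = (b, model)
    return best[1], pd.DataFrame(rows)
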