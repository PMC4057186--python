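"""Hopfield-style spectral decomposition of the coupling matrix.

The sparse i<j coupling blocks extend to a full symmetric 4L x 4L matrix
J-hat over (position, letter) indices, with zero within-position blocks.  Its
eigenvectors ("patterns") and real eigenvalues rewrite the pairwise energy as
a sum over patterns; keeping only the few largest-|eigenvalue| patterns gives
low-rank approximations of the interaction structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PIMParams


def build_full_matrix(params: PIMParams) -> np.ndarray:
    """Symmetric (4L, 4L) extension of the couplings; index = 4*i + a.

    Satisfies E(s) = sum_i h_i(s_i) + 0.5 * x(s)^T J-hat x(s) with x(s) the
    one-hot indicator vector of the sequence.
    """
    L = params.L
    M = np.zeros((4 * L, 4 * L))
    for (i, j), block in params.couplings.items():
        M[4 * i:4 * i + 4, 4 * j:4 * j + 4] = block
        M[4 * j:4 * j + 4, 4 * i:4 * i + 4] = block.T
    return M


def indicator(sites: np.ndarray, L: int) -> np.ndarray:
    """One-hot 4L indicator vector(s) x(s) of encoded sequence(s)."""
    s = np.atleast_2d(np.asarray(sites))
    x = np.zeros((s.shape[0], 4 * L))
    cols = 4 * np.arange(L)[None, :] + s
    x[np.arange(s.shape[0])[:, None], cols] = 1.0
    return x if np.asarray(sites).ndim == 2 else x[0]


@dataclass(frozen=True)
class CouplingSpectrum:
    """Eigendecomposition of J-hat, ranked by decreasing |eigenvalue|.

    ``patterns`` holds orthonormal eigenvectors as columns, sign-fixed so the
    largest-magnitude coordinate of each pattern is positive.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    patterns: np.ndarray

    @property
    def size(self) -> int:
        return self.eigenvalues.size


def decompose(matrix: np.ndarray) -> CouplingSpectrum:
    """Eigendecompose a symmetric coupling matrix.

    Ordering: decreasing |lambda|, then decreasing lambda, then index.
    """
    M = np.asarray(matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(M)
    order = np.lexsort((np.arange(w.size), -w, -np.abs(w)))
    w = w[order]
    v = v[:, order]
    flip = v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])] < 0
    v[:, flip] *= -1
    return CouplingSpectrum(matrix=M, eigenvalues=w, patterns=v)


def spectrum(params: PIMParams) -> CouplingSpectrum:
    return decompose(build_full_matrix(params))


def _zero_diagonal_blocks(M: np.ndarray) -> np.ndarray:
    out = M.copy()
    L = M.shape[0] // 4
    for i in range(L):
        out[4 * i:4 * i + 4, 4 * i:4 * i + 4] = 0.0
    return out


def truncate(spec: CouplingSpectrum, p: int) -> np.ndarray:
    """Rank-p reconstruction from the p largest-|lambda| patterns.

    Within-position diagonal blocks (a truncation artifact) are re-zeroed so
    the result is again a valid coupling matrix; p = 4L reproduces the input
    exactly and p = 0 gives the zero matrix.
    """
    if not 0 <= p <= spec.size:
        raise ValueError(f"p must be in 0..{spec.size}")
    if p == 0:
        return np.zeros_like(spec.matrix)
    V = spec.patterns[:, :p]
    Jp = (V * spec.eigenvalues[:p]) @ V.T
    if p == spec.size:
        return spec.matrix.copy()
    return _zero_diagonal_blocks(Jp)


def couplings_from_matrix(M: np.ndarray, drop_tol: float = 1e-12) -> dict:
    """Extract i<j coupling blocks from a full symmetric matrix."""
    L = M.shape[0] // 4
    out = {}
    for i in range(L):
        for j in range(i + 1, L):
            block = M[4 * i:4 * i + 4, 4 * j:4 * j + 4]
            if np.abs(block).max() > drop_tol:
                out[(i, j)] = block.copy()
    return out


def truncated_model(params: PIMParams, p: int) -> PIMParams:
    """The model with couplings replaced by their rank-p approximation."""
    Jp = truncate(spectrum(params), p)
    return PIMParams(params.h.copy(), couplings_from_matrix(Jp))
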