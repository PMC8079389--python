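"""Diffusion-map embedding of pixels by activity similarity.

Pixels are treated as points in activity space (their fluorescence
traces).  A Gaussian kernel turns pairwise Euclidean distances into a
weighted graph; eigenfunctions of the row-normalized Markov matrix give
diffusion coordinates in which functionally similar pixels cluster.  The
kernel scale adapts to the data: sigma is twice the standard deviation
of all pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform


def build_affinity(traces: np.ndarray) -> tuple[np.ndarray, float]:
    """Gaussian affinity W_ij = exp(-d_ij^2 / sigma^2) between pixel
    traces, with sigma = 2 x std of all pairwise Euclidean distances.

    Returns (W, sigma).  W is symmetric with a unit diagonal.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 3:
        raise ValueError("need at least 3 pixel traces")
    if not np.all(np.isfinite(traces)):
        raise ValueError("traces must be finite")
    d = pdist(traces)
    sigma = 2.0 * float(d.std())
    if sigma == 0:
        raise ValueError("all traces identical: kernel scale is zero")
    w = np.exp(-squareform(d) ** 2 / sigma**2)
    np.fill_diagonal(w, 1.0)
    return w, sigma


def markov_eigendecomposition(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the row-normalized Markov matrix P = D^-1 W.

    Solved through the symmetric conjugate S = D^-1/2 W D^-1/2 (same
    eigenvalues; eigenvectors mapped back by D^-1/2).  Eigenvalues are
    sorted descending; the leading pair is (1, constant vector).
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if np.any(w < 0) or not np.allclose(w, w.T):
        raise ValueError("affinity must be nonnegative and symmetric")
    deg = w.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero row sum in affinity matrix")
    d_isqrt = 1.0 / np.sqrt(deg)
    s = w * np.outer(d_isqrt, d_isqrt)
    evals, evecs = linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = (d_isqrt[:, None] * evecs)[:, order]
    # Normalize so the trivial eigenvector is the positive constant.
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return evals, evecs


@dataclass
class DiffusionEmbedding:
    """3-D diffusion coordinates of in-ROI pixels."""

    coords: np.ndarray          # (n_pixels, 3)
    eigenvalues: np.ndarray
    sigma: float
    pixels: np.ndarray | None = None   # (n_pixels, 2) (row, col) or None


def embed_3d(evals: np.ndarray, evecs: np.ndarray, t: int = 1,
             sigma: float = np.nan,
             pixels: np.ndarray | None = None) -> DiffusionEmbedding:
    """Diffusion coordinates from the first three nontrivial eigenpairs:
    coordinate k is lambda_{k+1}^t * v_{k+1} (the trivial pair skipped)."""
    if len(evals) < 4:
        raise ValueError("need at least 4 eigenpairs for a 3-D embedding")
    coords = evecs[:, 1:4] * (evals[1:4] ** t)
    return DiffusionEmbedding(coords=coords, eigenvalues=np.asarray(evals),
                              sigma=sigma, pixels=pixels)


def diffusion_embedding(traces: np.ndarray, t: int = 1,
                        pixels: np.ndarray | None = None) -> DiffusionEmbedding:
    """Affinity, Markov eigendecomposition and 3-D embedding in one call."""
    w, sigma = build_affinity(traces)
    evals, evecs = markov_eigendecomposition(w)
    return embed_3d(evals, evecs, t=t, sigma=sigma, pixels=pixels)


def embed_movie(movie, mask: np.ndarray, t: int = 1) -> DiffusionEmbedding:
    """Embed the in-mask pixels of a (preprocessed) movie."""
    pix = np.argwhere(mask)
    traces = movie.data[:, mask].T
    ok = ~np.isnan(traces).any(axis=1)
    return diffusion_embedding(traces[ok], t=t, pixels=pix[ok])
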