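"""Spectral PCA: cross-frequency covariance, eigenbasis, projection weights.

The covariance is the literal uncentered second-moment matrix of the
log-normalized spectra, ``C(f, f') = sum_obs P~(f) P~(f')``, pooling every
(segment, channel) pair of the session as one observation so that a single
spectral basis serves all channels.  Eigenvectors (spectral principal
components) are ordered by decreasing eigenvalue; each segment/channel
spectrum is summarized by its projection weights on the leading components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .spectral import LogPsdSet

#: eigenvector sign rule: mean over these bins (8-12 Hz) is made non-negative
_SIGN_BAND = (8.0, 12.0)


@dataclass
class SpectralBasis:
    """Ordered spectral eigensystem: eigenvalues descending, columns = e_k."""

    eigenvalues: np.ndarray  # (F,)
    eigenvectors: np.ndarray  # (F, F), column k is e_k
    freqs: np.ndarray
    sign_convention: str = "alpha-mean-positive"

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class ProjectionTable:
    """Projection weights W[m, n, k] of each segment/channel on the top-K PCs."""

    weights: np.ndarray  # (n_segments, n_channels, K)
    labels: np.ndarray
    channel_labels: tuple[str, ...]
    montage_xy: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[2]


def spectral_covariance(logpsd: LogPsdSet) -> np.ndarray:
    """Uncentered spectral second-moment matrix, observations = (segment, channel)."""
    m, n, f = logpsd.values.shape
    if m < 2:
        raise ValueError("need at least 2 segments to form a spectral covariance")
    x = logpsd.values.reshape(m * n, f)
    c = x.T @ x
    return (c + c.T) / 2.0  # exact symmetry


def eigendecompose(cov: np.ndarray, freqs: np.ndarray | None = None,
                   asym_tol: float = 1e-8) -> SpectralBasis:
    """Full eigensystem of a symmetric PSD matrix, descending, deterministic signs.

    Sign rule: flip each eigenvector so its mean over the 8-12 Hz bins is
    >= 0; on an exact tie, make its largest-magnitude component positive.
    Eigenvalues in [-tol, 0) are clipped to 0; more negative values raise.
    """
    cov = np.asarray(cov, dtype=float)
    scale = max(1.0, float(np.abs(cov).max()))
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if np.abs(cov - cov.T).max() > asym_tol * scale:
        raise ValueError("covariance matrix is not symmetric within tolerance")
    if freqs is None:
        freqs = np.arange(1, cov.shape[0] + 1, dtype=float)
    vals, vecs = linalg.eigh((cov + cov.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    neg_tol = 1e-10 * scale
    if vals[-1] < -neg_tol:
        raise ValueError("covariance has significantly negative eigenvalues")
    vals = np.maximum(vals, 0.0)
    band = (freqs >= _SIGN_BAND[0]) & (freqs <= _SIGN_BAND[1])
    for k in range(vecs.shape[1]):
        s = vecs[band, k].mean() if band.any() else 0.0
        if s < 0:
            vecs[:, k] = -vecs[:, k]
        elif s == 0 and vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    return SpectralBasis(eigenvalues=vals, eigenvectors=vecs,
                         freqs=np.asarray(freqs, dtype=float))


def project(logpsd: LogPsdSet, basis: SpectralBasis, n_components: int = 3) -> ProjectionTable:
    """Projection weights ``W[m, n, k] = sum_f e_k(f) P~[m, n, f]``."""
    f = logpsd.values.shape[2]
    if basis.eigenvectors.shape[0] != f:
        raise ValueError("basis frequency grid does not match the spectra")
    if not 1 <= n_components <= f:
        raise ValueError(f"n_components must be in [1, {f}]")
    weights = np.einsum("mnf,fk->mnk", logpsd.values,
                        basis.eigenvectors[:, :n_components])
    return ProjectionTable(weights=weights, labels=logpsd.labels,
                           channel_labels=logpsd.channel_labels,
                           montage_xy=logpsd.montage_xy)
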