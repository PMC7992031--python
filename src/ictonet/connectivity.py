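"""Amplitude-envelope-correlation networks from orthogonalized signals.

For every unordered region pair the zero-lag (leakage) component is removed
by time-domain regression in both directions, Hilbert envelopes are
correlated, and the two directed estimates are averaged into one symmetric
weight.  Negative envelope correlations are clipped to zero by default so
the downstream excitatory node model receives nonnegative weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import Segment

__all__ = [
    "FunctionalNetwork",
    "envelope",
    "orthogonalize",
    "aec_pair",
    "network_from_segment",
    "save_network",
]


@dataclass
class FunctionalNetwork:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    weights: np.ndarray  # (n, n)
    subject_id: str = ""
    segment_index: int = 0
    thresholded: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def density(self) -> float:
        n = self.n_regions
        return float((self.weights > 0).sum() / (n * (n - 1)))


def envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal (per row)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    return np.abs(hilbert(x, axis=-1))


def orthogonalize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove the zero-lag projection of ``x`` from ``y`` (least squares).

    The output has zero-lag correlation ~0 with ``x``.  If ``x`` is
    identically zero there is nothing to remove: ``y`` is returned
    unchanged with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    xx = float(x @ x)
    if xx == 0.0:
        warnings.warn("reference signal is identically zero; returning y unchanged",
                      RuntimeWarning, stacklevel=2)
        return y.copy()
    return y - (float(x @ y) / xx) * x


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=-1))
    nb = np.sqrt((b * b).sum(axis=-1))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=-1) / denom
    return np.where(denom > 0, r, 0.0)  # constant envelope -> weight 0


def aec_pair(x: np.ndarray, y: np.ndarray, clip_negative: bool = True) -> float:
    """Symmetric orthogonalized amplitude-envelope correlation in [0, 1].

    Averages corr(env(x), env(y orthogonalized to x)) with the reverse
    direction, so ``aec_pair(x, y) == aec_pair(y, x)`` exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 100:
        raise ValueError("need at least 100 samples for a stable estimate")

    def _res_corr(a, b):
        # residual of b on a; a collinear pair leaves only rounding noise
        # parallel to a, which must count as fully leakage (weight 0)
        res = orthogonalize(a, b)
        if float(res @ res) <= 1e-20 * float(b @ b):
            return 0.0
        return _pearson_rows(envelope(a)[None], envelope(res)[None])[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r1 = _res_corr(x, y)
        r2 = _res_corr(y, x)
    w = 0.5 * (r1 + r2)
    if clip_negative:
        w = max(w, 0.0)
    else:
        w = abs(w)
    return float(min(w, 1.0))


def network_from_segment(segment, clip_negative: bool = True,
                         chunk_pairs: int = 1024) -> FunctionalNetwork:
    """All-pairs orthogonalized AEC for one segment.

    Accepts a :class:`~ictonet.preprocess.Segment` or a plain
    (n_regions, n_samples) array.  Pairs are processed in chunks with
    batched Hilbert transforms.
    """
    if isinstance(segment, Segment):
        data, sid, idx = segment.data, segment.subject_id, segment.segment_index
    else:
        data, sid, idx = np.asarray(segment, dtype=np.float64), "", 0
    n, t = data.shape
    if n < 2:
        raise ValueError("need at least 2 regions")
    d = data - data.mean(axis=1, keepdims=True)
    g = d @ d.T  # zero-lag inner products
    diag = np.diag(g).copy()
    safe = np.where(diag > 0, diag, 1.0)
    env = envelope(d)

    iu, ju = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    for start in range(0, len(iu), chunk_pairs):
        i = iu[start:start + chunk_pairs]
        j = ju[start:start + chunk_pairs]
        # residual of j regressed on i, and of i regressed on j
        cij = g[i, j] / safe[i]
        cji = g[i, j] / safe[j]
        r1 = d[j] - cij[:, None] * d[i]  # y | x
        r2 = d[i] - cji[:, None] * d[j]  # x | y
        e1 = np.abs(hilbert(r1, axis=1))
        e2 = np.abs(hilbert(r2, axis=1))
        rho1 = _pearson_rows(env[i], e1)
        rho2 = _pearson_rows(env[j], e2)
        # collinear pairs leave only rounding noise parallel to the
        # reference: pure leakage, weight 0
        rho1[(r1 * r1).sum(axis=1) <= 1e-20 * diag[j]] = 0.0
        rho2[(r2 * r2).sum(axis=1) <= 1e-20 * diag[i]] = 0.0
        vals = 0.5 * (rho1 + rho2)
        vals = np.maximum(vals, 0.0) if clip_negative else np.abs(vals)
        w[i, j] = np.minimum(vals, 1.0)
    w = w + w.T
    return FunctionalNetwork(weights=w, subject_id=sid, segment_index=idx,
                             thresholded=False)


def save_network(network: FunctionalNetwork, path, sparse: bool = False) -> None:
    """Write a network as a dense CSV matrix or a Matrix Market sparse file.

    The sparse form is mainly useful after thresholding, when most entries
    are exactly zero.
    """
    if sparse:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(network.weights), symmetry="symmetric")
    else:
        np.savetxt(path, network.weights, delimiter=",")
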