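"""IAAFT surrogates and per-connection significance pruning.

Each regional series is surrogated independently with the iterative
amplitude-adjusted Fourier transform: the surrogate keeps the exact
amplitude distribution of the original (it is a value permutation) and
approximately its power spectrum, while destroying cross-channel
dependence.  Recomputing the envelope-correlation network on many such
surrogate datasets yields a per-connection null distribution; connections
whose observed weight does not beat the null at the 95% level are pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._rng import child_seed
from .connectivity import FunctionalNetwork, network_from_segment
from .preprocess import Segment

__all__ = ["SurrogateEnsemble", "iaaft", "edge_null", "threshold"]


@dataclass
class SurrogateEnsemble:
    """Null weight samples per connection from independent-channel surrogates."""

    null_weights: np.ndarray  # (n_surrogates, n_pairs), upper-triangle order
    n_regions: int
    n_surrogates: int
    n_iterations: int
    seed: int

    @property
    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_regions, k=1)


def iaaft(x: np.ndarray, n_iterations: int = 10,
          rng: np.random.Generator | int | None = None) -> np.ndarray:
    """One IAAFT surrogate of a 1-D series.

    Starts from an amplitude-adjusted phase-randomized copy, then
    alternates a spectrum-matching step with an amplitude (rank remap)
    step, ending on the amplitude step so the output is an exact value
    permutation of the input.  A constant input is returned unchanged with
    a warning (no phase information to randomize).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("need a 1-D series of at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    if np.ptp(x) == 0.0:
        warnings.warn("constant series: surrogate equals the input",
                      RuntimeWarning, stacklevel=2)
        return x.copy()
    rng = np.random.default_rng(rng)
    sorted_vals = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))

    # AAFT-style start: randomize phases, then restore the amplitude multiset
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.size)
    phases[0] = 0.0
    if x.size % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    y = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=x.size)
    y = sorted_vals[np.argsort(np.argsort(y))]

    for _ in range(n_iterations):
        spec_y = np.fft.rfft(y)
        mag = np.abs(spec_y)
        mag[mag == 0.0] = 1.0
        y = np.fft.irfft(target_amp * spec_y / mag, n=x.size)
        y = sorted_vals[np.argsort(np.argsort(y))]
    return y


def edge_null(segment, n_surrogates: int = 99, n_iterations: int = 10,
              rng_seed: int = 0, clip_negative: bool = True) -> SurrogateEnsemble:
    """Null AEC weights from channel-independent IAAFT surrogate datasets.

    Every surrogate dataset replaces each regional series by its own IAAFT
    surrogate (independent seeds derived from ``rng_seed``, region and
    surrogate index), then the full network is recomputed exactly as the
    connectivity stage does.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    data = segment.data if isinstance(segment, Segment) else np.asarray(segment)
    n = data.shape[0]
    iu = np.triu_indices(n, k=1)
    null = np.empty((n_surrogates, len(iu[0])))
    for s in range(n_surrogates):
        surr = np.empty_like(data)
        for r in range(n):
            surr[r] = iaaft(data[r], n_iterations=n_iterations,
                            rng=np.random.default_rng(child_seed(rng_seed, s, r)))
        net = network_from_segment(surr, clip_negative=clip_negative)
        null[s] = net.weights[iu]
    return SurrogateEnsemble(null_weights=null, n_regions=n,
                             n_surrogates=n_surrogates,
                             n_iterations=n_iterations, seed=rng_seed)


def threshold(network: FunctionalNetwork, ensemble: SurrogateEnsemble,
              alpha: float = 0.05) -> FunctionalNetwork:
    """Prune connections that do not beat the surrogate null.

    Connection (i, j) is retained with its original weight iff the
    rank-based one-sided exact p-value (1 + #{null >= observed}) /
    (1 + n_surrogates) is <= alpha; with 99 surrogates and alpha = 0.05
    this keeps weights exceeding the 95th largest null value.  Ties count
    against retention.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if ensemble.n_regions != network.n_regions:
        raise ValueError("ensemble does not match the network's region count")
    iu = ensemble.pair_indices
    obs = network.weights[iu]
    n_ge = (ensemble.null_weights >= obs[None, :]).sum(axis=0)
    pvals = (1.0 + n_ge) / (1.0 + ensemble.n_surrogates)
    keep = pvals <= alpha
    w = np.zeros_like(network.weights)
    w[iu] = np.where(keep, obs, 0.0)
    w = w + w.T
    meta = dict(network.meta)
    meta.update(alpha=alpha, n_surrogates=ensemble.n_surrogates)
    return replace(network, weights=w, thresholded=True, meta=meta)
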