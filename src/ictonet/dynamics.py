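"""Theta-model seizure dynamics on functional networks.

Each network node is a canonical theta neuron (phase oscillator undergoing a
SNIC bifurcation).  With excitability ``I0 < 0`` an isolated noise-free node
rests at a stable phase ``theta_s``; noise can kick it past the unstable
phase ``theta_u`` onto the rotating branch, which we label the seizure
state.  Nodes excite one another through the nonnegative coupling
``K * w_ij * (1 - cos(theta_j - theta_s))``, which vanishes at rest and is
maximal mid-rotation, so seizure activity spreads along network edges.

The stochastic differential equation integrated here (Euler--Maruyama) is

    dtheta_i = [(1 - cos theta_i)
                + (1 + cos theta_i) * (I0 + K * sum_j w_ij (1 - cos(theta_j - theta_s)))] dt
                + (1 + cos theta_i) * sigma dW_i ,

i.e. white noise enters through the input current, multiplied by the same
``(1 + cos theta)`` factor as the deterministic drive.

Seizure labelling: a node is instantaneously "escaped" when its phase,
wrapped relative to ``theta_s``, lies past the unstable fixed point and
outside a small margin below rest.  A rotating node necessarily re-transits
the neighbourhood of ``theta_s`` once per cycle, so to measure the fraction
of time *in the seizure state* (a rotation episode is one continuous
seizure) the instantaneous labels are closed over a short window
``t_close`` comparable to one rotation period: gaps shorter than the window
are bridged.  With ``t_close = 0`` the raw instantaneous labels are kept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ThetaParams",
    "PhaseTrajectory",
    "fixed_points",
    "simulate",
    "seizure_mask",
    "node_occupancy",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ThetaParams:
    """Constants of the node model and its integration.

    Attributes
    ----------
    i0 : float
        Excitability; distance to the SNIC bifurcation. Must be < 0 for a
        resting regime (the uncoupled noise-free node has a stable phase).
    noise_scale : float
        Standard deviation ``sigma`` of the white noise entering the input
        current (dimensionless model units).
    k : float
        Global scaling coupling multiplying all network weights.
    dt : float
        Euler--Maruyama step, model time units.
    t_total : float
        Simulated duration (model time units), including the transient.
    t_transient : float
        Initial duration discarded before any occupancy statistics.
    rest_margin : float
        Width (radians) of the arc below ``theta_s`` still counted as rest,
        absorbing noise fluctuations around the fixed point.
    t_close : float
        Closing window (model time units): gaps in the instantaneous
        seizure labels shorter than this are bridged, so one rotation
        episode counts as one continuous seizure. 0 disables closing.
    seed : int
        Seed of the noise stream.
    """

    i0: float = -1.2
    noise_scale: float = 1.0
    k: float = 0.0
    dt: float = 0.01
    t_total: float = 2000.0
    t_transient: float = 100.0
    rest_margin: float = 1.0
    t_close: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_transient >= self.t_total:
            raise ValueError("t_transient must be smaller than t_total")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if not 0 < self.rest_margin < math.pi:
            raise ValueError("rest_margin must lie in (0, pi)")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def n_transient(self) -> int:
        return int(round(self.t_transient / self.dt))

    def with_(self, **kw) -> "ThetaParams":
        return replace(self, **kw)


@dataclass
class PhaseTrajectory:
    """Simulated phases (unwrapped, radians) after transient removal."""

    phases: np.ndarray  # (n_nodes, n_retained_steps)
    params: ThetaParams
    seizure_fraction: np.ndarray = field(default=None)  # per node
    unstable_steps: int = 0

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[0]


def fixed_points(i0: float) -> tuple[float, float]:
    """Stable and unstable phases of the uncoupled noise-free node.

    Setting the vector field ``(1 - cos t) + (1 + cos t) I0`` to zero gives
    ``cos t* = (1 + I0) / (1 - I0)``; the stable root is the negative phase.

    Raises
    ------
    ValueError
        If ``i0 > 0`` (suprathreshold regime: the fixed points have
        annihilated in the SNIC bifurcation and the node rotates).
    """
    if i0 > 0:
        raise ValueError(
            f"i0={i0} > 0: suprathreshold regime, the model has no fixed points"
        )
    c = (1.0 + i0) / (1.0 - i0)
    t = math.acos(c)
    return -t, t


def _theta_star(i0: float) -> tuple[float, float]:
    """Fixed points, degenerating to (0, 0) at/after the bifurcation."""
    if i0 > 0:
        return 0.0, 0.0
    return fixed_points(i0)


@njit(cache=True)
def _integrate_kernel(w, k, i0, sigma, dt, n_steps, n_transient,
                      theta_s, rest_hi, rest_lo, seed, store):  # pragma: no cover
    n = w.shape[0]
    theta = np.full(n, theta_s)
    n_keep = n_steps - n_transient
    if store:
        phases = np.empty((n, n_keep))
    else:
        phases = np.empty((n, 0))
    raw = np.zeros((n, n_keep), np.uint8)
    big_steps = 0
    np.random.seed(seed)
    sqdt = sigma * math.sqrt(dt)
    s = np.empty(n)
    for t in range(n_steps):
        for j in range(n):
            s[j] = 1.0 - math.cos(theta[j] - theta_s)
        for i in range(n):
            coup = 0.0
            for j in range(n):
                wij = w[i, j]
                if wij != 0.0:
                    coup += wij * s[j]
            ci = math.cos(theta[i])
            drift = dt * ((1.0 - ci) + (1.0 + ci) * (i0 + k * coup))
            if sigma > 0.0:
                step = drift + (1.0 + ci) * sqdt * np.random.standard_normal()
            else:
                step = drift
            if abs(step) > 0.7853981633974483:  # pi/4
                big_steps += 1
            theta[i] = theta[i] + step
        if t >= n_transient:
            idx = t - n_transient
            for i in range(n):
                phi = (theta[i] - theta_s) % TWO_PI
                if phi > rest_hi and phi < TWO_PI - rest_lo:
                    raw[i, idx] = 1
                if store:
                    phases[i, idx] = theta[i]
    return phases, raw, big_steps


def _instantaneous_mask(phases: np.ndarray, i0: float, rest_margin: float) -> np.ndarray:
    """Raw escape labels: wrapped phase past theta_u, outside the rest margin."""
    theta_s, theta_u = _theta_star(i0)
    phi = np.mod(phases - theta_s, TWO_PI)
    return (phi > (theta_u - theta_s)) & (phi < TWO_PI - rest_margin)


def _close_mask(raw: np.ndarray, params: ThetaParams) -> np.ndarray:
    """Bridge sub-``t_close`` gaps so a rotation episode is one seizure."""
    if params.t_close <= 0:
        return raw.astype(bool)
    width = int(round(params.t_close / params.dt))
    if width <= 1:
        return raw.astype(bool)
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    dil = maximum_filter1d(raw.astype(np.uint8), size=width, axis=-1, mode="constant")
    return minimum_filter1d(dil, size=width, axis=-1, mode="constant", cval=1).astype(bool)


def _run(weights: np.ndarray, params: ThetaParams, store: bool):
    w = np.ascontiguousarray(np.asarray(weights, dtype=np.float64))
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("network weights must be finite and nonnegative")
    theta_s, theta_u = _theta_star(params.i0)
    rest_hi = theta_u - theta_s  # upper edge of the rest arc, wrapped coords
    phases, raw, big = _integrate_kernel(
        w, float(params.k), float(params.i0), float(params.noise_scale),
        float(params.dt), params.n_steps, params.n_transient,
        theta_s, rest_hi, float(params.rest_margin), int(params.seed), store,
    )
    if big > 0.01 * params.n_steps * w.shape[0]:
        warnings.warn(
            f"integration may be unstable: |dtheta| > pi/4 in {big} node-steps; "
            "reduce dt", RuntimeWarning, stacklevel=3,
        )
    mask = _close_mask(raw, params)
    return phases, mask, big


def simulate(network, params: ThetaParams) -> PhaseTrajectory:
    """Integrate the theta-model network and keep the full phase trajectory.

    ``network`` may be a FunctionalNetwork (anything with ``.weights``) or a
    plain square array. Initial condition is every node at rest (``theta_s``),
    so all seizure activity is noise-driven. The first ``t_transient`` model
    time units are discarded; stored phases are unwrapped.
    """
    weights = getattr(network, "weights", network)
    phases, mask, big = _run(weights, params, store=True)
    return PhaseTrajectory(phases=phases, params=params,
                           seizure_fraction=mask.mean(axis=1),
                           unstable_steps=big)


def node_occupancy(network, params: ThetaParams) -> np.ndarray:
    """Per-node seizure-state occupancy in [0, 1], without storing phases."""
    weights = getattr(network, "weights", network)
    _, mask, _ = _run(weights, params, store=False)
    return mask.mean(axis=1)


def seizure_mask(trajectory: PhaseTrajectory, params: ThetaParams | None = None) -> np.ndarray:
    """Boolean seizure-state labels recomputed from stored phases.

    A node is in the seizure state when its wrapped phase relative to the
    stable fixed point lies past the unstable fixed point (outside the
    ``rest_margin`` arc just below ``theta_s``), with sub-``t_close`` gaps
    bridged.  Depends only on the phases and (i0, rest_margin, t_close, dt),
    so recomputation from a stored trajectory reproduces the in-simulation
    labels exactly.
    """
    if params is None:
        params = trajectory.params
    raw = _instantaneous_mask(trajectory.phases, params.i0, params.rest_margin)
    return _close_mask(raw, params)
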