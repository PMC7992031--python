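"""Brain network ictogenicity: BNI(K) curves and the interval statistic.

BNI at a single coupling K is the average fraction of simulated time the
network's nodes spend in the seizure state.  Because any single K is
arbitrary, the subject-level statistic integrates BNI over a coupling
interval [K1, K2] calibrated once per study — on reference networks — so
that BNI runs from ~0 at K1 to ~1 at K2; the same interval is then frozen
for every subject and segment.  The integral is normalized by the interval
width so the statistic lives in [0, 1] (raw-area mode is available;
rankings are identical because the interval is fixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_seed
from .dynamics import ThetaParams, node_occupancy

__all__ = [
    "BNICurve",
    "SubjectBNI",
    "CalibrationResult",
    "bni_at",
    "bni_curve",
    "calibrate_interval",
    "bni_hat",
    "subject_summary",
]


@dataclass
class BNICurve:
    """BNI values over a strictly increasing coupling grid."""

    k_grid: np.ndarray
    bni_values: np.ndarray
    n_realizations: int = 1
    subject_id: str = ""
    segment_index: int = 0

    def __post_init__(self):
        self.k_grid = np.asarray(self.k_grid, dtype=np.float64)
        self.bni_values = np.asarray(self.bni_values, dtype=np.float64)
        if self.k_grid.ndim != 1 or len(self.k_grid) != len(self.bni_values):
            raise ValueError("grid and values must be 1-D and equally long")
        if np.any(np.diff(self.k_grid) <= 0):
            raise ValueError("K grid must be strictly increasing")
        if np.any((self.bni_values < 0) | (self.bni_values > 1)):
            raise ValueError("BNI values must lie in [0, 1]")


@dataclass
class SubjectBNI:
    """Per-subject interval-integrated BNI over segments."""

    subject_id: str
    group: str
    bni_hat_per_segment: np.ndarray
    k1: float
    k2: float

    def __post_init__(self):
        self.bni_hat_per_segment = np.asarray(self.bni_hat_per_segment, dtype=np.float64)

    @property
    def mean_bni_hat(self) -> float:
        return float(self.bni_hat_per_segment.mean())

    @property
    def sem(self) -> float:
        v = self.bni_hat_per_segment
        if len(v) < 2:
            return 0.0
        return float(v.std(ddof=1) / math.sqrt(len(v)))


@dataclass
class CalibrationResult:
    """Frozen coupling interval plus the pooled reference curve behind it."""

    k1: float
    k2: float
    k_grid: np.ndarray = field(default=None)
    pooled_bni: np.ndarray = field(default=None)

    def __iter__(self):  # allows `k1, k2 = calibrate_interval(...)`
        return iter((self.k1, self.k2))


def bni_at(network, k: float, params: ThetaParams, n_realizations: int = 2) -> float:
    """Mean seizure-state occupancy at one coupling value.

    Averages over ``n_realizations`` independent noise realizations (seeds
    derived from ``params.seed``) of the node-and-time mean occupancy.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    vals = [
        node_occupancy(network, params.with_(k=float(k),
                                             seed=child_seed(params.seed, "real", r))).mean()
        for r in range(n_realizations)
    ]
    return float(np.mean(vals))


def bni_curve(network, k_grid, params: ThetaParams, n_realizations: int = 2,
              subject_id: str = "", segment_index: int = 0) -> BNICurve:
    """Evaluate BNI on a strictly increasing coupling grid."""
    k_grid = np.asarray(k_grid, dtype=np.float64)
    if k_grid.ndim != 1 or len(k_grid) < 1:
        raise ValueError("k_grid must be a nonempty 1-D array")
    if np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")
    vals = np.array([
        bni_at(network, k, params.with_(seed=child_seed(params.seed, "k", i)),
               n_realizations=n_realizations)
        for i, k in enumerate(k_grid)
    ])
    return BNICurve(k_grid=k_grid, bni_values=vals, n_realizations=n_realizations,
                    subject_id=subject_id, segment_index=segment_index)


class CalibrationError(RuntimeError):
    pass


def _pooled_bni(networks, k, params, n_realizations, bni_fn):
    return float(np.mean([
        bni_fn(net, k, params.with_(seed=child_seed(params.seed, "ref", i)),
               n_realizations)
        for i, net in enumerate(networks)
    ]))


def calibrate_interval(reference_networks, params: ThetaParams,
                       targets: tuple[float, float] = (0.05, 0.95),
                       n_grid: int = 16, n_realizations: int = 2,
                       k_start: float = 1.0, max_expansions: int = 20,
                       expansion: float = 1.5, bni_fn=None) -> CalibrationResult:
    """Find the shared coupling interval [K1, K2] on reference networks.

    Expands the upper search bound geometrically until the pooled reference
    BNI reaches ``targets[1]``, lays a fixed linear grid over [0, K_max], and picks
    K1 = the largest grid point with pooled BNI <= targets[0], K2 = the
    smallest with pooled BNI >= targets[1].  The same grid and interval
    are then reused for every subject in a study run.

    ``bni_fn(network, k, params, n_realizations)`` may be substituted for
    the stochastic estimator (used by tests with analytic curves).
    """
    networks = list(reference_networks)
    if not networks:
        raise ValueError("need at least one reference network")
    if not 0.0 < targets[0] < targets[1] < 1.0:
        raise ValueError("targets must satisfy 0 < lo < hi < 1")
    fn = bni_fn if bni_fn is not None else (
        lambda net, k, p, nr: bni_at(net, k, p, n_realizations=nr))

    def _isolated_fraction():
        fracs = []
        for net in networks:
            w = getattr(net, "weights", net)
            w = np.asarray(w)
            fracs.append(float((w.sum(axis=1) == 0).mean()))
        return float(np.mean(fracs))

    k_hi = float(k_start)
    prev = -1.0
    for _ in range(max_expansions + 1):
        top = _pooled_bni(networks, k_hi, params, n_realizations, fn)
        if top >= targets[1]:
            break
        if top <= prev + 0.01 and top >= 0.5 * targets[1]:
            # ceiling reached: more coupling no longer raises occupancy
            raise CalibrationError(
                f"pooled BNI plateaued at {top:.3f} < {targets[1]} by K={k_hi:.1f}; "
                f"{_isolated_fraction():.0%} of reference nodes are isolated — "
                "the ceiling target is unreachable on these networks"
            )
        prev = top
        k_hi *= expansion
    else:
        raise CalibrationError(
            f"pooled BNI reached only {top:.3f} < {targets[1]} at K={k_hi / expansion:.1f}; "
            "networks may be too sparse for the searched coupling range"
        )

    for attempt in range(4):
        grid = np.linspace(0.0, k_hi, n_grid)
        pooled = np.array([
            _pooled_bni(networks, k,
                        params.with_(seed=child_seed(params.seed, "cal", attempt, i)),
                        n_realizations, fn)
            for i, k in enumerate(grid)
        ])
        below = np.nonzero(pooled <= targets[0])[0]
        above = np.nonzero(pooled >= targets[1])[0]
        if len(above) > 0 and len(below) > 0:
            break
        # targets unreachable on this range: widen and retry
        k_hi *= expansion
    else:
        if len(below) == 0:
            raise CalibrationError(
                f"pooled BNI never falls to {targets[0]} on the grid "
                f"(min {pooled.min():.3f}); floor target unreachable"
            )
        raise CalibrationError(
            f"pooled BNI never reaches {targets[1]} on the grid (max {pooled.max():.3f})"
        )
    k1 = float(grid[below[-1]])
    k2 = float(grid[above[0]])
    if k1 >= k2:
        # non-monotone noise wiggle: fall back to the first crossing bracket
        k1 = float(grid[below[below < above[0]][-1]]) if np.any(below < above[0]) else float(grid[0])
        k2 = float(grid[above[0]])
    return CalibrationResult(k1=k1, k2=k2, k_grid=grid, pooled_bni=pooled)


def bni_hat(curve: BNICurve, k1: float, k2: float, normalized: bool = True) -> float:
    """Integrate the BNI curve over [K1, K2] (trapezoid).

    With ``normalized=True`` (default) the integral is divided by
    ``K2 - K1`` so the statistic lies in [0, 1].
    """
    if k2 <= k1:
        raise ValueError("need K1 < K2")
    grid, vals = curve.k_grid, curve.bni_values
    if k1 < grid[0] - 1e-12 or k2 > grid[-1] + 1e-12:
        raise ValueError(
            f"curve grid [{grid[0]:.3g}, {grid[-1]:.3g}] does not cover "
            f"[{k1:.3g}, {k2:.3g}]"
        )
    inside = (grid > k1) & (grid < k2)
    ks = np.concatenate(([k1], grid[inside], [k2]))
    vs = np.concatenate(([np.interp(k1, grid, vals)], vals[inside],
                         [np.interp(k2, grid, vals)]))
    area = float(np.trapezoid(vs, ks))
    return area / (k2 - k1) if normalized else area


def subject_summary(curves, k1: float, k2: float, n_segments: int = 10,
                    group: str = "", normalized: bool = True) -> SubjectBNI:
    """Per-segment interval statistics and their mean for one subject."""
    curves = list(curves)
    if len(curves) != n_segments:
        present = sorted(c.segment_index for c in curves)
        missing = sorted(set(range(n_segments)) - set(present))
        raise ValueError(
            f"expected {n_segments} segment curves, got {len(curves)}"
            + (f"; missing segment indices {missing}" if missing else "")
        )
    curves = sorted(curves, key=lambda c: c.segment_index)
    vals = [bni_hat(c, k1, k2, normalized=normalized) for c in curves]
    sid = curves[0].subject_id if curves else ""
    return SubjectBNI(subject_id=sid, group=group,
                      bni_hat_per_segment=np.array(vals), k1=k1, k2=k2)
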