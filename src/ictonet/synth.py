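"""Synthetic cohorts of source-level alpha-band signals.

Stands in for non-deposited resting-state MEG source reconstructions: each
subject is a set of regional narrow-band oscillations whose amplitude
envelopes are coupled according to a known ground-truth network, passed
through an instantaneous linear mixing matrix that emulates source leakage.
The patient group gets a denser (or stronger) ground-truth coupling
network, mirroring the finding that generalized-epilepsy functional
networks carry more connections than those of controls.

Model per region i:

    x_i(t) = a_i(t) * cos(2 pi f_i t + phi_i) + eps_i(t),      X <- M X

with ``f_i`` uniform in the band, ``a_i = exp(s z_i - s^2/2)`` log-normal
envelopes driven by correlated Ornstein--Uhlenbeck processes ``z_i`` whose
cross-correlation follows the ground-truth coupling matrix, ``eps`` white
sensor noise, and ``M = I + leakage`` the zero-lag mixing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._rng import child_seed

__all__ = [
    "GroundTruthSpec",
    "SourceRecording",
    "generate_ground_truth",
    "simulate_recording",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "band_power_fraction",
]

GROUPS = ("control", "patient")
COVARIATE_COLUMNS = (
    "age_years",
    "epilepsy_duration_years",
    "seizure_freq_mj",
    "seizure_freq_abs",
    "seizure_freq_gtcs",
)


@dataclass(frozen=True)
class GroundTruthSpec:
    """Parameters of the synthetic cohort generator.

    ``base_density`` is the probability that a region pair carries genuine
    envelope coupling; ``base_strength`` the coupling coefficient (target
    envelope-driver correlation) of those pairs.  ``patient_effect``
    multiplies density (default) and/or strength in the patient group.
    ``leakage_strength`` scales the off-diagonal of the instantaneous
    mixing matrix; ``sensor_noise`` is the white-noise amplitude relative
    to the median signal RMS.
    """

    n_regions: int = 90
    fs: float = 600.0
    duration: float = 300.0
    band: tuple[float, float] = (8.0, 13.0)
    envelope_timescale: float = 0.3
    base_density: float = 0.15
    base_strength: float = 0.5
    patient_effect: float = 1.6
    patient_effect_on: str = "density"  # 'density' | 'strength' | 'both'
    leakage_strength: float = 0.15
    sensor_noise: float = 0.2
    log_amp_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        if not 0.0 <= self.base_density <= 1.0:
            raise ValueError("base_density must lie in [0, 1]")
        if not 0.0 <= self.base_strength < 1.0:
            raise ValueError("base_strength must lie in [0, 1)")
        if self.leakage_strength < 0 or self.sensor_noise < 0:
            raise ValueError("leakage_strength and sensor_noise must be >= 0")
        if self.envelope_timescale <= 0:
            raise ValueError("envelope_timescale must be positive")
        if self.fs <= 2.0 * self.band[1]:
            raise ValueError("fs must exceed twice the upper band edge")
        if self.band[0] <= 0 or self.band[1] <= self.band[0]:
            raise ValueError("band must satisfy 0 < low < high")
        if self.patient_effect_on not in ("density", "strength", "both"):
            raise ValueError("patient_effect_on must be density|strength|both")
        n_samples = self.duration * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def with_(self, **kw) -> "GroundTruthSpec":
        return replace(self, **kw)


@dataclass
class SourceRecording:
    """Multichannel regional time series with subject metadata."""

    subject_id: str
    group: str
    data: np.ndarray  # (n_regions, n_samples)
    fs: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_regions, n_samples) matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _group_density_strength(spec: GroundTruthSpec, group: str) -> tuple[float, float]:
    density, strength = spec.base_density, spec.base_strength
    if group == "patient":
        if spec.patient_effect_on in ("density", "both"):
            density = density * spec.patient_effect
        if spec.patient_effect_on in ("strength", "both"):
            strength = strength * spec.patient_effect
        if density > 1.0:
            warnings.warn(
                f"patient density {density:.3f} > 1; capping at 1", RuntimeWarning
            )
            density = 1.0
        if strength >= 1.0:
            warnings.warn(
                f"patient strength {strength:.3f} >= 1; capping at 0.99", RuntimeWarning
            )
            strength = 0.99
    return density, strength


def generate_ground_truth(spec: GroundTruthSpec, group: str, rng_seed: int) -> np.ndarray:
    """Draw a symmetric zero-diagonal ground-truth envelope-coupling matrix.

    Each unordered region pair independently carries coupling of magnitude
    ``strength`` with probability ``density`` (patient-group values scaled
    by ``patient_effect``).
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    density, strength = _group_density_strength(spec, group)
    rng = np.random.default_rng(rng_seed)
    n = spec.n_regions
    iu = np.triu_indices(n, k=1)
    edges = rng.random(len(iu[0])) < density
    w = np.zeros((n, n))
    w[iu] = np.where(edges, strength, 0.0)
    return w + w.T


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= 1e-10:
        return c
    vals = np.clip(vals, 1e-10, None)
    c2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c2))
    return c2 / np.outer(d, d)


def _correlated_ou(corr: np.ndarray, tau: float, fs: float, n_samples: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance OU drivers with given cross-correlation."""
    n = corr.shape[0]
    chol = np.linalg.cholesky(_nearest_correlation(corr))
    dt = 1.0 / fs
    a = math.exp(-dt / tau)
    b = math.sqrt(1.0 - a * a)
    burn = int(round(8 * tau * fs))  # burn-in reaches the stationary law
    eta = rng.standard_normal((n, n_samples + burn))
    e = chol @ eta
    # AR(1) recursion z_t = a z_{t-1} + b e_t, run as an IIR filter per row
    z = sps.lfilter([b], [1.0, -a], e, axis=1)
    return z[:, burn:]


def simulate_recording(truth: np.ndarray, spec: GroundTruthSpec, group: str,
                       subject_id: str, rng_seed: int,
                       covariates: dict | None = None,
                       return_state: bool = False):
    """Emit one subject's regional time series from a ground-truth network.

    Returns the ``SourceRecording``; with ``return_state=True`` also a dict
    holding the internal OU drivers, envelopes and mixing matrix (used by
    oracle tests that compare estimated quantities against the generated
    ground truth paths).
    """
    truth = np.asarray(truth, dtype=np.float64)
    if truth.shape != (spec.n_regions, spec.n_regions):
        raise ValueError("truth matrix dimensions do not match spec")
    if not np.allclose(truth, truth.T):
        raise ValueError("truth matrix must be symmetric")
    rng = np.random.default_rng(rng_seed)
    n, n_samples, fs = spec.n_regions, spec.n_samples, spec.fs
    t = np.arange(n_samples) / fs

    corr = np.eye(n) + truth
    z = _correlated_ou(corr, spec.envelope_timescale, fs, n_samples, rng)
    s = spec.log_amp_sigma
    env = np.exp(s * z - 0.5 * s * s)

    freqs = rng.uniform(spec.band[0], spec.band[1], size=n)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=n)
    x = env * np.cos(2.0 * math.pi * freqs[:, None] * t[None, :] + phases[:, None])

    rms = np.median(np.sqrt(np.mean(x**2, axis=1)))
    if spec.sensor_noise > 0:
        x = x + spec.sensor_noise * rms * rng.standard_normal((n, n_samples))

    mixing = np.eye(n)
    if spec.leakage_strength > 0:
        b = rng.standard_normal((n, n)) / math.sqrt(n)
        np.fill_diagonal(b, 0.0)
        mixing = mixing + spec.leakage_strength * b
        x = mixing @ x

    rec = SourceRecording(subject_id=subject_id, group=group, data=x, fs=fs,
                          covariates=dict(covariates or {}))
    if return_state:
        return rec, {"drivers": z, "envelopes": env, "mixing": mixing,
                     "freqs": freqs, "phases": phases}
    return rec


def _draw_covariates(rng: np.random.Generator, group: str) -> dict:
    """Synthetic clinical covariates; exercise the correlation statistics only."""
    age = float(rng.uniform(17.0, 47.0)) if group == "patient" else float(rng.uniform(18.0, 48.0))
    cov = {"age_years": round(age, 1)}
    if group == "patient":
        cov["epilepsy_duration_years"] = round(float(rng.uniform(2.0, min(age - 14.0, 41.0))), 1)
        for key in ("seizure_freq_mj", "seizure_freq_abs", "seizure_freq_gtcs"):
            if rng.random() < 0.25:
                cov[key] = 0.0
            else:
                cov[key] = float(np.round(np.exp(rng.uniform(np.log(0.2), np.log(365.0))), 1))
    return cov


def generate_cohort(spec: GroundTruthSpec, n_controls: int, n_patients: int,
                    master_seed: int, with_covariates: bool = True):
    """Generate a cohort of recordings plus the ground-truth archive.

    Deterministic in ``master_seed``: every subject's truth matrix, signal
    and covariates are derived from reproducible child seeds.

    Returns ``(recordings, truths)`` where ``truths`` maps subject id to
    its ground-truth coupling matrix.
    """
    if n_controls < 0 or n_patients < 0 or n_controls + n_patients < 1:
        raise ValueError("need at least one subject")
    recordings, truths = [], {}
    labels = [("control", i) for i in range(n_controls)] + \
             [("patient", i) for i in range(n_patients)]
    for group, i in labels:
        sid = f"{'ctl' if group == 'control' else 'pat'}{i:03d}"
        truth = generate_ground_truth(spec, group, child_seed(master_seed, sid, "truth"))
        cov_rng = np.random.default_rng(child_seed(master_seed, sid, "cov"))
        cov = _draw_covariates(cov_rng, group) if with_covariates else {}
        rec = simulate_recording(truth, spec, group, sid,
                                 child_seed(master_seed, sid, "signal"), covariates=cov)
        recordings.append(rec)
        truths[sid] = truth
    return recordings, truths


def band_power_fraction(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Fraction of total spectral power inside ``band`` (periodogram)."""
    f, pxx = sps.periodogram(np.atleast_2d(x), fs=fs, axis=1)
    inband = (f >= band[0]) & (f <= band[1])
    return float(pxx[:, inband].sum() / pxx.sum())


# ---------------------------------------------------------------------------
# cohort on-disk layout: <dir>/manifest.csv, <dir>/<subject>.npy,
#                        <dir>/truth/<subject>.csv

def save_cohort(recordings: list[SourceRecording], truths: dict | None,
                out_dir) -> Path:
    """Write one array file per subject, a manifest CSV, and truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.npy"
        np.save(out / fname, rec.data)
        row = {"subject_id": rec.subject_id, "group": rec.group,
               "fs": rec.fs, "file": fname}
        for c in COVARIATE_COLUMNS:
            row[c] = rec.covariates.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if truths:
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        for sid, w in truths.items():
            np.savetxt(tdir / f"{sid}.csv", w, delimiter=",")
    return out


def load_cohort(cohort_dir) -> list[SourceRecording]:
    """Read a cohort written by :func:`save_cohort` (or the same layout)."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    recs = []
    for _, row in manifest.iterrows():
        data = np.load(cohort_dir / row["file"])
        cov = {c: float(row[c]) for c in COVARIATE_COLUMNS
               if c in row and np.isfinite(row.get(c, np.nan))}
        recs.append(SourceRecording(subject_id=str(row["subject_id"]),
                                    group=str(row["group"]), data=data,
                                    fs=float(row["fs"]), covariates=cov))
    return recs
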