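"""Group comparison and classifier evaluation of the subject-level statistic.

The directional hypothesis is that patients have higher interval-integrated
ictogenicity than controls, tested with a one-sided Mann-Whitney U.  The
same statistic doubles as a classifier score: the ROC is swept over unique
score thresholds, AUC equals U/(n1*n2) with the shared half-credit tie
convention, and the reported operating point maximizes the Youden index
(ties broken toward higher sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "CohortResult",
    "mann_whitney_one_sided",
    "roc_analysis",
    "covariate_correlations",
    "evaluate_cohort",
    "plot_cohort",
]


@dataclass
class CohortResult:
    """Cohort-level statistics of the per-subject scores."""

    scores: np.ndarray
    labels: np.ndarray  # True = patient
    u_statistic: float
    p_value: float
    test_method: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    covariates: pd.DataFrame | None = None  # per-covariate r, p, n

    def to_dict(self) -> dict:
        d = {
            "n_patients": int(self.labels.sum()),
            "n_controls": int((~self.labels).sum()),
            "U": self.u_statistic,
            "p_one_sided": self.p_value,
            "test_method": self.test_method,
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
        if self.covariates is not None:
            d["covariates"] = self.covariates.to_dict(orient="index")
        return d


def mann_whitney_one_sided(patients, controls) -> tuple[float, float]:
    """One-sided Mann-Whitney U (patients > controls).

    Uses the exact null distribution when both groups have at most 30
    observations and the pooled sample has no ties; otherwise the normal
    approximation with tie and continuity correction.  Returns (U, p)
    where U counts patient-over-control wins with half credit for ties.
    """
    x = np.asarray(patients, dtype=np.float64)
    y = np.asarray(controls, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical; test degenerate", RuntimeWarning)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 30 and y.size <= 30 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="greater", method=method)
    mann_whitney_one_sided.last_method = method
    return float(res.statistic), float(res.pvalue)


mann_whitney_one_sided.last_method = None


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Threshold sweep over unique scores (predict patient if score >= thr)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last index of each run of tied scores
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    thresholds = np.r_[np.inf, s[last]]
    return fpr, tpr, thresholds


def roc_analysis(scores, labels) -> "CohortResult":
    """ROC curve, AUC and Youden operating point for patient-vs-control scores.

    ``labels`` is boolean/0-1 with True = patient.  AUC is computed by the
    trapezoid rule over the threshold sweep and therefore equals
    U/(n1*n2) exactly under the shared tie convention.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")

    fpr, tpr, thresholds = _roc_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))

    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    idx = best[np.argmax(tpr[best])]  # ties toward higher sensitivity
    thr = float(thresholds[idx])
    pred = scores >= thr
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    sens = tp / int(labels.sum())
    spec = tn / int((~labels).sum())
    acc = (tp + tn) / labels.size

    u, p = mann_whitney_one_sided(scores[labels], scores[~labels])
    return CohortResult(
        scores=scores, labels=labels, u_statistic=u, p_value=p,
        test_method=mann_whitney_one_sided.last_method,
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
        threshold=thr, sensitivity=float(sens), specificity=float(spec),
        accuracy=float(acc),
    )


DEFAULT_COVARIATES = (
    "epilepsy_duration_years",
    "seizure_freq_mj",
    "seizure_freq_abs",
    "seizure_freq_gtcs",
    "seizure_freq_total",
)


def covariate_correlations(scores, covariates: pd.DataFrame,
                           columns=None) -> pd.DataFrame:
    """Pearson r and two-sided p between scores and each clinical covariate.

    Rows with a missing covariate value are dropped pairwise.  A covariate
    with fewer than 3 complete pairs or zero variance is skipped with a
    flag.  If the individual seizure-frequency columns are present, their
    sum is added as ``seizure_freq_total``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    cov = covariates.copy()
    freq_cols = [c for c in ("seizure_freq_mj", "seizure_freq_abs", "seizure_freq_gtcs")
                 if c in cov.columns]
    if len(freq_cols) == 3 and "seizure_freq_total" not in cov.columns:
        cov["seizure_freq_total"] = cov[freq_cols].sum(axis=1, min_count=3)
    if columns is None:
        columns = [c for c in DEFAULT_COVARIATES if c in cov.columns]
    rows = {}
    for c in columns:
        vals = cov[c].to_numpy(dtype=np.float64)
        ok = np.isfinite(vals) & np.isfinite(scores)
        n = int(ok.sum())
        if n < 3:
            rows[c] = {"r": np.nan, "p": np.nan, "n": n, "flag": "fewer than 3 pairs"}
            continue
        if np.ptp(vals[ok]) == 0.0 or np.ptp(scores[ok]) == 0.0:
            rows[c] = {"r": np.nan, "p": np.nan, "n": n, "flag": "zero variance"}
            continue
        r, p = sstats.pearsonr(scores[ok], vals[ok])
        rows[c] = {"r": float(r), "p": float(p), "n": n, "flag": ""}
    return pd.DataFrame.from_dict(rows, orient="index")


def evaluate_cohort(subject_bnis, covariates: pd.DataFrame | None = None) -> CohortResult:
    """Full cohort evaluation from a list of per-subject BNI summaries."""
    scores = np.array([s.mean_bni_hat for s in subject_bnis])
    labels = np.array([s.group == "patient" for s in subject_bnis])
    result = roc_analysis(scores, labels)
    if covariates is not None:
        pat = labels
        result.covariates = covariate_correlations(scores[pat],
                                                   covariates.loc[pat].reset_index(drop=True))
    return result


def plot_cohort(result: CohortResult, path=None):
    """Two-panel summary: per-subject scores by group, and the ROC curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for flag, color, label in ((False, "tab:blue", "control"), (True, "tab:red", "patient")):
        idx = np.flatnonzero(result.labels == flag)
        ax1.scatter(idx, result.scores[result.labels == flag], color=color, label=label, s=22)
    ax1.set_xlabel("subject")
    ax1.set_ylabel("mean interval-integrated BNI")
    ax1.legend(frameon=False)
    ax2.plot(result.fpr, result.tpr, "-o", ms=3)
    ax2.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax2.plot(1 - result.specificity, result.sensitivity, "o", ms=9,
             mfc="none", mec="tab:green")
    ax2.set_xlabel("false positive rate")
    ax2.set_ylabel("true positive rate")
    ax2.set_title(f"AUC = {result.auc:.2f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
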