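"""End-to-end study orchestration with per-stage on-disk handoff.

Stages: synth -> preprocess -> connect -> null (surrogate pruning) ->
bni (calibration + per-subject curves) -> stats.  Each stage writes its
outputs under one run directory and records a completion marker, so a run
can be resumed per stage and every number in the final outputs is
traceable to the config document and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed
from .bni import bni_curve, calibrate_interval, subject_summary
from .config import StudyConfig
from .connectivity import FunctionalNetwork, network_from_segment
from .group_stats import plot_cohort
from .preprocess import preprocess
from .surrogates import edge_null, threshold
from .synth import COVARIATE_COLUMNS, generate_cohort, load_cohort, save_cohort, simulate_recording, generate_ground_truth

log = logging.getLogger("ictonet")

STAGES = ("synth", "preprocess", "connect", "null", "bni", "stats")


def _marker(stage_dir: Path) -> Path:
    return stage_dir / ".complete"


def _done(stage_dir: Path) -> bool:
    return _marker(stage_dir).exists()


def _finish(stage_dir: Path) -> None:
    _marker(stage_dir).write_text("ok\n")


def _hash_dir(stage_dir: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(stage_dir.rglob("*")):
        if f.is_file() and f.name != ".complete":
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def stage_synth(cfg: StudyConfig, run_dir: Path, resume: bool = False) -> Path:
    out = run_dir / "01_synth"
    if resume and _done(out):
        return out
    spec = cfg.synth.ground_truth_spec(seed=cfg.seed)
    recs, truths = generate_cohort(spec, cfg.synth.n_controls, cfg.synth.n_patients,
                                   master_seed=child_seed(cfg.seed, "cohort"))
    save_cohort(recs, truths, out)
    _finish(out)
    log.info("synth: %d subjects written to %s", len(recs), out)
    return out


def stage_preprocess(cfg: StudyConfig, run_dir: Path, resume: bool = False,
                     cohort_dir: Path | None = None) -> Path:
    out = run_dir / "02_preprocess"
    if resume and _done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    pp = cfg.preprocess
    rows = []
    for rec in load_cohort(cohort_dir or run_dir / "01_synth"):
        segs = preprocess(rec, low_hz=pp.low_hz, high_hz=pp.high_hz,
                          target_fs=pp.target_fs, total_s=pp.total_s,
                          segment_s=pp.segment_s)
        np.savez(out / f"{rec.subject_id}.npz",
                 **{f"seg{s.segment_index}": s.data for s in segs})
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "fs": segs[0].fs, "n_segments": len(segs),
                     **{c: rec.covariates.get(c, np.nan) for c in COVARIATE_COLUMNS}})
    pd.DataFrame(rows).to_csv(out / "segments.csv", index=False)
    _finish(out)
    log.info("preprocess: %d subjects segmented", len(rows))
    return out


def _iter_segments(pre_dir: Path):
    manifest = pd.read_csv(pre_dir / "segments.csv")
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        with np.load(pre_dir / f"{sid}.npz") as npz:
            for key in sorted(npz.files, key=lambda k: int(k[3:])):
                yield sid, str(row["group"]), int(key[3:]), npz[key], float(row["fs"])


def stage_connect(cfg: StudyConfig, run_dir: Path, resume: bool = False) -> Path:
    out = run_dir / "03_networks"
    if resume and _done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    for sid, group, idx, data, _fs in _iter_segments(run_dir / "02_preprocess"):
        net = network_from_segment(data, clip_negative=cfg.network.clip_negative)
        np.savetxt(out / f"{sid}_seg{idx}.csv", net.weights, delimiter=",")
    _finish(out)
    log.info("connect: networks written to %s", out)
    return out


def stage_null(cfg: StudyConfig, run_dir: Path, resume: bool = False) -> Path:
    out = run_dir / "04_thresholded"
    if resume and _done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    net_dir = run_dir / "03_networks"
    nc = cfg.network
    for sid, group, idx, data, _fs in _iter_segments(run_dir / "02_preprocess"):
        w = np.loadtxt(net_dir / f"{sid}_seg{idx}.csv", delimiter=",")
        net = FunctionalNetwork(weights=w, subject_id=sid, segment_index=idx)
        ens = edge_null(data, n_surrogates=nc.n_surrogates,
                        n_iterations=nc.n_iterations,
                        rng_seed=child_seed(cfg.seed, "null", sid, idx),
                        clip_negative=nc.clip_negative)
        thr = threshold(net, ens, alpha=nc.alpha)
        np.savetxt(out / f"{sid}_seg{idx}.csv", thr.weights, delimiter=",")
    _finish(out)
    log.info("null: thresholded networks written (alpha=%g, %d surrogates)",
             nc.alpha, nc.n_surrogates)
    return out


def reference_networks(cfg: StudyConfig):
    """Held-out control-like networks used only for interval calibration.

    A calibration reference must be able to express the full BNI range,
    which requires every node to be recruitable through at least one
    retained edge; candidates whose thresholded network leaves a node
    isolated are therefore skipped (subject networks are never filtered —
    their isolated nodes are genuine signal).
    """
    spec = cfg.synth.ground_truth_spec(seed=cfg.seed)
    dur = max(cfg.preprocess.segment_s * 1.5, 2 * cfg.preprocess.segment_s)
    spec = spec.with_(duration=float(np.ceil(dur)))
    nets = []
    max_attempts = 8 * cfg.bni.n_reference
    for i in range(max_attempts):
        sid = f"ref{i:02d}"
        truth = generate_ground_truth(spec, "control", child_seed(cfg.seed, sid, "truth"))
        rec = simulate_recording(truth, spec, "control", sid,
                                 child_seed(cfg.seed, sid, "signal"))
        segs = preprocess(rec, low_hz=cfg.preprocess.low_hz,
                          high_hz=cfg.preprocess.high_hz,
                          target_fs=cfg.preprocess.target_fs,
                          total_s=cfg.preprocess.segment_s,
                          segment_s=cfg.preprocess.segment_s)
        net = network_from_segment(segs[0], clip_negative=cfg.network.clip_negative)
        ens = edge_null(segs[0], n_surrogates=cfg.network.n_surrogates,
                        n_iterations=cfg.network.n_iterations,
                        rng_seed=child_seed(cfg.seed, "refnull", i),
                        clip_negative=cfg.network.clip_negative)
        thr = threshold(net, ens, alpha=cfg.network.alpha)
        if (thr.weights.sum(axis=1) > 0).all():
            nets.append(thr)
            if len(nets) == cfg.bni.n_reference:
                return nets
        else:
            log.info("reference candidate %s has isolated nodes; skipped", sid)
    raise RuntimeError(
        f"could only assemble {len(nets)}/{cfg.bni.n_reference} calibration "
        f"references without isolated nodes in {max_attempts} attempts; "
        "increase coupling density or region count"
    )


def stage_bni(cfg: StudyConfig, run_dir: Path, resume: bool = False) -> Path:
    out = run_dir / "05_bni"
    if resume and _done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.dynamics.theta_params(seed=child_seed(cfg.seed, "calib"))
    t0 = time.time()
    refs = reference_networks(cfg)
    cal = calibrate_interval(refs, params, targets=cfg.bni.calibration_targets,
                             n_grid=cfg.bni.n_grid,
                             n_realizations=cfg.bni.n_realizations,
                             k_start=cfg.bni.k_start)
    log.info("calibration: K1=%.3f K2=%.3f (%.1f s)", cal.k1, cal.k2, time.time() - t0)
    np.savetxt(out / "calibration_curve.csv",
               np.c_[cal.k_grid, cal.pooled_bni], delimiter=",",
               header="K,pooled_BNI", comments="")

    thr_dir = run_dir / "04_thresholded"
    manifest = pd.read_csv(run_dir / "02_preprocess" / "segments.csv")
    rows = []
    for _, mrow in manifest.iterrows():
        sid, group = str(mrow["subject_id"]), str(mrow["group"])
        n_seg = int(mrow["n_segments"])
        curves = []
        for idx in range(n_seg):
            w = np.loadtxt(thr_dir / f"{sid}_seg{idx}.csv", delimiter=",")
            params_i = cfg.dynamics.theta_params(seed=child_seed(cfg.seed, "bni", sid, idx))
            curves.append(bni_curve(w, cal.k_grid, params_i,
                                    n_realizations=cfg.bni.n_realizations,
                                    subject_id=sid, segment_index=idx))
        summ = subject_summary(curves, cal.k1, cal.k2, n_segments=n_seg,
                               group=group, normalized=cfg.bni.normalized)
        row = {"subject_id": sid, "group": group,
               **{f"bni_hat_seg{i}": v for i, v in enumerate(summ.bni_hat_per_segment)},
               "mean_bni_hat": summ.mean_bni_hat, "sem": summ.sem,
               "k1": cal.k1, "k2": cal.k2}
        rows.append(row)
        log.info("bni: %s mean=%.4f sem=%.4f", sid, summ.mean_bni_hat, summ.sem)
    df = pd.DataFrame(rows)
    df.to_csv(out / "subject_bni.csv", index=False)
    (out / "dynamics_config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    _finish(out)
    return out


def stage_stats(cfg: StudyConfig, run_dir: Path, resume: bool = False) -> Path:
    out = run_dir / "06_stats"
    if resume and _done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(run_dir / "05_bni" / "subject_bni.csv")
    manifest = pd.read_csv(run_dir / "02_preprocess" / "segments.csv")
    merged = df.merge(manifest[["subject_id"] + list(COVARIATE_COLUMNS)],
                      on="subject_id", how="left")

    from .group_stats import covariate_correlations, roc_analysis

    labels = (merged["group"] == "patient").to_numpy()
    scores = merged["mean_bni_hat"].to_numpy()
    result = roc_analysis(scores, labels)
    pat = merged[labels].reset_index(drop=True)
    result.covariates = covariate_correlations(
        pat["mean_bni_hat"].to_numpy(), pat[list(COVARIATE_COLUMNS)])

    (out / "results.json").write_text(json.dumps(result.to_dict(), indent=2))
    pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr,
                  "threshold": result.thresholds}).to_csv(out / "roc_points.csv",
                                                          index=False)
    plot_cohort(result, out / "cohort.png")
    _finish(out)
    log.info("stats: U=%.1f p=%.4g AUC=%.3f", result.u_statistic, result.p_value,
             result.auc)
    return out


_STAGE_FNS = {
    "synth": stage_synth,
    "preprocess": stage_preprocess,
    "connect": stage_connect,
    "null": stage_null,
    "bni": stage_bni,
    "stats": stage_stats,
}


def run_study(cfg: StudyConfig, out_dir, resume: bool = False) -> Path:
    """Run every stage and write a provenance manifest; returns the run dir."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    hashes = {}
    for stage in STAGES:
        t0 = time.time()
        try:
            stage_dir = _STAGE_FNS[stage](cfg, run_dir, resume=resume)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        hashes[stage] = _hash_dir(stage_dir)
        log.info("stage %s done in %.1f s", stage, time.time() - t0)
    (run_dir / "manifest.json").write_text(json.dumps(
        {"seed": cfg.seed, "stage_hashes": hashes}, indent=2))
    return run_dir
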