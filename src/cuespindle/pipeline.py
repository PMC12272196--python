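"""End-to-end orchestration: generate -> preprocess -> detect -> window -> score -> analyze.

A run is fully determined by a :class:`~cuespindle.synthetic_data.SimConfig`
(or a YAML document mirroring it) and writes, per subject, an EDF recording,
hypnogram/arousal/cue TSVs, detected-spindle and density CSVs, plus pooled
behavioural tables and a JSON statistics report.  The manifest records the
seed, a hash of the configuration, and every artifact path.

``validate_recovery`` reruns the generator with ground truth retained and
scores the detector (precision/recall/F1 against injected bursts), the
recovered behavioural effects, and the cue:no-cue density ratio against the
configured model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import behaviour as beh
from . import cue_windows as cw
from . import eeg_preproc as pre
from . import io as cio
from . import spindle_detection as det
from . import stats as st
from . import synthetic_data as syn
from .types import (Hypnogram, LEFT_MOTOR_CHANNELS, RIGHT_MOTOR_CHANNELS,
                    SpindleEvent, GroundTruthEvent)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: float
    finished: float = 0.0
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def config_hash(config: syn.SimConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_config(config) -> syn.SimConfig:
    if isinstance(config, syn.SimConfig):
        return config
    if isinstance(config, dict):
        return syn.SimConfig.from_dict(config)
    return syn.SimConfig.from_yaml(config)


def _subject_config(config: syn.SimConfig, subject: int) -> syn.SimConfig:
    sub = dataclasses.replace(config, seed=int(
        np.random.SeedSequence([config.seed, 1000 + subject])
        .generate_state(1)[0] % (2 ** 31)))
    return sub


def simulate_subject(config: syn.SimConfig, subject: int):
    """(hypnogram, cue log, raw EEG, ground truth) for one subject's night."""
    sub_cfg = _subject_config(config, subject)
    hyp = syn.generate_hypnogram(sub_cfg)
    cues = syn.generate_cue_log(sub_cfg, hyp)
    rec, truth = syn.generate_eeg(sub_cfg, hyp, cues)
    return hyp, cues, rec, truth


def detect_subject(rec, hyp, params: det.DetectorParams = det.DetectorParams()):
    """Preprocess a raw recording and run the spindle detector."""
    prepped = pre.preprocess(rec)
    return prepped, det.detect_spindles(prepped, hyp, params)


def density_subject(spindles, cues, hyp) -> pd.DataFrame:
    periods = cw.build_periods(cues)
    labelled = cw.label_spindles(spindles, periods, hyp)
    return cw.spindle_density(labelled, periods, hyp)


def analyze_outputs(benefits: pd.DataFrame, seqspecs: pd.DataFrame,
                    densities: dict[str, pd.DataFrame],
                    stage_pcts: dict[str, pd.Series]) -> dict:
    """The statistics report: density comparisons, correlations, mixed models.

    ``densities`` / ``stage_pcts`` map subject id to that subject's density
    table / stage-percentage series.
    """
    report: dict = {}
    subjects = sorted(densities)

    def motor_mean(subj, period, region="all"):
        md = cw.motor_density_means(densities[subj])
        return float(md[(md.region == region)
                        & (md.period == period)].density.iloc[0])

    if len(subjects) >= 3:
        cue = np.array([motor_mean(s, "cue") for s in subjects])
        nocue = np.array([motor_mean(s, "nocue") for s in subjects])
        ok = np.isfinite(cue) & np.isfinite(nocue)
        if ok.sum() >= 3:
            report["cue_vs_nocue_density"] = st.gated_paired_test(
                cue[ok], nocue[ok]).to_dict()
        left = np.array([motor_mean(s, "cue", "left") for s in subjects])
        right = np.array([motor_mean(s, "cue", "right") for s in subjects])
        ok = np.isfinite(left) & np.isfinite(right)
        if ok.sum() >= 3:
            report["left_vs_right_cue_density"] = st.gated_paired_test(
                left[ok], right[ok]).to_dict()

    # Stage-percentage vs cueing-benefit correlations, FDR over the 3 sessions.
    if stage_pcts and not benefits.empty:
        for stage in ("N2", "N3"):
            pcts = {s: float(stage_pcts[s][stage]) for s in stage_pcts}
            per_session = {}
            pvals, keys = [], []
            for sess in ("S2", "S3", "S4"):
                sub = benefits[benefits.session == sess]
                pairs = [(pcts[s], v) for s, v in
                         zip(sub.subject_id, sub.value) if s in pcts]
                if len(pairs) >= 4:
                    x, y = map(np.array, zip(*pairs))
                    try:
                        res = st.gated_correlation(x, y)
                    except ValueError:
                        continue
                    per_session[sess] = res.to_dict()
                    pvals.append(res.p_value)
                    keys.append(sess)
            adj = st.fdr_bh(pvals)
            for k, a in zip(keys, adj):
                per_session[k]["p_fdr"] = float(a)
            if per_session:
                report[f"{stage}_pct_vs_benefit"] = per_session

    # Mixed models on post-stimulation sessions (S2-S4), as lmer formulas.
    post = seqspecs[seqspecs.session.isin(["S2", "S3", "S4"])].copy()
    if post.subject_id.nunique() >= 3:
        for tp in ("early", "late"):
            sub = post[post.timepoint == tp]
            if sub.empty:
                continue
            try:
                report[f"{tp}_seqspecs_session_effect"] = st.lme_lrt(
                    sub, "value", ["session", "sequence"], "session").to_dict()
                report[f"{tp}_seqspecs_tmr_effect"] = st.lme_lrt(
                    sub, "value", ["session", "sequence"], "sequence").to_dict()
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.warning("mixed model for %s SeqSpecS failed: %s", tp, err)
    if not benefits.empty and benefits.subject_id.nunique() >= 3:
        try:
            report["benefit_time_effect"] = st.lme_lrt(
                benefits, "value", ["days_post_tmr"], "days_post_tmr").to_dict()
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("cueing-benefit time model failed: %s", err)
    return report


def run_pipeline(config, outdir, keep_ground_truth: bool = True,
                 detector_params: det.DetectorParams = det.DetectorParams(),
                 ) -> RunManifest:
    """Execute every stage on synthetic data and write all artifacts."""
    cfg = _load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed,
                           version=__version__, started=time.time())
    stage = "simulate-behaviour"
    try:
        trials = syn.generate_behaviour(cfg)
        trials.to_csv(out / "trials.csv", index=False)
        manifest.artifacts["trials"] = str(out / "trials.csv")

        densities, stage_pcts = {}, {}
        for subj in range(cfg.n_subjects):
            sid = f"sub{subj + 1:02d}"
            stage = f"simulate-eeg[{sid}]"
            hyp, cues, rec, truth = simulate_subject(cfg, subj)
            cio.write_edf(rec, out / f"{sid}_eeg.edf")
            cio.write_hypnogram(hyp, out / f"{sid}_hypnogram.tsv",
                                out / f"{sid}_arousals.tsv")
            cio.write_cue_log(cues, out / f"{sid}_cues.tsv")
            if keep_ground_truth:
                cio.write_ground_truth(truth, out / f"{sid}_ground_truth.csv")
            stage = f"detect[{sid}]"
            _, spindles = detect_subject(rec, hyp, detector_params)
            cio.write_spindles(spindles, out / f"{sid}_spindles.csv")
            stage = f"density[{sid}]"
            dens = density_subject(spindles, cues, hyp)
            dens.to_csv(out / f"{sid}_density.csv", index=False)
            densities[sid] = dens
            stage_pcts[sid] = cw.stage_percentages(hyp)
            for kind in ("eeg.edf", "hypnogram.tsv", "arousals.tsv",
                         "cues.tsv", "spindles.csv", "density.csv"):
                manifest.artifacts[f"{sid}_{kind}"] = str(out / f"{sid}_{kind}")

        stage = "score"
        kept = beh.filter_trials(trials)
        seqspecs = pd.concat([beh.seq_spec_skill(kept, tp)
                              for tp in ("early", "late")], ignore_index=True)
        benefits = beh.cueing_benefit(seqspecs)
        benefits = benefits[benefits.session.isin(["S2", "S3", "S4"])]
        seqspecs.to_csv(out / "seqspecs.csv", index=False)
        benefits.to_csv(out / "benefits.csv", index=False)
        manifest.artifacts["seqspecs"] = str(out / "seqspecs.csv")
        manifest.artifacts["benefits"] = str(out / "benefits.csv")

        stage = "analyze"
        report = analyze_outputs(benefits, seqspecs, densities, stage_pcts)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest.artifacts["report"] = str(out / "report.json")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    manifest.artifacts["manifest"] = str(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Parameter-recovery validation

def match_events(detected: list[SpindleEvent],
                 truth: list[GroundTruthEvent]) -> dict:
    """Precision / recall / F1: a detection matches an injected burst when
    its midpoint falls inside the injected interval on the same channel."""
    matched_truth: set[int] = set()
    tp = 0
    for ev in detected:
        hit = None
        for i, gt in enumerate(truth):
            if i in matched_truth or gt.channel != ev.channel:
                continue
            if gt.onset_s <= ev.midpoint_s <= gt.end_s:
                hit = i
                break
        if hit is not None:
            matched_truth.add(hit)
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1}


def validate_recovery(config, outdir=None,
                      thresholds: dict | None = None) -> dict:
    """Compare detector and scoring output against the generator's truth.

    Checks: detector F1 on injected bursts (motor channels); recovered late
    SeqSpecS on uncued blocks against the configured random-block penalty;
    recovered cue:no-cue density ratio against the configured model ratio.
    Returns a pass/fail table against ``thresholds``
    (defaults: f1 >= 0.85, penalty within 3 SE, ratio within 25 %).
    """
    cfg = _load_config(config)
    thr = {"min_f1": 0.85, "ratio_tolerance": 0.25, "penalty_z": 3.0}
    thr.update(thresholds or {})

    f1s, ratios = [], []
    for subj in range(cfg.n_subjects):
        hyp, cues, rec, truth = simulate_subject(cfg, subj)
        _, spindles = detect_subject(rec, hyp)
        # Mastoids are reference channels and carry no injected bursts.
        scored = [s for s in spindles
                  if s.channel not in ("TP9", "TP10")]
        f1s.append(match_events(scored, truth)["f1"])
        dens = density_subject(spindles, cues, hyp)
        md = cw.motor_density_means(dens)
        cue = md[(md.region == "all") & (md.period == "cue")].density.iloc[0]
        nocue = md[(md.region == "all") & (md.period == "nocue")].density.iloc[0]
        if np.isfinite(cue) and np.isfinite(nocue) and nocue > 0:
            ratios.append(cue / nocue)

    dm = cfg.spindle_model.density_per_min
    cfg_cue = np.mean([dm.get(("N2", "cue"), 0), dm.get(("N3", "cue"), 0)])
    cfg_nocue = np.mean([dm.get(("N2", "nocue"), 0), dm.get(("N3", "nocue"), 0)])
    cfg_ratio = cfg_cue / cfg_nocue if cfg_nocue else np.nan

    trials = beh.filter_trials(syn.generate_behaviour(cfg))
    late = beh.seq_spec_skill(trials, "late")
    uncued = late[late.sequence == "uncued"].value
    penalty = cfg.behaviour_model.random_block_penalty_ms
    se = uncued.std(ddof=1) / np.sqrt(len(uncued)) if len(uncued) > 1 else np.nan

    mean_ratio = float(np.mean(ratios)) if ratios else np.nan
    report = {
        "detector_f1": {"values": f1s, "mean": float(np.mean(f1s)),
                        "threshold": thr["min_f1"],
                        "pass": bool(np.mean(f1s) >= thr["min_f1"])},
        "density_ratio": {
            "recovered": mean_ratio, "configured": float(cfg_ratio),
            "pass": bool(np.isfinite(mean_ratio) and abs(
                mean_ratio - cfg_ratio) <= thr["ratio_tolerance"] * cfg_ratio)},
        "random_block_penalty": {
            "recovered_ms": float(uncued.mean()), "configured_ms": penalty,
            "se_ms": float(se),
            "pass": bool(np.isfinite(se)
                         and abs(uncued.mean() - penalty)
                         <= thr["penalty_z"] * se)},
    }
    report["pass"] = all(v["pass"] for v in report.values()
                         if isinstance(v, dict))
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "recovery_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
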