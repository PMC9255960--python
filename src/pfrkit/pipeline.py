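"""End-to-end pipeline: simulate -> detect -> measure -> fit -> report.

The cohort model mirrors the four-aperture cued saccade task: each simulated
participant has per-field oculomotor profiles (intact vs cortically blind)
and per-location psychophysical observers.  Trials cycle through the four
cue locations with stimulus-present/absent balanced; the cued aperture's
field label selects which profile generates the trial.  All randomness
derives from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import pfr, psychometrics, saccades, stats_report, trace_io
from .gaze_synth import OculomotorProfile, SimObserver, TrialRecord, make_trial, square_layout

__all__ = [
    "PipelineConfig",
    "load_config",
    "simulate_participant",
    "measure_trials",
    "subject_gain_table",
    "cohort_report",
    "run",
]

log = logging.getLogger("pfrkit")

#: study-scale cohort defaults: group-mean open-loop / foveal gains, correct
#: rates, landing error and latencies for the two fields
DEFAULT_CONFIG = {
    "seed": 1,
    "out_dir": "pfrkit_out",
    "cohort": {
        "n_subjects": 11,
        "trials_per_subject": 150,
        "blind_apertures": [0, 3],  # +x hemifield blind by default
        "profiles": {
            "intact": {
                "open_loop_gain": 0.157,
                "foveal_gain": 0.186,
                "misselect_prob": 0.032,
                "latency_mean_ms": 360.0,
                "latency_sd_ms": 45.0,
                "landing_mae_deg": 1.59,
                "fixation_noise_sd_deg": 0.08,
            },
            "blind": {
                "open_loop_gain": 0.0045,
                "foveal_gain": 0.150,
                "misselect_prob": 0.106,
                "latency_mean_ms": 382.0,
                "latency_sd_ms": 57.0,
                "landing_mae_deg": 1.59,
                "fixation_noise_sd_deg": 0.08,
            },
        },
    },
    "observers": {
        # per-location true NDR thresholds for the psychophysics stage
        "intact": [0.1, 0.2, 0.3],
        "blind": [0.2, 0.3, 0.6, 1.0],
    },
    "detector": {},
    "stats": {"B": 10_000, "prior_scale": float(np.sqrt(2) / 2), "pooled": False},
    # maximum saccade latency accepted as a response; the task's grace
    # period has no canonical value, exposed as configuration
    "grace_period_ms": 1000.0,
    "psych_trials": 100,
}


@dataclasses.dataclass
class PipelineConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]


def _validate(cfg: dict, path: str = "") -> None:
    """Schema checks with field paths; raises ValueError before any compute."""
    def err(field: str, msg: str):
        raise ValueError(f"config field '{field}': {msg}")

    cohort = cfg.get("cohort", {})
    for fld, prof in cohort.get("profiles", {}).items():
        base = f"cohort.profiles.{fld}"
        try:
            OculomotorProfile(**prof)
        except (ValueError, TypeError) as e:
            err(base, str(e))
    if cohort.get("n_subjects", 1) < 1:
        err("cohort.n_subjects", "must be >= 1")
    if cohort.get("trials_per_subject", 1) < 1:
        err("cohort.trials_per_subject", "must be >= 1")
    for fld, thresholds in cfg.get("observers", {}).items():
        for i, ndr_true in enumerate(thresholds):
            if not 0.0 <= ndr_true <= 1.0:
                err(f"observers.{fld}[{i}]", "NDR must be in [0, 1]")
    det = cfg.get("detector", {})
    try:
        saccades.DetectorParams(**det)
    except (ValueError, TypeError) as e:
        err("detector", str(e))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config, fill defaults, validate."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    _validate(cfg)
    return PipelineConfig(cfg)


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def simulate_participant(
    profiles: dict[str, OculomotorProfile],
    n_trials: int,
    seed: int | np.random.SeedSequence,
    blind_apertures: Sequence[int] = (),
    ecc_xy: tuple[float, float] = (5.0, 5.0),
) -> list[TrialRecord]:
    """Simulate one participant's session on the four-aperture task.

    The cue cycles through the apertures and stimulus-present alternates in
    blocks of four, so both factors are balanced.  The cued aperture's field
    label picks the generating profile (the generator itself is
    field-agnostic).  Motion direction (CW/CCW tangential) is drawn per
    aperture per trial.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_trials + 1)
    rng = np.random.default_rng(children[-1])
    labels = tuple(
        "blind" if i in blind_apertures else "intact" for i in range(4)
    )
    trials = []
    for k in range(n_trials):
        target = k % 4
        layout = square_layout(
            target_index=target,
            stimulus_present=(k // 4) % 2 == 0,
            ecc_xy=ecc_xy,
            clockwise=tuple(rng.random(4) < 0.5),
            field_labels=labels,
        )
        profile = profiles[labels[target]]
        trials.append(make_trial(profile, layout, children[k]))
    return trials


def measure_trials(
    trials: Sequence[TrialRecord],
    params: saccades.DetectorParams | None = None,
    grace_period_ms: float = 1000.0,
) -> pd.DataFrame:
    """Run detection, correctness labelling and PFR measures on trials.

    Returns one row per trial.  Trials with no primary saccade, a latency
    beyond the grace period, or an incorrect saccade have NaN PFR columns:
    only correct trials enter PFR statistics.
    """
    params = params or saccades.DetectorParams()
    rows = []
    for i, rec in enumerate(trials):
        lay = rec.layout
        row = {
            "trial": i,
            "field": lay.field_labels[lay.target_index],
            "stimulus_present": lay.stimulus_present,
            "has_primary": False,
            "correct": False,
            "latency_ms": np.nan,
            "landing_error_deg": np.nan,
            "open_loop_gain": np.nan,
            "foveal_gain": np.nan,
            "endpoint_shift_deg": np.nan,
        }
        events = saccades.detect(rec.trace, params)
        ev = saccades.primary_saccade(
            events, rec.trace, rec.cue_time_ms, lay.fixation_window_deg
        )
        if ev is not None and ev.latency_ms <= grace_period_ms:
            correct, landing_err = saccades.classify_correct(
                rec.trace, ev, lay.target_center,
                fixation_window_deg=lay.fixation_window_deg,
            )
            row.update(
                has_primary=True,
                correct=correct,
                latency_ms=ev.latency_ms,
                landing_error_deg=landing_err,
            )
            if correct:
                ol = pfr.open_loop_pfr(rec.trace, ev, lay)
                fv = pfr.foveal_gain(rec.trace, ev, lay)
                if ol.valid:
                    row["open_loop_gain"] = ol.gain
                if fv.valid:
                    row["foveal_gain"] = fv.gain
                row["endpoint_shift_deg"] = pfr.project(
                    ev.offset_pos - lay.target_center, lay.target_motion_dir
                )
        rows.append(row)
    return pd.DataFrame(rows)


def subject_gain_table(
    per_trial: pd.DataFrame, subject: str | int
) -> pd.DataFrame:
    """Per-field summary (mean gains, accuracy, latency, landing MAE) for one subject."""
    out = []
    for field, g in per_trial.groupby("field"):
        out.append(
            {
                "participant": subject,
                "field": field,
                "open_loop_gain": g["open_loop_gain"].mean(),
                "foveal_gain": g.loc[g["stimulus_present"], "foveal_gain"].mean(),
                "correct_rate": g["correct"].mean(),
                "latency_ms": g["latency_ms"].mean(),
                "landing_mae_deg": g.loc[g["correct"], "landing_error_deg"].mean(),
                "n_trials": len(g),
            }
        )
    return pd.DataFrame(out)


def cohort_report(
    subject_table: pd.DataFrame,
    psych_table: pd.DataFrame | None = None,
    B: int = 10_000,
    prior_scale: float = stats_report.DEFAULT_PRIOR_SCALE,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Group-level statistics from per-subject (or per-location) summaries.

    For each field: mean open-loop and foveal gain with bootstrap CI,
    one-sample t vs zero and JZS Bayes factor; intact-vs-blind two-sample
    comparison; and, when a psychophysics table with matching location rows
    is supplied, the NDR-PFR Pearson correlation per field.
    """
    report: dict = {"fields": {}, "comparisons": {}}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kids = iter(ss.spawn(16))
    for field, g in subject_table.groupby("field"):
        entry = {}
        for col in ("open_loop_gain", "foveal_gain"):
            vals = g[col].dropna().to_numpy()
            if vals.size >= 2:
                gr = stats_report.group_summary(
                    vals, B=B, seed=next(kids), prior_scale=prior_scale
                )
                entry[col] = dataclasses.asdict(gr)
        entry["correct_rate"] = float(g["correct_rate"].mean())
        entry["latency_ms"] = float(g["latency_ms"].mean())
        entry["landing_mae_deg"] = float(g["landing_mae_deg"].mean())
        report["fields"][field] = entry
    gi = subject_table.query("field == 'intact'")["open_loop_gain"].dropna()
    gb = subject_table.query("field == 'blind'")["open_loop_gain"].dropna()
    if len(gi) >= 2 and len(gb) >= 2:
        tt = stats_report.t_test(gi, gb)
        report["comparisons"]["open_loop_intact_vs_blind"] = {
            "t": tt.t,
            "df": tt.df,
            "p": tt.p,
            "bayes_factor": stats_report.jzs_bayes_factor(
                tt.t, len(gi), len(gb), prior_scale
            ),
        }
    if psych_table is not None:
        for field, g in psych_table.groupby("field"):
            merged = g.dropna(subset=["ndr", "open_loop_gain"])
            if len(merged) >= 3 and merged["ndr"].std() > 0:
                r, r2, F, p = stats_report.pearson_r2(
                    merged["ndr"], merged["open_loop_gain"]
                )
                report["fields"].setdefault(field, {})["ndr_pfr_correlation"] = {
                    "r": r, "r2": r2, "F": F, "p": p, "n": len(merged),
                }
    return report


def run(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline and write its output bundle.

    Writes per-subject event/PFR tables, the psychometric fit summary and
    the statistical report (JSON) plus a run log with stage timings and
    exclusion counts.  Deterministic given config + seed.
    """
    cfg = config.raw
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg["seed"])
    ss_cohort, ss_psych, ss_stats = master.spawn(3)

    profiles = {
        f: OculomotorProfile(**p) for f, p in cfg["cohort"]["profiles"].items()
    }
    det = saccades.DetectorParams(**cfg["detector"])
    n_sub = cfg["cohort"]["n_subjects"]
    n_tr = cfg["cohort"]["trials_per_subject"]
    sub_seeds = ss_cohort.spawn(n_sub)

    t0 = time.time()
    per_trial_all, subj_rows = [], []
    excluded = 0
    for s in range(n_sub):
        trials = simulate_participant(
            profiles, n_tr, sub_seeds[s], cfg["cohort"]["blind_apertures"]
        )
        df = measure_trials(trials, det, cfg["grace_period_ms"])
        df.insert(0, "participant", f"S{s:02d}")
        excluded += int((~df["correct"]).sum())
        per_trial_all.append(df)
        subj_rows.append(subject_gain_table(df, f"S{s:02d}"))
    per_trial = pd.concat(per_trial_all, ignore_index=True)
    subject_table = pd.concat(subj_rows, ignore_index=True)
    per_trial.to_csv(out / "pfr_trials.csv", index=False)
    subject_table.to_csv(out / "subject_summary.csv", index=False)
    t_sim = time.time() - t0

    # psychophysics: one simulated observer per configured location
    t0 = time.time()
    psych_rows = []
    obs_specs = [
        (field, ndr_true)
        for field, lst in cfg["observers"].items()
        for ndr_true in lst
    ]
    psych_seeds = ss_psych.spawn(max(len(obs_specs), 1))
    for k, (field, ndr_true) in enumerate(obs_specs):
        obs = SimObserver(threshold_range_deg=360.0 * (1.0 - ndr_true))
        sess = psychometrics.run_session(
            obs, cfg["psych_trials"], psych_seeds[k], field
        )
        fit = psychometrics.fit_weibull(sess)
        psych_rows.append(
            {
                "field": field,
                "true_ndr": ndr_true,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "lapse": fit.lapse,
                "range_threshold_deg": fit.range_threshold_deg,
                "ndr": fit.ndr,
                "measurable": fit.measurable,
            }
        )
    psych_table = pd.DataFrame(psych_rows)
    psych_table.to_csv(out / "psych_fits.csv", index=False)
    t_psych = time.time() - t0

    t0 = time.time()
    report = cohort_report(
        subject_table,
        B=cfg["stats"]["B"],
        prior_scale=cfg["stats"]["prior_scale"],
        seed=ss_stats,
    )
    if cfg["stats"].get("pooled"):
        pooled = stats_report.pooled_by_participant(subject_table)
        pooled.to_csv(out / "subject_summary_pooled.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    t_stats = time.time() - t0

    logpath = out / "run.log"
    logpath.write_text(
        f"seed={cfg['seed']}\n"
        f"simulate+measure: {t_sim:.1f}s ({n_sub} subjects x {n_tr} trials)\n"
        f"incorrect/absent-primary trials excluded from PFR: {excluded}\n"
        f"psychophysics: {t_psych:.1f}s ({len(obs_specs)} locations)\n"
        f"statistics: {t_stats:.1f}s\n"
    )
    return report
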