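"""Post-saccadic following response (PFR) measures.

The open-loop PFR is the 2D vector difference of the *raw* (non-smoothed)
eye position from 20 to 100 ms after saccade offset, normalized by that
interval, projected on the cued aperture's motion direction and expressed
as a gain relative to target speed (10 deg/s by default).  The first 20 ms
after offset are excluded to reduce saccade-related transients; with the
stimulus motion tangential to the saccade vector, residual radial
(saccade-induced) velocity projects to zero.

The foveally-guided gain uses the 100-200 ms epoch, in which post-saccadic
foveal motion (when present) drives ocular following.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .saccades import SaccadeEvent, velocity_trace
from .trace_io import GazeTrace, TrialLayout

__all__ = [
    "PfrMeasure",
    "ProjectedVelocityTrace",
    "project",
    "open_loop_pfr",
    "foveal_gain",
    "timelock_average",
    "endpoint_shift",
    "distractor_pfr",
]

OPEN_LOOP_EPOCH_MS = (20.0, 100.0)
FOVEAL_EPOCH_MS = (100.0, 200.0)


@dataclass
class PfrMeasure:
    """Per-trial drift-velocity vector, its projection and gain for one epoch."""

    drift_vector: np.ndarray  # deg/s
    projected_velocity: float  # deg/s along target motion
    gain: float  # projected_velocity / target_speed
    epoch: str  # "open_loop" | "foveal"
    valid: bool = True


@dataclass
class ProjectedVelocityTrace:
    """Two-stage (within- then across-participant) mean projected velocity."""

    t_ms: np.ndarray  # time relative to the alignment event
    mean: np.ndarray  # deg/s
    dispersion: np.ndarray  # +-2 SEM across participants
    alignment: str  # "onset" | "offset"
    condition: str  # "present" | "absent"


def project(velocity_2d: np.ndarray, motion_dir_unit: np.ndarray) -> float:
    """Signed velocity along the motion direction (positive = with the motion)."""
    d = np.asarray(motion_dir_unit, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("motion direction must be a unit vector")
    return float(np.dot(np.asarray(velocity_2d, dtype=float), d))


def _epoch_measure(
    trace: GazeTrace,
    saccade: SaccadeEvent,
    layout: TrialLayout,
    epoch_ms: tuple[float, float],
    epoch_name: str,
) -> PfrMeasure:
    t_off = trace.t_ms[saccade.offset_idx]
    t1, t2 = (t_off + e for e in epoch_ms)
    interval_s = (epoch_ms[1] - epoch_ms[0]) / 1000.0
    invalid = PfrMeasure(
        np.full(2, np.nan), np.nan, np.nan, epoch_name, valid=False
    )
    if t2 > trace.t_ms[-1]:
        return invalid
    i1 = int(np.argmin(np.abs(trace.t_ms - t1)))
    i2 = int(np.argmin(np.abs(trace.t_ms - t2)))
    if not (trace.valid[i1] and trace.valid[i2]):
        return invalid
    drift = (trace.xy[i2] - trace.xy[i1]) / interval_s
    proj = project(drift, layout.target_motion_dir)
    return PfrMeasure(drift, proj, proj / layout.target_speed, epoch_name)


def open_loop_pfr(
    trace: GazeTrace, saccade: SaccadeEvent, layout: TrialLayout
) -> PfrMeasure:
    """Open-loop PFR over 20-100 ms post-offset, from raw nearest-sample positions."""
    return _epoch_measure(trace, saccade, layout, OPEN_LOOP_EPOCH_MS, "open_loop")


def foveal_gain(
    trace: GazeTrace, saccade: SaccadeEvent, layout: TrialLayout
) -> PfrMeasure:
    """Foveally-guided following over 100-200 ms post-offset."""
    return _epoch_measure(trace, saccade, layout, FOVEAL_EPOCH_MS, "foveal")


def distractor_pfr(
    trace: GazeTrace, saccade: SaccadeEvent, layout: TrialLayout
) -> dict[int, float]:
    """Open-loop drift projected on each non-cued aperture's motion direction.

    Returns ``{aperture_index: gain}`` for the three distractors; empty when
    the open-loop measure is invalid.
    """
    measure = open_loop_pfr(trace, saccade, layout)
    if not measure.valid:
        return {}
    out = {}
    for i in range(4):
        if i == layout.target_index:
            continue
        proj = project(measure.drift_vector, layout.motion_dirs[i])
        out[i] = proj / layout.target_speed
    return out


def endpoint_shift(
    trials: Sequence[tuple[SaccadeEvent, TrialLayout]]
) -> float:
    """Mean signed endpoint displacement along target motion, correct trials only.

    Positive values mean landing points are shifted in the direction of the
    target's motion, a signature of pre-saccadic motion integration.
    """
    if len(trials) == 0:
        raise ValueError("no correct trials")
    shifts = [
        project(ev.offset_pos - lay.target_center, lay.target_motion_dir)
        for ev, lay in trials
    ]
    return float(np.mean(shifts))


def timelock_average(
    trials: Sequence[tuple[GazeTrace, SaccadeEvent, TrialLayout]],
    participant_ids: Sequence,
    align: str = "offset",
    condition: str = "present",
    halfwidth: int = 2,
) -> ProjectedVelocityTrace:
    """Projected-velocity trace time-locked to saccade onset or offset.

    Smoothed 2D velocity is projected on the target motion direction per
    trial, interpolated to a common grid (-100..0 ms around onset, 0..200 ms
    around offset, at the trace sample rate), averaged within participant
    and then across participants; dispersion is +-2 SEM across participants.
    Trials whose layout's stimulus-present flag does not match ``condition``
    are skipped.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    want_present = condition == "present"
    window = (-100.0, 0.0) if align == "onset" else (0.0, 200.0)

    per_subject: dict = {}
    grid = None
    for (trace, ev, lay), pid in zip(trials, participant_ids):
        if lay.stimulus_present != want_present:
            continue
        if grid is None:
            dt = trace.dt_ms
            grid = np.arange(window[0], window[1] + 0.5 * dt, dt)
        vel = velocity_trace(trace, halfwidth)
        proj = vel @ lay.target_motion_dir
        t0 = trace.t_ms[ev.onset_idx if align == "onset" else ev.offset_idx]
        rel = trace.t_ms - t0
        ok = np.isfinite(proj)
        if ok.sum() < 2:
            continue
        per_subject.setdefault(pid, []).append(np.interp(grid, rel[ok], proj[ok]))
    if not per_subject:
        raise ValueError(f"no trials in condition {condition!r}")
    subj_means = np.array([np.mean(v, axis=0) for v in per_subject.values()])
    mean = subj_means.mean(axis=0)
    if len(per_subject) > 1:
        sem = subj_means.std(axis=0, ddof=1) / np.sqrt(len(per_subject))
    else:
        sem = np.zeros_like(mean)
    return ProjectedVelocityTrace(grid, mean, 2.0 * sem, align, condition)
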