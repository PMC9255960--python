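"""Velocity-space saccade detection and primary-saccade classification.

Saccades are detected as deviations in 2D horizontal/vertical eye-velocity
space: per-component robust noise scales are estimated with a median-of-
squares estimator and a sample counts as saccadic when it lies outside the
ellipse ``(vx / (lambda sx))^2 + (vy / (lambda sy))^2 > 1`` (the classic
adaptive-threshold scheme of Engbert & Kliegl).  Short runs are discarded,
nearby runs merged.

The *primary* saccade of a trial is the first detected event after the cue
that starts inside the +-1 deg fixation window and ends outside it; it is
labelled correct when gaze comes within 3.5 deg of the cued aperture center
within 90 ms of the eye leaving the fixation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import GazeTrace

__all__ = [
    "DetectorParams",
    "SaccadeEvent",
    "velocity_trace",
    "robust_sigma",
    "detect",
    "primary_saccade",
    "classify_correct",
]


@dataclass
class DetectorParams:
    """Tunables of the adaptive velocity-threshold detector.

    ``lam`` multiplies the median-based noise scale; ``min_sigma_deg_s``
    floors that scale at roughly the velocity noise of an exceptionally
    clean 220 Hz recording (~0.05 deg RMS position noise), so that
    noiseless synthetic traces, where the median-of-squares estimate
    collapses to zero, still yield a finite threshold.
    """

    lam: float = 6.0
    min_duration_ms: float = 15.0
    merge_gap_ms: float = 20.0
    smoothing_halfwidth_samples: int = 2
    min_sigma_deg_s: float = 3.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.min_duration_ms < 0 or self.merge_gap_ms < 0:
            raise ValueError("durations must be >= 0")
        if self.smoothing_halfwidth_samples < 1:
            raise ValueError("smoothing halfwidth must be >= 1")


@dataclass
class SaccadeEvent:
    """One detected saccade (sample indices into the source trace)."""

    onset_idx: int
    offset_idx: int
    onset_pos: np.ndarray
    offset_pos: np.ndarray
    amplitude_deg: float
    peak_velocity_deg_s: float
    latency_ms: float | None = None  # filled for the primary saccade only

    def __post_init__(self) -> None:
        if self.onset_idx >= self.offset_idx:
            raise ValueError("onset_idx must precede offset_idx")


def velocity_trace(trace: GazeTrace, halfwidth: int = 2) -> np.ndarray:
    """2D eye velocity (deg/s) by central differences over a 2h+1 window.

    ``v[i] = (p[i+h] - p[i-h]) / (t[i+h] - t[i-h])``, which both
    differentiates and smooths.  The first/last h samples, and any sample
    whose window touches an invalid position, are NaN.
    """
    n = len(trace)
    if n < 2 * halfwidth + 1:
        raise ValueError("trace too short for the requested smoothing window")
    v = np.full((n, 2), np.nan)
    h = halfwidth
    span_s = (trace.t_ms[2 * h :] - trace.t_ms[: n - 2 * h]) / 1000.0
    v[h : n - h, 0] = (trace.x_deg[2 * h :] - trace.x_deg[: n - 2 * h]) / span_s
    v[h : n - h, 1] = (trace.y_deg[2 * h :] - trace.y_deg[: n - 2 * h]) / span_s
    ok = np.ones(n, dtype=bool)
    bad = ~trace.valid
    for off in range(-h, h + 1):
        ok[h : n - h] &= ~bad[h + off : n - h + off]
    v[~ok] = np.nan
    v[:h] = np.nan
    v[n - h :] = np.nan
    return v


def robust_sigma(vel: np.ndarray, min_sigma: float = 1.0) -> np.ndarray:
    """Per-component median-of-squares noise scale of a velocity series.

    ``sigma = sqrt(median(v^2) - median(v)^2)``, floored at ``min_sigma``.
    """
    ok = np.isfinite(vel).all(axis=1)
    if not ok.any():
        raise ValueError("all velocity samples invalid")
    v = vel[ok]
    sig = np.sqrt(
        np.maximum(np.median(v**2, axis=0) - np.median(v, axis=0) ** 2, 0.0)
    )
    return np.maximum(sig, min_sigma)


def _saccadic_mask(vel: np.ndarray, lam: float, sigma: np.ndarray) -> np.ndarray:
    test = (vel[:, 0] / (lam * sigma[0])) ** 2 + (vel[:, 1] / (lam * sigma[1])) ** 2
    mask = test > 1.0
    mask[~np.isfinite(test)] = False
    return mask


def detect(
    trace: GazeTrace,
    params: DetectorParams | None = None,
    vel: np.ndarray | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades on a gaze trace.

    Runs of supra-threshold samples shorter than ``min_duration_ms`` are
    dropped; runs separated by less than ``merge_gap_ms`` are merged.
    Events are returned in time order and never overlap.
    """
    params = params or DetectorParams()
    if vel is None:
        vel = velocity_trace(trace, params.smoothing_halfwidth_samples)
    sigma = robust_sigma(vel, params.min_sigma_deg_s)
    mask = _saccadic_mask(vel, params.lam, sigma)

    dt = trace.dt_ms
    runs = _runs(mask)
    runs = _merge_runs(runs, max_gap=int(np.ceil(params.merge_gap_ms / dt)))
    min_len = int(np.ceil(params.min_duration_ms / dt))
    runs = [(a, b) for a, b in runs if (b - a + 1) >= min_len]

    events = []
    for a, b in runs:
        seg_v = vel[a : b + 1]
        peak = float(np.nanmax(np.linalg.norm(seg_v, axis=1)))
        onset_pos = trace.xy[a]
        offset_pos = trace.xy[b]
        events.append(
            SaccadeEvent(
                onset_idx=int(a),
                offset_idx=int(b),
                onset_pos=onset_pos,
                offset_pos=offset_pos,
                amplitude_deg=float(np.linalg.norm(offset_pos - onset_pos)),
                peak_velocity_deg_s=peak,
            )
        )
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    """Merge runs whose separation is strictly less than ``max_gap`` samples."""
    if not runs:
        return []
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if a - pb - 1 < max_gap:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def primary_saccade(
    events: list[SaccadeEvent],
    trace: GazeTrace,
    cue_time_ms: float,
    fixation_window_deg: float = 1.0,
) -> SaccadeEvent | None:
    """First saccade after the cue that exits the fixation window.

    The event must start inside the window (radial distance <= window) and
    end outside it.  Its ``latency_ms`` (onset time minus cue time) is
    filled in.  Returns None when no event qualifies.  Ties (same onset
    sample) resolve to the earlier event in the list.
    """
    for ev in sorted(events, key=lambda e: e.onset_idx):
        t_on = trace.t_ms[ev.onset_idx]
        if t_on < cue_time_ms:
            continue
        inside = np.linalg.norm(ev.onset_pos) <= fixation_window_deg
        outside = np.linalg.norm(ev.offset_pos) > fixation_window_deg
        if inside and outside:
            ev.latency_ms = float(t_on - cue_time_ms)
            return ev
    return None


def window_exit_index(
    trace: GazeTrace, event: SaccadeEvent, fixation_window_deg: float = 1.0
) -> int:
    """First sample at/after saccade onset where gaze is outside the window."""
    r = np.linalg.norm(trace.xy[event.onset_idx : event.offset_idx + 1], axis=1)
    rel = np.flatnonzero(r > fixation_window_deg)
    if rel.size == 0:
        return event.offset_idx
    return event.onset_idx + int(rel[0])


def classify_correct(
    trace: GazeTrace,
    event: SaccadeEvent,
    target_center: np.ndarray,
    radius_deg: float = 3.5,
    settle_ms: float = 90.0,
    fixation_window_deg: float = 1.0,
) -> tuple[bool, float]:
    """Correctness label and landing error of a primary saccade.

    Correct iff gaze comes within ``radius_deg`` of the cued aperture
    center at some sample no later than ``settle_ms`` after the eye leaves
    the fixation window.  The landing error is the distance from the
    saccade endpoint to the target center, regardless of label.
    """
    if target_center is None:
        raise ValueError("target_center is required")
    target_center = np.asarray(target_center, dtype=float)
    exit_i = window_exit_index(trace, event, fixation_window_deg)
    t_exit = trace.t_ms[exit_i]
    in_win = (trace.t_ms >= t_exit) & (trace.t_ms <= t_exit + settle_ms)
    d = np.linalg.norm(trace.xy[in_win] - target_center, axis=1)
    d = d[trace.valid[in_win]]
    correct = bool(d.size and np.min(d) < radius_deg)
    landing_error = float(np.linalg.norm(event.offset_pos - target_center))
    return correct, landing_error
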