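"""Synthetic cued-saccade trials and simulated psychophysical observers.

The generator emulates the four-aperture, centrally cued saccade task:
fixation with jitter, a latency-distributed main-sequence saccade with
landing scatter and occasional mis-selection of a non-cued aperture, and
post-saccadic smooth drift along the selected aperture's motion direction at
configurable open-loop and foveally-guided gains.  Every trial carries its
ground truth so downstream detection and gain estimates can be checked
against the generating parameters.

The generator is field-agnostic: callers pass the gain appropriate to the
cued field (intact vs cortically blind) through the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace_io import GazeTrace, TrialLayout

__all__ = [
    "OculomotorProfile",
    "TrialRecord",
    "SimObserver",
    "square_layout",
    "make_trial",
    "make_session",
    "observe",
]

#: main-sequence approximation: duration = slope * amplitude + intercept
MAIN_SEQUENCE_MS_PER_DEG = 2.2
MAIN_SEQUENCE_INTERCEPT_MS = 21.0

#: drift-velocity decay time constant after the open-loop epoch when the
#: stimulus is absent at landing (ms)
DECAY_TAU_MS = 100.0

#: open-loop epoch length: pre-saccadic motion drives drift for this long
#: after saccade offset before foveal feedback can take over (ms)
OPEN_LOOP_MS = 100.0


@dataclass
class OculomotorProfile:
    """Generating parameters for one simulated participant/field.

    ``open_loop_gain`` is the drift velocity in the 0-100 ms post-offset
    epoch as a fraction of target speed; ``foveal_gain`` applies in the
    100-200 ms epoch when the stimulus is present at landing.  Landing
    scatter is an isotropic 2D Gaussian parameterized by its mean absolute
    radial error (per-axis sigma = MAE / sqrt(pi/2)).  Latencies are
    Gaussian truncated at ``min_latency_ms``.
    """

    open_loop_gain: float = 0.157
    foveal_gain: float = 0.186
    latency_mean_ms: float = 360.0
    latency_sd_ms: float = 45.0
    landing_mae_deg: float = 1.59
    misselect_prob: float = 0.0
    fixation_noise_sd_deg: float = 0.08
    sample_rate_hz: float = 220.0
    min_latency_ms: float = 100.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.open_loop_gain <= 1.0:
            raise ValueError("open_loop_gain must be in [-1, 1]")
        if not -1.0 <= self.foveal_gain <= 1.0:
            raise ValueError("foveal_gain must be in [-1, 1]")
        if not 0.0 <= self.misselect_prob <= 1.0:
            raise ValueError("misselect_prob must be in [0, 1]")
        for name in ("latency_sd_ms", "landing_mae_deg", "fixation_noise_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def landing_sigma_deg(self) -> float:
        """Per-axis Gaussian sigma giving the requested mean absolute radial error."""
        return self.landing_mae_deg / np.sqrt(np.pi / 2.0)


@dataclass
class TrialRecord:
    """One generated trial: trace, layout, cue time and generator ground truth."""

    trace: GazeTrace
    layout: TrialLayout
    cue_time_ms: float
    ground_truth: dict
    seed: int


@dataclass
class SimObserver:
    """Bernoulli observer for the 2AFC global-direction task.

    Probability correct falls with direction range as a decreasing
    Weibull-type function anchored so that p(threshold_range_deg) = 0.75.
    """

    threshold_range_deg: float
    slope: float = 2.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_range_deg <= 360.0:
            raise ValueError("threshold_range_deg must be in [0, 360]")
        if self.guess_rate != 0.5:
            raise ValueError("guess_rate is fixed at 0.5 (2AFC)")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    @property
    def alpha(self) -> float:
        """Weibull scale such that p(threshold_range_deg) = 0.75."""
        span = 1.0 - self.guess_rate - self.lapse_rate
        # 0.75 = guess + span * exp(-(thr/alpha)^beta)
        target = (0.75 - self.guess_rate) / span
        if target <= 0 or target >= 1:
            raise ValueError("lapse_rate too large for a 75% threshold")
        return self.threshold_range_deg / (-np.log(target)) ** (1.0 / self.slope)

    def p_correct(self, range_deg: float | np.ndarray) -> np.ndarray:
        """Probability of a correct response at the given direction range."""
        r = np.asarray(range_deg, dtype=float)
        if np.any((r < 0) | (r > 360)):
            raise ValueError("range_deg must be in [0, 360]")
        span = 1.0 - self.guess_rate - self.lapse_rate
        if self.threshold_range_deg == 0.0:
            # degenerate chance observer: no usable signal at any range
            return np.full_like(r, self.guess_rate)
        decay = np.exp(-((r / self.alpha) ** self.slope))
        return self.guess_rate + span * decay


def observe(
    observer: SimObserver, range_deg: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli draw of a correct/incorrect response at a range level."""
    p = float(observer.p_correct(range_deg))
    return bool(rng.random() < p)


def _tangential(center: np.ndarray, clockwise: bool) -> np.ndarray:
    u = center / np.linalg.norm(center)
    # counter-clockwise tangent is the 90 deg CCW rotation of the radial vector
    return np.array([u[1], -u[0]]) if clockwise else np.array([-u[1], u[0]])


def square_layout(
    target_index: int,
    stimulus_present: bool,
    ecc_xy: tuple[float, float] = (5.0, 5.0),
    clockwise: Sequence[bool] = (False, False, False, False),
    field_labels: tuple[str, str, str, str] = ("intact",) * 4,
    target_speed: float = 10.0,
) -> TrialLayout:
    """Standard four-quadrant aperture layout at (+-x, +-y) eccentricity.

    Aperture order: (+x,+y), (-x,+y), (-x,-y), (+x,-y).  Each aperture's
    motion runs tangentially to its center-out direction, clockwise or
    counter-clockwise per ``clockwise``.
    """
    ex, ey = ecc_xy
    centers = np.array([[ex, ey], [-ex, ey], [-ex, -ey], [ex, -ey]], dtype=float)
    dirs = np.array([_tangential(c, cw) for c, cw in zip(centers, clockwise)])
    return TrialLayout(
        aperture_centers=centers,
        target_index=target_index,
        motion_dirs=dirs,
        stimulus_present=stimulus_present,
        field_labels=field_labels,
        target_speed=target_speed,
    )


def _saccade_fraction(u: np.ndarray) -> np.ndarray:
    """Raised-cosine position profile on u in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def make_trial(
    profile: OculomotorProfile,
    layout: TrialLayout,
    seed: int | np.random.SeedSequence,
    cue_time_ms: float = 200.0,
    post_offset_ms: float = 300.0,
) -> TrialRecord:
    """Generate one cued-saccade trial.

    The trace runs from t=0 (fixation) through at least ``post_offset_ms``
    after the true saccade offset.  The saccade starts at cue time plus a
    truncated-Gaussian latency, follows a raised-cosine position profile
    whose duration scales with amplitude (main sequence), and lands at the
    selected aperture center plus isotropic Gaussian scatter.  After offset
    the eye drifts at ``open_loop_gain`` x target speed along the *selected*
    aperture's motion direction for 100 ms, then at ``foveal_gain`` x speed
    if the stimulus is present, else the drift velocity decays exponentially
    (tau = 100 ms).
    """
    if not isinstance(seed, (int, np.integer, np.random.SeedSequence)):
        raise TypeError("seed must be an int or SeedSequence")
    rng = np.random.default_rng(seed)
    speed = layout.target_speed

    # latency: Gaussian truncated at min_latency by rejection
    lat = rng.normal(profile.latency_mean_ms, profile.latency_sd_ms)
    while lat < profile.min_latency_ms:
        lat = rng.normal(profile.latency_mean_ms, profile.latency_sd_ms)

    # aperture selection and landing point
    misselected = rng.random() < profile.misselect_prob
    if misselected:
        others = [i for i in range(4) if i != layout.target_index]
        selected = int(rng.choice(others))
    else:
        selected = layout.target_index
    scatter = rng.normal(0.0, profile.landing_sigma_deg, size=2)
    endpoint = layout.aperture_centers[selected] + scatter
    mdir = layout.motion_dirs[selected]

    amplitude = float(np.linalg.norm(endpoint))
    duration = MAIN_SEQUENCE_MS_PER_DEG * amplitude + MAIN_SEQUENCE_INTERCEPT_MS
    t_on = cue_time_ms + lat
    t_off = t_on + duration

    dt = 1000.0 / profile.sample_rate_hz
    n = int(np.ceil((t_off + post_offset_ms) / dt)) + 1
    t = np.arange(n) * dt

    pos = np.zeros((n, 2))
    in_sac = (t >= t_on) & (t < t_off)
    pos[in_sac] = endpoint * _saccade_fraction((t[in_sac] - t_on) / duration)[:, None]

    after = t >= t_off
    ta = t[after] - t_off  # ms since offset
    v_open = profile.open_loop_gain * speed / 1000.0  # deg per ms
    drift = np.where(ta <= OPEN_LOOP_MS, v_open * ta, v_open * OPEN_LOOP_MS)
    late = np.clip(ta - OPEN_LOOP_MS, 0.0, None)
    if layout.stimulus_present:
        v_fov = profile.foveal_gain * speed / 1000.0
        drift = drift + v_fov * late
    else:
        # velocity decays exponentially; integrate to displacement
        drift = drift + v_open * DECAY_TAU_MS * (1.0 - np.exp(-late / DECAY_TAU_MS))
    pos[after] = endpoint + drift[:, None] * mdir

    # ground-truth correctness from the noise-free path: does gaze come
    # within 3.5 deg of the cued center within 90 ms of leaving the +-1 deg
    # fixation window?  (same rule the classifier applies downstream)
    r = np.linalg.norm(pos, axis=1)
    exit_candidates = np.flatnonzero((t >= t_on) & (r > layout.fixation_window_deg))
    if exit_candidates.size:
        t_exit = t[exit_candidates[0]]
        settle = (t >= t_exit) & (t <= t_exit + 90.0)
        d_target = np.linalg.norm(pos[settle] - layout.target_center, axis=1)
        gt_correct = bool(d_target.size and d_target.min() < 3.5)
    else:
        gt_correct = False

    if profile.fixation_noise_sd_deg > 0:
        pos = pos + rng.normal(0.0, profile.fixation_noise_sd_deg, size=pos.shape)

    trace = GazeTrace(t_ms=t, x_deg=pos[:, 0], y_deg=pos[:, 1])
    ground_truth = {
        "latency_ms": float(lat),
        "onset_ms": float(t_on),
        "offset_ms": float(t_off),
        "onset_idx": int(np.searchsorted(t, t_on)),
        "offset_idx": int(np.searchsorted(t, t_off)),
        "endpoint": endpoint.copy(),
        "selected_index": selected,
        "misselected": bool(misselected),
        "correct": gt_correct,
        "open_loop_gain": profile.open_loop_gain,
        "foveal_gain": profile.foveal_gain,
        "duration_ms": float(duration),
    }
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return TrialRecord(trace, layout, cue_time_ms, ground_truth, int(seed_int))


def make_session(
    profile: OculomotorProfile,
    layouts: Sequence[TrialLayout],
    n_trials: int,
    seed: int | np.random.SeedSequence,
) -> list[TrialRecord]:
    """Generate a balanced session of trials.

    Cue location cycles through the four apertures and stimulus-present
    alternates, so both factors are balanced to within rounding over the
    session.  ``layouts`` supplies template layouts (typically the four
    single-target variants); each trial re-targets and toggles
    stimulus-present on a copy.  Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(layouts) == 0:
        raise ValueError("layouts must be non-empty")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(n_trials)
    trials: list[TrialRecord] = []
    for k in range(n_trials):
        template = layouts[k % len(layouts)]
        layout = TrialLayout(
            aperture_centers=template.aperture_centers,
            target_index=k % 4,
            motion_dirs=template.motion_dirs,
            stimulus_present=(k // 4) % 2 == 0,
            field_labels=template.field_labels,
            target_speed=template.target_speed,
            aperture_diameter_deg=template.aperture_diameter_deg,
            fixation_window_deg=template.fixation_window_deg,
        )
        trials.append(make_trial(profile, layout, children[k]))
    return trials
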