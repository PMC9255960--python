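"""Direction-range staircase and Weibull threshold estimation.

The 2AFC global-direction task varies the *range* of dot directions (0-360
deg in 40-deg steps).  The staircase is 3-up/1-down: after three consecutive
correct responses the range increases one step (harder); every incorrect
response decreases it one step (easier).  A Weibull psychometric function,
decreasing in direction range,

    p(range) = 0.5 + (0.5 - lapse) * exp(-(range / alpha) ** beta)

is fit by maximum likelihood over all trials in a session; the direction-
range threshold is the level at which performance reaches 75% correct, and
the normalized direction range (NDR) threshold is

    NDR = (360 - threshold) / 360

so 0 means excellent motion integration and 1 poor or unmeasurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .gaze_synth import SimObserver, observe

__all__ = [
    "StaircaseState",
    "PsychSession",
    "PsychFit",
    "staircase_step",
    "run_session",
    "fit_weibull",
    "ndr",
    "LEVEL_STEP_DEG",
]

LEVEL_STEP_DEG = 40.0
MAX_LEVEL_DEG = 360.0
LAPSE_MAX = 0.06


@dataclass
class StaircaseState:
    """Current level (deg of direction range) and consecutive-correct count."""

    level: float = 0.0
    consecutive_correct: int = 0

    def __post_init__(self) -> None:
        if self.level not in np.arange(0.0, MAX_LEVEL_DEG + 1, LEVEL_STEP_DEG):
            raise ValueError("level must lie on the 0,40,...,360 lattice")


@dataclass
class PsychSession:
    """Per-trial staircase records for one visual field location."""

    levels_deg: np.ndarray
    correct: np.ndarray
    location_label: str = "intact"

    def __post_init__(self) -> None:
        self.levels_deg = np.asarray(self.levels_deg, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        if self.levels_deg.size != self.correct.size:
            raise ValueError("levels and responses must have equal length")

    @property
    def n_trials(self) -> int:
        return self.levels_deg.size


@dataclass
class PsychFit:
    """Weibull fit summary: scale/shape, lapse, threshold and NDR."""

    alpha: float
    beta: float
    lapse: float
    guess: float = 0.5
    range_threshold_deg: float = np.nan
    ndr: float = 1.0
    measurable: bool = False


def staircase_step(state: StaircaseState, response_correct: bool) -> StaircaseState:
    """Apply the 3-up/1-down transition rule and return the next state."""
    if response_correct:
        cc = state.consecutive_correct + 1
        if cc >= 3:
            return StaircaseState(
                min(state.level + LEVEL_STEP_DEG, MAX_LEVEL_DEG), 0
            )
        return StaircaseState(state.level, cc)
    return StaircaseState(max(state.level - LEVEL_STEP_DEG, 0.0), 0)


def run_session(
    observer: SimObserver,
    n_trials: int = 100,
    seed: int | np.random.SeedSequence = 0,
    location_label: str = "intact",
) -> PsychSession:
    """Simulate one staircase session against a Bernoulli observer."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    state = StaircaseState()
    levels = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    for k in range(n_trials):
        levels[k] = state.level
        correct[k] = observe(observer, state.level, rng)
        state = staircase_step(state, correct[k])
    return PsychSession(levels, correct, location_label)


def _nll(theta: np.ndarray, levels: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    log_alpha, log_beta, lapse = theta
    alpha, beta = np.exp(log_alpha), np.exp(log_beta)
    p = 0.5 + (0.5 - lapse) * np.exp(-((levels / alpha) ** beta))
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))


def threshold_from_params(alpha: float, beta: float, lapse: float) -> float:
    """Direction-range level at which the fitted function crosses 75% correct."""
    target = 0.25 / (0.5 - lapse)  # exp(-(thr/alpha)^beta) at p = 0.75
    return float(alpha * (-np.log(target)) ** (1.0 / beta))


def fit_weibull(session: PsychSession) -> PsychFit:
    """Maximum-likelihood Weibull fit over all trials, pooled by level.

    Guess rate is fixed at 0.5 (2AFC); the lapse rate is fitted but bounded
    in [0, 0.06].  Three starting points guard against local optima.  The
    fit is flagged unmeasurable (NDR = 1) for degenerate sessions (a single
    level, or all responses identical) and when the fitted 75% threshold
    falls outside (0, 360].
    """
    if session.n_trials == 0:
        raise ValueError("empty session")
    uniq, inv = np.unique(session.levels_deg, return_inverse=True)
    n = np.bincount(inv).astype(float)
    k = np.bincount(inv, weights=session.correct.astype(float))

    degenerate = uniq.size < 2 or session.correct.all() or (~session.correct).all()
    if degenerate:
        return PsychFit(np.nan, np.nan, np.nan)

    # levels=0 are fine: (0/alpha)^beta = 0 gives p = 1 - lapse there
    bounds = [(np.log(1.0), np.log(5000.0)), (np.log(0.2), np.log(10.0)), (0.0, LAPSE_MAX)]
    best = None
    for alpha0 in (80.0, 200.0, 330.0):
        res = minimize(
            _nll,
            x0=np.array([np.log(alpha0), np.log(2.0), 0.01]),
            args=(uniq, k, n),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return PsychFit(np.nan, np.nan, np.nan)
    alpha, beta = np.exp(best.x[0]), np.exp(best.x[1])
    lapse = float(best.x[2])
    thr = threshold_from_params(alpha, beta, lapse)
    if not np.isfinite(thr) or thr <= 0 or thr > MAX_LEVEL_DEG:
        return PsychFit(alpha, beta, lapse)
    return PsychFit(
        alpha,
        beta,
        lapse,
        range_threshold_deg=thr,
        ndr=ndr(thr),
        measurable=True,
    )


def ndr(range_threshold_deg: float | None) -> float:
    """Normalized direction range threshold; unmeasurable (None/NaN) maps to 1."""
    if range_threshold_deg is None or not np.isfinite(range_threshold_deg):
        return 1.0
    if not 0.0 <= range_threshold_deg <= MAX_LEVEL_DEG:
        raise ValueError("threshold must be in [0, 360]")
    return float((MAX_LEVEL_DEG - range_threshold_deg) / MAX_LEVEL_DEG)
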