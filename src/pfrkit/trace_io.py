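"""Plain-text I/O for gaze trials and session manifests.

Trial files are CSV with header ``t_ms,x_deg,y_deg,valid`` followed by a
comment-style metadata block (lines starting with ``#``) holding the trial
layout and cue time.  Positions are degrees of visual angle, screen-centered,
rightward/upward positive; any y-down source must be flipped at import.
Session manifests are JSON.

No proprietary eye-tracker binary formats (EDF/Arrington native) are parsed;
an adapter for externally deposited datasets is left as a stub.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GazeTrace",
    "TrialLayout",
    "read_trial",
    "write_trial",
    "write_manifest",
    "read_manifest",
]


@dataclass
class GazeTrace:
    """Timestamped 2D eye position for one trial.

    Parameters
    ----------
    t_ms : array
        Strictly increasing sample times in milliseconds.  The nominal
        sampling interval must be constant to within 10%.
    x_deg, y_deg : array
        Eye position in degrees of visual angle (screen-centered, x right,
        y up).
    valid : bool array, optional
        Per-sample validity flag (False during blinks / track loss).
        Non-finite positions are flagged invalid automatically.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        n = self.t_ms.size
        if self.x_deg.size != n or self.y_deg.size != n:
            raise ValueError("t_ms, x_deg, y_deg must have equal length")
        if n == 0:
            raise ValueError("empty trace")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != n:
                raise ValueError("valid flag length mismatch")
        # samples with non-finite coordinates are unusable regardless of flag
        finite = np.isfinite(self.x_deg) & np.isfinite(self.y_deg)
        self.valid = self.valid & finite
        if n >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise ValueError("t_ms must be strictly increasing")
            med = np.median(dt)
            if np.any(np.abs(dt - med) > 0.10 * med):
                raise ValueError("sampling interval varies by more than 10%")

    def __len__(self) -> int:
        return self.t_ms.size

    @property
    def dt_ms(self) -> float:
        """Nominal sampling interval in ms."""
        if len(self) < 2:
            raise ValueError("need >= 2 samples for a sampling interval")
        return float(np.median(np.diff(self.t_ms)))

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array."""
        return np.column_stack([self.x_deg, self.y_deg])

    def position_at(self, t_ms: float) -> np.ndarray:
        """Raw (non-smoothed) position at the sample nearest to ``t_ms``."""
        i = int(np.argmin(np.abs(self.t_ms - t_ms)))
        return self.xy[i]


@dataclass
class TrialLayout:
    """Geometry and motion metadata for the four-aperture cued saccade task.

    ``motion_dirs`` are unit vectors tangential (clockwise or
    counter-clockwise) to the center-out direction of each aperture, so the
    stimulus motion is orthogonal to the saccade vector.
    """

    aperture_centers: np.ndarray  # (4, 2) deg
    target_index: int
    motion_dirs: np.ndarray  # (4, 2) unit vectors
    stimulus_present: bool
    field_labels: tuple[str, str, str, str] = ("intact", "intact", "intact", "intact")
    target_speed: float = 10.0  # deg/s
    aperture_diameter_deg: float = 5.5
    fixation_window_deg: float = 1.0

    def __post_init__(self) -> None:
        self.aperture_centers = np.asarray(self.aperture_centers, dtype=float)
        self.motion_dirs = np.asarray(self.motion_dirs, dtype=float)
        if self.aperture_centers.shape != (4, 2):
            raise ValueError("exactly 4 aperture centers required")
        if self.motion_dirs.shape != (4, 2):
            raise ValueError("exactly 4 motion directions required")
        if not 0 <= self.target_index < 4:
            raise ValueError("target_index must be in 0..3")
        if self.target_speed <= 0:
            raise ValueError("target_speed must be positive")
        norms = np.linalg.norm(self.motion_dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("motion_dirs must be unit vectors")
        # tangential constraint: motion orthogonal to fixation-to-aperture vector
        radial = self.aperture_centers / np.linalg.norm(
            self.aperture_centers, axis=1, keepdims=True
        )
        dots = np.abs(np.sum(radial * self.motion_dirs, axis=1))
        if np.any(dots > 1e-6):
            raise ValueError("motion_dirs must be tangential to the center-out direction")
        if len(self.field_labels) != 4 or any(
            lab not in ("intact", "blind") for lab in self.field_labels
        ):
            raise ValueError("field_labels must be four of 'intact'|'blind'")

    @property
    def target_center(self) -> np.ndarray:
        return self.aperture_centers[self.target_index]

    @property
    def target_motion_dir(self) -> np.ndarray:
        return self.motion_dirs[self.target_index]

    def to_dict(self) -> dict:
        return {
            "aperture_centers": self.aperture_centers.tolist(),
            "target_index": int(self.target_index),
            "motion_dirs": self.motion_dirs.tolist(),
            "stimulus_present": bool(self.stimulus_present),
            "field_labels": list(self.field_labels),
            "target_speed": float(self.target_speed),
            "aperture_diameter_deg": float(self.aperture_diameter_deg),
            "fixation_window_deg": float(self.fixation_window_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialLayout":
        return cls(
            aperture_centers=np.asarray(d["aperture_centers"]),
            target_index=int(d["target_index"]),
            motion_dirs=np.asarray(d["motion_dirs"]),
            stimulus_present=bool(d["stimulus_present"]),
            field_labels=tuple(d.get("field_labels", ("intact",) * 4)),
            target_speed=float(d.get("target_speed", 10.0)),
            aperture_diameter_deg=float(d.get("aperture_diameter_deg", 5.5)),
            fixation_window_deg=float(d.get("fixation_window_deg", 1.0)),
        )


def write_trial(
    trace: GazeTrace, layout: TrialLayout, cue_time_ms: float, path: str | Path
) -> None:
    """Write one trial as CSV; layout + cue time go in a ``#meta`` header line.

    Positions are written with enough digits for a lossless round trip at
    1e-9 precision.
    """
    path = Path(path)
    meta = {"cue_time_ms": float(cue_time_ms), "layout": layout.to_dict()}
    with open(path, "w") as fh:
        fh.write("#meta " + json.dumps(meta) + "\n")
        fh.write("t_ms,x_deg,y_deg,valid\n")
        for t, x, y, v in zip(trace.t_ms, trace.x_deg, trace.y_deg, trace.valid):
            fh.write(f"{t:.6f},{x:.12g},{y:.12g},{int(v)}\n")


def read_trial(path: str | Path) -> tuple[GazeTrace, TrialLayout, float]:
    """Read a trial CSV written by :func:`write_trial`.

    Samples with non-finite positions are flagged invalid, not dropped.
    Raises on missing columns or non-monotonic time.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#meta "):
            raise ValueError(f"{path}: missing #meta header line")
        meta = json.loads(first[len("#meta "):])
        df = pd.read_csv(fh)
    required = {"t_ms", "x_deg", "y_deg", "valid"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    trace = GazeTrace(
        t_ms=df["t_ms"].to_numpy(),
        x_deg=df["x_deg"].to_numpy(),
        y_deg=df["y_deg"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
    )
    layout = TrialLayout.from_dict(meta["layout"])
    return trace, layout, float(meta["cue_time_ms"])


def write_manifest(
    participant_id: str,
    trial_paths: list[str | Path],
    field_labels: dict[str, str],
    path: str | Path,
) -> None:
    """Write a JSON session manifest referencing per-trial CSV files."""
    path = Path(path)
    entries = []
    for p in trial_paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing trial file {p}")
        entries.append(str(p))
    manifest = {
        "participant": participant_id,
        "field_labels": field_labels,
        "trials": entries,
    }
    path.write_text(json.dumps(manifest, indent=1))


def read_manifest(path: str | Path) -> dict:
    """Read and validate a session manifest; every trial file must exist."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    for key in ("participant", "trials"):
        if key not in manifest:
            raise ValueError(f"manifest missing key {key!r}")
    for p in manifest["trials"]:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest references missing trial file {p}")
    return manifest


def import_deposit(path: str | Path):  # pragma: no cover - stub
    """Adapter for externally deposited raw datasets (layout undocumented).

    Not implemented: convert such data to the CSV/JSON formats above first.
    """
    raise NotImplementedError(
        "external deposit layout is not documented; convert to trial CSVs first"
    )
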