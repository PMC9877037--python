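"""Preprocessing of calcium traces and tracked behavior.

Converts raw fluorescence traces into a binary activity matrix (a cell is
"active" on frames where its filtered, z-scored trace exceeds a threshold
while rising), derives running speed from tracked position, and segments a
linear-track session into tone-cued runs, trials, and the task variables
(elapsed time and distance traveled since departure from the reward site).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SessionBehavior",
    "NeuralData",
    "compute_speed",
    "locomotion_mask",
    "binarize_traces",
    "derive_task_variables",
]


@dataclass
class SessionBehavior:
    """Frame-aligned behavior of one recording session.

    ``position`` is 1-D (cm along the track) or ``(n, 2)`` (open field, cm).
    ``elapsed_s`` and ``distance_cm`` are measured since the most recent
    departure from the reward site and reset together; ``tone_state`` counts
    completed runs within the current trial (0..runs_per_reward-1);
    ``trial_correct`` marks frames belonging to trials without any
    direction-reversal error.
    """

    time_s: np.ndarray
    position: np.ndarray
    speed: np.ndarray
    locomotion_mask: np.ndarray
    elapsed_s: np.ndarray
    distance_cm: np.ndarray
    tone_state: np.ndarray
    trial_id: np.ndarray
    trial_correct: np.ndarray
    stim_mask: np.ndarray
    frame_rate: float
    runs: Optional[pd.DataFrame] = None
    reward_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("speed", "locomotion_mask", "elapsed_s", "distance_cm",
                     "tone_state", "trial_id", "trial_correct", "stim_mask"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if len(self.position) != n:
            raise ValueError(f"position has length {len(self.position)}, expected {n}")
        if np.any(self.elapsed_s < 0) or np.any(self.distance_cm < 0):
            raise ValueError("elapsed_s and distance_cm must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def is_2d(self) -> bool:
        return self.position.ndim == 2

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time_s}
        if self.is_2d:
            cols["x_cm"] = self.position[:, 0]
            cols["y_cm"] = self.position[:, 1]
        else:
            cols["x_cm"] = self.position
        cols.update(
            speed_cm_s=self.speed,
            locomotion=self.locomotion_mask.astype(int),
            tone_state=self.tone_state,
            trial_id=self.trial_id,
            trial_correct=self.trial_correct.astype(int),
            elapsed_s=self.elapsed_s,
            distance_cm=self.distance_cm,
            stim_on=self.stim_mask.astype(int),
        )
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float) -> "SessionBehavior":
        if "y_cm" in df.columns:
            position = df[["x_cm", "y_cm"]].to_numpy(float)
        else:
            position = df["x_cm"].to_numpy(float)
        return cls(
            time_s=df["time_s"].to_numpy(float),
            position=position,
            speed=df["speed_cm_s"].to_numpy(float),
            locomotion_mask=df["locomotion"].to_numpy() > 0,
            elapsed_s=df["elapsed_s"].to_numpy(float),
            distance_cm=df["distance_cm"].to_numpy(float),
            tone_state=df["tone_state"].to_numpy(int),
            trial_id=df["trial_id"].to_numpy(int),
            trial_correct=df["trial_correct"].to_numpy() > 0,
            stim_mask=df["stim_on"].to_numpy() > 0,
            frame_rate=frame_rate,
        )

    def replace(self, **kwargs) -> "SessionBehavior":
        return dataclasses.replace(self, **kwargs)


@dataclass
class NeuralData:
    """Raw dF/F traces and the matching binarized activity matrix."""

    traces: np.ndarray          # cells x frames, dF/F
    binary: np.ndarray          # cells x frames, {0, 1}
    frame_rate: float
    cell_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, float))
        self.binary = np.atleast_2d(np.asarray(self.binary))
        if self.traces.shape != self.binary.shape:
            raise ValueError("traces and binary must have the same shape")
        vals = np.unique(self.binary)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("binary matrix must contain only 0 and 1")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.traces.shape[0])

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


def compute_speed(
    position: np.ndarray,
    time_s: np.ndarray,
    smooth_sigma_s: float = 0.033,
) -> np.ndarray:
    """Instantaneous speed |Δd|/Δt, Gaussian-smoothed.

    Position may be 1-D or (n, 2). The first value is duplicated so the
    output has one speed per frame. ``smooth_sigma_s`` is the Gaussian sigma
    in seconds (33 ms removes single-frame tracking glitches).
    """
    position = np.asarray(position, float)
    time_s = np.asarray(time_s, float)
    if len(time_s) < 2:
        raise ValueError("need at least two frames to compute speed")
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    if position.ndim == 2:
        step = np.linalg.norm(np.diff(position, axis=0), axis=1)
    else:
        step = np.abs(np.diff(position))
    speed = step / dt
    speed = np.concatenate([[speed[0]], speed])
    if smooth_sigma_s > 0:
        sigma_frames = smooth_sigma_s / float(np.median(dt))
        speed = gaussian_filter1d(speed, sigma_frames, mode="nearest")
    return np.maximum(speed, 0.0)


def locomotion_mask(speed: np.ndarray, threshold_cm_s: float) -> np.ndarray:
    """Boolean mask of locomotion frames (speed strictly above threshold).

    Use 5 cm/s on the linear track and 2 cm/s in the open field.
    """
    if threshold_cm_s <= 0:
        raise ValueError("threshold_cm_s must be positive")
    return np.asarray(speed, float) > threshold_cm_s


def binarize_traces(
    traces: np.ndarray,
    frame_rate: float,
    z_threshold: float = 2.0,
    lowpass_hz: float = 2.0,
) -> np.ndarray:
    """Binarize dF/F traces: active where the filtered z-scored trace is
    above ``z_threshold`` and rising.

    Each trace is low-pass filtered (zero-phase 4th-order Butterworth at
    ``lowpass_hz``), z-scored over the whole session, and a frame is marked
    active when z > z_threshold and the first difference of the filtered
    trace is positive (the difference is attributed to the later frame, so
    frame 0 is never active). Only the rising phase of a calcium transient
    is retained, which makes the binary events a proxy for onsets rather
    than for the slow decay.

    Constant (zero-variance) traces yield all-zero rows.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    if frame_rate <= 2 * lowpass_hz:
        raise ValueError("frame_rate must exceed twice the low-pass cutoff")
    sos = signal.butter(4, lowpass_hz, btype="low", fs=frame_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, traces, axis=1)
    sd = filtered.std(axis=1, keepdims=True)
    mean = filtered.mean(axis=1, keepdims=True)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (filtered - mean) / safe_sd
    z[sd[:, 0] == 0, :] = 0.0
    rising = np.zeros_like(z, dtype=bool)
    rising[:, 1:] = np.diff(z, axis=1) > 0
    return ((z > z_threshold) & rising).astype(np.uint8)


def _end_zone(position: np.ndarray, track_length: float, tol_cm: float) -> np.ndarray:
    """-1/0/+1 label per frame: near start end, in the middle, near far end."""
    zone = np.zeros(len(position), dtype=int)
    zone[position <= tol_cm] = -1
    zone[position >= track_length - tol_cm] = 1
    return zone


def derive_task_variables(
    position: np.ndarray,
    time_s: np.ndarray,
    track_length: float,
    frame_rate: float,
    runs_per_reward: int = 4,
    end_tol_cm: float = 3.0,
    depart_cm: float = 5.0,
    speed: Optional[np.ndarray] = None,
    locomotion_threshold_cm_s: float = 5.0,
    stim_mask: Optional[np.ndarray] = None,
) -> SessionBehavior:
    """Reconstruct task structure from a 1-D trajectory.

    End-sensor crossings are detected when the trajectory enters the zone
    within ``end_tol_cm`` of either track end coming from the opposite end.
    Each crossing completes a run and advances the tone state; the
    ``runs_per_reward``-th crossing (back at the reward end, position 0)
    delivers a reward. Errors follow the sensors' operational scoring: a
    run is an error when the mouse re-enters the end zone it departed from
    before triggering the opposite sensor (a return to the empty reward
    site, including false starts). Mid-run meanders that stay clear of the
    end zones are not errors. ``elapsed_s`` and ``distance_cm`` reset at
    the departure from the reward site, i.e. the first frame after a
    reward where position exceeds ``depart_cm``.
    """
    position = np.asarray(position, float)
    time_s = np.asarray(time_s, float)
    if position.ndim != 1:
        raise ValueError("derive_task_variables expects a 1-D track position")
    if np.any(position < -end_tol_cm) or np.any(position > track_length + end_tol_cm):
        raise ValueError("position outside the track bounds")
    n = len(position)
    zone = _end_zone(position, track_length, end_tol_cm)

    # --- run segmentation by end-zone visits -------------------------------
    runs = []            # (end_frame, error_flag) per completed run
    tone_state = np.zeros(n, dtype=int)
    trial_id = np.zeros(n, dtype=int)
    reward_frames = []

    last_end = -1        # assume session starts at the reward end (pos 0)
    run_error = False
    has_left = False     # well clear of the origin end zone since run start
    run_count = 0
    tone = 0
    trial = 0
    tone_series = np.zeros(n, dtype=int)
    trial_series = np.zeros(n, dtype=int)
    for i in range(n):
        x = position[i]
        origin_pos = 0.0 if last_end == -1 else track_length
        if abs(x - origin_pos) > end_tol_cm + 2.0:
            has_left = True
        if zone[i] == last_end and has_left:
            # back at the sensor it departed from: error
            run_error = True
            has_left = False
        elif zone[i] == -last_end and zone[i] != 0:
            # completed a run into the opposite end zone
            run_count += 1
            runs.append({"end_frame": i, "error": run_error,
                         "direction": -last_end, "trial": trial})
            run_error = False
            has_left = False
            last_end = zone[i]
            if run_count % runs_per_reward == 0:
                reward_frames.append(i)
                tone = 0
                trial += 1
            else:
                tone += 1
        tone_series[i] = tone
        trial_series[i] = trial

    runs_df = pd.DataFrame(runs) if runs else pd.DataFrame(
        columns=["end_frame", "error", "direction", "trial"])

    # --- trial correctness -------------------------------------------------
    trial_correct_by_id = {}
    for t, grp in runs_df.groupby("trial"):
        trial_correct_by_id[int(t)] = not bool(grp["error"].any())
    trial_correct = np.array(
        [trial_correct_by_id.get(int(t), True) for t in trial_series], dtype=bool)

    # --- elapsed time and distance since reward-site departure -------------
    step = np.concatenate([[0.0], np.abs(np.diff(position))])
    cum_dist = np.cumsum(step)
    elapsed = np.zeros(n)
    distance = np.zeros(n)
    # departure anchors: session start plus first frame after each reward
    # where position exceeds depart_cm
    anchors = [0]
    for rf in reward_frames:
        beyond = np.flatnonzero(position[rf:] > depart_cm)
        if len(beyond):
            anchors.append(rf + beyond[0])
    anchors = sorted(set(anchors))
    bounds = anchors + [n]
    for a, b in zip(anchors, bounds[1:]):
        elapsed[a:b] = time_s[a:b] - time_s[a]
        distance[a:b] = cum_dist[a:b] - cum_dist[a]

    if speed is None:
        speed = compute_speed(position, time_s)
    loco = locomotion_mask(speed, locomotion_threshold_cm_s)
    if stim_mask is None:
        stim_mask = np.zeros(n, dtype=bool)

    return SessionBehavior(
        time_s=time_s,
        position=position,
        speed=np.asarray(speed, float),
        locomotion_mask=loco,
        elapsed_s=elapsed,
        distance_cm=distance,
        tone_state=tone_series,
        trial_id=trial_series,
        trial_correct=trial_correct,
        stim_mask=np.asarray(stim_mask, bool),
        frame_rate=frame_rate,
        runs=runs_df,
        reward_times=time_s[np.asarray(reward_frames, int)] if reward_frames else np.array([]),
    )
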