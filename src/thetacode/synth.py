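"""Synthetic sessions with known ground truth.

Generates (i) linear-track behavior with the three-tone / reward-every-4th-run
trial structure, (ii) Bernoulli-tuned neurons with calcium-kernel convolution
and noise, (iii) LFP with 1/f background, speed-coupled theta, optogenetic
stimulation epochs and injected ripples, and (iv) open-field random-walk
sessions. Every generator is a pure function of its parameters and a seed.

A note on trajectory realism: on a back-and-forth track, perfectly
stereotyped runs make distance-since-reward a deterministic function of
(run index, position), so any position-tuned cell would carry genuine
distance information and no exclusive coding could exist. Mice are not
stereotyped — they pause, hesitate mid-run, poke out of the reward site and
come back, and occasionally reverse direction (scored as errors). The track
generator reproduces this non-stereotypy (per-run speed jitter, end pauses
with sub-threshold wander, mid-run hesitations, false starts, reversal
errors), which decorrelates position, elapsed time, and distance the same
way real behavior does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import (
    NeuralData,
    SessionBehavior,
    compute_speed,
    locomotion_mask,
)
from .lfp import LFPSignal

__all__ = [
    "TrackConfig",
    "CellSpec",
    "LfpPlan",
    "GroundTruth",
    "simulate_track_session",
    "simulate_neurons",
    "simulate_lfp",
    "simulate_open_field",
    "make_population",
]

VARIABLE_NAMES = ("location", "time", "distance")


@dataclass
class TrackConfig:
    """Parameters of a simulated linear-track session.

    Errors follow the task's operational scoring (end sensors only): a run
    is an error when the mouse returns to the end zone it started from
    before triggering the opposite sensor. ``error_rate`` is the per-run
    probability of such a full return; ``false_start_prob`` the per-trial
    probability of poking out of the reward site and coming back (also an
    error). With the defaults the expected fraction of correct trials is
    ~0.78, matching baseline behavior on this task.

    The remaining fields model the non-stereotyped movements that do NOT
    trip the end sensors but decorrelate position, elapsed time and
    distance: slow sniffing departures from the reward site,
    sub-threshold hesitations, supra-threshold mid-run exploration bouts,
    and long rest bouts.
    """

    track_length: float = 134.0        # cm
    n_runs: int = 56
    runs_per_reward: int = 4
    mean_speed: float = 20.0           # cm/s
    speed_cv: float = 0.45
    pause_range: Tuple[float, float] = (1.0, 8.0)   # s at each track end
    error_rate: float = 0.02
    frame_rate: float = 30.0           # Hz
    false_start_prob: float = 0.15
    hesitation_rate: float = 0.8       # expected mid-run hesitations per run
    wander_speed: float = 3.0          # cm/s during pauses (below threshold)
    slow_departure_prob: float = 1.0   # sniffing departure from reward site
    exploration_rate: float = 0.4      # mid-run meander bouts per run
    rest_rate: float = 0.4             # long mid-run rest bouts per run
    partial_reversal_rate: float = 1.2  # partial double-backs per run
    reversal_depth: Tuple[float, float] = (10.0, 60.0)  # cm
    trial_pace_sd: float = 0.45        # log-SD of the per-trial pace factor

    def validate(self) -> None:
        if self.track_length <= 0:
            raise ValueError("track_length must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if self.runs_per_reward < 1:
            raise ValueError("runs_per_reward must be at least 1")
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 0 <= self.false_start_prob < 1:
            raise ValueError("false_start_prob must lie in [0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pause_range[0] < 0 or self.pause_range[1] < self.pause_range[0]:
            raise ValueError("pause_range must be a non-decreasing pair of non-negative values")


@dataclass
class CellSpec:
    """Bernoulli tuning of one simulated neuron.

    ``cell_class`` is one of place/time/distance/conjunctive/untuned. For a
    single-variable cell the field is a Gaussian bump over that variable:
    the per-frame activation probability is
    ``baseline + (peak - baseline) * exp(-(v - center)^2 / (2 width^2))``.
    Conjunctive cells multiply the Gaussian factors of every component.

    ``visit_reliability`` is the probability that any given traversal of
    the field engages the cell at all (hippocampal cells are typically
    active on only a fraction of passes through their field); on skipped
    traversals the cell stays at baseline.
    """

    cell_class: str
    field_center: Optional[float] = None
    field_width: Optional[float] = None
    peak_prob: float = 0.3
    baseline_prob: float = 0.02
    conjunctive_components: Tuple[Tuple[str, float, float], ...] = ()
    visit_reliability: float = 0.5

    def validate(self) -> None:
        if self.cell_class not in ("place", "time", "distance", "conjunctive", "untuned"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if not 0 <= self.baseline_prob < self.peak_prob <= 1 and self.cell_class != "untuned":
            raise ValueError("need 0 <= baseline_prob < peak_prob <= 1")
        if self.cell_class in ("place", "time", "distance"):
            if self.field_center is None or self.field_width is None or self.field_width <= 0:
                raise ValueError("tuned cells need field_center and positive field_width")
        if self.cell_class == "conjunctive" and len(self.conjunctive_components) < 2:
            raise ValueError("conjunctive cells need at least two components")

    def components(self) -> Tuple[Tuple[str, float, float], ...]:
        if self.cell_class == "untuned":
            return ()
        if self.cell_class == "conjunctive":
            return self.conjunctive_components
        mapping = {"place": "location", "time": "time", "distance": "distance"}
        return ((mapping[self.cell_class], self.field_center, self.field_width),)


@dataclass
class LfpPlan:
    """Recipe for a synthetic LFP trace."""

    duration: float                    # s
    fs: float = 1000.0                 # Hz
    theta_base_freq: float = 6.0       # Hz at zero speed
    theta_speed_gain: float = 0.05     # Hz per cm/s
    theta_amp: float = 40.0            # uV
    noise_exponent: float = 1.0        # 1/f slope of the background
    noise_sd: float = 20.0             # uV
    stim_epochs: Tuple[Tuple[float, float, str], ...] = ()
    ripple_times: Tuple[float, ...] = ()
    ripple_freq: float = 180.0         # Hz
    ripple_amp_sd: float = 8.0         # amplitude in background-SD units
    ripple_envelope_sd: float = 0.015  # s

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs < 1000:
            raise ValueError("fs must be at least 1000 Hz")
        if not 150 <= self.ripple_freq <= 250:
            raise ValueError("ripple_freq must lie in [150, 250] Hz")
        epochs = sorted(self.stim_epochs)
        for (s, e, pat) in epochs:
            if not 0 <= s < e <= self.duration:
                raise ValueError("stim_epochs must lie within the recording duration")
            if pat not in ("none", "pace8", "scrambled", "random_freq"):
                raise ValueError(f"unknown stimulation pattern {pat!r}")
        for (a, b) in zip(epochs, epochs[1:]):
            if b[0] < a[1]:
                raise ValueError("stim_epochs must not overlap")


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""

    rng_seed: int
    cell_classes: Optional[List[str]] = None
    cell_specs: Optional[List[CellSpec]] = None
    activations: Optional[np.ndarray] = None          # cells x frames, bool
    ripple_times_s: Optional[np.ndarray] = None
    epoch_patterns: Optional[List[Tuple[float, float, str]]] = None
    epoch_frequencies: Optional[List[float]] = None   # for random_freq epochs
    pause_fraction: Optional[float] = None


class _Trajectory:
    """Incremental 1-D trajectory builder (piecewise-constant velocity)."""

    def __init__(self, frame_rate: float, x0: float = 0.0):
        self.fr = frame_rate
        self.x = [x0]
        self.pause_frames = 0

    @property
    def pos(self) -> float:
        return self.x[-1]

    @property
    def n(self) -> int:
        return len(self.x)

    def move_to(self, target: float, speed: float) -> None:
        dist = abs(target - self.pos)
        n = max(1, int(round(dist / speed * self.fr)))
        self.x.extend(np.linspace(self.pos, target, n + 1)[1:])

    def pause(self, duration: float, rng: np.random.Generator,
              wander_speed: float, lo: float, hi: float) -> None:
        n = int(round(duration * self.fr))
        if n <= 0:
            return
        steps = rng.normal(0.0, 0.5 * wander_speed / self.fr, n)
        xs = self.pos + np.cumsum(steps)
        xs = np.clip(xs, lo, hi)
        self.x.extend(xs)
        self.pause_frames += n


def simulate_track_session(cfg: TrackConfig, seed: int) -> SessionBehavior:
    """Simulate a tone-cued linear-track session.

    The mouse shuttles between the reward end (x = 0) and the far end
    (x = track_length). Completing a run triggers the end sensor and
    advances the tone; every ``runs_per_reward``-th run ends back at the
    reward site and delivers a reward. Elapsed time and traveled distance
    reset when the mouse departs (> 5 cm) from the reward site.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    fr = cfg.frame_rate
    L = cfg.track_length
    traj = _Trajectory(fr, x0=0.0)

    runs = []
    reward_frames = []
    run_end_frames = []
    errors_per_run = []

    def draw_speed() -> float:
        v = rng.normal(cfg.mean_speed, cfg.speed_cv * cfg.mean_speed) * pace
        return float(np.clip(v, 0.2 * cfg.mean_speed, 3.0 * cfg.mean_speed))

    def draw_pause() -> float:
        lo, hi = cfg.pause_range
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    # per-trial motivational state: pace (speed multiplier) and rest
    # propensity. Quantile-stratified draws guarantee that every session
    # mixes vigorous and slow/resty trials (slow trials rest more).
    n_trials = int(np.ceil(cfg.n_runs / cfg.runs_per_reward))
    from scipy.stats import norm as _norm
    q = (np.arange(n_trials) + 0.5) / n_trials
    paces = np.exp(_norm.ppf(q) * cfg.trial_pace_sd)
    paces = np.clip(paces[rng.permutation(n_trials)], 0.35, 2.8)
    rest_mults = -np.log(1.0 - q)          # stratified Exp(1) quantiles
    rest_mults = rest_mults[rng.permutation(n_trials)] / np.maximum(paces, 0.5)
    pace = 1.0
    rest_mult = 1.0
    for run in range(cfg.n_runs):
        heading_out = run % 2 == 0           # True: 0 -> L
        origin, target = (0.0, L) if heading_out else (L, 0.0)
        sgn = 1.0 if heading_out else -1.0
        run_error = False
        start_frame = traj.n - 1

        first_run = run % cfg.runs_per_reward == 0
        if first_run:
            trial_i = run // cfg.runs_per_reward
            pace = float(paces[trial_i])
            rest_mult = float(rest_mults[trial_i])
        if first_run and heading_out and rng.random() < cfg.false_start_prob:
            # poke out of the reward site and come back: trips the start
            # sensor again, scored as an error
            out = float(rng.uniform(8.0, 40.0))
            v = draw_speed()
            traj.move_to(out, v)
            traj.pause(rng.uniform(0.3, 1.0), rng, cfg.wander_speed, out - 2, out + 2)
            traj.move_to(2.0, v)
            traj.pause(rng.uniform(0.3, 1.0), rng, cfg.wander_speed, 0.0, 3.0)
            run_error = True
        elif first_run and heading_out and rng.random() < cfg.slow_departure_prob:
            # slow sniffing departure: sub-threshold outward drift with
            # wander over the first stretch of the track
            dur = float(rng.uniform(1.5, 12.0))
            nfr = int(round(dur * fr))
            drift = rng.uniform(1.0, 3.5) / fr
            steps = drift + rng.normal(0.0, 0.7 * cfg.wander_speed / fr, nfr)
            xs = np.clip(traj.pos + np.cumsum(steps), 4.0, 45.0)
            traj.x.extend(xs)

        v = draw_speed()
        if rng.random() < cfg.error_rate:
            # full return to the origin sensor before the opposite one
            frac = rng.uniform(0.15, 0.85)
            traj.move_to(origin + frac * (target - origin), v)
            traj.move_to(origin + sgn * 2.0, v)
            traj.pause(draw_pause(), rng, cfg.wander_speed,
                       max(0.0, traj.pos - 2), min(L, traj.pos + 2))
            run_error = True

        # non-stereotyped mid-run events (none of them trip the sensors)
        events = [(float(rng.uniform(0.15, 0.85)), kind)
                  for kind, rate in (("hesitate", cfg.hesitation_rate),
                                     ("explore", cfg.exploration_rate),
                                     ("rest", cfg.rest_rate * rest_mult),
                                     ("reverse", cfg.partial_reversal_rate))
                  for _ in range(rng.poisson(rate))]
        for frac, kind in sorted(events):
            stop = origin + frac * (target - origin)
            if (stop - traj.pos) * sgn <= 0:
                continue
            traj.move_to(stop, v)
            if kind == "hesitate":
                traj.pause(rng.uniform(0.3, 1.5), rng, cfg.wander_speed,
                           max(0.0, stop - 2), min(L, stop + 2))
            elif kind == "rest":
                traj.pause(rng.uniform(3.0, 40.0), rng, cfg.wander_speed,
                           max(0.0, stop - 2), min(L, stop + 2))
            elif kind == "reverse":
                # partial double-back that stays clear of the origin sensor
                depth = float(rng.uniform(*cfg.reversal_depth))
                back = float(np.clip(stop - sgn * depth, 4.0, L - 4.0))
                if abs(back - stop) >= 2.0:
                    traj.move_to(back, v)
            else:
                # supra-threshold exploratory meander around the stop point
                half = rng.uniform(5.0, 20.0)
                spd = rng.uniform(7.0, 12.0)
                lo_b, hi_b = max(4.0, stop - half), min(L - 4.0, stop + half)
                t_left = rng.uniform(2.0, 6.0)
                for _ in range(64):
                    if t_left <= 0 or hi_b - lo_b < 4:
                        break
                    tgt = float(rng.uniform(lo_b, hi_b))
                    d = abs(tgt - traj.pos)
                    if d < 1.0:
                        continue
                    traj.move_to(tgt, spd)
                    t_left -= d / spd
        traj.move_to(target, v)
        run_end_frames.append(traj.n - 1)
        errors_per_run.append(run_error)
        runs.append({"run": run, "direction": 1 if heading_out else -1,
                     "start_frame": start_frame, "end_frame": traj.n - 1,
                     "error": run_error, "trial": run // cfg.runs_per_reward})
        if (run + 1) % cfg.runs_per_reward == 0:
            reward_frames.append(traj.n - 1)
        # pause at the end of the run (reward consumption or turn-around)
        traj.pause(draw_pause(), rng, cfg.wander_speed,
                   max(0.0, traj.pos - 3), min(L, traj.pos + 3))

    position = np.clip(np.asarray(traj.x), 0.0, L)
    n = len(position)
    time_s = np.arange(n) / fr
    speed = compute_speed(position, time_s)
    loco = locomotion_mask(speed, 5.0)

    # tone / trial bookkeeping from the known run structure
    tone_state = np.zeros(n, dtype=int)
    trial_id = np.zeros(n, dtype=int)
    tone, trial = 0, 0
    prev = 0
    for i, ef in enumerate(run_end_frames):
        tone_state[prev:ef + 1] = tone
        trial_id[prev:ef + 1] = trial
        if (i + 1) % cfg.runs_per_reward == 0:
            tone, trial = 0, trial + 1
        else:
            tone += 1
        prev = ef + 1
    tone_state[prev:] = tone
    trial_id[prev:] = trial

    runs_df = pd.DataFrame(runs)
    trial_err = runs_df.groupby("trial")["error"].any()
    trial_correct = np.array([not trial_err.get(t, False) for t in trial_id])

    # elapsed / distance reset at reward-site departures
    step = np.concatenate([[0.0], np.abs(np.diff(position))])
    cum = np.cumsum(step)
    anchors = [0]
    for rf in reward_frames:
        beyond = np.flatnonzero(position[rf:] > 5.0)
        if len(beyond):
            anchors.append(rf + beyond[0])
    anchors = sorted(set(anchors))
    elapsed = np.zeros(n)
    distance = np.zeros(n)
    for a, b in zip(anchors, anchors[1:] + [n]):
        elapsed[a:b] = time_s[a:b] - time_s[a]
        distance[a:b] = cum[a:b] - cum[a]

    return SessionBehavior(
        time_s=time_s,
        position=position,
        speed=speed,
        locomotion_mask=loco,
        elapsed_s=elapsed,
        distance_cm=distance,
        tone_state=tone_state,
        trial_id=trial_id,
        trial_correct=trial_correct,
        stim_mask=np.zeros(n, dtype=bool),
        frame_rate=fr,
        runs=runs_df,
        reward_times=time_s[np.asarray(reward_frames, int)] if reward_frames else np.array([]),
    )


def _variable_series(behavior: SessionBehavior, name: str) -> np.ndarray:
    if name == "location":
        if behavior.is_2d:
            raise ValueError("location tuning on a 2-D session needs 2-D components")
        return behavior.position
    if name in ("x", "y"):
        return behavior.position[:, 0 if name == "x" else 1]
    if name == "time":
        return behavior.elapsed_s
    if name == "distance":
        return behavior.distance_cm
    raise ValueError(f"unknown tuning variable {name!r}")


def simulate_neurons(
    behavior: SessionBehavior,
    specs: Sequence[CellSpec],
    calcium_tau: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> Tuple[NeuralData, GroundTruth]:
    """Draw Bernoulli activations from each cell's tuning and render dF/F.

    Traces are the activation train convolved with a single-exponential
    calcium kernel (decay ``calcium_tau`` seconds, unit amplitude) plus
    white Gaussian noise of SD ``noise_sd``.
    """
    if behavior.n_frames == 0:
        raise ValueError("behavior session is empty")
    if len(specs) == 0:
        raise ValueError("specs must contain at least one cell")
    rng = np.random.default_rng(seed)
    n = behavior.n_frames
    series = {}

    prob = np.zeros((len(specs), n))
    for c, spec in enumerate(specs):
        spec.validate()
        p = np.ones(n)
        for (var, center, width) in spec.components():
            if var not in series:
                series[var] = _variable_series(behavior, var)
            v = series[var]
            lo, hi = float(np.min(v)), float(np.max(v))
            if not lo <= center <= hi:
                raise ValueError(
                    f"cell {c}: field_center {center} outside the {var} range [{lo:.1f}, {hi:.1f}]")
            p = p * np.exp(-((v - center) ** 2) / (2.0 * width ** 2))
        if spec.cell_class == "untuned":
            prob[c] = spec.baseline_prob
            continue
        if spec.visit_reliability < 1.0:
            # gate whole field traversals: contiguous stretches within
            # ~2 SD of the field engage the cell with visit_reliability
            in_field = p > np.exp(-2.0)
            edges = np.diff(in_field.astype(int), prepend=0)
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            if len(ends) < len(starts):
                ends = np.append(ends, n)
            gate = np.ones(n)
            for s0, e0 in zip(starts, ends):
                if rng.random() >= spec.visit_reliability:
                    gate[s0:e0] = 0.0
            p = p * gate
        prob[c] = spec.baseline_prob + (spec.peak_prob - spec.baseline_prob) * p

    activations = rng.random((len(specs), n)) < prob
    decay = np.exp(-1.0 / (calcium_tau * behavior.frame_rate))
    traces = lfilter([1.0], [1.0, -decay], activations.astype(float), axis=1)
    traces = traces + rng.normal(0.0, noise_sd, traces.shape)

    neural = NeuralData(traces=traces,
                        binary=activations.astype(np.uint8),
                        frame_rate=behavior.frame_rate)
    truth = GroundTruth(
        rng_seed=seed,
        cell_classes=[s.cell_class for s in specs],
        cell_specs=list(specs),
        activations=activations,
    )
    return neural, truth


def make_population(
    n_place: int,
    n_time: int,
    n_distance: int,
    n_untuned: int,
    rng: np.random.Generator,
    peak_prob: float = 0.3,
    baseline_prob: float = 0.02,
    place_range: Tuple[float, float] = (15.0, 129.0),
    time_range: Tuple[float, float] = (8.0, 50.0),
    distance_range: Tuple[float, float] = (60.0, 500.0),
    place_reliability: float = 0.35,
    progress_reliability: float = 0.8,
    n_conjunctive: int = 0,
) -> List[CellSpec]:
    """Draw a mixed population of tuned and untuned cell specs.

    Default field-center bands balance two demands on the same
    population. For exclusive-label recovery, fields should avoid the
    trial origin: there position, elapsed time and traveled distance are
    mutually determined by movement continuity (a mouse 10 s into a trial
    cannot be far along the distance axis, and on the first run distance
    nearly equals position), so a cell with a field there is genuinely
    informative about several variables at once and exclusive coding is
    undefined in principle. For population decoding, fields should tile
    as much of each variable's range as possible. The defaults trim only
    the strongly degenerate early region and keep broad coverage.

    ``place_reliability`` is lower than ``progress_reliability`` because a
    place field is traversed on every run, while a time or distance field
    is met only once per 4-run trial; the defaults equalize the number of
    engaged field passes per session (~10-15) across classes.
    """
    specs: List[CellSpec] = []
    for _ in range(n_place):
        specs.append(CellSpec("place",
                              field_center=float(rng.uniform(*place_range)),
                              field_width=float(rng.uniform(4, 8)),
                              peak_prob=peak_prob, baseline_prob=baseline_prob,
                              visit_reliability=place_reliability))
    for _ in range(n_time):
        specs.append(CellSpec("time",
                              field_center=float(rng.uniform(*time_range)),
                              field_width=float(rng.uniform(1.0, 2.2)),
                              peak_prob=peak_prob, baseline_prob=baseline_prob,
                              visit_reliability=progress_reliability))
    for _ in range(n_distance):
        specs.append(CellSpec("distance",
                              field_center=float(rng.uniform(*distance_range)),
                              field_width=float(rng.uniform(5, 12)),
                              peak_prob=peak_prob, baseline_prob=baseline_prob,
                              visit_reliability=progress_reliability))
    for _ in range(n_conjunctive):
        comps = (("location", float(rng.uniform(*place_range)), float(rng.uniform(4, 8))),
                 ("time", float(rng.uniform(*time_range)), float(rng.uniform(1.0, 2.2))))
        specs.append(CellSpec("conjunctive", conjunctive_components=comps,
                              peak_prob=peak_prob, baseline_prob=baseline_prob,
                              visit_reliability=progress_reliability))
    for _ in range(n_untuned):
        specs.append(CellSpec("untuned", peak_prob=peak_prob,
                              baseline_prob=baseline_prob))
    return specs


def _one_over_f_noise(n: int, fs: float, exponent: float, sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if exponent == 0 or sd == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    x_sd = x.std()
    return sd * x / x_sd if x_sd > 0 else x


def simulate_lfp(
    plan: LfpPlan,
    speed_series: Optional[np.ndarray] = None,
    speed_frame_rate: float = 30.0,
    seed: int = 0,
) -> Tuple[LFPSignal, GroundTruth]:
    """Render an LFP trace from a plan.

    Outside stimulation epochs the theta component has instantaneous
    frequency ``theta_base_freq + theta_speed_gain * speed(t)``. ``pace8``
    epochs replace theta with a fixed 8 Hz sinusoid phase-reset at epoch
    onset; ``scrambled`` epochs replace it with variance-matched white
    noise; ``random_freq`` epochs use a single frequency drawn uniformly
    from 4-12 Hz (recorded in the ground truth). Ripples are Gaussian-
    enveloped sinusoid bursts added at the requested times.
    """
    plan.validate()
    rng = np.random.default_rng(seed)
    n = int(round(plan.duration * plan.fs))
    t = np.arange(n) / plan.fs

    if speed_series is not None:
        speed_series = np.asarray(speed_series, float)
        expected = int(round(plan.duration * speed_frame_rate))
        if abs(len(speed_series) - expected) > 1:
            raise ValueError(
                f"speed_series has {len(speed_series)} samples; expected ~{expected} "
                f"at {speed_frame_rate} Hz for {plan.duration} s")
        t_speed = np.arange(len(speed_series)) / speed_frame_rate
        speed = np.interp(t, t_speed, speed_series)
    else:
        speed = np.zeros(n)

    inst_freq = plan.theta_base_freq + plan.theta_speed_gain * speed
    phase = 2 * np.pi * np.cumsum(inst_freq) / plan.fs
    theta = plan.theta_amp * np.sin(phase)

    epoch_freqs: List[float] = []
    for (s, e, pattern) in plan.stim_epochs:
        i0, i1 = int(round(s * plan.fs)), int(round(e * plan.fs))
        seg_t = t[i0:i1] - t[i0]
        if pattern == "pace8":
            theta[i0:i1] = plan.theta_amp * np.sin(2 * np.pi * 8.0 * seg_t)
        elif pattern == "scrambled":
            theta[i0:i1] = rng.normal(0.0, plan.theta_amp / np.sqrt(2), i1 - i0)
        elif pattern == "random_freq":
            f0 = float(rng.uniform(4.0, 12.0))
            epoch_freqs.append(f0)
            theta[i0:i1] = plan.theta_amp * np.sin(2 * np.pi * f0 * seg_t)

    background = _one_over_f_noise(n, plan.fs, plan.noise_exponent, plan.noise_sd, rng)
    samples = theta + background
    base_sd = samples.std() if samples.std() > 0 else 1.0

    ripple_times = np.asarray(plan.ripple_times, float)
    for tr in ripple_times:
        half = 4 * plan.ripple_envelope_sd
        i0 = max(0, int(round((tr - half) * plan.fs)))
        i1 = min(n, int(round((tr + half) * plan.fs)))
        seg_t = t[i0:i1] - tr
        envelope = np.exp(-seg_t ** 2 / (2 * plan.ripple_envelope_sd ** 2))
        samples[i0:i1] += (plan.ripple_amp_sd * base_sd * envelope
                           * np.sin(2 * np.pi * plan.ripple_freq * seg_t))

    sig = LFPSignal(samples=samples, fs=plan.fs,
                    stim_epochs=list(plan.stim_epochs), channel="synthetic")
    truth = GroundTruth(rng_seed=seed,
                        ripple_times_s=ripple_times,
                        epoch_patterns=list(plan.stim_epochs),
                        epoch_frequencies=epoch_freqs)
    return sig, truth


def simulate_open_field(
    arena_cm: Tuple[float, float] = (45.0, 45.0),
    duration: float = 600.0,
    seed: int = 0,
    frame_rate: float = 30.0,
    speed_sd: float = 6.0,
    relaxation_s: float = 1.0,
) -> SessionBehavior:
    """Smooth bounded random walk in a rectangular arena.

    Velocity follows an Ornstein-Uhlenbeck process (stationary per-axis SD
    ``speed_sd``) reflected at the walls, which yields a speed distribution
    spanning both rest (< 2 cm/s) and locomotion.
    """
    w, h = arena_cm
    if w <= 0 or h <= 0:
        raise ValueError("arena dimensions must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    theta = 1.0 / relaxation_s
    pos = np.zeros((n, 2))
    vel = np.zeros(2)
    pos[0] = (w / 2, h / 2)
    sigma = speed_sd * np.sqrt(2 * theta)
    for i in range(1, n):
        vel = vel - theta * vel * dt + sigma * np.sqrt(dt) * rng.standard_normal(2)
        p = pos[i - 1] + vel * dt
        for ax, bound in enumerate((w, h)):
            if p[ax] < 0:
                p[ax] = -p[ax]
                vel[ax] = -vel[ax]
            elif p[ax] > bound:
                p[ax] = 2 * bound - p[ax]
                vel[ax] = -vel[ax]
        pos[i] = p
    time_s = np.arange(n) / frame_rate
    speed = compute_speed(pos, time_s)
    return SessionBehavior(
        time_s=time_s,
        position=pos,
        speed=speed,
        locomotion_mask=locomotion_mask(speed, 2.0),
        elapsed_s=time_s.copy(),
        distance_cm=np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pos, axis=0), axis=1))]),
        tone_state=np.zeros(n, dtype=int),
        trial_id=np.zeros(n, dtype=int),
        trial_correct=np.ones(n, dtype=bool),
        stim_mask=np.zeros(n, dtype=bool),
        frame_rate=frame_rate,
    )
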