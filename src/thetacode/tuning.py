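"""Tuning curves, mutual information, and cell classification.

The probabilistic tuning curve of a cell is P(active | state bin), the
occupancy-normalized active-frame count (restricted to locomotion frames).
Mutual information between the binarized activity and the binned behavioral
state quantifies tuning without assuming a linear relation; significance is
assessed against a null of random circular shifts of the activity vector,
which preserves the transient autocorrelation of calcium events while
breaking their alignment to behavior. A cell is labeled place/time/distance
if exactly one variable is significant, conjunctive if more than one, and
untuned otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.stats import pearsonr

__all__ = [
    "BinningSpec",
    "TuningCurve",
    "MIResult",
    "default_binning",
    "compute_tuning_curve",
    "compute_mi",
    "circular_shuffle_test",
    "classify_cells",
    "stim_modulation",
    "rate_map_2d",
    "field_stability",
]


@dataclass
class BinningSpec:
    """Discretization of one behavioral variable.

    Defaults follow the standard convention for this analysis: 3-cm bins
    for location and distance, 1-s bins for time, with Gaussian smoothing
    sigmas of 5, 10, and 15 bins respectively (smoothing is applied to a
    copy; information is always computed on unsmoothed curves).
    """

    variable: str
    bin_size: float
    range: Tuple[float, float]
    smoothing_sigma_bins: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.range[1] <= self.range[0]:
            raise ValueError("range max must exceed range min")
        if self.smoothing_sigma_bins < 0:
            raise ValueError("smoothing_sigma_bins must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.range[1] - self.range[0]) / self.bin_size))

    @property
    def centers(self) -> np.ndarray:
        return self.range[0] + (np.arange(self.n_bins) + 0.5) * self.bin_size

    def bin(self, values: np.ndarray) -> np.ndarray:
        """Bin indices; values outside the range get index -1 (excluded).

        Frames outside the analyzed range of a variable (e.g. elapsed time
        beyond the last bin on an unusually long trial) carry no defined
        state for that variable and are dropped from its analysis rather
        than piled into an edge bin.
        """
        values = np.asarray(values, float)
        idx = np.floor((values - self.range[0]) / self.bin_size).astype(np.int64)
        idx[(values < self.range[0]) | (values >= self.range[1])] = -1
        return idx


def default_binning(variable: str) -> BinningSpec:
    """The canonical binning for location, time, or distance."""
    presets = {
        "location": BinningSpec("location", 3.0, (0.0, 135.0), 5.0),
        "time": BinningSpec("time", 1.0, (0.0, 60.0), 10.0),
        "distance": BinningSpec("distance", 3.0, (0.0, 540.0), 15.0),
    }
    if variable not in presets:
        raise ValueError(f"unknown variable {variable!r}")
    return presets[variable]


@dataclass
class TuningCurve:
    """Activity likelihood per state bin."""

    likelihood: np.ndarray        # P(A=1 | S_i); NaN where unoccupied
    occupancy: np.ndarray         # frames per bin
    marginal: float               # P(A=1) over analyzed frames
    smoothed: np.ndarray          # Gaussian-smoothed likelihood
    spec: Optional[BinningSpec] = None


@dataclass
class MIResult:
    """MI and shuffle significance of one cell for several variables."""

    mi_bits: Dict[str, float]
    p_value: Dict[str, float]
    n_shuffles: int
    label: str = "none"


def _nan_smooth(values: np.ndarray, occupied: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that excludes missing bins from normalization."""
    if sigma <= 0:
        return values.copy()
    filled = np.where(occupied, values, 0.0)
    smooth = gaussian_filter1d if values.ndim == 1 else gaussian_filter
    num = smooth(filled, sigma, mode="constant")
    den = smooth(occupied.astype(float), sigma, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~occupied] = np.nan
    return out


def compute_tuning_curve(
    activity: np.ndarray,
    bin_idx: np.ndarray,
    spec: BinningSpec,
) -> TuningCurve:
    """Occupancy-normalized activity likelihood per bin.

    ``activity`` is the binary vector of one cell and ``bin_idx`` the state
    bin per frame, both already restricted to the analyzed (locomotion)
    frames. Unoccupied bins are NaN and stay excluded from smoothing
    normalization.
    """
    activity = np.asarray(activity).astype(bool)
    bin_idx = np.asarray(bin_idx, np.int64)
    if len(activity) != len(bin_idx):
        raise ValueError("activity and bin indices must be aligned")
    valid = bin_idx >= 0
    activity, bin_idx = activity[valid], bin_idx[valid]
    if len(activity) == 0:
        raise ValueError("no analyzed frames")
    m = spec.n_bins
    occupancy = np.bincount(bin_idx, minlength=m).astype(float)
    active = np.bincount(bin_idx[activity], minlength=m).astype(float)
    occupied = occupancy > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        likelihood = active / occupancy
    likelihood[~occupied] = np.nan
    smoothed = _nan_smooth(likelihood, occupied, spec.smoothing_sigma_bins)
    return TuningCurve(
        likelihood=likelihood,
        occupancy=occupancy,
        marginal=float(activity.mean()),
        smoothed=smoothed,
        spec=spec,
    )


def _mi_from_counts(active_counts: np.ndarray, occupancy: np.ndarray,
                    n_frames: int) -> np.ndarray:
    """MI (bits) for one or many count vectors.

    ``active_counts`` has shape (..., M); occupancy is (M,). Zero-probability
    cells of the joint contribute zero.
    """
    occ = occupancy / n_frames                       # P(S_i)
    j1 = active_counts / n_frames                    # P(S_i, A=1)
    j0 = occ - j1                                    # P(S_i, A=0)
    p1 = j1.sum(axis=-1, keepdims=True)              # P(A=1)
    p0 = 1.0 - p1
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = j1 * np.log2(j1 / (occ * p1))
        t0 = j0 * np.log2(j0 / (occ * p0))
    t1 = np.where(j1 > 0, t1, 0.0)
    t0 = np.where(j0 > 0, t0, 0.0)
    return np.maximum((t1 + t0).sum(axis=-1), 0.0)


def compute_mi(activity: np.ndarray, bin_idx: np.ndarray, n_bins: int) -> float:
    """Mutual information (bits) between binary activity and the state bin."""
    activity = np.asarray(activity).astype(bool)
    bin_idx = np.asarray(bin_idx, np.int64)
    valid = bin_idx >= 0
    activity, bin_idx = activity[valid], bin_idx[valid]
    n = len(activity)
    if n == 0:
        raise ValueError("no analyzed frames")
    occupancy = np.bincount(bin_idx, minlength=n_bins).astype(float)
    active = np.bincount(bin_idx[activity], minlength=n_bins).astype(float)
    return float(_mi_from_counts(active, occupancy, n))


def circular_shuffle_test(
    activity: np.ndarray,
    bin_idx: np.ndarray,
    n_bins: int,
    n_shuffles: int = 1000,
    seed: Optional[int] = None,
    min_shift_frames: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float, np.ndarray]:
    """Circular-permutation significance of the activity-state MI.

    Each surrogate circularly shifts the activity vector over the FULL
    session timeline by an offset drawn uniformly from
    [min_shift_frames, N - min_shift_frames] (avoiding near-identity
    shifts; 30 frames = 1 s at 30 Hz). Frames with bin index -1 (outside
    the locomotion mask or the variable's range) are excluded from the MI
    computation, but surrogate events may be shifted into them — exactly
    as when the raw trace is permuted and the whole analysis re-run — so
    the null correctly reflects the uncertainty from which events fall
    into analyzed periods. The p-value is the fraction of surrogates whose
    MI strictly exceeds the actual MI, so ties count toward significance.
    Returns ``(mi, p, shuffle_mis)``; an all-zero activity vector carries
    no information and yields p = 1.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    activity = np.asarray(activity).astype(bool)
    bin_idx = np.asarray(bin_idx, np.int64)
    if len(bin_idx) != len(activity):
        raise ValueError("activity and bin indices must be aligned")
    n = len(activity)
    valid = bin_idx >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no analyzed frames")
    if rng is None:
        rng = np.random.default_rng(seed)
    active_idx = np.flatnonzero(activity)
    if len(active_idx) == 0:
        return 0.0, 1.0, np.zeros(n_shuffles)
    occupancy = np.bincount(bin_idx[valid], minlength=n_bins).astype(float)
    actual = float(_mi_from_counts(
        np.bincount(bin_idx[valid & activity], minlength=n_bins).astype(float),
        occupancy, n_valid))
    lo = min(min_shift_frames, max(1, n - 1))
    hi = max(lo + 1, n - min_shift_frames)
    offsets = rng.integers(lo, hi, n_shuffles)
    shifted_bins = bin_idx[(active_idx[None, :] + offsets[:, None]) % n]
    # events shifted onto excluded frames go to a dummy bin and are dropped
    shifted_bins = np.where(shifted_bins >= 0, shifted_bins, n_bins)
    flat = shifted_bins + np.arange(n_shuffles)[:, None] * (n_bins + 1)
    counts = np.bincount(flat.ravel(), minlength=n_shuffles * (n_bins + 1))
    counts = counts.reshape(n_shuffles, n_bins + 1)[:, :n_bins].astype(float)
    shuffle_mis = _mi_from_counts(counts, occupancy, n_valid)
    p = float((shuffle_mis > actual).sum() / n_shuffles)
    return actual, p, shuffle_mis


def classify_cells(p_values: Dict[str, float], alpha: float = 0.05) -> str:
    """Label a cell from its per-variable shuffle p-values.

    Exactly one significant variable gives that variable's label
    (location -> "place", time -> "time", distance -> "distance"); two or
    more give "conjunctive"; none gives "none".
    """
    label_map = {"location": "place", "time": "time", "distance": "distance"}
    sig = [v for v, p in p_values.items() if p <= alpha]
    if len(sig) == 0:
        return "none"
    if len(sig) == 1:
        return label_map.get(sig[0], sig[0])
    return "conjunctive"


def stim_modulation(
    activity: np.ndarray,
    stim_mask: np.ndarray,
    n_shuffles: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, object]:
    """Stimulation modulation: MI against the binarized stimulation state.

    The two-state stimulation signal is treated exactly like a behavioral
    variable (same circular-shuffle test). Direction is "excited" if the
    cell is more likely active during stimulation, "inhibited" otherwise;
    a never-active cell has p = 1 and no direction.
    """
    activity = np.asarray(activity).astype(bool)
    stim_mask = np.asarray(stim_mask).astype(bool)
    if len(activity) != len(stim_mask):
        raise ValueError("activity and stim_mask must be aligned")
    if stim_mask.all() or (~stim_mask).all():
        raise ValueError("stim_mask must contain both states")
    mi, p, shuffles = circular_shuffle_test(
        activity, stim_mask.astype(np.int64), 2,
        n_shuffles=n_shuffles, seed=seed, rng=rng)
    if not activity.any():
        return {"mi_bits": 0.0, "p_value": 1.0, "direction": None}
    p_on = activity[stim_mask].mean()
    p_off = activity[~stim_mask].mean()
    return {
        "mi_bits": mi,
        "p_value": p,
        "direction": "excited" if p_on > p_off else "inhibited",
    }


def rate_map_2d(
    activity: np.ndarray,
    position: np.ndarray,
    epoch_mask: np.ndarray,
    bin_cm: float = 3.0,
    sigma_bins: float = 2.0,
    ranges: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
) -> np.ndarray:
    """2-D activity-likelihood map over an open-field arena.

    Frames outside ``epoch_mask`` are ignored (use it to split in-stim vs
    out-of-stim epochs). Zero-occupancy bins are NaN and are excluded from
    the smoothing normalization.
    """
    activity = np.asarray(activity).astype(bool)
    position = np.asarray(position, float)
    epoch_mask = np.asarray(epoch_mask).astype(bool)
    if position.ndim != 2 or position.shape[1] != 2:
        raise ValueError("position must be (n, 2)")
    if not epoch_mask.any():
        raise ValueError("epoch mask selects no frames")
    pos = position[epoch_mask]
    act = activity[epoch_mask]
    if ranges is None:
        ranges = ((0.0, float(np.ceil(pos[:, 0].max()))),
                  (0.0, float(np.ceil(pos[:, 1].max()))))
    edges = [np.arange(lo, hi + bin_cm, bin_cm) for (lo, hi) in ranges]
    occ, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=edges)
    on, _, _ = np.histogram2d(pos[act, 0], pos[act, 1], bins=edges)
    occupied = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        like = on / occ
    like[~occupied] = np.nan
    return _nan_smooth(like, occupied, sigma_bins)


def field_stability(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Pearson correlation of two tuning curves over jointly occupied bins."""
    a = np.asarray(curve_a, float).ravel()
    b = np.asarray(curve_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("curves must share their binning")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 jointly occupied bins")
        return float("nan")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant tuning curve: stability undefined")
        return float("nan")
    r, _ = pearsonr(a, b)
    return float(r)
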