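"""Naive Bayes decoding of behavioral variables from binary population activity.

A decoder is fit from per-cell, per-bin activity likelihoods (the tuning
curves) with a uniform prior over occupied state bins. Decoding combines
per-neuron evidence under the independence assumption, accumulates it over
a trailing temporal window (default 2 s), and reports the maximum a
posteriori state per frame. Two scoring variants are provided:

* ``exact``  — the log-posterior sum(log P(A_k|S)) + log P(S), using the
  likelihood of each cell's observed binary state (active or inactive);
* ``approx`` — the historical sum(log(1 + P(A_k|S) P(S) / P(A_k))) - 1
  score, a smooth monotone distortion of the same evidence that avoids
  underflow without leaving log space.

Both select the same MAP bin on the vast majority of frames; the exact
variant's posterior is properly normalized and is what the posterior
matrix reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .tuning import BinningSpec

__all__ = [
    "DecoderModel",
    "DecodingResult",
    "fit_decoder",
    "decode",
    "train_test_split_frames",
    "bootstrap_decode",
    "zscore_error",
    "confusion_matrix",
]


@dataclass
class DecoderModel:
    """Per-cell state likelihoods plus priors for naive Bayes decoding."""

    likelihood: np.ndarray      # cells x bins, P(A_k=1 | S_i); NaN unoccupied
    prior: np.ndarray           # bins, uniform over occupied, 0 elsewhere
    marginal: np.ndarray        # cells, P(A_k=1) in training
    occupied: np.ndarray        # bins, bool
    spec: Optional[BinningSpec] = None

    @property
    def n_cells(self) -> int:
        return self.likelihood.shape[0]

    @property
    def n_bins(self) -> int:
        return self.likelihood.shape[1]


@dataclass
class DecodingResult:
    """Frame-by-frame decoding output."""

    posterior: np.ndarray           # bins x frames, columns sum to 1
    map_bins: np.ndarray            # frames, argmax bin index
    map_series: np.ndarray          # frames, decoded value (bin centers)
    actual_series: Optional[np.ndarray] = None
    error_series: Optional[np.ndarray] = None
    mean_error: Optional[float] = None
    confusion: Optional[np.ndarray] = None
    n_fallback_frames: int = 0      # frames decoded from the prior alone


def fit_decoder(
    binary: np.ndarray,
    bin_idx: np.ndarray,
    spec: BinningSpec,
    smooth_sigma_bins: Optional[float] = None,
) -> DecoderModel:
    """Fit per-cell likelihoods and a uniform prior from training frames.

    ``binary`` is cells x frames and ``bin_idx`` the training state bin per
    frame (frames with bin -1 are ignored). Likelihood curves are
    Gaussian-smoothed with the binning spec's sigma (override with
    ``smooth_sigma_bins``; 0 disables): smoothing regularizes the sparse
    per-bin estimates, flattening the spurious peaks an untuned cell picks
    up from a finite session while preserving real fields. Likelihoods are
    then clipped to [1/(occ_i + 2), 1 - 1/(occ_i + 2)] per bin (add-one
    style) so that a cell that was never (or always) active in a bin
    cannot zero out the posterior at test time.
    """
    binary = np.atleast_2d(np.asarray(binary))
    bin_idx = np.asarray(bin_idx, np.int64)
    if binary.shape[1] != len(bin_idx):
        raise ValueError("binary and bin_idx must be frame-aligned")
    valid = bin_idx >= 0
    binary = binary[:, valid]
    bin_idx = bin_idx[valid]
    if binary.shape[1] == 0:
        raise ValueError("no training frames")
    m = spec.n_bins
    occ = np.bincount(bin_idx, minlength=m).astype(float)
    occupied = occ > 0
    counts = np.vstack([
        np.bincount(bin_idx, weights=binary[c].astype(float), minlength=m)
        for c in range(binary.shape[0])
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        like = counts / occ
    if smooth_sigma_bins is None:
        smooth_sigma_bins = spec.smoothing_sigma_bins
    if smooth_sigma_bins > 0:
        from .tuning import _nan_smooth
        like = np.vstack([_nan_smooth(like[c], occupied, smooth_sigma_bins)
                          for c in range(like.shape[0])])
    floor = 1.0 / (occ + 2.0)
    like = np.clip(like, floor, 1.0 - floor)
    like[:, ~occupied] = np.nan
    prior = np.where(occupied, 1.0 / occupied.sum(), 0.0)
    n = binary.shape[1]
    marginal = np.clip(binary.mean(axis=1), 1.0 / (n + 2.0), 1.0 - 1.0 / (n + 2.0))
    return DecoderModel(likelihood=like, prior=prior, marginal=marginal,
                        occupied=occupied, spec=spec)


def _frame_scores(model: DecoderModel, binary: np.ndarray,
                  variant: str, evidence: str) -> np.ndarray:
    """Per-frame per-bin evidence scores (frames x occupied-bins)."""
    occ = model.occupied
    P = model.likelihood[:, occ]                 # cells x bins
    A = binary.astype(float).T                   # frames x cells
    if variant == "exact":
        if evidence == "binary":
            return A @ np.log(P) + (1.0 - A) @ np.log(1.0 - P)
        return A @ np.log(P)                     # active-only evidence
    if variant == "approx":
        # historical log(1 + x) - 1 score: only the observed active states
        # contribute evidence, as printed
        prior = model.prior[occ]
        ratio_on = np.log1p(P * prior[None, :] / model.marginal[:, None])
        return A @ ratio_on - 1.0
    raise ValueError(f"unknown variant {variant!r}")


def decode(
    model: DecoderModel,
    binary: np.ndarray,
    window_s: float = 2.0,
    frame_rate: float = 30.0,
    variant: str = "exact",
    evidence: str = "binary",
    actual_bins: Optional[np.ndarray] = None,
) -> DecodingResult:
    """MAP-decode each test frame from the population activity.

    Evidence is accumulated over the trailing ``window_s`` seconds (the
    window is truncated at the start of the test block). Ties at the
    argmax resolve to the lowest bin index. When ``actual_bins`` is given,
    the per-frame error |decoded - actual| (in the variable's units, via
    bin centers) and the row-normalized confusion matrix are filled in.
    """
    binary = np.atleast_2d(np.asarray(binary))
    if binary.shape[0] != model.n_cells:
        raise ValueError("cell count does not match the fitted model")
    occ = model.occupied
    scores = _frame_scores(model, binary, variant, evidence)
    w = max(1, int(round(window_s * frame_rate)))
    if w > 1:
        cs = np.cumsum(scores, axis=0)
        windowed = cs.copy()
        windowed[w:] = cs[w:] - cs[:-w]
    else:
        windowed = scores
    log_prior = np.log(model.prior[occ])
    log_post = windowed + log_prior[None, :]

    bad = ~np.isfinite(log_post).any(axis=1)
    if bad.any():
        log_post[bad] = log_prior[None, :]
    log_post -= log_post.max(axis=1, keepdims=True)
    post_occ = np.exp(log_post)
    post_occ /= post_occ.sum(axis=1, keepdims=True)

    n_frames = binary.shape[1]
    posterior = np.zeros((model.n_bins, n_frames))
    posterior[occ, :] = post_occ.T
    occ_indices = np.flatnonzero(occ)
    map_bins = occ_indices[np.argmax(post_occ, axis=1)]
    centers = model.spec.centers if model.spec is not None else np.arange(model.n_bins, dtype=float)
    map_series = centers[map_bins]

    result = DecodingResult(
        posterior=posterior,
        map_bins=map_bins,
        map_series=map_series,
        n_fallback_frames=int(bad.sum()),
    )
    if actual_bins is not None:
        actual_bins = np.asarray(actual_bins, np.int64)
        ok = actual_bins >= 0
        actual_series = np.full(n_frames, np.nan)
        actual_series[ok] = centers[actual_bins[ok]]
        error = np.abs(map_series - actual_series)
        result.actual_series = actual_series
        result.error_series = error
        result.mean_error = float(np.nanmean(error)) if ok.any() else float("nan")
        result.confusion = confusion_matrix(actual_bins[ok], map_bins[ok], model.n_bins)
    return result


def train_test_split_frames(
    n_frames: int,
    train_frac: float = 0.9,
    scheme: str = "blocks",
    trial_id: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean (train, test) masks over frames.

    ``blocks`` holds out the final contiguous block of frames (whole
    trials when ``trial_id`` is given) to prevent temporal leakage;
    ``interleaved`` samples test frames at random.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    train = np.zeros(n_frames, dtype=bool)
    if scheme == "blocks":
        if trial_id is not None:
            # hold out whole trials from the end of the session until the
            # requested frame fraction is reached (the trailing partial
            # trial alone is usually just the final reward pause)
            trial_id = np.asarray(trial_id)
            ids = np.unique(trial_id)
            counts = {t: int((trial_id == t).sum()) for t in ids}
            target = (1.0 - train_frac) * n_frames
            held, total = [], 0
            for t in ids[::-1]:
                if total >= target and len(held) > 0:
                    break
                if len(ids) - len(held) <= 1:
                    break
                held.append(t)
                total += counts[t]
            train = ~np.isin(trial_id, held)
        else:
            split = int(round(train_frac * n_frames))
            train[:split] = True
    elif scheme == "interleaved":
        rng = rng or np.random.default_rng()
        train[rng.random(n_frames) < train_frac] = True
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    return train, ~train


def zscore_error(actual_errors: np.ndarray, shuffled_errors: np.ndarray) -> float:
    """z = (mean actual - mean shuffled) / SD(actual).

    Negative values mean better-than-chance decoding; negate for display
    if a "higher is better" convention is preferred.
    """
    actual_errors = np.asarray(actual_errors, float)
    shuffled_errors = np.asarray(shuffled_errors, float)
    if len(actual_errors) == 0 or len(shuffled_errors) == 0:
        raise ValueError("both error samples must be non-empty")
    sd = actual_errors.std(ddof=1) if len(actual_errors) > 1 else 0.0
    if sd == 0:
        raise ValueError("zero variance in actual errors: z undefined")
    return float((actual_errors.mean() - shuffled_errors.mean()) / sd)


def confusion_matrix(actual_bins: np.ndarray, decoded_bins: np.ndarray,
                     n_bins: int) -> np.ndarray:
    """Row-normalized decoded-bin rates per actual bin (NaN rows unvisited)."""
    actual_bins = np.asarray(actual_bins, np.int64)
    decoded_bins = np.asarray(decoded_bins, np.int64)
    if actual_bins.shape != decoded_bins.shape:
        raise ValueError("series must be aligned")
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (actual_bins, decoded_bins), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts / rows
    out[rows[:, 0] == 0, :] = np.nan
    return out


def bootstrap_decode(
    binary: np.ndarray,
    bin_idx: np.ndarray,
    spec: BinningSpec,
    frame_rate: float = 30.0,
    n_boot: int = 50,
    cells_per_boot: int = 160,
    window_s: float = 2.0,
    train_frac: float = 0.9,
    trial_id: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    variant: str = "exact",
    evidence: str = "binary",
    min_shift_frames: int = 30,
) -> Dict[str, object]:
    """Bootstrap decoding errors for actual and circularly shuffled activity.

    Each of ``n_boot`` surrogates samples ``cells_per_boot`` cells with
    replacement, fits on the training frames, decodes the held-out frames
    and records the mean absolute error. Matched shuffled surrogates use
    the same resampled cells with each cell's activity circularly shifted
    by an independent random offset before the split, destroying the
    activity-behavior alignment while preserving activity statistics.
    Returns actual and shuffled error distributions and the z-score of
    the actual errors against the shuffled mean.
    """
    binary = np.atleast_2d(np.asarray(binary))
    bin_idx = np.asarray(bin_idx, np.int64)
    n_cells, n_frames = binary.shape
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    train, test = train_test_split_frames(n_frames, train_frac, "blocks", trial_id)
    train_bins = np.where(train, bin_idx, -1)
    test_bins = np.where(test, bin_idx, -1)
    test_sel = np.flatnonzero(test)

    def run_once(mat: np.ndarray) -> float:
        model = fit_decoder(mat, train_bins, spec)
        res = decode(model, mat[:, test_sel], window_s, frame_rate,
                     variant, evidence, actual_bins=test_bins[test_sel])
        return res.mean_error

    actual = np.empty(n_boot)
    shuffled = np.empty(n_boot)
    for b in range(n_boot):
        cells = rng.integers(0, n_cells, cells_per_boot)
        mat = binary[cells]
        actual[b] = run_once(mat)
        offsets = rng.integers(min_shift_frames, n_frames - min_shift_frames,
                               cells_per_boot)
        idx = (np.arange(n_frames)[None, :] - offsets[:, None]) % n_frames
        shuf = mat[np.arange(cells_per_boot)[:, None], idx]
        shuffled[b] = run_once(shuf)

    try:
        z = zscore_error(actual, shuffled)
    except ValueError:
        import warnings
        warnings.warn("degenerate bootstrap errors (zero variance): z undefined")
        z = float("nan")
    return {
        "actual_errors": actual,
        "shuffled_errors": shuffled,
        "z": z,
        "mean_error": float(actual.mean()),
        "shuffled_mean_error": float(shuffled.mean()),
    }
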