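"""Behavioral performance metrics and ANOVA effect sizes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ExplorationBout",
    "AnovaSums",
    "recognition_index",
    "track_performance",
    "effect_sizes",
]


@dataclass
class ExplorationBout:
    """One object-exploration bout in the novel-place recognition task."""

    object_id: str              # "novel" or "familiar"
    duration: float             # s

    def __post_init__(self) -> None:
        if self.object_id not in ("novel", "familiar"):
            raise ValueError("object_id must be 'novel' or 'familiar'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class AnovaSums:
    """Sums of squares feeding the effect-size ratios."""

    ss_between: Optional[float] = None
    ss_total: Optional[float] = None
    ss_effect: Optional[float] = None
    ss_error: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ss_between", "ss_total", "ss_effect", "ss_error"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.ss_between is not None and self.ss_total is not None
                and self.ss_between > self.ss_total):
            raise ValueError("ss_between cannot exceed ss_total")


def recognition_index(bouts: Iterable[ExplorationBout]) -> float:
    """RI = t_novel / (t_novel + t_familiar); 0.5 is chance preference."""
    t_novel = t_familiar = 0.0
    for b in bouts:
        if b.object_id == "novel":
            t_novel += b.duration
        else:
            t_familiar += b.duration
    total = t_novel + t_familiar
    if total <= 0:
        warnings.warn("no exploration recorded: RI undefined")
        return float("nan")
    return t_novel / total


def track_performance(
    trial_correct: Sequence[bool],
    n_runs: Optional[int] = None,
    min_runs: int = 12,
) -> Dict[str, object]:
    """Fraction of correct (error-free) trials on the tone-cued track.

    Sessions with fewer than ``min_runs`` runs are flagged as excluded
    (their fraction is still reported). ``n_runs`` defaults to 4 runs per
    trial when omitted.
    """
    trial_correct = list(trial_correct)
    if len(trial_correct) == 0:
        raise ValueError("no trials")
    if n_runs is None:
        n_runs = 4 * len(trial_correct)
    return {
        "fraction_correct": float(np.mean([bool(t) for t in trial_correct])),
        "n_trials": len(trial_correct),
        "n_runs": int(n_runs),
        "included": bool(n_runs >= min_runs),
    }


def effect_sizes(sums: AnovaSums) -> Dict[str, float]:
    """Eta-squared (SS_between/SS_total) and partial eta-squared
    (SS_effect/(SS_effect + SS_error)); NaN where the denominator is 0."""
    out: Dict[str, float] = {}
    if sums.ss_between is not None and sums.ss_total is not None:
        if sums.ss_total <= 0:
            warnings.warn("zero total sum of squares: eta^2 undefined")
            out["eta2"] = float("nan")
        else:
            out["eta2"] = sums.ss_between / sums.ss_total
    if sums.ss_effect is not None and sums.ss_error is not None:
        denom = sums.ss_effect + sums.ss_error
        if denom <= 0:
            warnings.warn("zero effect+error sum of squares: partial eta^2 undefined")
            out["partial_eta2"] = float("nan")
        else:
            out["partial_eta2"] = sums.ss_effect / denom
    return out
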