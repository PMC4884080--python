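"""Quadrant-arena and T-maze conditioning scores.

Two groups of flies are trained with reciprocal stimulus-punishment
pairings and then allowed to distribute between the two stimuli.  Per frame,
each group's preference index is

    PI = (N_A - N_B) / (N_A + N_B),

signed so that avoidance of that group's punished stimulus is positive, and
the learning index is the mean of the two reciprocally signed PIs, which
cancels any intrinsic stimulus preference.  Visual assays pool the LI over
the whole 90 s test (1 frame/s); olfactory assays pool each group's PI over
the last 10 s of the 2 min choice before averaging the reciprocal groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ArenaFrameCounts",
    "PreferenceSeries",
    "LearningIndexResult",
    "preference_index",
    "signed_preference",
    "learning_index",
    "pool_visual",
    "pool_olfactory",
    "generate_arena_experiment",
]


@dataclass
class ArenaFrameCounts:
    """Per-frame fly counts by stimulus zone for one group.

    ``punished`` names which of the two stimuli ("A" or "B") was paired with
    shock during training.  Counts may sum to less than ``n_flies`` (flies
    lost by the tracker); frames where both counts are zero are flagged
    downstream and excluded from pooling.
    """

    group_id: str
    punished: str  # "A" | "B"
    counts_a: np.ndarray
    counts_b: np.ndarray
    n_flies: int

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a, dtype=np.int64)
        self.counts_b = np.asarray(self.counts_b, dtype=np.int64)
        if self.punished not in ("A", "B"):
            raise ValueError("punished must be 'A' or 'B'")
        if self.counts_a.shape != self.counts_b.shape:
            raise ValueError("count series must have equal length")
        if np.any(self.counts_a < 0) or np.any(self.counts_b < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts_a + self.counts_b > self.n_flies):
            raise ValueError("counts exceed number of flies")

    @property
    def n_frames(self) -> int:
        return len(self.counts_a)


@dataclass
class PreferenceSeries:
    group_id: str
    punished: str
    pi_per_frame: np.ndarray  # NaN where no flies were tracked

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi_per_frame, dtype=float)
        finite = pi[np.isfinite(pi)]
        if len(finite) and np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError("preference index out of [-1, 1]")
        self.pi_per_frame = pi


@dataclass
class LearningIndexResult:
    li_per_frame: np.ndarray
    pooled_li: float
    n_valid_frames: int
    convention: str = "mean of reciprocally signed group PIs; positive = avoidance of punished stimulus"


def preference_index(counts_a, counts_b) -> np.ndarray:
    """Frame-wise (N_A - N_B) / (N_A + N_B); NaN where both counts are zero."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(total > 0, (a - b) / np.where(total > 0, total, 1.0), np.nan)
    return pi


def signed_preference(frames: ArenaFrameCounts) -> PreferenceSeries:
    """PI signed so avoidance of the group's punished stimulus is positive."""
    pi = preference_index(frames.counts_a, frames.counts_b)
    sign = -1.0 if frames.punished == "A" else 1.0
    return PreferenceSeries(frames.group_id, frames.punished, sign * pi)


def learning_index(
    series_1: PreferenceSeries, series_2: PreferenceSeries
) -> LearningIndexResult:
    """Frame-wise LI of a reciprocal pair of groups.

    Both series must have the same length and opposite pairings.  Frames
    flagged (NaN) in either group propagate to NaN and are excluded from the
    pooled mean.
    """
    if series_1.punished == series_2.punished:
        raise ValueError("reciprocal groups must have opposite pairings")
    p1, p2 = series_1.pi_per_frame, series_2.pi_per_frame
    if len(p1) != len(p2):
        raise ValueError("series must cover the same number of frames")
    li = 0.5 * (p1 + p2)
    valid = np.isfinite(li)
    if not valid.any():
        raise ValueError("no valid frames: all flagged in at least one group")
    return LearningIndexResult(
        li_per_frame=li,
        pooled_li=float(np.nanmean(li)),
        n_valid_frames=int(valid.sum()),
    )


def pool_visual(result: LearningIndexResult) -> float:
    """Pooled visual LI: mean over all valid frames of the test."""
    return result.pooled_li


def pool_olfactory(
    series_1: PreferenceSeries,
    series_2: PreferenceSeries,
    frame_rate_hz: float = 1.0,
    window_s: float = 10.0,
) -> float:
    """Olfactory LI: each group's PI averaged over the last ``window_s`` of
    the choice period, then the reciprocal groups averaged."""
    n_last = int(round(window_s * frame_rate_hz))
    if series_1.punished == series_2.punished:
        raise ValueError("reciprocal groups must have opposite pairings")
    out = []
    for s in (series_1, series_2):
        if len(s.pi_per_frame) < n_last:
            raise ValueError(
                f"series shorter ({len(s.pi_per_frame)} frames) than the "
                f"{window_s} s pooling window"
            )
        tail = s.pi_per_frame[-n_last:]
        if not np.isfinite(tail).any():
            raise ValueError("all frames flagged within the pooling window")
        out.append(float(np.nanmean(tail)))
    return 0.5 * (out[0] + out[1])


def generate_arena_experiment(
    n_flies: int = 40,
    bias: float = 0.3,
    n_frames: int = 90,
    seed=0,
    intrinsic_pref_a: float = 0.0,
) -> Tuple[ArenaFrameCounts, ArenaFrameCounts]:
    """Simulate one reciprocal pair of arena groups.

    Each frame, each fly independently sits in its punished stimulus' zones
    with probability (1 - bias)/2, shifted by half of ``intrinsic_pref_a``
    (an un-trained attraction toward stimulus A shared by both groups).  The
    expected signed PI is ``bias`` for either group when the intrinsic
    preference is zero, and the reciprocal design cancels the intrinsic term
    in the LI.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    if not -1.0 <= intrinsic_pref_a <= 1.0:
        raise ValueError("intrinsic_pref_a must be in [-1, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    groups = []
    for punished, child in zip(("A", "B"), ss.spawn(2)):
        rng = np.random.default_rng(child)
        if punished == "A":
            p_a = (1.0 - bias) / 2.0 + intrinsic_pref_a / 2.0
        else:
            p_a = (1.0 + bias) / 2.0 + intrinsic_pref_a / 2.0
        p_a = min(max(p_a, 0.0), 1.0)
        counts_a = rng.binomial(n_flies, p_a, size=n_frames)
        groups.append(
            ArenaFrameCounts(
                group_id=f"group_punished_{punished}",
                punished=punished,
                counts_a=counts_a,
                counts_b=n_flies - counts_a,
                n_flies=n_flies,
            )
        )
    return groups[0], groups[1]
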