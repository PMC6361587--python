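"""Post-hoc cleaning and interpretation of decoded state sequences.

Raw MAP state labels are filtered by posterior confidence, despiked
(brief excursions and single-frame dwells are treated as observation
noise), reordered from slow/turning to fast/straight states, and
summarized as dwell-time distributions and origin-aligned track
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StateSequence",
    "DwellTimes",
    "filter_and_despike",
    "run_length_encode",
    "sort_states",
    "apply_state_order",
    "transform_tracks",
    "transform_track",
    "dwell_times",
    "FPS",
]

FPS = 30
CONFIDENCE_THRESHOLD = 0.85
FLICKER_MAX_FRAMES = 5  # a->b->a excursions shorter than this are relabeled a
UNASSIGNED = 0


@dataclass
class StateSequence:
    """Per-frame HL/LL labels (1-based; 0 = unassigned) with confidence."""

    hl: np.ndarray
    ll: np.ndarray
    confidence: np.ndarray
    frames: np.ndarray | None = None

    def __post_init__(self):
        self.hl = np.asarray(self.hl, dtype=np.int64)
        self.ll = np.asarray(self.ll, dtype=np.int64)
        self.confidence = np.asarray(self.confidence, dtype=float)

    def __len__(self) -> int:
        return self.hl.size

    @property
    def assigned(self) -> np.ndarray:
        return self.hl != UNASSIGNED

    def to_frame(self) -> pd.DataFrame:
        frames = (
            self.frames if self.frames is not None else np.arange(len(self))
        )
        return pd.DataFrame(
            {
                "frame": frames,
                "hl": self.hl,
                "ll": self.ll,
                "confidence": self.confidence,
            }
        )


def run_length_encode(labels: np.ndarray):
    """(label, start, length) runs of a label sequence."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def filter_and_despike(
    seq: StateSequence,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    flicker_max_frames: int = FLICKER_MAX_FRAMES,
) -> StateSequence:
    """Clean a state sequence with the three noise rules, in order.

    1. Frames whose HL confidence is at or below the threshold (0.85)
       become unassigned.
    2. Excursions a -> b -> a in which state b lasts fewer than
       ``flicker_max_frames`` (5 frames, ~170 ms) are relabeled a.
    3. Remaining single-frame dwells are unassigned.

    Unassigned frames break run adjacency, so an excursion must return
    to the same state with no unassigned gap.  The whole filter is
    idempotent.
    """
    hl = seq.hl.copy()
    ll = seq.ll.copy()
    hl[seq.confidence <= confidence_threshold] = UNASSIGNED

    # Rule 2 to a fixpoint: relabeling can merge runs and expose new
    # short excursions.
    changed = True
    while changed:
        changed = False
        runs = run_length_encode(hl)
        for idx in range(1, len(runs) - 1):
            label, start, length = runs[idx]
            prev_label = runs[idx - 1][0]
            next_label = runs[idx + 1][0]
            if (
                label != UNASSIGNED
                and prev_label != UNASSIGNED
                and prev_label == next_label
                and prev_label != label
                and length < flicker_max_frames
            ):
                hl[start : start + length] = prev_label
                changed = True
                break

    # Rule 3 targets single frames spent in a state *before changing
    # states*: a 1-frame dwell at the end of the track, or one followed
    # by an unassigned gap, never changes state and is kept.
    runs = run_length_encode(hl)
    for idx, (label, start, length) in enumerate(runs):
        if label == UNASSIGNED or length != 1 or idx + 1 >= len(runs):
            continue
        if runs[idx + 1][0] != UNASSIGNED:
            hl[start] = UNASSIGNED

    ll[hl == UNASSIGNED] = UNASSIGNED
    return replace(seq, hl=hl, ll=ll)


def sort_states(
    seq: StateSequence,
    speed: np.ndarray,
    curvature: np.ndarray,
    n_states: int,
) -> np.ndarray:
    """Order HL states by mean(speed) / var(curvature), ascending.

    Returns ``order`` with ``order[rank] = original label``; rank 0 is
    the slowest-and-turniest state.  States with fewer than two assigned
    frames (undefined ratio) are placed last, in label order.
    """
    ratios = np.full(n_states, np.inf)
    for state in range(1, n_states + 1):
        mask = (seq.hl == state) & np.isfinite(curvature) & np.isfinite(speed)
        if mask.sum() >= 2:
            var_c = np.var(curvature[mask], ddof=1)
            if var_c > 0:
                ratios[state - 1] = np.mean(speed[mask]) / var_c
    order = np.argsort(ratios, kind="stable") + 1
    return order


def apply_state_order(seq: StateSequence, order: np.ndarray) -> StateSequence:
    """Relabel HL states so that ``order[rank]`` becomes label rank+1."""
    mapping = np.zeros(int(np.max(order)) + 1, dtype=np.int64)
    for rank, old in enumerate(order):
        mapping[int(old)] = rank + 1
    hl = np.where(seq.hl == UNASSIGNED, UNASSIGNED, mapping[seq.hl])
    return replace(seq, hl=hl)


def transform_track(
    xy: np.ndarray, prior_xy: np.ndarray | None = None
) -> np.ndarray:
    """Translate a segment to the origin and rotate its intent to +y.

    The directional intent is the overall displacement of the 10 frames
    preceding the segment (all available prior frames if fewer; the
    segment's own first displacement if none), mapped onto the positive
    y axis.  The transform is rigid.
    """
    xy = np.asarray(xy, dtype=float)
    if prior_xy is not None and len(prior_xy) >= 2:
        prior_xy = np.asarray(prior_xy, dtype=float)[-11:]
        heading = prior_xy[-1] - prior_xy[0]
    elif xy.shape[0] >= 2:
        heading = xy[1] - xy[0]
    else:
        heading = np.array([0.0, 1.0])
    if np.hypot(*heading) == 0:
        heading = np.array([0.0, 1.0])
    theta = np.pi / 2.0 - np.arctan2(heading[1], heading[0])
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    return (xy - xy[0]) @ rot.T


def transform_tracks(segments) -> list:
    """Apply :func:`transform_track` to ``(xy, prior_xy)`` pairs."""
    return [transform_track(xy, prior) for xy, prior in segments]


@dataclass
class DwellTimes:
    """Per-state dwell durations (frames) from a despiked sequence."""

    dwells: dict  # state label -> np.ndarray of run lengths in frames
    fps: float = FPS

    def durations_s(self, state: int) -> np.ndarray:
        return self.dwells.get(state, np.empty(0)) / self.fps

    def total_frames(self) -> int:
        return int(sum(arr.sum() for arr in self.dwells.values()))

    def fraction_above(self, min_duration_s: float) -> float:
        """Fraction of assigned time spent in dwells longer than a cutoff."""
        total = self.total_frames()
        if total == 0:
            return np.nan
        min_frames = min_duration_s * self.fps
        kept = sum(
            arr[arr > min_frames].sum() for arr in self.dwells.values()
        )
        return kept / total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"hl": state, "dwell_frames": int(n), "dwell_s": n / self.fps}
            for state, arr in sorted(self.dwells.items())
            for n in arr
        ]
        return pd.DataFrame(rows, columns=["hl", "dwell_frames", "dwell_s"])


def dwell_times(seq: StateSequence, fps: float = FPS) -> DwellTimes:
    """Run-length encode the HL labels into per-state dwell samples."""
    dwells: dict[int, list[int]] = {}
    for label, _start, length in run_length_encode(seq.hl):
        if label != UNASSIGNED:
            dwells.setdefault(label, []).append(length)
    return DwellTimes(
        dwells={k: np.asarray(v, dtype=np.int64) for k, v in dwells.items()},
        fps=fps,
    )
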