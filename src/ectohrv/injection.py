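"""Artificial beat-detection-error injection.

Two error types are simulated on a clean beat sequence:

* a *missed* beat: an annotated beat is deleted, merging its two flanking
  intervals into one long interval;
* a *false* beat: a spurious annotation is inserted inside an interval,
  splitting it into two short intervals.

For a given error rate the total number of errors is ``round(rate *
n_beats)``; the miss/false split is itself random, with the missed fraction
drawn uniformly per repetition.  Deletions are applied before insertions,
and insertion gaps are indexed on the post-deletion sequence, so an
inserted beat can never be deleted within the same repetition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .cohort import QRSSequence
from .restoration import IBISeries

__all__ = [
    "ErrorPlan",
    "plan_errors",
    "apply_miss_detections",
    "apply_false_detections",
    "inject",
    "build_ectopic_dataset",
    "plans_to_frame",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero (non-negative input)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ErrorPlan:
    """The realized injection plan for one repetition at one error rate.

    error_rate : fraction of beats turned into errors (0-0.5).
    miss_indices : beat indices (on the clean sequence) to delete;
        interior beats only.
    false_positions : array of shape (n_false, 2); each row is
        (gap index on the post-deletion sequence, fractional position
        strictly inside that gap).
    """

    error_rate: float
    n_total: int
    n_miss: int
    n_false: int
    miss_indices: np.ndarray
    false_positions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "miss_indices",
                           np.asarray(self.miss_indices, dtype=int))
        fp = np.asarray(self.false_positions, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "false_positions", fp)
        if self.n_miss + self.n_false != self.n_total:
            raise ValueError("n_miss + n_false must equal n_total")
        if self.miss_indices.size != self.n_miss:
            raise ValueError("miss_indices length mismatch")
        if np.unique(self.miss_indices).size != self.miss_indices.size:
            raise ValueError("miss_indices must be distinct")
        if fp.shape[0] != self.n_false:
            raise ValueError("false_positions length mismatch")
        if fp.size and not np.all((fp[:, 1] > 0) & (fp[:, 1] < 1)):
            raise ValueError("fractional positions must lie strictly in (0, 1)")


def plan_errors(
    n_beats: int,
    error_rate: float,
    rng: Union[int, Generator],
    min_gap_fraction: float = 0.0,
) -> ErrorPlan:
    """Draw one injection plan.

    n_beats : number of beats in the clean record.
    error_rate : fraction of beats to corrupt, in [0, 0.5].
    min_gap_fraction : optional refractory margin; false-beat positions are
        drawn uniformly on (min_gap_fraction, 1 - min_gap_fraction).
    """
    rng = rng if isinstance(rng, Generator) else default_rng(rng)
    if not (0.0 <= error_rate <= 0.5):
        raise ValueError("error_rate must lie in [0, 0.5]")
    if n_beats < 3:
        raise ValueError("need at least 3 beats to inject errors")
    if not (0.0 <= min_gap_fraction < 0.5):
        raise ValueError("min_gap_fraction must lie in [0, 0.5)")

    n_total = _round_half_away(error_rate * n_beats)
    if n_total == 0:
        return ErrorPlan(error_rate, 0, 0, 0,
                         np.empty(0, dtype=int), np.empty((0, 2)))

    u = rng.uniform()
    n_miss = _round_half_away(u * n_total)
    n_false = n_total - n_miss

    n_interior = n_beats - 2
    if n_miss > n_interior:
        raise ValueError(
            f"cannot delete {n_miss} beats: only {n_interior} interior beats"
        )
    n_gaps = n_beats - n_miss - 1
    if n_false > 0 and n_gaps < 1:
        raise ValueError("no gaps left to insert false beats into")

    miss_indices = np.sort(
        rng.choice(np.arange(1, n_beats - 1), size=n_miss, replace=False)
    )
    gap_idx = rng.integers(0, n_gaps, size=n_false)
    frac = rng.uniform(min_gap_fraction, 1.0 - min_gap_fraction, size=n_false)
    # avoid degenerate endpoints when min_gap_fraction == 0
    frac = np.clip(frac, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    false_positions = np.column_stack([gap_idx.astype(float), frac])
    order = np.lexsort((false_positions[:, 1], false_positions[:, 0]))
    return ErrorPlan(error_rate, n_total, n_miss, n_false,
                     miss_indices, false_positions[order])


def apply_miss_detections(
    qrs: QRSSequence, miss_indices: Sequence[int]
) -> QRSSequence:
    """Delete the beats at ``miss_indices`` (interior beats only).

    Each deletion merges the two flanking intervals; the record span
    (last minus first beat time) is unchanged.
    """
    idx = np.asarray(miss_indices, dtype=int)
    if idx.size == 0:
        return QRSSequence(qrs.times.copy(), subject_id=qrs.subject_id)
    if np.any(idx <= 0) or np.any(idx >= qrs.n_beats - 1):
        raise IndexError("miss indices must be interior beats")
    return QRSSequence(np.delete(qrs.times, idx), subject_id=qrs.subject_id)


def apply_false_detections(
    qrs: QRSSequence, false_positions: np.ndarray
) -> QRSSequence:
    """Insert a beat inside each selected gap at the given fraction."""
    fp = np.asarray(false_positions, dtype=float).reshape(-1, 2)
    if fp.shape[0] == 0:
        return QRSSequence(qrs.times.copy(), subject_id=qrs.subject_id)
    gap = fp[:, 0].astype(int)
    frac = fp[:, 1]
    if np.any(gap < 0) or np.any(gap >= qrs.n_beats - 1):
        raise IndexError("gap index out of range")
    if np.any(frac <= 0) or np.any(frac >= 1):
        raise ValueError("fractional positions must lie strictly in (0, 1)")
    t = qrs.times
    new_times = t[gap] + frac * (t[gap + 1] - t[gap])
    merged = np.sort(np.concatenate([t, new_times]))
    if np.any(np.diff(merged) <= 0):
        raise ValueError("duplicate beat time produced; redraw the position")
    return QRSSequence(merged, subject_id=qrs.subject_id)


def inject(qrs: QRSSequence, plan: ErrorPlan) -> QRSSequence:
    """Apply one plan: deletions first, then insertions."""
    out = apply_miss_detections(qrs, plan.miss_indices)
    return apply_false_detections(out, plan.false_positions)


def build_ectopic_dataset(
    cohort: Sequence[QRSSequence],
    error_rate: float,
    n_reps: int,
    seed: Union[int, SeedSequence] = 0,
) -> Dict[str, List[IBISeries]]:
    """Create the ectopic-containing interval dataset for one error rate.

    For every subject and repetition an independent plan is drawn and
    applied; the result maps subject_id to ``n_reps`` labelled IBI series.
    Fully deterministic given the seed (per subject x repetition streams
    are spawned from it).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    subject_seeds = ss.spawn(len(cohort))
    out: Dict[str, List[IBISeries]] = {}
    for qrs, sub_ss in zip(cohort, subject_seeds):
        reps: List[IBISeries] = []
        for rep, rep_ss in enumerate(sub_ss.spawn(n_reps)):
            rng = default_rng(rep_ss)
            plan = plan_errors(qrs.n_beats, error_rate, rng)
            noisy = inject(qrs, plan)
            series = noisy.ibi()
            series.repetition = rep
            series.rate = error_rate * 100.0
            reps.append(series)
        out[qrs.subject_id] = reps
    return out


def plans_to_frame(
    plans: Iterable[tuple],
) -> pd.DataFrame:
    """Serialize plans for audit/replay.

    ``plans`` yields (subject_id, repetition, plan) triples; the output has
    one row per individual error with columns
    subject, repetition, rate, kind, index, position.
    """
    rows = []
    for subject_id, rep, plan in plans:
        for i in plan.miss_indices:
            rows.append((subject_id, rep, plan.error_rate, "miss", int(i), np.nan))
        for g, f in plan.false_positions:
            rows.append((subject_id, rep, plan.error_rate, "false", int(g), float(f)))
    return pd.DataFrame(
        rows, columns=["subject", "repetition", "rate", "kind", "index", "position"]
    )
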