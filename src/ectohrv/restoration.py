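"""Ectopic-interval flagging and restoration.

An interbeat-interval (IBI) series contaminated by missed or false beat
detections contains intervals that are abruptly too long (two true intervals
merged by a missed beat) or too short (one interval split by a spurious
beat).  Such intervals are flagged by an adaptive threshold: interval ``n``
is accepted only if it lies strictly inside

    lower_coef * ref < IBI_n < upper_coef * ref

where ``ref`` is the most recent *accepted* interval.  The default
coefficients 0.675 and 1.245 correspond to a decrease of more than 32.5 %
or an increase of more than 24.5 % relative to the previous normal
interval.  Flagged intervals are then either deleted or replaced by
nearest-neighbor (NNI), linear (LI) or cubic-spline (CSI) interpolation
over the interval index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "ThresholdRule",
    "IBISeries",
    "flag_ectopic",
    "interpolate_nni",
    "interpolate_li",
    "interpolate_csi",
    "restore",
    "RESTORE_METHODS",
]

RESTORE_METHODS = ("none", "delete", "NNI", "LI", "CSI")


@dataclass(frozen=True)
class ThresholdRule:
    """Acceptance band for an interval relative to the last accepted one.

    lower_coef, upper_coef : dimensionless multipliers applied to the
        reference interval; an interval outside the open interval
        (lower_coef*ref, upper_coef*ref) is flagged as ectopic.
    """

    lower_coef: float = 0.675
    upper_coef: float = 1.245

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_coef < 1.0 < self.upper_coef):
            raise ValueError(
                "ThresholdRule requires 0 < lower_coef < 1 < upper_coef, "
                f"got ({self.lower_coef}, {self.upper_coef})"
            )


@dataclass
class IBISeries:
    """An interbeat-interval series in milliseconds with per-interval flags.

    values : interval durations, ms.
    flags : boolean array marking ectopic (or interpolated) intervals;
        ``None`` until :func:`flag_ectopic` has run.
    subject_id, repetition, rate : provenance labels carried through the
        simulation pipeline (rate is the beat-error rate in percent).
    """

    values: np.ndarray
    flags: Optional[np.ndarray] = None
    subject_id: str = ""
    repetition: Optional[int] = None
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("IBI values must be one-dimensional")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ValueError("flags must have the same length as values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_flagged(self) -> int:
        return 0 if self.flags is None else int(self.flags.sum())

    def with_values(self, values: np.ndarray, flags: Optional[np.ndarray]) -> "IBISeries":
        return IBISeries(
            values=np.asarray(values, dtype=float),
            flags=flags,
            subject_id=self.subject_id,
            repetition=self.repetition,
            rate=self.rate,
        )


def flag_ectopic(
    ibi: IBISeries,
    rule: ThresholdRule = ThresholdRule(),
    reference: str = "previous",
) -> IBISeries:
    """Mark intervals falling outside the acceptance band.

    reference:
      - ``"previous"`` (default): the comparator is the raw previous
        interval IBI_{n-1}.  A flagged interval can cost its one or two
        successors a spurious flag, but the rule re-anchors as soon as two
        adjacent intervals agree, so flagging stays local.
      - ``"last_accepted"``: the comparator is the most recent unflagged
        interval.  This keeps one ectopic from licensing its successor,
        but a split interval that slips inside the band can trap the
        reference low and cascade flags over the remainder of the record;
        offered for comparison, not as the default.

    The first interval is never flagged and seeds the reference.
    """
    if reference not in ("previous", "last_accepted"):
        raise ValueError("reference must be 'previous' or 'last_accepted'")
    v = ibi.values
    if v.size < 2:
        raise ValueError("need at least 2 intervals to flag ectopic beats")
    flags = np.zeros(v.size, dtype=bool)
    if reference == "previous":
        ratio_ok = (rule.lower_coef * v[:-1] < v[1:]) & (v[1:] < rule.upper_coef * v[:-1])
        flags[1:] = ~ratio_ok
    else:
        ref = v[0]
        for n in range(1, v.size):
            if rule.lower_coef * ref < v[n] < rule.upper_coef * ref:
                ref = v[n]
            else:
                flags[n] = True
    return ibi.with_values(v.copy(), flags)


def _require_flags(ibi: IBISeries) -> np.ndarray:
    if ibi.flags is None:
        raise ValueError("flags not set; run flag_ectopic first")
    return ibi.flags


def interpolate_nni(ibi: IBISeries) -> IBISeries:
    """Replace each flagged interval by the nearest unflagged value.

    Distance is measured in interval index; ties go to the earlier
    (previous) value, matching the zero-order "previous interval" rule for
    an isolated interior flag.  A flagged run at the left boundary is filled
    from the first unflagged value to its right.
    """
    flags = _require_flags(ibi)
    good = np.flatnonzero(~flags)
    if good.size == 0:
        raise ValueError("cannot interpolate: every interval is flagged")
    bad = np.flatnonzero(flags)
    out = ibi.values.copy()
    if bad.size:
        pos = np.searchsorted(good, bad)
        left_idx = good[np.clip(pos - 1, 0, good.size - 1)]
        right_idx = good[np.clip(pos, 0, good.size - 1)]
        d_left = np.where(pos > 0, bad - left_idx, np.iinfo(np.int64).max)
        d_right = np.where(pos < good.size, right_idx - bad, np.iinfo(np.int64).max)
        source = np.where(d_left <= d_right, left_idx, right_idx)
        out[bad] = ibi.values[source]
    return ibi.with_values(out, flags.copy())


def interpolate_li(ibi: IBISeries) -> IBISeries:
    """Replace flagged runs by the straight line through the bracketing
    unflagged neighbors, with x the interval index.

    Runs touching a series boundary are extrapolated from the line through
    the two nearest unflagged points.
    """
    flags = _require_flags(ibi)
    good = np.flatnonzero(~flags)
    if good.size < 2:
        raise ValueError("linear interpolation needs at least 2 unflagged values")
    out = ibi.values.copy()
    bad = np.flatnonzero(flags)
    if bad.size:
        f = interp1d(
            good, ibi.values[good], kind="linear",
            bounds_error=False, fill_value="extrapolate", assume_sorted=True,
        )
        out[bad] = f(bad)
    return ibi.with_values(out, flags.copy())


def interpolate_csi(
    ibi: IBISeries, bc_type: str = "not-a-knot"
) -> IBISeries:
    """Replace flagged values by a cubic spline through all unflagged
    (index, value) points; boundary runs are extrapolated by the spline."""
    flags = _require_flags(ibi)
    good = np.flatnonzero(~flags)
    if good.size < 4:
        raise ValueError("cubic-spline interpolation needs at least 4 unflagged values")
    out = ibi.values.copy()
    bad = np.flatnonzero(flags)
    if bad.size:
        cs = CubicSpline(good, ibi.values[good], bc_type=bc_type)
        out[bad] = cs(bad)
    return ibi.with_values(out, flags.copy())


def restore(
    ibi: IBISeries,
    rule: ThresholdRule = ThresholdRule(),
    method: str = "none",
    bc_type: str = "not-a-knot",
    reference: str = "previous",
) -> IBISeries:
    """Flag ectopic intervals and repair the series.

    method:
      - ``"none"``   : return the series untouched (the raw ectopic path);
      - ``"delete"`` : drop flagged intervals, shortening the series;
      - ``"NNI"`` / ``"LI"`` / ``"CSI"`` : replace flagged intervals in
        place, preserving length.
    """
    key = method if method in RESTORE_METHODS else str(method).upper()
    if key == "none" or method == "none":
        return ibi.with_values(ibi.values.copy(),
                               None if ibi.flags is None else ibi.flags.copy())
    if key not in RESTORE_METHODS:
        raise ValueError(f"unknown restoration method {method!r}; choose from {RESTORE_METHODS}")
    flagged = flag_ectopic(ibi, rule, reference=reference)
    if key == "delete":
        keep = ~flagged.flags
        return ibi.with_values(flagged.values[keep], np.zeros(int(keep.sum()), dtype=bool))
    if key == "NNI":
        return interpolate_nni(flagged)
    if key == "LI":
        return interpolate_li(flagged)
    return interpolate_csi(flagged, bc_type=bc_type)
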