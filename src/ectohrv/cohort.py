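"""Synthetic resting cohorts of beat sequences.

The simulation needs ectopic-free interbeat-interval (IBI) series with the
statistical structure of short-term resting recordings: a stable mean
interval near 1 s, low-frequency (~0.1 Hz, baroreflex/Mayer-wave) and
high-frequency (~0.25 Hz, respiratory sinus arrhythmia) oscillations, and
broadband beat-to-beat noise.  Each subject's intervals follow an additive
sinusoid model

    IBI_n = mean_ibi
            + lf_amplitude * sin(2*pi*lf_freq * t_{n-1} + phi_lf)
            + hf_amplitude * sin(2*pi*hf_freq * t_{n-1} + phi_hf)
            + eps_n,           eps_n ~ Normal(0, noise_sd^2)

with t_{n-1} the cumulative occurrence time of the previous beat and the
phases drawn uniformly per subject.  Beat times are the cumulative sums of
the intervals, generated until the record duration is exceeded.

With the default amplitudes the analytic SDNN is
sqrt(lf_amplitude^2/2 + hf_amplitude^2/2 + noise_sd^2) ~ 52 ms at a mean
interval of 1010 ms, i.e. a healthy young adult at supine rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .restoration import IBISeries, ThresholdRule, flag_ectopic

__all__ = ["CohortConfig", "QRSSequence", "generate_subject", "generate_cohort",
           "screen_preexisting"]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic resting cohort.

    n_subjects : number of subjects (records).
    duration : record length in seconds.
    mean_ibi : mean interbeat interval, ms.
    lf_amplitude, hf_amplitude : sinusoidal modulation amplitudes, ms.
    lf_freq, hf_freq : modulation frequencies, Hz; must fall inside the
        conventional LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands.
    noise_sd : beat-to-beat Gaussian noise standard deviation, ms.
    seed : master seed; per-subject streams are spawned from it.
    """

    n_subjects: int = 28
    duration: float = 1200.0
    mean_ibi: float = 1010.0
    lf_amplitude: float = 50.0
    lf_freq: float = 0.1
    hf_amplitude: float = 40.0
    hf_freq: float = 0.25
    noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if not (0.04 <= self.lf_freq <= 0.15):
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15] Hz")
        if not (0.15 <= self.hf_freq <= 0.4):
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.4] Hz")
        if min(self.lf_amplitude, self.hf_amplitude, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        headroom = self.mean_ibi - (
            self.lf_amplitude + self.hf_amplitude + 4.0 * self.noise_sd
        )
        if headroom <= 0:
            raise ValueError(
                "configuration can produce non-positive intervals: require "
                "mean_ibi > lf_amplitude + hf_amplitude + 4*noise_sd"
            )


@dataclass(frozen=True)
class QRSSequence:
    """Ordered beat occurrence times (seconds) for one record."""

    times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a beat sequence needs at least 2 times")
        if t[0] < 0:
            raise ValueError("first beat time must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n_beats(self) -> int:
        return self.times.size

    def ibi(self) -> IBISeries:
        """Interbeat intervals in milliseconds."""
        return IBISeries(np.diff(self.times) * 1000.0, subject_id=self.subject_id)


def generate_subject(
    config: CohortConfig,
    subject_seed: Union[int, SeedSequence, Generator],
    subject_id: str = "S00",
) -> QRSSequence:
    """Generate one subject's beat times under the additive-sinusoid model.

    Deterministic given the seed.  Intervals are generated sequentially
    because each modulation term is evaluated at the previous beat's
    cumulative time; generation stops once that time exceeds the configured
    duration, so the final beat may overshoot by at most one interval.
    """
    rng = subject_seed if isinstance(subject_seed, Generator) else default_rng(subject_seed)
    phi_lf = rng.uniform(0.0, _TWO_PI)
    phi_hf = rng.uniform(0.0, _TWO_PI)
    w_lf = _TWO_PI * config.lf_freq
    w_hf = _TWO_PI * config.hf_freq
    t = 0.0
    times = [0.0]
    while t < config.duration:
        ibi_ms = (
            config.mean_ibi
            + config.lf_amplitude * np.sin(w_lf * t + phi_lf)
            + config.hf_amplitude * np.sin(w_hf * t + phi_hf)
            + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
        )
        if ibi_ms <= 0:
            raise ValueError("generated a non-positive interval; config invalid")
        t += ibi_ms / 1000.0
        times.append(t)
    return QRSSequence(np.asarray(times), subject_id=subject_id)


def generate_cohort(config: CohortConfig) -> List[QRSSequence]:
    """Generate ``n_subjects`` independent records.

    Per-subject random streams are spawned sequentially from
    ``SeedSequence(config.seed)`` so the cohort is bitwise reproducible and
    any one subject can be regenerated in isolation.
    """
    children = SeedSequence(config.seed).spawn(config.n_subjects)
    return [
        generate_subject(config, child, subject_id=f"S{i + 1:02d}")
        for i, child in enumerate(children)
    ]


def screen_preexisting(
    ibi: IBISeries, rule: ThresholdRule = ThresholdRule()
) -> IBISeries:
    """Delete intervals violating the acceptance band before any injection.

    This mirrors the pre-cleaning step applied to real recordings: intervals
    flagged by the same threshold rule used during restoration are removed
    outright (not interpolated).  Flag-and-delete passes repeat until no
    interval violates the rule (deleting an interval changes its successor's
    comparator), so the operation is idempotent by construction.
    """
    if len(ibi) == 0:
        raise ValueError("cannot screen an empty IBI series")
    values = ibi.values.copy()
    while values.size >= 2:
        flags = flag_ectopic(ibi.with_values(values, None), rule).flags
        if not flags.any():
            break
        values = values[~flags]
    return ibi.with_values(values, np.zeros(values.size, dtype=bool))
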