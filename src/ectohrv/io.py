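"""Plain-text readers and writers for beat times, interval series, metric
tables, and YAML run configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, QRSSequence
from .metrics import DISPLAY_NAMES, METRIC_FIELDS, HRVMetrics, SpectralConfig
from .restoration import IBISeries, ThresholdRule
from .sweep import SweepConfig, default_rate_grid

__all__ = [
    "write_beat_times", "read_beat_times",
    "write_ibi", "read_ibi",
    "write_cohort_csv", "read_cohort_csv",
    "metrics_to_frame", "write_metrics_csv",
    "load_config",
]

_PathLike = Union[str, Path]


def write_beat_times(path: _PathLike, qrs: QRSSequence) -> None:
    """One beat time per line, seconds; unit noted in a header comment."""
    lines = [f"# beat occurrence times [s] subject={qrs.subject_id}"]
    lines += [f"{t:.6f}" for t in qrs.times]
    Path(path).write_text("\n".join(lines) + "\n")


def read_beat_times(path: _PathLike, subject_id: str = "") -> QRSSequence:
    vals = _read_column(path)
    return QRSSequence(vals, subject_id=subject_id or Path(path).stem)


def write_ibi(path: _PathLike, ibi: IBISeries) -> None:
    """One interval per line, milliseconds."""
    lines = [f"# interbeat intervals [ms] subject={ibi.subject_id}"]
    lines += [f"{v:.6f}" for v in ibi.values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ibi(path: _PathLike, subject_id: str = "") -> IBISeries:
    vals = _read_column(path)
    return IBISeries(vals, subject_id=subject_id or Path(path).stem)


def _read_column(path: _PathLike) -> np.ndarray:
    vals: List[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals.append(float(line))
    if not vals:
        raise ValueError(f"no values found in {path}")
    return np.asarray(vals)


def write_cohort_csv(path: _PathLike, cohort: Sequence[QRSSequence],
                     kind: str = "beats") -> None:
    """Two-column CSV (subject_id, value); beat times in s or IBIs in ms."""
    if kind not in ("beats", "ibi"):
        raise ValueError("kind must be 'beats' or 'ibi'")
    rows = []
    for q in cohort:
        vals = q.times if kind == "beats" else q.ibi().values
        rows.extend((q.subject_id, v) for v in vals)
    unit = "s" if kind == "beats" else "ms"
    header = f"# {'beat times' if kind == 'beats' else 'interbeat intervals'} [{unit}]\n"
    df = pd.DataFrame(rows, columns=["subject_id", "value"])
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_cohort_csv(path: _PathLike, kind: str = "beats") -> List[QRSSequence]:
    df = pd.read_csv(path, comment="#")
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        vals = grp.value.to_numpy(dtype=float)
        if kind == "beats":
            out.append(QRSSequence(vals, subject_id=str(sid)))
        else:
            times = np.concatenate([[0.0], np.cumsum(vals) / 1000.0])
            out.append(QRSSequence(times, subject_id=str(sid)))
    return out


def metrics_to_frame(records: Dict[str, HRVMetrics]) -> pd.DataFrame:
    """One row per record, columns in the documented metric order."""
    rows = []
    for sid, rec in records.items():
        d = rec.to_dict()
        rows.append([sid] + [d[m] for m in METRIC_FIELDS])
    cols = ["subject_id"] + [DISPLAY_NAMES[m] for m in METRIC_FIELDS]
    return pd.DataFrame(rows, columns=cols)


def write_metrics_csv(path: _PathLike, records: Dict[str, HRVMetrics]) -> None:
    metrics_to_frame(records).to_csv(path, index=False)


def load_config(path: _PathLike) -> Tuple[CohortConfig, SweepConfig,
                                          SpectralConfig, ThresholdRule]:
    """Build the run configuration from a YAML file.

    Top-level keys ``cohort``, ``sweep``, ``spectral`` and ``threshold``
    mirror the corresponding dataclass fields; ``sweep.rate_start/stop/step``
    may replace an explicit ``rate_grid``.  Missing sections fall back to
    defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_cfg = CohortConfig(**raw.get("cohort", {}))
    sweep_raw = dict(raw.get("sweep", {}))
    if "rate_grid" not in sweep_raw and {"rate_start", "rate_stop", "rate_step"} & set(sweep_raw):
        sweep_raw["rate_grid"] = default_rate_grid(
            sweep_raw.pop("rate_start", 0.0),
            sweep_raw.pop("rate_stop", 50.0),
            sweep_raw.pop("rate_step", 0.1),
        )
    for key in ("rate_grid", "methods", "metrics"):
        if key in sweep_raw and isinstance(sweep_raw[key], list):
            sweep_raw[key] = tuple(sweep_raw[key])
    sweep_cfg = SweepConfig(**sweep_raw)
    spectral_raw = dict(raw.get("spectral", {}))
    for key in ("vlf_band", "lf_band", "hf_band"):
        if key in spectral_raw and isinstance(spectral_raw[key], list):
            spectral_raw[key] = tuple(spectral_raw[key])
    spectral_cfg = SpectralConfig(**spectral_raw)
    rule = ThresholdRule(**raw.get("threshold", {}))
    return cohort_cfg, sweep_cfg, spectral_cfg, rule
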