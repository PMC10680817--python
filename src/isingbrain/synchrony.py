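"""Binarization of parcellated fMRI signals and empirical synchrony statistics.

A region-parcellated resting-state scan is reduced to Ising spins by the sign
of the signal's slope between consecutive time points: an increasing signal
maps to +1, a decreasing one to -1. The *synchrony* s(t) is the mean spin over
all regions at time t (the magnetization per spin), and the empirical
segregation probability Pseg is the fraction of time points whose absolute
synchrony lies strictly below a threshold s*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RegionTimeSeries",
    "MomentSummary",
    "DataQualityError",
    "binarize",
    "compute_synchrony",
    "empirical_moments",
    "pseg_empirical",
    "read_timeseries",
    "write_timeseries",
    "read_metadata",
    "write_synchrony",
]


class DataQualityError(ValueError):
    """Raised when an input scan violates basic quality requirements."""


@dataclass
class RegionTimeSeries:
    """One subject's parcellated signal matrix plus demographics.

    ``values`` is region-major: shape (n_regions, t_scan). On-disk files are
    time-major (rows = time points, header = region labels) and transposed by
    the readers.
    """

    subject_id: str
    values: np.ndarray
    age: Optional[float] = None
    sex: Optional[str] = None
    handedness: Optional[str] = None
    region_labels: Optional[list] = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"{self.subject_id}: values must be 2-D")
        n_regions, t_scan = self.values.shape
        if n_regions < 2:
            raise ValueError(f"{self.subject_id}: need at least 2 regions")
        if t_scan < 3:
            raise ValueError(f"{self.subject_id}: need at least 3 time points")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def t_scan(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MomentSummary:
    """Second and fourth moments of a synchrony series (or of a model pmf)."""

    m2: float
    m4: float
    t_used: Optional[int] = None


def binarize(ts: RegionTimeSeries) -> np.ndarray:
    """Map a region x time signal matrix to spins by the slope sign.

    Entry (i, t) is +1 when region i's signal increases from t to t+1 and -1
    when it decreases. An exact tie (zero slope) maps deterministically to +1;
    real-valued scans make ties measure-zero, and determinism keeps synthetic
    integer-valued inputs unambiguous.

    Returns an int8 array of shape (n_regions, t_scan - 1).
    """
    if not np.all(np.isfinite(ts.values)):
        raise DataQualityError(
            f"subject {ts.subject_id!r}: non-finite values in signal matrix"
        )
    diff = np.diff(ts.values, axis=1)
    spins = np.where(diff >= 0, 1, -1).astype(np.int8)
    return spins


def compute_synchrony(spins: np.ndarray) -> np.ndarray:
    """Mean spin across regions at each time point: s(t) = (1/N) sum_i sigma_i(t).

    Values lie on the parity grid {-1, -1 + 2/N, ..., 1}: N*s(t) is an integer
    with the parity of N.
    """
    spins = np.asarray(spins)
    if spins.ndim != 2:
        raise ValueError("spin matrix must be 2-D (regions x time)")
    if not np.all(np.abs(spins) == 1):
        raise ValueError("spin matrix entries must be exactly -1 or +1")
    return spins.sum(axis=0) / spins.shape[0]


def empirical_moments(s: np.ndarray) -> MomentSummary:
    """Mean of s^2 and s^4 over all retained time points (no burn-in trim)."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty synchrony series")
    s2 = s * s
    return MomentSummary(m2=float(s2.mean()), m4=float((s2 * s2).mean()), t_used=s.size)


def pseg_empirical(s: np.ndarray, s_star: float) -> tuple[float, float]:
    """Fraction of time points with |s(t)| < s_star (strict), and its complement.

    Returns ``(pseg, pint)`` with pseg + pint = 1; boundary points |s| == s*
    count as integrated, matching the calibration convention.
    """
    if not 0.0 < s_star < 1.0:
        raise ValueError(f"s_star must lie in (0, 1), got {s_star}")
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty synchrony series")
    pseg = float(np.mean(np.abs(s) < s_star))
    return pseg, 1.0 - pseg


# ---------------------------------------------------------------------------
# Plain-text I/O: time-major TSV matrices with a header of region labels,
# and a tab-separated subject metadata table.
# ---------------------------------------------------------------------------

def read_timeseries(path, subject_id: Optional[str] = None,
                    **demographics) -> RegionTimeSeries:
    """Read a tab-separated region-time matrix (rows = time, header = labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataQualityError(f"{path}: need at least 2 region columns")
    sid = subject_id if subject_id is not None else path.stem
    return RegionTimeSeries(
        subject_id=sid,
        values=df.to_numpy(dtype=float).T,
        region_labels=list(df.columns),
        **demographics,
    )


def write_timeseries(ts: RegionTimeSeries, path) -> None:
    labels = ts.region_labels or [f"R{i:03d}" for i in range(ts.n_regions)]
    # %.17g guarantees bit-exact float round-trips through the text format
    pd.DataFrame(ts.values.T, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_metadata(path) -> pd.DataFrame:
    """Read the subject metadata table (subject_id, age, sex, handedness, t_scan)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    required = {"subject_id", "age"}
    missing = required - set(df.columns)
    if missing:
        raise DataQualityError(f"{path}: metadata missing columns {sorted(missing)}")
    return df


def write_synchrony(s: np.ndarray, path) -> None:
    """Write a per-subject synchrony series as a one-column TSV."""
    pd.DataFrame({"synchrony": np.asarray(s, dtype=float)}).to_csv(
        path, sep="\t", index=False
    )
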