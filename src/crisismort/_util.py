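"""Shared helpers: calendar months, seed derivation, small numerics."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

MONTH = "M"


def month_range(start: str, end: str) -> pd.PeriodIndex:
    """Inclusive range of calendar months, e.g. month_range('2014-01', '2018-12')."""
    idx = pd.period_range(start, end, freq=MONTH)
    if len(idx) == 0:
        raise ValueError(f"empty month range {start}..{end}")
    return idx


def as_month(value) -> pd.Period:
    return pd.Period(value, freq=MONTH)


def days_in_months(months: pd.PeriodIndex) -> np.ndarray:
    return np.asarray([m.days_in_month for m in months], dtype=float)


def month_overlap_days(start: pd.Timestamp, end: pd.Timestamp, month: pd.Period) -> float:
    """Number of days of the closed interval [start, end) falling in `month`."""
    m_start, m_end = month.start_time, month.end_time + pd.Timedelta(seconds=1)
    lo = max(start, m_start)
    hi = min(end, m_end)
    return max((hi - lo) / pd.Timedelta(days=1), 0.0)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed, stable across platforms.

    Uses SHA-256 of "<master>:<stage>" truncated below 2**31 so the same
    master seed always fans out to the same stage seeds.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def round_to(x, base: float = 100.0):
    """Round to the nearest multiple of `base`, halves up (44,650 -> 44,700)."""
    return np.floor(np.asarray(x, dtype=float) / base + 0.5) * base
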