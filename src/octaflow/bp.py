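"""Longitudinal blood-pressure summary features.

Visit-to-visit blood-pressure variability is summarized per patient over
the year strictly preceding enrollment: the 1-year average, the 1-year
maximum, the within-patient standard deviation (sample SD, n-1), and the
proportion of readings with SBP above 140 mmHg.  The enrollment-day
reading is kept separate and never enters the 1-year aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

WINDOW_DAYS = 365
HIGH_SBP_CUTOFF = 140  # strictly greater counts as "high"
MIN_MEASUREMENTS = 3  # eligibility: fewer in-window visits excludes a patient


class EmptyWindowError(ValueError):
    """No visit falls inside the 1-year pre-enrollment window."""


@dataclass(frozen=True)
class BPVisit:
    """One dated office blood-pressure reading (mmHg)."""

    date: date
    sbp: int
    dbp: int

    def __post_init__(self) -> None:
        if not 60 <= self.sbp <= 260:
            raise ValueError(f"implausible SBP {self.sbp}")
        if not 30 <= self.dbp <= 160:
            raise ValueError(f"implausible DBP {self.dbp}")
        if self.sbp <= self.dbp:
            raise ValueError("SBP must exceed DBP")


@dataclass(frozen=True)
class BPSeries:
    """A patient's dated BP readings around an enrollment date.

    The analysis window is the 365 days strictly before enrollment:
    ``enrollment - 365d < visit date < enrollment``.  Visits are stored
    sorted by date.
    """

    patient_id: str
    enrollment_date: date
    visits: tuple[BPVisit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "visits", tuple(sorted(self.visits, key=lambda v: v.date))
        )

    def in_window(self) -> tuple[BPVisit, ...]:
        lo = self.enrollment_date - timedelta(days=WINDOW_DAYS)
        return tuple(
            v for v in self.visits if lo < v.date < self.enrollment_date
        )

    def on_enrollment_day(self) -> BPVisit | None:
        for v in self.visits:
            if v.date == self.enrollment_date:
                return v
        return None


@dataclass(frozen=True)
class BPFeatureSet:
    """The four 1-year BP parameters plus the enrollment-day reading."""

    patient_id: str
    n_measurements: int
    avg_sbp: float
    avg_dbp: float
    max_sbp: float
    max_dbp: float
    sd_sbp: float
    sd_dbp: float
    prop_high_sbp: float
    sbp_enroll: float = np.nan
    dbp_enroll: float = np.nan
    sd_insufficient: bool = False  # single in-window reading: SD reported as 0

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_measurements": self.n_measurements,
            "avg_sbp": self.avg_sbp,
            "avg_dbp": self.avg_dbp,
            "max_sbp": self.max_sbp,
            "max_dbp": self.max_dbp,
            "sd_sbp": self.sd_sbp,
            "sd_dbp": self.sd_dbp,
            "prop_high_sbp": self.prop_high_sbp,
            "sbp_enroll": self.sbp_enroll,
            "dbp_enroll": self.dbp_enroll,
        }


def compute_bp_features(series: BPSeries) -> BPFeatureSet:
    """Derive the 1-year BP parameters from one patient's visit record.

    Averages and maxima run over the in-window visits only; the SD is the
    sample standard deviation (n-1); ``prop_high_sbp`` is the fraction of
    in-window readings with SBP strictly above 140 mmHg.  A single
    in-window reading has no defined SD and is reported as 0 with
    ``sd_insufficient=True``.
    """
    window = series.in_window()
    if not window:
        raise EmptyWindowError(
            f"patient {series.patient_id}: no visit in the 1-year window"
        )
    sbp = np.array([v.sbp for v in window], dtype=float)
    dbp = np.array([v.dbp for v in window], dtype=float)
    n = len(window)
    insufficient = n < 2
    enroll = series.on_enrollment_day()
    return BPFeatureSet(
        patient_id=series.patient_id,
        n_measurements=n,
        avg_sbp=float(np.mean(sbp)),
        avg_dbp=float(np.mean(dbp)),
        max_sbp=float(np.max(sbp)),
        max_dbp=float(np.max(dbp)),
        sd_sbp=0.0 if insufficient else float(np.std(sbp, ddof=1)),
        sd_dbp=0.0 if insufficient else float(np.std(dbp, ddof=1)),
        prop_high_sbp=float(np.mean(sbp > HIGH_SBP_CUTOFF)),
        sbp_enroll=float(enroll.sbp) if enroll else np.nan,
        dbp_enroll=float(enroll.dbp) if enroll else np.nan,
        sd_insufficient=insufficient,
    )


def filter_eligible(series: BPSeries) -> bool:
    """Eligibility per the study rule: at least 3 BP measurements in the
    1-year pre-enrollment window."""
    return len(series.in_window()) >= MIN_MEASUREMENTS


def series_from_frame(
    bp_df: pd.DataFrame,
    enrollment: dict[str, date] | None = None,
) -> list[BPSeries]:
    """Build per-patient BPSeries from a long-format visit table.

    Expects columns ``patient_id, date, sbp, dbp`` and, unless an
    ``enrollment`` mapping is given, an ``enrollment_date`` column.
    """
    df = bp_df.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        if enrollment is not None:
            enr = enrollment[pid]
        else:
            enr = pd.to_datetime(grp["enrollment_date"].iloc[0]).date()
        visits = tuple(
            BPVisit(date=r.date, sbp=int(r.sbp), dbp=int(r.dbp))
            for r in grp.itertuples()
        )
        out.append(BPSeries(patient_id=str(pid), enrollment_date=enr, visits=visits))
    return out


def features_table(series_list: list[BPSeries]) -> pd.DataFrame:
    """BP feature rows for every *eligible* patient in a list of series."""
    rows = [
        compute_bp_features(s).as_dict() for s in series_list if filter_eligible(s)
    ]
    return pd.DataFrame(rows)
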