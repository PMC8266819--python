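"""Hair-section chronology: from collected guard hairs to month- and
season-assigned 15-mm sections.

Guard-hair keratin archives diet sequentially: hair grows at roughly 15 mm
per month during the activity period, and the annual moult (July-August)
resets the record. Hairs collected in June (pre-moult) are fully grown hairs
from the previous activity period, so their basal section corresponds to the
last month of growth before dormancy (November of the previous year); hairs
collected in September (post-moult) grew during the current season, so the
basal section is the month preceding collection. Sections step one calendar
month backwards from root to tip. Dietary seasons pool months: spring
(Mar-May), early summer (Jun-Jul), late summer (Aug-Sep), autumn (Oct-Nov);
dormancy months map to no season.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "SEASON_OF_MONTH",
    "SEASONS",
    "HairSample",
    "ChronologyAssignment",
    "HairSection",
    "classify_sampling_period",
    "section_hair",
    "assign_months",
    "month_to_season",
    "build_chronology",
]

SEASONS = ("spring", "early_summer", "late_summer", "autumn")

SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "early_summer", 7: "early_summer",
    8: "late_summer", 9: "late_summer",
    10: "autumn", 11: "autumn",
    12: None, 1: None, 2: None,
}

#: Activity period (inclusive month bounds); sections assigned outside it are
#: flagged and excluded from models.
ACTIVITY_MONTHS = (3, 11)

SECTION_LENGTH_MM = 15.0


@dataclass(frozen=True)
class HairSample:
    """One collected hair (tuft) from an identified bear."""

    sample_id: str
    bear_id: str
    collection_date: dt.date
    length_mm: float
    method: str = ""

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ValueError("hair length must be positive")


@dataclass(frozen=True)
class ChronologyAssignment:
    """Calendar placement of one 15-mm section (0-based index from the root)."""

    section_index: int
    month: int
    year: int
    season: Optional[str]
    out_of_activity: bool = False


@dataclass(frozen=True)
class HairSection:
    sample_id: str
    assignment: ChronologyAssignment
    d13C: float
    d15N: float


def classify_sampling_period(collection_date: dt.date) -> str:
    """June -> pre_moult; September -> post_moult; July/August -> excluded_moult;
    anything else -> excluded_out_of_window."""
    m = collection_date.month
    if m == 6:
        return "pre_moult"
    if m == 9:
        return "post_moult"
    if m in (7, 8):
        return "excluded_moult"
    return "excluded_out_of_window"


def section_hair(
    length_mm: float, section_length_mm: float = SECTION_LENGTH_MM
) -> tuple[int, float]:
    """Number of full sections and the discarded tip remainder in mm."""
    if length_mm <= 0:
        raise ValueError("hair length must be positive")
    n = int(length_mm // section_length_mm)
    return n, length_mm - n * section_length_mm


def month_to_season(month: int) -> Optional[str]:
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1-12, got {month}")
    return SEASON_OF_MONTH[month]


def _step_back(month: int, year: int, k: int) -> tuple[int, int]:
    """Calendar month k steps before (month, year)."""
    idx = (year * 12 + (month - 1)) - k
    return idx % 12 + 1, idx // 12


def assign_months(
    sample: HairSample, period: str, n_sections: int
) -> list[ChronologyAssignment]:
    """Assign each section (root-first) to its calendar month and season.

    Pre-moult hairs anchor the root at November of the year before collection;
    post-moult hairs anchor it at the calendar month preceding collection.
    Months before the activity start (March) are flagged out-of-activity.
    """
    if period not in ("pre_moult", "post_moult"):
        raise ValueError(f"cannot assign months for period {period!r}")
    if n_sections < 0:
        raise ValueError("n_sections must be >= 0")
    if period == "pre_moult":
        root_month, root_year = 11, sample.collection_date.year - 1
    else:
        root_month, root_year = _step_back(
            sample.collection_date.month, sample.collection_date.year, 1
        )
    out = []
    for i in range(n_sections):
        month, year = _step_back(root_month, root_year, i)
        # pre-moult hairs record the previous activity period, so only months
        # from March of the root year onward are in-activity; earlier months
        # (or another year entirely) are flagged.
        in_activity = (
            year == root_year and ACTIVITY_MONTHS[0] <= month <= ACTIVITY_MONTHS[1]
        )
        out.append(
            ChronologyAssignment(
                section_index=i,
                month=month,
                year=year,
                season=month_to_season(month),
                out_of_activity=not in_activity,
            )
        )
    return out


def build_chronology(hairs: pd.DataFrame, sections: pd.DataFrame) -> pd.DataFrame:
    """Join hairs.csv and sections.csv into a chronology table.

    ``hairs`` columns: sample_id, bear_id, collection_date (ISO-8601),
    length_mm, method. ``sections`` columns: sample_id, section_index, d13C,
    d15N. The result adds month, year, season and exclusion_reason (empty for
    usable sections).
    """
    hairs = hairs.copy()
    hairs["collection_date"] = pd.to_datetime(hairs["collection_date"]).dt.date
    rows = []
    sec_by_sample = dict(tuple(sections.groupby("sample_id", sort=False)))
    for _, h in hairs.iterrows():
        sample = HairSample(
            sample_id=str(h["sample_id"]),
            bear_id=str(h["bear_id"]),
            collection_date=h["collection_date"],
            length_mm=float(h["length_mm"]),
            method=str(h.get("method", "")),
        )
        period = classify_sampling_period(sample.collection_date)
        n_sections, _ = section_hair(sample.length_mm)
        measured = sec_by_sample.get(sample.sample_id)
        if period.startswith("excluded"):
            assignments = None
        else:
            assignments = {
                a.section_index: a
                for a in assign_months(sample, period, n_sections)
            }
        if measured is None:
            continue
        for _, s in measured.iterrows():
            idx = int(s["section_index"])
            base = {
                "sample_id": sample.sample_id,
                "bear_id": sample.bear_id,
                "section_index": idx,
                "d13C": float(s["d13C"]),
                "d15N": float(s["d15N"]),
                "period": period,
            }
            if assignments is None:
                base.update(
                    month=pd.NA, year=pd.NA, season=pd.NA, exclusion_reason=period
                )
            elif idx not in assignments:
                base.update(
                    month=pd.NA, year=pd.NA, season=pd.NA,
                    exclusion_reason="section_index_beyond_hair_length",
                )
            else:
                a = assignments[idx]
                reason = ""
                if a.out_of_activity:
                    reason = "out_of_activity"
                elif a.season is None:
                    reason = "dormancy_month"
                base.update(
                    month=a.month, year=a.year,
                    season=a.season if a.season else pd.NA,
                    exclusion_reason=reason,
                )
            rows.append(base)
    cols = [
        "sample_id", "bear_id", "section_index", "d13C", "d15N",
        "period", "month", "year", "season", "exclusion_reason",
    ]
    return pd.DataFrame(rows, columns=cols)
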