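"""Key-food source data: domain types, CSV I/O, delta-notation conversion and
aggregation of individual food samples into diet-source categories.

Isotope values are expressed in delta notation (per-mil deviation from VPDB
for carbon, atmospheric N2 for nitrogen). Key foods are grouped a priori into
seven diet categories plus C4 plants (corn); category-level statistics pool
species-level means and SDs exactly (weighted grand mean, within + between
sums of squares with denominator N-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_LABELS",
    "MODEL_SOURCES",
    "IsotopeMeasurement",
    "SourceSample",
    "SourceCategory",
    "BearRecord",
    "delta_from_ratio",
    "ratio_from_delta",
    "read_sources",
    "aggregate_category",
    "aggregate_all",
    "pool_groups",
    "write_categories",
]

#: Closed category vocabulary: the seven diet sources plus C4 plants (corn).
CATEGORY_LABELS: tuple[str, ...] = (
    "Cultivated fleshy fruits",
    "Cultivated vegetables",
    "Formicidae",
    "Hard masts",
    "Herbs",
    "Ungulates",
    "Wild fleshy fruits",
    "C4",
)

#: The categories that enter mixing models, in the fixed (alphabetical) order
#: used everywhere downstream. C4 is screened in diagnostics but never a source.
MODEL_SOURCES: tuple[str, ...] = tuple(c for c in CATEGORY_LABELS if c != "C4")

SOURCE_COLUMNS = (
    "species",
    "category",
    "trophic_class",
    "d13C",
    "d15N",
    "C_pct",
    "N_pct",
    "digest_C_pct",
    "digest_N_pct",
)


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta value (per mil) from heavy-to-light isotope ratios.

    delta = ((R_sample - R_standard) / R_standard) * 1000.
    """
    if r_standard <= 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"r_sample must be non-negative, got {r_sample}")
    return (r_sample - r_standard) / r_standard * 1e3


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`: recover R_sample."""
    if r_standard <= 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    return r_standard * (1.0 + delta / 1e3)


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A paired (d13C, d15N) measurement, optionally with its raw ratios."""

    d13C: float
    d15N: float
    r_sample: Optional[float] = None
    r_standard: Optional[float] = None

    def __post_init__(self):
        if not (np.isfinite(self.d13C) and np.isfinite(self.d15N)):
            raise ValueError("delta values must be finite")
        if self.r_sample is not None:
            if self.r_standard is None or self.r_standard <= 0:
                raise ValueError("r_standard must be positive when ratios given")
            implied = delta_from_ratio(self.r_sample, self.r_standard)
            if not (
                abs(implied - self.d13C) < 1e-9 or abs(implied - self.d15N) < 1e-9
            ):
                raise ValueError(
                    "stored delta does not match the delta implied by the ratios"
                )


@dataclass(frozen=True)
class SourceSample:
    """One analysed key-food sample."""

    species: str
    category: str
    trophic_class: str
    measurement: IsotopeMeasurement
    c_pct: float
    n_pct: float
    digest_c_pct: Optional[float] = None
    digest_n_pct: Optional[float] = None

    def __post_init__(self):
        if self.category not in CATEGORY_LABELS:
            raise ValueError(f"unknown category label {self.category!r}")
        if self.trophic_class not in ("vegetable", "animal"):
            raise ValueError(f"unknown trophic class {self.trophic_class!r}")
        for name in ("c_pct", "n_pct"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")


@dataclass
class SourceCategory:
    """Pooled isotopic/elemental distribution of one diet-source category.

    ``digest_c`` / ``digest_n`` are digestible elemental concentrations in
    percent dry weight (fractions are normalised only inside the mixing
    equation).
    """

    name: str
    trophic_class: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    n: int
    digest_c: float
    digest_n: float
    sd_digest_c: float = 0.0
    sd_digest_n: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("sd_d13C", "sd_d15N", "sd_digest_c", "sd_digest_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.digest_c <= 0 or self.digest_n <= 0:
            raise ValueError("digestible concentrations must be positive")


@dataclass(frozen=True)
class BearRecord:
    """Identity and covariates of one sampled bear."""

    bear_id: str
    sex: str = "unknown"  # F | M | unknown
    status: str = "unknown"  # management | non-management | unknown

    def __post_init__(self):
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")
        if self.status not in ("management", "non-management", "unknown"):
            raise ValueError(f"invalid management status {self.status!r}")


def read_sources(
    path, category_whitelist: Sequence[str] = CATEGORY_LABELS
) -> list[SourceSample]:
    """Read a key-food sample table (one row per analysed sample).

    Columns: species, category, trophic_class, d13C, d15N, C_pct, N_pct,
    digest_C_pct, digest_N_pct (the digestible columns may be empty, in which
    case total concentrations are used downstream).
    """
    df = pd.read_csv(path)
    missing = [c for c in SOURCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {', '.join(missing)}")
    samples: list[SourceSample] = []
    for idx, row in df.iterrows():
        if row["category"] not in category_whitelist:
            raise ValueError(
                f"row {idx}: unknown category label {row['category']!r}"
            )
        vals = {}
        for col in ("d13C", "d15N", "C_pct", "N_pct"):
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {idx}: non-numeric value {row[col]!r} in column {col}"
                ) from None
        digest = {}
        for col in ("digest_C_pct", "digest_N_pct"):
            digest[col] = None if pd.isna(row[col]) else float(row[col])
        samples.append(
            SourceSample(
                species=str(row["species"]),
                category=str(row["category"]),
                trophic_class=str(row["trophic_class"]),
                measurement=IsotopeMeasurement(d13C=vals["d13C"], d15N=vals["d15N"]),
                c_pct=vals["C_pct"],
                n_pct=vals["N_pct"],
                digest_c_pct=digest["digest_C_pct"],
                digest_n_pct=digest["digest_N_pct"],
            )
        )
    return samples


def pool_groups(
    means: np.ndarray, sds: np.ndarray, ns: np.ndarray
) -> tuple[float, float]:
    """Pool group-level summaries into a grand mean and total SD.

    The grand mean is the sample-size-weighted mean of group means. The total
    SD combines within-group sums of squares sum((n_i - 1) sd_i^2) and
    between-group sums of squares sum(n_i (m_i - m)^2), divided by N - 1.
    Equals the plain sample SD over all underlying observations.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.size == 0:
        raise ValueError("cannot pool zero groups")
    n_total = ns.sum()
    grand = float(np.sum(ns * means) / n_total)
    if n_total <= 1:
        return grand, 0.0
    ss_within = float(np.sum((ns - 1) * sds**2))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    return grand, float(np.sqrt((ss_within + ss_between) / (n_total - 1)))


def aggregate_category(
    samples: Iterable[SourceSample],
    name: str,
    digestibility_c: float = 1.0,
    digestibility_n: float = 1.0,
) -> SourceCategory:
    """Pool all samples of one category into a :class:`SourceCategory`.

    Digestible concentrations default to the measured elemental percentages
    scaled by per-category digestibility multipliers (1.0 unless configured);
    rows that carry explicit digest_*_pct values override the multiplier.
    """
    samples = list(samples)
    if not samples:
        raise ValueError(f"no samples for category {name!r}")
    bad = {s.category for s in samples if s.category != name}
    if bad:
        raise ValueError(f"samples from other categories present: {sorted(bad)}")
    classes = {s.trophic_class for s in samples}
    if len(classes) > 1:
        raise ValueError(f"mixed trophic classes in category {name!r}")

    d13 = np.array([s.measurement.d13C for s in samples])
    d15 = np.array([s.measurement.d15N for s in samples])
    dc = np.array(
        [
            s.digest_c_pct if s.digest_c_pct is not None else s.c_pct * digestibility_c
            for s in samples
        ]
    )
    dn = np.array(
        [
            s.digest_n_pct if s.digest_n_pct is not None else s.n_pct * digestibility_n
            for s in samples
        ]
    )
    n = len(samples)
    ddof = 1 if n > 1 else 0
    return SourceCategory(
        name=name,
        trophic_class=classes.pop(),
        mean_d13C=float(d13.mean()),
        sd_d13C=float(d13.std(ddof=ddof)),
        mean_d15N=float(d15.mean()),
        sd_d15N=float(d15.std(ddof=ddof)),
        n=n,
        digest_c=float(dc.mean()),
        digest_n=float(dn.mean()),
        sd_digest_c=float(dc.std(ddof=ddof)),
        sd_digest_n=float(dn.std(ddof=ddof)),
    )


def aggregate_all(
    samples: Iterable[SourceSample],
    digestibility: Optional[dict] = None,
) -> list[SourceCategory]:
    """Aggregate every category present, ordered as :data:`CATEGORY_LABELS`."""
    samples = list(samples)
    digestibility = digestibility or {}
    out = []
    for name in CATEGORY_LABELS:
        subset = [s for s in samples if s.category == name]
        if subset:
            mult = digestibility.get(name, {})
            out.append(
                aggregate_category(
                    subset,
                    name,
                    digestibility_c=mult.get("C", 1.0),
                    digestibility_n=mult.get("N", 1.0),
                )
            )
    return out


def write_categories(categories: Sequence[SourceCategory], path) -> None:
    """Export pooled category statistics as categories.csv."""
    rows = [
        {
            "category": c.name,
            "trophic_class": c.trophic_class,
            "mean_d13C": c.mean_d13C,
            "sd_d13C": c.sd_d13C,
            "mean_d15N": c.mean_d15N,
            "sd_d15N": c.sd_d15N,
            "n": c.n,
            "digest_C_pct": c.digest_c,
            "digest_N_pct": c.digest_n,
            "sd_digest_C_pct": c.sd_digest_c,
            "sd_digest_N_pct": c.sd_digest_n,
        }
        for c in categories
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
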