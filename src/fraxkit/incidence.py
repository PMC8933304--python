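"""Hip-fracture incidence estimation from an admission line list.

Turns raw hospital admissions into deduplicated fracture cases, accumulates
person-years from mid-year population counts, and reports age- and
sex-specific incidence per 100,000 person-years with exact (Garwood)
Poisson confidence intervals — the layout of a registry incidence table.
Direct age standardization with a Fay–Feuer gamma interval and a log-scale
z-test support comparison of two populations (e.g. nationals vs
expatriates) with different age structures.

Case-selection rules: ICD-10 hip codes S72.0/S72.1/S72.2 (any further
subdigits), age 40 and over, admissions irrespective of the degree of
trauma, and one case per patient per fracture episode — repeat admissions
of the same patient within a configurable window (default 365 days) of an
earlier retained admission count as the same fracture.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import AGE_BANDS, AGE_FLOOR, band_of

logger = logging.getLogger(__name__)

HIP_CODE_RE = re.compile(r"^S72\.?[012]")

SEXES = ("male", "female")
NATIONALITIES = ("national", "expatriate")

PER = 100_000  # reporting scale: events per 100,000 person-years


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospital admission row, pre-deduplication."""

    patient_id: str
    admission_date: dt.date
    sex: str
    nationality: str
    icd10: str
    age_at_admission: int | None = None
    birth_date: dt.date | None = None

    def age(self) -> int:
        """Completed years at admission, from the age field or birth date."""
        if self.age_at_admission is not None:
            return int(self.age_at_admission)
        if self.birth_date is None:
            raise ValueError(
                f"record {self.patient_id}: neither age nor birth date present"
            )
        b, a = self.birth_date, self.admission_date
        return a.year - b.year - ((a.month, a.day) < (b.month, b.day))


@dataclass(frozen=True)
class FractureCase(AdmissionRecord):
    """A deduplicated fracture episode; the admission defining it is the
    patient's earliest retained one."""

    age_band: str = ""
    year: int = 0


def select_index_admissions(
    records: Iterable[AdmissionRecord],
    window_days: int = 365,
    study_years: Sequence[int] | None = None,
    issues: list[str] | None = None,
) -> list[FractureCase]:
    """Reduce an admission line list to one case per fracture episode.

    Keeps hip-coded admissions (S72.0/.1/.2) at ages >= 40 inside the study
    window; within each patient, an admission within ``window_days`` of an
    earlier retained admission is dropped as the same fracture. No
    trauma-based exclusion is applied. Unusable records (missing sex,
    underivable age) are skipped, counted, and reported via ``issues`` /
    a logged warning — never silently dropped.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    collected = issues if issues is not None else []

    usable: list[AdmissionRecord] = []
    for rec in records:
        try:
            if rec.sex not in SEXES:
                raise ValueError(f"unrecognized sex {rec.sex!r}")
            rec.age()  # raises if underivable
        except (ValueError, TypeError) as exc:
            collected.append(f"{rec.patient_id} @ {rec.admission_date}: {exc}")
            continue
        usable.append(rec)
    if collected and issues is None:
        logger.warning("skipped %d unusable admission record(s)", len(collected))

    eligible = [
        r
        for r in usable
        if HIP_CODE_RE.match(r.icd10)
        and r.age() >= AGE_FLOOR
        and (study_years is None or r.admission_date.year in study_years)
    ]

    cases: list[FractureCase] = []
    by_patient: dict[str, list[AdmissionRecord]] = {}
    for r in eligible:
        by_patient.setdefault(r.patient_id, []).append(r)
    for pid in sorted(by_patient):
        admissions = sorted(by_patient[pid], key=lambda r: r.admission_date)
        last_kept: dt.date | None = None
        for r in admissions:
            if last_kept is not None and (r.admission_date - last_kept).days <= window_days:
                continue  # same fracture episode
            last_kept = r.admission_date
            cases.append(
                FractureCase(
                    patient_id=r.patient_id,
                    admission_date=r.admission_date,
                    sex=r.sex,
                    nationality=r.nationality,
                    icd10=r.icd10,
                    age_at_admission=r.age(),
                    birth_date=r.birth_date,
                    age_band=band_of(r.age()),
                    year=r.admission_date.year,
                )
            )
    return cases


def person_years(
    population: pd.DataFrame,
    years: Sequence[int],
    scope: str = "all",
) -> pd.DataFrame:
    """Person-years by sex and age band: sum of mid-year head counts over
    the study years (one person-year per person per calendar year).

    ``scope`` restricts the denominator to 'national', 'expatriate', or
    'all' (both strata). A missing stratum-year is a hard error naming the
    stratum.
    """
    if scope not in (*NATIONALITIES, "all"):
        raise ValueError(f"scope must be one of {NATIONALITIES + ('all',)}")
    pop = population if scope == "all" else population[population["nationality"] == scope]

    nats = NATIONALITIES if scope == "all" else (scope,)
    cells = pop.set_index(["year", "sex", "nationality", "age_band"])["count"]
    if cells.index.has_duplicates:
        cells = cells.groupby(level=[0, 1, 2, 3]).sum()
    rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            py = 0.0
            for year in years:
                for nat in nats:
                    key = (year, sex, nat, band)
                    if key not in cells.index:
                        raise ValueError(
                            f"population table missing stratum year={year}, "
                            f"sex={sex}, nationality={nat}, age_band={band}"
                        )
                    py += float(cells.loc[key])
            rows.append({"sex": sex, "age_band": band, "py": py})
    return pd.DataFrame(rows)


def poisson_exact_ci(n, py, level: float = 0.95):
    """Exact (Garwood) two-sided Poisson interval for a rate, per 100,000.

    lower = chi2(alpha/2, 2n)/2/PY (0 when n = 0),
    upper = chi2(1-alpha/2, 2n+2)/2/PY — asymmetric and valid at small n.
    """
    n = np.asarray(n, dtype=float)
    py = np.asarray(py, dtype=float)
    alpha = 1.0 - level
    lo = np.where(n == 0, 0.0, stats.chi2.ppf(alpha / 2, 2 * n) / 2.0) / py * PER
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0 / py * PER
    return lo, hi


def estimate_rates(
    cases: Sequence[FractureCase],
    py: pd.DataFrame,
) -> pd.DataFrame:
    """Incidence table: events, person-years, rate per 100,000 and exact
    95% CI, per sex x age band. ``py`` is the output of `person_years`."""
    if (py["py"] <= 0).any():
        bad = py.loc[py["py"] <= 0, ["sex", "age_band"]].to_records(index=False)
        raise ValueError(f"non-positive person-years in strata: {list(bad)}")
    counts = pd.Series(0, index=pd.MultiIndex.from_frame(py[["sex", "age_band"]]))
    for c in cases:
        key = (c.sex, c.age_band)
        if key in counts.index:
            counts.loc[key] += 1
    table = py.copy()
    table["n"] = counts.to_numpy()
    table["rate"] = table["n"] / table["py"] * PER
    lo, hi = poisson_exact_ci(table["n"].to_numpy(), table["py"].to_numpy())
    table["ci_low"], table["ci_high"] = lo, hi
    return table[["sex", "age_band", "n", "py", "rate", "ci_low", "ci_high"]]


def format_incidence(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting layer: one-decimal 'rate (low-high)' strings, registry
    table style. Internal values stay full precision elsewhere."""
    out = table.copy()
    out["display"] = [
        f"{r:.1f} ({lo:.1f}–{hi:.1f})"
        for r, lo, hi in zip(out["rate"], out["ci_low"], out["ci_high"])
    ]
    return out


@dataclass(frozen=True)
class StandardizedRate:
    """Directly age-standardized rate per 100,000 with a Fay-Feuer gamma
    95% interval; ``se`` is the delta-method standard error on the same
    scale, ``weights`` the standard-population proportions used."""

    rate: float
    ci_low: float
    ci_high: float
    se: float
    weights: Mapping[str, float] = field(default_factory=dict)


def _standard_weights(standard) -> pd.Series:
    """Normalize a standard population (Series band->count, dict, or a
    population DataFrame summed over years/sexes) to proportions."""
    if isinstance(standard, pd.DataFrame):
        s = standard.groupby("age_band")["count"].sum()
    elif isinstance(standard, Mapping):
        s = pd.Series(standard, dtype=float)
    else:
        s = pd.Series(standard, dtype=float)
    total = float(s.sum())
    if total <= 0:
        raise ValueError("standard population is empty")
    return s / total


def age_standardize(table: pd.DataFrame, standard) -> StandardizedRate:
    """Direct standardization of a one-sex incidence table: rate = sum of
    w_band * rate_band with weights from the standard population's age
    distribution; 95% CI by the Fay-Feuer gamma method (valid for sparse
    counts)."""
    if table["sex"].nunique() != 1:
        raise ValueError("pass a one-sex incidence table (filter by sex first)")
    w = _standard_weights(standard)
    bands = list(table["age_band"])
    missing = [b for b in bands if b not in w.index]
    if missing:
        raise ValueError(f"standard population missing bands: {missing}")
    w = w.loc[bands]

    n = table["n"].to_numpy(dtype=float)
    py = table["py"].to_numpy(dtype=float)
    wi = w.to_numpy() / py  # per-event weight in each stratum
    x = float((wi * n).sum())  # standardized rate, events per person-year
    v = float((wi**2 * n).sum())
    wm = float(wi.max())

    if x == 0:
        lo = 0.0
    else:
        lo = stats.gamma.ppf(0.025, a=x**2 / v, scale=v / x)
    hi = stats.gamma.ppf(0.975, a=(x + wm) ** 2 / (v + wm**2), scale=(v + wm**2) / (x + wm))
    return StandardizedRate(
        rate=x * PER,
        ci_low=lo * PER,
        ci_high=hi * PER,
        se=float(np.sqrt(v)) * PER,
        weights=dict(w),
    )


def compare_standardized(a: StandardizedRate, b: StandardizedRate) -> float:
    """Two-sided p-value for a difference between two standardized rates:
    z-test on the log scale with delta-method standard errors."""
    if a.rate <= 0 or b.rate <= 0:
        raise ValueError(
            "zero standardized rate: the log-scale z-test is undefined; "
            "use an exact conditional (binomial) comparison of the counts instead"
        )
    se_ln = np.hypot(a.se / a.rate, b.se / b.rate)
    z = (np.log(b.rate) - np.log(a.rate)) / se_ln
    return float(2 * stats.norm.sf(abs(z)))


def crude_sex_ratio(cases: Sequence[FractureCase], py: pd.DataFrame) -> float:
    """Crude female:male incidence ratio, (female events / female PY) /
    (male events / male PY)."""
    totals = py.groupby("sex")["py"].sum()
    counts = {s: sum(1 for c in cases if c.sex == s) for s in SEXES}
    male_rate = counts["male"] / totals["male"]
    if male_rate == 0:
        raise ValueError("male crude rate is zero; ratio undefined")
    return (counts["female"] / totals["female"]) / male_rate


def case_share(n_sub: int, n_total: int) -> float:
    """Percentage share of a subgroup among all cases (e.g. nationals
    among all identified fractures)."""
    if n_total <= 0:
        raise ValueError("total case count must be positive")
    return 100.0 * n_sub / n_total
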