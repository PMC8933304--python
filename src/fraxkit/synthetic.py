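"""Synthetic national fracture registry.

Generates the three inputs the pipeline consumes — mid-year population
tables, an admission line list, and an abridged-to-single-year life table —
with the statistical structure the analysis assumes: a three-year national
admission extract with duplicate admissions of the same fracture, two
nationality strata with different fracture rates, and fracture and death
hazards that rise exponentially with age.

True hazards (the quantities downstream estimation tries to recover):

* fracture: Gompertz, h_f(age) = a * exp(b * age), scaled per stratum by a
  female:male multiplier and an expatriate:national multiplier;
* death: Gompertz-Makeham, h_d(age) = alpha + beta * exp(c * age), per sex.

Stratum event counts are Poisson with mean = head count * h_f(band
midpoint) — band-midpoint evaluation of the continuous hazard, whose error
is second order in the band width. One pseudo-random stream per run, keyed
by the seed; operations consume from it in a fixed documented order
(populations, then line list strata in sorted order, then decoys), so an
identical seed and configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import AGE_BANDS, band_bounds, band_midpoint
from .incidence import NATIONALITIES, SEXES, AdmissionRecord

# Default head counts per sex within each nationality stratum, by band.
# Bottom-heavy within 40+, thinning with age, as census pyramids do; the
# expatriate stratum is larger and younger (a migrant-workforce profile).
_DEFAULT_POP_NATIONAL = {
    "40-44": 6000, "45-49": 5500, "50-54": 5000, "55-59": 4200,
    "60-64": 3200, "65-69": 2200, "70-74": 1400, "75-79": 800, "80+": 600,
}
_DEFAULT_POP_EXPAT = {
    "40-44": 20000, "45-49": 16000, "50-54": 12000, "55-59": 8000,
    "60-64": 5000, "65-69": 2500, "70-74": 1200, "75-79": 600, "80+": 400,
}

DECOY_CODES = ("S82.1", "S52.5", "S42.2")  # tibia, distal radius, humerus


@dataclass(frozen=True)
class MakehamParams:
    """Gompertz-Makeham death hazard alpha + beta*exp(c*age), per year."""

    alpha: float
    beta: float
    c: float

    def hazard(self, age) -> np.ndarray:
        return self.alpha + self.beta * np.exp(self.c * np.asarray(age, dtype=float))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generated registry.

    Defaults emulate a small-country three-year extract: ~150 national and
    ~500 total hip fractures, female:male hazard ratio 1.25, expatriate
    rates 1.4x national, near-exponential incidence doubling roughly every
    5.3 years of age, and Gompertz-Makeham mortality.
    """

    seed: int = 0
    years: tuple[int, ...] = (2017, 2018, 2019)
    pop_size: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "national": dict(_DEFAULT_POP_NATIONAL),
            "expatriate": dict(_DEFAULT_POP_EXPAT),
        }
    )
    growth: float = 1.0  # per-year factor applied beyond the first year
    frac_hazard_scale: float = 2.0e-7  # a: baseline hazard at age 0, /year
    frac_hazard_slope: float = 0.13  # b: log-hazard increase per year of age
    expat_rate_multiplier: float = 1.4
    sex_multiplier: float = 1.25  # female:male fracture-hazard ratio
    dup_prob: float = 0.15  # chance a fracture yields a second admission
    decoy_fraction: float = 0.10  # non-hip records appended, per index case
    mort_makeham: Mapping[str, MakehamParams] = field(
        default_factory=lambda: {
            "male": MakehamParams(6e-4, 4e-5, 0.090),
            "female": MakehamParams(4e-4, 2.5e-5, 0.095),
        }
    )
    age_min: int = 40
    age_max: int = 105  # terminal age of the life table

    def __post_init__(self) -> None:
        if not (0.0 <= self.dup_prob <= 1.0):
            raise ValueError("dup_prob must be in [0, 1]")
        if self.decoy_fraction < 0:
            raise ValueError("decoy_fraction must be nonnegative")
        for p in (self.frac_hazard_scale, self.frac_hazard_slope,
                  self.expat_rate_multiplier, self.sex_multiplier, self.growth):
            if p < 0:
                raise ValueError("hazard parameters must be nonnegative")
        for mk in self.mort_makeham.values():
            if mk.alpha < 0 or mk.beta < 0 or mk.c < 0:
                raise ValueError("Makeham parameters must be nonnegative")
        for nat, bands in self.pop_size.items():
            if not bands:
                raise ValueError(f"empty age-band list for stratum {nat!r}")
            if any(v < 0 for v in bands.values()):
                raise ValueError(f"negative population count in stratum {nat!r}")

    # -- true hazards -----------------------------------------------------

    def fracture_hazard(self, age, sex: str, nationality: str) -> np.ndarray:
        """True annual fracture hazard at (continuous) age for a stratum."""
        h = self.frac_hazard_scale * np.exp(
            self.frac_hazard_slope * np.asarray(age, dtype=float)
        )
        if sex == "female":
            h = h * self.sex_multiplier
        if nationality == "expatriate":
            h = h * self.expat_rate_multiplier
        return h

    def death_hazard(self, age, sex: str) -> np.ndarray:
        return self.mort_makeham[sex].hazard(age)


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Mid-year head counts per year x sex x nationality x age band.

    The first year holds the configured counts; later years are the first
    year's counts grown by a fixed per-year factor, mirroring denominators
    projected forward from a single census year.
    """
    y0 = min(config.years)
    rows = []
    for year in sorted(config.years):
        g = config.growth ** (year - y0)
        for sex in SEXES:
            for nat in NATIONALITIES:
                bands = config.pop_size.get(nat)
                if bands is None:
                    raise ValueError(f"pop_size missing stratum {nat!r}")
                for band in AGE_BANDS:
                    if band not in bands:
                        raise ValueError(f"pop_size[{nat!r}] missing band {band!r}")
                    rows.append(
                        {
                            "year": year,
                            "sex": sex,
                            "nationality": nat,
                            "age_band": band,
                            "count": float(bands[band]) * g,
                        }
                    )
    return pd.DataFrame(rows)


def _open_band_ages(config: SyntheticConfig, sex: str) -> tuple[np.ndarray, np.ndarray]:
    """Candidate single-year ages and sampling weights for the open 80+
    band: a stationary-population profile, weighting each age by survival
    from 80 under the stratum's own death hazard (truncated at 100)."""
    ages = np.arange(80, 101)
    cumdeath = np.concatenate(
        [[0.0], np.cumsum(config.death_hazard(ages[:-1], sex))]
    )
    w = np.exp(-cumdeath)
    return ages, w / w.sum()


def _draw_age(rng: np.random.Generator, config: SyntheticConfig, band: str, sex: str) -> int:
    lo, hi = band_bounds(band)
    if hi is None:
        ages, w = _open_band_ages(config, sex)
        return int(rng.choice(ages, p=w))
    return int(rng.integers(lo, hi))


def _uniform_date(rng: np.random.Generator, year: int) -> dt.date:
    days = (dt.date(year + 1, 1, 1) - dt.date(year, 1, 1)).days
    return dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(days)))


def generate_line_list(
    config: SyntheticConfig, population: pd.DataFrame
) -> list[AdmissionRecord]:
    """Admission records implied by the population and the true hazards.

    Per stratum-year the fracture count is Poisson with mean = head count
    x h_f(band midpoint). Each fracture yields one index admission at a
    uniform in-year date with a hip ICD-10 code; with probability
    ``dup_prob`` a duplicate admission of the same patient follows 1-90
    days later (well inside any plausible same-fracture window). A
    configurable fraction of decoy records with non-hip codes is appended.
    """
    if population.empty:
        raise ValueError("population table is empty")
    rng = np.random.default_rng(config.seed)
    records: list[AdmissionRecord] = []
    pid = 0

    strata = population.sort_values(
        ["year", "sex", "nationality", "age_band"]
    ).itertuples(index=False)
    for row in strata:
        h = float(
            config.fracture_hazard(band_midpoint(row.age_band), row.sex, row.nationality)
        )
        n_frac = int(rng.poisson(row.count * h))
        for _ in range(n_frac):
            pid += 1
            patient = f"P{pid:06d}"
            age = _draw_age(rng, config, row.age_band, row.sex)
            date0 = _uniform_date(rng, row.year)
            records.append(
                AdmissionRecord(
                    patient_id=patient,
                    admission_date=date0,
                    sex=row.sex,
                    nationality=row.nationality,
                    icd10=str(rng.choice(["S72.0", "S72.1", "S72.2"])),
                    age_at_admission=age,
                )
            )
            # duplicate draws are consumed unconditionally so the stream —
            # and hence the index admissions — are identical across dup_prob
            dup_u = rng.random()
            gap = int(rng.integers(1, 91))
            dup_code = str(rng.choice(["S72.0", "S72.1", "S72.2"]))
            if dup_u < config.dup_prob:
                records.append(
                    AdmissionRecord(
                        patient_id=patient,
                        admission_date=date0 + dt.timedelta(days=gap),
                        sex=row.sex,
                        nationality=row.nationality,
                        icd10=dup_code,
                        age_at_admission=age,
                    )
                )

    n_index = pid
    n_decoys = int(round(config.decoy_fraction * n_index))
    if n_decoys > 0:
        cells = population.reset_index(drop=True)
        p = cells["count"].to_numpy()
        p = p / p.sum()
        picks = rng.choice(len(cells), size=n_decoys, p=p)
        for i in picks:
            cell = cells.iloc[int(i)]
            pid += 1
            records.append(
                AdmissionRecord(
                    patient_id=f"P{pid:06d}",
                    admission_date=_uniform_date(rng, int(cell["year"])),
                    sex=str(cell["sex"]),
                    nationality=str(cell["nationality"]),
                    icd10=str(rng.choice(DECOY_CODES)),
                    age_at_admission=_draw_age(
                        rng, config, str(cell["age_band"]), str(cell["sex"])
                    ),
                )
            )
    return records


def generate_life_table(config: SyntheticConfig) -> pd.DataFrame:
    """Single-year life table, ages 40..age_max per sex: central death
    rate m(age) = alpha + beta*exp(c*age) and q(age) = 1 - exp(-m)."""
    ages = np.arange(config.age_min, config.age_max + 1)
    frames = []
    for sex in SEXES:
        m = config.death_hazard(ages, sex)
        frames.append(
            pd.DataFrame(
                {"sex": sex, "age": ages, "m": m, "q": 1.0 - np.exp(-m)}
            )
        )
    return pd.concat(frames, ignore_index=True)
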