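"""Continuous per-age annual hazards from banded inputs.

Three conversions feed the probability engine:

* banded incidence -> smoothed hip-fracture hazard, by Poisson regression
  of band counts on band-midpoint age (log link, person-years offset,
  log-quadratic in age by default — hip incidence is near-exponential in
  age, and two shape parameters avoid overfitting nine bands);
* hip hazard -> major-osteoporotic-fracture (MOF) hazard, via an external
  table of other-MOF:hip incidence ratios (the Malmö-style imputation used
  when a country lacks direct spine/forearm/humerus incidence):
  mof(age) = hip(age) * (1 + r(age));
* life table -> death hazard, m = -ln(1 - q) for annual death
  probabilities, central rates used directly; abridged bands expand
  constant-within-band and extrapolate log-linearly (Gompertz) beyond the
  last band.

All curves live on a single-year age grid from 40 to a terminal age
(default 105, the closed-table convention); the smoothed incidence curve
is fitted up to 90 and held constant beyond, with the open "80+" band
anchored at a nominal midpoint of 85.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bands import band_bounds, band_midpoint

TERMINAL_AGE = 105
SMOOTH_MAX_AGE = 90  # constant extrapolation beyond this fitted age


@dataclass(frozen=True)
class HazardCurve:
    """Annual hazard (events/person-year) on a single-year age grid."""

    sex: str
    kind: str  # 'hip', 'mof', or 'death'
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.values):
            raise ValueError("ages and values must have equal length")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("hazards must be nonnegative")

    def at(self, age) -> np.ndarray:
        """Hazard at integer age(s); exact grid lookup, no interpolation."""
        idx = np.searchsorted(self.ages, np.asarray(age))
        flat = np.atleast_1d(idx)
        if np.any(flat >= len(self.ages)) or np.any(
            self.ages[np.clip(flat, 0, len(self.ages) - 1)] != np.atleast_1d(age)
        ):
            raise KeyError(f"age {age} not on the curve grid")
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "sex": self.sex, "kind": self.kind,
             "hazard": self.values}
        )


def smooth_incidence(
    table: pd.DataFrame,
    sex: str,
    degree: int = 2,
    terminal_age: int = TERMINAL_AGE,
) -> HazardCurve:
    """Smooth a banded incidence table into a per-age hip-fracture hazard.

    Fits a Poisson GLM of band event counts on a degree-``degree``
    polynomial of band-midpoint age with log link and log person-years
    offset; evaluates at single years 40..90 and holds the age-90 value
    constant to the terminal age. Needs at least degree+2 bands with
    positive person-years; an all-zero count vector yields a zero curve
    with a warning.
    """
    sub = table[(table["sex"] == sex) & (table["py"] > 0)]
    if len(sub) < max(4, degree + 2):
        raise ValueError(
            f"need at least {max(4, degree + 2)} bands with person-years; "
            f"got {len(sub)} for sex={sex}"
        )
    ages_out = np.arange(40, terminal_age + 1)
    counts = sub["n"].to_numpy(dtype=float)
    if counts.sum() == 0:
        warnings.warn(f"all-zero counts for sex={sex}: returning zero hazard curve")
        return HazardCurve(sex, "hip", ages_out, np.zeros_like(ages_out, dtype=float))

    mid = np.array([band_midpoint(b) for b in sub["age_band"]])
    z = (mid - 65.0) / 10.0  # centered/scaled age for conditioning
    X = np.vander(z, degree + 1, increasing=True)
    model = sm.GLM(
        counts, X, family=sm.families.Poisson(), offset=np.log(sub["py"].to_numpy())
    )
    try:
        res = model.fit()
    except Exception as exc:  # noqa: BLE001 - report the data with the failure
        raise RuntimeError(
            f"incidence smoothing failed for sex={sex}: {exc}; "
            f"counts={counts.tolist()}, PY={sub['py'].tolist()}"
        ) from exc

    fit_ages = np.arange(40, SMOOTH_MAX_AGE + 1)
    zf = (fit_ages - 65.0) / 10.0
    h = np.exp(np.vander(zf, degree + 1, increasing=True) @ res.params)
    values = np.concatenate([h, np.full(terminal_age - SMOOTH_MAX_AGE, h[-1])])
    return HazardCurve(sex, "hip", ages_out, values)


def _expand_bands(ratios: pd.DataFrame, sex: str, ages: np.ndarray) -> np.ndarray:
    """Step-expand a sex's banded values onto a single-year grid; the last
    (or open) band extends to the end of the grid."""
    sub = ratios[ratios["sex"] == sex]
    if sub.empty:
        raise ValueError(f"ratio table has no rows for sex={sex}")
    out = np.full(len(ages), np.nan)
    top_band_value, top_band_lo = None, -1
    for _, row in sub.iterrows():
        lo, hi = band_bounds(str(row["age_band"]))
        if hi is None or lo > top_band_lo:
            top_band_value, top_band_lo = float(row["ratio"]), lo
        mask = (ages >= lo) & (ages < (hi if hi is not None else ages[-1] + 1))
        out[mask] = float(row["ratio"])
    out[ages >= top_band_lo] = top_band_value
    if np.isnan(out).any():
        missing = ages[np.isnan(out)]
        raise ValueError(f"ratio table does not cover ages {missing.min()}-{missing.max()}")
    return out


def mof_from_hip(hip: HazardCurve, ratios: pd.DataFrame) -> HazardCurve:
    """MOF hazard from the hip hazard and other-MOF:hip ratios.

    mof(age) = hip(age) * (1 + r(age, sex)): hip plus the ratio-implied
    clinical spine/forearm/humerus hazard. Overlap between fracture types
    within a person is not modeled — a documented simplification.
    """
    r = _expand_bands(ratios, hip.sex, hip.ages)
    if np.any(r < 0):
        raise ValueError("ratios must be nonnegative")
    return HazardCurve(hip.sex, "mof", hip.ages, hip.values * (1.0 + r))


def mortality_hazard(
    lt: pd.DataFrame, sex: str, terminal_age: int = TERMINAL_AGE
) -> HazardCurve:
    """Per-age death hazard from a life table.

    Accepts single-year rows (``age``) or abridged bands (``age_band``),
    with either annual death probabilities ``q`` (converted via
    m = -ln(1-q)) or central rates ``m`` (used directly). Abridged bands
    are constant within band; beyond the table, the hazard follows a
    log-linear (Gompertz) extrapolation through the last two bands'
    midpoints, up to the terminal age.
    """
    sub = lt[lt["sex"] == sex].copy()
    if sub.empty:
        raise ValueError(f"life table has no rows for sex={sex}")
    if "m" in sub.columns and sub["m"].notna().all():
        rates = sub["m"].to_numpy(dtype=float)
    elif "q" in sub.columns:
        q = sub["q"].to_numpy(dtype=float)
        if np.any(q >= 1.0):
            raise ValueError("q = 1 implies an infinite hazard")
        rates = -np.log1p(-q)
    else:
        raise ValueError("life table needs a 'q' or 'm' column")
    if np.any(rates < 0):
        raise ValueError("death rates must be nonnegative")

    ages_out = np.arange(40, terminal_age + 1)
    values = np.full(len(ages_out), np.nan)
    mids, vals = [], []
    if "age" in sub.columns and sub["age"].notna().all():
        for age, m in zip(sub["age"].to_numpy(dtype=int), rates):
            mids.append(float(age))
            vals.append(m)
            if 40 <= age <= terminal_age:
                values[age - 40] = m
    else:
        for band, m in zip(sub["age_band"], rates):
            lo, hi = band_bounds(str(band))
            hi = hi if hi is not None else lo + 5
            mids.append((lo + hi) / 2.0)
            vals.append(m)
            mask = (ages_out >= lo) & (ages_out < hi)
            values[mask] = m

    covered = ages_out[~np.isnan(values)]
    if covered.size == 0 or covered.min() > 40 or covered.max() < 85:
        raise ValueError("life table must cover at least ages 40-85")
    if np.isnan(values).any():
        # Gompertz tail through the last two distinct table points
        (m1, m2), (a1, a2) = vals[-2:], mids[-2:]
        if m1 <= 0 or m2 <= 0 or a2 == a1:
            raise ValueError("cannot extrapolate: need two positive trailing rates")
        slope = (np.log(m2) - np.log(m1)) / (a2 - a1)
        nan_ages = ages_out[np.isnan(values)]
        values[np.isnan(values)] = m2 * np.exp(slope * (nan_ages - a2))
    return HazardCurve(sex, "death", ages_out, values)
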