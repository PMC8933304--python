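"""File schemas and run configuration.

All tabular I/O is header-bearing delimited text (comma by default, tab
accepted on read). Schemas:

* line list: patient_id, admission_date (ISO 8601), birth_date or age,
  sex (male/female), nationality (national/expatriate), icd10
* population: year, sex, nationality, age_band, count
* life table: sex, age or age_band, q and/or m
* ratio table: sex, age_band, ratio
* hazard curves: age, sex, kind, hazard
* probabilities: age, sex, outcome, horizon, probability, percent

Writers prepend '#'-prefixed header lines echoing the run settings (config
hash, seed), so every output records the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .incidence import NATIONALITIES, SEXES, AdmissionRecord

logger = logging.getLogger(__name__)

_LINE_LIST_REQUIRED = ["patient_id", "admission_date", "sex", "nationality", "icd10"]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_line_list(path, issues: list[str] | None = None) -> list[AdmissionRecord]:
    """Parse an admission line list. Malformed rows are collected in
    ``issues`` (or logged) and skipped — counted, never silent."""
    df = _read_table(path)
    for col in _LINE_LIST_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"line list {path}: missing required column {col!r}")
    has_age = "age" in df.columns or "age_at_admission" in df.columns
    if not has_age and "birth_date" not in df.columns:
        raise ValueError(f"line list {path}: needs an 'age' or 'birth_date' column")
    age_col = "age" if "age" in df.columns else "age_at_admission"

    collected = issues if issues is not None else []
    records: list[AdmissionRecord] = []
    for i, row in df.iterrows():
        try:
            adm = dt.date.fromisoformat(str(row["admission_date"]))
            birth = (
                dt.date.fromisoformat(str(row["birth_date"]))
                if "birth_date" in df.columns and pd.notna(row.get("birth_date"))
                else None
            )
            age = (
                int(row[age_col])
                if has_age and pd.notna(row.get(age_col))
                else None
            )
            records.append(
                AdmissionRecord(
                    patient_id=str(row["patient_id"]),
                    admission_date=adm,
                    sex=str(row["sex"]),
                    nationality=str(row["nationality"]),
                    icd10=str(row["icd10"]),
                    age_at_admission=age,
                    birth_date=birth,
                )
            )
        except (ValueError, TypeError) as exc:
            collected.append(f"row {i}: {exc}")
    if collected and issues is None:
        logger.warning("line list %s: %d malformed row(s) skipped", path, len(collected))
    return records


def write_line_list(records, path, header_lines: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "admission_date": [r.admission_date.isoformat() for r in records],
            "age": [r.age() for r in records],
            "sex": [r.sex for r in records],
            "nationality": [r.nationality for r in records],
            "icd10": [r.icd10 for r in records],
        }
    )
    _write_csv(df, path, header_lines)


def read_population(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, path, ["year", "sex", "nationality", "age_band", "count"])
    bad_sex = set(df["sex"]) - set(SEXES)
    bad_nat = set(df["nationality"]) - set(NATIONALITIES)
    if bad_sex or bad_nat:
        raise ValueError(f"population {path}: unrecognized codes {bad_sex | bad_nat}")
    return df


def read_life_table(path) -> pd.DataFrame:
    df = _read_table(path)
    if "sex" not in df.columns or ("q" not in df.columns and "m" not in df.columns):
        raise ValueError(f"life table {path}: needs 'sex' and 'q' or 'm' columns")
    if "age" not in df.columns and "age_band" not in df.columns:
        raise ValueError(f"life table {path}: needs an 'age' or 'age_band' column")
    return df


def read_ratio_table(path) -> pd.DataFrame:
    df = _read_table(path)
    _require(df, path, ["sex", "age_band", "ratio"])
    return df


def _require(df: pd.DataFrame, path, cols) -> None:
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def _write_csv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


write_table = _write_csv


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; hashable for provenance."""

    line_list: str = ""
    population: str = ""
    life_table: str = ""
    ratio_table: str = ""
    output_dir: str = "output"
    years: tuple[int, ...] = (2017, 2018, 2019)
    dedup_window_days: int = 365
    model_scope: str = "national"  # stratum whose incidence enters the model
    smoothing_degree: int = 2
    terminal_age: int = 105
    horizon: int = 10
    curve_ages: tuple[int, ...] = tuple(range(50, 91, 5))
    lifetime_from_age: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("years", "curve_ages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def settings_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("years", "curve_ages"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.settings_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def header_lines(self) -> list[str]:
        return [f"config_hash={self.config_hash()}", f"seed={self.seed}"]
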