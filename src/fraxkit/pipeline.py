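"""End-to-end model construction: line list to fracture probabilities.

Stages, in order: case selection -> person-years -> incidence rates ->
age-standardized national/expatriate comparison -> incidence smoothing ->
MOF imputation -> mortality hazard -> 10-year and lifetime probabilities.
Each stage failure aborts the run naming the stage; outputs carry the
configuration hash, and a manifest records settings, versions, and
row-drop counts, so two runs with identical configurations produce
identical files.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, incidence, io
from .hazards import mof_from_hip, mortality_hazard, smooth_incidence
from .incidence import SEXES
from .probability import CompetingHazards, lifetime_probability, probability_curve


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(config: io.RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the written output paths."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()
    outputs: dict[str, Path] = {}

    issues: list[str] = []
    records = _stage("read_line_list", io.read_line_list, config.line_list, issues)
    population = _stage("read_population", io.read_population, config.population)
    life = _stage("read_life_table", io.read_life_table, config.life_table)
    ratios = _stage("read_ratio_table", io.read_ratio_table, config.ratio_table)

    cases = _stage(
        "select_index_admissions",
        incidence.select_index_admissions,
        records,
        window_days=config.dedup_window_days,
        study_years=config.years,
        issues=issues,
    )

    # incidence tables for the whole population and the model scope
    tables = {}
    for scope in ("all", config.model_scope):
        py = _stage("person_years", incidence.person_years, population, config.years, scope)
        scoped = cases if scope == "all" else [c for c in cases if c.nationality == scope]
        tables[scope] = _stage("estimate_rates", incidence.estimate_rates, scoped, py)
    inc_all, inc_model = tables["all"], tables[config.model_scope]

    report = pd.concat(
        [
            incidence.format_incidence(t).assign(scope=s)
            for s, t in (("all", inc_all), (config.model_scope, inc_model))
        ],
        ignore_index=True,
    )
    outputs["incidence"] = out_dir / "incidence_table.csv"
    io.write_table(report, outputs["incidence"], header)

    # standardized national vs expatriate comparison (standard: the
    # model scope's own population age distribution)
    std_rows = []
    standard = population[population["nationality"] == config.model_scope]
    for sex in SEXES:
        per_nat = {}
        for nat in ("national", "expatriate"):
            py_n = incidence.person_years(population, config.years, nat)
            sub = [c for c in cases if c.nationality == nat and c.sex == sex]
            tab = incidence.estimate_rates(sub, py_n)
            tab = tab[tab["sex"] == sex]
            std = _stage(
                "age_standardize",
                incidence.age_standardize,
                tab,
                standard[standard["sex"] == sex],
            )
            per_nat[nat] = std
            std_rows.append(
                {
                    "sex": sex,
                    "nationality": nat,
                    "rate": std.rate,
                    "ci_low": std.ci_low,
                    "ci_high": std.ci_high,
                    "se": std.se,
                }
            )
        try:
            p = incidence.compare_standardized(per_nat["national"], per_nat["expatriate"])
        except ValueError:
            p = float("nan")
        for row in std_rows[-2:]:
            row["p_vs_other"] = p
    outputs["standardized"] = out_dir / "standardized_comparison.csv"
    io.write_table(pd.DataFrame(std_rows), outputs["standardized"], header)

    # hazards and probabilities from the model scope's incidence
    curve_frames, prob_frames, lifetime_rows = [], [], []
    for sex in SEXES:
        hip = _stage(
            "smooth_incidence",
            smooth_incidence,
            inc_model,
            sex,
            degree=config.smoothing_degree,
            terminal_age=config.terminal_age,
        )
        mof = _stage("mof_from_hip", mof_from_hip, hip, ratios)
        death = _stage(
            "mortality_hazard", mortality_hazard, life, sex, config.terminal_age
        )
        for curve in (hip, mof, death):
            curve_frames.append(curve.to_frame())
        for outcome, curve in (("hip", hip), ("mof", mof)):
            ch = CompetingHazards.from_curves(curve, death)
            tab = _stage(
                "probability_curve",
                probability_curve,
                ch,
                ages=config.curve_ages,
                horizon=config.horizon,
            )
            prob_frames.append(tab.assign(sex=sex, outcome=outcome))
            lt = lifetime_probability(ch, config.lifetime_from_age, config.terminal_age)
            lifetime_rows.append(
                {
                    "sex": sex,
                    "outcome": outcome,
                    "from_age": config.lifetime_from_age,
                    "probability": lt.probability,
                    "percent": round(lt.percent, 1),
                }
            )

    outputs["hazards"] = out_dir / "hazard_curves.csv"
    io.write_table(pd.concat(curve_frames, ignore_index=True), outputs["hazards"], header)
    outputs["probabilities"] = out_dir / "probability_curves.csv"
    io.write_table(pd.concat(prob_frames, ignore_index=True), outputs["probabilities"], header)
    outputs["lifetime"] = out_dir / "lifetime_probabilities.csv"
    io.write_table(pd.DataFrame(lifetime_rows), outputs["lifetime"], header)

    manifest = {
        "config_hash": config.config_hash(),
        "settings": config.settings_dict(),
        "versions": {
            "fraxkit": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_records": len(records),
        "n_cases": len(cases),
        "n_dropped": len(issues),
        "issues": issues,
    }
    outputs["manifest"] = out_dir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outputs
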