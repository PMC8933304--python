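"""Case selection, person-years, exact Poisson rates, direct
standardization, and the national/expatriate comparison test."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fraxkit as fx
from fraxkit.bands import AGE_BANDS
from fraxkit.incidence import PER, StandardizedRate, case_share, poisson_exact_ci


def _rec(pid="P1", date="2018-06-01", sex="female", nat="national",
         icd="S72.0", age=75):
    return fx.AdmissionRecord(
        patient_id=pid, admission_date=dt.date.fromisoformat(date),
        sex=sex, nationality=nat, icd10=icd, age_at_admission=age,
    )


def _flat_py(py=10_000.0):
    rows = [{"sex": s, "age_band": b, "py": py}
            for s in ("male", "female") for b in AGE_BANDS]
    return pd.DataFrame(rows)


class TestSelectIndexAdmissions:
    def test_readmission_within_window_is_one_case(self):
        recs = [_rec(date="2018-06-01", icd="S72.0"),
                _rec(date="2018-07-01", icd="S72.1")]
        assert len(fx.select_index_admissions(recs)) == 1

    def test_admissions_outside_window_are_two_cases(self):
        recs = [_rec(date="2017-06-01"), _rec(date="2018-07-06")]  # +400 days
        assert len(fx.select_index_admissions(recs)) == 2

    def test_age_floor(self):
        assert fx.select_index_admissions([_rec(age=39)]) == []
        assert len(fx.select_index_admissions([_rec(age=40)])) == 1

    @pytest.mark.parametrize("icd,kept", [
        ("S72.0", True), ("S72.1", True), ("S72.2", True), ("S72.01", True),
        ("S720", True), ("S72.3", False), ("S82.1", False), ("S52.5", False),
    ])
    def test_hip_code_filter_with_subdigits(self, icd, kept):
        assert len(fx.select_index_admissions([_rec(icd=icd)])) == int(kept)

    def test_study_window_filter(self):
        recs = [_rec(date="2016-12-31"), _rec(pid="P2", date="2017-01-01")]
        cases = fx.select_index_admissions(recs, study_years=(2017, 2018, 2019))
        assert [c.patient_id for c in cases] == ["P2"]

    def test_earliest_admission_defines_age_and_year(self):
        recs = [_rec(date="2018-12-20", age=79),
                _rec(date="2019-01-10", age=80)]
        (case,) = fx.select_index_admissions(recs)
        assert (case.year, case.age_band) == (2018, "75-79")

    def test_unusable_records_counted_not_silently_dropped(self):
        bad = fx.AdmissionRecord(
            patient_id="PX", admission_date=dt.date(2018, 1, 1),
            sex="female", nationality="national", icd10="S72.0",
        )  # no age and no birth date
        issues = []
        cases = fx.select_index_admissions([bad, _rec()], issues=issues)
        assert len(cases) == 1 and len(issues) == 1

    def test_birth_date_gives_completed_age(self):
        rec = fx.AdmissionRecord(
            patient_id="P1", admission_date=dt.date(2018, 6, 1),
            sex="male", nationality="national", icd10="S72.0",
            birth_date=dt.date(1978, 6, 2),
        )  # one day short of the 40th birthday
        assert fx.select_index_admissions([rec]) == []

    def test_dedup_idempotence(self, registry):
        once = fx.select_index_admissions(registry["records"], study_years=(2017, 2018, 2019))
        twice = fx.select_index_admissions(once, study_years=(2017, 2018, 2019))
        assert [(c.patient_id, c.admission_date) for c in twice] == [
            (c.patient_id, c.admission_date) for c in once
        ]


class TestPersonYears:
    def test_sum_over_years(self):
        cfg = fx.SyntheticConfig(
            pop_size={n: {b: 10_000 for b in AGE_BANDS}
                      for n in ("national", "expatriate")}
        )
        pop = fx.generate_population(cfg)
        py = fx.person_years(pop, cfg.years, "national")
        assert (py["py"] == 30_000).all()
        one = fx.person_years(pop, [2017], "national")
        assert (one["py"] == 10_000).all()

    def test_geometric_growth_sum(self):
        cfg = fx.SyntheticConfig(
            growth=1.02,
            pop_size={n: {b: 10_000 for b in AGE_BANDS}
                      for n in ("national", "expatriate")},
        )
        pop = fx.generate_population(cfg)
        py = fx.person_years(pop, cfg.years, "expatriate")
        assert py["py"].iloc[0] == pytest.approx(10_000 + 10_200 + 10_404)

    def test_missing_stratum_names_it(self):
        cfg = fx.SyntheticConfig()
        pop = fx.generate_population(cfg)
        with pytest.raises(ValueError, match="year=2020"):
            fx.person_years(pop, [2020], "national")


class TestEstimateRates:
    def test_registry_table_worked_example(self):
        """7 events over 16,627 person-years: 42.1 per 100,000, exact
        Poisson interval 16.9-86.7 at one-decimal reporting."""
        cases = [_rec(pid=f"P{i}", sex="female", age=57) for i in range(7)]
        py = _flat_py()
        py.loc[(py["sex"] == "female") & (py["age_band"] == "55-59"), "py"] = 16_627
        cases = fx.select_index_admissions(cases)
        tab = fx.estimate_rates(cases, py)
        row = tab.query("sex == 'female' and age_band == '55-59'").iloc[0]
        assert (round(row["rate"], 1), round(row["ci_low"], 1),
                round(row["ci_high"], 1)) == (42.1, 16.9, 86.7)

    def test_zero_count_interval(self):
        lo, hi = poisson_exact_ci(0, 10_000)
        assert lo == 0.0
        assert hi == pytest.approx(36.9, abs=0.05)

    @pytest.mark.parametrize("n", [1, 2, 10, 100])
    def test_ordering_invariant(self, n):
        lo, hi = poisson_exact_ci(n, 5_000)
        rate = n / 5_000 * PER
        assert lo < rate < hi

    def test_rate_identity_and_zero_rule(self):
        tab = fx.estimate_rates([], _flat_py())
        assert (tab["n"] == 0).all() and (tab["rate"] == 0).all()
        assert (tab["ci_low"] == 0).all() and (tab["ci_high"] > 0).all()

    def test_nonpositive_py_rejected(self):
        py = _flat_py()
        py.loc[0, "py"] = 0.0
        with pytest.raises(ValueError, match="person-years"):
            fx.estimate_rates([], py)

    def test_exact_interval_never_undercovers(self):
        """Coverage of the exact interval at small means stays at or above
        the nominal level (the interval is conservative by construction);
        10,000 Poisson draws at each mean."""
        rng = np.random.default_rng(42)
        for lam in (1, 3, 7, 20):
            draws = rng.poisson(lam, size=10_000)
            lo, hi = poisson_exact_ci(draws, 1.0)
            lam_scaled = lam * PER
            coverage = np.mean((lo <= lam_scaled) & (lam_scaled <= hi))
            assert coverage >= 0.945, lam


class TestAgeStandardize:
    def _table(self, sex="female", rates=None, py=30_000.0):
        rates = rates if rates is not None else [10.0] * len(AGE_BANDS)
        n = [r * py / PER for r in rates]
        return pd.DataFrame(
            {"sex": sex, "age_band": AGE_BANDS, "n": n, "py": py,
             "rate": rates, "ci_low": 0.0, "ci_high": 0.0}
        )

    def test_self_standardization_is_crude_rate(self):
        tab = self._table(rates=[5, 8, 12, 20, 35, 60, 120, 250, 500])
        weights = {b: 1.0 / len(AGE_BANDS) for b in AGE_BANDS}  # equal PY
        std = fx.age_standardize(tab, weights)
        crude = tab["n"].sum() / tab["py"].sum() * PER
        assert std.rate == pytest.approx(crude)

    def test_weighted_mean_example(self):
        tab = self._table(rates=[10, 30] + [0] * 7)
        w = {b: 0.0 for b in AGE_BANDS}
        w["40-44"], w["45-49"] = 0.25, 0.75
        assert fx.age_standardize(tab, w).rate == pytest.approx(25.0)

    def test_band_mismatch_is_hard_error(self):
        tab = self._table()
        with pytest.raises(ValueError, match="missing bands"):
            fx.age_standardize(tab, {"40-44": 1.0})

    def test_standardization_linearity(self):
        base = [5, 8, 12, 20, 35, 60, 120, 250, 500]
        w = {b: p for b, p in zip(AGE_BANDS, np.linspace(2, 1, 9) / np.linspace(2, 1, 9).sum())}
        r1 = fx.age_standardize(self._table(rates=base), w).rate
        r3 = fx.age_standardize(self._table(rates=[3 * r for r in base]), w).rate
        assert r3 == pytest.approx(3 * r1)

    def test_gamma_interval_coverage_at_sparse_counts(self):
        """Fay-Feuer interval holds >=93% coverage over 2,000 simulated
        registries at registry-like sparse band counts."""
        rng = np.random.default_rng(7)
        true_rates = np.array([9, 0.1, 20, 42, 50, 178, 176, 512, 886], dtype=float)
        py = np.full(9, 12_000.0)
        w = np.array([0.19, 0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.05, 0.04])
        w = w / w.sum()
        true_std = float((w * true_rates).sum())
        hits = 0
        reps = 2_000
        draws = rng.poisson(true_rates / PER * py, size=(reps, 9))
        for k in range(reps):
            tab = pd.DataFrame(
                {"sex": "female", "age_band": AGE_BANDS, "n": draws[k],
                 "py": py, "rate": draws[k] / py * PER,
                 "ci_low": 0.0, "ci_high": 0.0}
            )
            std = fx.age_standardize(tab, dict(zip(AGE_BANDS, w)))
            hits += std.ci_low <= true_std <= std.ci_high
        assert hits / reps >= 0.93


class TestCompareStandardized:
    def test_identical_rates_give_p_one(self):
        a = StandardizedRate(rate=80.0, ci_low=0, ci_high=0, se=9.0)
        assert fx.compare_standardized(a, a) == pytest.approx(1.0)

    def test_log_scale_z_worked_example(self):
        a = StandardizedRate(rate=74.0, ci_low=0, ci_high=0, se=8.0)
        b = StandardizedRate(rate=107.0, ci_low=0, ci_high=0, se=10.0)
        assert fx.compare_standardized(a, b) == pytest.approx(0.00987, abs=2e-4)

    def test_zero_rate_directs_to_exact_alternative(self):
        a = StandardizedRate(rate=0.0, ci_low=0, ci_high=0, se=0.0)
        b = StandardizedRate(rate=50.0, ci_low=0, ci_high=0, se=5.0)
        with pytest.raises(ValueError, match="exact"):
            fx.compare_standardized(a, b)

    def test_agrees_with_parametric_bootstrap(self):
        """z-test p within 0.005 of a 100,000-replicate parametric
        bootstrap of the log-rate difference under the null."""
        a = StandardizedRate(rate=74.0, ci_low=0, ci_high=0, se=8.0)
        b = StandardizedRate(rate=107.0, ci_low=0, ci_high=0, se=10.0)
        p_test = fx.compare_standardized(a, b)
        rng = np.random.default_rng(123)
        s_a, s_b = a.se / a.rate, b.se / b.rate
        obs = abs(np.log(b.rate) - np.log(a.rate))
        null_diff = rng.normal(0, s_a, 100_000) - rng.normal(0, s_b, 100_000)
        p_boot = float(np.mean(np.abs(null_diff) >= obs))
        assert abs(p_test - p_boot) <= 0.005


class TestCrudeSexRatioAndShares:
    def test_equal_rates_give_unity(self):
        cases = [_rec(pid=f"P{i}", sex=s, age=70)
                 for i, s in enumerate(["male"] * 5 + ["female"] * 5)]
        cases = fx.select_index_admissions(cases)
        assert fx.crude_sex_ratio(cases, _flat_py()) == pytest.approx(1.0)

    def test_printed_ratio_form(self):
        # female 100 per 1e5 vs male 80 per 1e5 -> 1.25
        cases = [_rec(pid=f"F{i}", sex="female", age=70) for i in range(100)]
        cases += [_rec(pid=f"M{i}", sex="male", age=70) for i in range(80)]
        cases = fx.select_index_admissions(cases)
        assert fx.crude_sex_ratio(cases, _flat_py()) == pytest.approx(1.25)

    def test_case_share_percent(self):
        assert round(case_share(151, 492)) == 31

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_share_bounds(self, a, b):
        n_total = a + b
        assert 0 < case_share(a, n_total) < 100
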