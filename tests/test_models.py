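"""Mixed-model group contrasts, association slopes, and reporting."""

import numpy as np
import pandas as pd
import pytest

from corticomap.models import (
    CoefficientEstimate,
    ModelFamily,
    default_families,
    estimates_to_frame,
    fit_association_model,
    fit_group_model,
    render_tables,
    stack_long,
    stratified_association,
)
from tests.conftest import simulate_long_cohort


def wide_cohort(n_per_group, tests, rng, missing=0):
    rows = []
    for label in ("LBP", "control"):
        for i in range(n_per_group):
            row = {"subject": f"{label}{i:02d}", "group": label}
            row.update({t: rng.normal() for t in tests})
            rows.append(row)
    df = pd.DataFrame(rows)
    if missing:
        flat = [(r, t) for r in df.index for t in tests]
        for r, t in [flat[k] for k in rng.choice(len(flat), missing, replace=False)]:
            df.loc[r, t] = np.nan
    return df


class TestStackLong:
    def test_50_subjects_4_muscles_gives_200_rows(self):
        rng = np.random.default_rng(0)
        fam = default_families()["area"]
        df = wide_cohort(25, fam.tests, rng)
        assert len(stack_long(df, fam)) == 200

    def test_13_missing_gives_187_rows(self):
        rng = np.random.default_rng(1)
        fam = default_families()["area"]
        df = wide_cohort(25, fam.tests, rng, missing=13)
        assert len(stack_long(df, fam)) == 187

    def test_single_test_family(self):
        rng = np.random.default_rng(2)
        fam = ModelFamily("one", ("temporal_summation",))
        df = wide_cohort(5, fam.tests, rng)
        long = stack_long(df, fam)
        assert set(long["test"]) == {"temporal_summation"} and len(long) == 10

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            stack_long(pd.DataFrame({"subject": ["a"]}), ModelFamily("f", ("absent",)))

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            ModelFamily("f", ())


class TestFitGroupModel:
    def test_noiseless_two_tests_equal_mean_differences(self):
        rows = []
        for label, shift in (("LBP", 1.0), ("control", 0.0)):
            for i in range(4):
                rows.append({"subject": f"{label}{i}", "group": label, "test": "a",
                             "value": 2.0 + 3.0 * shift + 0.1 * i})
                rows.append({"subject": f"{label}{i}", "group": label, "test": "b",
                             "value": -1.0 - 2.0 * shift + 0.1 * i})
        ests = {e.test: e for e in fit_group_model(pd.DataFrame(rows))}
        assert ests["a"].beta == pytest.approx(3.0, abs=1e-6)
        assert ests["b"].beta == pytest.approx(-2.0, abs=1e-6)

    def test_planted_effect_recovered_within_ci(self):
        rng = np.random.default_rng(12)
        effects = {"t1": 0.0, "t2": 3.0}
        long = simulate_long_cohort(25, effects, rng, subject_sd=1.0, residual_sd=0.5)
        ests = {e.test: e for e in fit_group_model(long)}
        assert ests["t2"].beta == pytest.approx(3.0, abs=0.6)
        assert ests["t2"].ci_low <= 3.0 <= ests["t2"].ci_high
        assert ests["t2"].p < 0.001

    def test_identical_groups_degenerate_flagged(self):
        rows = [
            {"subject": f"{g}{i}", "group": g, "test": t, "value": 5.0}
            for g in ("LBP", "control") for i in range(3) for t in ("a", "b")
        ]
        for e in fit_group_model(pd.DataFrame(rows)):
            assert e.beta == 0.0 and e.se == 0.0 and "singular_fit" in e.flags

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        long = simulate_long_cohort(10, {"t1": 1.0, "t2": -1.0}, rng)
        a = fit_group_model(long)
        b = fit_group_model(long.sample(frac=1.0, random_state=0).reset_index(drop=True))
        for ea, eb in zip(sorted(a, key=lambda e: e.test), sorted(b, key=lambda e: e.test)):
            assert ea.beta == pytest.approx(eb.beta, abs=1e-6)
            assert ea.se == pytest.approx(eb.se, rel=1e-4)

    def test_too_few_subjects_rejected(self):
        long = pd.DataFrame(
            {"subject": ["a", "b"], "group": ["LBP", "LBP"], "test": ["t", "t"], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            fit_group_model(long)

    def test_wald_ci_uses_1_96_se(self):
        rng = np.random.default_rng(4)
        long = simulate_long_cohort(12, {"t1": 0.5, "t2": 0.0}, rng)
        for e in fit_group_model(long):
            assert e.ci_low == pytest.approx(e.beta - 1.96 * e.se, abs=1e-9)
            assert e.ci_high == pytest.approx(e.beta + 1.96 * e.se, abs=1e-9)


class TestAssociationModels:
    @staticmethod
    def _assoc_long(rng, slope_by_group, n=25, tests=("m1", "m2"), residual=0.5):
        rows = []
        for label, slope in slope_by_group.items():
            for i in range(n):
                sid = f"{label}{i:02d}"
                pred = rng.uniform(0.0, 10.0)
                u = rng.normal(0.0, 1.0)
                for t in tests:
                    rows.append({"subject": sid, "group": label, "test": t, "predictor": pred,
                                 "value": slope * pred + u + rng.normal(0.0, residual)})
        return pd.DataFrame(rows)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(21)
        long = self._assoc_long(rng, {"LBP": 0.8, "control": 0.8})
        for e in fit_association_model(long):
            assert e.ci_low <= 0.8 <= e.ci_high
            assert e.beta == pytest.approx(0.8, abs=0.25)

    def test_null_predictor_gives_null_slopes(self):
        rng = np.random.default_rng(22)
        long = self._assoc_long(rng, {"LBP": 0.0, "control": 0.0})
        for e in fit_association_model(long):
            assert abs(e.beta) < 0.2

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(23)
        long = self._assoc_long(rng, {"LBP": 0.5})
        long["predictor"] = 4.0
        with pytest.raises(ValueError, match="variance"):
            fit_association_model(long)

    def test_planted_heterogeneity_found_by_stratification(self):
        rng = np.random.default_rng(24)
        long = self._assoc_long(rng, {"LBP": 1.0, "control": 0.0}, residual=0.4)
        pooled = fit_association_model(long)
        assert any(e.p < 0.05 for e in pooled)  # gate passes
        in_lbp = stratified_association(long, "LBP")
        in_ctrl = stratified_association(long, "control")
        assert all(e.p < 0.01 for e in in_lbp)
        assert all(abs(e.beta) < 0.2 for e in in_ctrl)

    def test_homogeneous_slope_recovered_in_both_groups(self):
        rng = np.random.default_rng(25)
        long = self._assoc_long(rng, {"LBP": 0.6, "control": 0.6}, residual=0.4)
        for grp in ("LBP", "control"):
            for e in stratified_association(long, grp):
                assert e.ci_low <= 0.6 <= e.ci_high

    def test_small_subgroup_rejected(self):
        rng = np.random.default_rng(26)
        long = self._assoc_long(rng, {"LBP": 0.5, "control": 0.5}, n=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            stratified_association(long, "LBP")


class TestReporting:
    def _est(self, test, p, beta=1.0):
        return CoefficientEstimate(test, beta, 0.5, beta - 0.98, beta + 0.98, p)

    def test_significance_marker_threshold(self):
        text = render_tables({"fam": [self._est("a", 0.049), self._est("b", 0.051)]})
        lines = {ln.split()[0]: ln for ln in text.splitlines() if ln.startswith(("a", "b"))}
        assert lines["a"].rstrip().endswith("*")
        assert not lines["b"].rstrip().endswith("*")

    def test_two_point_coefficients_scaled_by_5(self):
        text = render_tables(
            {"fam": [self._est("cog_z:longissimus_L5", 0.02, beta=0.425)]},
            predictor="two_point",
        )
        assert "2.125" in text  # 0.425 x 5

    def test_empty_and_single_row_tables(self):
        assert render_tables({}) .startswith("Group differences")
        df = estimates_to_frame({"fam": [self._est("a", 0.5)]})
        assert len(df) == 1 and set(df["family"]) == {"fam"}
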