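"""Statistics tests: fits, model comparison, ANOVA, binning, coupling, culture."""

import numpy as np
import pandas as pd
import pytest

from zonequant import lamstats as ls
from zonequant import synthcortex as sc

from conftest import make_positive_cells


def normal_equations_poly(x, y, degree):
    """Closed-form (X'X)^-1 X'y oracle."""
    X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def simulate_cohort(condition, cells_per_case, seed, **overrides):
    g = sc.make_geometry(1000, 2400, 0, 0.5)
    cfg = sc.GeneratorConfig.for_condition(
        condition, cells_per_case=cells_per_case, min_spacing=0.0, **overrides
    )
    return sc.sample_cells(g, cfg, seed=seed)


class TestFits:
    def test_constant_response_has_zero_slope_and_r2(self):
        fit = ls.fit_linear([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_exact_line_recovered(self):
        x = np.arange(1, 7)
        fit = ls.fit_linear(x, 2 * x + 1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients == pytest.approx((1.0, 2.0))

    def test_linear_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 25)
        y = 3 - 0.5 * x + rng.normal(0, 1, 25)
        fit = ls.fit_linear(x, y)
        assert np.allclose(fit.coefficients, normal_equations_poly(x, y, 1), atol=1e-10)

    def test_quadratic_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 6, 30)
        y = 1 + 2 * x - 0.3 * x**2 + rng.normal(0, 0.5, 30)
        fit = ls.fit_quadratic(x, y)
        assert np.allclose(fit.coefficients, normal_equations_poly(x, y, 2), atol=1e-9)

    def test_exact_parabola_vertex(self):
        x = np.arange(1, 7, dtype=float)
        y = -((x - 4.5) ** 2) + 3
        fit = ls.fit_quadratic(x, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.vertex == pytest.approx(4.5)

    @pytest.mark.parametrize("printed_r2,n,expected", [(0.155, 18, 0.043), (0.71, 24, 0.68)])
    def test_adjusted_r2_matches_reported_values(self, printed_r2, n, expected):
        assert ls.adjusted_r2(printed_r2, n, 2) == pytest.approx(expected, abs=0.005)

    def test_adjusted_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(0, 6, 12)
            y = rng.normal(0, 1, 12)
            quad = ls.fit_quadratic(x, y)
            lin = ls.fit_linear(x, y)
            assert quad.adjusted_r2 <= quad.r2 + 1e-12
            assert lin.adjusted_r2 <= lin.r2 + 1e-12
            assert quad.r2 >= lin.r2 - 1e-12  # nesting

    def test_insufficient_data_rejected(self):
        with pytest.raises(ls.InsufficientDataError):
            ls.fit_linear([1, 2], [1, 2])
        with pytest.raises(ls.InsufficientDataError):
            ls.fit_quadratic([1, 2, 3], [1, 2, 3])


class TestCompareModels:
    def test_parabola_prefers_quadratic_with_large_f(self):
        x = np.tile(np.arange(1, 7, dtype=float), 3)
        y = -((x - 4.5) ** 2) + 3 + np.random.default_rng(3).normal(0, 0.05, len(x))
        cmp_ = ls.compare_models(ls.fit_linear(x, y), ls.fit_quadratic(x, y))
        assert cmp_.preferred == "quadratic"
        assert cmp_.f_stat > 50

    def test_minimal_n_has_one_residual_df(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.2, 2.9, 4.4])
        cmp_ = ls.compare_models(ls.fit_linear(x, y), ls.fit_quadratic(x, y))
        assert cmp_.df == (1, 1)
        assert np.isfinite(cmp_.f_stat)

    def test_mismatched_n_rejected(self):
        a = ls.fit_linear([1, 2, 3, 4], [1, 2, 3, 4])
        b = ls.fit_quadratic([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        with pytest.raises(ls.AnalysisError):
            ls.compare_models(a, b)

    def test_partial_f_type_one_error_calibrated(self):
        # linear truth: the quadratic term should be rejected ~5% of the time
        rng = np.random.default_rng(4)
        x = np.tile(np.arange(1, 7, dtype=float), 3)
        hits = 0
        nsim = 300
        for _ in range(nsim):
            y = 0.5 + 0.2 * x + rng.normal(0, 1, len(x))
            cmp_ = ls.compare_models(ls.fit_linear(x, y), ls.fit_quadratic(x, y))
            hits += cmp_.p_value < 0.05
        assert hits / nsim == pytest.approx(0.05, abs=0.03)


class TestZoneSummary:
    @pytest.fixture()
    def toy_cells(self):
        rng = np.random.default_rng(5)
        n = 2400
        return pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "case_id": "UC1",
                "condition": "UC",
                "zone": np.repeat(np.arange(1, 7), n // 6),
                "damage_positive": rng.random(n) < 0.05,
            }
        )

    def test_counts_fractions_and_conservation(self, toy_cells):
        areas = np.full(6, 0.1)
        out = ls.zone_summary(toy_cells, areas)
        assert len(out) == 6
        assert out["n_total"].sum() == len(toy_cells)
        assert np.allclose(out["fraction"], out["n_positive"] / out["n_total"])
        assert np.allclose(out["density_per_mm2"], out["n_positive"] / 0.1)

    def test_all_positive_saturates_fraction(self, toy_cells):
        toy_cells["damage_positive"] = True
        out = ls.zone_summary(toy_cells, np.full(6, 0.1))
        assert (out["fraction"] == 1.0).all()

    def test_unassigned_cells_excluded(self, toy_cells):
        toy_cells.loc[:99, "zone"] = 0
        out = ls.zone_summary(toy_cells, np.full(6, 0.1))
        assert out["n_total"].sum() == len(toy_cells) - 100

    def test_empty_zone_yields_missing_fraction(self, toy_cells):
        toy = toy_cells[toy_cells["zone"] != 3]
        out = ls.zone_summary(toy, np.full(6, 0.1))
        row = out[out["zone"] == 3].iloc[0]
        assert row["n_total"] == 0 and np.isnan(row["fraction"])


class TestTwoWayAnova:
    @staticmethod
    def design():
        cases = [("AD", f"AD{i}") for i in range(4)] + [("UC", f"UC{i}") for i in range(3)]
        return pd.DataFrame(
            [(cid, cond, z) for cond, cid in cases for z in range(1, 7)],
            columns=["case_id", "condition", "zone"],
        )

    def test_constant_response_reports_missing_f(self):
        df = self.design()
        df["y"] = 1.0
        tab = ls.two_way_anova(df, "y")
        assert np.allclose(tab["sum_sq"].fillna(0), 0)
        assert tab["F"].isna().all()

    def test_single_case_condition_rejected(self):
        df = self.design()
        df = df[df["case_id"] != "UC1"]
        df = df[df["case_id"] != "UC2"]
        df["y"] = np.arange(len(df), dtype=float)
        with pytest.raises(ls.AnalysisError):
            ls.two_way_anova(df, "y")

    def test_condition_shift_detected_with_high_power(self):
        rng = np.random.default_rng(6)
        base = self.design()
        hits = 0
        nsim = 500
        for _ in range(nsim):
            df = base.copy()
            case_eff = {c: rng.normal(0, 1.0) for c in df["case_id"].unique()}
            # zone-level responses are means over many cells, so within-case
            # noise is small relative to the between-case effect
            df["y"] = (
                df["case_id"].map(case_eff)
                + np.where(df["condition"] == "AD", 2.0, 0.0)  # 2 between-case sd
                + rng.normal(0, 0.1, len(df))
            )
            tab = ls.two_way_anova(df, "y")
            hits += tab.loc["C(condition)", "PR(>F)"] < 0.01
        assert hits / nsim >= 0.90


class TestUnpairedT:
    def test_identical_groups_give_null_result(self):
        t, p = ls.unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_value(self):
        t, _ = ls.unpaired_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t1, p1 = ls.unpaired_t(a, b)
        t2, p2 = ls.unpaired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ls.AnalysisError):
            ls.unpaired_t([1.0], [2.0, 3.0])


class TestSizeRankedProfile:
    def test_remainder_rule(self):
        rng = np.random.default_rng(8)
        cells = pd.DataFrame(
            {"cell_id": np.arange(250), "nuclear_area": rng.uniform(10, 100, 250),
             "i53bp1": rng.normal(50, 5, 250)}
        )
        prof = ls.size_ranked_profile(cells, bin_size=100)
        assert len(prof.bins) == 2
        assert prof.n_dropped == 50
        assert prof.fit is None  # two points carry no slope test

    def test_too_few_bins_rejected(self):
        cells = pd.DataFrame(
            {"cell_id": np.arange(150), "nuclear_area": np.arange(150.0), "i53bp1": 1.0}
        )
        with pytest.raises(ls.InsufficientDataError):
            ls.size_ranked_profile(cells, bin_size=100)

    def test_bins_ordered_by_area(self):
        rng = np.random.default_rng(9)
        cells = pd.DataFrame(
            {"cell_id": np.arange(1000), "nuclear_area": rng.uniform(10, 100, 1000),
             "i53bp1": rng.normal(50, 5, 1000)}
        )
        prof = ls.size_ranked_profile(cells, bin_size=100)
        assert prof.bins["mean_area"].is_monotonic_increasing
        assert (prof.bins["n"] == 100).all()

    def test_size_slope_detected_at_study_scale(self):
        # 12,000 cells with the default κ: slope positive and significant in
        # >= 90% of 200 simulated fields
        cfg = sc.GeneratorConfig.for_condition("AD", n_cases=1, cells_per_case=12000, min_spacing=0.0)
        g = sc.make_geometry(1000, 2400, 0, 0.5)
        hits = 0
        nsim = 200
        for s in range(nsim):
            cells = sc.sample_cells(g, cfg, seed=1000 + s)
            out = sc.assign_intensities(cells, cfg, seed=1001 + s)
            prof = ls.size_ranked_profile(out, bin_size=100)
            hits += (prof.fit.coefficients[1] > 0) and (prof.fit.slope_p < 0.05)
        assert hits / nsim >= 0.90

    def test_zero_size_slope_null_is_calibrated(self):
        rng = np.random.default_rng(11)
        cfg = sc.GeneratorConfig.for_condition("AD", size_slope=0.0)
        hits = 0
        nsim = 200
        for s in range(nsim):
            cells = make_positive_cells(3000, rng)
            cells["damage_positive"] = rng.random(3000) < 0.2
            out = sc.assign_intensities(cells, cfg, seed=2000 + s)
            prof = ls.size_ranked_profile(out, bin_size=100)
            hits += prof.fit.slope_p < 0.05
        assert hits / nsim == pytest.approx(0.05, abs=0.04)


class TestCouplingRegression:
    @staticmethod
    def cohort(condition, seed, n_cases=4, n_pos=2000):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(n_cases):
            cells = make_positive_cells(n_pos, rng)
            cells["case_id"] = f"{condition}{i + 1}"
            cells["cell_id"] = cells["cell_id"] + i * n_pos
            frames.append(cells)
        cohort = pd.concat(frames, ignore_index=True)
        cfg = sc.GeneratorConfig.for_condition(condition)
        return sc.assign_intensities(cohort, cfg, seed=seed + 1)

    def test_zero_noise_gives_perfect_r2(self):
        rng = np.random.default_rng(12)
        cells = make_positive_cells(500, rng)
        cfg = sc.GeneratorConfig.for_condition("AD", coupling_noise_ratio=0.0, p16_depth_slope=0.0)
        out = sc.assign_intensities(cells, cfg, seed=3)
        res = ls.coupling_regression(out, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_shortfall_case_uses_all_cells(self, caplog):
        rng = np.random.default_rng(13)
        cells = make_positive_cells(60, rng)
        cfg = sc.GeneratorConfig.for_condition("AD")
        out = sc.assign_intensities(cells, cfg, seed=4)
        with caplog.at_level("WARNING"):
            res = ls.coupling_regression(out, per_case_n=100, seed=0)
        assert res.n == 60
        assert "only 60" in caplog.text

    def test_empty_case_raises_naming_it(self):
        cells = pd.DataFrame(
            {"cell_id": [1], "case_id": ["AD1"], "i53bp1": [1.0], "p16_nuclear": [1.0],
             "damage_positive": [False]}
        )
        with pytest.raises(ls.AnalysisError, match="AD1"):
            ls.coupling_regression(cells, seed=0)

    def test_default_r2_near_closed_form_both_conditions(self):
        ad = ls.coupling_regression(self.cohort("AD", 14), seed=5)
        uc = ls.coupling_regression(self.cohort("UC", 15, n_cases=3), seed=5)
        assert ad.r2 == pytest.approx(1 / (1 + 0.62**2), abs=0.10)
        assert uc.r2 == pytest.approx(1 / (1 + 1.60**2), abs=0.10)
        assert ad.n == 400 and uc.n == 300

    def test_ad_coupling_exceeds_uc_in_paired_simulations(self):
        wins = 0
        nsim = 60
        for s in range(nsim):
            ad = ls.coupling_regression(self.cohort("AD", 100 + s, n_pos=500), seed=s)
            uc = ls.coupling_regression(self.cohort("UC", 700 + s, n_cases=3, n_pos=500), seed=s)
            wins += ad.r2 > uc.r2
        assert wins == nsim

    def test_sampling_is_seeded_and_reproducible(self):
        cohort = self.cohort("AD", 16)
        a = ls.coupling_regression(cohort, seed=9)
        b = ls.coupling_regression(cohort, seed=9)
        assert a.sampled_ids == b.sampled_ids and a.r2 == b.r2


class TestSubsetProfiles:
    @staticmethod
    def cohort(seed, condition="AD", cells_per_case=1000):
        cells = simulate_cohort(condition, cells_per_case, seed)
        cfg = sc.GeneratorConfig.for_condition(condition)
        out = sc.assign_intensities(cells, cfg, seed=seed + 1)
        return out.rename(columns={"zone_true": "zone"})

    def test_flat_intensities_give_zero_slope(self):
        cells = self.cohort(17)
        cells["p16_nuclear"] = 5.0
        _, fit = ls.subset_intensity_profiles(cells, subset="positive", compartment="nuclear")
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-9)

    def test_negative_subset_dimmer_than_positive_in_every_zone(self):
        cells = self.cohort(18, cells_per_case=3000)
        pos, _ = ls.subset_intensity_profiles(cells, "positive", "nuclear")
        neg, _ = ls.subset_intensity_profiles(cells, "negative", "nuclear")
        merged = pos.merge(neg, on=["case_id", "condition", "zone"], suffixes=("_p", "_n"))
        ok = merged.dropna()
        assert (ok["mean_intensity_p"] > ok["mean_intensity_n"]).all()

    def test_ad_positive_nuclear_slope_significant_at_study_scale(self):
        hits = 0
        nsim = 200
        for s in range(nsim):
            cells = self.cohort(3000 + 2 * s)
            _, fit = ls.subset_intensity_profiles(cells, "positive", "nuclear")
            hits += (fit.coefficients[1] > 0) and (fit.slope_p < 0.05)
        assert hits / nsim >= 0.90

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ls.AnalysisError):
            ls.subset_intensity_profiles(self.cohort(19), compartment="membrane")


class TestCultureFractions:
    def test_all_negative_culture_gives_zero_fractions(self):
        cfg = sc.CultureConfig(damage_prob={"control": 0.0}, p27_prob=0.0)
        table = sc.simulate_culture(cfg, seed=20)
        res = ls.culture_fractions(table)
        assert (res["summary"]["gh2ax_fraction"] == 0).all()
        assert (res["summary"]["p27_fraction"] == 0).all()

    def test_single_replicate_rejected(self):
        table = sc.simulate_culture(seed=21)
        one = table[table["replicate_id"].isin([f"{c}_r1" for c in sc.CULTURE_CONDITIONS])]
        with pytest.raises(ls.AnalysisError):
            ls.culture_fractions(one)

    def test_dose_effect_power_and_p27_independence(self):
        # 10 µM vs control t-test p < 0.01 in >= 95% of simulations at 1,000
        # cells/replicate; the per-cell p27-on-γH2AX slope stays null-like
        dose_hits = 0
        slope_hits = 0
        nsim = 200
        for s in range(nsim):
            table = sc.simulate_culture(sc.CultureConfig(cells_per_replicate=1000), seed=5000 + s)
            res = ls.culture_fractions(table)
            pair = res["pairwise_gh2ax"]
            row = pair[(pair["a"] == "control") & (pair["b"] == "etop_10uM")].iloc[0]
            dose_hits += row["p"] < 0.01
            slope_hits += res["p27_on_gh2ax"]["etop_10uM"].slope_p < 0.05
        assert dose_hits / nsim >= 0.95
        assert slope_hits / nsim <= 0.10
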