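"""Age adjustment, paired seasonal testing, BY-FDR and direction calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hibernaclock import (
    SyntheticConfig,
    age_adjust,
    by_fdr,
    call_directions,
    detect_dmps,
    direction_summary,
    generate_beta_matrix,
    generate_cohort,
    paired_season_test,
    standardized_effect,
)


def _paired_sheet(n_pairs, ages=None):
    rows = []
    for i in range(n_pairs):
        age = ages[i] if ages is not None else 2.0 + 0.5 * i
        for season in ("winter", "summer"):
            rows.append({"sample_id": f"i{i:02d}_{season[0]}",
                         "individual_id": f"i{i:02d}", "season": season,
                         "birthplace": "captive", "age_years": age,
                         "age_is_minimum": False})
    return pd.DataFrame(rows)


def _betas(sheet, values):
    return pd.DataFrame(values, columns=sheet["sample_id"].to_list())


class TestAgeAdjust:
    def test_constant_probe_has_zero_residuals_and_slope(self):
        sheet = _paired_sheet(4)
        betas = _betas(sheet, np.full((1, 8), 0.30))
        adj = age_adjust(betas, sheet)
        assert np.allclose(adj.residuals, 0.0)
        assert adj.slopes.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_age_line_has_zero_residuals(self):
        sheet = _paired_sheet(5)
        ages = sheet.set_index("sample_id")["age_years"]
        betas = _betas(sheet, (0.01 * ages.to_numpy())[None, :])
        adj = age_adjust(betas, sheet)
        assert np.allclose(adj.residuals, 0.0, atol=1e-12)
        assert adj.slopes.iloc[0] == pytest.approx(0.01, abs=1e-10)

    def test_matches_normal_equations_per_probe(self):
        rng = np.random.default_rng(0)
        sheet = _paired_sheet(3, ages=[1.0, 4.0, 9.0])
        B = rng.uniform(0, 1, (6, 6))
        adj = age_adjust(_betas(sheet, B), sheet)
        ages = sheet["age_years"].to_numpy()
        X = np.column_stack([np.ones(6), ages])
        for i in range(6):
            coef = np.linalg.solve(X.T @ X, X.T @ B[i])
            assert np.allclose(adj.residuals.iloc[i], B[i] - X @ coef,
                               atol=1e-10)

    def test_residuals_sum_to_zero_per_probe(self, betas_truth, cohort):
        betas, _ = betas_truth
        adj = age_adjust(betas, cohort)
        assert np.allclose(adj.residuals.sum(axis=1), 0.0, atol=1e-8)

    def test_zero_age_variance_rejected(self):
        sheet = _paired_sheet(3, ages=[2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="age variance"):
            age_adjust(_betas(sheet, np.ones((2, 6)) * 0.4), sheet)


class TestPairedSeasonTest:
    def test_constant_paired_shift_recovered(self):
        sheet = _paired_sheet(6)
        winter = (sheet["season"] == "winter").to_numpy()
        base = np.linspace(0.3, 0.5, 6).repeat(2)
        betas = _betas(sheet, (base + 0.05 * winter)[None, :])
        adj = age_adjust(betas, sheet)
        table = paired_season_test(adj, sheet)
        assert table["coef"].iloc[0] == pytest.approx(0.05, abs=1e-10)

    def test_season_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        sheet = _paired_sheet(8)
        B = rng.uniform(0.2, 0.8, (10, 16))
        t1 = paired_season_test(age_adjust(_betas(sheet, B), sheet), sheet)
        swapped = sheet.copy()
        swapped["season"] = swapped["season"].map(
            {"winter": "summer", "summer": "winter"})
        t2 = paired_season_test(age_adjust(_betas(swapped, B), swapped), swapped)
        m1 = t1.set_index("probe_id").sort_index()
        m2 = t2.set_index("probe_id").sort_index()
        assert np.allclose(m1["coef"], -m2["coef"], atol=1e-12)
        assert np.allclose(m1["p_raw"], m2["p_raw"], atol=1e-12)

    def test_matches_paired_t_oracle(self):
        rng = np.random.default_rng(2)
        sheet = _paired_sheet(10)
        B = rng.uniform(0.2, 0.8, (20, 20))
        adj = age_adjust(_betas(sheet, B), sheet)
        table = paired_season_test(adj, sheet).set_index("probe_id")
        w_ids = sheet.loc[sheet["season"] == "winter", "sample_id"].tolist()
        s_ids = sheet.loc[sheet["season"] == "summer", "sample_id"].tolist()
        for probe in adj.residuals.index[:5]:
            t_or = stats.ttest_rel(adj.residuals.loc[probe, w_ids],
                                   adj.residuals.loc[probe, s_ids])
            assert table.loc[probe, "p_raw"] == pytest.approx(
                t_or.pvalue, abs=1e-12)

    def test_reml_path_agrees_with_paired_path(self):
        rng = np.random.default_rng(3)
        sheet = _paired_sheet(9)
        ind_effect = rng.normal(0, 0.1, 9).repeat(2)
        B = 0.5 + ind_effect + rng.normal(0, 0.03, (4, 18))
        adj = age_adjust(_betas(sheet, B), sheet)
        paired = paired_season_test(adj, sheet).set_index("probe_id")
        reml = paired_season_test(adj, sheet, method="reml").set_index("probe_id")
        for probe in adj.residuals.index:
            assert reml.loc[probe, "coef"] == pytest.approx(
                paired.loc[probe, "coef"], abs=1e-6)
            assert reml.loc[probe, "p_raw"] == pytest.approx(
                paired.loc[probe, "p_raw"], abs=1e-6)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        sheet = _paired_sheet(7)
        B = rng.uniform(0.2, 0.8, (6, 14))
        betas = _betas(sheet, B)
        t1 = paired_season_test(age_adjust(betas, sheet), sheet)
        perm = rng.permutation(14)
        betas2 = betas.iloc[:, perm]
        sheet2 = sheet.iloc[perm].reset_index(drop=True)
        t2 = paired_season_test(age_adjust(betas2, sheet2), sheet2)
        m1, m2 = t1.set_index("probe_id"), t2.set_index("probe_id")
        assert np.allclose(m1["p_raw"], m2.loc[m1.index, "p_raw"], atol=1e-12)

    def test_probe_with_no_contrast_flagged(self):
        sheet = _paired_sheet(4)
        betas = _betas(sheet, np.full((2, 8), 0.4))
        table = paired_season_test(age_adjust(betas, sheet), sheet)
        assert (table["p_raw"] == 1.0).all()
        assert (table["direction"] == "none").all()


class TestByFdr:
    def test_single_p_unchanged(self):
        assert by_fdr([0.04])[0] == pytest.approx(0.04)

    def test_brute_force_formula(self):
        """Hand evaluation of the BY step-up on m=4: c(4)=25/12."""
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = by_fdr(p)
        # min_j>=i of min(1, m*c(m)*p_(j)/j): every term is 4*(25/12)*0.01
        assert np.allclose(adj, 25 / 3 * 0.01)

    def test_brute_force_random_inputs(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 37)
        m = len(p)
        c = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p)
        ranked = p[order]
        raw = np.minimum(1.0, m * c * ranked / np.arange(1, m + 1))
        stepup = np.minimum.accumulate(raw[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = stepup
        assert np.allclose(by_fdr(p), expect, atol=1e-12)

    def test_zeros_stay_zero(self):
        assert np.allclose(by_fdr([0.0, 0.0, 0.0]), 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.5])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    def test_monotone_and_dominates_bh(self, p):
        p = np.asarray(p)
        adj = by_fdr(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        from statsmodels.stats.multitest import multipletests
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(adj >= bh - 1e-12)


class TestDirections:
    def test_proportion_up_from_planted_split(self):
        n = 1000
        table = pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(n)],
            "coef": np.where(np.arange(n) < 775, 0.1, -0.1),
            "p_by": np.full(n, 0.001),
        })
        called = call_directions(table, threshold=0.05)
        s = direction_summary(called)
        assert s["proportion_up"] == pytest.approx(0.775)

    def test_no_significant_sites(self):
        table = pd.DataFrame({"probe_id": ["a", "b"], "coef": [0.1, -0.2],
                              "p_by": [0.5, 0.9]})
        s = direction_summary(call_directions(table))
        assert s["n_winter_up"] == 0 and s["n_winter_down"] == 0

    def test_vacuous_threshold_calls_every_site(self):
        table = pd.DataFrame({"probe_id": ["a", "b", "c"],
                              "coef": [0.1, -0.2, 0.3],
                              "p_by": [0.99, 0.5, 0.7]})
        called = call_directions(table, threshold=1.0)
        assert list(called["direction"]) == ["winter-up", "winter-down",
                                             "winter-up"]

    def test_direction_calls_match_planted_signs(self):
        """>= 99% of detected DMPs carry the planted direction."""
        cfg = SyntheticConfig(seed=11)
        sheet = generate_cohort(cfg)
        betas, truth = generate_beta_matrix(sheet, cfg)
        table = detect_dmps(betas, sheet, fdr=0.05)
        called = table[table["direction"] != "none"].set_index("probe_id")
        planted = truth.dmp_sites.set_index("probe_id")
        overlap = called.index.intersection(planted.index)
        agree = (called.loc[overlap, "direction"]
                 == planted.loc[overlap, "true_direction"]).mean()
        assert len(overlap) > 50
        assert agree >= 0.99


class TestStandardizedEffect:
    def test_pre_scaled_residuals(self):
        sheet = _paired_sheet(8)
        winter = (sheet["season"] == "winter").to_numpy()
        rng = np.random.default_rng(6)
        r = rng.normal(0, 1, 16) + 0.5 * winter
        adj_res = pd.DataFrame(r[None, :], index=["cgX"],
                               columns=sheet["sample_id"])
        from hibernaclock.dmp import AgeAdjustedMatrix
        adj = AgeAdjustedMatrix(adj_res, pd.Series([0.0], index=["cgX"]),
                                pd.Series([0.0], index=["cgX"]))
        eff = standardized_effect(adj, sheet, "cgX")
        # z-scoring divides by the overall residual SD
        expect = (r[winter].mean() - r[~winter].mean()) / r.std(ddof=1)
        assert eff == pytest.approx(expect, abs=1e-10)

    def test_scale_invariance(self):
        sheet = _paired_sheet(5)
        rng = np.random.default_rng(7)
        r = rng.normal(0, 0.05, 10)
        from hibernaclock.dmp import AgeAdjustedMatrix

        def make(scale):
            res = pd.DataFrame((r * scale)[None, :], index=["cgX"],
                               columns=sheet["sample_id"])
            return AgeAdjustedMatrix(res, pd.Series([0.0], index=["cgX"]),
                                     pd.Series([0.0], index=["cgX"]))

        e1 = standardized_effect(make(1.0), sheet, "cgX")
        e2 = standardized_effect(make(2.0), sheet, "cgX")
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_equals_coefficient_over_residual_sd(self):
        sheet = _paired_sheet(5)
        rng = np.random.default_rng(8)
        B = rng.uniform(0.3, 0.7, (3, 10))
        adj = age_adjust(_betas(sheet, B), sheet)
        table = paired_season_test(adj, sheet).set_index("probe_id")
        probe = adj.residuals.index[1]
        sd = adj.residuals.loc[probe].std(ddof=1)
        assert standardized_effect(adj, sheet, probe) == pytest.approx(
            table.loc[probe, "coef"] / sd, abs=1e-10)

    def test_zero_variance_flagged(self):
        sheet = _paired_sheet(4)
        from hibernaclock.dmp import AgeAdjustedMatrix
        res = pd.DataFrame(np.zeros((1, 8)), index=["cgX"],
                           columns=sheet["sample_id"])
        adj = AgeAdjustedMatrix(res, pd.Series([0.0], index=["cgX"]),
                                pd.Series([0.0], index=["cgX"]))
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            assert standardized_effect(adj, sheet, "cgX") == 0.0


class TestNullCalibration:
    def test_null_data_by_significant_fraction(self):
        """On data with no planted DMPs the mean BY-significant fraction
        stays below the nominal 0.05 level (20 seeds)."""
        fracs = []
        for seed in range(20):
            cfg = SyntheticConfig(n_probes=400, n_clock_sites=0,
                                  n_dmp_sites=0, seed=300 + seed)
            sheet = generate_cohort(cfg)
            betas, _ = generate_beta_matrix(sheet, cfg)
            table = detect_dmps(betas, sheet, fdr=0.05)
            fracs.append((table["p_by"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05
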