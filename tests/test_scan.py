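"""Association engine: logit MLE vs oracles, fallbacks, Bonferroni, scan surface."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from medwas.cohort import ExposureCohort
from medwas.scan import (
    MedWAS,
    MedWASResults,
    ScanConfig,
    bonferroni_threshold,
    contingency,
    fit_cells,
    fit_pair,
)


class TestFitPair:
    def test_cross_product_oracle(self):
        pf = fit_cells(30, 70, 10, 90)
        assert pf.method == "logit"
        assert pf.odds_ratio == pytest.approx((30 * 90) / (70 * 10), abs=1e-9)

    def test_balanced_table_is_null(self):
        pf = fit_cells(25, 25, 25, 25)
        assert pf.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert pf.p_value == pytest.approx(1.0, abs=1e-9)

    def test_zero_cell_uses_fisher_with_haldane_or(self):
        pf = fit_cells(5, 0, 10, 90)
        assert pf.method == "fisher_fallback"
        expected_or = (5.5 * 90.5) / (0.5 * 10.5)
        assert pf.odds_ratio == pytest.approx(expected_or)
        _, fisher_p = stats.fisher_exact([[5, 0], [10, 90]])
        assert pf.p_value == pytest.approx(fisher_p)
        assert np.isfinite(pf.odds_ratio)

    def test_all_constant_outcome_degenerate(self):
        pf = fit_pair([1, 1, 0, 0], [0, 0, 0, 0])
        assert pf.method == "degenerate_outcome"
        assert np.isnan(pf.odds_ratio)

    def test_vector_and_cells_agree(self, rng):
        x = rng.random(500) < 0.3
        y = rng.random(500) < 0.2
        a = int((x & y).sum()); b = int((x & ~y).sum())
        c = int((~x & y).sum()); d = int((~x & ~y).sum())
        assert fit_pair(x, y) == fit_cells(a, b, c, d)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(deadline=None, max_examples=60)
    def test_logit_equals_cross_product_or(self, a, b, c, d):
        """Saturated one-predictor logit: exp(beta) is the cross-product OR."""
        pf = fit_cells(a, b, c, d)
        assert pf.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-9)

    @pytest.mark.parametrize("cells", [(30, 70, 10, 90), (12, 44, 7, 131), (80, 20, 60, 40)])
    def test_matches_statsmodels_logit(self, cells):
        """Independent oracle: iterative statsmodels fit on row-level data."""
        a, b, c, d = cells
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        pf = fit_cells(a, b, c, d)
        assert pf.beta == pytest.approx(ref.params[1], abs=1e-8)
        assert pf.se == pytest.approx(ref.bse[1], abs=1e-8)
        assert pf.p_value == pytest.approx(ref.pvalues[1], abs=1e-8)

    def test_lrt_matches_statsmodels_llr(self):
        a, b, c, d = 30, 70, 10, 90
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        pf = fit_cells(a, b, c, d, ScanConfig(p_method="lrt"))
        assert pf.p_value == pytest.approx(ref.llr_pvalue, abs=1e-8)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 1, 0.05), (0.05, 1678, 0.05 / 1678), (0.05, 50, 1e-3)],
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestContingency:
    def test_empty_cohort_all_zero(self):
        t = contingency(ExposureCohort("x", set(), set()), {})
        assert (t == 0).all()

    def test_manual_tabulation(self):
        cohort = ExposureCohort("x", {"b1", "b2"}, {"b3", "b4"})
        statuses = {"b1": "case", "b2": "control", "b3": "case", "b4": "control"}
        t = contingency(cohort, statuses)
        assert t.tolist() == [[1, 1], [1, 1]]

    def test_excluded_in_neither_margin(self):
        cohort = ExposureCohort("x", {"b1", "b2"}, {"b3"})
        statuses = {"b1": "case", "b2": "excluded", "b3": "excluded"}
        assert contingency(cohort, statuses).tolist() == [[1, 0], [0, 0]]


def _toy_model(n=600, seed=0, **cfg_kwargs):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"b{i}" for i in range(n)])
    expo = pd.DataFrame(rng.random((n, 2)) < 0.3, index=idx, columns=["d1", "d2"])
    case = pd.DataFrame(rng.random((n, 3)) < 0.25, index=idx, columns=["p1", "p2", "p3"])
    return MedWAS(expo, case, config=ScanConfig(min_cases=1, **cfg_kwargs))


class TestScan:
    def test_cross_product_row_count(self):
        res = _toy_model().fit()
        assert len(res.table) == 2 * 3

    def test_scan_rows_match_fit_pair(self):
        model = _toy_model()
        res = model.fit()
        for _, row in res.table.iterrows():
            x = model.exposure[row["drug"]].to_numpy()
            y = model.case[row["phecode"]].to_numpy()
            pf = fit_pair(x, y, model.config)
            assert row["p_value"] == pytest.approx(pf.p_value, rel=1e-9)
            assert row["odds_ratio"] == pytest.approx(pf.odds_ratio, rel=1e-9)
            assert row["method"] == pf.method

    def test_excluded_babies_dropped_from_margins(self):
        idx = pd.Index(["b1", "b2", "b3", "b4"])
        expo = pd.DataFrame({"d": [True, True, False, False]}, index=idx)
        case = pd.DataFrame({"p": [True, False, True, False]}, index=idx)
        excl = pd.DataFrame({"p": [False, True, False, False]}, index=idx)
        res = MedWAS(expo, case, excl, ScanConfig(min_cases=1)).fit()
        row = res.table.iloc[0]
        assert row["n_case"] == 2 and row["n_control"] == 1
        assert row["n_exposed_control"] == 0

    def test_min_cases_skip(self):
        model = _toy_model()
        model.config = ScanConfig(min_cases=10**6)
        res = model.fit()
        assert (res.table["method"] == "skipped_min_cases").all()
        assert not res.table["bonferroni_significant"].any()

    def test_per_drug_family_threshold_is_panel_size(self):
        res = _toy_model().fit()
        assert res.metadata["m"] == 3
        res_g = _toy_model(family="global").fit()
        assert res_g.metadata["m"] == 6

    def test_count_invariants(self):
        res = _toy_model(seed=3).fit()
        t = res.table
        assert (t["n_exposed_case"] <= t["n_case"]).all()
        assert (t["n_exposed_control"] <= t["n_control"]).all()
        cr = t["coincidence_rate"].dropna()
        assert ((cr >= 0) & (cr <= 1)).all()
        assert np.allclose(
            t["coincidence_rate"], t["n_exposed_case"] / t["n_case"], equal_nan=True
        )

    def test_bonferroni_flag_consistent_with_threshold(self):
        res = _toy_model(seed=5).fit()
        thr = res.metadata["bonferroni_threshold"]
        t = res.table.dropna(subset=["p_value"])
        assert (t["bonferroni_significant"] == (t["p_value"] <= thr)).all()

    def test_result_tsv_roundtrip_and_determinism(self, tmp_path):
        for name in ("r1.tsv", "r2.tsv"):
            _toy_model(seed=9).fit().to_tsv(tmp_path / name)
        assert (tmp_path / "r1.tsv").read_bytes() == (tmp_path / "r2.tsv").read_bytes()
        back = MedWASResults.from_tsv(tmp_path / "r1.tsv")
        assert len(back.table) == 6
        assert back.metadata["family"] == "per_drug"

    def test_sorted_by_drug_then_p(self):
        t = _toy_model(seed=2).fit().table
        for _, grp in t.groupby("drug", sort=False):
            p = grp["p_value"].to_numpy()
            assert (np.diff(p[~np.isnan(p)]) >= 0).all()

    def test_label_permutation_null_p_uniform(self, rng):
        """Permuting exposure labels yields ~uniform p-values (KS check)."""
        n = 4000
        y = rng.random(n) < 0.2
        pvals = []
        for _ in range(300):
            x = rng.permutation(np.r_[np.ones(800, bool), np.zeros(n - 800, bool)])
            pvals.append(fit_pair(x, y).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_summary_mentions_key_quantities(self):
        s = _toy_model().fit().summary()
        assert "Bonferroni" in s and "alpha=0.05" in s

    def test_covariate_adjusted_fit_matches_statsmodels(self, rng):
        n = 500
        idx = pd.Index([f"b{i}" for i in range(n)])
        z = rng.random(n) < 0.4
        x = rng.random(n) < 0.3
        y = rng.random(n) < (0.1 + 0.15 * x + 0.1 * z)
        expo = pd.DataFrame({"d": x}, index=idx)
        case = pd.DataFrame({"p": y}, index=idx)
        covs = pd.DataFrame({"z": z.astype(float)}, index=idx)
        model = MedWAS(
            expo, case, config=ScanConfig(min_cases=1, covariates=["z"]), covariates=covs
        )
        row = model.fit().table.iloc[0]
        assert row["method"] == "logit_adjusted"
        import statsmodels.api as sm

        X = np.column_stack([np.ones(n), x.astype(float), z.astype(float)])
        ref = sm.GLM(y.astype(float), X, family=sm.families.Binomial()).fit()
        assert row["beta"] == pytest.approx(ref.params[1], abs=1e-8)
        assert row["p_value"] == pytest.approx(ref.pvalues[1], abs=1e-8)

    def test_covariates_named_without_data_rejected(self):
        idx = pd.Index(["a", "b"])
        expo = pd.DataFrame({"d": [True, False]}, index=idx)
        case = pd.DataFrame({"p": [True, False]}, index=idx)
        with pytest.raises(ValueError, match="covariate"):
            MedWAS(expo, case, config=ScanConfig(covariates=["z"]))

    def test_run_scan_wrapper_matches_model(self, small_population, dictionary):
        from medwas.cohort import apply_inclusion_rule, exposure_matrix
        from medwas.scan import run_scan
        from medwas.calibration import _synthetic_phecode_map
        from medwas.vocab import phenotype_status_matrix

        tables, _ = small_population
        dyads, _ = apply_inclusion_rule(tables, dictionary)
        drugs = [f"drug_{i:03d}" for i in range(5)]
        phecodes = [f"{i + 1:03d}.0" for i in range(8)]
        pmap = _synthetic_phecode_map(
            __import__("medwas.simulate", fromlist=["SimulationConfig"]).SimulationConfig(
                n_drugs=5, n_phecodes=8
            )
        )
        ids = [d.baby_id for d in dyads]
        case, excl = phenotype_status_matrix(
            tables["condition_occurrence"], ids, phecodes, pmap
        )
        res = run_scan(dyads, drugs, phecodes, case, excl, ScanConfig(min_cases=5))
        assert len(res.table) == 5 * 8
        expo = exposure_matrix(dyads, drugs)
        ref = MedWAS(expo, case, excl, ScanConfig(min_cases=5)).fit()
        pd.testing.assert_frame_equal(res.table, ref.table)

        with pytest.raises(ValueError):
            run_scan(dyads, [], phecodes, case, excl)
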