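"""Tests of the REML engine: likelihood correctness, rank tests, Wald test."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from divmat import (
    FitOptions,
    ModelSpec,
    SimulationConfig,
    covariance_param_count,
    dense_minus2ll,
    estimate_rank,
    likelihood_ratio_from_values,
    likelihood_ratio_test,
    make_rank_k_cov,
    reml_fit,
    separate_vs_pooled_D,
    simulate_experiment,
    standardize_table,
    treatment_mean_test,
)
from divmat.reml_models import _RemlData, _pack_cov_tril
from divmat.trait_data import TRAITS, UsageError

FAST = FitOptions(n_starts=2)


def _sim_std(seed, **kw):
    table, _ = simulate_experiment(SimulationConfig(seed=seed, **kw))
    return standardize_table(table.without_ancestor())


class TestParamCounts:
    @pytest.mark.parametrize(
        "k,expected", [(4, 20), (3, 19), (2, 17), (1, 14), (0, 10)]
    )
    def test_factor_analytic_ladder(self, k, expected):
        spec = ModelSpec(lineage="fa", fa_rank=k) if k else ModelSpec(lineage="zero")
        assert covariance_param_count(4, spec) == expected

    def test_full_rank_fa_equals_unstructured(self):
        for p in (2, 3, 4, 6):
            assert covariance_param_count(
                p, ModelSpec(lineage="fa", fa_rank=p)
            ) == covariance_param_count(p, ModelSpec())

    def test_separate_doubles_lineage_block(self):
        spec = ModelSpec(separate_by_treatment=True)
        assert covariance_param_count(4, spec, n_groups=2) == 30


class TestDenseOracle:
    """The factored restricted likelihood equals a brute-force dense
    evaluation of the same model on a tiny instance, over a grid of
    well-conditioned parameter values."""

    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec(),
            ModelSpec(lineage="fa", fa_rank=2),
            ModelSpec(lineage="fa", fa_rank=1),
            ModelSpec(lineage="zero"),
            ModelSpec(lineage="unstructured", separate_by_treatment=True),
        ],
    )
    def test_factored_equals_dense(self, small_std_table, spec):
        data = _RemlData(small_std_table)
        n_blocks = data.q if spec.separate_by_treatment else 1
        m_lin = {"unstructured": 10, "zero": 0, "fa": None}[spec.lineage]
        if m_lin is None:
            k = spec.fa_rank
            m_lin = k * (2 * 4 - k + 1) // 2
        m = m_lin * n_blocks + 10
        rng = np.random.default_rng(11)
        base_R = _pack_cov_tril(np.eye(4))
        for _ in range(6):
            th = 0.3 * rng.standard_normal(m)
            th[-10:] += base_R  # keep the residual well conditioned
            a = data.minus2ll(th, spec=spec)
            b = dense_minus2ll(small_std_table, spec, th)
            assert a == pytest.approx(b, abs=1e-6, rel=1e-9)

    def test_unbalanced_replicates_also_agree(self, small_sim):
        table, _ = small_sim
        df = table.data.drop(index=[1, 5]).reset_index(drop=True)  # uneven r_k
        tbl = standardize_table(
            type(table)(df, table.transform_log).without_ancestor()
        )
        data = _RemlData(tbl)
        rng = np.random.default_rng(4)
        th = 0.2 * rng.standard_normal(20)
        th[-10:] += _pack_cov_tril(np.eye(4))
        spec = ModelSpec()
        assert data.minus2ll(th, spec=spec) == pytest.approx(
            dense_minus2ll(tbl, spec, th), abs=1e-6, rel=1e-9
        )


class TestRemlFit:
    def test_zero_lineage_variance_fit_matches_closed_form(self):
        # with no lineage variance the model is a multivariate linear
        # model whose REML residual covariance is the residual SSCP
        # divided by (rows - groups); the optimizer must reach the same
        # restricted likelihood as that closed-form maximizer
        tbl = _sim_std(21, true_D=make_rank_k_cov(4, 0, ()))
        fit = reml_fit(tbl, ModelSpec(lineage="zero"), FAST)
        df = tbl.data
        Y = df[list(TRAITS)].to_numpy()
        groups = df["treatment"].to_numpy()
        resid = Y.copy()
        for g in np.unique(groups):
            resid[groups == g] -= Y[groups == g].mean(axis=0)
        R_hat = resid.T @ resid / (len(Y) - len(np.unique(groups)))
        data = _RemlData(tbl)
        m2ll_closed = data.minus2ll(_pack_cov_tril(R_hat),
                                    spec=ModelSpec(lineage="zero"))
        assert fit.minus2ll == pytest.approx(m2ll_closed, abs=1e-6)

    def test_full_rank_fa_reaches_unstructured_maximum(self, default_std_table):
        f1 = reml_fit(default_std_table, ModelSpec(), FAST)
        f2 = reml_fit(default_std_table, ModelSpec(lineage="fa", fa_rank=4), FAST)
        assert f1.minus2ll == pytest.approx(f2.minus2ll, abs=1e-4)

    def test_aic_identity(self, default_std_table):
        fit = reml_fit(default_std_table, ModelSpec(), FAST)
        assert fit.aic == fit.minus2ll + 2 * fit.n_cov_params

    def test_fit_invariant_to_lineage_order(self, small_std_table):
        fit1 = reml_fit(small_std_table, ModelSpec(), FAST)
        rng = np.random.default_rng(0)
        ids = small_std_table.lineage_ids
        order = rng.permutation(len(ids))
        df = small_std_table.data
        shuffled = (
            df.set_index("lineage_id")
            .loc[[ids[i] for i in order]]
            .reset_index()
        )
        tbl = type(small_std_table)(shuffled, small_std_table.transform_log)
        fit2 = reml_fit(tbl, ModelSpec(), FAST)
        assert fit1.minus2ll == pytest.approx(fit2.minus2ll, abs=1e-6)

    def test_reml_D_estimate_close_to_moment_estimate(self, default_std_table):
        # on balanced data the unstructured REML D should match the
        # between/within method-of-moments decomposition closely
        fit = reml_fit(default_std_table, ModelSpec(), FAST)
        data = _RemlData(default_std_table)
        G0, _ = data.mom_start()
        assert np.abs(fit.lineage_cov.values - G0).max() < 0.05


class TestLikelihoodRatio:
    def test_published_rank4_test(self):
        res = likelihood_ratio_from_values(1670.3, 1681.45, 1)
        assert res.chi2 == pytest.approx(11.15)
        assert res.p_value == pytest.approx(0.0008, abs=5e-5)

    def test_identical_fits_give_null_result(self):
        res = likelihood_ratio_from_values(100.0, 100.0, 3)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("chi2,df", [(11.15, 1), (0.587, 3), (9.0, 10)])
    def test_survival_matches_density_quadrature(self, chi2, df):
        val, _ = integrate.quad(lambda x: stats.chi2.pdf(x, df), chi2, np.inf)
        assert stats.chi2.sf(chi2, df) == pytest.approx(val, rel=1e-8)

    def test_non_nested_rejected(self, small_std_table):
        f1 = reml_fit(small_std_table, ModelSpec(), FAST)
        with pytest.raises(UsageError):
            likelihood_ratio_test(f1, f1)


class TestEstimateRank:
    def test_ladder_monotone_and_full_rank_recovered(self, default_std_table):
        rt = estimate_rank(default_std_table, FAST)
        m2 = [row.minus2ll for row in rt.rows]  # k = 4 .. 0
        assert all(m2[i] <= m2[i + 1] + 1e-6 for i in range(len(m2) - 1))
        assert rt.selected_rank == 4  # generator truth is full rank

    def test_zero_truth_prefers_rank_zero(self):
        hits = 0
        for s in range(8):
            tbl = _sim_std(300 + s, true_D=make_rank_k_cov(4, 0, ()))
            rt = estimate_rank(tbl, FitOptions(n_starts=1))
            hits += rt.selected_rank == 0
        assert hits >= 6  # rank 0 in the large majority of null draws

    def test_tsv_columns(self, default_std_table, tmp_path):
        rt = estimate_rank(default_std_table, FAST)
        path = tmp_path / "ladder.tsv"
        rt.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["dimensions", "minus2_log_likelihood",
                          "n_parameters", "AIC", "p_value"]


class TestTreatmentMeanTest:
    def test_large_shift_detected(self):
        tbl = _sim_std(77, treatment_shift=np.array([1.5, 1.5, 0.0, 0.0]))
        fit = reml_fit(tbl, ModelSpec(), FAST)
        F, df1, df2, p = treatment_mean_test(fit)
        assert F > 0
        assert df1 == 4
        assert p < 1e-3

    def test_null_rejection_rate_near_alpha(self):
        # type-I calibration at a reduced seed count; binomial 3*SE band
        n_seeds, alpha = 100, 0.05
        rej = 0
        for s in range(n_seeds):
            tbl = _sim_std(1000 + s)
            fit = reml_fit(tbl, ModelSpec(), FitOptions(n_starts=1))
            rej += treatment_mean_test(fit)[3] < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_seeds)
        assert abs(rej / n_seeds - alpha) < 3 * se + 1e-12


class TestSeparateVsPooled:
    def test_df_is_ten_for_two_groups(self, default_std_table):
        res = separate_vs_pooled_D(default_std_table, FAST)
        assert res.df == 10
        assert res.chi2 >= 0

    def test_power_against_inflated_group(self):
        # one group simulated from 3D diverges detectably from the other
        base = SimulationConfig(seed=0)
        detected = 0
        for s in range(5):
            ta, _ = simulate_experiment(dataclasses.replace(base, seed=600 + s))
            tb, _ = simulate_experiment(
                dataclasses.replace(
                    base,
                    seed=700 + s,
                    true_D=type(base.true_D)(
                        base.true_D.labels, 3 * base.true_D.values, 0, "ground_truth"
                    ),
                )
            )
            da = ta.data[ta.data["treatment"] == "small"]
            db = tb.data[tb.data["treatment"] == "large"]
            import pandas as pd

            tbl = type(ta)(pd.concat([da, db], ignore_index=True),
                           ta.transform_log)
            std = standardize_table(tbl)
            if separate_vs_pooled_D(std, FitOptions(n_starts=1)).p_value < 0.01:
                detected += 1
        assert detected >= 4

    def test_requires_two_groups(self, small_sim):
        table, _ = small_sim
        df = table.data[table.data["treatment"] == "small"].reset_index(drop=True)
        tbl = type(table)(df, table.transform_log)
        with pytest.raises(UsageError):
            separate_vs_pooled_D(standardize_table(tbl), FAST)
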