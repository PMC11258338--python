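"""Per-gene gaussian GLM, BH adjustment, cohort intersection, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from wgdtx.dge import (
    DGEThresholds,
    WGDExpressionModel,
    bh_adjust,
    fit_gene_glm,
    intersect_cohorts,
)


class TestFitGeneGlm:
    def test_two_group_closed_form(self):
        """OLS on a 0/1 indicator equals the pooled-variance two-sample t-test."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        coef, se, p = fit_gene_glm(y, X)
        assert coef == pytest.approx(2.0, abs=1e-12)
        assert coef / se == pytest.approx(2.828, abs=1e-3)
        assert p == pytest.approx(0.1056, abs=1e-3)

    def test_matches_statsmodels_on_random_designs(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 30))
            X = np.column_stack(
                [np.ones(n), rng.integers(0, 2, n), rng.normal(size=(n, 2))]
            )
            y = rng.normal(size=n)
            coef, se, p = fit_gene_glm(y, X)
            fit = sm.OLS(y, X).fit()
            assert coef == pytest.approx(fit.params[1], abs=1e-10)
            assert se == pytest.approx(fit.bse[1], abs=1e-10)
            assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constant_response_is_flagged_uninformative(self):
        y = np.full(6, 3.7)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        coef, se, p = fit_gene_glm(y, X)
        assert coef == pytest.approx(0.0, abs=1e-10)
        assert p == 1.0

    def test_duplicated_covariate_raises(self):
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_gene_glm(np.arange(6.0), X)

    def test_too_few_samples_raises(self):
        X = np.column_stack([np.ones(2), [0, 1]])
        with pytest.raises(ValueError, match="more samples"):
            fit_gene_glm(np.array([1.0, 2.0]), X)


def _bh_reference(p):
    """Literal step-up definition: monotone minimum of n*p/rank."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_all_permutations_of_five(self):
        base = [0.001, 0.02, 0.04, 0.2, 0.9]
        for perm in itertools.permutations(base):
            assert np.allclose(bh_adjust(list(perm)), _bh_reference(perm))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_definition(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, _bh_reference(p))
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1).all()


def _toy_model(n=40, n_genes=30, seed=3, beta=0.0, thresholds=DGEThresholds()):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    wgd = np.repeat([0, 1], n // 2)
    design = pd.DataFrame(
        {"wgd": wgd, "hr": rng.uniform(0, 1, n), "purity": rng.uniform(0.4, 1, n)},
        index=pd.Index(samples, name="sample"),
    )
    genes = [f"g{i}" for i in range(n_genes)]
    y = rng.normal(5, 1, size=(n_genes, n)) + beta * wgd
    norm = pd.DataFrame(y, index=genes, columns=samples)
    cnlr = pd.DataFrame(
        rng.normal(0, 0.3, size=(n_genes, n)), index=genes, columns=samples
    )
    return WGDExpressionModel(norm, design, cnlr, thresholds=thresholds)


class TestModelFit:
    def test_planted_shift_recovered_and_called(self):
        res = _toy_model(beta=-3.0).fit()
        rec = res.records
        assert (rec.fit_status == "ok").all()
        assert rec.coef_wgd.mean() == pytest.approx(-3.0, abs=0.3)
        assert rec.significant.all() and (rec.direction == "down").all()

    def test_infinite_threshold_calls_nothing(self):
        res = _toy_model(
            beta=-3.0, thresholds=DGEThresholds(coef=np.inf)
        ).fit()
        assert not res.records.significant.any()

    def test_padj_never_below_praw(self):
        rec = _toy_model().fit().records
        assert (rec.p_adj >= rec.p_raw - 1e-15).all()

    def test_collinear_gene_flagged_not_fatal(self):
        m = _toy_model(n=10, n_genes=8)
        # make one gene's cnlr equal to the wgd indicator -> rank deficient
        m.cnlr.loc["g0"] = m.design["wgd"].to_numpy()
        # and that alone must not abort the run
        res = m.fit()
        assert res.records.set_index("gene_id").loc["g0", "fit_status"].startswith("failed")
        assert res.n_failed == 1

    def test_mass_failure_aborts_with_summary(self):
        m = _toy_model(n=10, n_genes=6)
        m.cnlr.loc[:, :] = np.tile(
            m.design["wgd"].to_numpy(), (6, 1)
        )  # every gene collinear
        with pytest.raises(RuntimeError, match="fits failed"):
            m.fit()

    def test_no_cn_mode_drops_covariate(self):
        m = _toy_model()
        m_nocn = WGDExpressionModel(m.norm, m.design, None, include_cn=False)
        assert "cnlr" not in m_nocn.exog_names
        assert (m_nocn.fit().records.fit_status == "ok").all()

    def test_summary_reports_counts(self):
        res = _toy_model(beta=-3.0).fit()
        text = res.summary()
        assert "significant down" in text.lower()
        assert str(len(res.records)) in text


class TestResidualDiagnostics:
    def test_structure_and_determinism(self):
        res = _toy_model(seed=9).fit()
        d1 = res.residual_diagnostics()
        d2 = res.residual_diagnostics()
        assert list(d1.columns) == [
            "quantile", "gene_id", "mean_expr", "ks_stat", "ks_p",
            "n_outliers", "wgd_var_ratio",
        ]
        assert len(d1) == 3
        pd.testing.assert_frame_equal(d1, d2)

    def test_gaussian_data_passes_ks(self):
        # correct-model calibration: most tertile genes look gaussian
        d = _toy_model(n=60, seed=4).fit().residual_diagnostics()
        assert (d.ks_p > 0.05).sum() >= 2

    def test_heavy_tailed_noise_yields_outliers(self):
        rng = np.random.default_rng(0)
        m = _toy_model(n=60, n_genes=9, seed=5)
        m.norm.loc[:, :] = 5 + rng.standard_t(2, size=m.norm.shape) * 1.0
        d = m.fit().residual_diagnostics()
        assert d.n_outliers.sum() > 0


class TestIntersectCohorts:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "coef_wgd", "p_adj", "fit_status"]
        )

    def test_concordant_and_discordant_genes(self):
        disc = self._table(
            [("g1", -2.0, 0.001, "ok"), ("g2", -1.8, 0.01, "ok"),
             ("g3", 2.5, 0.001, "ok")]
        )
        val = self._table(
            [("g1", -0.3, 0.04, "ok"),  # small magnitude still counts
             ("g2", 0.9, 0.01, "ok"),   # sign flip -> excluded
             ("g3", 1.1, 0.2, "ok")]    # not significant -> excluded
        )
        out = intersect_cohorts(disc, val)
        assert list(out.gene_id) == ["g1"]
        assert out.iloc[0].direction == "down"
        assert out.iloc[0].coef_validation == pytest.approx(-0.3)

    def test_empty_overlap_errors(self):
        disc = self._table([("g1", -2.0, 0.001, "ok")])
        val = self._table([("g9", -2.0, 0.001, "ok")])
        with pytest.raises(ValueError, match="no gene overlap"):
            intersect_cohorts(disc, val)
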