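import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolsel.afc_scan import (
    GlmFit,
    _batch_slope_fit,
    bonferroni_threshold,
    haldane_anscombe,
    irls_binomial_fit,
    model1_contrasts,
    model2_scan,
)
from poolsel.counts_io import SiteCounts


def logit(p):
    return np.log(p / (1 - p))


def two_group_design():
    return np.array([[1.0, 0.0], [1.0, 1.0]])


class TestIrls:
    def test_saturated_two_group_closed_form(self):
        fit = irls_binomial_fit(two_group_design(), [20, 40], [100, 100])
        assert fit.converged
        assert fit.coef[1] == pytest.approx(logit(0.4) - logit(0.2), abs=1e-8)
        assert fit.coef[0] == pytest.approx(logit(0.2), abs=1e-8)

    def test_identical_groups_zero_effect(self):
        X = np.column_stack([np.ones(4), np.eye(4)[:, 1:]])
        fit = irls_binomial_fit(X, [30, 30, 30, 30], [100, 100, 100, 100])
        np.testing.assert_allclose(fit.coef[1:], 0.0, atol=1e-8)

    def test_wald_z_matches_log_or(self):
        # 2x2 table 10/90 vs 30/70: z = log-OR / sqrt(sum 1/cell)
        fit = irls_binomial_fit(two_group_design(), [10, 30], [100, 100])
        est, se, z, p = fit.wald([0.0, 1.0])
        log_or = np.log((30 / 70) / (10 / 90))
        se_hand = np.sqrt(1 / 10 + 1 / 90 + 1 / 30 + 1 / 70)
        assert est == pytest.approx(log_or, abs=1e-8)
        assert se == pytest.approx(se_hand, rel=1e-6)
        assert z == pytest.approx(log_or / se_hand, rel=1e-6)

    def test_rank_deficiency_error(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(np.linalg.LinAlgError):
            irls_binomial_fit(X, [1, 2, 3], [10, 10, 10])

    def test_zero_total_rows_ignored(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        fit_a = irls_binomial_fit(X, [20, 40, 0], [100, 100, 0])
        fit_b = irls_binomial_fit(two_group_design(), [20, 40], [100, 100])
        np.testing.assert_allclose(fit_a.coef, fit_b.coef, atol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        n = rng.integers(20, 200, 8)
        p = 1 / (1 + np.exp(-(0.3 - 0.5 * X[:, 1])))
        y = rng.binomial(n, p)
        # keep away from separation for a clean comparison
        y = np.clip(y, 1, n - 1)
        fit = irls_binomial_fit(X, y, n, adjust_separation=False)
        sm_fit = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef, sm_fit.params, rtol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), sm_fit.bse, rtol=1e-5)

    def test_covariance_symmetric_psd(self):
        fit = irls_binomial_fit(two_group_design(), [20, 40], [100, 100])
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)


class TestHaldaneAnscombe:
    def test_triggered_by_fixed_cell(self):
        y, n, adj = haldane_anscombe(np.array([0.0, 40.0]), np.array([100.0, 100.0]))
        assert adj
        np.testing.assert_allclose(y, [0.5, 40.5])
        np.testing.assert_allclose(n, [101.0, 101.0])

    def test_not_triggered(self):
        y, n, adj = haldane_anscombe(np.array([5.0, 40.0]), np.array([100.0, 100.0]))
        assert not adj

    def test_separated_fit_stays_finite(self):
        fit = irls_binomial_fit(two_group_design(), [0, 40], [100, 100])
        est, se, z, p = fit.wald([0.0, 1.0])
        assert fit.adjusted and np.isfinite(z)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 263_373) == pytest.approx(1.8985e-7, rel=1e-4)
        assert bonferroni_threshold(0.05, 202_926) == pytest.approx(2.4640e-7, rel=1e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


@st.composite
def grouped_binomial(draw):
    k = draw(st.integers(3, 6))
    g = np.linspace(0, 1, k)
    n = np.array(draw(st.lists(st.integers(20, 500), min_size=k, max_size=k)), dtype=float)
    p = draw(st.floats(0.1, 0.9))
    slope = draw(st.floats(-1.5, 1.5))
    eta = logit(p) + slope * g
    mu = 1 / (1 + np.exp(-eta))
    y = np.clip(np.round(n * mu), 1, n - 1)
    return g, y, n


class TestBatchSlopeFit:
    def test_matches_generic_irls(self, rng):
        g = np.array([0.0, 13.0, 22.0, 31.0])
        y = rng.integers(5, 50, size=(30, 4)).astype(float)
        n = y + rng.integers(5, 50, size=(30, 4))
        b0, b1, se1, conv, adj = _batch_slope_fit(g, y, n)
        X = np.column_stack([np.ones(4), g])
        for i in range(30):
            fit = irls_binomial_fit(X, y[i], n[i])
            assert b0[i] == pytest.approx(fit.coef[0], abs=1e-6)
            assert b1[i] == pytest.approx(fit.coef[1], abs=1e-8)
            assert se1[i] == pytest.approx(np.sqrt(fit.cov[1, 1]), rel=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(grouped_binomial())
    def test_matches_statsmodels_property(self, data):
        import statsmodels.api as sm

        g, y, n = data
        b0, b1, se1, conv, adj = _batch_slope_fit(g, y[None, :], n[None, :])
        X = np.column_stack([np.ones(len(g)), g])
        sm_fit = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
        assert b1[0] == pytest.approx(sm_fit.params[1], abs=1e-6)
        assert se1[0] == pytest.approx(sm_fit.bse[1], rel=1e-4)


def sites_from_cells(freqs_by_gen, depth, samples_meta):
    """Build a one-SNP SiteCounts with one sample per (generation) entry."""
    samples = [m[0] for m in samples_meta]
    alt = np.array([[int(round(freqs_by_gen[m[3]] * depth)) for m in samples_meta]])
    ref = depth - alt
    sites = SiteCounts(np.array(["I"], dtype=object), np.array([100]),
                       np.array(["A"], dtype=object), np.array(["T"], dtype=object),
                       samples, ref, alt)
    meta = pd.DataFrame(samples_meta, columns=["sample_id", "regime", "replicate", "generation"])
    return sites, meta


MODEL2_META = [
    ("ANC_P1_G0", "ANC", 0, 0),
    ("WS-PO_R1_G13", "WS-PO", 1, 13),
    ("WS-PO_R1_G22", "WS-PO", 1, 22),
    ("WS-PO_R1_G31", "WS-PO", 1, 31),
]


class TestModel2:
    def test_logit_linear_slope_recovered(self):
        # frequencies on the logit line from 0.2 at G0 to 0.4 at G31
        slope = (logit(0.4) - logit(0.2)) / 31
        freqs = {g: 1 / (1 + np.exp(-(logit(0.2) + slope * g))) for g in (0, 13, 22, 31)}
        sites, meta = sites_from_cells(freqs, 100_000, MODEL2_META)
        out = model2_scan(sites, meta, "WS-PO")
        assert out.iloc[0]["estimate"] == pytest.approx(0.98083 / 31, abs=1e-3)

    def test_constant_frequency_not_significant(self):
        sites, meta = sites_from_cells({g: 0.3 for g in (0, 13, 22, 31)}, 1000, MODEL2_META)
        out = model2_scan(sites, meta, "WS-PO")
        assert abs(out.iloc[0]["estimate"]) < 1e-6
        assert not out.iloc[0]["significant"]

    def test_too_few_generations_skipped(self):
        meta3 = MODEL2_META[:2]
        sites, meta = sites_from_cells({0: 0.3, 13: 0.35}, 100, meta3)
        out = model2_scan(sites, meta, "WS-PO")
        assert len(out) == 0

    def test_unknown_regime(self, small_experiment):
        _, counts, meta, _ = small_experiment
        with pytest.raises(ValueError):
            model2_scan(counts, meta, "ANC")

    def test_selected_site_detected(self, small_experiment):
        _, counts, meta, truth = small_experiment
        out = model2_scan(counts, meta, "BS-PO")
        row = out[out["pos"] == counts.pos[10]].iloc[0]
        assert row["significant"] and row["estimate"] > 0

    def test_bonferroni_m_attr(self, small_experiment):
        _, counts, meta, _ = small_experiment
        out = model2_scan(counts, meta, "WS-P&P", alpha=0.05)
        assert out.attrs["m"] == len(out)
        assert out.attrs["bonferroni_threshold"] == pytest.approx(0.05 / len(out))


MODEL1_META = [
    ("ANC_P1_G0", "ANC", 0, 0),
    ("WS-P&P_R1_G31", "WS-P&P", 1, 31),
    ("WS-PO_R1_G31", "WS-PO", 1, 31),
    ("BS-P&P_R1_G31", "BS-P&P", 1, 31),
    ("BS-PO_R1_G31", "BS-PO", 1, 31),
]


class TestModel1:
    def test_all_levels_equal(self):
        sites, meta = sites_from_cells({0: 0.3, 31: 0.3}, 1000, MODEL1_META)
        out = model1_contrasts(sites, meta)
        assert len(out) == 4
        np.testing.assert_allclose(out["z"], 0.0, atol=1e-6)

    def test_saturated_contrast_closed_form(self):
        depth = 10_000
        sites, meta = sites_from_cells({0: 0.2, 31: 0.35}, depth, MODEL1_META)
        out = model1_contrasts(sites, meta)
        # contrast = logit(p_anc) - logit(p_regime), identical for all regimes
        expect = logit(0.2) - logit(0.35)
        np.testing.assert_allclose(out["estimate"], expect, atol=1e-6)

    def test_g13_samples_excluded(self):
        meta_extra = MODEL1_META + [("WS-PO_R1_G13", "WS-PO", 1, 13)]
        freqs = {0: 0.2, 31: 0.35, 13: 0.9}  # wild G13 value must not matter
        sites_a, meta_a = sites_from_cells(freqs, 1000, meta_extra)
        sites_b, meta_b = sites_from_cells({0: 0.2, 31: 0.35}, 1000, MODEL1_META)
        out_a = model1_contrasts(sites_a, meta_a)
        out_b = model1_contrasts(sites_b, meta_b)
        np.testing.assert_allclose(out_a["estimate"], out_b["estimate"], atol=1e-10)
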