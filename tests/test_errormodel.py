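"""Variance model, chi-square normalisation, (K, g) refinement and rejection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflqc.errormodel import (
    NoiseModel,
    SigmaScalingModel,
    chi2,
    group_chi2_terms,
    reject_outliers,
    variance_model,
)
from reflqc.merging import merge
from reflqc.simulate import SimulationConfig, default_ice_contamination, simulate_dataset
from reflqc.symmetry import LAUE_MMM


def group_df(intensities, sigmas, hkl=(1, 2, 3)):
    return pd.DataFrame(
        [
            {"h": hkl[0], "k": hkl[1], "l": hkl[2], "batch": 1, "I": i, "sigma": s, "d": 5.0}
            for i, s in zip(intensities, sigmas)
        ]
    )


class TestVarianceModel:
    def test_all_zero(self):
        nm = NoiseModel(0, 0, 0, g_true=0)
        assert variance_model(0.0, nm) == 0.0

    def test_pure_poisson_term(self):
        nm = NoiseModel(0, 0, 0, g_true=0)
        assert variance_model(400.0, nm) == pytest.approx(400.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        sd=st.floats(0, 10), sr=st.floats(0, 10), sb=st.floats(0, 20),
        g=st.floats(0, 0.2), i=st.floats(0, 1e5),
    )
    def test_physical_form_equals_polynomial_form(self, sd, sr, sb, g, i):
        nm = NoiseModel(sd, sr, sb, g_true=g)
        k0, k1, k2 = nm.k_coefficients
        assert variance_model(i, nm) == pytest.approx(k0 + k1 * i + k2 * i * i, rel=1e-12)


class TestChi2:
    def test_exact_group_has_zero_term(self):
        m = merge(group_df([100.0, 100.0, 100.0], [10.0] * 3), LAUE_MMM)
        assert group_chi2_terms(m).iloc[0] == 0.0

    def test_hand_evaluated_group_term(self):
        # (90, 110), sigma 10: mean 100, sum 2.0, x N/(N-1) = 4.0
        m = merge(group_df([90.0, 110.0], [10.0, 10.0]), LAUE_MMM)
        assert group_chi2_terms(m).iloc[0] == pytest.approx(4.0)
        # observation-weighted average: 4.0 / 2 observations
        assert chi2(m) == pytest.approx(2.0)

    def test_null_simulation_chi2_near_one(self):
        # correctly delivered sigmas, no fractional term: chi2 ~ 1
        nm = NoiseModel(g_true=0.0, K_true=1.0)
        cfg = SimulationConfig(d_min=2.8, noise=nm, seed=42)
        obs, _ = simulate_dataset(cfg)
        assert chi2(merge(obs, LAUE_MMM)) == pytest.approx(1.0, abs=0.05)

    def test_scale_invariance(self, standard_merged):
        df = standard_merged.obs.drop(columns=["asu_h", "asu_k", "asu_l", "group"])
        scaled = df.assign(I=df["I"] * 7.5, sigma=df["sigma"] * 7.5)
        assert chi2(merge(scaled, LAUE_MMM)) == pytest.approx(chi2(standard_merged),
                                                              rel=1e-9)

    def test_no_multiplets_signalled(self):
        m = merge(group_df([100.0], [10.0]), LAUE_MMM)
        with pytest.raises(ValueError):
            chi2(m)


class TestRefinement:
    def test_null_recovery(self):
        # sigmas already correct, no fractional term -> K ~ 1, g ~ 0
        nm = NoiseModel(g_true=0.0, K_true=1.0)
        cfg = SimulationConfig(d_min=2.8, noise=nm, seed=42)
        obs, _ = simulate_dataset(cfg)
        res = SigmaScalingModel(merge(obs, LAUE_MMM)).fit()
        assert res.K == pytest.approx(1.0, abs=0.1)
        assert res.g == pytest.approx(0.0, abs=0.005)
        assert res.chi2_after == pytest.approx(1.0, abs=0.1)

    def test_parameter_recovery_with_analytic_mapping(self):
        # delivered sigmas miss K_true and the (g I)^2 term; refinement
        # should find K ~ K_true and g ~ g_true/sqrt(K_true)
        nm = NoiseModel(g_true=0.03, K_true=1.2)
        cfg = SimulationConfig(d_min=2.6, noise=nm, seed=7)
        obs, truth = simulate_dataset(cfg)
        assert len(truth) >= 5000
        res = SigmaScalingModel(merge(obs, LAUE_MMM)).fit()
        assert res.K == pytest.approx(1.2, rel=0.15)
        assert res.g == pytest.approx(0.03 / np.sqrt(1.2), rel=0.15)
        assert res.chi2_after == pytest.approx(1.0, abs=0.1)

    def test_refinement_is_fixed_point(self):
        cfg = SimulationConfig(d_min=2.8, seed=13)
        obs, _ = simulate_dataset(cfg)
        m = merge(obs, LAUE_MMM)
        first = SigmaScalingModel(m).fit()
        again = SigmaScalingModel(first.apply(m)).fit()
        assert again.K == pytest.approx(1.0, abs=0.1)
        assert again.g == pytest.approx(0.0, abs=0.01)

    def test_degenerate_input_falls_back(self):
        rows = []
        for j in range(60):
            rows.append(group_df([100.0, 100.0], [10.0, 10.0], hkl=(1, 2, j + 1)))
        m = merge(pd.concat(rows, ignore_index=True), LAUE_MMM)
        res = SigmaScalingModel(m).fit()
        assert (res.K, res.g) == (1.0, 0.0)
        assert not res.converged

    def test_too_few_groups_raises(self):
        m = merge(group_df([90.0, 110.0], [10.0, 10.0]), LAUE_MMM)
        with pytest.raises(ValueError, match="groups"):
            SigmaScalingModel(m).fit()


class TestRejection:
    def test_single_gross_outlier_flagged(self):
        # nine I=100 plus one I=200 at sigma 10: the 200 deviates ~10 sigma
        m = merge(group_df([100.0] * 9 + [200.0], [10.0] * 10), LAUE_MMM)
        res = reject_outliers(m, threshold=4.0)
        assert res.n_rejected == 1
        flagged = res.observations[res.observations["rejected_outlier"]]
        assert flagged["I"].tolist() == [200.0]

    def test_all_equal_group_untouched(self):
        m = merge(group_df([100.0] * 6, [10.0] * 6), LAUE_MMM)
        assert reject_outliers(m).n_rejected == 0

    def test_invalid_threshold(self, standard_merged):
        with pytest.raises(ValueError):
            reject_outliers(standard_merged, threshold=0.0)

    def test_ice_contamination_recall(self):
        # redundancy 10 with planted ice: >= 90% of contaminated
        # observations flagged at 4 sigma after sigma correction
        cfg = SimulationConfig(
            d_min=2.6, target_redundancy=10,
            ice_windows=default_ice_contamination(), seed=11,
        )
        obs, _ = simulate_dataset(cfg)
        m = merge(obs, LAUE_MMM)
        res = SigmaScalingModel(m).fit()
        rej = reject_outliers(res.apply(m), threshold=4.0)
        o = rej.observations
        flagged = o["rejected_outlier"].to_numpy(dtype=bool)
        cont = o["contaminated"].to_numpy(dtype=bool)
        recall = (flagged & cont).sum() / cont.sum()
        assert recall >= 0.90
        # and healthy observations are essentially untouched
        fpr = (flagged & ~cont).sum() / (~cont).sum()
        assert fpr < 0.01

    def test_rejection_count_grows_with_redundancy(self):
        rates = {}
        for red in (5, 20):
            cfg = SimulationConfig(
                d_min=2.8, target_redundancy=red,
                ice_windows=default_ice_contamination(), seed=17,
            )
            obs, _ = simulate_dataset(cfg)
            m = merge(obs, LAUE_MMM)
            res = SigmaScalingModel(m).fit()
            rej = reject_outliers(res.apply(m))
            o = rej.observations
            cont = o["contaminated"].to_numpy(dtype=bool)
            fl = o["rejected_outlier"].to_numpy(dtype=bool)
            rates[red] = (fl & cont).sum() / cont.sum()
        assert rates[20] >= rates[5]
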