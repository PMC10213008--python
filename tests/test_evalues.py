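"""Evaluation maps, e-value distributions, and the quantile selection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpevals import (
    BootstrapEnsemble,
    EvalueSummary,
    evaluate_map,
    evalue_distributions,
    reduced_model_point,
    select_snps_mean,
    select_snps_quantile,
)


class TestEvaluateMap:
    def test_reference_mean_scores_one(self):
        m = np.array([1.0, -2.0, 3.0])
        sd = np.array([0.5, 1.0, 2.0])
        assert evaluate_map(m, m, sd, "E1") == 1.0
        assert evaluate_map(m, m, sd, "E2") == 1.0

    @pytest.mark.parametrize(
        "norm, e1, e2", [(1.0, 0.5, np.exp(-1)), (2.0, 0.2, np.exp(-2))]
    )
    def test_closed_form_values(self, norm, e1, e2):
        # one coordinate deviating by `norm` standard deviations
        x = np.array([norm, 0.0])
        zero = np.zeros(2)
        one = np.ones(2)
        assert evaluate_map(x, zero, one, "E1") == pytest.approx(e1)
        assert evaluate_map(x, zero, one, "E2") == pytest.approx(e2)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError, match="positive"):
            evaluate_map(np.ones(2), np.zeros(2), np.array([1.0, 0.0]))

    @given(
        z=st.lists(st.floats(-5, 5), min_size=1, max_size=8).map(np.array)
    )
    @settings(max_examples=50, deadline=None)
    def test_e1_dominates_e2(self, z):
        # exp(r) >= 1 + r^2 for r >= 0, so E1 >= E2 with equality only at z = 0
        e1 = evaluate_map(z, np.zeros_like(z), np.ones_like(z), "E1")
        e2 = evaluate_map(z, np.zeros_like(z), np.ones_like(z), "E2")
        assert 0 < e1 <= 1 and 0 < e2 <= 1
        assert e1 >= e2 - 1e-12


class TestReducedModelPoint:
    def test_zeroes_requested_coordinate(self):
        np.testing.assert_array_equal(
            reduced_model_point(np.array([1.0, 2.0, 3.0]), 1), [1.0, 0.0, 3.0]
        )

    def test_noop_when_already_zero(self):
        theta = np.array([1.0, 0.0, 3.0])
        np.testing.assert_array_equal(reduced_model_point(theta, 1), theta)

    def test_sum_over_drops_reconstructs(self):
        theta = np.array([1.0, 2.0, 3.0, 4.0])
        total = sum(reduced_model_point(theta, j) for j in range(4))
        np.testing.assert_allclose(total, 3 * theta)


def _toy_summary(ref_draws, ev_draws, kind="E2", q_set=(0.5, 0.6, 0.7, 0.8, 0.9)):
    ref = BootstrapEnsemble(draws=np.asarray(ref_draws, float))
    ev = BootstrapEnsemble(draws=np.asarray(ev_draws, float), require_spread=False)
    return ref, ev, evalue_distributions(ref, ev, kind, q_set)


class TestEvalueDistributions:
    def test_matches_per_draw_oracle(self):
        # rank-one-update path vs direct re-evaluation of every dropped model
        rng = np.random.default_rng(0)
        ref_draws = rng.normal(size=(200, 4)) * [1, 2, 0.5, 1] + [0, 1, -1, 3]
        ev_draws = rng.normal(size=(150, 4)) * [1, 2, 0.5, 1] + [0, 1, -1, 3]
        for kind in ("E1", "E2"):
            ref, ev, summary = _toy_summary(ref_draws, ev_draws, kind)
            direct_star = np.array(
                [evaluate_map(x, ref.ref_mean, ref.ref_sd, kind) for x in ev.draws]
            )
            np.testing.assert_allclose(summary.e_star_samples, direct_star, atol=1e-12)
            for j in range(4):
                direct_minus = np.array(
                    [
                        evaluate_map(
                            reduced_model_point(x, j), ref.ref_mean, ref.ref_sd, kind
                        )
                        for x in ev.draws
                    ]
                )
                np.testing.assert_allclose(
                    summary.e_minus_samples[j], direct_minus, atol=1e-12
                )
            np.testing.assert_allclose(
                summary.quantiles_minus[1],
                np.quantile(summary.e_minus_samples[1], summary.q_set),
                atol=1e-12,
            )

    def test_zero_coordinate_draws_make_drop_a_noop(self):
        rng = np.random.default_rng(1)
        ref_draws = rng.normal(size=(300, 3)) + [0.5, 0.0, -0.5]
        ev_draws = rng.normal(size=(300, 3)) + [0.5, 0.0, -0.5]
        ev_draws[:, 1] = 0.0
        ref_draws[:, 1] *= 0.3  # keep reference sd positive
        _, _, summary = _toy_summary(ref_draws, ev_draws)
        np.testing.assert_allclose(
            summary.e_minus_samples[1], summary.e_star_samples, atol=1e-12
        )

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(2)
        ref_draws = rng.normal(size=(400, 5))
        ev_draws = rng.normal(size=(400, 5))
        _, _, base = _toy_summary(ref_draws, ev_draws)
        a = np.array([0.2, 3.0, 1.0, 0.7, 10.0])
        b = np.array([-5.0, 0.0, 2.0, 1.0, 100.0])
        _, _, moved = _toy_summary(ref_draws * a + b, ev_draws * a + b)
        np.testing.assert_allclose(
            moved.e_star_samples, base.e_star_samples, atol=1e-10
        )

    def test_quantile_curves_monotone_in_q(self):
        rng = np.random.default_rng(3)
        _, _, summary = _toy_summary(
            rng.normal(size=(250, 6)), rng.normal(size=(250, 6)) + 0.3
        )
        assert np.all(np.diff(summary.quantiles_star) >= 0)
        assert np.all(np.diff(summary.quantiles_minus, axis=1) >= 0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(4)
        _, _, summary = _toy_summary(
            rng.normal(size=(120, 3)), 5 + rng.normal(size=(120, 3))
        )
        for arr in (summary.e_star_samples, summary.e_minus_samples):
            assert np.all(arr > 0) and np.all(arr <= 1)

    def test_strong_signal_separates_tail_quantiles(self, sim_small_fit):
        from snpevals import GbsConfig, gbs_ensemble

        _, ds, truth, fit = sim_small_fit
        hits = 0
        for seed in range(10):
            ref, ev = gbs_ensemble(
                fit, ds, GbsConfig(s=0.3, B_ref=400, B_eval=400, seed=seed)
            )
            summary = evalue_distributions(ref, ev, "E2")
            ratios = summary.quantile_ratios(0.9)
            strongest = int(np.argmax(np.abs(fit.beta_g / fit.beta_g_se)))
            hits += ratios[strongest] < 1.0
        assert hits >= 9


class TestSelectionRules:
    def _summary_from_quantiles(self, q_minus, q_star):
        # bypass sampling: build a summary with prescribed quantiles
        summary = EvalueSummary.__new__(EvalueSummary)
        summary.q_set = (0.5, 0.6, 0.7, 0.8, 0.9)
        summary.quantiles_star = np.asarray(q_star, float)
        summary.quantiles_minus = np.asarray(q_minus, float)
        summary.mean_star = float(np.mean(q_star))
        summary.mean_minus = np.mean(q_minus, axis=1)
        return summary

    def test_conjunction_over_all_quantiles(self):
        q_star = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        q_minus = np.vstack(
            [
                0.5 * q_star,  # passes at every q
                np.concatenate([[0.35], 0.5 * q_star[1:]]),  # fails only at q=0.5
            ]
        )
        summary = self._summary_from_quantiles(q_minus, q_star)
        assert select_snps_quantile(summary, 0.8) == {0}

    def test_threshold_zero_limit_selects_nothing(self):
        q_star = np.full(5, 0.5)
        q_minus = np.full((3, 5), 1e-9)
        summary = self._summary_from_quantiles(q_minus, q_star)
        assert select_snps_quantile(summary, 1e-12) == set()

    def test_tie_is_not_selected(self):
        q_star = np.full(5, 0.5)
        summary = self._summary_from_quantiles(0.4 * np.ones((1, 5)), q_star)
        assert select_snps_quantile(summary, 0.8) == set()  # 0.4 == 0.8*0.5 exactly

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_selection_nested_in_t(self, seed):
        rng = np.random.default_rng(seed)
        q_star = np.sort(rng.uniform(0.1, 1.0, 5))
        q_minus = np.sort(rng.uniform(0.0, 1.0, (8, 5)), axis=1)
        summary = self._summary_from_quantiles(q_minus, q_star)
        assert select_snps_quantile(summary, 0.5) <= select_snps_quantile(summary, 0.8)

    def test_rejects_invalid_threshold(self):
        summary = self._summary_from_quantiles(np.ones((1, 5)), np.ones(5))
        for t in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                select_snps_quantile(summary, t)

    def test_mean_rule_empty_when_identical(self):
        rng = np.random.default_rng(5)
        ev = rng.normal(size=(200, 3))
        _, _, summary = _toy_summary(rng.normal(size=(200, 3)), ev)
        summary.mean_minus = np.full(3, summary.mean_star)
        assert select_snps_mean(summary) == set()

    def test_mean_rule_catches_strong_signal(self, sim_small_fit):
        from snpevals import GbsConfig, gbs_ensemble

        _, ds, truth, fit = sim_small_fit
        ref, ev = gbs_ensemble(fit, ds, GbsConfig(s=0.3, seed=1))
        summary = evalue_distributions(ref, ev, "E2")
        strongest = int(np.argmax(np.abs(fit.beta_g / fit.beta_g_se)))
        assert strongest in select_snps_mean(summary)

    def test_deterministic_given_seed(self, sim_small_fit):
        from snpevals import GbsConfig, gbs_ensemble

        _, ds, _, fit = sim_small_fit
        sels = []
        for _ in range(2):
            ref, ev = gbs_ensemble(fit, ds, GbsConfig(s=0.5, seed=42))
            summary = evalue_distributions(ref, ev, "E2")
            sels.append(select_snps_quantile(summary, 0.6))
        assert sels[0] == sels[1]
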