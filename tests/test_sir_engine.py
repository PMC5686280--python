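"""SIR engine: importance weighting, weighted resampling without
replacement, iterations and the automated procedure."""

import numpy as np
import pytest

import sirnlme as s
from sirnlme import proposal as prop
from sirnlme.sir_engine import (
    Schedule,
    SirConfig,
    WeightedSample,
    _weighted_order,
    importance_ratio,
    resample,
    run_iteration,
    run_sir,
    weight_sample,
)


def _flat_ws(ir, values=None):
    ir = np.asarray(ir, dtype=float)
    M = ir.size
    if values is None:
        values = np.arange(M, dtype=float)[:, None]
    return WeightedSample(
        values=values, ofv=np.zeros(M), dofv=np.zeros(M),
        relpdf=np.ones(M), ir=ir, reference_ofv=0.0,
    )


class TestImportanceRatio:
    def test_closed_forms(self):
        assert importance_ratio(0.0, 1.0)[0] == 1.0
        assert importance_ratio(2.0 * np.log(4.0), 1.0)[0] == pytest.approx(0.25)
        assert importance_ratio(0.0, 0.5)[0] == pytest.approx(2.0)

    def test_zero_relpdf_gives_zero_ir(self):
        assert importance_ratio(np.array([1.0]), np.array([0.0]))[0] == 0.0

    def test_huge_dofv_underflows_to_zero_not_nan(self):
        out = importance_ratio(np.array([5000.0]), np.array([1e-300]))
        assert out[0] == 0.0 or np.isfinite(out[0])


class TestWeightSample:
    def test_final_estimates_get_unit_weight(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, cov)
        ref = s.evaluate_ofv(fx.model, fx.data, est)
        mask = np.asarray(est.spec.estimated_flags, bool)
        ws = weight_sample(fx.model, fx.data, est.values[None, mask], p, ref)
        assert ws.dofv[0] == pytest.approx(0.0, abs=1e-10)
        assert ws.ir[0] == pytest.approx(1.0, rel=1e-10)

    def test_negative_dofv_warns_and_records_best_vector(self, toy, caplog):
        import logging

        fx, est, cov = toy
        # anchor the reference above the optimum: every vector near the
        # center now beats it
        p = prop.from_covariance(est, cov)
        ref = s.evaluate_ofv(fx.model, fx.data, est) + 5.0
        drawn = prop.sample(p, 100, seed=0)
        with caplog.at_level(logging.WARNING, logger="sirnlme.sir_engine"):
            ws = weight_sample(fx.model, fx.data, drawn.values, p, ref)
        assert ws.n_negative_dofv > 0
        assert ws.best_vector is not None
        assert any("local minimum" in r.message for r in caplog.records)

    def test_all_ir_finite_nonnegative_on_fixture(self, toy_weighted):
        assert np.all(np.isfinite(toy_weighted.ir))
        assert np.all(toy_weighted.ir >= 0.0)

    def test_exact_proposal_gives_flat_weights(self, toy_weighted):
        # proposal = exact sampling distribution of a quadratic-OFV model:
        # IR = exp(-dOFV/2)/relPDF is identically 1
        np.testing.assert_allclose(toy_weighted.ir, 1.0, rtol=1e-8)


class TestResample:
    def test_equal_weights_full_resample_is_permutation(self):
        ws = _flat_ws(np.ones(20))
        idx = resample(ws, 20, seed=0)
        assert sorted(idx) == list(range(20))

    def test_single_positive_weight_always_chosen(self):
        ws = _flat_ws([1.0, 0.0, 0.0])
        for seed in range(20):
            assert resample(ws, 1, seed=seed)[0] == 0

    def test_resamples_are_subset_without_duplicates(self, toy_weighted):
        idx = resample(toy_weighted, 500, seed=3)
        assert len(set(idx.tolist())) == 500
        assert idx.max() < toy_weighted.M

    def test_too_few_positive_weights_aborts(self):
        ws = _flat_ws([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(RuntimeError, match="positive importance ratio"):
            resample(ws, 3, seed=0)

    def test_with_replacement_option_allows_duplicates(self):
        ws = _flat_ws([1.0, 1.0, 1.0])
        idx = resample(ws, 3, seed=0, replacement=True)
        assert idx.size == 3  # duplicates possible, subset not guaranteed

    def test_inclusion_probabilities_match_enumeration(self):
        # 3 vectors, IR=(0.5,0.3,0.2), m=2 without replacement: compare
        # against brute-force enumeration over ordered pairs
        ir = np.array([0.5, 0.3, 0.2])
        ws = _flat_ws(ir)
        exact = np.zeros(3)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                pij = ir[i] / ir.sum() * ir[j] / (ir.sum() - ir[i])
                exact[i] += pij
                exact[j] += pij
        T = 20_000
        counts = np.zeros(3)
        root = np.random.SeedSequence(77)
        for child in root.spawn(T):
            counts[resample(ws, 2, np.random.default_rng(child))] += 1
        np.testing.assert_allclose(counts / T, exact, atol=0.01)

    def test_weighted_order_deterministic_per_seed(self):
        w = np.array([0.2, 0.5, 0.3, 0.0])
        a = _weighted_order(w, np.random.default_rng(1))
        b = _weighted_order(w, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)
        assert a[-1] == 3  # zero weight sorts last


class TestSchedule:
    def test_default_schedule_values(self):
        sched = Schedule()
        assert sched.at(1) == (1000, 200)
        assert sched.at(2) == (1000, 400)
        assert sched.at(3) == (1000, 500)
        assert sched.at(4) == (2000, 1000)
        assert sched.at(11) == (2000, 1000)

    def test_invalid_entry_rejected(self):
        with pytest.raises(ValueError):
            Schedule(entries=((100, 100),))


class TestRunIteration:
    def test_records_schedule_sizes(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, cov)
        ref = s.evaluate_ofv(fx.model, fx.data, est)
        cfg = SirConfig(master_seed=5)
        it = run_iteration(fx.model, fx.data, p, 1000, 200, ref, cfg, index=1)
        assert (it.M, it.m) == (1000, 200)
        assert it.resampled_values.shape == (200, 5)

    def test_exact_posterior_proposal_df_near_parameter_count(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, cov)
        ref = s.evaluate_ofv(fx.model, fx.data, est)
        cfg = SirConfig(master_seed=6)
        it = run_iteration(fx.model, fx.data, p, 2000, 1000, ref, cfg, index=1)
        k = 5
        assert abs(it.df_resamples.df - k) < 0.5 * np.sqrt(2 * k) + 0.5


class TestRunSir:
    def test_converges_from_own_covariance(self, lm_large, lm_large_fit):
        # 200 subjects: the asymptotic covariance is close to the true
        # uncertainty, so the procedure should settle quickly
        fit = lm_large_fit
        p = prop.from_covariance(fit.estimate, fit.covariance)
        res = run_sir(
            lm_large.model, lm_large.data, p,
            config=SirConfig(master_seed=8), reference_ofv=fit.ofv,
        )
        assert res.status == "converged"
        assert res.n_iterations <= 5
        assert res.final_resamples.shape[1] == 4

    def test_shrunk_proposal_triggers_inflation(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, 0.25 * cov)
        res = run_sir(fx.model, fx.data, p, config=SirConfig(master_seed=9))
        assert res.inflation_applied > 1.0

    def test_zero_iterations_returns_initial_diagnostics_only(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, cov)
        res = run_sir(fx.model, fx.data, p, config=SirConfig(master_seed=10, max_iterations=0))
        assert res.status == "max_iterations"
        assert res.n_iterations == 0

    def test_self_normalized_mean_converges_to_posterior_mean(self, toy):
        # importance-weighted mean with (vectors, IR) must match the exact
        # posterior mean of the conjugate toy within Monte-Carlo error
        fx, est, cov = toy
        widened = prop.from_covariance(est, 2.0 * cov)
        drawn = prop.sample(widened, 10_000, seed=11)
        ref = s.evaluate_ofv(fx.model, fx.data, est)
        ws = weight_sample(fx.model, fx.data, drawn.values, widened, ref)
        w = ws.ir / ws.ir.sum()
        post_mean = (w[:, None] * ws.values).sum(axis=0)
        ess = 1.0 / np.sum(w**2)
        mc_se = np.sqrt(np.diag(cov) / ess)
        np.testing.assert_array_less(np.abs(post_mean - est.values), 3.0 * mc_se)

    def test_resample_df_not_above_sample_df_plus_noise(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, cov)
        ref = s.evaluate_ofv(fx.model, fx.data, est)
        cfg = SirConfig(master_seed=12)
        it = run_iteration(fx.model, fx.data, p, 2000, 1000, ref, cfg, index=1)
        assert it.df_resamples.df <= it.df_proposal.df + 1.0

    def test_doubling_m_does_not_inflate_final_df(self, toy):
        fx, est, cov = toy
        ref = s.evaluate_ofv(fx.model, fx.data, est)
        p = prop.from_covariance(est, 1.5 * cov)
        cfg = SirConfig(master_seed=13)
        small = run_iteration(fx.model, fx.data, p, 1000, 500, ref, cfg, index=1)
        big = run_iteration(fx.model, fx.data, p, 2000, 500, ref, cfg, index=2)
        noise = 0.5 * np.sqrt(2 * 5)  # df-estimate noise envelope at k=5
        assert big.df_resamples.df <= small.df_resamples.df + 2 * noise

    def test_reproducible_for_fixed_master_seed(self, toy):
        fx, est, cov = toy
        p = prop.from_covariance(est, cov)
        a = run_sir(fx.model, fx.data, p, config=SirConfig(master_seed=14))
        b = run_sir(fx.model, fx.data, p, config=SirConfig(master_seed=14))
        np.testing.assert_array_equal(a.final_resamples, b.final_resamples)
        assert a.status == b.status
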