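"""Normalization, threshold schedule, MTRRP curves and the derived metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtrrp as M
from mtrrp.metrics import FitError, ScheduleError, _plateau_cutoff
from mtrrp.recurrence import DegenerateInputError
from mtrrp.signals import ParameterError


class TestNormalize:
    def test_basic_example(self):
        np.testing.assert_allclose(
            M.normalize(np.array([2.0, 4, 6])).samples, [0, 0.5, 1])

    def test_identity_on_unit_range(self):
        x = np.array([0.0, 0.25, 0.9, 1.0])
        np.testing.assert_array_equal(M.normalize(x).samples, x)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            M.normalize(np.array([5.0, 5, 5]))

    @given(seed=st.integers(0, 100))
    @settings(derandomize=True, max_examples=30)
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).normal(size=50)
        once = M.normalize(x).samples
        twice = M.normalize(once).samples
        np.testing.assert_array_equal(once, twice)


class TestSchedule:
    def test_arithmetic_example_sigma_02(self):
        """sigma=0.2, Q=0.3 -> step 0.06: 0.10, 0.16, ..., 0.94, 1.00."""
        x = np.array([0.5 - 0.2, 0.5 + 0.2] * 500)  # sd exactly 0.2
        sch = M.build_schedule(x, eps_min=0.1, q=0.3)
        np.testing.assert_allclose(sch.thresholds, np.arange(0.10, 1.001, 0.06))

    def test_arithmetic_example_sigma_05(self):
        x = np.array([0.0, 1.0] * 500)  # sd exactly 0.5
        sch = M.build_schedule(x, eps_min=0.1, q=0.3)
        np.testing.assert_allclose(
            sch.thresholds, [0.10, 0.25, 0.40, 0.55, 0.70, 0.85, 1.00])

    def test_strictly_increasing_within_unit_interval(self):
        x = np.random.default_rng(0).uniform(size=512)
        sch = M.build_schedule(M.normalize(x))
        assert np.all(np.diff(sch.thresholds) > 0)
        assert sch.thresholds[0] == 0.1
        assert sch.thresholds[-1] <= 1.0 + 1e-12

    def test_zero_q_rejected(self):
        with pytest.raises(ScheduleError):
            M.build_schedule(np.array([0.0, 1.0] * 50), q=0.0)

    def test_too_coarse_ladder_rejected(self):
        with pytest.raises(ScheduleError):
            M.build_schedule(np.array([0.0, 1.0] * 50), q=2.0)


class TestMTRRPCurve:
    def test_rates_monotone_and_saturating_on_noise(self):
        for seed in range(5):
            x = M.generate_reference("white_noise", 1000, seed=seed).samples
            c = M.compute_mtrrp(x, embedding=M.EmbeddingConfig(m=2, tau=1))
            assert np.all(np.diff(c.rates) >= 0)
            assert c.rates.max() > 0.95  # reaches saturation before eps=1
            assert np.all((c.rates >= 0) & (c.rates <= 1))

    def test_pair_counting_halves_saturation(self):
        x = M.generate_reference("white_noise", 800, seed=1).samples
        full = M.compute_mtrrp(x, embedding=M.EmbeddingConfig(m=2, tau=1))
        pairs = M.compute_mtrrp(x, embedding=M.EmbeddingConfig(m=2, tau=1),
                                counting="pairs")
        assert pairs.rates.max() <= 0.5
        n = len(x) - 1
        np.testing.assert_allclose(
            pairs.rates, (full.rates * n * n - n) / (2 * n * n), atol=1e-12)

    def test_deterministic(self):
        x = M.generate_fbm(M.FbmSpec(hurst=0.4, n=1024, seed=2)).samples
        a = M.compute_mtrrp(x)
        b = M.compute_mtrrp(x)
        np.testing.assert_array_equal(a.rates, b.rates)
        assert a.embedding == b.embedding

    def test_epoch_averaging_matches_manual(self):
        x = M.generate_reference("white_noise", 1200, seed=3).samples
        emb = M.EmbeddingConfig(m=2, tau=1)
        c = M.compute_mtrrp(x, embedding=emb, epoch_length=600)
        normed = M.normalize(x).samples
        sch = M.build_schedule(normed)
        manual = np.mean([
            M.recurrence_rates(M.embed(normed[:600], emb), sch.thresholds),
            M.recurrence_rates(M.embed(normed[600:], emb), sch.thresholds)],
            axis=0)
        np.testing.assert_allclose(c.rates, manual)

    def test_fbm_low_threshold_ordering_by_hurst(self):
        """Smooth (high-H) fBm recurs more at low thresholds than rough fBm."""
        lo, hi = [], []
        for seed in range(20):
            a = M.generate_fbm(M.FbmSpec(hurst=0.1, n=1024, seed=seed)).samples
            b = M.generate_fbm(M.FbmSpec(hurst=0.9, n=1024, seed=seed)).samples
            emb = M.EmbeddingConfig(m=2, tau=1)
            lo.append(M.compute_mtrrp(a, embedding=emb).rates[0])
            hi.append(M.compute_mtrrp(b, embedding=emb).rates[0])
        assert np.mean(hi) > np.mean(lo)


class TestRecurrenceRateGradient:
    def test_exact_line_recovered(self):
        thr = np.linspace(0.1, 0.7, 7)
        curve = M.MTRRPCurve(thresholds=thr, rates=0.2 + 1.5 * thr)
        assert M.recurrence_rate_gradient(curve) == pytest.approx(1.5, abs=1e-12)

    def test_uniform_max_strategy(self):
        thr = np.linspace(0.1, 1.0, 10)
        rates = np.clip(0.2 + 1.5 * thr, None, 1.0)
        curve = M.MTRRPCurve(thresholds=thr, rates=rates)
        rrg = M.recurrence_rate_gradient(curve, fit_strategy="uniform_max",
                                         uniform_max_eps=0.5)
        assert rrg == pytest.approx(1.5, abs=1e-12)

    def test_instant_plateau_raises(self):
        thr = np.linspace(0.1, 1.0, 10)
        curve = M.MTRRPCurve(thresholds=thr, rates=np.ones(10))
        with pytest.raises(FitError):
            M.recurrence_rate_gradient(curve)

    def test_noise_steeper_than_persistent_fbm(self):
        noise, fbm = [], []
        for seed in range(10):
            x = M.generate_reference("white_noise", 2048, seed=seed).samples
            noise.append(M.recurrence_rate_gradient(M.compute_mtrrp(x)))
            y = M.generate_fbm(M.FbmSpec(hurst=0.9, n=2048, seed=seed)).samples
            fbm.append(M.recurrence_rate_gradient(M.compute_mtrrp(y)))
        assert np.mean(noise) > np.mean(fbm)


class TestRecurrenceHurst:
    @pytest.mark.parametrize("aggregator", ["slope", "median", "mean"])
    @given(rh=st.floats(-1.0, 1.0), alpha=st.floats(0.1, 1.0))
    @settings(derandomize=True, max_examples=60)
    def test_exact_model_round_trip(self, aggregator, rh, alpha):
        """Curves synthesized from the model recover RH to 1e-9."""
        thr = np.linspace(0.1, 0.9, 9)
        rates = alpha * (1 - rh * np.log(thr))
        curve = M.MTRRPCurve(thresholds=thr, rates=rates, alpha=alpha)
        if np.count_nonzero((rates < 1) & (thr < 1)) < 3:
            return  # saturated synthetic curve, outside the estimator contract
        est = M.recurrence_hurst(curve, aggregator=aggregator)
        assert est == pytest.approx(rh, abs=1e-9)

    def test_pointwise_zero_at_alpha(self):
        assert M.pointwise_recurrence_hurst(0.5, 0.3, alpha=0.5) == 0.0

    def test_saturated_curve_rejected(self):
        curve = M.MTRRPCurve(thresholds=np.linspace(0.1, 1.0, 5),
                             rates=np.ones(5))
        with pytest.raises(DegenerateInputError):
            M.recurrence_hurst(curve)

    def test_plateau_cutoff_definition(self):
        thr = np.linspace(0.1, 1.0, 10)
        rates = np.minimum(1.0, 0.2 + 2.0 * thr)
        curve = M.MTRRPCurve(thresholds=thr, rates=rates)
        cut = _plateau_cutoff(curve, 0.95)
        assert cut == thr[np.nonzero(rates >= 0.95)[0][0]]


class TestRecurrenceComplexity:
    def test_product_identity(self):
        assert M.recurrence_complexity(1.5, 0.4) == pytest.approx(0.6)
        assert M.recurrence_complexity(1.5, 0.0) == 0.0
        assert M.recurrence_complexity(-2.0, 0.5) < 0

    def test_metric_triple_consistency(self):
        x = M.generate_fbm(M.FbmSpec(hurst=0.6, n=1024, seed=5)).samples
        curve = M.compute_mtrrp(x)
        t = M.metric_triple(curve)
        assert t.rc == t.rrg * t.rh  # bit-exact product


class TestModelFit:
    def test_joint_fit_recovers_exact_model(self):
        thr = np.linspace(0.1, 0.9, 9)
        rates = 0.4 * (1 - 0.6 * np.log(thr))
        curve = M.MTRRPCurve(thresholds=thr, rates=rates)
        alpha, rh = M.fit_rr_model(curve)
        assert alpha == pytest.approx(0.4, abs=1e-9)
        assert rh == pytest.approx(0.6, abs=1e-9)

    def test_counting_validation(self):
        x = np.random.default_rng(0).normal(size=300)
        with pytest.raises(ParameterError):
            M.compute_mtrrp(x, counting="upper")
        with pytest.raises(ParameterError):
            M.compute_mtrrp(x, counting="pairs", theiler=2)
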