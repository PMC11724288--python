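import numpy as np
import pytest

import taumap as tm


def dwell_list(durations, censored=None):
    if censored is None:
        censored = [False] * len(durations)
    return [tm.DwellRecord(duration=float(d), censored=bool(c))
            for d, c in zip(durations, censored)]


class TestExtractDwells:
    def test_noise_free_single_run(self):
        donor = np.ones(50)
        acceptor = np.zeros(50)
        acceptor[20:30] = 0.5
        donor[20:30] = 0.5
        dwells = tm.extract_dwells(tm.Trace(frame_time=0.2, donor=donor,
                                            acceptor=acceptor))
        assert len(dwells) == 1
        assert dwells[0].duration == pytest.approx(2.0)
        assert not dwells[0].censored

    def test_run_to_trace_end_is_censored(self):
        acceptor = np.zeros(60)
        acceptor[50:] = 0.5
        dwells = tm.extract_dwells(
            tm.Trace(frame_time=0.2, donor=1 - acceptor, acceptor=acceptor))
        assert len(dwells) == 1 and dwells[0].censored

    def test_run_touching_bleach_frame_is_censored(self):
        acceptor = np.zeros(60)
        acceptor[30:40] = 0.5
        t = tm.Trace(frame_time=0.2, donor=1 - acceptor, acceptor=acceptor,
                     bleach_frame=35)
        dwells = tm.extract_dwells(t)
        assert len(dwells) == 1 and dwells[0].censored
        assert dwells[0].duration == pytest.approx(1.0)  # clipped at bleach

    def test_all_flat_trace_yields_no_dwells(self):
        t = tm.Trace(frame_time=0.2, donor=np.ones(100), acceptor=np.zeros(100))
        assert tm.extract_dwells(t) == []

    def test_pure_noise_trace_yields_no_dwells(self):
        rng = np.random.default_rng(4)
        t = tm.Trace(frame_time=0.2, donor=1 + rng.normal(0, 0.02, 600),
                     acceptor=rng.normal(0, 0.02, 600))
        assert tm.extract_dwells(t) == []

    def test_ground_truth_recovery_from_synthetic_traces(self):
        traces = tm.gen_traces(tm.TraceSimConfig(n_traces=500, seed=5))
        n_true = n_rec = 0
        for t in traces:
            dwells = tm.extract_dwells(t)
            for s, e in t.bound_intervals:
                if e - s < 3:
                    continue
                n_true += 1
                target = (e - s) * t.frame_time
                if any(abs(d.duration - target) <= t.frame_time + 1e-9
                       for d in dwells):
                    n_rec += 1
        assert n_true > 500
        assert n_rec / n_true >= 0.95

    def test_single_bleach_step_detected(self):
        from taumap.dwell_kinetics import detect_bleach_step
        rng = np.random.default_rng(6)
        donor = np.concatenate([np.ones(200), np.zeros(100)])
        donor += rng.normal(0, 0.02, 300)
        t = tm.Trace(frame_time=0.2, donor=donor,
                     acceptor=rng.normal(0, 0.02, 300))
        frame, single = detect_bleach_step(t)
        assert single and abs(frame - 200) <= 2

    def test_stepless_trace_flagged_as_no_single_bleach(self):
        from taumap.dwell_kinetics import detect_bleach_step
        rng = np.random.default_rng(8)
        t = tm.Trace(frame_time=0.2, donor=1 + rng.normal(0, 0.02, 300),
                     acceptor=rng.normal(0, 0.02, 300))
        _, single = detect_bleach_step(t)
        assert not single


class TestFitExpMixture:
    def test_k1_mle_is_sample_mean(self):
        fit = tm.fit_exp_mixture(dwell_list([2.0] * 12), k=1)
        assert fit.lifetimes[0] == pytest.approx(2.0)
        rng = np.random.default_rng(0)
        d = rng.exponential(3.0, 500)
        fit = tm.fit_exp_mixture(dwell_list(d), k=1)
        assert fit.lifetimes[0] == pytest.approx(float(np.mean(d)), rel=1e-12)

    def test_k1_with_censoring_total_time_over_events(self):
        # tau_hat = (sum of all durations) / (# uncensored)
        d = [1.0, 2.0, 3.0] * 5
        c = [False, False, True] * 5
        fit = tm.fit_exp_mixture(dwell_list(d, c), k=1)
        assert fit.lifetimes[0] == pytest.approx(sum(d) / 10)

    def test_k1_truncation_correction(self):
        # durations measured from t0: lifetime = mean(d - t0)
        rng = np.random.default_rng(1)
        d = 0.2 + rng.exponential(1.5, 1000)
        fit = tm.fit_exp_mixture(dwell_list(d), k=1, truncation=0.2)
        assert fit.lifetimes[0] == pytest.approx(float(np.mean(d - 0.2)), rel=1e-9)

    def test_k2_recovers_ab_construct_parameters(self, ab_dwells):
        fit = tm.fit_exp_mixture(ab_dwells, k=2)
        assert fit.converged and fit.k == 2
        assert fit.lifetimes[0] == pytest.approx(1.2, rel=0.10)
        assert fit.lifetimes[1] == pytest.approx(49.0, rel=0.10)
        assert fit.weights[0] == pytest.approx(0.615, abs=0.05)
        assert fit.lifetimes[0] < fit.lifetimes[1]

    def test_k2_recovers_mutant_construct_weight(self):
        cfg = tm.DwellSimConfig(n_dwells=10_000, lifetimes=(0.8, 54.0),
                                weights=(0.8, 0.2), frame_time=None, seed=29)
        fit = tm.fit_exp_mixture(tm.gen_dwells(cfg), k=2)
        assert fit.weights[0] == pytest.approx(0.8, abs=0.05)

    def test_k2_collapses_to_k1_on_single_component_data(self):
        rng = np.random.default_rng(2)
        d = rng.exponential(2.0, 2000)
        fit = tm.fit_exp_mixture(dwell_list(d), k=2)
        # either collapse to k=1 or nearly equal lifetimes with same mean scale
        if fit.k == 2:
            assert np.average(fit.lifetimes, weights=fit.weights) == pytest.approx(
                float(np.mean(d)), rel=0.05)
        else:
            assert fit.lifetimes[0] == pytest.approx(float(np.mean(d)), rel=1e-6)

    def test_censoring_aware_fit_unbiased(self):
        # right-censor everything above 6 s; naive mean underestimates tau
        rng = np.random.default_rng(3)
        raw = rng.exponential(2.0, 5000)
        cens = raw > 6.0
        d = np.minimum(raw, 6.0)
        fit = tm.fit_exp_mixture(dwell_list(d, cens), k=1)
        assert fit.lifetimes[0] == pytest.approx(2.0, rel=0.05)
        assert float(np.mean(d)) < fit.lifetimes[0]  # naive mean is biased down

    def test_left_truncation_correction_removes_bias(self):
        # left-truncated observation: dwells below one frame are unobservable;
        # by memorylessness the observed law is 0.2 + Exp(tau)
        rng = np.random.default_rng(31)
        d = 0.2 + rng.exponential(1.2, 20_000)
        biased = tm.fit_exp_mixture(dwell_list(d), k=1)
        corrected = tm.fit_exp_mixture(dwell_list(d), k=1, truncation=0.2)
        assert biased.lifetimes[0] == pytest.approx(1.4, rel=0.05)  # upward bias
        assert corrected.lifetimes[0] == pytest.approx(1.2, rel=0.05)

    def test_too_few_uncensored_dwells_rejected(self):
        with pytest.raises(ValueError):
            tm.fit_exp_mixture(dwell_list([1.0] * 5), k=1)

    def test_bootstrap_sd_reported(self):
        rng = np.random.default_rng(5)
        d = rng.exponential(2.0, 200)
        fit = tm.fit_exp_mixture(dwell_list(d), k=1, n_bootstrap=50, seed=1)
        assert fit.bootstrap_sd is not None
        # sd of the mean of n exponentials ~ tau/sqrt(n)
        assert fit.bootstrap_sd["lifetime_0"] == pytest.approx(
            2.0 / np.sqrt(200), rel=0.5)


class TestModelSelect:
    def test_single_exponential_data_prefers_k1(self):
        cfg = tm.DwellSimConfig(n_dwells=10_000, lifetimes=(2.0,), weights=(1.0,),
                                frame_time=None, seed=37)
        sel = tm.model_select(tm.gen_dwells(cfg))
        assert sel.k == 1

    def test_separated_mixture_prefers_k2(self):
        cfg = tm.DwellSimConfig(n_dwells=10_000, lifetimes=(1.0, 50.0),
                                weights=(0.6, 0.4), frame_time=None, seed=41)
        sel = tm.model_select(tm.gen_dwells(cfg))
        assert sel.k == 2 and sel.delta_bic > 0

    def test_small_ambiguous_sample_prefers_parsimony(self):
        rng = np.random.default_rng(43)
        d = rng.exponential(2.0, 12)
        sel = tm.model_select(dwell_list(d))
        assert sel.k == 1


class TestMedianLifetime:
    def test_exponential_median_is_tau_ln2(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(3.0, 100_000)
        est = tm.median_lifetime(dwell_list(d), n_bootstrap=50, seed=1)
        assert est.median == pytest.approx(3.0 * np.log(2.0), rel=0.02)

    def test_single_dwell(self):
        est = tm.median_lifetime(dwell_list([5.0]), n_bootstrap=10, seed=1)
        assert est.median == 5.0

    def test_mixture_median_matches_analytic_root(self):
        from scipy.optimize import brentq
        analytic = brentq(
            lambda t: 0.615 * np.exp(-t / 1.2) + 0.385 * np.exp(-t / 49.0) - 0.5,
            1e-6, 50.0)
        assert analytic == pytest.approx(1.87, abs=0.01)
        cfg = tm.DwellSimConfig(n_dwells=100_000, lifetimes=(1.2, 49.0),
                                weights=(0.615, 0.385), frame_time=None, seed=47)
        est = tm.median_lifetime(tm.gen_dwells(cfg), n_bootstrap=50, seed=1)
        assert est.median == pytest.approx(analytic, rel=0.03)
        assert 1.0 <= est.median <= 3.0  # within the reported 2 +/- 1 s

    def test_censored_dwells_excluded(self):
        est = tm.median_lifetime(dwell_list([1.0, 2.0, 3.0, 100.0],
                                            [False, False, False, True]),
                                 n_bootstrap=10, seed=1)
        assert est.median == 2.0


class TestComputeFret:
    def test_equal_channels_give_half(self):
        e = tm.compute_fret(np.ones(10), np.ones(10))
        np.testing.assert_allclose(e, 0.5)

    def test_zero_acceptor_gives_zero(self):
        e = tm.compute_fret(np.ones(10), np.zeros(10))
        np.testing.assert_allclose(e, 0.0)

    def test_zero_total_intensity_is_nan(self):
        e = tm.compute_fret(np.zeros(3), np.zeros(3))
        assert np.all(np.isnan(e))

    def test_crosstalk_and_gamma_corrections(self):
        # D=0.5, A=0.6 with crosstalk 0.1 and gamma 2:
        # a = 0.6 - 0.1*0.5 = 0.55 ; E = 0.55 / (2*0.5 + 0.55)
        e = tm.compute_fret(np.array([0.5]), np.array([0.6]),
                            crosstalk=0.1, gamma=2.0)
        assert e[0] == pytest.approx(0.55 / 1.55)

    def test_known_efficiency_recovered_from_trace(self):
        cfg = tm.TraceSimConfig(n_traces=5, seed=9, fret_state_means=(0.7,),
                                fret_state_sds=(0.0,), fret_transition_rate=0.0,
                                noise_sd=0.01)
        traces = tm.gen_traces(cfg)
        vals = []
        for t in traces:
            e = tm.compute_fret(t.donor, t.acceptor)
            for s, end in t.bound_intervals:
                vals.extend(e[s:end])
        assert len(vals) > 50
        assert float(np.nanmean(vals)) == pytest.approx(0.7, abs=0.02)


class TestFitGaussianComponents:
    def test_single_tight_component(self):
        rng = np.random.default_rng(11)
        vals = 0.5 + rng.normal(0, 0.01, 500)
        fit = tm.fit_gaussian_components(np.clip(vals, 0, 1), 1, seed=1)
        assert fit.means[0] == pytest.approx(0.5, abs=0.01)

    def test_two_planted_components_recovered(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([
            rng.normal(0.3, 0.08, 5000), rng.normal(0.7, 0.08, 5000)])
        fit = tm.fit_gaussian_components(np.clip(vals, 0, 1), 2, seed=1)
        assert fit.means[0] == pytest.approx(0.3, abs=0.02)
        assert fit.means[1] == pytest.approx(0.7, abs=0.02)

    def test_two_state_trace_data_prefers_two_components_by_bic(self):
        cfg = tm.TraceSimConfig(n_traces=30, seed=15,
                                fret_state_means=(0.3, 0.7),
                                fret_state_sds=(0.03, 0.03),
                                noise_sd=0.01)
        traces = tm.gen_traces(cfg)
        vals = []
        for t in traces:
            e = tm.compute_fret(t.donor, t.acceptor)
            for s, end in t.bound_intervals:
                vals.extend(e[s:end])
        vals = np.clip(np.array(vals), 0, 1)
        fit1 = tm.fit_gaussian_components(vals, 1, seed=1)
        fit2 = tm.fit_gaussian_components(vals, 2, seed=1)
        assert fit2.bic < fit1.bic

    def test_out_of_range_values_clipped_with_warning(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(0.5, 0.3, 200)
        with pytest.warns(UserWarning):
            fit = tm.fit_gaussian_components(vals, 1, seed=1)
        assert 0.0 <= fit.means[0] <= 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tm.fit_gaussian_components(np.full(10, 0.5), 1)
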