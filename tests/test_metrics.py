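import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from actimetry import (ActivityTransformer, DatasetSeries, EpochParams,
                       RawRecording, ScenarioParams, activity_index,
                       compute_activity, enmo, epochs,
                       estimate_noise_variance, generate_recording, hfen,
                       mad, pim, tat, zcm)
from actimetry.exceptions import (ApplicabilityError, ParameterError,
                                  SizeError)

TS = 0.1
EP = EpochParams(60.0)


class TestEpochs:
    def test_floor_division_drops_remainder(self):
        w = epochs(np.arange(1250.0), EP, TS)
        assert w.shape == (2, 600)
        np.testing.assert_array_equal(w[0], np.arange(600.0))

    def test_exactly_one_epoch(self):
        assert epochs(np.arange(600.0), EP, TS).shape == (1, 600)

    def test_too_short_rejected(self):
        with pytest.raises(SizeError):
            epochs(np.arange(599.0), EP, TS)

    def test_non_multiple_epoch_length_rejected(self):
        with pytest.raises(ParameterError):
            EpochParams(60.05).samples_per_epoch(TS)


@pytest.fixture(scope="module")
def random_epochs():
    rng = np.random.default_rng(1234)
    return rng.normal(1.0, 0.5, (1000, 60))


class TestMetricOracleEquivalence:
    """Every vectorized kernel matches the naive scalar-loop oracle."""

    def test_pim_riemann(self, random_epochs):
        got = pim(random_epochs, TS, rule="riemann")
        want = [oracles.pim_riemann(e, TS) for e in random_epochs]
        assert np.max(np.abs(got - want)) < 1e-12

    def test_zcm(self, random_epochs):
        level = 1.0
        got = zcm(random_epochs, level)
        want = [oracles.zcm_loop(e, level) for e in random_epochs]
        assert np.max(np.abs(got - np.asarray(want, float))) == 0

    def test_tat(self, random_epochs):
        got = tat(random_epochs, 1.0, TS)
        want = [oracles.tat_loop(e, 1.0, TS) for e in random_epochs]
        assert np.max(np.abs(got - want)) < 1e-12

    def test_mad(self, random_epochs):
        got = mad(random_epochs)
        want = [oracles.mad_loop(e) for e in random_epochs]
        assert np.max(np.abs(got - want)) < 1e-12

    def test_enmo(self, random_epochs):
        got = enmo(random_epochs)
        want = [oracles.enmo_loop(e) for e in random_epochs]
        assert np.max(np.abs(got - want)) < 1e-12

    def test_hfen(self, random_epochs):
        x = np.abs(random_epochs)
        got = hfen(x)
        want = [oracles.hfen_loop(e) for e in x]
        assert np.max(np.abs(got - want)) < 1e-12

    @pytest.mark.parametrize("variant", ["linear", "sqrt"])
    def test_activity_index(self, variant):
        rng = np.random.default_rng(99)
        ex, ey, ez = rng.normal(0, 0.3, (3, 200, 60))
        nv = 0.01
        got = activity_index(ex, ey, ez, nv, variant=variant)
        want = [oracles.ai_loop(a, b, c, nv, variant)
                for a, b, c in zip(ex, ey, ez)]
        assert np.max(np.abs(got - want)) < 1e-12


class TestPim:
    def test_simple_riemann_sum(self):
        assert pim(np.array([1.0, 2.0, 3.0]), 0.1) == pytest.approx(0.6)

    def test_constant_epoch(self):
        c, n = 2.5, 600
        assert pim(np.full(n, c), TS) == pytest.approx(c * n * TS)

    def test_simpson38_exact_on_cubic(self):
        # 100 samples -> 99 intervals, a multiple of 3: pure 3/8 panels
        t = np.linspace(0.0, 9.9, 100)
        x = 2 * t ** 3 - 3 * t ** 2 + t + 5
        exact = (0.5 * 9.9 ** 4 - 9.9 ** 3 + 0.5 * 9.9 ** 2 + 5 * 9.9)
        got = pim(x, TS, rule="simpson38")
        assert got == pytest.approx(exact, rel=1e-10)

    def test_simpson38_tail_handled(self):
        # 600 samples -> 599 intervals = 199 panels + 2 trapezoid intervals
        t = np.arange(600) * TS
        x = np.sin(0.2 * t) + 2
        riemann = pim(x, TS)
        simpson = pim(x, TS, rule="simpson38")
        assert simpson == pytest.approx(riemann, rel=5e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_homogeneity(self, a):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 120)
        assert pim(a * x, TS) == pytest.approx(a * pim(x, TS))


class TestZcm:
    def test_enumerated_crossings(self):
        assert zcm(np.array([0.2, 0.8, 0.3, 0.9]), 0.5) == 3

    def test_constant_series_never_crosses(self):
        assert zcm(np.full(50, 0.3), 0.5) == 0

    def test_sinusoid_120_crossings_per_minute(self):
        """1 Hz sinusoid, 10 Hz sampling, 60 s epoch, level 0.

        A quarter-period phase offset keeps the zeros of the waveform off
        the sample grid; the continuous signal then crosses zero 120 times
        within the epoch.  Verified against the enumeration oracle.
        """
        t = np.arange(600) * TS
        x = np.cos(2 * np.pi * 1.0 * t)
        assert zcm(x, 0.0) == 120
        assert oracles.zcm_loop(x, 0.0) == 120

    def test_exact_level_samples_inherit_side(self):
        # 0.5 samples sit on the level: +,T,- is one crossing, not two
        assert zcm(np.array([0.8, 0.5, 0.2]), 0.5) == 1
        # +,T,+ is no crossing
        assert zcm(np.array([0.8, 0.5, 0.9]), 0.5) == 0
        # leading on-level samples are ignored
        assert zcm(np.array([0.5, 0.5, 0.9, 0.2]), 0.5) == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_loop_oracle_on_random_epochs(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(0.5, 0.3, 80), 2)  # ties with the level
        assert zcm(x, 0.5) == oracles.zcm_loop(x, 0.5)


class TestTat:
    def test_enumerated(self):
        assert tat(np.array([0.2, 0.8, 0.9, 0.1]), 0.5, TS) == \
            pytest.approx(0.2)

    def test_all_above_gives_full_epoch(self):
        x = np.full(600, 2.0)
        assert tat(x, 0.5, TS) == pytest.approx(60.0)

    def test_square_wave_duty_cycle(self):
        """TAT of a duty-d square wave is d * T_e within one sample."""
        d = 0.3
        period = 100  # samples
        x = np.tile(np.r_[np.ones(int(d * period)),
                          np.zeros(period - int(d * period))], 6)
        got = tat(x, 0.5, TS)
        assert abs(got - d * 60.0) <= TS

    def test_boundary_samples_not_counted(self):
        assert tat(np.array([0.5, 0.5, 0.6]), 0.5, TS) == pytest.approx(TS)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.0, 0.5), st.floats(0.5, 1.5))
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1.5, 200)
        assert tat(x, t2, TS) <= tat(x, t1, TS)


class TestMadEnmoHfen:
    def test_mad_example(self):
        assert mad(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0 / 3.0)

    def test_mad_constant_epoch_zero(self):
        assert mad(np.full(60, 1.7)) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-2, 2))
    def test_mad_offset_invariant(self, c):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 100)
        assert mad(x + c) == pytest.approx(mad(x), abs=1e-12)

    def test_enmo_example(self):
        assert enmo(np.array([1.2, 0.8, 1.0])) == pytest.approx(0.2 / 3)

    def test_enmo_resting_zero(self):
        assert enmo(np.ones(600)) == 0.0

    def test_enmo_clipping_ignores_subgravity_values(self):
        assert enmo(np.array([0.1, 0.9, 0.99])) == 0.0

    def test_hfen_is_epoch_mean(self):
        x = np.abs(np.random.default_rng(0).normal(0, 0.2, 600))
        assert hfen(x) == pytest.approx(np.mean(x))

    def test_hfen_scales_with_motion_amplitude(self):
        """Linear filter + norm homogeneity: scaling axial motion by a
        scales HFEN by a (gravity-free synthetic input)."""
        from actimetry.preprocess import hfen_magnitude
        rng = np.random.default_rng(8)
        base = rng.normal(0, 0.1, (1200, 3))
        a = 2.5
        rec1 = RawRecording(*base.T, sampling_interval=TS)
        rec2 = RawRecording(*(a * base).T, sampling_interval=TS)
        h1 = hfen(epochs(hfen_magnitude(rec1).values, EP, TS))
        h2 = hfen(epochs(hfen_magnitude(rec2).values, EP, TS))
        np.testing.assert_allclose(h2, a * h1, rtol=1e-6)


class TestActivityIndex:
    def test_all_constant_axes_zero(self):
        e = np.ones(60)
        assert activity_index(e, e, e, 0.0) == 0.0

    def test_noise_matched_variance_zero(self):
        rng = np.random.default_rng(2)
        ex, ey, ez = rng.normal(0, 0.1, (3, 60))
        nv = float(np.mean([ex.var(), ey.var(), ez.var()]))
        assert activity_index(ex, ey, ez, nv) == pytest.approx(0.0, abs=1e-3)

    def test_floor_at_zero(self):
        e = np.ones(60)
        assert activity_index(e, e, e, 5.0) == 0.0

    def test_sqrt_variant(self):
        rng = np.random.default_rng(2)
        ex, ey, ez = rng.normal(0, 0.3, (3, 60))
        lin = activity_index(ex, ey, ez, 0.0, variant="linear")
        sq = activity_index(ex, ey, ez, 0.0, variant="sqrt")
        assert sq == pytest.approx(np.sqrt(lin))


class TestNoiseVarianceEstimation:
    def test_pure_noise_recovers_variance(self):
        rng = np.random.default_rng(21)
        sigma = 0.02
        xyz = rng.normal(0, sigma, (12000, 3))
        rec = RawRecording(*xyz.T, sampling_interval=TS)
        nm = estimate_noise_variance(rec, EP, quantile=0.5)
        assert nm.variance == pytest.approx(sigma ** 2, rel=0.1)

    def test_constant_recording_zero(self):
        n = 6000
        rec = RawRecording(np.zeros(n), np.zeros(n), np.ones(n),
                           sampling_interval=TS)
        assert estimate_noise_variance(rec, EP).variance == 0.0

    def test_motion_bursts_do_not_inflate_estimate(self):
        """Still segments dominate the low quantile despite bursts."""
        p0 = ScenarioParams(duration_s=3600.0, burst_amplitude_g=0.0,
                            drift_rate=0.0, noise_g=0.015,
                            quantization_g=0.0, seed=31,
                            initial_orientation=(0.0, 0.0, 1.0))
        rec0, _ = generate_recording(p0)
        from dataclasses import replace
        rec1, _ = generate_recording(replace(p0, burst_amplitude_g=0.15))
        v0 = estimate_noise_variance(rec0, EP).variance
        v1 = estimate_noise_variance(rec1, EP).variance
        assert v1 == pytest.approx(v0, rel=0.15)

    def test_too_few_epochs_rejected(self):
        rec = RawRecording(*np.zeros((3, 1200)), sampling_interval=TS)
        with pytest.raises(SizeError):
            estimate_noise_variance(rec, EP)


class TestApplicabilityMatrix:
    def _series(self, kind, values=None):
        vals = values if values is not None else np.abs(
            np.random.default_rng(0).normal(1, 0.1, 1200))
        return DatasetSeries(kind=kind, values=vals, sampling_interval=TS)

    def test_pim_on_raw_axial_rejected(self):
        triple = [self._series(k, np.random.default_rng(0).normal(0, 1, 600))
                  for k in ("UFX", "UFY", "UFZ")]
        with pytest.raises((ApplicabilityError, ParameterError)):
            compute_activity(triple[0], "PIMr", EP)

    def test_enmo_on_filtered_magnitude_rejected(self):
        s = DatasetSeries(kind="FMpost",
                          values=np.random.default_rng(0).normal(0, .1, 600),
                          sampling_interval=TS)
        with pytest.raises(ApplicabilityError):
            compute_activity(s, "ENMO", EP)

    def test_mad_per_axis_allowed(self):
        s = DatasetSeries(kind="UFY",
                          values=np.random.default_rng(0).normal(0, .5, 600),
                          sampling_interval=TS)
        out = compute_activity(s, "MAD", EP)
        assert out.metric_id == "MAD"
        assert out.dataset_kind == "UFY"
        assert len(out) == 1

    def test_zcm_without_threshold_rejected(self):
        with pytest.raises(ParameterError):
            compute_activity(self._series("UFNM"), "ZCM", EP)

    def test_pim_rectifies_signed_datasets(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.2, 600)
        s = DatasetSeries(kind="FMpost", values=vals, sampling_interval=TS)
        out = compute_activity(s, "PIMr", EP)
        assert out.values[0] == pytest.approx(TS * np.sum(np.abs(vals)))
        assert out.params["rectified"] is True

    def test_zcm_integer_range_invariant(self, short_datasets):
        from actimetry import sd_threshold
        s = short_datasets["UFNM"]
        out = compute_activity(s, "ZCM", EP, threshold=sd_threshold(s))
        assert np.all(out.values == np.round(out.values))
        assert np.all((out.values >= 0) & (out.values <= 599))

    def test_tat_bounded_by_epoch_length(self, short_datasets):
        from actimetry import sd_threshold
        s = short_datasets["UFNM"]
        out = compute_activity(s, "TAT", EP, threshold=sd_threshold(s))
        assert np.all((out.values >= 0) & (out.values <= 60.0))


class TestActivityTransformer:
    def test_sklearn_protocol(self, short_recording):
        from sklearn.base import clone
        rec, _ = short_recording
        X = rec.as_array()
        est = ActivityTransformer(metric="ZCM", dataset="UFNM")
        assert clone(est).get_params() == est.get_params()
        Y = est.fit_transform(X)
        assert Y.shape == (60, 1)
        assert est.threshold_.mode == "sd_adaptive"
        assert est.get_feature_names_out()[0] == "ZCM(UFNM)"

    def test_matches_functional_path(self, short_recording, short_datasets):
        from actimetry import sd_threshold
        rec, _ = short_recording
        est = ActivityTransformer(metric="TAT", dataset="UFM").fit(
            rec.as_array())
        s = short_datasets["UFM"]
        direct = compute_activity(s, "TAT", EP, threshold=sd_threshold(s))
        np.testing.assert_allclose(est.transform(rec.as_array())[:, 0],
                                   direct.values)

    def test_ai_learns_noise_variance(self, short_recording):
        rec, _ = short_recording
        est = ActivityTransformer(metric="AI", dataset="UFXYZ").fit(
            rec.as_array())
        assert est.noise_variance_ >= 0
        Y = est.transform(rec.as_array())
        assert np.all(Y >= 0)

    def test_pipeline_composition(self, short_recording):
        from sklearn.pipeline import Pipeline
        rec, _ = short_recording
        pipe = Pipeline([
            ("act", ActivityTransformer(metric="MAD", dataset="UFM")),
        ])
        Y = pipe.fit_transform(rec.as_array())
        assert Y.shape == (60, 1)

    def test_disallowed_pair_raises_at_fit(self, short_recording):
        rec, _ = short_recording
        with pytest.raises(ApplicabilityError):
            ActivityTransformer(metric="ENMO", dataset="FMpost").fit(
                rec.as_array())
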