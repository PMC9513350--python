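"""Hill dose-response fitting and synthetic VSD movie generation."""

import numpy as np
import pytest

from icmsim.response_model import (
    FIELD_MM,
    HillFitError,
    HillParams,
    ResponseKinetics,
    StimSource,
    VSDMovie,
    charges_from_amplitudes,
    fit_hill,
    hill_response,
    line_profile,
    peak_amplitude,
    roi_bbox,
    synth_dose_response,
    synth_vsd_movie,
)

P = HillParams(0.9, 2.4, 2.5)


class TestHillResponse:
    def test_zero_at_threshold(self):
        assert hill_response(P.i_th, P) == 0.0
        assert hill_response(0.0, P) == 0.0

    def test_half_maximum_at_i50(self):
        assert hill_response(P.i_50, P) == pytest.approx(0.5)

    def test_value_matches_direct_formula(self):
        # independent oracle: direct arithmetic on the threshold-shifted Hill
        q = 4.0
        expected = (q - 0.9) ** 2.5 / ((q - 0.9) ** 2.5 + (2.4 - 0.9) ** 2.5)
        assert hill_response(q, P) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.859946, abs=5e-6)

    def test_continuous_at_threshold_strictly_increasing_bounded(self):
        q = np.linspace(0, 20, 2001)
        r = hill_response(q, P)
        assert r[q <= P.i_th].max() == 0.0
        above = r[q > P.i_th]
        assert np.all(np.diff(above) > 0)
        assert np.all((r >= 0) & (r < 1))
        # continuity: response just above threshold is still ~0
        assert hill_response(P.i_th + 1e-9, P) < 1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HillParams(2.4, 0.9, 2.5)
        with pytest.raises(ValueError):
            HillParams(0.9, 2.4, 0.0)
        with pytest.raises(ValueError):
            hill_response(-1.0, P)


class TestFitHill:
    # the 8-level charge series of a ~5 uA-step, 0.2 ms/phase amplitude sweep
    CHARGES = charges_from_amplitudes([5, 10, 15, 20, 25, 30, 35, 40], 0.2)

    def test_charge_series_links_to_dac_quantization(self):
        # charge = quantized amplitude x phase duration, in nC
        assert self.CHARGES[0] == pytest.approx(0.9375)  # 3 codes * 1.5625 uA * 0.2 ms
        assert self.CHARGES[-1] == pytest.approx(8.125)

    def test_noiseless_recovery_to_machine_tolerance(self):
        params, resid = fit_hill(self.CHARGES, hill_response(self.CHARGES, P))
        assert params.i_th == pytest.approx(P.i_th, rel=1e-6)
        assert params.i_50 == pytest.approx(P.i_50, rel=1e-6)
        assert params.n == pytest.approx(P.n, rel=1e-6)
        assert resid < 1e-8

    def test_degenerate_data_raises(self):
        with pytest.raises(HillFitError):
            fit_hill(self.CHARGES, np.zeros(8))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1, 2, 3], [0.1, 0.5, 0.9])

    def test_monte_carlo_i50_recovery_under_noise(self):
        # 200 seeded replicates at sigma = 0.05: median |i50 error| < 10%,
        # bias < 5% -- the desk-scale stand-in for the in-vivo fit
        rel_errors = []
        estimates = []
        for rep in range(200):
            df = synth_dose_response(P, self.CHARGES, noise_sd=0.05, seed=1000 + rep)
            try:
                params, _ = fit_hill(df["charge_nC"], df["response_norm"])
            except HillFitError:
                continue
            estimates.append(params.i_50)
            rel_errors.append(abs(params.i_50 - P.i_50) / P.i_50)
        assert len(rel_errors) >= 195
        assert np.median(rel_errors) < 0.10
        bias = abs(np.mean(estimates) - P.i_50) / P.i_50
        assert bias < 0.05


class TestSynthMovie:
    def test_deterministic_given_seed(self):
        src = [StimSource(3.0, 3.0, 4.0)]
        m1 = synth_vsd_movie(src, noise_sd=0.02, seed=7)
        m2 = synth_vsd_movie(src, noise_sd=0.02, seed=7)
        assert np.array_equal(m1.frames, m2.frames)
        m3 = synth_vsd_movie(src, noise_sd=0.02, seed=8)
        assert not np.array_equal(m1.frames, m3.frames)

    def test_zero_charge_movie_is_pure_noise(self):
        noise_sd = 0.05
        movie = synth_vsd_movie([StimSource(3.0, 3.0, 0.0)], noise_sd=noise_sd, seed=3)
        r0, r1, c0, c1 = roi_bbox(3.0, 3.0, 0.5)
        vals = movie.frames[:, r0:r1, c0:c1]
        sem = noise_sd / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * sem

    def test_trial_averaging_shrinks_noise(self):
        src = [StimSource(3.0, 3.0, 0.0)]
        m1 = synth_vsd_movie(src, noise_sd=0.05, seed=3, n_trials=1)
        m16 = synth_vsd_movie(src, noise_sd=0.05, seed=3, n_trials=16)
        assert m16.frames.std() == pytest.approx(m1.frames.std() / 4, rel=0.05)

    def test_peak_time_equals_kinetics_t_peak(self):
        k = ResponseKinetics()
        movie = synth_vsd_movie([StimSource(3.0, 3.0, 4.0)], k=k)
        amp, t_peak = peak_amplitude(movie, roi_bbox(3.0, 3.0, 0.2))
        assert t_peak == k.t_peak_ms
        assert amp > 0

    def test_peak_amplitude_tracks_hill_curve(self):
        charges = [1.5, 2.0, 2.5, 3.5, 5.0, 8.0]
        peaks = []
        for q in charges:
            movie = synth_vsd_movie([StimSource(3.0, 3.0, q)])
            peaks.append(peak_amplitude(movie, roi_bbox(3.0, 3.0, 0.2))[0])
        expected = hill_response(np.array(charges), HillParams())
        corr = np.corrcoef(peaks, expected)[0, 1]
        assert corr > 0.999999

    def test_all_zero_movie_has_zero_peak(self):
        movie = VSDMovie(np.zeros((10, 100, 100)))
        amp, _ = peak_amplitude(movie, (0, 10, 0, 10))
        assert amp == 0.0

    def test_empty_roi_rejected(self):
        movie = VSDMovie(np.zeros((5, 100, 100)))
        with pytest.raises(ValueError):
            peak_amplitude(movie, (4, 4, 0, 10))

    def test_sources_outside_field_rejected(self):
        with pytest.raises(ValueError):
            StimSource(FIELD_MM + 1, 0.0, 1.0)

    def test_hdf5_roundtrip(self, tmp_path):
        movie = synth_vsd_movie([StimSource(2.0, 2.0, 3.0)], duration_ms=30)
        path = tmp_path / "movie.h5"
        movie.save(path)
        back = VSDMovie.load(path)
        assert np.array_equal(back.frames, movie.frames)
        assert back.pixel_pitch_mm == movie.pixel_pitch_mm


def count_local_maxima_1d(profile: np.ndarray) -> int:
    # collapse plateaus (bilinear sampling can land flat on a symmetric apex)
    v = profile[np.r_[True, np.diff(profile) != 0]]
    inner = v[1:-1]
    return int(np.sum((inner > v[:-2]) & (inner > v[2:])))


class TestSpatialStructure:
    def test_two_sites_0_6mm_apart_resolve_as_two_loci(self):
        # paired stimulation at >=0.6 mm separation initiates excitation at
        # two discernible locations in the 3-4 ms frames; 0.3 mm merges
        k = ResponseKinetics()
        for sep, expected in [(0.6, 2), (0.3, 1)]:
            srcs = [
                StimSource(3.0 - sep / 2, 3.0, 4.0, is_bipolar_pair=True),
                StimSource(3.0 + sep / 2, 3.0, 4.0, is_bipolar_pair=True),
            ]
            movie = synth_vsd_movie(srcs, k=k, duration_ms=10)
            prof = line_profile(movie, (1.5, 3.0), (4.5, 3.0), (3, 4), n_samples=241)
            assert count_local_maxima_1d(prof["dff"].to_numpy()) == expected

    def test_single_site_profile_unimodal_and_symmetric(self):
        movie = synth_vsd_movie([StimSource(3.125, 3.125, 4.0)], duration_ms=20)
        prof = line_profile(movie, (1.125, 3.125), (5.125, 3.125), (10, 15), n_samples=201)
        v = prof["dff"].to_numpy()
        assert count_local_maxima_1d(v) == 1
        assert v[100] == v.max()  # electrode sits at the line midpoint
        assert np.allclose(v, v[::-1], atol=1e-10)

    def test_profile_integral_scales_with_hill_response(self):
        integrals, expected = [], []
        for q in (2.0, 3.0, 6.0):
            movie = synth_vsd_movie([StimSource(3.0, 3.0, q)], duration_ms=20)
            prof = line_profile(movie, (0.5, 3.0), (5.5, 3.0), (12, 14))
            integrals.append(np.trapezoid(prof["dff"], prof["distance_mm"]))
            expected.append(hill_response(q, HillParams()))
        ratio = np.array(integrals) / np.array(expected)
        assert np.allclose(ratio, ratio[0], rtol=1e-6)

    def test_sequential_train_attenuates_by_inhibition_gain_squared(self):
        # three pulses, 20 ms apart, at well-separated electrodes: the third
        # response peak is inhibition_gain^2 times the first (noiseless)
        k = ResponseKinetics()
        srcs = [
            StimSource(1.0, 3.0, 4.0, onset_ms=0.0),
            StimSource(3.0, 3.0, 4.0, onset_ms=20.0),
            StimSource(5.0, 3.0, 4.0, onset_ms=40.0),
        ]
        movie = synth_vsd_movie(srcs, k=k, duration_ms=80)
        p1, _ = peak_amplitude(movie, roi_bbox(1.0, 3.0, 0.15), t_start_ms=0)
        p3, _ = peak_amplitude(movie, roi_bbox(5.0, 3.0, 0.15), t_start_ms=40)
        assert p3 / p1 == pytest.approx(k.inhibition_gain ** 2, rel=1e-6)

    def test_simultaneous_sites_do_not_inhibit_each_other(self):
        k = ResponseKinetics()
        one = synth_vsd_movie([StimSource(1.0, 3.0, 4.0)], k=k, duration_ms=30)
        two = synth_vsd_movie(
            [StimSource(1.0, 3.0, 4.0), StimSource(5.0, 3.0, 4.0)], k=k, duration_ms=30
        )
        roi = roi_bbox(1.0, 3.0, 0.15)
        assert peak_amplitude(two, roi)[0] == pytest.approx(peak_amplitude(one, roi)[0], rel=1e-9)
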