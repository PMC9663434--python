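"""Sinusoidal image code: lattice structure, linearity, Poisson statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeweave.encoding import (
    CodingParams,
    EncodedSignal,
    SpikeTrain,
    combine_signals,
    encode_image,
    evaluate_signal,
    poisson_spikes,
    recover_quadrature,
    signal_to_rate,
)


def brute_force_signal(image, constant, f_max, t_seconds):
    """Independent term-by-term oracle for the encoded signal."""
    n, m = image.shape
    total = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a = image[i - 1, j - 1] + constant
            f = j * f_max / m
            phi = math.radians(i * 360.0 / n)
            total += a * math.sin(2 * math.pi * f * t_seconds + phi)
    return total


class TestEncodeImage:
    def test_corner_pixel_reaches_lattice_extremes(self):
        params = CodingParams(f_max=80.0, brightness_constant=0.0)
        sig = encode_image(np.ones((3, 5)), params)
        assert sig.n_components == 15
        assert sig.frequencies.max() == pytest.approx(80.0)
        assert sig.phases.max() == pytest.approx(360.0)
        # 1-based indexing: smallest frequency is f_max/M, smallest phase 360/N
        assert sig.frequencies.min() == pytest.approx(80.0 / 5)
        assert sig.phases.min() == pytest.approx(360.0 / 3)

    def test_zero_image_zero_constant_gives_null_signal(self):
        sig = encode_image(
            np.zeros((4, 4)), CodingParams(brightness_constant=0.0)
        )
        t = np.linspace(0, 500, 97)
        assert np.allclose(evaluate_signal(sig, t), 0.0)

    def test_2x2_matches_brute_force_sum(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        params = CodingParams(f_max=2.0, brightness_constant=0.0)
        sig = encode_image(img, params)
        got = evaluate_signal(sig, np.array([100.0]))[0]  # t = 0.1 s
        assert got == pytest.approx(brute_force_signal(img, 0.0, 2.0, 0.1), rel=1e-12)

    def test_rejects_bad_images(self):
        params = CodingParams()
        with pytest.raises(ValueError):
            encode_image(np.array([[1.0, -0.5]]), params)
        with pytest.raises(ValueError):
            encode_image(np.empty((0, 3)), params)
        with pytest.raises(ValueError):
            encode_image(np.array([[np.nan]]), params)

    def test_column_constant_content_is_invisible(self):
        # phases span the full circle within a column, so a full-height bar
        # (and the brightness offset itself) cancels out of the signal
        img = np.zeros((8, 8))
        img[:, 3] = 1.0
        sig = encode_image(img, CodingParams(brightness_constant=1.0))
        t = np.linspace(0, 900, 411)
        assert np.max(np.abs(evaluate_signal(sig, t))) < 1e-9


class TestEvaluateAndCombine:
    def test_zero_component_signal(self):
        sig = EncodedSignal(np.empty(0), np.empty(0), np.empty(0))
        assert np.all(evaluate_signal(sig, np.arange(5.0)) == 0)

    def test_single_component_at_phase_90(self):
        sig = EncodedSignal(np.array([1.0]), np.array([7.0]), np.array([90.0]))
        assert evaluate_signal(sig, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_multi_component_termwise_oracle(self, rng):
        k = 37
        sig = EncodedSignal(
            rng.random(k), rng.random(k) * 50, rng.random(k) * 360
        )
        t_ms = rng.random(11) * 1000
        expected = np.zeros(11)
        for a, f, p in zip(sig.amplitudes, sig.frequencies, sig.phases):
            expected += a * np.sin(
                2 * np.pi * f * t_ms / 1000.0 + np.deg2rad(p)
            )
        np.testing.assert_allclose(
            evaluate_signal(sig, t_ms), expected, rtol=1e-9, atol=1e-12
        )

    def test_combine_rejects_empty_list(self):
        with pytest.raises(ValueError):
            combine_signals([])

    def test_combine_with_null_signal_is_identity(self, rng):
        sig = EncodedSignal(rng.random(5), rng.random(5) * 40, rng.random(5) * 360)
        null = EncodedSignal(np.empty(0), np.empty(0), np.empty(0))
        t = rng.random(7) * 500
        np.testing.assert_allclose(
            evaluate_signal(combine_signals([sig, null]), t),
            evaluate_signal(sig, t),
        )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_combine_is_pointwise_additive(self, seed):
        r = np.random.default_rng(seed)
        a = EncodedSignal(r.random(4), r.random(4) * 60, r.random(4) * 360)
        b = EncodedSignal(r.random(6), r.random(6) * 60, r.random(6) * 360)
        t = r.random(9) * 800
        np.testing.assert_allclose(
            evaluate_signal(combine_signals([a, b]), t),
            evaluate_signal(a, t) + evaluate_signal(b, t),
            rtol=1e-12,
            atol=1e-9,
        )

    def test_coprime_column_counts_give_distinct_lattices(self):
        params = CodingParams(f_max=77.0)
        sa = encode_image(np.ones((3, 7)), params)
        sb = encode_image(np.ones((3, 11)), params)
        la = set(np.round(np.unique(sa.frequencies), 9))
        lb = set(np.round(np.unique(sb.frequencies), 9))
        # coprime M: the lattices j*f_max/M meet only at f_max itself
        assert la & lb == {77.0}

    def test_json_round_trip(self, rng):
        sig = encode_image(rng.random((4, 5)), CodingParams())
        back = EncodedSignal.from_json(sig.to_json())
        np.testing.assert_array_equal(back.amplitudes, sig.amplitudes)
        np.testing.assert_array_equal(back.frequencies, sig.frequencies)
        assert back.source_shape == [(4, 5)]


class TestPoissonSpikes:
    def test_zero_rate_gives_empty_train(self):
        train = poisson_spikes(np.zeros(100), 1.0, 4, seed=0)
        assert train.n_spikes == 0
        assert train.duration == pytest.approx(100.0)

    def test_constant_rate_count_envelope(self):
        # 100 spikes/s for 10 s: count within 1000 +- 3*sqrt(1000)
        train = poisson_spikes(np.full(10_000, 100.0), 1.0, 1, seed=42)
        count = train.n_spikes
        assert abs(count - 1000) < 3 * math.sqrt(1000)

    def test_expected_count_matches_rate_integral(self):
        # invariant: E[count] = integral of rate, verified within 4 sigma
        rates = np.abs(np.sin(np.arange(2000) / 50.0)) * 80.0
        lam = rates.sum() * 1.0 / 1000.0
        counts = [
            poisson_spikes(rates, 1.0, 1, seed=s).n_spikes for s in range(100)
        ]
        assert abs(np.mean(counts) - lam) < 4 * math.sqrt(lam / 100)

    def test_determinism_under_seed(self):
        rates = np.linspace(0, 60, 500)
        a = poisson_spikes(rates, 1.0, 3, seed=7)
        b = poisson_spikes(rates, 1.0, 3, seed=7)
        assert a.spikes.keys() == b.spikes.keys()
        for k in a.spikes:
            np.testing.assert_array_equal(a.spikes[k], b.spikes[k])

    def test_strictly_increasing_times(self):
        train = poisson_spikes(np.full(200, 400.0), 1.0, 5, seed=3)
        for t in train.spikes.values():
            assert np.all(np.diff(t) > 0)

    def test_rejects_nonfinite_rates(self):
        with pytest.raises(ValueError):
            poisson_spikes(np.array([1.0, np.inf]), 1.0, 1, seed=0)

    def test_matches_thinning_oracle_distribution(self):
        # exact bin-count sampling vs an independent thinning realization
        from scipy.stats import ks_2samp

        rates = 50.0 + 40.0 * np.sin(np.arange(500) / 20.0)
        rates = np.maximum(rates, 0.0)
        dt = 1.0
        impl = [
            poisson_spikes(rates, dt, 1, seed=s).n_spikes for s in range(200)
        ]

        def thinning(seed):
            r = np.random.default_rng(seed)
            lam_max = rates.max()
            t = 0.0
            total = 0
            horizon = rates.size * dt
            while True:
                t += r.exponential(1000.0 / lam_max)
                if t >= horizon:
                    return total
                if r.random() < rates[int(t // dt)] / lam_max:
                    total += 1

        oracle = [thinning(10_000 + s) for s in range(200)]
        assert ks_2samp(impl, oracle).pvalue > 0.01


class TestQuadratureRecovery:
    def test_single_component(self):
        sig = EncodedSignal(np.array([2.0]), np.array([5.0]), np.array([30.0]))
        (i, q), = recover_quadrature(sig).values()
        assert i == pytest.approx(2 * math.cos(math.radians(30)))
        assert q == pytest.approx(2 * math.sin(math.radians(30)))

    def test_same_frequency_components_add_vectorially(self):
        sig = EncodedSignal(
            np.array([1.0, 3.0]), np.array([5.0, 5.0]), np.array([0.0, 90.0])
        )
        pairs = recover_quadrature(sig)
        assert len(pairs) == 1
        i, q = pairs[5.0]
        assert (i, q) == (pytest.approx(1.0), pytest.approx(3.0))

    def test_linearity_over_combined_images(self, rng):
        params = CodingParams(brightness_constant=0.2)
        a = encode_image(rng.random((3, 4)), params)
        b = encode_image(rng.random((3, 4)), params)
        qa = recover_quadrature(a)
        qb = recover_quadrature(b)
        qc = recover_quadrature(combine_signals([a, b]))
        for f in qc:
            assert qc[f][0] == pytest.approx(qa[f][0] + qb[f][0], abs=1e-12)
            assert qc[f][1] == pytest.approx(qa[f][1] + qb[f][1], abs=1e-12)


class TestSignalToRate:
    def test_rectification_modes(self):
        sig = EncodedSignal(np.array([1.0]), np.array([10.0]), np.array([0.0]))
        relu = signal_to_rate(sig, 0, 100, CodingParams(rate_scale=2.0))[1]
        folded = signal_to_rate(
            sig, 0, 100, CodingParams(rate_scale=2.0, rectify="abs")
        )[1]
        assert np.all(relu >= 0) and np.all(folded >= 0)
        assert folded.sum() > relu.sum()  # folding keeps negative lobes


class TestSpikeTrainContainer:
    def test_tsv_round_trip(self, tmp_path):
        train = poisson_spikes(np.full(300, 90.0), 1.0, 3, seed=5)
        path = tmp_path / "spikes.tsv"
        train.to_tsv(path)
        back = SpikeTrain.from_tsv(path, duration=train.duration)
        assert back.counts() == train.counts()
        for k in train.spikes:
            np.testing.assert_allclose(back.spikes[k], train.spikes[k], atol=1e-6)

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            SpikeTrain(spikes={0: np.array([2.0, 1.0])}, duration=5.0)
        with pytest.raises(ValueError):
            SpikeTrain(spikes={0: np.array([1.0, 7.0])}, duration=5.0)
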