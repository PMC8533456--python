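import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegsq.containers import EpochSet
from eegsq.features import (
    BandScheme,
    asymmetry_features,
    band_filter,
    band_power,
    class_topography,
    default_bands,
    diff_entropy,
    hjorth,
)
from eegsq.montage import make_montage

RATE = 200.0


def _sine(freq, duration=1.0, rate=RATE, amp=1.0):
    t = np.arange(0, duration, 1 / rate)
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandScheme:
    def test_default_bands_cover_1_to_49(self):
        scheme = default_bands()
        assert scheme.names == ("delta", "theta", "alpha", "beta", "gamma")
        assert scheme.span == (1.0, 49.0)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            BandScheme(bands=(("a", 1.0, 5.0), ("b", 4.0, 8.0)))

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="low must be"):
            BandScheme(bands=(("a", 5.0, 4.0),))


class TestBandFilter:
    def test_in_band_sinusoid_preserved(self):
        x = _sine(10.0, duration=5.0)
        y = band_filter(x, (8.0, 12.0), RATE)
        mid = slice(200, 800)
        assert np.std(y[mid]) == pytest.approx(np.std(x[mid]), rel=0.05)

    def test_out_of_band_sinusoid_rejected(self):
        x = _sine(10.0, duration=5.0)
        y = band_filter(x, (30.0, 49.0), RATE)
        assert np.sqrt(np.mean(y**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|inside"):
            band_filter(np.zeros(100), (30.0, 120.0), RATE)


class TestBandPower:
    def test_unit_sinusoid_alpha_power_half(self):
        # time-domain oracle: variance of a unit sinusoid is 1/2
        x = _sine(10.0)
        assert band_power(x, RATE, (8.0, 12.0)) == pytest.approx(0.5, rel=1e-6)

    def test_zero_signal_zero_power(self):
        assert band_power(np.zeros(200), RATE, (8.0, 12.0)) == 0.0

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        # averaged over 200 seeded draws the band power is sigma^2 * BW/Nyquist
        draws = rng.standard_normal((200, 200)) * 2.0
        beta = band_power(draws, RATE, (12.0, 30.0)).mean()
        expected = 4.0 * 18.0 / 100.0
        assert beta == pytest.approx(expected, rel=0.1)

    def test_five_band_sum_matches_total(self, rng):
        x = rng.standard_normal(1000)
        total = band_power(x, RATE, (1.0, 49.0))
        parts = sum(band_power(x, RATE, (lo, hi)) for _, lo, hi in default_bands().bands)
        assert parts == pytest.approx(total, rel=1e-10)

    def test_agrees_with_time_domain_variance_of_filtered_signal(self, rng):
        x = rng.standard_normal(2000)
        band = (8.0, 12.0)
        welch = band_power(x, RATE, band)
        filtered_var = band_filter(x, band, RATE).var()
        assert welch == pytest.approx(filtered_var, rel=0.1)

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            band_power(np.zeros(100), RATE, (8.0, 12.0))


class TestHjorth:
    def test_sinusoid_identities(self):
        # activity = A^2/2, mobility = omega, complexity = 1 for a pure tone
        amp, freq, rate = 3.0, 5.0, 2000.0
        x = amp * np.sin(2 * np.pi * freq * np.arange(0, 4, 1 / rate))
        act, mob, comp = hjorth(x, rate)
        assert act == pytest.approx(amp**2 / 2, rel=0.01)
        assert mob == pytest.approx(2 * np.pi * freq, rel=0.01)
        assert comp == pytest.approx(1.0, rel=0.01)

    def test_differencing_oracle(self, rng):
        # brute-force definition: variance ratios of explicit differences
        x = rng.standard_normal(500)
        rate = 100.0
        act, mob, comp = hjorth(x, rate)
        d1 = np.diff(x) * rate
        d2 = np.diff(d1) * rate
        assert act == pytest.approx(x.var())
        assert mob == pytest.approx(np.sqrt(d1.var() / x.var()))
        assert comp == pytest.approx(np.sqrt(d2.var() / d1.var()) / mob)

    def test_constant_signal_guarded_to_zero(self):
        assert hjorth(np.full(100, 2.5), RATE) == (0.0, 0.0, 0.0)

    def test_white_noise_activity_is_variance(self, rng):
        x = 2.0 * rng.standard_normal(100_000)
        act, _, _ = hjorth(x, RATE)
        assert act == pytest.approx(4.0, rel=0.02)


class TestDiffEntropy:
    def test_unit_variance_closed_form(self, rng):
        x = rng.standard_normal(200_000)
        expected = 0.5 * math.log(2 * math.pi * math.e)
        assert diff_entropy(x) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(1.4189, abs=1e-4)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scaling_identity(self, a):
        x = np.random.default_rng(7).standard_normal(500)
        assert diff_entropy(a * x) - diff_entropy(x) == pytest.approx(math.log(a), abs=1e-9)

    def test_gaussian_sigma2_4(self, rng):
        x = 2.0 * rng.standard_normal(100_000)
        assert diff_entropy(x) == pytest.approx(0.5 * math.log(2 * math.pi * math.e * 4), abs=0.01)

    def test_zero_variance_sentinel(self):
        assert diff_entropy(np.full(10, 1.0)) == -np.inf

    def test_monotone_in_variance(self, rng):
        base = rng.standard_normal(1000)
        des = [diff_entropy(s * base) for s in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(des) > 0)


def _epochs_from(data, montage, labels=None, rate=RATE):
    n = data.shape[0]
    return EpochSet(
        data=data,
        rate=rate,
        labels=np.zeros(n, dtype=int) if labels is None else labels,
        order=np.arange(n),
        block=np.arange(n),
        montage=montage,
    )


class TestAsymmetryFeatures:
    def test_identical_hemispheres_give_null_asymmetry(self, rng):
        m = make_montage(channels=["F3", "F4", "C3", "C4"])
        half = rng.standard_normal((6, 2, 200))
        data = np.stack([half[:, 0], half[:, 0], half[:, 1], half[:, 1]], axis=1)
        fm = asymmetry_features(_epochs_from(data, m), bases={"PSD", "DE"})
        dasm = [j for j, d in enumerate(fm.descriptors) if d.mode == "DASM"]
        rasm = [j for j, d in enumerate(fm.descriptors) if d.mode == "RASM"]
        assert np.allclose(fm.values[:, dasm], 0.0, atol=1e-9)
        assert np.allclose(fm.values[:, rasm], 1.0, atol=1e-6)

    def test_default_dimensionalities(self, rng):
        m = make_montage(62)
        data = rng.standard_normal((4, 62, 200))
        es = _epochs_from(data, m)
        assert asymmetry_features(es, bases={"PSD"}, modes={"DASM"}).n_features == 130
        assert asymmetry_features(es, bases={"Hjorth"}, modes={"DASM"}).n_features == 390

    @pytest.mark.parametrize(
        "channels,n_pairs", [(["F3", "F4", "Cz"], 1), (["F3", "F4", "C3", "C4", "P3", "P4"], 3)]
    )
    def test_feature_count_formula(self, rng, channels, n_pairs):
        m = make_montage(channels=channels)
        es = _epochs_from(rng.standard_normal((3, len(channels), 200)), m)
        fm = asymmetry_features(es, bases={"PSD", "Hjorth", "DE"}, modes={"DASM", "RASM"})
        assert fm.n_features == 2 * n_pairs * 5 * (1 + 3 + 1)

    def test_doubled_left_power(self, rng):
        m = make_montage(channels=["F3", "F4"])
        right = rng.standard_normal((5, 200))
        data = np.stack([np.sqrt(2.0) * right, right], axis=1)
        fm = asymmetry_features(_epochs_from(data, m), bases={"PSD"})
        for j, d in enumerate(fm.descriptors):
            band = default_bands().edges(d.band)
            rp = band_power(right, RATE, band)
            if d.mode == "RASM":
                assert fm.values[:, j] == pytest.approx(2.0, rel=1e-6)
            else:
                assert fm.values[:, j] == pytest.approx(rp, rel=1e-6)

    def test_swapping_hemispheres_negates_dasm_inverts_rasm(self, rng):
        m = make_montage(channels=["F3", "F4"])
        data = rng.standard_normal((4, 2, 200))
        fm = asymmetry_features(_epochs_from(data, m), bases={"PSD", "DE"})
        swapped = asymmetry_features(_epochs_from(data[:, ::-1], m), bases={"PSD", "DE"})
        for j, d in enumerate(fm.descriptors):
            if d.mode == "DASM":
                assert swapped.values[:, j] == pytest.approx(-fm.values[:, j], rel=1e-9)
            else:
                assert swapped.values[:, j] == pytest.approx(1.0 / fm.values[:, j], rel=1e-6)

    def test_empty_pair_table_rejected(self, rng):
        m = make_montage(channels=["Fz", "Cz"])
        es = _epochs_from(rng.standard_normal((2, 2, 200)), m)
        with pytest.raises(ValueError, match="pair table"):
            asymmetry_features(es)

    def test_column_order_is_deterministic(self, small_features, small_epochs):
        # DASM block precedes RASM; within a mode, pairs follow montage order
        modes = [d.mode for d in small_features.descriptors]
        assert modes == sorted(modes)
        pairs_seen = []
        for d in small_features.descriptors:
            if d.mode == "DASM" and d.pair not in pairs_seen:
                pairs_seen.append(d.pair)
        assert pairs_seen == list(small_epochs.montage.pairs)
        # recomputation yields the identical descriptor sequence
        again = asymmetry_features(
            small_epochs, default_bands(), bases={"PSD", "Hjorth", "DE"}, modes={"DASM", "RASM"}
        )
        assert [str(d) for d in again.descriptors] == [str(d) for d in small_features.descriptors]
        assert np.array_equal(again.values, small_features.values)


class TestClassTopography:
    def test_zero_signal_gives_zero_table(self):
        m = make_montage(channels=["F3", "F4", "Cz"])
        data = np.zeros((6, 3, 200))
        es = _epochs_from(data, m, labels=np.array([-1, -1, 0, 0, 1, 1]))
        table = class_topography(es)
        assert (table["power"] == 0).all()
        assert len(table) == 3 * 5 * 3  # channel x band x class

    def test_missing_class_rejected(self, rng):
        m = make_montage(channels=["F3", "F4"])
        es = _epochs_from(rng.standard_normal((4, 2, 200)), m, labels=np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="class"):
            class_topography(es)

    def test_symmetric_input_has_equal_homologue_columns(self, rng):
        m = make_montage(channels=["F3", "F4"])
        half = rng.standard_normal((6, 1, 200))
        data = np.concatenate([half, half], axis=1)
        es = _epochs_from(data, m, labels=np.array([-1, -1, 0, 0, 1, 1]))
        table = class_topography(es)
        wide = table.pivot_table(index=["band", "class"], columns="channel", values="power")
        assert np.allclose(wide["F3"], wide["F4"])

    def test_comfort_rows_have_least_power(self, small_epochs):
        table = class_topography(small_epochs)
        sums = table.groupby("class")["power"].sum()
        assert sums[-1] < sums[0]
        assert sums[-1] < sums[1]
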