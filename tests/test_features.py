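"""Feature extraction: each feature against an independent oracle."""

import math

import numpy as np
import pytest

from emdpcnn.emd import SiftConfig, decompose, reconstruct
from emdpcnn.features import (
    FuzzyEntropyParams,
    ar_coefficients,
    build_feature_vector,
    energy,
    feature_table,
    fuzzy_approximate_entropy,
    kurtosis,
    peak_to_peak,
    skewness,
)
from emdpcnn.io import Epoch


def fap_oracle(f, m, r):
    """Brute-force O(N^2) fuzzy approximate entropy, double loops throughout."""
    f = np.asarray(f, dtype=float)
    n = len(f)
    r_eff = r * np.var(f)

    def phi(mm):
        templates = []
        for i in range(n - mm + 1):
            seg = f[i : i + mm]
            templates.append(seg - seg.mean())
        nt = len(templates)
        logs = []
        for i in range(nt):
            total = 0.0
            for j in range(nt):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                total += math.exp(-(d**2) / r_eff)
            logs.append(math.log(total / nt))
        return sum(logs) / nt

    return phi(m) - phi(m + 1)


class TestEnergy:
    @pytest.mark.parametrize(
        "signal,expected",
        [
            (np.zeros(10), 0.0),
            (np.full(7, 2.0), 7 * 4.0),
            (np.array([1.0, -2.0, 3.0]), 14.0),
        ],
    )
    def test_closed_forms(self, signal, expected):
        assert energy(signal) == pytest.approx(expected)


class TestArCoefficients:
    @staticmethod
    def simulate_ar(coefs, n, seed, burn=500):
        rng = np.random.default_rng(seed)
        p = len(coefs)
        x = np.zeros(n + burn)
        e = rng.normal(size=n + burn)
        for t in range(p, n + burn):
            x[t] = np.dot(coefs, x[t - p : t][::-1]) + e[t]
        return x[burn:]

    def test_ar1_recovery(self):
        x = self.simulate_ar([0.8], 5000, seed=0)
        a = ar_coefficients(x, p=1)
        assert abs(a[0] - 0.8) < 0.05

    def test_ar7_recovery(self):
        # stable AR(7): roots well inside the unit circle
        true = np.array([0.5, -0.3, 0.2, -0.1, 0.1, -0.05, 0.05])
        x = self.simulate_ar(true, 5000, seed=1)
        a = ar_coefficients(x, p=7)
        rmse = np.sqrt(np.mean((a - true) ** 2))
        assert rmse < 0.1

    def test_white_noise_coefficients_are_small(self):
        x = np.random.default_rng(2).normal(size=5000)
        a = ar_coefficients(x, p=7)
        assert np.all(np.abs(a) < 0.1)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.full(100, 1.0), p=7)
        with pytest.raises(ValueError):
            ar_coefficients(np.arange(10.0), p=7)


class TestFuzzyApproximateEntropy:
    def test_constant_signal_is_zero(self):
        assert fuzzy_approximate_entropy(np.full(50, 2.0)) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 201))
        x = rng.normal(size=n)
        params = FuzzyEntropyParams(m=2, r=0.2)
        got = fuzzy_approximate_entropy(x, params)
        want = fap_oracle(x, 2, 0.2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_noise_is_more_entropic_than_sinusoid(self):
        t = np.arange(500) / 250.0
        tone = np.sin(2 * np.pi * 10 * t)
        tone = tone / np.std(tone)
        params = FuzzyEntropyParams(m=2, r=0.2)
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(size=500)
            noise = noise / np.std(noise)
            assert fuzzy_approximate_entropy(noise, params) > fuzzy_approximate_entropy(
                tone, params
            )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            fuzzy_approximate_entropy(np.arange(4.0), FuzzyEntropyParams(m=2))


class TestMomentFeatures:
    def test_peak_to_peak(self):
        assert peak_to_peak([1.0, 5.0, 3.0]) == 4.0
        assert peak_to_peak(np.full(5, 2.0)) == 0.0
        t = np.arange(0, 1, 1e-4)
        assert peak_to_peak(3.0 * np.sin(2 * np.pi * 5 * t)) == pytest.approx(6.0, rel=1e-4)

    def test_skewness_symmetric_sample_is_zero(self):
        assert skewness(np.array([-1.0, 0.0, 1.0])) == 0.0

    def test_skewness_mirror_antisymmetry(self):
        x = np.random.default_rng(3).exponential(size=500)
        assert skewness(-x) == pytest.approx(-skewness(x))

    def test_skewness_of_exponential_sample(self):
        x = np.random.default_rng(4).exponential(size=10_000)
        assert abs(skewness(x) - 2.0) < 0.15

    def test_kurtosis_alternating_is_minus_two(self):
        x = np.array([-1.0, 1.0] * 10)
        assert kurtosis(x) == pytest.approx(-2.0)

    def test_kurtosis_of_gaussian_sample(self):
        x = np.random.default_rng(5).normal(size=10_000)
        assert abs(kurtosis(x)) < 0.15

    def test_kurtosis_scale_invariance(self):
        x = np.random.default_rng(6).normal(size=300)
        assert kurtosis(3.7 * x) == pytest.approx(kurtosis(x), rel=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            skewness(np.full(10, 1.0))
        with pytest.raises(ValueError):
            kurtosis(np.full(10, 1.0))


@pytest.fixture(scope="module")
def epoch():
    rng = np.random.default_rng(0)
    t = np.arange(500) / 250.0
    data = np.vstack(
        [
            np.sin(2 * np.pi * 10 * t) + 0.5 * rng.normal(size=500),
            np.sin(2 * np.pi * 22 * t) + 0.5 * rng.normal(size=500),
            rng.normal(size=500),
        ]
    )
    return Epoch(data=data, label=1)


class TestFeatureVector:
    def test_three_channel_layout_length(self, epoch):
        fv = build_feature_vector(epoch, K_imfs=4, p=7)
        assert len(fv) == 3 * 4 * 12 == 144
        assert len(fv.names) == 144
        assert fv.label == 1

    def test_twenty_two_channel_layout_length(self):
        rng = np.random.default_rng(1)
        epoch = Epoch(data=rng.normal(size=(22, 128)), label=0)
        fv = build_feature_vector(epoch, SiftConfig(max_imfs=6), K_imfs=4, p=7)
        assert len(fv) == 22 * 4 * 12 == 1056

    def test_deterministic(self, epoch):
        a = build_feature_vector(epoch, K_imfs=3, p=4)
        b = build_feature_vector(epoch, K_imfs=3, p=4)
        assert np.array_equal(a.values, b.values)

    def test_missing_imfs_are_zero_padded_and_flagged(self):
        t = np.arange(500) / 250.0
        epoch = Epoch(data=np.sin(2 * np.pi * 10 * t)[None, :], label=0)
        fv = build_feature_vector(epoch, SiftConfig(max_imfs=2), K_imfs=6, p=7)
        assert any("missing" in f for f in fv.flags)
        assert len(fv) == 6 * 12
        assert np.all(fv.values[2 * 12 :] == 0.0)

    def test_energy_completeness_corollary(self, epoch):
        x = epoch.data[0]
        s = decompose(x)
        assert energy(reconstruct(s)) == pytest.approx(energy(x), rel=1e-6)

    def test_feature_table_columns(self, epoch):
        df = feature_table([build_feature_vector(epoch, K_imfs=2, p=3)], subjects=[7])
        assert df.shape == (1, 3 * 2 * 8 + 2)
        assert list(df.columns[-2:]) == ["label", "subject"]
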