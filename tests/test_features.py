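import numpy as np
import pytest

from neurocode import features as feat
from neurocode import simulate as sim
from neurocode.detect import Waveform
from neurocode.errors import ConfigError, ValidationError

RATE = 30000.0


def _tone(freq, rate, duration):
    t = np.arange(int(rate * duration)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestWaveformProperties:
    def test_symmetric_triangle_rise_equals_decay(self):
        x = np.concatenate([np.linspace(0, 1, 31), np.linspace(1, 0, 31)[1:]])
        p = feat.waveform_properties(x, RATE)
        assert p.rise_time_ms == pytest.approx(p.decay_time_ms, rel=1e-6)

    def test_time_properties_amplitude_invariant(self):
        (tpl,) = sim.synth_templates(n_neuronal=1, n_tumor=0, seed=2)
        p1 = feat.waveform_properties(tpl.shape * 10, RATE)
        p2 = feat.waveform_properties(tpl.shape * 20, RATE)
        assert p1.duration_ms == pytest.approx(p2.duration_ms)
        assert p1.rise_time_ms == pytest.approx(p2.rise_time_ms)
        assert p1.decay_time_ms == pytest.approx(p2.decay_time_ms)
        assert p2.amplitude_uv == pytest.approx(2 * p1.amplitude_uv)

    def test_neuronal_template_duration_in_physical_window(self):
        for seed in range(4):
            (tpl,) = sim.synth_templates(n_neuronal=1, n_tumor=0, seed=seed)
            p = feat.waveform_properties(tpl.shape * 30, RATE)
            assert 0.3 <= p.duration_ms <= 1.5
            assert p.duration_ms >= p.rise_time_ms + p.decay_time_ms - 1e-6

    def test_flat_waveform_flagged(self):
        with pytest.warns(UserWarning, match="flat"):
            p = feat.waveform_properties(np.zeros(50), RATE)
        assert p.flagged


class TestBandPower:
    def test_50hz_tone_lands_in_gamma(self):
        x = _tone(50, 1000.0, 20.0)
        frac, absolute = feat.band_power(x, 1000.0, "gamma")
        assert frac >= 0.95
        assert absolute > 0

    def test_6hz_tone_lands_in_theta(self):
        x = _tone(6, 1000.0, 20.0)
        frac, _ = feat.band_power(x, 1000.0, "theta")
        assert frac >= 0.95

    def test_white_noise_fraction_tracks_bandwidth(self, rng):
        x = rng.normal(size=120000)
        frac, _ = feat.band_power(x, 1000.0, (30.0, 100.0), total_band=(1.0, 150.0))
        expected = 70.0 / 149.0
        assert abs(frac - expected) / expected < 0.2

    def test_fraction_invariant_to_amplitude(self):
        x = _tone(50, 1000.0, 10.0)
        f1, a1 = feat.band_power(x, 1000.0, "gamma")
        f2, a2 = feat.band_power(3 * x, 1000.0, "gamma")
        assert f1 == pytest.approx(f2)
        assert a2 == pytest.approx(9 * a1, rel=1e-6)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            feat.band_power(np.zeros(10000), 1000.0, (400.0, 600.0))


class TestMorletEnergies:
    def test_zero_trace_zero_energy(self):
        e, _ = feat.morlet_energies(np.zeros(3000), RATE)
        assert np.allclose(e, 0.0)

    def test_1khz_tone_peaks_in_matching_band(self):
        x = _tone(1000, RATE, 0.2)
        e, edges = feat.morlet_energies(x, RATE)
        b = np.argmax(e)
        assert edges[b] <= 1000 <= edges[b + 1]

    def test_quadratic_amplitude_scaling(self):
        x = _tone(500, RATE, 0.1)
        e1, _ = feat.morlet_energies(x, RATE)
        e2, _ = feat.morlet_energies(2 * x, RATE)
        assert np.allclose(e2, 4 * e1, rtol=1e-8)

    def test_bad_edges_rejected(self):
        with pytest.raises(ConfigError):
            feat.morlet_energies(np.zeros(100), RATE, band_edges=[100.0, 20000.0])


class TestHHT:
    def test_reconstruction_is_exact(self, rng):
        for x in (
            rng.normal(size=512),
            _tone(5, 1000.0, 1.0) + _tone(50, 1000.0, 1.0),
            np.cumsum(rng.normal(size=400)),
        ):
            imfs, residual = feat.emd(x)
            recon = imfs.sum(axis=0) + residual
            assert np.max(np.abs(recon - x)) <= 1e-6 * max(np.max(np.abs(x)), 1.0)

    def test_two_tone_separation(self):
        rate = 2000.0
        x = _tone(5, rate, 2.0) + _tone(200, rate, 2.0)
        imfs, _ = feat.emd(x)
        energies = [float(np.sum(i * i)) for i in imfs]
        top2 = np.argsort(energies)[-2:]
        mifs = sorted(
            feat.mean_instantaneous_frequency(imfs[k], rate) for k in top2
        )
        assert abs(mifs[0] - 5.0) / 5.0 < 0.2
        assert abs(mifs[1] - 200.0) / 200.0 < 0.2

    def test_pure_tone_first_imf_dominates(self):
        x = _tone(100, 2000.0, 1.0)
        imfs, residual = feat.emd(x)
        energies = np.array([np.sum(i * i) for i in imfs])
        assert energies[0] / (energies.sum() + np.sum(residual**2)) >= 0.9

    def test_short_trace_rejected(self):
        with pytest.raises(ConfigError):
            feat.emd(np.zeros(32))

    def test_hht_features_deterministic(self, rng):
        x = rng.normal(size=600)
        f1 = feat.hht_features(x, 1000.0)["features"]
        f2 = feat.hht_features(x, 1000.0)["features"]
        assert f1 == f2


class TestRFE:
    @staticmethod
    def _informative_problem(seed, n=200, n_noise=20):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, n_noise + 2))
        X[:, 0] += 3.0 * y
        X[:, 1] -= 3.0 * y
        names = ["inf_a", "inf_b"] + [f"noise{i}" for i in range(n_noise)]
        return X, y, names

    def test_informative_features_selected(self):
        hits = 0
        for seed in range(50):
            X, y, names = self._informative_problem(seed)
            sel = feat.rfe_select(X, y, feature_names=names, k=2)
            hits += set(sel) == {"inf_a", "inf_b"}
        assert hits >= 48  # >= 95% of runs

    def test_k_equal_to_n_features_is_identity(self):
        X, y, names = self._informative_problem(0)
        assert feat.rfe_select(X, y, feature_names=names, k=len(names)) == names

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValidationError):
            feat.rfe_select(X, np.zeros(10), k=2)


class TestClassifySignals:
    @staticmethod
    def _waveform_classes(seed=0, n_per=60, snr=10.0):
        """Neuronal vs tumor template instances at a given SNR."""
        rng = np.random.default_rng(seed)
        templates = sim.synth_templates(
            n_neuronal=1, n_tumor=1, seed=3, tumor_duration_ms=4.0
        )
        rows, labels = [], []
        rate = 30000.0
        for tpl, label in [(templates[0], "neuronal"), (templates[1], "tumor")]:
            for _ in range(n_per):
                amp = snr * 2.4
                w = np.zeros(400)
                lo = 150 - tpl.alignment_index
                w[lo : lo + tpl.shape.size] += amp * tpl.shape
                w += rng.normal(0, 2.4, w.size)
                wf = Waveform(samples_uv=w, alignment_index=int(np.argmax(np.abs(w))))
                rows.append(feat.feature_vector(wf, rate))
                labels.append(label)
        names = list(rows[0].keys())
        X = np.array([[r[n] for n in names] for r in rows])
        return X, np.array(labels), names

    def test_well_separated_classes_high_cv_accuracy(self):
        X, y, _ = self._waveform_classes(seed=1, snr=10.0)
        out = feat.classify_signals(X, y, folds=5, seed=0)
        assert out["accuracy"] >= 0.95
        assert "neuronal" in out["report"]

    def test_shuffled_labels_near_chance(self):
        X, y, _ = self._waveform_classes(seed=2, snr=10.0)
        rng = np.random.default_rng(0)
        out = feat.classify_signals(X, rng.permutation(y), folds=5, seed=0)
        assert abs(out["accuracy"] - 0.5) <= 0.10

    def test_folds_exceeding_class_count_rejected(self):
        X = np.zeros((4, 3))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            feat.classify_signals(X, y, folds=5)
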