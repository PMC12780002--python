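import numpy as np
import pytest

from neurocode import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neuronal_templates():
    return sim.synth_templates(n_neuronal=2, n_tumor=0, seed=7)


@pytest.fixture
def small_recording():
    """5 s, 2 channels, neuronal spikes at 5 Hz on 2.4 uV noise."""
    cfg = sim.SimConfig(
        seed=11, duration_s=5.0, n_channels=2, neuron_rate_hz=5.0,
        neuron_amplitude_uv=30.0,
    )
    return sim.synth_recording(cfg)


def make_template_bank(n_codes, n_samples=61, amp_uv=80.0, seed=0,
                       max_cross=0.75):
    """Well-separated synthetic code templates for codebook/render tests.

    Spike-like shapes: a dominant first lobe followed by decaying
    alternating lobes (so the extremum is stable under noise), with lobe
    widths/counts/polarity varied per code. Candidates too similar to an
    accepted template (sample-consistency above ``max_cross`` at the 30%
    tolerance) are rejected, so ground-truth classes are unambiguous.
    """
    from neurocode.codebook import _standardize_length, sample_consistency
    from neurocode.simulate import _half_sine_lobes

    rng = np.random.default_rng(seed)
    bank = []
    while len(bank) < n_codes:
        k = int(rng.integers(2, 6))
        widths = np.concatenate([[rng.uniform(1.0, 3.0)],
                                 rng.uniform(0.6, 1.6, size=k - 1)])
        decay = rng.uniform(0.45, 0.7)
        sign = rng.choice([-1.0, 1.0])
        amps = sign * np.array([(-1.0) ** j * decay**j for j in range(k)])
        shape = _half_sine_lobes(n_samples, widths, amps)
        shape = shape / np.max(np.abs(shape)) * amp_uv
        peak = int(np.argmax(np.abs(shape)))
        ok = True
        for other in bank:
            other_peak = int(np.argmax(np.abs(other)))
            cand = _standardize_length(shape, peak, n_samples, other_peak)
            if sample_consistency(cand, other) > max_cross:
                ok = False
                break
        if ok:
            bank.append(shape)
    return bank
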