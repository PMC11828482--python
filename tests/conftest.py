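"""Shared fixtures: small seeded synthetic datasets."""

import numpy as np
import pytest

from azquant.synthetic import (
    BleachSimConfig,
    SynapseSimConfig,
    simulate_bleach_trace,
    simulate_synapse_stack,
)


@pytest.fixture(scope="session")
def noiseless_staircase():
    """Instant conversion, no blinking, no noise: a pure bleaching staircase."""

    def make(n_channels: int, seed: int = 4, n_frames: int = 600, onset: int = 50,
             bleach_rate: float = 0.01, require_late_event: bool = False):
        """When ``require_late_event`` is set, walk seeds deterministically
        until the truth sidecar contains a bleaching event in the second
        half of the trace — the precondition for unitary estimation."""
        for s in range(seed, seed + 50):
            cfg = BleachSimConfig(
                channels_per_az=n_channels,
                conversion_rate=1.0,
                bleach_rate=bleach_rate,
                blink_off_rate=0.0,
                blink_on_rate=0.0,
                noise_sd=0.0,
                n_frames=n_frames,
                uv_onset_frame=onset,
                seed=s,
            )
            trace, truth = simulate_bleach_trace(cfg)
            half = onset + (n_frames - onset) // 2
            if not require_late_event or (truth.bleach_frame >= half).any():
                return (trace, truth), cfg
        raise RuntimeError("no seed produced a late bleaching event")

    return make


@pytest.fixture(scope="session")
def synapse_stacks():
    """Noiseless and default-noise STED-like stacks with truth tables."""

    out = {}
    for label, noise in (("noiseless", 0.0), ("noisy", 5.0)):
        cfg = SynapseSimConfig(noise_sd=noise, seed=2, n_boutons=2, az_per_bouton=4)
        out[label] = (cfg, *simulate_synapse_stack(cfg))
    return out


@pytest.fixture(scope="session")
def correlated_image_pair():
    """Two-population 64x64 pair: correlated foreground, independent background."""
    rng = np.random.default_rng(11)
    a = rng.uniform(0, 20, size=(64, 64))
    b = rng.uniform(0, 20, size=(64, 64))
    fg = np.zeros((64, 64), dtype=bool)
    fg[10:30, 12:34] = True
    a_fg = rng.uniform(60, 140, size=fg.sum())
    a[fg] = a_fg
    b[fg] = 0.8 * a_fg + rng.normal(0, 8, size=fg.sum())
    return a, b, fg
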