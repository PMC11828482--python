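"""Synthetic two-electrode voltage-clamp sweeps with known event amplitudes.

Each stimulus deposits an EPSC kernel (difference of exponentials, inward
negative) whose amplitude follows either a paired-pulse ratio (two-stimulus
protocols) or a depression recursion toward a plateau (trains). Miniature
EPSCs arrive as a Poisson process. The truth sidecar records every event's
noiseless amplitude, which downstream metrics are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..ephys import Sweep

__all__ = ["TevcSimConfig", "StimProtocol", "simulate_tevc_sweeps", "depression_amplitudes"]


@dataclass(frozen=True)
class StimProtocol:
    """Stimulus onsets (s) within a sweep of the given duration."""

    stimulus_times: tuple[float, ...]
    duration: float

    def __post_init__(self) -> None:
        times = self.stimulus_times
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("stimulus times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] >= self.duration):
            raise ValueError("stimulus after sweep end (or before start)")

    @classmethod
    def paired_pulse(cls, ipi_ms: float, onset: float = 0.05, tail: float = 0.15) -> "StimProtocol":
        t1 = onset
        t2 = onset + ipi_ms / 1e3
        return cls(stimulus_times=(t1, t2), duration=t2 + tail)

    @classmethod
    def train(cls, frequency_hz: float, train_duration: float,
              onset: float = 0.05, tail: float = 0.1) -> "StimProtocol":
        n = int(round(train_duration * frequency_hz))
        times = tuple(onset + k / frequency_hz for k in range(n))
        return cls(stimulus_times=times, duration=times[-1] + tail)

    @property
    def ipi_ms(self) -> float:
        if len(self.stimulus_times) != 2:
            raise ValueError("ipi_ms defined only for two-stimulus protocols")
        return (self.stimulus_times[1] - self.stimulus_times[0]) * 1e3


@dataclass(frozen=True)
class TevcSimConfig:
    """Conditions of one synthetic TEVC recording.

    ``ppr_true`` scales the second pulse of two-stimulus protocols; longer
    trains follow the depression recursion with time constant
    ``depression_tau`` (s) toward ``depression_plateau`` (fraction of the
    first amplitude). Kernel time constants are in ms.
    """

    sampling_rate: float = 50_000.0
    epsc_amplitude: float = 60.0
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 6.0
    ppr_true: float | None = None
    depression_tau: float = 5.0
    depression_plateau: float = 0.8
    mepsc_amplitude: float = 0.8
    mepsc_amplitude_cv: float = 0.25
    mepsc_rate: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.depression_plateau <= 1.0):
            raise ValueError(
                f"depression_plateau must be in (0, 1], got {self.depression_plateau}"
            )
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= self.rise_tau_ms:
            raise ValueError("require 0 < rise_tau_ms < decay_tau_ms")
        if self.epsc_amplitude <= 0:
            raise ValueError("epsc_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _kernel(config: TevcSimConfig) -> np.ndarray:
    """Unit-peak biexponential kernel (positive; applied with negative sign)."""
    tr = config.rise_tau_ms / 1e3
    td = config.decay_tau_ms / 1e3
    dur = td * 8 + tr * 4
    t = np.arange(0.0, dur, 1.0 / config.sampling_rate)
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def depression_amplitudes(config: TevcSimConfig, stimulus_times) -> np.ndarray:
    """Per-stimulus amplitude scale from the depression recursion.

    d_1 = 1; d_{k+1} = plateau + (d_k - plateau) exp(-dt_k / tau). For a
    uniform train this telescopes to the single-exponential time course
    plateau + (1 - plateau) exp(-(t - t_1)/tau).
    """
    times = np.asarray(stimulus_times, dtype=float)
    d = np.empty(times.size)
    if times.size == 0:
        return d
    d[0] = 1.0
    p, tau = config.depression_plateau, config.depression_tau
    for k in range(1, times.size):
        dt = times[k] - times[k - 1]
        d[k] = p + (d[k - 1] - p) * np.exp(-dt / tau)
    return d


def simulate_tevc_sweeps(
    config: TevcSimConfig,
    protocol: StimProtocol,
    n_sweeps: int = 1,
) -> tuple[list[Sweep], pd.DataFrame]:
    """Generate voltage-clamp sweeps and the per-event truth table.

    Returns
    -------
    sweeps : list of :class:`azquant.ephys.Sweep`; overlapping kernels sum.
    truth : DataFrame of evoked events (``sweep``, ``stim_index``,
        ``time_s``, ``amplitude_nA`` — noiseless magnitudes); spontaneous
        events are in ``truth.attrs["mepscs"]``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_sweeps)
    kernel = _kernel(config)
    n_samples = int(round(protocol.duration * config.sampling_rate))

    scales = depression_amplitudes(config, protocol.stimulus_times)
    if config.ppr_true is not None and len(protocol.stimulus_times) == 2:
        scales = np.array([1.0, config.ppr_true])
    true_amps = config.epsc_amplitude * scales

    sweeps: list[Sweep] = []
    rows = []
    mepsc_rows = []
    for s in range(n_sweeps):
        rng = np.random.default_rng(children[s])
        current = np.zeros(n_samples)
        for k, t_stim in enumerate(protocol.stimulus_times):
            i0 = int(round(t_stim * config.sampling_rate))
            seg = kernel[: n_samples - i0]
            current[i0 : i0 + seg.size] -= true_amps[k] * seg
            rows.append({"sweep": s, "stim_index": k, "time_s": t_stim,
                         "amplitude_nA": true_amps[k]})
        if config.mepsc_rate > 0:
            n_mini = rng.poisson(config.mepsc_rate * protocol.duration)
            t_minis = np.sort(rng.uniform(0, protocol.duration, size=n_mini))
            for tm in t_minis:
                amp = config.mepsc_amplitude * max(
                    1.0 + config.mepsc_amplitude_cv * rng.standard_normal(), 0.05
                )
                i0 = int(round(tm * config.sampling_rate))
                seg = kernel[: n_samples - i0]
                if seg.size:
                    current[i0 : i0 + seg.size] -= amp * seg
                mepsc_rows.append({"sweep": s, "time_s": float(tm), "amplitude_nA": amp})
        if config.noise_sd > 0:
            current = current + rng.normal(0, config.noise_sd, size=n_samples)
        sweeps.append(
            Sweep(current=current, sampling_rate=config.sampling_rate,
                  stimulus_times=protocol.stimulus_times,
                  metadata={"sweep": s, "seed": config.seed})
        )
    truth = pd.DataFrame(rows, columns=["sweep", "stim_index", "time_s", "amplitude_nA"])
    truth.attrs["mepscs"] = pd.DataFrame(
        mepsc_rows, columns=["sweep", "time_s", "amplitude_nA"]
    )
    return sweeps, truth
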