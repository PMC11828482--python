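"""Evoked-transmission metrics from two-electrode voltage-clamp sweeps.

All currents are in nA with the physiological sign convention: excitatory
postsynaptic currents (EPSCs) are inward, i.e. negative deflections from
baseline. Reported amplitudes are positive magnitudes. Charge is in nC
(nA x s).

The processing chain mirrors the standard offline workflow: zero-phase
Gaussian low-pass (-3 dB cutoff specified in Hz), per-stimulus EPSC
measurement against a pre-stimulus baseline, paired-pulse ratios under two
averaging schemes, single-exponential depression fits per train, burst
charge transfer, and mean quantal content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "Sweep",
    "EPSCMeasure",
    "PPRResult",
    "DepressionFit",
    "QuantalStats",
    "gaussian_lowpass",
    "measure_epsc",
    "burst_charge",
    "compute_ppr",
    "ppr_cov",
    "fit_depression",
    "mean_quantal_content",
]


@dataclass
class Sweep:
    """One voltage-clamp current sweep.

    current : nA per sample, inward negative.
    sampling_rate : Hz, uniform.
    stimulus_times : s, nerve-stimulation onsets within the sweep.
    metadata : free-form labels (animal, genotype, external calcium ...).
    """

    current: np.ndarray
    sampling_rate: float = 50_000.0
    stimulus_times: tuple[float, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        dur = self.duration
        for t in self.stimulus_times:
            if not (0.0 <= t < dur):
                raise ValueError(
                    f"stimulus time {t} s outside sweep duration {dur} s"
                )

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.current.size) / self.sampling_rate


@dataclass
class EPSCMeasure:
    """Per-stimulus EPSC quantification (positive amplitude magnitude)."""

    baseline: float
    amplitude: float
    half_width_ms: float
    charge_nc: float
    window: tuple[float, float]
    flags: tuple[str, ...] = ()


@dataclass
class PPRResult:
    """Paired-pulse ratio under both averaging schemes.

    scheme_a averages the per-sweep ratios A2/A1; scheme_b is the ratio of
    the mean second amplitude over the mean first amplitude. The two
    coincide exactly when all first amplitudes are equal.
    """

    ipi_ms: float
    ppr_per_sweep: np.ndarray
    scheme_a: float
    scheme_b: float
    n_excluded: int = 0


@dataclass
class DepressionFit:
    """Single-exponential fit A(t) = plateau + (A0 - plateau) exp(-t/tau)."""

    tau_s: float
    plateau: float
    initial_amplitude: float
    residual_rms: float
    flags: tuple[str, ...] = ()

    @property
    def plateau_fraction(self) -> float:
        return self.plateau / self.initial_amplitude


@dataclass
class QuantalStats:
    mean_epsc: float
    mean_mepsc: float
    mqc: float


def gaussian_lowpass(sweep: Sweep, cutoff_minus3db: float) -> Sweep:
    """Zero-phase Gaussian low-pass with the given -3 dB cutoff.

    The Gaussian transfer function is H(f) = exp(-2 pi^2 sigma_t^2 f^2);
    requiring |H(f_c)| = 10^(-3/20) = 2^(-1/2) gives
    sigma_t = sqrt(ln 2) / (2 pi f_c). DC gain is exactly 1 and the filter
    is symmetric, hence zero phase.
    """
    nyquist = sweep.sampling_rate / 2.0
    if cutoff_minus3db >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_minus3db} Hz must be below Nyquist {nyquist} Hz"
        )
    if cutoff_minus3db <= 0:
        raise ValueError("cutoff must be positive")
    sigma_samples = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_minus3db) * sweep.sampling_rate
    filtered = ndimage.gaussian_filter1d(
        sweep.current, sigma_samples, mode="nearest", truncate=6.0
    )
    return Sweep(
        current=filtered,
        sampling_rate=sweep.sampling_rate,
        stimulus_times=sweep.stimulus_times,
        metadata=dict(sweep.metadata),
    )


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def measure_epsc(
    sweep: Sweep,
    stim_time: float,
    response_window: float = 0.020,
    baseline_window: float = 0.005,
    baseline_gap: float = 0.0005,
    clip_charge: bool = True,
) -> EPSCMeasure:
    """Measure one evoked EPSC against its pre-stimulus baseline.

    Baseline is the mean current over ``baseline_window`` seconds ending
    ``baseline_gap`` before the stimulus. Amplitude is baseline minus the
    most negative sample in the response window (a positive magnitude).
    Half-width is the full width at half amplitude with linear
    interpolation between samples. Charge integrates (baseline - current)
    over the response window; with ``clip_charge`` only samples below
    baseline contribute.
    """
    fs = sweep.sampling_rate
    i_stim = int(round(stim_time * fs))
    i_end = int(round((stim_time + response_window) * fs))
    if i_end > sweep.current.size:
        raise ValueError("response window exceeds sweep length")
    i_b1 = int(round((stim_time - baseline_gap) * fs))
    i_b0 = int(round((stim_time - baseline_gap - baseline_window) * fs))
    i_b0 = max(i_b0, 0)
    if i_b1 <= i_b0:
        raise ValueError("baseline window empty; stimulus too close to sweep start")
    pre = sweep.current[i_b0:i_b1]
    baseline = float(pre.mean())
    noise_sd = float(pre.std())

    seg = sweep.current[i_stim:i_end]
    i_peak = int(np.argmin(seg))
    amplitude = baseline - float(seg[i_peak])
    flags: list[str] = []
    if amplitude < 3.0 * noise_sd or amplitude <= 0:
        flags.append("no event")
        amplitude = max(amplitude, 0.0)

    # half-width via interpolated crossings of baseline - amplitude/2
    half_width_ms = 0.0
    if amplitude > 0:
        level = baseline - amplitude / 2.0
        t = (np.arange(i_stim, i_end) / fs) - stim_time
        below = seg < level
        if below.any():
            j = i_peak
            # walk left from the peak to the last crossing
            left = j
            while left > 0 and below[left - 1]:
                left -= 1
            right = j
            while right < seg.size - 1 and below[right + 1]:
                right += 1
            t_left = (
                _interp_crossing(t[left - 1], t[left], seg[left - 1], seg[left], level)
                if left > 0
                else t[left]
            )
            t_right = (
                _interp_crossing(t[right], t[right + 1], seg[right], seg[right + 1], level)
                if right < seg.size - 1
                else t[right]
            )
            half_width_ms = (t_right - t_left) * 1e3

    deflect = baseline - seg
    if clip_charge:
        deflect = np.clip(deflect, 0.0, None)
    charge_nc = float(np.sum(deflect) / fs)

    return EPSCMeasure(
        baseline=baseline,
        amplitude=float(amplitude),
        half_width_ms=float(half_width_ms),
        charge_nc=charge_nc,
        window=(stim_time, stim_time + response_window),
        flags=tuple(flags),
    )


def burst_charge(
    sweep: Sweep,
    burst_window: tuple[float, float],
    baseline_window: float = 0.005,
) -> float:
    """Total charge transfer (nC) below the pre-burst baseline.

    Baseline is estimated immediately before ``burst_window``; only samples
    below baseline contribute, so noise above baseline does not cancel
    genuine inward charge.
    """
    fs = sweep.sampling_rate
    start, end = burst_window
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    if i0 < 0 or i1 > sweep.current.size or i1 <= i0:
        raise ValueError("burst window outside sweep")
    ib0 = max(int(round((start - baseline_window) * fs)), 0)
    if ib0 >= i0:
        raise ValueError("no room for baseline before burst window")
    baseline = float(sweep.current[ib0:i0].mean())
    deflect = np.clip(baseline - sweep.current[i0:i1], 0.0, None)
    return float(deflect.sum() / fs)


def compute_ppr(first_amps, second_amps, ipi_ms: float = np.nan) -> PPRResult:
    """Paired-pulse ratios per sweep and under both averaging schemes.

    Sweeps whose first amplitude is zero are excluded (with a warning) from
    scheme a, since their per-sweep ratio is undefined; scheme b uses the
    remaining pairs as well for consistency.
    """
    a1 = np.asarray(first_amps, dtype=float)
    a2 = np.asarray(second_amps, dtype=float)
    if a1.size != a2.size or a1.size == 0:
        raise ValueError("first and second amplitude lists must be equal length >= 1")
    keep = a1 != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} sweep(s) with zero first amplitude",
                      stacklevel=2)
    a1, a2 = a1[keep], a2[keep]
    if a1.size == 0:
        raise ValueError("no sweeps with nonzero first amplitude")
    ratios = a2 / a1
    return PPRResult(
        ipi_ms=float(ipi_ms),
        ppr_per_sweep=ratios,
        scheme_a=float(ratios.mean()),
        scheme_b=float(a2.mean() / a1.mean()),
        n_excluded=n_excluded,
    )


def ppr_cov(values) -> float:
    """Coefficient of variation across animals, in percent (SD/mean x 100)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(v.std(ddof=1) / mean * 100.0)


def fit_depression(times, amplitudes) -> DepressionFit:
    """Fit A(t) = plateau + (A0 - plateau) exp(-t / tau) to a train.

    Times are re-referenced to the first stimulus. Initialization follows
    the shape of the data: A0 = first amplitude, plateau = mean of the last
    20% of points, tau = time to decay halfway between the two. Constant
    trains are returned as plateau = A0 with tau flagged unidentifiable.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.size != a.size or t.size < 5:
        raise ValueError("need >= 5 (time, amplitude) points")
    if np.any(a <= 0):
        raise ValueError("amplitudes must be positive")
    t = t - t[0]

    a0 = a[0]
    tail = a[-max(1, t.size // 5):]
    plateau0 = float(tail.mean())
    if np.ptp(a) < 1e-9 * max(abs(a0), 1.0):
        return DepressionFit(
            tau_s=float("nan"), plateau=a0, initial_amplitude=a0,
            residual_rms=0.0, flags=("tau unidentifiable: constant amplitudes",),
        )
    halfway = (a0 + plateau0) / 2.0
    below = np.nonzero(a <= halfway)[0] if a0 > plateau0 else np.nonzero(a >= halfway)[0]
    tau0 = float(t[below[0]]) if below.size and t[below[0]] > 0 else max(t[-1] / 5, 1e-3)

    def model(tt, a0_, plat_, tau_):
        return plat_ + (a0_ - plat_) * np.exp(-tt / tau_)

    try:
        popt, _ = optimize.curve_fit(
            model, t, a,
            p0=[a0, plateau0, tau0],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        resid = a - model(t, a0, plateau0, tau0)
        return DepressionFit(
            tau_s=float("nan"), plateau=plateau0, initial_amplitude=a0,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            flags=("fit did not converge",),
        )
    resid = a - model(t, *popt)
    return DepressionFit(
        tau_s=float(popt[2]),
        plateau=float(popt[1]),
        initial_amplitude=float(popt[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def mean_quantal_content(epsc_amps, mepsc_amps) -> QuantalStats:
    """Mean quantal content: mean EPSC amplitude over mean mEPSC amplitude."""
    e = np.asarray(epsc_amps, dtype=float)
    m = np.asarray(mepsc_amps, dtype=float)
    if e.size == 0 or m.size == 0:
        raise ValueError("both amplitude lists must be non-empty")
    me, mm = float(e.mean()), float(m.mean())
    if me <= 0 or mm <= 0:
        raise ValueError("mean amplitudes must be positive")
    return QuantalStats(mean_epsc=me, mean_mepsc=mm, mqc=me / mm)
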