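"""Single-molecule channel counting from photoconversion/bleaching movies.

The estimator reproduces a ratiometric counting procedure: the number of
tagged channels in an active zone equals the maximal converted fluorescence
shortly after UV onset divided by the fluorescence of a single tag molecule,
the latter estimated from discrete step amplitudes (bleaching and blinking
events) late in the trace, where few molecules remain and steps are
unitary.

Steps are found by exact penalized least-squares change-point segmentation
(optimal partitioning by dynamic programming): minimize over all
segmentations the within-segment sum of squared residuals plus a per-change
penalty. The default penalty is BIC-like, 2 * sigma^2 * log(n), with sigma
estimated robustly from first differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "Movie",
    "BleachTrace",
    "StepModel",
    "ChannelCountEstimate",
    "correct_drift",
    "extract_roi_trace",
    "detect_steps",
    "estimate_unitary_intensity",
    "count_channels",
    "count_channels_from_trace",
    "aggregate_counts",
]


@dataclass
class Movie:
    """A single-channel bleaching movie: (frame, row, col) intensities."""

    frames: np.ndarray
    frame_interval: float = 0.05
    pixel_size: float = 71.0
    uv_onset_frame: int = 250

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) array")
        if not (0 <= self.uv_onset_frame < self.frames.shape[0]):
            raise ValueError("uv_onset_frame outside movie")


@dataclass
class BleachTrace:
    """Background-subtracted summed ROI intensity of one AZ over time."""

    intensity: np.ndarray
    times: np.ndarray
    uv_onset_frame: int
    roi_center: tuple[int, int] = (0, 0)
    roi_size: int = 5

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.intensity.shape != self.times.shape:
            raise ValueError("intensity and times must have equal length")


@dataclass
class StepModel:
    """Piecewise-constant fit: segment k covers [boundaries[k], boundaries[k+1])."""

    change_points: np.ndarray  # strictly increasing interior boundaries
    segment_levels: np.ndarray
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.change_points = np.asarray(self.change_points, dtype=int)
        self.segment_levels = np.asarray(self.segment_levels, dtype=float)
        if self.segment_levels.size != self.change_points.size + 1:
            raise ValueError("need one more level than change points")
        if np.any(np.diff(self.change_points) <= 0):
            raise ValueError("change points must be strictly increasing")

    @property
    def step_amplitudes(self) -> np.ndarray:
        """Signed level differences at each change point."""
        return np.diff(self.segment_levels)

    @property
    def n_steps(self) -> int:
        return self.change_points.size


@dataclass
class ChannelCountEstimate:
    """Peak/unitary intensity ratio for one AZ, with QC."""

    peak_intensity: float
    unitary_intensity: float
    n_channels: float
    n_unitary_events: int
    qc_pass: bool
    qc_reasons: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# drift correction


def correct_drift(movie: Movie, upsample_factor: int = 20) -> tuple[Movie, np.ndarray]:
    """Estimate and remove rigid lateral drift frame by frame.

    Each frame is registered against the temporal-median image by
    cross-correlation with subpixel refinement, then shifted back with
    spline interpolation. Returns the corrected movie and the applied
    (dy, dx) shifts per frame.
    """
    frames = movie.frames
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 frames to correct drift")
    if not np.any(frames):
        warnings.warn("all-zero movie; drift correction skipped", stacklevel=2)
        return movie, np.zeros((n_frames, 2))

    # register every frame against the temporal median, then gate on the
    # post-shift correlation with the reference: frames without repeatable
    # structure (pure noise before photoconversion, fully bleached tails)
    # produce arbitrary shifts and near-zero correlation, and instead
    # inherit the temporally nearest reliable estimate.
    reference = np.median(frames, axis=0)
    shifts = np.zeros((n_frames, 2))
    quality = np.zeros(n_frames)
    ref_c = reference - reference.mean()
    ref_norm = np.sqrt((ref_c**2).sum())
    for t in range(n_frames):
        shift, _, _ = phase_cross_correlation(
            reference, frames[t], upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = shift
        moved = ndimage.shift(frames[t], shift, order=1, mode="nearest")
        mc = moved - moved.mean()
        denom = ref_norm * np.sqrt((mc**2).sum())
        quality[t] = (ref_c * mc).sum() / denom if denom > 0 else 0.0
    reliable = quality >= 0.2
    if not reliable.any():
        warnings.warn("no frames register reliably against the temporal "
                      "median; drift correction skipped", stacklevel=2)
        return movie, np.zeros((n_frames, 2))
    idx = np.nonzero(reliable)[0]
    for t in np.nonzero(~reliable)[0]:
        shifts[t] = shifts[idx[np.argmin(np.abs(idx - t))]]
    corrected = np.empty_like(frames)
    for t in range(n_frames):
        corrected[t] = ndimage.shift(frames[t], shifts[t], order=1, mode="nearest")
    out = Movie(
        frames=corrected,
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        uv_onset_frame=movie.uv_onset_frame,
    )
    return out, shifts


# ---------------------------------------------------------------------------
# ROI extraction


def extract_roi_trace(
    movie: Movie,
    center: tuple[int, int],
    roi_size: int = 5,
    annulus: tuple[int, int] = (5, 9),
) -> BleachTrace:
    """Summed ROI intensity minus local background, per frame.

    The readout region is ``roi_size x roi_size`` pixels centered on
    ``center``. Background per frame is the mean over a square annulus
    between the ``annulus[0]``- and ``annulus[1]``-pixel windows around the
    same center (clipped at the image edge), scaled to the ROI area.
    """
    half = roi_size // 2
    r, c = center
    n_t, n_r, n_c = movie.frames.shape
    if r - half < 0 or c - half < 0 or r + half >= n_r or c + half >= n_c:
        raise ValueError(f"ROI center {center} within {half} px of the border")
    roi = movie.frames[:, r - half : r + half + 1, c - half : c + half + 1]
    roi_sum = roi.sum(axis=(1, 2))

    inner, outer = annulus
    hi_in, hi_out = inner // 2, outer // 2
    r0, r1 = max(r - hi_out, 0), min(r + hi_out + 1, n_r)
    c0, c1 = max(c - hi_out, 0), min(c + hi_out + 1, n_c)
    block = movie.frames[:, r0:r1, c0:c1]
    mask = np.ones(block.shape[1:], dtype=bool)
    ir0, ir1 = r - hi_in - r0, r + hi_in + 1 - r0
    ic0, ic1 = c - hi_in - c0, c + hi_in + 1 - c0
    mask[max(ir0, 0) : ir1, max(ic0, 0) : ic1] = False
    if not mask.any():
        raise ValueError("background annulus empty; widen the outer window")
    bg_per_px = block[:, mask].mean(axis=1)

    intensity = roi_sum - bg_per_px * roi_size**2
    times = np.arange(n_t) * movie.frame_interval
    return BleachTrace(
        intensity=intensity,
        times=times,
        uv_onset_frame=movie.uv_onset_frame,
        roi_center=(r, c),
        roi_size=roi_size,
    )


# ---------------------------------------------------------------------------
# change-point segmentation


def default_penalty(trace_values: np.ndarray) -> float:
    """BIC-like penalty 2 * sigma^2 * log(n), sigma from robust first differences."""
    x = np.asarray(trace_values, dtype=float)
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6745 / np.sqrt(2.0)
    sigma = max(sigma, 1e-12)
    return 2.0 * sigma**2 * np.log(x.size)


def segment_trace(values: np.ndarray, penalty: float) -> tuple[np.ndarray, float]:
    """Exact penalized least-squares segmentation (optimal partitioning).

    Minimizes sum of within-segment squared deviations from the segment
    mean plus ``penalty`` per change point, over all segmentations. Ties
    are broken toward fewer change points. Returns (change points,
    penalized objective).
    """
    if penalty <= 0:
        raise ValueError(f"penalty must be positive, got {penalty}")
    x = np.asarray(values, dtype=float)
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    f = np.empty(n + 1)
    n_cp = np.zeros(n + 1, dtype=int)
    back = np.zeros(n + 1, dtype=int)
    f[0] = -penalty
    tol = 1e-9 * max(float(s2[-1]), 1.0)
    for t in range(1, n + 1):
        starts = np.arange(t)
        lengths = t - starts
        seg_cost = (s2[t] - s2[starts]) - (s1[t] - s1[starts]) ** 2 / lengths
        total = f[:t] + seg_cost + penalty
        m = total.min()
        cand = np.nonzero(total <= m + tol)[0]
        best = cand[np.argmin(n_cp[cand])]
        f[t] = total[best]
        back[t] = best
        n_cp[t] = n_cp[best] + 1
    # recover boundaries
    bounds = []
    t = n
    while t > 0:
        bounds.append(back[t])
        t = back[t]
    bounds = np.array(bounds[::-1], dtype=int)
    return bounds[1:], float(f[n])  # drop the leading 0


def detect_steps(trace: BleachTrace, penalty: float | None = None) -> StepModel:
    """Fit a piecewise-constant step model to a bleaching trace.

    Exact dynamic-programming search for the penalized least-squares
    segmentation. ``penalty`` defaults to :func:`default_penalty` of the
    trace. A trace that is best fit by a single segment yields a StepModel
    with zero steps.
    """
    x = trace.intensity
    if x.size - trace.uv_onset_frame < 20:
        raise ValueError("need >= 20 frames after UV onset")
    if penalty is None:
        penalty = default_penalty(x)
    elif penalty <= 0:
        raise ValueError(f"penalty must be positive, got {penalty}")
    cps, objective = segment_trace(x, penalty)
    bounds = np.concatenate([[0], cps, [x.size]])
    levels = np.array(
        [x[b0:b1].mean() for b0, b1 in zip(bounds[:-1], bounds[1:])]
    )
    return StepModel(change_points=cps, segment_levels=levels, objective=objective)


# ---------------------------------------------------------------------------
# unitary intensity


def _kmeans_1d(x: np.ndarray, k: int, n_iter: int = 50) -> np.ndarray:
    """Lloyd's algorithm on sorted 1-D data with quantile init; returns labels."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    labels = np.zeros(x.size, dtype=int)
    for _ in range(n_iter):
        labels_new = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        if np.array_equal(labels_new, labels) and _ > 0:
            break
        labels = labels_new
        for j in range(k):
            if np.any(labels == j):
                centers[j] = x[labels == j].mean()
    return labels


def _mean_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    vals = []
    for i in range(x.size):
        same = x[(labels == labels[i])]
        if same.size <= 1:
            vals.append(0.0)
            continue
        a = np.abs(same - x[i]).sum() / (same.size - 1)
        b = np.inf
        for j in np.unique(labels):
            if j == labels[i]:
                continue
            other = x[labels == j]
            b = min(b, np.abs(other - x[i]).mean())
        vals.append(0.0 if b == np.inf else (b - a) / max(a, b, 1e-300))
    return float(np.mean(vals))


def estimate_unitary_intensity(
    step_model: StepModel,
    trace: BleachTrace,
    use_upward: bool = True,
    min_silhouette: float = 0.5,
    noise_floor_sigmas: float = 4.0,
    min_segment_frames: int = 5,
) -> tuple[float, int]:
    """Single-molecule intensity from late-trace step amplitudes.

    Collects absolute amplitudes of steps whose post-step segment starts in
    the second half of the illumination sequence (frames beyond
    uv_onset + (n - uv_onset)/2), where single-molecule bleaching and
    blinking dominate. Two reliability filters apply: amplitudes below
    ``noise_floor_sigmas`` robust trace sigmas are discarded (spurious
    noise steps), as are steps flanked by a segment shorter than
    ``min_segment_frames`` (whose levels are too uncertain). Because
    amplitudes fall on an integer-multiple ladder, the distribution is
    isolated into 1 to 3 modes by 1-D k-means (k chosen by mean
    silhouette); the unitary intensity is the median of the
    smallest-amplitude mode.

    Returns (unitary, n_events); (nan, 0) when no usable events exist.
    """
    n = trace.intensity.size
    half_start = trace.uv_onset_frame + (n - trace.uv_onset_frame) // 2
    amps = step_model.step_amplitudes
    starts = step_model.change_points  # post-step segment start frames
    bounds = np.concatenate([[0], starts, [n]])
    seg_len = np.diff(bounds)
    reliable = (seg_len[:-1] >= min_segment_frames) & (seg_len[1:] >= min_segment_frames)
    late = (starts >= half_start) & reliable
    if not use_upward:
        late &= amps < 0
    selected = np.abs(amps[late])
    d = np.diff(trace.intensity)
    sigma = np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0)
    selected = selected[selected > noise_floor_sigmas * sigma]
    if selected.size == 0:
        return float("nan"), 0
    if selected.size < 4 or np.ptp(selected) < 1e-12 * selected.max():
        return float(np.median(selected)), int(selected.size)

    best_labels = np.zeros(selected.size, dtype=int)
    best_sil = -np.inf
    for k in (2, 3):
        if selected.size <= k:
            continue
        labels = _kmeans_1d(np.sort(selected), k)
        sil = _mean_silhouette(np.sort(selected), labels)
        if sil > best_sil:
            best_sil, best_k, best_sorted_labels = sil, k, labels
    x_sorted = np.sort(selected)
    if best_sil >= min_silhouette:
        labels = best_sorted_labels
        centers = [x_sorted[labels == j].mean() for j in np.unique(labels)]
        smallest = np.unique(labels)[int(np.argmin(centers))]
        mode = x_sorted[labels == smallest]
    else:
        mode = x_sorted
    return float(np.median(mode)), int(mode.size)


# ---------------------------------------------------------------------------
# channel count


def count_channels(
    trace: BleachTrace,
    step_model: StepModel,
    unitary: float,
    peak_window_frac: float = 0.25,
) -> ChannelCountEstimate:
    """Channel count = peak converted intensity / unitary intensity.

    The peak is the maximum fitted segment level within the window from UV
    onset to ``peak_window_frac`` of the post-onset frames ("shortly after
    starting the photoconversion"). Counts are reported un-rounded.
    """
    if not np.isfinite(unitary) or unitary <= 0:
        raise ValueError(f"unitary intensity must be positive, got {unitary}")
    n = trace.intensity.size
    onset = trace.uv_onset_frame
    win_end = onset + max(int(peak_window_frac * (n - onset)), 1)

    bounds = np.concatenate([[0], step_model.change_points, [n]])
    reasons: list[str] = []
    peak = -np.inf
    peak_seg_start = 0
    for b0, b1, level in zip(bounds[:-1], bounds[1:], step_model.segment_levels):
        if b1 <= onset or b0 >= win_end:
            continue
        if level > peak:
            peak = level
            peak_seg_start = b0
    if not np.isfinite(peak) or peak <= 0:
        return ChannelCountEstimate(
            peak_intensity=max(peak, 0.0) if np.isfinite(peak) else 0.0,
            unitary_intensity=unitary,
            n_channels=0.0,
            n_unitary_events=0,
            qc_pass=False,
            qc_reasons=("no signal",),
        )
    if peak_seg_start < onset:
        reasons.append("peak segment spans UV onset")
    n_channels = peak / unitary
    return ChannelCountEstimate(
        peak_intensity=float(peak),
        unitary_intensity=float(unitary),
        n_channels=float(n_channels),
        n_unitary_events=0,
        qc_pass=not reasons,
        qc_reasons=tuple(reasons),
    )


def count_channels_from_trace(
    trace: BleachTrace,
    penalty: float | None = None,
    peak_window_frac: float = 0.25,
) -> ChannelCountEstimate:
    """Full per-AZ pipeline: segment, estimate unitary, form the ratio."""
    model = detect_steps(trace, penalty=penalty)
    unitary, n_events = estimate_unitary_intensity(model, trace)
    if n_events == 0 or not np.isfinite(unitary) or unitary <= 0:
        return ChannelCountEstimate(
            peak_intensity=float(np.max(model.segment_levels, initial=0.0)),
            unitary_intensity=float("nan"),
            n_channels=float("nan"),
            n_unitary_events=0,
            qc_pass=False,
            qc_reasons=("no single-molecule events",),
        )
    est = count_channels(trace, model, unitary, peak_window_frac=peak_window_frac)
    est.n_unitary_events = n_events
    return est


# ---------------------------------------------------------------------------
# cohort aggregation


def aggregate_counts(
    estimates: Sequence[ChannelCountEstimate],
    animals: Sequence,
    genotypes: Sequence,
    min_az_per_animal: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal and per-genotype channel-count summaries.

    QC-failing AZs are excluded from the means but counted. Genotype means
    average the animal means (each animal one observation). Animals with
    fewer than ``min_az_per_animal`` QC-passing AZs are flagged, mirroring
    the minimum-AZ inclusion rule of the original cohorts.
    """
    if not (len(estimates) == len(animals) == len(genotypes)):
        raise ValueError("estimates, animals, genotypes must align")
    df = pd.DataFrame(
        {
            "animal": list(animals),
            "genotype": list(genotypes),
            "n_channels": [e.n_channels for e in estimates],
            "qc_pass": [e.qc_pass for e in estimates],
        }
    )
    rows = []
    for (genotype, animal), sub in df.groupby(["genotype", "animal"], sort=True):
        passing = sub.loc[sub.qc_pass, "n_channels"]
        if passing.empty:
            warnings.warn(f"animal {animal!r} has no QC-passing AZs; omitted",
                          stacklevel=2)
            continue
        rows.append(
            {
                "genotype": genotype,
                "animal": animal,
                "mean_channels": passing.mean(),
                "sd_channels": passing.std(ddof=1) if passing.size > 1 else 0.0,
                "n_az": int(passing.size),
                "n_excluded": int((~sub.qc_pass).sum()),
                "below_minimum": bool(passing.size < min_az_per_animal),
            }
        )
    per_animal = pd.DataFrame(
        rows,
        columns=["genotype", "animal", "mean_channels", "sd_channels",
                 "n_az", "n_excluded", "below_minimum"],
    )
    per_genotype = (
        per_animal.groupby("genotype", sort=True)
        .agg(
            mean_channels=("mean_channels", "mean"),
            sd_between_animals=("mean_channels", "std"),
            n_animals=("animal", "nunique"),
            n_az=("n_az", "sum"),
        )
        .reset_index()
    )
    return per_animal, per_genotype
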