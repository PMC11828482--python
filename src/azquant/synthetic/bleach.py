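"""Photoconversion/bleaching movie generator for single-molecule counting.

Emulates TIRF imaging of photoconvertible-tag (mEOS4b-class) labelled calcium
channels clustered at active zones: continuous red-channel illumination, UV
onset at a configurable frame triggering stochastic green-to-red conversion,
then irreversible bleaching with reversible dark-state blinking.

Each fluorophore follows a four-state chain stepped per frame::

    unconverted --(conversion_rate, after UV onset)--> bright
    bright --(blink_off_rate)--> dark --(blink_on_rate)--> bright
    bright --(bleach_rate)--> bleached            (absorbing)

Bleaching occurs from the bright state only (photobleaching requires
excitation); dark-state fluorophores are protected. The red intensity of an
AZ at frame *t* is ``unitary_intensity`` times its number of bright
fluorophores, so a noiseless trace is an integer staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BleachSimConfig", "simulate_bleach_trace", "simulate_bleach_movie"]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class BleachSimConfig:
    """Conditions of one photoconversion/bleaching acquisition.

    Parameters
    ----------
    n_az : number of active zones in the field.
    channels_per_az : fixed integer, or a draw distribution given as
        ``("uniform", low, high)`` (inclusive integers) or
        ``("poisson", mean)``.
    unitary_intensity : red fluorescence of one bright fluorophore, a.u.
    conversion_rate : per-frame probability of green-to-red photoconversion
        once the UV laser is on.
    bleach_rate : per-frame probability that a bright fluorophore bleaches.
    blink_off_rate, blink_on_rate : per-frame probabilities of the
        reversible bright<->dark transitions.
    background_level : constant camera background, a.u. per pixel.
    noise_sd : additive Gaussian noise, a.u. For movies this is per pixel
        per frame; :func:`simulate_bleach_trace` applies it directly to the
        summed ROI trace.
    frame_rate : Hz. 20 Hz matches the acquisition this emulates.
    n_frames : movie length; must leave >= 10 frames after UV onset.
    uv_onset_frame : frame index at which photoconversion becomes possible.
    pixel_size : nm, isotropic.
    drift_per_frame : (dy, dx) rigid lateral drift, pixels per frame.
    psf_sigma_px : Gaussian PSF sigma for spot rendering, pixels.
    poisson_noise : add Poisson shot noise on top of the rendered signal
        (off by default; Gaussian read noise is the primary model).
    seed : top-level seed; per-AZ child streams are spawned from it.
    """

    n_az: int = 1
    channels_per_az: int | tuple = 10
    unitary_intensity: float = 100.0
    conversion_rate: float = 0.35
    bleach_rate: float = 0.001
    blink_off_rate: float = 0.003
    blink_on_rate: float = 0.1
    background_level: float = 50.0
    noise_sd: float = 10.0
    frame_rate: float = 20.0
    n_frames: int = 2500
    uv_onset_frame: int = 250
    pixel_size: float = 71.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    psf_sigma_px: float = 1.3
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_az < 1:
            raise ValueError(f"n_az must be >= 1, got {self.n_az}")
        if self.unitary_intensity <= 0:
            raise ValueError(
                f"unitary_intensity must be > 0, got {self.unitary_intensity}"
            )
        for name in ("conversion_rate", "bleach_rate", "blink_off_rate", "blink_on_rate"):
            _check_prob(name, getattr(self, name))
        if self.bleach_rate + self.blink_off_rate > 1.0:
            raise ValueError("bleach_rate + blink_off_rate must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.background_level < 0:
            raise ValueError(
                f"background_level must be >= 0, got {self.background_level}"
            )
        if self.n_frames < self.uv_onset_frame + 10:
            raise ValueError(
                "n_frames must be >= uv_onset_frame + 10 "
                f"(got n_frames={self.n_frames}, uv_onset_frame={self.uv_onset_frame})"
            )

    def draw_channel_count(self, rng: np.random.Generator) -> int:
        """Sample one AZ's true channel count from ``channels_per_az``."""
        spec = self.channels_per_az
        if isinstance(spec, (int, np.integer)):
            return int(spec)
        kind = spec[0]
        if kind == "uniform":
            return int(rng.integers(spec[1], spec[2] + 1))
        if kind == "poisson":
            return int(rng.poisson(spec[1]))
        raise ValueError(f"unknown channels_per_az distribution {kind!r}")


def _geometric(rng: np.random.Generator, p: float) -> int:
    """Frames until an event with per-frame probability p (support 1, 2, ...)."""
    if p >= 1.0:
        return 1
    return int(rng.geometric(p))


def _simulate_fluorophore(
    config: BleachSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int, int]:
    """Bright/dark history of one fluorophore.

    Returns (bright boolean per frame, conversion frame, bleach frame);
    frames use -1 for "never within the movie".
    """
    n = config.n_frames
    bright = np.zeros(n, dtype=bool)
    if config.conversion_rate == 0.0:
        return bright, -1, -1
    t_conv = config.uv_onset_frame + _geometric(rng, config.conversion_rate) - 1
    if t_conv >= n:
        return bright, -1, -1
    t = t_conv
    p_leave = config.bleach_rate + config.blink_off_rate
    t_bleach = -1
    while t < n:
        # bright dwell
        if p_leave == 0.0:
            bright[t:] = True
            break
        dwell = _geometric(rng, p_leave)
        bright[t : min(t + dwell, n)] = True
        t += dwell
        if t >= n:
            break
        if rng.random() < config.bleach_rate / p_leave:
            t_bleach = t
            break
        # dark dwell
        if config.blink_on_rate == 0.0:
            break
        t += _geometric(rng, config.blink_on_rate)
    return bright, t_conv, t_bleach


def simulate_bleach_trace(
    config: BleachSimConfig, child_seed: np.random.SeedSequence | int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a single AZ's background-subtracted ROI intensity trace.

    The trace is ``unitary_intensity`` times the number of bright
    fluorophores per frame, plus additive Gaussian noise of sd
    ``config.noise_sd`` (interpreted at the trace level here: the per-pixel
    read noise of a summed ROI collapses onto the trace as one Gaussian
    term).

    Returns
    -------
    trace : float array, one entry per frame.
    truth : DataFrame with one row per fluorophore
        (``fluorophore``, ``conversion_frame``, ``bleach_frame``) and the
        attribute ``truth.attrs["n_channels"]``.
    """
    if child_seed is None:
        child_seed = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(child_seed)
    n_channels = config.draw_channel_count(rng)
    n_bright = np.zeros(config.n_frames, dtype=np.int64)
    rows = []
    for i in range(n_channels):
        bright, t_conv, t_bleach = _simulate_fluorophore(config, rng)
        n_bright += bright
        rows.append({"fluorophore": i, "conversion_frame": t_conv, "bleach_frame": t_bleach})
    trace = config.unitary_intensity * n_bright.astype(float)
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, size=config.n_frames)
    truth = pd.DataFrame(rows, columns=["fluorophore", "conversion_frame", "bleach_frame"])
    truth.attrs["n_channels"] = n_channels
    return trace, truth


def _az_grid(n_az: int, margin: int, spacing: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Lay AZ centers on a square grid; returns centers and frame shape."""
    side = int(np.ceil(np.sqrt(n_az)))
    coords = []
    for i in range(n_az):
        r, c = divmod(i, side)
        coords.append((margin + r * spacing, margin + c * spacing))
    extent = margin + (side - 1) * spacing + margin + 1
    return np.asarray(coords, dtype=float), (extent, extent)


def simulate_bleach_movie(
    config: BleachSimConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a full bleaching movie plus its ground-truth sidecar.

    AZs are diffraction-limited Gaussian spots on a regular grid (margin 7,
    spacing 14 px, comfortably separating 5x5 readout ROIs). Per frame the
    image is background + sum of spots scaled by each AZ's bright-fluorophore
    count, rigidly translated by the cumulative drift, plus Gaussian noise.

    Returns
    -------
    movie : float array (frame, row, col).
    truth : DataFrame, one row per AZ: ``az_id``, ``row``, ``col`` (initial
        spot center, pixels), ``n_channels``. Per-fluorophore event frames
        are in ``truth.attrs["fluorophores"]`` (DataFrame with az_id).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_az + 1)
    centers, shape = _az_grid(config.n_az, margin=7, spacing=14)

    brightness = np.zeros((config.n_az, config.n_frames), dtype=np.int64)
    az_rows = []
    fluor_tables = []
    for a in range(config.n_az):
        rng = np.random.default_rng(children[a])
        n_channels = config.draw_channel_count(rng)
        for i in range(n_channels):
            bright, t_conv, t_bleach = _simulate_fluorophore(config, rng)
            brightness[a] += bright
            fluor_tables.append(
                {"az_id": a, "fluorophore": i,
                 "conversion_frame": t_conv, "bleach_frame": t_bleach}
            )
        az_rows.append(
            {"az_id": a, "row": centers[a, 0], "col": centers[a, 1],
             "n_channels": n_channels}
        )

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    sig2 = 2.0 * config.psf_sigma_px**2
    dy, dx = config.drift_per_frame
    frames = np.full((config.n_frames, h, w), float(config.background_level))
    # spot profiles are unit-sum Gaussians so the ROI sum approximates
    # unitary_intensity * n_bright
    norm = 1.0 / (2.0 * np.pi * config.psf_sigma_px**2)
    for t in range(config.n_frames):
        if not brightness[:, t].any() and (dy == 0 and dx == 0):
            continue
        cy = centers[:, 0] + dy * t
        cx = centers[:, 1] + dx * t
        for a in np.nonzero(brightness[:, t])[0]:
            amp = config.unitary_intensity * brightness[a, t] * norm
            frames[t] += amp * np.exp(
                -((yy - cy[a]) ** 2 + (xx - cx[a]) ** 2) / sig2
            )
    noise_rng = np.random.default_rng(children[-1])
    if config.poisson_noise:
        frames = noise_rng.poisson(np.clip(frames, 0, None)).astype(float)
    if config.noise_sd > 0:
        frames = frames + noise_rng.normal(0.0, config.noise_sd, size=frames.shape)

    truth = pd.DataFrame(az_rows, columns=["az_id", "row", "col", "n_channels"])
    truth.attrs["fluorophores"] = pd.DataFrame(
        fluor_tables,
        columns=["az_id", "fluorophore", "conversion_frame", "bleach_frame"],
    )
    return frames, truth
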