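"""Three-channel synapse stack generator with ground-truth geometry.

Emulates STED/confocal stacks of neuromuscular boutons triple-labelled for
the active-zone scaffold Bruchpilot (brp), calcium-channel isoform tags
(two "cac" channels, one per splice-isoform tag), and the neuronal membrane
marker HRP. Each active zone is a central cac cluster ringed by
``brp_puncta_per_az`` brp puncta at ``ring_radius`` nm, all within one
optical section — the planar "top view" arrangement used for
nearest-punctum distance quantification.

Coordinates follow one convention everywhere: 0-based voxel indices in
(z, y, x) order, intensity centered on voxel centers, physical position =
index * voxel_size (nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["SynapseSimConfig", "simulate_synapse_stack"]

CONTENT_CLASSES = ("both", "A_only", "B_only")


@dataclass(frozen=True)
class SynapseSimConfig:
    """Conditions of one synthetic synapse stack.

    Defaults emulate STED sampling (24.44 nm in plane, 191.69 nm axial)
    with four brp puncta ringing each cac cluster at 106 nm, and a 2:1
    intensity ratio between the two cac isoform channels (B:A), the
    arrangement and stoichiometry these stacks are used to measure.
    """

    stack_shape: tuple[int, int, int] = (9, 128, 128)
    voxel_size: tuple[float, float, float] = (191.69, 24.44, 24.44)
    n_boutons: int = 1
    az_per_bouton: int = 4
    brp_puncta_per_az: int = 4
    ring_radius: float = 106.0
    psf_sigma: tuple[float, float, float] = (150.0, 30.0, 30.0)
    cac_intensity_A: float = 500.0
    cac_intensity_B: float = 1000.0
    brp_intensity: float = 1000.0
    hrp_intensity: float = 200.0
    content_fractions: dict = field(
        default_factory=lambda: {"both": 0.95, "A_only": 0.0, "B_only": 0.05}
    )
    intensity_cv: float = 0.15
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError(f"ring_radius must be > 0, got {self.ring_radius}")
        unknown = set(self.content_fractions) - set(CONTENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown content classes {sorted(unknown)}")
        total = sum(self.content_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"content_fractions must sum to 1, got {total}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _add_spot(
    volume: np.ndarray,
    center_vox: np.ndarray,
    sigma_vox: np.ndarray,
    integrated: float,
) -> None:
    """Deposit a Gaussian spot of given integrated intensity in place.

    A zero sigma on every axis collapses to a single-voxel deposit.
    """
    if np.all(sigma_vox == 0):
        idx = tuple(int(round(c)) for c in center_vox)
        if all(0 <= i < s for i, s in zip(idx, volume.shape)):
            volume[idx] += integrated
        return
    half = np.maximum(np.ceil(4 * sigma_vox).astype(int), 1)
    lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half).astype(int) + 1, volume.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
    )
    exponent = np.zeros(grids[0].shape)
    norm = 1.0
    for g, c, s in zip(grids, center_vox, sigma_vox):
        if s == 0:
            # treat as a 1-voxel-wide axis: keep only the nearest plane
            exponent = np.where(g == int(round(c)), exponent, -np.inf)
        else:
            exponent = exponent - (g - c) ** 2 / (2 * s**2)
            norm *= s * np.sqrt(2 * np.pi)
    volume[tuple(slice(l, h) for l, h in zip(lo, hi))] += (
        integrated / norm * np.exp(exponent)
    )


def simulate_synapse_stack(
    config: SynapseSimConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Generate the four channel volumes and the geometry truth table.

    Returns
    -------
    channels : dict with keys ``"cac_a"``, ``"cac_b"``, ``"cac"`` (sum of
        the two isoform channels), ``"brp"``, ``"hrp"``; each a float array
        of ``config.stack_shape``.
    truth : DataFrame with one row per punctum: ``kind`` ("cac"/"brp"),
        ``az_id``, ``punctum``, ``plane_index``, ``z_nm``, ``y_nm``,
        ``x_nm``. Per-AZ content classes and channel intensities are in
        ``truth.attrs["az_table"]``.
    """
    vz, vy, vx = config.voxel_size
    if config.ring_radius < min(vy, vx):
        warnings.warn(
            f"ring_radius {config.ring_radius} nm is below one in-plane voxel "
            f"({min(vy, vx)} nm); geometry generated anyway",
            stacklevel=2,
        )
    nz, ny, nx = config.stack_shape
    ss = np.random.SeedSequence(config.seed)
    n_total_az = config.n_boutons * config.az_per_bouton
    children = ss.spawn(n_total_az + 2)  # one per AZ, layout, noise
    layout_rng = np.random.default_rng(children[-2])

    shape = config.stack_shape
    chan = {k: np.zeros(shape) for k in ("cac_a", "cac_b", "brp", "hrp")}
    sigma_vox = np.asarray(config.psf_sigma) / np.asarray(config.voxel_size)

    # bouton membrane (HRP): smoothed ellipsoidal blobs filling the field
    zz, yy, xxg = np.mgrid[0:nz, 0:ny, 0:nx]
    bouton_centers = []
    for b in range(config.n_boutons):
        cz = nz / 2.0
        cy = ny * (0.5 if config.n_boutons == 1 else (b + 0.5) / config.n_boutons)
        cx = nx / 2.0
        bouton_centers.append((cz, cy, cx))
        rz, ry, rx = nz * 0.45, ny * 0.42 / config.n_boutons + ny * 0.05, nx * 0.42
        inside = (
            ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xxg - cx) / rx) ** 2
        ) <= 1.0
        chan["hrp"] += inside * config.hrp_intensity
    chan["hrp"] = ndimage.gaussian_filter(chan["hrp"], sigma=(0.5, 1.5, 1.5))

    classes = list(config.content_fractions.keys())
    probs = np.array([config.content_fractions[c] for c in classes])

    ring_r_vox_y = config.ring_radius / vy
    margin_y = ring_r_vox_y + 4 * max(sigma_vox[1], 1)
    margin_x = config.ring_radius / vx + 4 * max(sigma_vox[2], 1)

    punctum_rows = []
    az_rows = []
    az_id = 0
    for b, (cz, cy, cx) in enumerate(bouton_centers):
        # AZ centers on a coarse in-plane grid inside the bouton so rings
        # never overlap; z planes cycle through the interior sections
        per_side = int(np.ceil(np.sqrt(config.az_per_bouton)))
        span_y = ny / config.n_boutons * 0.5
        span_x = nx * 0.5
        for k in range(config.az_per_bouton):
            rng = np.random.default_rng(children[az_id])
            gy, gx = divmod(k, per_side)
            ay = cy - span_y / 2 + (gy + 0.5) * span_y / per_side
            ax = cx - span_x / 2 + (gx + 0.5) * span_x / per_side
            ay = float(np.clip(ay + rng.uniform(-2, 2), margin_y, ny - 1 - margin_y))
            ax = float(np.clip(ax + rng.uniform(-2, 2), margin_x, nx - 1 - margin_x))
            # central sections only: near the z edges the bouton cross-section
            # (and with it the membrane mask) shrinks away from the rings
            mid = nz // 2
            offsets = (0, -1, 1) if nz >= 5 else (0,)
            plane = int(np.clip(mid + offsets[az_id % len(offsets)], 0, nz - 1))
            content = classes[rng.choice(len(classes), p=probs)]
            jitter = lambda: max(1.0 + config.intensity_cv * rng.standard_normal(), 0.1)
            int_a = config.cac_intensity_A * jitter() if content in ("both", "A_only") else 0.0
            int_b = config.cac_intensity_B * jitter() if content in ("both", "B_only") else 0.0

            center_vox = np.array([plane, ay, ax])
            if int_a > 0:
                _add_spot(chan["cac_a"], center_vox, sigma_vox, int_a)
            if int_b > 0:
                _add_spot(chan["cac_b"], center_vox, sigma_vox, int_b)
            punctum_rows.append(
                {"kind": "cac", "az_id": az_id, "punctum": -1, "plane_index": plane,
                 "z_nm": plane * vz, "y_nm": ay * vy, "x_nm": ax * vx}
            )
            theta0 = rng.uniform(0, 2 * np.pi)
            for j in range(config.brp_puncta_per_az):
                th = theta0 + 2 * np.pi * j / config.brp_puncta_per_az
                py = ay + (config.ring_radius / vy) * np.sin(th)
                px = ax + (config.ring_radius / vx) * np.cos(th)
                pv = np.array([plane, py, px])
                _add_spot(chan["brp"], pv, sigma_vox, config.brp_intensity)
                punctum_rows.append(
                    {"kind": "brp", "az_id": az_id, "punctum": j, "plane_index": plane,
                     "z_nm": plane * vz, "y_nm": py * vy, "x_nm": px * vx}
                )
            az_rows.append(
                {"az_id": az_id, "bouton_id": b, "content_class": content,
                 "intensity_a": int_a, "intensity_b": int_b,
                 "plane_index": plane, "y_nm": ay * vy, "x_nm": ax * vx}
            )
            az_id += 1

    if config.noise_sd > 0:
        # additive read noise; channels emulate background-subtracted data,
        # so small negative excursions are kept (clipping would skew the
        # background mean above its median)
        noise_rng = np.random.default_rng(children[-1])
        for key in chan:
            chan[key] = chan[key] + noise_rng.normal(0, config.noise_sd, size=shape)

    chan["cac"] = chan["cac_a"] + chan["cac_b"]
    truth = pd.DataFrame(
        punctum_rows,
        columns=["kind", "az_id", "punctum", "plane_index", "z_nm", "y_nm", "x_nm"],
    )
    truth.attrs["az_table"] = pd.DataFrame(
        az_rows,
        columns=["az_id", "bouton_id", "content_class", "intensity_a",
                 "intensity_b", "plane_index", "y_nm", "x_nm"],
    )
    return chan, truth
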