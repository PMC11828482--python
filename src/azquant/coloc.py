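"""Masked Pearson/Manders colocalization with automatic Costes thresholds.

All statistics are evaluated strictly inside a membrane mask (the HRP
channel at the neuromuscular junction): voxels outside the mask never enter
the regression, the threshold scan, or the coefficients.

The Costes procedure fits the two channels' masked intensities by
orthogonal (total least squares) regression, then walks a threshold pair
(T_a, T_b = slope * T_a + intercept) down from the channel-a maximum until
the Pearson correlation of the voxels *below both* thresholds first drops
to zero or below; above-threshold voxels are then deemed genuine signal.
Manders coefficients M1/M2 are intensity co-occurrence fractions above
those thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "Mask",
    "ColocResult",
    "build_mask",
    "pearson_within_mask",
    "costes_thresholds",
    "manders_within_mask",
    "colocalize",
]


@dataclass
class Mask:
    """Boolean analysis region plus a provenance record."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not self.values.any():
            raise ValueError("mask empty")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class ColocResult:
    pearson_r: float
    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    regression_slope: float
    regression_intercept: float
    n_voxels: int
    flags: tuple[str, ...] = ()


def build_mask(
    image: np.ndarray,
    smooth_sigma: float = 1.0,
    min_component_voxels: int = 10,
) -> Mask:
    """Otsu threshold on the smoothed channel, small components removed."""
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("cannot build a mask from a constant image")
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    raw = smoothed > thr
    labels, n = ndimage.label(raw)
    if n:
        counts = np.bincount(labels.ravel())
        keep = np.nonzero(counts >= min_component_voxels)[0]
        keep = keep[keep != 0]
        raw = np.isin(labels, keep)
    if not raw.any():
        raise ValueError("mask empty after removing small components")
    return Mask(
        values=raw,
        provenance=f"otsu(sigma={smooth_sigma}, min_component={min_component_voxels})",
    )


def pearson_within_mask(a: np.ndarray, b: np.ndarray, mask: Mask) -> float:
    """Sample Pearson correlation over masked voxels; NaN if degenerate."""
    av = np.asarray(a, dtype=float)[mask.values]
    bv = np.asarray(b, dtype=float)[mask.values]
    if av.size < 2 or av.std() == 0 or bv.std() == 0:
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def _orthogonal_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line through masked intensities (slope, intercept)."""
    xm, ym = x.mean(), y.mean()
    cov = np.cov(x, y)
    sxx, syy, sxy = cov[0, 0], cov[1, 1], cov[0, 1]
    if sxy == 0:
        # no linear relation: fall back to unit slope through the means
        return 1.0, ym - xm
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    return float(slope), float(ym - slope * xm)


def costes_thresholds(
    a: np.ndarray, b: np.ndarray, mask: Mask
) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Automatic threshold pair by the below-threshold decorrelation scan.

    Candidate thresholds T_a descend through the unique masked intensities
    of channel a (from the maximum); T_b follows the orthogonal-regression
    line. The first pair for which the correlation of voxels with
    a < T_a and b < T_b is <= 0 (or becomes undefined after being defined)
    wins. If the correlation never crosses, the minimum intensities are
    returned with a ``"no Costes crossing"`` flag.

    Returns (threshold_a, threshold_b, slope, intercept, flags).
    """
    av = np.asarray(a, dtype=float)[mask.values]
    bv = np.asarray(b, dtype=float)[mask.values]
    if av.size < 2:
        raise ValueError("need >= 2 masked voxels")
    slope, intercept = _orthogonal_regression(av, bv)

    flags: tuple[str, ...] = ()
    candidates = np.unique(av)[::-1]  # descending
    found = None
    for t_a in candidates:
        t_b = slope * t_a + intercept
        below = (av < t_a) & (bv < t_b)
        if below.sum() < 2:
            continue
        x, y = av[below], bv[below]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if r <= 0:
            found = (float(t_a), float(t_b))
            break
    if found is None:
        found = (float(av.min()), float(slope * av.min() + intercept))
        flags = ("no Costes crossing",)
    return found[0], found[1], slope, intercept, flags


def manders_within_mask(
    a: np.ndarray,
    b: np.ndarray,
    mask: Mask,
    thresholds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Manders co-occurrence coefficients over masked voxels.

    M1 is the fraction of channel a's summed intensity found in voxels
    where b exceeds its threshold; M2 swaps the roles. With
    ``thresholds=None`` co-occurrence means strictly positive signal in the
    partner channel.
    """
    av = np.asarray(a, dtype=float)[mask.values]
    bv = np.asarray(b, dtype=float)[mask.values]
    t_a, t_b = thresholds if thresholds is not None else (0.0, 0.0)
    denom_a = av.sum()
    denom_b = bv.sum()
    if denom_a <= 0 or denom_b <= 0:
        return float("nan"), float("nan")
    m1 = av[bv > t_b].sum() / denom_a
    m2 = bv[av > t_a].sum() / denom_b
    return float(m1), float(m2)


def colocalize(a: np.ndarray, b: np.ndarray, mask: Mask) -> ColocResult:
    """Full masked colocalization: Pearson, Costes thresholds, Manders."""
    r = pearson_within_mask(a, b, mask)
    t_a, t_b, slope, intercept, flags = costes_thresholds(a, b, mask)
    m1, m2 = manders_within_mask(a, b, mask, thresholds=(t_a, t_b))
    return ColocResult(
        pearson_r=r,
        m1=m1,
        m2=m2,
        threshold_a=t_a,
        threshold_b=t_b,
        regression_slope=slope,
        regression_intercept=intercept,
        n_voxels=mask.n_voxels,
        flags=flags,
    )
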