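"""Puncta detection, geometry, masked intensity, and content classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from azquant.coloc import Mask, build_mask
from azquant.puncta import (
    Punctum,
    classify_az_content,
    detect_puncta,
    masked_intensity,
    nearest_brp_distance,
    normalize_to_control,
)
from azquant.synthetic import SynapseSimConfig, simulate_synapse_stack

VS = (191.69, 24.44, 24.44)  # STED-like voxel size, nm


def gaussian_spot(shape, center, sigma, amplitude=100.0):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    cz, cy, cx = center
    return amplitude * np.exp(
        -((zz - cz) ** 2 / (2 * 0.7**2) + (yy - cy) ** 2 / (2 * sigma**2)
          + (xx - cx) ** 2 / (2 * sigma**2))
    )


class TestDetectPuncta:
    def test_single_spot_subvoxel_center(self):
        img = gaussian_spot((5, 40, 40), (2, 20.3, 17.6), sigma=1.5)
        found = detect_puncta(img, None, VS)
        assert len(found) == 1
        p = found[0]
        assert p.plane_index == 2
        assert abs(p.center_nm[1] / VS[1] - 20.3) <= 0.25
        assert abs(p.center_nm[2] / VS[2] - 17.6) <= 0.25

    def test_two_separated_spots(self):
        img = gaussian_spot((3, 40, 40), (1, 10, 10), 1.2)
        img += gaussian_spot((3, 40, 40), (1, 10, 24), 1.2)
        found = detect_puncta(img, None, VS)
        assert len(found) == 2

    def test_empty_image_returns_no_puncta(self):
        rng = np.random.default_rng(0)
        found = detect_puncta(rng.normal(10, 1, (3, 30, 30)), None, VS)
        assert found == []

    def test_recall_precision_on_synthetic_stack(self, synapse_stacks):
        """Default-noise stack: recall and precision >= 0.95 against the
        truth table at a 2-voxel match radius."""
        cfg, chan, truth = synapse_stacks["noisy"]
        mask = build_mask(chan["hrp"])
        for channel, kind in (("cac", "cac"), ("brp", "brp")):
            found = detect_puncta(chan[channel], mask, cfg.voxel_size)
            tr = truth[truth.kind == kind]
            matched_truth = set()
            n_matched = 0
            for p in found:
                d = np.sqrt(
                    ((tr.plane_index - p.plane_index) * cfg.voxel_size[0]) ** 2
                    + (tr.y_nm - p.center_nm[1]) ** 2
                    + (tr.x_nm - p.center_nm[2]) ** 2
                )
                j = d.idxmin()
                if d[j] <= 2 * cfg.voxel_size[1]:
                    n_matched += 1
                    matched_truth.add(j)
            assert n_matched / len(found) >= 0.95  # precision
            assert len(matched_truth) / len(tr) >= 0.95  # recall


class TestNearestDistance:
    def _p(self, z, y_nm, x_nm):
        return Punctum(center_nm=(z * VS[0], y_nm, x_nm), plane_index=z,
                       peak_intensity=1.0, integrated_intensity=1.0)

    def test_simple_distance(self):
        d, excl = nearest_brp_distance([self._p(0, 0, 0)], [self._p(0, 0, 100.0)])
        assert d[0] == pytest.approx(100.0)
        assert excl == 0

    def test_other_plane_excluded(self):
        d, excl = nearest_brp_distance([self._p(0, 0, 0)], [self._p(1, 0, 100.0)])
        assert d.size == 0 and excl == 1

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            nearest_brp_distance([], [self._p(0, 0, 0)])

    def test_ring_median_within_half_voxel(self, synapse_stacks):
        cfg, chan, _ = synapse_stacks["noiseless"]
        mask = build_mask(chan["hrp"])
        cac = detect_puncta(chan["cac"], mask, cfg.voxel_size)
        brp = detect_puncta(chan["brp"], mask, cfg.voxel_size)
        d, _ = nearest_brp_distance(cac, brp)
        assert abs(np.median(d) - cfg.ring_radius) <= cfg.voxel_size[1] / 2

    def test_rotation_invariance(self, synapse_stacks):
        """Rotating the stack 90 degrees in-plane leaves the distance
        distribution unchanged within quantization error."""
        cfg, chan, _ = synapse_stacks["noiseless"]

        def distances(cac_img, brp_img, hrp_img):
            mask = build_mask(hrp_img)
            cac = detect_puncta(cac_img, mask, cfg.voxel_size)
            brp = detect_puncta(brp_img, mask, cfg.voxel_size)
            return np.sort(nearest_brp_distance(cac, brp)[0])

        d0 = distances(chan["cac"], chan["brp"], chan["hrp"])
        rot = lambda v: np.rot90(v, axes=(1, 2)).copy()
        d90 = distances(rot(chan["cac"]), rot(chan["brp"]), rot(chan["hrp"]))
        assert d0.size == d90.size
        assert np.allclose(d0, d90, atol=1.0)


class TestMaskedIntensity:
    def test_constant_signal_inside_mask(self):
        rng = np.random.default_rng(1)
        mask_src = np.zeros((3, 40, 40))
        mask_src[1, 10:20, 10:20] = 100.0 + rng.random((10, 10))
        signal = np.full((3, 40, 40), 7.5)
        per_az, global_mean, labels = masked_intensity(signal, mask_src)
        assert global_mean == pytest.approx(7.5)
        assert per_az.mean_intensity.iloc[0] == pytest.approx(7.5)

    def test_zero_dilation_is_identity(self):
        rng = np.random.default_rng(2)
        mask_src = np.zeros((3, 40, 40))
        mask_src[1, 10:20, 10:20] = 100.0 + rng.random((10, 10))
        signal = rng.random((3, 40, 40))
        out0 = masked_intensity(signal, mask_src, dilation_radius=0)
        out0b = masked_intensity(signal, mask_src, dilation_radius=0)
        assert out0[1] == out0b[1]
        pd.testing.assert_frame_equal(out0[0], out0b[0])

    def test_dilation_monotonically_dilutes_peaked_signal(self):
        """A centrally peaked signal: per-AZ masked mean is non-increasing
        with dilation radius on a noiseless fixture."""
        mask_src = np.zeros((5, 40, 40))
        mask_src[2, 17:23, 17:23] = 100.0
        signal = gaussian_spot((5, 40, 40), (2, 20, 20), sigma=2.0)
        means = []
        for radius in (0, 1, 2, 4):
            per_az, _, _ = masked_intensity(signal, mask_src, dilation_radius=radius)
            means.append(per_az.mean_intensity.iloc[0])
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))

    def test_intensity_ratio_recovery(self):
        """Two conditions with true per-AZ cac amplitude ratio 2:1 under the
        same noise: the measured brp-masked mean ratio lands in [1.8, 2.2].
        Confocal-like sampling, where the blurred cac cluster fills the brp
        mask — the resolution regime this measurement is defined for."""
        means = {}
        for label, amp in (("high", 3000.0), ("low", 1500.0)):
            vals = []
            for seed in range(7):
                cfg = SynapseSimConfig(
                    seed=100 + seed, n_boutons=2, az_per_bouton=4,
                    voxel_size=(300.0, 80.0, 80.0),
                    psf_sigma=(350.0, 130.0, 130.0),
                    stack_shape=(7, 96, 96),
                    noise_sd=2.0,
                    cac_intensity_A=0.0, cac_intensity_B=amp,
                    content_fractions={"both": 0.0, "A_only": 0.0, "B_only": 1.0},
                )
                chan, _ = simulate_synapse_stack(cfg)
                per_az, _, _ = masked_intensity(chan["cac"], chan["brp"])
                vals.extend(per_az.mean_intensity)
            means[label] = np.mean(vals)
        ratio = means["high"] / means["low"]
        assert 1.8 <= ratio <= 2.2


class TestNormalization:
    def test_control_normalizes_to_one(self):
        df = pd.DataFrame({"group": ["c"] * 3, "value": [2.0, 2.0, 2.0]})
        out = normalize_to_control(df, "c")
        assert np.allclose(out.normalized, 1.0)

    def test_test_group_scaled_by_control_mean(self):
        df = pd.DataFrame({"group": ["c", "c", "t", "t"], "value": [2, 2, 1, 1.0]})
        out = normalize_to_control(df, "c")
        assert out.loc[out.group == "t", "normalized"].mean() == pytest.approx(0.5)

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"group": ["c"] * 50 + ["t"] * 50,
                           "value": rng.random(100) + 0.5})
        once = normalize_to_control(df, "c")
        twice = normalize_to_control(
            once.drop(columns="value").rename(columns={"normalized": "value"}), "c"
        )
        assert np.allclose(once.normalized, twice.normalized, atol=1e-12)

    def test_missing_control_rejected(self):
        df = pd.DataFrame({"group": ["t"], "value": [1.0]})
        with pytest.raises(ValueError, match="control"):
            normalize_to_control(df, "c")


class TestContentClassification:
    BG = np.random.default_rng(9).normal(5, 1, size=500)

    def test_high_high_is_both(self):
        classes, _ = classify_az_content([100.0], [100.0], self.BG, self.BG)
        assert classes == ["both"]

    def test_high_background_is_a_only(self):
        classes, _ = classify_az_content([100.0], [5.0], self.BG, self.BG)
        assert classes == ["A_only"]

    def test_cohort_fractions_within_multinomial_bounds(self):
        """Stacks generated at {both: 0.95, B_only: 0.05}: estimated class
        fractions from the images are consistent with the truth multinomial
        (exact binomial test, alpha 0.01)."""
        ia, ib = [], []
        n_true_b_only = 0
        n_az = 0
        for seed in range(8):
            cfg = SynapseSimConfig(
                seed=40 + seed, n_boutons=2, az_per_bouton=4,
                voxel_size=(300.0, 80.0, 80.0), psf_sigma=(350.0, 130.0, 130.0),
                stack_shape=(7, 96, 96), noise_sd=2.0,
                cac_intensity_A=3000.0, cac_intensity_B=6000.0,
            )
            chan, truth = simulate_synapse_stack(cfg)
            hrp = build_mask(chan["hrp"])
            per_az, _, labels = masked_intensity(chan["cac"], chan["brp"])
            bg = hrp.values & (labels == 0)
            for az in per_az.az_id:
                ia.append(chan["cac_a"][labels == az].mean())
                ib.append(chan["cac_b"][labels == az].mean())
            bg_a, bg_b = chan["cac_a"][bg], chan["cac_b"][bg]
            n_true_b_only += (truth.attrs["az_table"].content_class == "B_only").sum()
            n_az += len(per_az)
        classes, fractions = classify_az_content(ia, ib, bg_a, bg_b)
        n_b_only = sum(c == "B_only" for c in classes)
        assert fractions["both"] + fractions["B_only"] >= 0.95
        res = stats.binomtest(n_b_only, n_az, 0.05)
        assert res.pvalue >= 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            classify_az_content([], [], self.BG, self.BG)
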