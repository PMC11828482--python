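#!/usr/bin/env python
"""Active-zone geometry, isoform content, and relative intensity.

Three measurements on synthetic synapse stacks:

1. STED-like stacks: distance from each cac cluster center to the nearest
   brp punctum in the same optical section (ground-truth ring radius
   106.1 nm).
2. Confocal-like stacks: fraction of brp-positive AZs containing both
   isoform tags (generated at 95% dual content).
3. Confocal-like cohorts tagged on one isoform each: brp-masked intensity
   ratio between the B- and A-tagged cohorts (generated at 2:1).

Writes results/az_distances.csv, results/az_content.csv,
results/az_intensity_ratio.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from azquant.coloc import build_mask
from azquant.puncta import (
    classify_az_content,
    detect_puncta,
    masked_intensity,
    nearest_brp_distance,
)
from azquant.synthetic import SynapseSimConfig, simulate_synapse_stack

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"
CONFOCAL = dict(voxel_size=(300.0, 80.0, 80.0), psf_sigma=(350.0, 130.0, 130.0),
                stack_shape=(7, 96, 96), noise_sd=2.0)


def ring_distances() -> None:
    distances = []
    for rep in range(4):
        cfg = SynapseSimConfig(seed=SEED + rep, n_boutons=2, az_per_bouton=4,
                               ring_radius=106.1)
        chan, _ = simulate_synapse_stack(cfg)
        mask = build_mask(chan["hrp"])
        cac = detect_puncta(chan["cac"], mask, cfg.voxel_size)
        brp = detect_puncta(chan["brp"], mask, cfg.voxel_size)
        d, n_skip = nearest_brp_distance(cac, brp)
        distances.extend(d)
    pd.DataFrame({"distance_nm": distances}).to_csv(
        RESULTS / "az_distances.csv", index=False)
    print(f"cac-brp nearest-punctum distance: median "
          f"{np.median(distances):.1f} nm over {len(distances)} AZs "
          f"(generated ring radius 106.1 nm)")


def content_classification() -> None:
    ia, ib, bg_a, bg_b = [], [], [], []
    for rep in range(10):
        cfg = SynapseSimConfig(
            seed=SEED + 100 + rep, n_boutons=2, az_per_bouton=4,
            cac_intensity_A=3000.0, cac_intensity_B=6000.0,
            content_fractions={"both": 0.95, "A_only": 0.0, "B_only": 0.05},
            **CONFOCAL,
        )
        chan, _ = simulate_synapse_stack(cfg)
        hrp = build_mask(chan["hrp"])
        per_az, _, labels = masked_intensity(chan["cac"], chan["brp"])
        bg = hrp.values & (labels == 0)
        for az in per_az.az_id:
            ia.append(chan["cac_a"][labels == az].mean())
            ib.append(chan["cac_b"][labels == az].mean())
        bg_a.extend(chan["cac_a"][bg])
        bg_b.extend(chan["cac_b"][bg])
    classes, fractions = classify_az_content(
        ia, ib, np.asarray(bg_a), np.asarray(bg_b))
    pd.DataFrame({"intensity_a": ia, "intensity_b": ib,
                  "content_class": classes}).to_csv(
        RESULTS / "az_content.csv", index=False)
    print(f"isoform content over {len(classes)} brp-positive AZs: "
          + json.dumps({k: round(v, 3) for k, v in fractions.items()}))


def intensity_ratio() -> None:
    rows = []
    for cohort, amp in (("b_tagged", 3000.0), ("a_tagged", 1500.0)):
        for rep in range(6):
            cfg = SynapseSimConfig(
                seed=SEED + 200 + rep, n_boutons=2, az_per_bouton=4,
                cac_intensity_A=0.0, cac_intensity_B=amp,
                content_fractions={"both": 0.0, "A_only": 0.0, "B_only": 1.0},
                **CONFOCAL,
            )
            chan, _ = simulate_synapse_stack(cfg)
            per_az, _, _ = masked_intensity(chan["cac"], chan["brp"])
            for v in per_az.mean_intensity:
                rows.append({"cohort": cohort, "replicate": rep,
                             "masked_mean_intensity": v})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "az_intensity_ratio.csv", index=False)
    means = df.groupby("cohort").masked_mean_intensity.mean()
    print(f"brp-masked intensity ratio B:A = "
          f"{means['b_tagged'] / means['a_tagged']:.2f} (generated 2.00)")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    ring_distances()
    content_classification()
    intensity_ratio()


if __name__ == "__main__":
    main()
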