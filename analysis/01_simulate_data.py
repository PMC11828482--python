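#!/usr/bin/env python
"""Generate the demonstration datasets all later analyses consume.

Writes, under results/data/: a photoconversion/bleaching movie with its
per-AZ ground truth, an STED-like and a confocal-like three-channel synapse
stack, and a paired-pulse TEVC sweep — each with a truth sidecar, all from
one seed.
"""

from pathlib import Path

import numpy as np

from azquant import io
from azquant.synthetic import (
    BleachSimConfig,
    StimProtocol,
    SynapseSimConfig,
    TevcSimConfig,
    simulate_bleach_movie,
    simulate_synapse_stack,
    simulate_tevc_sweeps,
)

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    bcfg = BleachSimConfig(n_az=6, channels_per_az=("uniform", 4, 16),
                           n_frames=1500, uv_onset_frame=150, noise_sd=2.0,
                           seed=SEED)
    movie, btruth = simulate_bleach_movie(bcfg)
    io.save_tiff(OUT / "bleach_movie.tif", movie, pixel_size_nm=bcfg.pixel_size)
    btruth.to_csv(OUT / "bleach_truth.csv", index=False)
    print(f"bleach movie: {movie.shape} frames x px, "
          f"{bcfg.n_az} AZs, true counts {btruth.n_channels.tolist()}")

    sted = SynapseSimConfig(seed=SEED + 1, n_boutons=2, az_per_bouton=4,
                            ring_radius=106.1)
    chan, struth = simulate_synapse_stack(sted)
    for name in ("cac", "brp", "hrp"):
        io.save_tiff(OUT / f"sted_{name}.tif", chan[name],
                     pixel_size_nm=sted.voxel_size[1])
    struth.to_csv(OUT / "sted_truth.csv", index=False)
    print(f"STED-like stack: {sted.stack_shape}, "
          f"{len(struth[struth.kind == 'cac'])} AZs, ring radius {sted.ring_radius} nm")

    conf = SynapseSimConfig(seed=SEED + 2, n_boutons=2, az_per_bouton=4,
                            voxel_size=(300.0, 80.0, 80.0),
                            psf_sigma=(350.0, 130.0, 130.0),
                            stack_shape=(7, 96, 96), noise_sd=2.0,
                            cac_intensity_A=3000.0, cac_intensity_B=6000.0)
    chan, struth = simulate_synapse_stack(conf)
    for name in ("cac", "cac_a", "cac_b", "brp", "hrp"):
        io.save_tiff(OUT / f"confocal_{name}.tif", chan[name],
                     pixel_size_nm=conf.voxel_size[1])
    struth.to_csv(OUT / "confocal_truth.csv", index=False)
    struth.attrs["az_table"].to_csv(OUT / "confocal_truth_az.csv", index=False)
    print(f"confocal-like stack: {conf.stack_shape}, "
          f"content classes {struth.attrs['az_table'].content_class.value_counts().to_dict()}")

    tcfg = TevcSimConfig(seed=SEED + 3, noise_sd=0.4, ppr_true=0.9)
    protocol = StimProtocol.paired_pulse(30.0)
    sweeps, ttruth = simulate_tevc_sweeps(tcfg, protocol)
    io.save_sweep_text(OUT / "tevc_paired_pulse.txt", sweeps[0])
    ttruth.to_csv(OUT / "tevc_truth.csv", index=False)
    print(f"TEVC paired pulse: {sweeps[0].current.size} samples at "
          f"{tcfg.sampling_rate:.0f} Hz, true amplitudes "
          f"{np.round(ttruth.amplitude_nA.values, 1).tolist()} nA")


if __name__ == "__main__":
    main()
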