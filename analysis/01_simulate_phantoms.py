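#!/usr/bin/env python
"""Render the reference phantom set and write holograms plus ground truth.

Produces, under results/simulated/: the 10 um silica microsphere and the
three macrophage-phenotype phantoms (M0 rounded cap, M1 spread pancake
with pseudopodia, M2 cap) as 32-bit float hologram TIFFs with thickness
maps, masks, and ground-truth JSON sidecars.
"""

import argparse
from pathlib import Path

import holovol as hv
from holovol import io

PHANTOMS = [
    ("microsphere", hv.OpticalConfig(n_object=1.46, n_medium=1.34),
     dict(kind="sphere", diameter_um=10.0), 0.0),
    ("M0_cap", hv.OpticalConfig(), dict(kind="spherical_cap", target_volume_um3=970.54), 0.01),
    ("M1_pancake", hv.OpticalConfig(), dict(kind="pancake_pseudopodia", target_volume_um3=3822.00), 0.01),
    ("M2_cap", hv.OpticalConfig(), dict(kind="spherical_cap", target_volume_um3=2743.10), 0.01),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--grid", type=int, default=1024)
    parser.add_argument("--out", type=str, default="results/simulated")
    args = parser.parse_args()

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, config, spec_kw, noise in PHANTOMS:
        spec = hv.PhantomSpec(seed=args.seed, **spec_kw)
        gt = hv.make_phantom(spec, (args.grid, args.grid), config)
        holo = hv.render_hologram(
            hv.thickness_to_phase(gt, config),
            hv.default_carrier(config),
            config,
            noise_sigma=noise,
            seed=args.seed,
        )
        gt.carrier_cycles_per_um = hv.default_carrier(config)
        sub = outdir / name
        sub.mkdir(exist_ok=True)
        io.write_raster(sub / "hologram.tif", holo.intensity)
        io.write_raster(sub / "thickness.tif", gt.thickness_map)
        io.write_mask(sub / "mask.tif", gt.mask)
        io.write_ground_truth(sub / "ground_truth.json", gt, config, mask_path="mask.tif")
        print(f"{name}: volume {gt.volume_um3:.2f} um^3, "
              f"peak thickness {gt.thickness_map.max():.2f} um -> {sub}")


if __name__ == "__main__":
    main()
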