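#!/usr/bin/env python
"""Generate one example synthetic dataset per measurement type.

Writes, under scratch/data/: a goniometer spectral map per
nutrient-condition preset (delimited text + JSON sidecar), one
cell-profile CSV per growth condition, and one domain-mosaic image per
condition-like ordering level.  These files are inputs for the later
drivers and for eyeballing the formats; all downstream statistics are
regenerated in memory by the drivers themselves.
"""

from pathlib import Path

from colonyoptics.conditions import MORPHOMETRY_PRESETS, OPTICS_PRESETS, morphometry_preset, optics_preset
from colonyoptics.io import write_cell_profiles, write_domain_image, write_spectral_map
from colonyoptics.simulate import (
    DomainImageParams,
    simulate_cell_profiles,
    simulate_domain_image,
    simulate_spectral_map,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in OPTICS_PRESETS:
        smap = simulate_spectral_map(optics_preset(name, seed=1))
        path = write_spectral_map(smap, OUT / f"map_{name}.csv")
        print(f"wrote {path}")
    for name in MORPHOMETRY_PRESETS:
        profiles = simulate_cell_profiles(morphometry_preset(name, seed=1))
        path = write_cell_profiles(profiles, OUT / f"cells_{name}.csv")
        print(f"wrote {path} ({len(profiles)} cells)")
    for label, mds in (("ordered", 6000.0), ("fucoidan_like", 1500.0)):
        image = simulate_domain_image(
            DomainImageParams(mean_domain_size=mds, pixel_pitch=50.0, seed=1)
        )
        path = write_domain_image(image, OUT / f"domains_{label}.tif")
        print(f"wrote {path} ({image.meta['n_domains']} domains)")


if __name__ == "__main__":
    main()
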