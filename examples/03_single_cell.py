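"""Single 14-um cell: dose by source distribution and target compartment.

1436.8 MeV released per cell (1 MeV/um^3). The nuclear dose depends strongly
on where the radionuclide sits; membrane doses from surface-bound activity are
dominated by the short-range Auger electrons.
"""

import augerdose as ad
from augerdose.engine import category_contribution

for dist in ("cell_surface", "cytoplasm", "nucleus"):
    cfg = ad.ScenarioConfig(nuclide="Pd103_series", geometry="cell",
                            distribution=dist, histories=8000, seed=3)
    t = ad.run_scenario(cfg)
    print(f"source: {dist}")
    for comp in ("nucleus", "cytoplasm", "membrane"):
        ae = category_contribution(t, 0, "AE", comp)
        print(f"  {comp:9s} {t.dose(0, comp):9.1f} +- {t.stderr(0, comp):6.1f} Gy"
              f"   (AE share {100 * ae:4.1f}%)")
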