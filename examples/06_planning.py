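"""From simulated dose to decays and initial activity.

Given the nuclear dose per reference release (1436.8 MeV per cell), how many
decays — and what initial cell-bound activity, assuming full decay in place —
deliver a prescribed dose?
"""

import augerdose as ad

# nuclear dose per reference release with surface-bound activity
cfg = ad.ScenarioConfig(nuclide="Pd103_series", geometry="cell",
                        distribution="cell_surface", histories=8000, seed=7)
dose_ref = ad.run_scenario(cfg).dose(0, "nucleus")
target = 7.3  # Gy

n = ad.decays_for_dose("Pd103_series", dose_ref, target)
a0 = ad.initial_activity_bq("Pd103_series", n)
print(f"Pd103_series: {dose_ref:.1f} Gy per reference release")
print(f"  -> {n:,.0f} decays, initial activity {a0 * 1e3:.2f} mBq per cell "
      f"for {target} Gy to the nucleus")

cfg_lu = ad.ScenarioConfig(nuclide="Lu177", geometry="cell",
                           distribution="cell_surface", histories=8000, seed=7)
dose_lu = ad.run_scenario(cfg_lu).dose(0, "nucleus")
n_lu = ad.decays_for_dose("Lu177", dose_lu, target)
print(f"Lu177: {dose_lu:.2f} Gy per reference release"
      f" -> {n_lu:,.0f} decays, {ad.initial_activity_bq('Lu177', n_lu) * 1e3:.1f} mBq")
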