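# augerdose

Monte Carlo cellular dosimetry for the Auger/conversion-electron emitter
Pd-103 (with its Rh-103m daughter) and the beta emitters Lu-177 and Tb-161.

The package transports electrons event by event in liquid water down to a
7.4 eV cutoff and scores absorbed dose in water spheres (1–1000 µm), in a
14-µm cell with a 10-µm nucleus and a 10-nm membrane, in a 19-cell hexagonal
cluster, and in a seven-cluster layout with one unlabeled cluster. Activity
can be placed in the nucleus, cytoplasm, whole cell, or on the cell surface;
tallies resolve dose by compartment, source cell, nuclide (Pd-103 vs
Rh-103m), and emission category (Auger, conversion, beta), so S-values,
self/cross-dose splits and spectral contributions all come from a single run.
See [docs/methods.md](docs/methods.md) for the physics.

## Worked example

Dose to water spheres with uniformly distributed decays, normalised to a
released electron energy density of 1 MeV/µm³ (complete absorption would give
160.2 Gy):

```python
import augerdose as ad

for d in (1000.0, 100.0, 20.0, 10.0, 2.0):
    doses = {}
    for nuc in ("Pd103_series", "Lu177", "Tb161"):
        cfg = ad.ScenarioConfig(nuclide=nuc, geometry="sphere", diameter=d,
                                distribution="uniform_sphere",
                                histories=4000, seed=2)
        doses[nuc] = ad.run_scenario(cfg).dose(0, "inside")
    print(d, doses)
```

`examples/02_sphere_doses.py` runs exactly this and formats it as:

```
  diameter   Pd103_series      Lu177      Tb161   (Gy)
    1000 um          157.9     110.47      112.6   ratio vs Lu177:   1.4
     100 um          135.3      24.29       42.8   ratio vs Lu177:   5.6
      20 um           63.0       6.10       20.3   ratio vs Lu177:  10.3
      10 um           40.2       3.58       13.2   ratio vs Lu177:  11.2
       2 um           21.6       1.28        5.5   ratio vs Lu177:  16.9
```

In a 1000-µm sphere nearly all electron energy is absorbed for every nuclide;
as the sphere shrinks to cellular size the short-range Pd-103/Rh-103m cascade
retains an order of magnitude more of its energy than the Lu-177 betas.

Treatment planning from a simulated S-value (examples/06_planning.py):

```
Pd103_series: 16.8 Gy per reference release
  -> 14,344 decays, initial activity 6.77 mBq per cell for 7.3 Gy to the nucleus
Lu177: 1.75 Gy per reference release -> 40,426 decays, 48.8 mBq
```

The `examples/` directory walks through the full study: point-source ranges,
sphere doses, single-cell S-values by compartment, cluster self/cross-dose by
ring, heterogeneous labeling and dual targeting, planning, and the
seven-cluster range-limit demonstration.

## Command line

```bash
augerdose spectra validate                # check shipped emission schemes
augerdose run --nuclide Pd103_series --geometry cell \
              --distribution cell_surface --histories 5000 --out tally.tsv
augerdose run --config scenario.yaml      # or from a YAML scenario file
augerdose plan decays --nuclide Pd103_series --dose-per-cell 15.9 --target-dose 7.3
augerdose report --outdir tables/         # CSV tables for all geometries
```

## Layout

- `src/augerdose/` — library (`nuclides`, `physics`, `transport`, `_kernels`,
  `geometry`, `engine`, `scenarios`, `cli`)
- `src/augerdose/data/` — emission scheme TSVs
- `examples/` — narrative scripts
- `scripts/acceptance.py` — end-to-end reproduction script
- `docs/methods.md` — physics and limitations
- `tests/` — unit, property, and acceptance tests
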