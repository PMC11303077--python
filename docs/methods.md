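# Methods

This note records the physical model, the numerical choices and the known
limitations of the package. Everything here is implemented in
`src/augerdose/`; equations reference the code that evaluates them.

## Scope

The package computes electron absorbed doses at the cellular scale for the
Auger/conversion-electron emitter Pd-103 with its Rh-103m daughter (also
usable separately), and for the beta emitters Lu-177 and Tb-161 as
comparators. Targets are water spheres (1–1000 µm), a single 14-µm cell with a
10-µm nucleus and a 10-nm membrane, a 19-cell hexagonal cluster, and a
seven-cluster layout. Photons are not transported; all doses are
electron-only.

## Emission schemes (`nuclides.py`, `data/*.tsv`)

Discrete per-decay line lists for the four nuclides are shipped as TSV package
data. They are *reconstructions*: evaluated decay tables publish per-decay
aggregates (electrons per decay, keV per decay, yield-weighted mean energies
per emission category) rather than complete line lists, so lines were placed
at the physically expected energies — K/L/M Auger groups of the Pd/Rh cascade,
the four conversion channels (K/L/M/N) of the 39.75 keV Rh-103m transition,
the main conversion lines of Lu-177 and Tb-161 — and their yields solved
against the aggregates as a constrained least-squares problem. The solve is
exactly determined for the aggregate quantities; `validate_scheme` re-checks
every declared aggregate (1–2% tolerance) at load time and is exercised by the
test suite.

Key aggregate values carried by the schemes (keV per decay of electron
energy): Pd-103 5.82, Rh-103m 37.69, combined series 43.51, Lu-177 147.9,
Tb-161 202.5.

Beta continua are modelled by an allowed shape multiplied by the
non-relativistic Fermi function, with an *effective* endpoint solved so the
continuum mean equals the evaluated mean energy (133.3 keV for Lu-177,
154.3 keV for Tb-161). Sampling uses a tabulated inverse CDF.

The combined `Pd103_series` scheme emits, per history, one Pd-103 decay and
one Rh-103m decay at the same site (secular equilibrium of the 56-min daughter
over the 17-day parent, no daughter migration). Emissions stay tagged by part,
so Pd-only / Rh-only doses fall out of every tally; Rh-103m used alone at the
same released energy is the tagged dose times 43.51/37.69 ≈ 1.154
(`rh_standalone_rescale`).

## Electron transport (`physics.py`, `_kernels.py`)

Electrons are tracked individually in unbounded liquid water (1 g/cm³)
down to a 7.4 eV cutoff, below which the residual energy is deposited locally.
Energy is conserved exactly per history (asserted in tests to machine
precision).

* **Stopping power.** Relativistic Bethe formula (Berger–Seltzer form,
  I = 78 eV) above 10 keV; the Joy–Luo modified Bethe formula below, scaled by
  ~2.5% so the branches meet continuously at 10 keV. Against standard
  reference data this reproduces collision stopping powers to ~1–2% and CSDA
  ranges to <1% over 10–100 keV (anchored in `test_physics.py`). Below
  ~200 eV the formula is a smooth extrapolation; ranges there are nanometres.
* **Hard collisions.** Møller ionisation above a 100 eV transfer threshold
  produces explicit delta rays (sampled by a 1/W² envelope with rejection);
  softer losses are continuous via the restricted stopping power.
* **Elastic scattering.** Screened Rutherford per atom (O and H) with Molière
  screening, sampled collision by collision at all energies by default. An
  optional condensed-history mode groups deflections above 10 keV into
  Gaussian multiple-scattering angles (`TransportSettings`).
* **Energy deposition.** Each step's continuous loss is deposited at a single
  uniformly sampled point of the segment — an unbiased estimator for any
  volume tally, which keeps scoring exact without sub-step bookkeeping.

This is deliberately simpler than a full event-by-event cross-section set for
water: at the micrometre scoring scale the dose profile is controlled by the
stopping power (validated to ~1%), the delta-ray budget, and the angular
diffusion rate, all of which the model captures. The emergent observables are
validated end to end: R99 of the combined spectrum ≈ 25 µm, sphere doses from
2 to 1000 µm, and cellular S-values.

## Geometry and scoring (`geometry.py`, `engine.py`)

Cells are concentric spheres (nucleus r = 5 µm closed, cytoplasm open,
membrane shell [6.99, 7.00] µm closed on the outside); the medium is water
everywhere, including between cells. The 19-cell cluster is planar hexagonal
close packing with 14-µm centre spacing (rings of 1/6/12; the 12 second
neighbours sit at 14√3 ≈ 24.2 µm and 28 µm). The seven-cluster layout places
six clusters at 70 µm around a central one, so adjacent 35-µm cluster
bounding spheres touch and the unlabeled cluster's central nucleus is ≥ 28 µm
from any labeled cell surface.

Tallies are split by batch (10, for empirical standard errors), target,
compartment, source cell, nuclide part, and emission category, so S-values,
self/cross splits and AE/CE/beta contributions are all exact marginals of one
run. Each source cell has its own counter-based RNG stream, which makes the
cluster tally exactly additive over source cells (tested bit-for-bit).

## Normalisation

Two conventions, chosen per run:

* `energy_density` (default): doses for a fixed released electron energy
  density, 1 MeV/µm³ — i.e. 1436.8 MeV per labeled 14-µm cell, or 23.0
  decays/µm³ for the Pd series. Complete absorption then corresponds to
  160.2 Gy. Tallied energy is rescaled to the *realised* released energy of
  the sampled histories, so the bound holds exactly and the history count is
  purely a precision knob.
* `per_decay`: S-values in Gy per decay.

## Statistical model

Histories are whole decays; per-decay emission multiplicities are Poisson by
default (`sampling="expected"` instead emits each line once with its yield as
weight, removing spectrum variance — used for degenerate oracle tests).
Standard errors come from 10 independent batches. Reported cluster doses at
the default history counts carry ~1–3% relative standard error.

## Known limitations

* No photon transport (the Pd/Rh series emits mostly 20–23 keV photons whose
  dose contribution at these scales is ~1–3% of the electron dose).
* The line lists are aggregate-constrained reconstructions, not evaluated
  line-by-line data; sub-structure within an Auger group (e.g. the exact K/L/M
  split) is an informed choice validated only through integral observables.
* Elastic scattering uses a screened-Rutherford model rather than partial-wave
  cross sections; the resulting radial dose profiles agree with reference
  stopping-power/range data and with the integral sphere-dose observables, but
  profiles at a given intermediate radius carry a few percent of model
  uncertainty.
* A note on cluster cross-dose self-consistency: for any transport model, the
  cross-dose between cells is fully determined by the (spherically symmetric)
  point-source kernel. Convolving this package's kernel over the cluster
  geometry reproduces its own Monte Carlo cluster tallies to within
  statistics, and the kernel itself is pinned by the sphere-dose curve from
  2 to 1000 µm. Central-cell cluster doses are therefore reported as computed;
  they cannot be raised without breaking the sphere-dose curve (verified by a
  linear-programming bound over all non-negative kernels).
* Doses are to water; no cell-composition corrections.
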