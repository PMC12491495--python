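# paintbench

Simulation and analysis of multiplexed DNA-PAINT experiments that combine
speed-optimized right-handed docking sequences with their left-handed
(L-DNA) mirror analogs.

DNA-PAINT reads out target positions through the transient hybridization of
dye-labeled imager strands with target-bound docking strands: binding
kinetics, not photophysics, produce the blinking used for single-molecule
localization. Because mirror-image L-DNA hybridizes only with L-DNA, a
pooled library of right- and left-handed speed-optimized sequences doubles
the orthogonal sequence space for Exchange-PAINT multiplexing — 12 rounds
with zero cross-chirality crosstalk — while the concatenated, hairpin-free
repeat design keeps effective association rates high and acquisition times
short. `paintbench` implements the quantitative backbone of that workflow
for people who want to test, calibrate or extend such analyses without raw
microscope data:

- a **synthetic-data generator** for Exchange-PAINT localization tables:
  DNA-origami site grids (15 nm and 5 nm), Nup96 nuclear-pore standards
  (two rings 50 nm apart, corner pairs 14.3 nm), filaments, two-state
  binding kinetics, gold-fiducial tracks, random-walk drift, per-round
  imager species and chirality-orthogonal crosstalk;
- the **analysis stages**: fiducial drift correction, cross-correlation
  channel alignment and 2×2 tile stitching, fixed-radius single-molecule
  clustering (6.5 nm radius, min. 5 localizations, frame analysis),
  bright/dark-time kinetics with normalization to 100 pM and a single
  site (`τ_d,norm = τ_d,raw · (c/100 pM) · n`), NeNA localization
  precision, spacing/ring/filament geometry, crosstalk matrices and the
  experiment-time model;
- **HDF5/CSV localization I/O** in the common localization-list dialect
  (`locs` dataset + YAML sidecar);
- **sequence-design checks** for concatenated docking strands: tandem
  repeats, hairpin stems, cross-hybridization with chirality blocking.

The key relations: bright time `τ_b = 1/k_off`, single-site dark time
`τ_d = 1/(k_on·c)`, FWHM resolution `2√(2 ln 2)·σ`, and total experiment
time `n_targets·t_round + n_exchanges·t_exchange`.

See `docs/methods.md` for the model, estimators and their validity limits.

## Worked example

Simulate the 12-plex origami benchmark (12 species × 12 grids of 4×3 sites
at 15 nm pitch, 15,000 frames at 75 ms, drift + 3 fiducials), run the full
analysis and print the headline numbers:

```python
from paintbench.pipeline import scenario_config, run_scenario

summary = run_scenario(scenario_config("origami12", seed=1))
r = summary["results"]
print(f"site spacing : {r['site_spacing_nm']['mean']:.2f} nm "
      f"({r['site_spacing_nm']['n_pairs']} neighbor pairs)")
print(f"NeNA sigma   : {r['nena_sigma_nm']:.2f} nm")
print(f"max crosstalk: {r['crosstalk']['max_off_diagonal']:.3f}")
k = r["kinetics"][0]
print(f"{k['species']}: tau_b={k['tau_b']:.2f} s  "
      f"tau_d(100 pM, 1 site)={k['tau_d_norm']:.1f} s")
```

Output:

```
site spacing : 14.90 nm (1533 neighbor pairs)
NeNA sigma   : 1.51 nm
max crosstalk: 0.000
R1: tau_b=0.60 s  tau_d(100 pM, 1 site)=22.3 s
```

The recovered lattice spacing matches the 15 nm design within 1 %, the
NeNA estimate matches the simulated 1.5 nm precision, and with crosstalk
disabled the 12×12 assignment matrix is exactly diagonal. The bright time
reads slightly above the simulated `1/k_off = 0.5 s` — the expected
event-merging bias of pick-level mean estimators at 100 pM on a 12-site
structure (see `docs/methods.md`). The same entry points drive the `npc`,
`origami5nm`, `tubulin` and `neuron13` (tile-stitching) scenarios.

A CLI wraps the same machinery:

```sh
paintbench run --scenario npc --seed 1 --out out/npc
paintbench convert out/npc/round00.hdf5 locs.csv
paintbench analyze locs.csv --radius 6.5 --min-locs 5
paintbench seqcheck
```

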