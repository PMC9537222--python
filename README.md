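# atriavar

Cellular heterogeneity and electrotonic coupling in human atrial
electrophysiology: a population-of-models toolkit built around the
Courtemanche–Ramirez–Nattel (CRN) human atrial cell model, with regional
biomarker clustering, a monodomain finite-element tissue solver with
fibre anisotropy, conduction-velocity (CV) calibration, and analyses of
how tissue coupling reshapes repolarisation biomarkers.

The scientific question the package addresses: experimentally measured
atrial action potentials vary enormously between cells and regions — how
much of that variability survives once cells are electrically coupled in
tissue? The pipeline answers it end to end:

1. **Population of models** — sample thousands of CRN variants by scaling
   nine ionic conductances uniformly on [0, 3], pace each to steady state
   (101 beats at 1 Hz), and screen out unstable or non-physiological
   members (~81% survive).
2. **Regional clustering** — assign stable members to eight atrial
   regions (RA, RAA, LA, LAA, AVR, CT/BBra, BBla, PM) by requiring all
   five biomarkers (RMP, APA, APD20/50/90) to fall inside the region's
   experimental mean ± 2 SD box; membership is non-exclusive.
3. **Tissue slabs** — monodomain reaction–diffusion on 300 µm hexahedral
   meshes; each node carries a regional AP model (heterogeneous) or the
   regional mean model (homogeneous).
4. **CV calibration** — iterate longitudinal/transverse conductivities on
   a 1.8 × 1.8 × 18 mm slab until measured CV hits per-material targets;
   homogeneous and heterogeneous calibrations agree within 5%.
5. **Coupling analysis** — compare per-node tissue biomarkers with the
   source single-cell population: biomarker SDs collapse (electrotonic
   smoothing), early repolarisation lengthens, triangulation falls.

See [`docs/methods.md`](docs/methods.md) for model equations, numerical
schemes and parameter tables.

## Worked example

```python
from atriavar import (ConductanceScaling, PacingProtocol, pace_cell,
                      build_population, cluster_population)
from atriavar.biomarkers import compute_biomarkers

# one cell
last_beat, quiescent, end = pace_cell(ConductanceScaling(),
                                      PacingProtocol(n_beats=30))
print(compute_biomarkers(last_beat))
# BiomarkerSet(RMP=-81.1, APA=103.4, APD20=3.3, APD50=154.6,
#              APD90=291.2, TRI=136.6)   (values for the baseline cell)

# a small population, screened and clustered
pop = build_population(n=100, seed=42, fast=True)
print(pop.n_stable, "of", pop.n, "stable")       # ~80 of 100
regional = cluster_population(pop, warn_empty=False)
print(regional["RA"].n, "RA members, APD90",
      round(regional["RA"].summary.loc["APD90", "mean"], 1), "ms")
```

The `examples/` directory walks through the full pipeline in five short
narrative scripts (single cell → population → clustering → slab
conduction → coupling analysis), each runnable in about a minute.

There is also a thin CLI:

```bash
atriavar baseline --beats 30          # pace the baseline cell
atriavar population --n 100 --seed 42 --fast --out pop
atriavar cluster --population pop
atriavar reproduce --target t3 --seed 1 --out results.json
```

## Layout

- `src/atriavar/` — library (`crn`, `biomarkers`, `population`,
  `regions`, `tissue`, `cv`, `coupling`, `experiments`, `io`, `cli`)
- `src/atriavar/data/` — regional biomarker statistics and material/CV
  target tables (editable CSV)
- `examples/` — narrative walk-throughs
- `scripts/acceptance.py` — end-to-end reproduction run
- `tests/` — unit, property-based and acceptance suites
- `docs/methods.md` — models, numerics, limitations
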