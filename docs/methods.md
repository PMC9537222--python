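# Methods

This document describes the models, numerical methods, parameter choices
and known limitations of `atriavar`. Units follow cardiac-electrophysiology
convention: mV, ms, pA/pF for transmembrane current density, mS/cm for
conductivity, cm/s for conduction velocity (CV).

## 1. Cellular model

The cellular substrate is the Courtemanche–Ramirez–Nattel (CRN) human
atrial action-potential model: 21 state variables (membrane potential V,
15 Hodgkin–Huxley gates, and the intracellular concentrations Na+, K+,
Ca2+ plus the Ca2+ content of the uptake and release compartments of the
sarcoplasmic reticulum). Membrane capacitance is 100 pF with the standard
cell volumes (V_i = 13,668 µm³, V_up = 1,109.52 µm³, V_rel = 96.48 µm³).
Stimulus and ionic currents are expressed in pA/pF, so a current of
−45 pA/pF changes V at +45 mV/ms (C_m specific = 1 µF/cm² at tissue
scale).

### Conductance variability

Nine maximal conductances/fluxes carry inter-subject variability: g_Na,
g_to, g_Kur, g_Kr, g_Ks, g_K1, g_CaL, the Na+/K+-pump maximum and the
Na+/Ca2+-exchanger maximum. Each population member scales them by an
independent multiplier drawn uniformly on [0, 3] (−100% to +200% of
baseline). `ConductanceScaling` validates the range.

### Pacing protocol

The reference protocol is 101 beats at basic cycle length (BCL) 1000 ms
with a −45 pA/pF, 1 ms stimulus, followed by a 10 s quiescent
(stimulus-free) window used by the spontaneous-depolarisation screen.
Biomarkers are read from the final (101st) beat. A reduced protocol
(20 beats, 5 s tail) exists for exploration and CI and is flagged in the
population metadata.

### Numerical integration

Gates use the Rush–Larsen exponential update with analytic steady
state/time constant; V and concentrations use forward Euler. Two fixed
steps are used: dt = 0.02 ms inside a window around each stimulus and for
the entire recorded final beat, dt = 0.1 ms elsewhere. Because forward
Euler is first-order, the ~400 mV/ms upstroke would otherwise carry a
~2 ms APD bias at dt = 0.02 ms; each step is therefore sub-divided so
that no sub-step advances V by more than 0.2 mV (ΔV-limited substepping,
capped at 200 sub-steps). With this scheme the fixed-step solution agrees
with an adaptive LSODA integration of the identical right-hand side to
within 1 ms in APD50/APD90 and 0.5 mV in APA/RMP (enforced by an oracle
test). States are checked for finiteness; |V| > 500 mV marks numerical
blow-up and the member is excluded.

## 2. Biomarkers and exclusion screen

From the final beat: RMP (last sample before the stimulus), APA
(peak − RMP), APD20/50/90 (from the maximum-dV/dt instant to the linearly
interpolated crossing of V_peak − x%·APA) and TRI = APD90 − APD50
(triangulation). A member is excluded when any of the following trips:

- spontaneous depolarisation: a rise of more than 10 mV above the running
  diastolic minimum during the 10 s quiescent window (or numerical
  blow-up);
- RMP above −50 mV;
- APD90 over 1000 ms, or no repolarisation crossing at all;
- peak above +60 mV (non-physiological) or below 0 mV (no overshoot).

## 3. Regional clustering

Eight atrial regions (RA, RAA, LA, LAA, AVR, CT/BBra, BBla, PM) are
characterised by experimental means and SDs of the five biomarkers RMP,
APA, APD20, APD50, APD90 (packaged in
`atriavar/data/regional_biomarkers.csv`). A stable member belongs to a
region when all five biomarkers fall inside the mean ± 2 SD box; duration
boxes are lower-clipped at 0 ms. Membership is non-exclusive. Each region
designates a mean AP model — the member minimising the z-scored Euclidean
distance to the regional member means — used for homogeneous tissue.
Pulmonary-vein tissue reuses the LA population, as no complete PV
biomarker set exists.

## 4. Tissue model

### Monodomain equation and discretisation

Tissue follows the monodomain equation
χC_m ∂V/∂t = ∇·(Σ∇V) − χ(I_ion + I_stim) with surface-to-volume ratio
χ = 1400 /cm and C_m = 1 µF/cm². The conductivity tensor is transversely
isotropic, Σ = σ_L[(1−r) n_f n_fᵀ + r I] with r = σ_T/σ_L and fibre
direction n_f; in the solver it is converted to a diffusivity
D = σ/(χ C_m) (σ in mS/cm → D in mm²/ms via the factor 100/1400).

Space is discretised with trilinear hexahedral finite elements on a
regular 300 µm lattice; the mass matrix is lumped. Zero-flux boundaries
are the natural FEM boundary condition. Time stepping uses first-order
(Godunov) operator splitting at dt = 0.02 ms: a cell-wise ionic step
(same Rush–Larsen/ΔV-limited kernel as the single-cell path) followed by
a Crank–Nicolson diffusion step whose system matrix is prefactorised
(sparse LU) once per run.

### Geometry and AP-model assignment

The calibration geometry is a 1.8 × 1.8 × 18 mm slab (6 × 6 × 60
elements, 2,989 nodes), fibres along the long axis. A two-material slab
split at the mid-plane serves as a surrogate for inter-regional
boundaries. Ten materials (`atriavar/data/materials.csv`) define CV
targets, anisotropy ratios and a mixture of source regions (e.g. RA
material: 80.0% RA, 7.9% AVR, 12.1% RAA models); the fossa ovalis is
non-conductive. Two printed mixtures sum to 100.1% and are renormalised
at load time. Node assignment draws each node's source region from the
mixture fractions (restricted to non-empty regional populations,
renormalised) and then either a uniformly drawn member (heterogeneous) or
the regional mean model (homogeneous). Nodes start from their member's
end-of-pacing checkpoint state.

### Stimulation

Tissue stimuli default to a fixed −80 pA/pF, 2 ms transmembrane current
on the selected node set (for CV runs: the z = 0 face). A fixed, amply
supra-threshold current was chosen over a per-run threshold search for
determinism and speed; the measured CV window (below) is insensitive to
stimulus strength.

## 5. CV measurement and calibration

CV is measured from the wavefront crossing times (first upward crossing
of −10 mV) as the median-activation delay between the cross-sections at
25% and 75% of the slab's long axis — a window that avoids both stimulus
and far-boundary artefacts. σ_L is iterated with a secant update in
log(σ)/log(CV) space, seeded with the cable-theory jump σ ← σ(CV*/CV)²,
until the measured CV is within tolerance of the target (max 25
iterations). The default tolerance is 0.5 cm/s; because σ ~ CV² near the
solution, a CV tolerance `tol` leaves a relative σ slack of about
2·tol/CV per calibration, so the experiment driver tightens the
tolerance to 0.625% of the target CV (capped at 0.5 cm/s) whenever
calibrated σ values are to be compared at the few-percent level — at a
fixed 0.5 cm/s the slowest material (≈ 23 cm/s) alone would permit
apparent homogeneous-vs-heterogeneous σ differences of ~8.6% with no
physical difference. Transverse conductivity is obtained the same way on a slab
with fibres rotated 90°, or — where only σ_L matters — from the squared
target-CV ratio. Isotropic materials (isthmus, sinoatrial node) calibrate
once with σ_L = σ_T. Calibration is performed per material for both
homogeneous and heterogeneous slabs; CV variability is the SD of
longitudinal CV over re-sampled heterogeneous assignments at fixed
calibrated σ.

## 6. Coupling analysis

Per-node biomarkers are extracted from voltage frames stored every 1 ms,
with the APD clock started at the solver-tracked activation time (maximum
temporal voltage step of the fine trace, not the frame grid). APA from
1 ms frames systematically misses the true peak and is flagged
low-confidence; percent-change analyses therefore use RMP and
APD20/50/90. Before analysis, all nodes of elements within a configurable
number of element layers (default 3, inclusive) of an inter-material
interface, non-conductive tissue, or the stimulated node set are
excluded; the outer surface does not trigger exclusion. Percent changes
are (tissue − population)/|population| × 100, grouped by (material,
source region); triangulation comparisons report regional mean TRI in
homogeneous vs heterogeneous tissue and relative to the single-cell
population.

## 7. Reproduction targets and problem sizes

`scripts/acceptance.py` recomputes six headline quantities at desk scale
(single CPU, < 20 min): the stable-model count (n = 500 scaled to the
200,000-member design), baseline APD90 restitution between BCL 1000 and
800 ms, CV variability over 10 heterogeneous replicates for the CT and RA
materials, the homogeneous-vs-heterogeneous calibrated-conductivity
agreement across all nine conductive materials, and the clustered RA
population's mean APD90 (≥ 200 members). The slab sizes, n = 500
population and 10-replicate counts are this package's own desk-scale
choices; organ-scale quantities (whole-atria activation maps) are out of
scope and covered only directionally by two-material slab surrogates.

## 8. Limitations

- Forward-Euler/Rush–Larsen with ΔV-limited substepping is robust but
  first-order; biomarker accuracy is ~1 ms, not reference-grade.
- The homogeneous-vs-heterogeneous conductance comparison uses σ_L
  (transverse values follow the fixed target ratio), halving calibration
  cost.
- APA in tissue is frame-rate limited (1 ms) and excluded from
  percent-change analyses by default.
- Tissue runs start from single-cell steady-state checkpoints without
  additional coupled pre-pacing by default (`pre_pace_tissue` exists when
  a coupled steady state is required); CV and activation-order analyses
  are insensitive to this, long-APD analyses may shift slightly.
- The baseline cell has a slow intracellular-concentration drift: the
  measured APD90 reduction from BCL 1000 to 800 ms grows with the number
  of pre-beats (≈ 0.55% at 21 beats, 0.81% at 51, 1.34% at 101, 2.91% at
  301), and an independent adaptive (LSODA) integration reproduces the
  101-beat value to 0.01 pp. Restitution numbers are therefore only
  comparable at matched pacing protocols.
- The homogeneous-vs-heterogeneous conductivity comparison is limited
  by mean-model sampling noise at small population sizes: homogeneous
  tissue uses the single member nearest the regional centroid, and at
  region sizes of ~30–200 members (n = 500 population) that member's
  CV-relevant conductances deviate from the true regional mean by
  several percent, which maps directly onto calibrated σ (observed up
  to ~10%). The heterogeneous calibrations themselves are stable to
  ~2% across independent populations; the comparison converges only as
  the population (and hence the mean model) approaches the design
  scale.
- CV variability across re-sampled heterogeneous slabs is strongly
  self-averaged: with ~3,000 independently assigned nodes per slab, the
  median-plane activation delay pools hundreds of cells, so replicate-
  to-replicate CV SD is ~0.1 cm/s — far below the cell-to-cell
  variability scale. Larger CV spread requires spatially correlated
  (patch- or organ-scale) heterogeneity, which is out of scope here.
- No organ-scale atrial anatomy, fibrosis, or restitution-dependent CV
  calibration.
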