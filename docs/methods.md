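# Methods

## System and scope

`commetab` analyses a dual-chamber MFC in which a fermenter (*E. coli*)
and a dissimilatory metal reducer (*S. oneidensis*) are co-inoculated in
the anode chamber on 20 mM glucose. The measurement chain is: voltage
across a 1 kΩ load resistor sampled every 5 min; metabolite
concentrations (mM) in the 20 mL anolyte; drop-plate CFU counts with
GFP fluorescence marking the reducer; two-channel confocal stacks of
the electrode biofilm; plate-reader fluorescence for flavins; and a
gene count table per species. The package computes summary statistics
and balances from these inputs; it does not model the mutualism
mechanistically (no rate laws), simulate reads, or process raw
chromatograms or microscope files.

## Electrochemistry

Current density is J = V/(R·A) in µA/cm². A is the projected
single-face area of the 2 cm × 5 cm carbon-felt anode (10 cm²); felt
has a much larger true surface and some conventions use both faces
(20 cm²), so A is an explicit argument and recorded in trace metadata.
Charge is the trapezoidal integral of current (A) over seconds on the
requested window, computed on the raw (unsmoothed) trace; window edges
are linearly interpolated, so integration is exact for piecewise-linear
traces sampled at their breakpoints, and additivity over adjacent
windows holds to 1e-9 relative. Electron counts divide by the
elementary charge (scipy's SI value).

Peak current density is the maximum of a centred moving average
(default window 1 h ≈ 12 samples; 0 disables smoothing). The onset
slope is an ordinary least-squares fit on the segment from the first
sample above 5% of the peak to the first sample reaching 90% of the
peak — the window excludes the lag phase and plateau curvature and is
exact on a linear ramp. A series that never rises has no defined slope
and raises an error. Replicate summaries are mean ± sample SD (ddof 1;
SD 0 for a single replicate).

## Fermentation stoichiometry and balances

Electron equivalents per molecule oxidised at the anode: formate 2
(HCOO⁻ → CO₂ + 2e⁻; chemically forced) and lactate 4 (incomplete
oxidation to acetate + CO₂, the canonical anaerobic *Shewanella*
route — complete oxidation would give 12 and is selectable through
`StoichiometrySpec`). The choice of 4 is consistent with acetate
accumulating rather than being consumed in this system.

Degree of reduction is γ = 4C + H − 2O − 3N electrons per molecule;
biomass is the standard CH₁.₈O₀.₅N₀.₂ (24.63 g per C-mol, 4.2 e-eq per
C-mol). Carbon recovery of a window is (product C-mol + biomass
C-mol)/glucose C-mol; unmeasured CO₂ and ethanol mean recovery below 1
is expected on real data. Mixed-acid fermentation caps both formate
and acetate at 2 mol per mol glucose (1 glucose → 2 pyruvate, each
split by pyruvate-formate lyase into formate + acetyl-CoA); exceeding
a cap raises a flag rather than an exception, because measured pools
can legitimately over-run it (carry-over, other routes) — notably the
default 45 mM formate peak against 20 mM glucose trips the flag, an
inconsistency the balance is designed to surface, not hide.

Glucose consumption by planktonic cells is inferred from biomass:
consumed mass = dry weight / Y_glucose with Y_glucose = 0.524 g/g
(growth-phase fermentation yield). The CFU→dry-weight factor defaults
to 3 × 10⁻¹³ g/CFU (≈0.3 pg per cell, typical for *E. coli*); the
empirical correlation it stands for is not published, so the factor is
exposed in `BiomassRecord` and echoed in reports. The fraction is
capped at 1 with a flag.

Flavin concentrations invert the linear plate-reader response
conc = (reading − blank − intercept)/slope; negative inversions are
clipped to 0 with a warning.

## Electron partitioning

The reducer's electrons are taken as externally supplied per-interval
counts (computed from metabolite Δmol via `electrons_from_metabolites`,
or quoted values); the budget never silently re-derives them from
concentration curves, because the oxidised amount on an interval is not
identifiable from net concentration changes alone (production and
consumption overlap). The total comes from charge integration of the
full trace. The fermenter's share is the remainder, clipped at 0 with a
loud warning if the supplied counts exceed the total; the two fractions
sum to 1 exactly.

`reference_trace()` is a named calibration, not a measurement: a
piecewise-linear total-current trace (20 µA peak = 2.0 µA/cm² × 10 cm²,
rise over 0–12 h, plateau to 48 h, decay to 0 at 108 h) integrating to
5.184 C. Against it, the reference per-interval reducer counts
(4.36/6.05/2.41 × 10¹⁷ at 24/48/72 h) give a 3.96% share. Whether such
printed counts are per-interval or cumulative readings is ambiguous in
typical reports; both interpretations land in the 3–4% band under this
trace, and the per-interval reading is used.

## Community structure

Drop plates: species CFU/mL = colonies/(dilution × plated volume); the
reducer from fluorescent colonies, the fermenter by subtraction. Only
countable plates (3–300 colonies, the drop-plate convention) enter;
dilutions and replicates are pooled as Σcolonies/Σ(dilution × volume),
the minimum-variance weighting under Poisson counting. A time point
with no countable plate yields NaN, never an exception. Fluorescence
misclassification is assumed absent.

Biovolume: each channel is thresholded on the whole stack (Otsu by
default — stable for sparse biofilm signal and invariant to uniform
intensity rescaling — or a fixed grey value); biovolume is the
above-threshold voxel count × voxel volume (µm³), and the reducer share
is GFP/DAPI, clipped to [0, 1] with a warning since GFP-positive voxels
are by definition a subset of all-biomass DAPI voxels. A constant
(all-dark) channel segments as empty; an empty DAPI segmentation makes
the fraction undefined and raises.

## Expression summaries

RPKM[g, r] = counts × 10⁹/(length_bp × library size). The fold-change
ratio is R = (mean treated RPKM + c)/(mean control RPKM + c) with
pseudocount c = 0.5 by default (no standard value exists; recorded in
output), reported as log2 R. Significance is a per-gene Welch t-test on
log2(RPKM + c) at p ≤ 0.05 with no multiplicity correction by default —
mirroring common single-organism MFC transcriptomics practice — with
Benjamini–Hochberg behind a flag. Genes constant within both groups get
p = 1 and a flag. Fold changes are computed on per-replicate RPKM means
(pooling reads first is the alternative; means were chosen as the more
common convention). Note that RPKM fold changes of strongly induced
genes are slightly compressed because the induced gene itself inflates
the treated library size; the effect is ~log2(1 + m/M) for a gene
contributing m of M mapped reads.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (config, seed): NumPy
`default_rng` seeded per-generator from the config seed plus a fixed
stream id, so outputs are bit-identical across runs and independent
across generators. Defaults encode the wild-type co-culture condition:
current peak 2.0 µA/cm² (mutant preset 3.0), onset 0.17 µA/cm²/h,
plateau to 48 h, zero at 108 h; formate 0 → 45 mM at 48 h → 0 at 100 h,
acetate 10 mM, lactate 0.5 mM, glucose from 20 mM; planktonic *E. coli*
fraction 0.98; biofilm reducer biovolume fraction 0.60; flavins 25 nM
in co-culture (8.0/8.2 nM monocultures) on a linear standard curve;
negative-binomial counts with 3 replicates per condition.

Shapes are deliberately minimal: the trace is piecewise linear (only a
peak, a slope and a decline window are specified by the scenario); the
metabolite curves are piecewise linear; the biofilm is an axis-aligned
ellipsoid (the volume-fraction statistic is shape-agnostic); noise is
additive Gaussian in measurement space, clipped at 0 — the simplest
model consistent with replicate SDs of the scenario (e.g. trace sd
0.05 µA/cm², flavin noise matching a ±2.44 nM replicate SD at the
default slope, image noise 5% of signal). Plate totals are Poisson,
species splits binomial. Real data differ in ways the generators do not
emulate: autocorrelated drift and electrode aging in traces, HPLC
quantification bias, colony overlap and misclassification, optical
attenuation with depth, and count-table batch effects. Passing recovery
tests therefore demonstrates estimator correctness under the stated
statistical model, not robustness to instrument artefacts.

Stoichiometric mode is an exact-bookkeeping variant: the formate peak
is capped at 2 × glucose₀, acetate ramps in over the first 12 h (a
constant level from t = 0 would imply product before any substrate was
consumed), glucose declines as max(cum formate, cum acetate)/2 — the
pyruvate route makes the larger product the binding constraint — and
noise is disabled so the 2-mol/mol caps and carbon closure hold exactly
at every time point. With noise on, measurement error could violate the
caps, which would defeat the mode's purpose.

The noiseless image-stack fraction is exact up to voxel quantisation:
the generator labels round(f·N) of the N biomass voxels, so the
realised fraction differs from f by at most 1/(2N) (N ≈ 28k at the
default 16 × 128 × 128 geometry).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 3 trace replicates
at 5-min sampling over 108 h (~1300 samples), 61-point metabolite
series, 3 drop plates at a countable dilution (~100 colonies each),
10 stacks of 16 × 128 × 128 voxels, 2000-gene null tables with 3 + 3
replicates. Integration tolerances are float-level (1e-9 relative
additivity); recovery tolerances follow the statistical error of each
design (peak ±0.1 µA/cm², onset ±0.02 µA/cm²/h, plating ±1 point,
biovolume ±3 points, null significant fraction 0.05 ± 0.02, spike-in
log2FC ±0.1).

## Known limitations

- The electron budget depends on the calibration trace when totals are
  not measured; report it as such.
- Per-interval reducer electron counts must be supplied; the package
  does not infer oxidised amounts from net concentration series.
- The countable-plate window, CFU↔dry-weight factor and RPKM
  pseudocount are conventions, surfaced in configuration and output
  rather than buried.
- No multiplicity correction by default means the significant-gene list
  at the null contains ~5% false positives by construction.
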