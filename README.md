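# commetab

Communal-metabolism analysis for a two-species microbial fuel cell (MFC):
a fermenter (*Escherichia coli*) and a dissimilatory metal reducer
(*Shewanella oneidensis*) share an anode chamber, where the fermenter
converts glucose to mixed acids (formate, acetate, lactate) and the
reducer respires formate on the electrode while secreting flavin
mediators. `commetab` packages the quantitative analysis of such a
system for bioelectrochemistry and microbial-ecology researchers:

- **electrochemistry** — voltage traces across the load resistor to
  current density J = V/(R·A), peak and onset-slope statistics, and
  coulombic accounting Q = ∫I dt, nₑ = Q/e;
- **metabolism** — metabolite Δmol on time windows, electron
  equivalents (formate → CO₂: 2 e⁻; lactate → acetate + CO₂: 4 e⁻),
  degree-of-reduction balances (γ = 4C + H − 2O − 3N), glucose
  consumption from biomass via Y_glucose, and flavin quantification by
  standard-curve inversion;
- **partitioning** — the per-species electron budget: the reducer's
  share from metabolite oxidation versus the total from charge
  integration, the fermenter taking the (flavin-mediated) remainder;
- **community** — two-species structure from drop-plate counts
  (fluorescent-colony subtraction) and from two-channel confocal stacks
  (Otsu-thresholded GFP/DAPI biovolume ratio);
- **transcriptomics** — RPKM, fold-change ratio R (treated/control) and
  a Welch t-test significance filter at p ≤ 0.05;
- **synthetic** — generators for every input with known ground truth,
  so each estimator is testable by parameter recovery.

## Worked example

```python
import commetab as cm
from commetab import synthetic as syn, electrochemistry as ec, partitioning as pt

cfg = cm.preset("co_culture", seed=1, trace={"noise_sd_j": 0.0})
series = ec.to_current_density(syn.generate_current_trace(cfg))
print(ec.peak_current_density(series))   # (2.0, 12.333...) -> 2.0 uA/cm2 plateau
print(ec.initial_rise_rate(series))      # 0.16999... -> 0.17 uA/cm2/h onset

budget = pt.build_electron_budget(pt.reference_trace(),
                                  pt.REFERENCE_SO_ELECTRONS,
                                  pt.REFERENCE_INTERVALS)
print(budget.e_total)                    # 3.236e19 electrons (5.184 C)
print(100 * budget.fraction_shewanella)  # 3.96 -> the reducer's ~4% share
print(100 * budget.fraction_ecoli)       # 96.04 -> fermenter majority
```

The peak (2.0 µA/cm²) and onset slope (0.17 µA/cm²/h) are the generating
parameters of the co-culture preset recovered by the estimators. The
electron budget integrates the reference calibration trace to 5.184 C
(≈3.24 × 10¹⁹ electrons) and attributes 1.28 × 10¹⁸ of them (per-interval
counts 4.36/6.05/2.41 × 10¹⁷) to the metal reducer's formate/lactate
oxidation — a ~4% share, the rest flowing from the fermenter via flavin
mediators.

A CLI mirrors the library (`commetab simulate`, `commetab trace stats`,
`commetab partition`, `commetab community cfu|biovolume`,
`commetab rpkm`, `commetab balance`).

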