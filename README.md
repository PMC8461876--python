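# phenoplate

Computational core of an automated 96-well microplate phenotyping platform
for metabolic engineering: photometric pipette calibration for fixed-tip
liquid handlers, decontamination (sterility) QC statistics, anaerobic
enzyme-kinetics analysis, and a scale-down microbial phenotyping pipeline
(growth rates, fermentation yields, PCA/t-SNE clustering). Seeded
synthetic-data generators emulate every instrument output, so the whole
pipeline is testable without a robot, plate reader, or HPLC.

## Who it is for

Labs running fixed-tip liquid handlers and plate readers for strain or
enzyme screening, who need the *analysis* half of the workflow: turning
plate maps and reader exports into calibrated volumes, sterility
statistics, kinetic constants, and comparable strain phenotypes.

## The models at the core

**Pipette calibration.** A potassium dichromate standard obeys
Beer–Lambert at 350 nm, so absorbance is linear in dispensed volume within
each working range (3–10, 10–50, 50–200 μL). A standard curve
`A = c₁·V + c₀` fitted on manually pipetted levels inverts robot-dispensed
absorbances to volumes `V̂ = (A − c₀)/c₁`. Per tip, OLS of actual on
programmed volume gives `actual = a·programmed + b`; programming
`(desired − b)/a` restores accuracy. Accuracy is reported as systematic
error `100·(mean − programmed)/programmed` and CV `100·sd/mean`, checked
against user-supplied limits (e.g. ISO 8655).

**Sterility QC.** Wells re-pipetted with washed tips either grow
(contaminated) or not; effectiveness = `100·(1 − n_grew/n_wells)` with an
exact Clopper–Pearson interval on the sterile proportion.

**Enzyme kinetics.** NADPH absorbs at 340 nm; an NADPH-consuming reaction
gives a falling trace whose initial slope converts to a rate via
`v [μmol/min] = |dA/dt| / (ε·ℓ) · V` with ε = 6.3 mM⁻¹cm⁻¹, ℓ = 0.56 cm,
V = 0.2 mL. Rates across a substrate titration are fitted to
`v = V_max·S/(K_M + S)` by non-linear least squares; pH screens yield an
optimum band (levels within 10% of the maximal mean activity).

**Phenotyping.** Specific growth rate `μ(t) = d ln X/dt` is averaged over
the detected exponential phase; yields on glucose are
`Δproduct/Δglucose` (mol/mol). Each culture becomes a 7-analyte vector
(growth rate + yields of acetate, formate, lactate, pyruvate, succinate,
biomass), standardised and embedded with PCA (components chosen to explain
≥ 90% of variance) or t-SNE (hyperparameters selected by minimal KL
divergence over seeded restarts); cluster agreement against strain labels
is scored with the adjusted Rand index.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```sh
$ python examples/enzyme_kinetics_fit.py
K_M   = 0.356 +/- 0.014 mM   (truth 0.35)
V_max = 0.0508 +/- 0.0006 umol/min (truth 0.05)
fit r^2 = 0.9959 over 21 wells
```

The generator created noisy A340 depletion traces from a known
K_M = 0.35 mM enzyme; the pipeline (window-selected initial rates →
Beer–Lambert conversion → MM fit) recovers it within one standard error.
Similarly `examples/calibrate_pipettes.py` prints the pre-calibration
median systematic error (~18%, single tips up to ~40%) collapsing to
~0.04% after inverse correction, and `examples/strain_clustering.py`
shows t-SNE + k-means recovering the three true strain groups (ARI = 1.0)
with the two distribution-identical evolution stages merged.

A thin CLI wraps the same library (`phenoplate calibrate|sterility|
kinetics|phenotype|simulate`); every command writes a run manifest with
input digests and seeds before its results.

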