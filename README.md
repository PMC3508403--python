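# benthicnloss

Inference of benthic nitrogen-loss rates — denitrification and anaerobic
ammonium oxidation (anammox) — from ¹⁵N isotope-pairing incubation
experiments in marine sediments, written for biogeochemists working with
slurry and intact-core incubations under oxygen minimum zones.

## The problem and the method

Two microbial pathways remove fixed nitrogen from sediments as N₂:

* **denitrification** (NO₃⁻ → NO₂⁻ → NO → N₂O → N₂), which pairs two N
  atoms from the same NOₓ pool, and
* **anammox** (NH₄⁺ + NO₂⁻ → N₂), which pairs one reduced and one oxidized
  N atom.

After adding a ¹⁵N tracer, the isotopologue composition of produced N₂
(²⁸N₂/²⁹N₂/³⁰N₂, measured by GC-IRMS as ratios against ²⁸N₂) identifies the
pathway.  With a NOₓ pool of ¹⁵N mole fraction *F*, denitrification
produces ³⁰N₂ at *D·F²* and ²⁹N₂ at *2F(1−F)·D*, while anammox produces
²⁹N₂ only.  The package implements the full inference chain:

1. **Excess and slopes** — ratio time series are converted to excess
   concentrations over the air-equilibrium baseline and fitted by OLS;
   only channels with a significant slope (p < 0.05) and no initial delay
   are used.
2. **Pairing algebra** — with ¹⁵NH₄⁺ labeling (Experiment 1):
   *A = p²⁹/F(NH₄⁺)*; with ¹⁵NO₃⁻ labeling (Experiment 2):
   *D = p³⁰/F²* and *A = (p²⁹ − 2·((1−F)/F)·p³⁰)/F*.
3. **Labeling-fraction inversion** — sediments hosting nitrate-storing
   organisms (e.g. foraminifera) release unlabeled ¹⁴NO₃⁻ when slurries
   are mixed, diluting *F* below its nominal value.  Requiring both
   experiments to see the same anammox rate turns the pairing equation
   into a quadratic in *F*; its admissible root *F\** yields the
   denitrification rate and the **excess nitrate**
   [¹⁵NO₃⁻]·(1/F\* − 1/F) attributable to the intracellular store.
4. **Areal fluxes and cores** — volumetric layer rates are integrated to
   the nitrate penetration depth (default 2 cm); intact cores are
   evaluated with the revised isotope pairing technique (rIPT), which
   combines the ²⁹N₂/³⁰N₂ production ratio *R²⁹* with the slurry-derived
   anammox fraction *ra = A/(A+D)* to obtain total N-loss.
5. **Context** — the water-column deficit
   N\* = [NH₄⁺]+[NO₂⁻]+[NO₃⁻]−16·[PO₄³⁻]+2.9, anammox shares of nirS gene
   copies from qPCR tables, cell-specific rates, and basin-scale annual
   N-loss extrapolations in Tg N yr⁻¹.

A forward simulator (`benthicnloss.simulate`) generates slurry and core
incubations with known true rates, so every stage is validated by
parameter recovery.

## Worked example

Simulate one sediment layer with true rates D = 100 and A = 20 nmol N₂
cm⁻³ d⁻¹, an intracellular ¹⁴NO₃⁻ store of 100 nmol cm⁻³, plus a core with
true total N-loss 0.96 mmol N m⁻² d⁻¹, at 1 % ratio noise — then run the
pipeline:

```python
from benthicnloss import SlurryScenario, CoreScenario, \
    simulate_slurry_ex1, simulate_slurry_ex2, simulate_core, RunConfig
from benthicnloss.pipeline import run_pipeline

scn = SlurryScenario(true_D=100.0, true_A=20.0, seed=7,
                     intracellular_14no3=100.0, noise_sd_ratio=0.01)
core = CoreScenario(true_D14=150.0, true_D15=250.0, true_A=80.0, seed=9,
                    noise_sd_ratio=0.01)
out = run_pipeline(RunConfig(), [simulate_slurry_ex1(scn),
                                 simulate_slurry_ex2(scn),
                                 simulate_core(core)])
print(out["slurry_rates"][["anammox_nmol_n_cm3_d", "denit_nmol_n_cm3_d",
                           "f_no3_star", "excess_no3_nmol_cm3"]])
print(out["core_nloss"][["ra", "R29_ratio", "nloss_total_mmol_n_m2_d"]])
```

prints (N-atom units, so truth is A = 40 and D = 200):

```
 anammox_nmol_n_cm3_d  denit_nmol_n_cm3_d  f_no3_star  excess_no3_nmol_cm3
               39.462             199.023        0.73               97.829
    ra  R29_ratio  nloss_total_mmol_n_m2_d
0.1655     1.6074                    1.005
```

The anammox and denitrification rates, the diluted labeling fraction
(truth 0.728), the injected nitrate store and the core total N-loss
(truth 0.96 mmol N m⁻² d⁻¹) are all recovered to within the level set by
the measurement noise.

The same chain is available from the shell:

```sh
nloss simulate --scenario scenario.yaml --seed 7 --out sim.csv
nloss run-all  --input sim.csv --out report/
nloss budget   --rate 0.3 --area 4.93e12
```

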