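# Methods

This note documents the models, numerical choices and limitations of the
`benthicnloss` inference chain.  Notation: *A* and *D* are anammox and
denitrification N₂ production rates; *F* is the ¹⁵N mole fraction of a
substrate pool; p²⁹N₂ and p³⁰N₂ are production rates of the singly and
doubly labeled isotopologues; *ra = A/(A+D)*.

## Isotope signals

**Air baseline.** Ratios are converted to excess concentrations with
excess29ᵢ = (r29ᵢ − r29_air)·[²⁸N₂]ᵢ (likewise ³⁰N₂).  The air-equilibrium
ratios are computed from the atmospheric ¹⁵N atom fraction x = 0.0036765
under binomial pairing: r29_air = 2x(1−x)/(1−x)² ≈ 7.380×10⁻³,
r30_air = x²/(1−x)² ≈ 1.362×10⁻⁵.  Both are configurable so locally
calibrated air standards can override them.  The ²⁸N₂ reference
concentration is a per-series scalar (default 500 µmol l⁻¹,
air-saturation order of magnitude) unless per-time-point values are
supplied; ²⁸N₂ is effectively constant relative to tracer excess, so the
choice cancels out of slope ratios and only scales absolute excesses.

**Slope filter.** Production rates are unweighted OLS slopes of excess
against time with a two-sided t-test (df = n−2); replicate exetainers at
a time point enter as independent observations.  A channel is *accepted*
only if p < alpha (default 0.05) **and** no initial delay is detected.
"Delay" is operationalized as: the first point's externally studentized
residual exceeds 2.0, or refitting without the earliest time point shifts
the slope by more than 2 pooled standard errors.  Both thresholds are
configurable.  The rule is sensitive to onsets in the first half of
typical sampling grids (e.g. a 10 h onset on a 0–27 h grid) but, like any
low-n diagnostic, cannot flag an onset so late that only one or two points
carry signal.  Residuals at the floating-point rounding floor (relative
RMS ≤ 10⁻⁸ of the signal scale) skip the delay diagnostics: studentizing
pure round-off would produce spurious delays on noise-free data.
Rejected channels propagate as *absent* — never zero — and any layer with
an absent rate contributes nothing to depth integrals (a conservative
choice).

**Unit bridge.** Aqueous slopes (µmol N₂ l⁻¹ h⁻¹) become volumetric
sediment rates via rate = slope·24·f·(V_water/V_sed)·10³ with f = 2 for
N-atom reporting.  The aqueous slurry volume is the added degassed water
(default 200 ml) plus pore water estimated as porosity·V_sed with porosity
0.8 (configurable); total liquid volume is rarely reported for slurry
bags, and this decomposition makes the assumption explicit.  Rates are
carried in N₂ units through the pairing algebra and doubled to N atoms at
the reporting boundary only.

## Pairing algebra and the labeling-fraction inversion

With a nitrate pool at fraction F, denitrification distributes N₂
binomially: p³⁰ = D·F², p²⁹(den) = 2F(1−F)·D; anammox adds p²⁹ = A·F and
no ³⁰N₂.  The three estimators are

* Experiment 1 (¹⁵NH₄⁺ + ¹⁴NO₂⁻, ATU): A = p²⁹/F(NH₄⁺),
* Experiment 2 (¹⁵NO₃⁻): D = p³⁰/F², A = (p²⁹ − 2((1−F)/F)p³⁰)/F.

Setting A(Ex1) = A(Ex2) and solving for F gives the quadratic
A·F² − (p²⁹+2p³⁰)·F + 2p³⁰ = 0; for A = 0 it degenerates to
F = 2p³⁰/(p²⁹+2p³⁰).  Root selection: among real roots in (0, 1], the one
closest to the nominal tracer fraction when available, else the larger
root (nominal proximity is the physically conservative choice; the other
root usually implies implausibly strong dilution).  Infeasible
observations raise an error carrying the discriminant.  Excess nitrate is
[¹⁵NO₃⁻]·(1/F* − 1/F_nominal), converted to nmol (cm³ sediment)⁻¹ with the
slurry-volume factor.  Noise-driven negative anammox rates and negative
excess nitrate are floored at zero and logged, never silently dropped.

## Revised isotope pairing technique (cores)

The core estimator assumes one effective ¹⁵N fraction f of the NOₓ pool in
the reduction zone.  Measured quantities are p²⁹, p³⁰ and their ratio
R²⁹; ra comes from the slurry incubations of the same station
(depth-integrated A and D).  Eliminating f:

    r₁₄ ≡ (1−f)/f = [(1−ra)·R²⁹ − ra] / (2 − ra)
    D = p³⁰·(1+r₁₄)²,  A = D·ra/(1−ra)
    N-loss (atoms) = 2·(A+D) = 2·p³⁰·(1+r₁₄)²/(1−ra)

Typeset renderings of this estimator in the literature are easy to
misread, so the algebra was re-derived from the pairing model and is pinned by two tests that are
treated as authoritative: (i) at ra = 0 it reduces exactly to the
classical isotope-pairing total (p²⁹+2p³⁰)·(1+p²⁹/(2p³⁰)); (ii) on
simulator output it recovers the true D14+D15+A over a 5×5×5 truth grid
to better than 10⁻⁶ relative.  An observed R²⁹ below the anammox-free
minimum for the given ra implies r₁₄ < 0; it is clamped to a fully
labeled pool with a warning.  The station transfer of ra assumes the
slurry-derived pathway split applies to the core; when the core's true
split differs, total N-loss is biased by the mismatch (the pipeline
reports ra alongside so this is auditable).

## Water column, genes, budgets

N* = [NH₄⁺]+[NO₂⁻]+[NO₃⁻]−16[PO₄³⁻]+2.9 (µmol N l⁻¹; 16:1 Redfield, the
+2.9 offset in the same units as the nutrients, per the standard
formulation).  Annual basin loss = rate·10⁻³·14.007 g mol⁻¹·365 d·area·
10⁻¹² Tg g⁻¹; a 365-day year and the compiled areas (OMZ-contact seafloor
1.15×10¹² m²; basin north of 6°N 4.93×10¹² m²) are config keys.  qPCR
measurements below detection are excluded from nirS fractions rather than
zeroed; fraction uncertainty is first-order delta-method from the
measurement sds.  Cell-specific rates assume single-copy nirS; the dry
bulk density default of 1.0 g cm⁻³ is a placeholder — per-cell rates scale
inversely with it.

## Synthetic incubations

The simulator emulates the incubation conditions: Experiment 1 at 200/100
µmol l⁻¹ ¹⁵NH₄⁺/¹⁴NO₂⁻ with nitrification inhibited, Experiment 2 at
200 µmol l⁻¹ ¹⁵NO₃⁻, cores at 50 µmol l⁻¹ ¹⁵NO₃⁻ in the overlying water
with five time points over 15 h and sacrificial triplicates, slurries
with six time points over 27 h, ~160 cm³ sediment + 200 ml degassed water.
Dissolved ¹⁴NO₃⁻ pools default to 30 (bottom water) and 20 (pore water)
µmol l⁻¹, inside the observed bottom-water (22–39) and surface pore-water
(7–31) ranges; ambient ¹⁴NH₄⁺ defaults to 10 µmol l⁻¹, a realistic
margin-sediment pore-water value chosen because measured values are not
reported — it only sets F(NH₄⁺) ≈ 0.95 and cancels from recovery tests.
Defaults for simulated true rates in tests (D ≈ 50–150, A ≈ 10–40 nmol N₂
cm⁻³ d⁻¹; stores up to 300 nmol cm⁻³) bracket the reported rate and
excess-nitrate ranges.

Production is zero-order (substrate depletion is not modeled; tracer
amendments are large relative to consumption over ≤ 28 h).  Noise is
multiplicative Gaussian on the isotope *ratios* — the IRMS error
structure — not on concentrations.  Intracellular release is
instantaneous at t = 0 by default (stores are released when the slurry is
mixed); a linear gradual-release option integrates the time-varying
labeling fraction numerically (2001-point trapezoid) and exists for
sensitivity checks only.  The core simulator is well mixed, with the
reduction-zone fraction f = D15/(D14+D15): it deliberately shares the
rIPT's own labeling assumption, because its job is to test the estimator
algebra, not sediment diffusion physics.  Consequently, passing recovery
tests demonstrates correctness of the inference chain, **not** robustness
to diffusion gradients, time-varying f, pre-incubation air contamination,
bioturbation or temperature effects, none of which are modeled.

## Problem sizes and determinism

Monte-Carlo checks use 10³ replicates for the labeling-fraction error
under 2 % ratio noise and for slope-coverage properties, and 10⁴ null
replicates for the slope test's type-I rate — sizes at which the binomial
sampling error of the checked bands is comfortably below the band widths.
The type-I check isolates the t-test by disabling the delay thresholds;
with them enabled the filter is strictly more conservative.  All
randomness flows through explicit integer seeds via numpy Generators;
identical config + seed reproduces report bundles byte-for-byte.

## Known limitations

* The slurry→core transfer of ra is an assumption, not an inference.
* Nominal F(NH₄⁺) must come from configuration when pore-water ammonium
  was not measured; rates from Experiment 1 scale as 1/F.
* The delay rule cannot detect very late onsets (see above).
* Depth integration treats rejected layers as zero production —
  integrated fluxes are lower bounds in that respect.
* Headspace re-equilibration and instrument drift are assumed corrected
  upstream; the pipeline consumes dissolved-phase-equivalent ratios.
* Anammox contributions are often quoted at different roundings (e.g. a
  deep-station ra of 0.379 appears as both 38 % and 40 %); the pipeline
  reports unrounded ra and leaves rounding to the caller.
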