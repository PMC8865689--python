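# Methods

This note documents the models, estimators and numerical choices behind
`phagestress`, and what the synthetic-data generator does and does not
emulate.

## Titering and censoring

A plate that received `v` mL of a `10⁻ᵈ` serial dilution and shows `c`
plaques estimates the undiluted titer as `c / (v · 10⁻ᵈ)` PFU/mL. A
sample's titer is the arithmetic mean of per-plate estimates over plates
whose count lies in the countable range, default **3–300 plaques/plate**
(the classical plaque/colony countable-range convention; the range is
configurable, and a pooled-count mode — total plaques over total effective
volume — is available, which weights dilutions by their information
content). If no plate is countable but some show plaques, the plate with
the highest count at the highest nonzero dilution is used and the estimate
flagged `out_of_range`. If every plate shows zero plaques the sample is
**censored** at the limit of detection:

    LOD = pre_dilution_factor / (v · 10⁻ᵈ_min)

the titer implied by a single plaque on the least-dilute plate actually
plated for that sample. The LOD is per-sample because dilution series
differ between samples and batches. `pre_dilution_factor` covers protocol
dilutions applied before plating, e.g. the 200-fold termination dilution
used to stop urea/saline exposure (making the chemical-stress LOD 200×
higher than the same plating without it).

Percent survival is `100 · N / N_ref` computed from mean titers (a
per-replicate variant is a config flag). The reference is chosen per
stressor: for a temperature gradient, the mildest temperature at the
shortest exposure (default 5 min; a 0-min variant exists because figure
and protocol conventions differ — `heat_reference_policy`); for a long
time course, the unstressed source stock; for saline, the growth-medium
control (0.17 M) at 0 min; for urea, the 0 M control at 0 min. References
are matched per stock where possible, with a global fallback. The
reference samples themselves enter the survival table as exact 100 %
observations; with k strata this yields the residual degrees of freedom
the stratified model expects (n − 2k). Censored observations are carried
through the survival table (flagged, at their LOD-implied percent) for
plotting and bookkeeping but are **excluded from every model fit**; this
exclusion is asserted by an invariance test (appending censored rows
changes no coefficient, SS, or p-value).

## Decay model

Within each stratum (temperature, concentration, or stock) survival is
log-linear in exposure time:

    log₁₀(% survival) = αₛ + βₛ · t

fitted by ordinary least squares with one intercept and one slope per
stratum and **no pooled duration main effect** (a config flag adds one for
sensitivity analysis). The Gaussian-on-log₁₀ reading is deliberate: the
reported t and F statistics of this experimental tradition come from
least-squares fits on the log scale, not from a count-level GLM. Slopes
are tested one-tailed against zero (direction "less": decay) with t =
β̂/SE on the model's residual df, Bonferroni-adjusted over the family of
estimable strata (default m = number of strata with data; strata whose
observations are all censored are reported as NA rows, not errors — a
condition hot enough to drive everything below detection has no estimable
slope). The ANCOVA is sequential (Type I) in the fixed order *factor,
then factor × duration*; this matters, as Type II sums of squares would
change the F values, and it matches the convention of the statistical
environment this analysis style descends from. Sequential SS are computed
by successive SVD-orthogonalized block projections (algebraically
identical to nested re-fits, verified to 1e−10 against brute-force nested
least squares); factor coding is treatment contrasts with the first
sorted level as baseline.

Biphasic decay (a fast-decaying subpopulation followed by a resistant
residue) is **generated but never fitted**: plaque assays with a handful
of timepoints have limited resolution to distinguish it from log-linear
decay, so the fitted model stays log-linear and a test demonstrates the
systematic residual curvature biphasic truth leaves behind.

## Growth-curve fitness

OD600↔CFU conversion uses a log-linear standard curve
(`log₁₀ CFU/mL = a + b·OD`, defaults a = 8, b = 1, valid on OD 0–1;
readings outside the range are flagged, not rejected). Dosing solves for
the phage volume and intermediate serial dilution that deliver the target
PFU (default 200/well) within pipettable volumes (1 µL–0.1 mL), and sets
bacteria per well from the MOI target (200 PFU / 10⁻⁵ = 2×10⁷ cells).
Stocks too dilute to reach the target are flagged `insufficient`; their
wells are reported but excluded from the treatment ANOVA.

Curves are smoothed with a **moving median, window 5** (25 min at 5-min
reads) — robust to single-read spikes; moving average is available and
both the method and window are recorded in output metadata. The fitness
proxy is the **first local maximum** of the smoothed series: the earliest
index that (i) is maximal within its centered window (shrunk at the
edges) and (ii) is followed by a drop of at least the prominence
threshold. The default prominence is 3× the median absolute successive
difference of the series — a data-driven noise floor, so pure noise
wiggles on a rising curve do not count as peaks. Ties break to the
earliest index; a series with no qualifying interior maximum (e.g. a
phage-free control that plateaus) returns its global maximum with
`boundary_flag` set. The implementation is verified against an exhaustive
scan of this definition on random series.

Treatment comparison: OLS ANOVA `peak ~ treatment + stock +
treatment:stock` (sequential SS), Tukey–Kramer HSD over treatment levels
using the model's residual mean square and the studentized-range
distribution (scipy's CDF, cross-checked against direct numerical double
integration to 1e−6), and a Welch t-test (Welch–Satterthwaite df) for the
two phage-free control groups. The compact letter display is built by
insert-and-absorb: starting from one group of all levels, each
significant pair splits every group containing both; the resulting
letters are not unique as a display, but the sharing relation is exactly
"adjusted p ≥ α" (asserted by test).

## Synthetic-data generator

The generator's defaults are the study conditions the analysis targets.

**Decay assay.** True titer per condition:
`N(t) = N₀ · (f·10^(k₁t) + (1−f)·10^(k₂t))`, mono-exponential when f = 1.
Default N₀ = 10⁹ PFU/mL (a typical high-titer lysate), temperatures
55/60/65/70 °C with rates 0.0008, 0.0005, −0.0028, −0.0182 log₁₀/min (the
published per-temperature estimates for this phage), durations 5/30/60/90
min, 0.1 mL plated across dilutions 10⁰–10⁻⁷ in triplicate. The small
positive rates at the no-decay temperatures are intentional: they are
what sampling drift looks like, and the one-tailed tests must call them
null. Each plate's count is Poisson with mean `N(t)·v·10⁻ᵈ` (physical
counting statistics); between-stock heterogeneity is a lognormal titer
offset (log₁₀ sd `stock_sd`) — stock-level variation is reported in this
assay tradition but not modeled mechanistically, so a multiplicative
offset is the generator's own choice. Noise-free mode rounds expected
counts, giving exactly 100 % survival under zero decay. Not emulated:
pipetting error beyond Poisson, plate-to-plate efficiency differences,
plaque-morphology changes.

**Growth curves.** Wells integrate

    dB/dt  = rB(1 − (B+ΣIⱼ)/K) − aBP
    dI₁/dt = aBP − (n/λ)I₁
    dIⱼ/dt = (n/λ)(Iⱼ₋₁ − Iⱼ)      j = 2…n
    dP/dt  = β(n/λ)Iₙ − aBP

with logistic host growth (r = 0.025/min ≈ 28-min doubling, K = 1.5×10⁹
cells/mL), mass-action adsorption a = 2.4×10⁻⁹ mL/min, burst β = 150,
latent period λ = 35 min as n = 5 Erlang stages (a smooth surrogate for a
fixed delay; no delay-equation machinery), OD = 0.04 blank +
10⁻⁹ OD·mL/cell × total cells + Gaussian read noise (sd 0.005). Damage
multiplies the adsorption rate (or burst size, configurable) by a factor
in (0, 1] **without changing the inoculated PFU** — the
conformational-damage reading of heat injury; the generator does not
attempt to discriminate damage mechanisms. In the packaged fixture every
shocked treatment shares one damage factor (0.2), reproducing the
saturation phenomenon: any shock reduces fitness, longer shocks no
further. The shocked-medium control gets a 7 % lower carrying capacity
(heat-degraded nutrients), so it peaks *below* the plain control — the
direction the control contrast is expected to show.

**Integration.** The system is stiff once free phage amplify to ~10¹¹/mL
(adsorption turnover ≪ the 5-min read interval), so the default
integrator is LSODA (rtol 1e−8) evaluated at the measurement grid; a
fixed-step RK4 (step = interval/4) is available for gentle parameter
ranges and raises an instability error otherwise. Total viable cells
never exceed K (up to integration tolerance); this conservation is
asserted in tests. Determinism: one numpy `Generator` per call, seeded
from the config; identical seed and config give byte-identical tables.

## Problem sizes and runtime choices

The calibration tests and the acceptance script use 50–200 simulated
experiments of the 4 × 4 × triplicate design (seconds each); the
slope-recovery invariant for shallow rates (−0.003 log₁₀/min) uses the
long-exposure design (5–360 min), since 90 minutes of stress cannot
resolve a rate that small above counting noise — the same reason long
time courses exist in the laboratory protocol. Each simulated plate holds
36 wells × 145 reads; full plates (96 wells) parse and analyze the same
way.

## Known limitations

* The decay fit is strictly log-linear; no Weibull/biphasic estimation.
* No mixed-effects treatment of stocks (stock enters as a fixed factor).
* Peak density is the only fitness proxy — no growth rate, lag or AUC.
* The dosing planner models dilution and volume arithmetic, not pipetting
  error.
* Reproduction mode requires the archived cleaned dataset locally; its
  column mapping must be supplied because archive layouts differ from
  this package's schemas.
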