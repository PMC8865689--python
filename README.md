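# phagestress

Decay and damage analysis for therapeutic bacteriophage stocks.

Bacteriophage therapy candidates — such as phage OMKO1, a myovirus that
kills *Pseudomonas aeruginosa* — must survive storage, transport and the
conditions of the human body. Two distinct things can go wrong when virions
meet an environmental stressor (heat, urea, saline): particles can **decay**
(lose the ability to form plaques at all) and surviving particles can be
**damaged** (form plaques but suppress bacterial growth less). Both matter
for dosing and pharmacokinetics, and both are measurable with classical
microbiology: serial-dilution plaque assays for decay, and phage-challenged
bacterial growth curves for damage.

This package implements that analysis end to end, for anyone running phage
stability experiments:

* **Titering** — plaque counts → PFU/mL: per-plate estimate
  `c / (v · 10⁻ᵈ)` for `c` plaques on `v` mL of a `10⁻ᵈ` dilution, averaged
  over plates in the countable range (default 3–300); samples with zero
  plaques everywhere are *censored* at the limit of detection (the titer a
  single plaque on the least-dilute plate would imply, times any
  pre-plating termination dilution).
* **Percent survival** — titer relative to a per-stressor reference
  (mildest temperature at the shortest exposure; unstressed source stock;
  medium or 0 M control at time zero), carried on a log₁₀ scale.
* **Decay kinetics** — stratified log-linear model
  `log₁₀(% survival) = αₛ + βₛ·t` with one intercept and one slope per
  stratum *s* (temperature, concentration, or stock), fitted by OLS on
  uncensored observations only. Per-stratum one-tailed t-tests against
  β = 0 (direction "less" detects decay) with Bonferroni adjustment, and a
  sequential (Type I) ANCOVA (factor, then factor × duration).
* **Growth-curve fitness** — OD600 trajectories are smoothed (moving
  median, window 5 = 25 min) and the *first local maximum* is extracted;
  a higher peak bacterial density means the phage inoculum suppressed
  growth less, i.e. lower phage fitness. Treatments are compared with a
  two-factor ANOVA (treatment + stock + interaction), Tukey HSD with a
  compact letter display, and a Welch t-test for the phage-free control
  pair. Wells that could not receive the target dose (200 PFU at MOI 10⁻⁵)
  are flagged and excluded from the ANOVA.
* **Synthetic data** — a generator that emulates the entire measurement
  process: exponential (optionally biphasic) decay observed through
  Poisson plaque counting with a detection limit, and phage–bacteria
  growth dynamics (logistic host growth, mass-action adsorption,
  Erlang-staged latent period, burst release) with a *damage factor* that
  lowers per-particle fitness without changing the inoculated PFU. Every
  statistical stage is therefore testable against known ground truth.

## Worked example

Simulate a heat-gradient experiment (four temperatures × four exposure
durations, triplicate titering through a full dilution series) and run the
survival → decay analysis:

```python
from phagestress.synthetic_data import DecaySimConfig, simulate_decay_assay
from phagestress.assay_io import validate_plaque_counts
from phagestress.pipeline import RunConfig, analyze_survival

table = validate_plaque_counts(simulate_decay_assay(DecaySimConfig(seed=1)))
res = analyze_survival(table, RunConfig())
print(res["slopes"]["heat"].round(4).to_string(index=False))
```

```
 level   slope  std_err  t_value  df  p_one_tailed  p_bonferroni  n_tests
  55.0 -0.0005   0.0006  -0.8471   8        0.2108        0.8431        4
  60.0  0.0009   0.0006   1.4032   8        0.9009        1.0000        4
  65.0 -0.0028   0.0006  -4.4682   8        0.0010        0.0042        4
  70.0 -0.0173   0.0006 -28.0058   8        0.0000        0.0000        4
```

Each row is one temperature stratum: the slope is the decay rate in
log₁₀(percent survival) per minute (−0.0173 at 70 °C ≈ a tenfold loss every
58 minutes), with its standard error, one-tailed t against zero slope on
the model's 8 residual degrees of freedom, and the Bonferroni-adjusted
p-value over the four estimable strata. The generator's true rates here
were 0.0008, 0.0005, −0.0028 and −0.0182: the two no-decay temperatures are
correctly non-significant and the two decaying ones are recovered within
counting noise. The matching ANCOVA (`res["ancova"]["heat"]`) reports the
temperature × duration interaction on 4 and 8 degrees of freedom.

The same stages run from the shell:

```sh
psk simulate fixture --seed 7 --out data/
psk run --config run.yaml
psk decay-fit data/plaque_counts.csv --stressor heat
psk growth-fit data/measurements.csv data/layout.csv --smooth moving_median --window 5
```

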