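"""Stratified log-linear decay models and their tests.

The decay model: within each stratum (temperature, stock, or concentration)
log10(percent survival) is linear in exposure duration, with its own
intercept and slope and no pooled duration main effect — the design has one
intercept column and one duration column per stratum. Censored (below
limit-of-detection) observations are removed before fitting, so with k
strata carrying data and n uncensored points the residual df is n - 2k.

Outputs:

* per-stratum slope tests — one-tailed t against a zero slope (default
  direction "less", i.e. detecting decay), Bonferroni-adjusted over the
  family of estimable strata; strata with no uncensored data are reported
  as NA rows rather than errors;
* a sequential (Type I) ANCOVA table in the order stratum factor, then
  stratum:duration interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_engine as se

__all__ = ["DecayModelSpec", "DecayFit", "fit_stratified_decay",
           "slope_tests", "ancova_table", "decay_table"]


@dataclass
class DecayModelSpec:
    """Model structure: which column stratifies, which is the covariate."""

    stratifying_factor: str = "level"   # "level" or "stock_id"
    covariate: str = "duration_min"
    response: str = "log10_percent"
    include_main_effect: bool = False   # pooled duration slope, for sensitivity


@dataclass
class DecayFit:
    fit: se.LinearModelFit
    strata: list
    spec: DecayModelSpec

    def slope_name(self, stratum) -> str:
        return f"slope[{stratum}]"

    def intercept_name(self, stratum) -> str:
        return f"intercept[{stratum}]"


def _uncensored(observations: pd.DataFrame) -> pd.DataFrame:
    if "censored" in observations.columns:
        return observations[~observations["censored"].astype(bool)]
    return observations


def fit_stratified_decay(observations: pd.DataFrame,
                         spec: DecayModelSpec | None = None) -> DecayFit:
    """OLS fit of the stratified decay model on uncensored observations."""
    spec = spec or DecayModelSpec()
    obs = _uncensored(observations)
    if len(obs) == 0:
        raise ValueError("no uncensored observations to fit")
    strata = sorted(obs[spec.stratifying_factor].unique().tolist())

    for s in strata:
        sub = obs[obs[spec.stratifying_factor] == s]
        if sub[spec.covariate].nunique() < 2:
            raise ValueError(
                f"stratum {s!r} has fewer than 2 distinct durations; "
                "its slope is not estimable")

    n = len(obs)
    cols: dict[str, np.ndarray] = {}
    term_of: dict[str, str] = {}
    for s in strata:
        ind = (obs[spec.stratifying_factor] == s).to_numpy(dtype=float)
        cols[f"intercept[{s}]"] = ind
        term_of[f"intercept[{s}]"] = spec.stratifying_factor
    if spec.include_main_effect:
        cols["duration"] = obs[spec.covariate].to_numpy(dtype=float)
        term_of["duration"] = spec.covariate
    for s in strata:
        ind = (obs[spec.stratifying_factor] == s).to_numpy(dtype=float)
        cols[f"slope[{s}]"] = ind * obs[spec.covariate].to_numpy(dtype=float)
        term_of[f"slope[{s}]"] = f"{spec.stratifying_factor}:{spec.covariate}"
    design = pd.DataFrame(cols, index=range(n))
    fit = se.fit_ols(design, obs[spec.response].to_numpy(dtype=float), term_of)
    return DecayFit(fit=fit, strata=strata, spec=spec)


def slope_tests(decay_fit: DecayFit, direction: str = "less",
                n_tests: int | None = None,
                all_strata: list | None = None) -> pd.DataFrame:
    """Per-stratum one-tailed slope tests with Bonferroni adjustment.

    `all_strata` may list strata beyond those fitted (e.g. conditions whose
    observations were all censored); these become NA rows. The Bonferroni
    family size defaults to the number of estimable strata.
    """
    fit = decay_fit.fit
    if fit.residual_df <= 0 or fit.residual_ms < 1e-16:
        raise ValueError("zero residual variance: slope test undefined "
                         "(perfect fit; report the coefficients directly)")
    estimable = decay_fit.strata
    m = n_tests if n_tests is not None else len(estimable)
    if m < len(estimable):
        raise ValueError("n_tests smaller than the number of reported strata")
    rows = []
    for s in (all_strata if all_strata is not None else estimable):
        if s not in estimable:
            rows.append({"level": s, "slope": np.nan, "std_err": np.nan,
                         "t_value": np.nan, "df": fit.residual_df,
                         "p_one_tailed": np.nan, "p_bonferroni": np.nan,
                         "n_tests": m})
            continue
        name = decay_fit.slope_name(s)
        slope = float(fit.coefficients[name])
        stderr = fit.std_err(name)
        t = slope / stderr
        p = se.one_tailed_p(t, fit.residual_df, direction)
        rows.append({"level": s, "slope": slope, "std_err": stderr,
                     "t_value": t, "df": fit.residual_df,
                     "p_one_tailed": p, "p_bonferroni": se.bonferroni(p, m),
                     "n_tests": m})
    return pd.DataFrame(rows)


def ancova_table(observations: pd.DataFrame,
                 spec: DecayModelSpec | None = None) -> pd.DataFrame:
    """Sequential ANCOVA: stratum factor first, then stratum:duration.

    Term df follow the usual factor-model convention: with k strata the
    factor term carries k-1 df (after the grand mean) and the interaction
    k df (one slope per stratum), or k-1 if a pooled duration main effect
    is included in between.
    """
    spec = spec or DecayModelSpec()
    obs = _uncensored(observations)
    if len(obs) == 0:
        raise ValueError("no uncensored observations")
    strata = sorted(obs[spec.stratifying_factor].unique().tolist())
    n = len(obs)
    factor_cols, inter_cols = [], []
    cols: dict[str, np.ndarray] = {}
    dur = obs[spec.covariate].to_numpy(dtype=float)
    for s in strata:
        ind = (obs[spec.stratifying_factor] == s).to_numpy(dtype=float)
        cols[f"f[{s}]"] = ind
        factor_cols.append(f"f[{s}]")
        cols[f"fx[{s}]"] = ind * dur
        inter_cols.append(f"fx[{s}]")
    design = pd.DataFrame(cols, index=range(n))
    terms = [(spec.stratifying_factor, factor_cols)]
    if spec.include_main_effect:
        design["dur"] = dur
        terms.append((spec.covariate, ["dur"]))
    terms.append((f"{spec.stratifying_factor}:{spec.covariate}", inter_cols))
    return se.sequential_anova(design, obs[spec.response].to_numpy(dtype=float),
                              terms, include_intercept=True)


def decay_table(observations: pd.DataFrame,
                spec: DecayModelSpec | None = None,
                direction: str = "less",
                n_tests: int | None = None) -> pd.DataFrame:
    """Slope tests including NA rows for fully censored strata."""
    spec = spec or DecayModelSpec()
    all_strata = sorted(observations[spec.stratifying_factor].unique().tolist())
    fit = fit_stratified_decay(observations, spec)
    return slope_tests(fit, direction=direction, n_tests=n_tests,
                       all_strata=all_strata)
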