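"""Plaque counts -> PFU/mL titers -> percent survival.

A plate that received ``volume_ml`` of a 10^-d dilution and shows ``c``
plaques implies c / (volume_ml * 10^-d) PFU/mL in the undiluted sample.
Replicate plates whose counts fall in the countable range (default 3-300
plaques) are averaged at the titer level. A sample whose every plate shows
zero plaques is censored at the limit of detection: the titer implied by a
single plaque on the least-dilute plate actually plated for that sample,
scaled by any pre-plating dilution of the stressed sample (e.g. the
200-fold termination dilution used for urea/saline exposures).

Percent survival is the titer relative to a per-stressor reference
(heat gradient: the mildest temperature at the shortest exposure; heat
time course: the unstressed source stock; saline: the growth-medium
control at 0 min; urea: the 0 M control at 0 min). Censored observations
carry the LOD-implied percent and are excluded from all model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TiterEstimate",
    "SurvivalObservation",
    "ReferencePolicy",
    "estimate_titer",
    "limit_of_detection",
    "percent_survival",
    "titer_table",
    "survival_table",
]

DEFAULT_COUNTABLE_RANGE = (3, 300)


class CensoredReferenceError(ValueError):
    """A survival reference titer is itself below the limit of detection."""


@dataclass
class TiterEstimate:
    sample_id: str
    pfu_per_ml: float
    lod_pfu_per_ml: float
    censored: bool
    n_plates_used: int
    out_of_range: bool = False
    # sample metadata carried along for downstream grouping
    stressor: str = "none"
    level: float = np.nan
    duration_min: float = np.nan
    stock_id: str = ""


@dataclass
class SurvivalObservation:
    stressor: str
    level: float
    duration_min: float
    stock_id: str
    percent_survival: float
    log10_percent: float
    censored: bool
    reference_id: str
    sample_id: str = ""


def limit_of_detection(lowest_dilution_exponent: int, volume_ml: float,
                       pre_dilution_factor: float = 1.0) -> float:
    """Titer implied by one plaque on the least-dilute plate."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be positive")
    if pre_dilution_factor < 1:
        raise ValueError("pre_dilution_factor must be >= 1")
    return pre_dilution_factor / (volume_ml * 10.0 ** (-lowest_dilution_exponent))


def _per_plate_estimate(row) -> float:
    return row.plaques / (row.volume_ml * 10.0 ** (-row.dilution_exponent))


def estimate_titer(plates: pd.DataFrame,
                   countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
                   pre_dilution_factor: float = 1.0,
                   pooled: bool = False) -> TiterEstimate:
    """Estimate one sample's titer from its plate rows.

    Default mode averages per-plate estimates over countable plates;
    ``pooled=True`` instead sums plaques and divides by total effective
    volume across countable plates. If no plate is countable but some show
    plaques, the plate with the highest count at the highest dilution with a
    nonzero count is used and the estimate flagged ``out_of_range``. All
    plates at zero -> censored at the LOD.
    """
    if len(plates) == 0:
        raise ValueError("no plates supplied")
    lo, hi = countable_range
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid countable_range {countable_range}")
    sample_id = str(plates["sample_id"].iloc[0])
    meta = dict(
        stressor=str(plates["stressor"].iloc[0]),
        level=float(plates["level"].iloc[0]),
        duration_min=float(plates["duration_min"].iloc[0]),
        stock_id=str(plates["stock_id"].iloc[0]),
    )
    lod = limit_of_detection(int(plates["dilution_exponent"].min()),
                             float(plates.loc[plates["dilution_exponent"].idxmin(),
                                              "volume_ml"]),
                             pre_dilution_factor)

    countable = plates[(plates["plaques"] >= lo) & (plates["plaques"] <= hi)]
    if len(countable) > 0:
        if pooled:
            eff_vol = (countable["volume_ml"]
                       * 10.0 ** (-countable["dilution_exponent"])).sum()
            titer = countable["plaques"].sum() / eff_vol
        else:
            titer = float(np.mean(
                [_per_plate_estimate(r) for r in countable.itertuples()]))
        return TiterEstimate(sample_id, pre_dilution_factor * float(titer), lod,
                             censored=False, n_plates_used=len(countable), **meta)

    nonzero = plates[plates["plaques"] > 0]
    if len(nonzero) > 0:
        top_dil = nonzero["dilution_exponent"].max()
        at_top = nonzero[nonzero["dilution_exponent"] == top_dil]
        best = max(at_top.itertuples(), key=lambda r: r.plaques)
        titer = pre_dilution_factor * _per_plate_estimate(best)
        return TiterEstimate(sample_id, float(titer), lod, censored=False,
                             n_plates_used=1, out_of_range=True, **meta)

    return TiterEstimate(sample_id, lod, lod, censored=True,
                         n_plates_used=0, **meta)


def percent_survival(obs: TiterEstimate, reference: TiterEstimate) -> SurvivalObservation:
    """Survival of `obs` relative to `reference`, as a percentage."""
    if reference.censored:
        raise CensoredReferenceError(
            f"reference sample {reference.sample_id!r} is censored; "
            "cannot normalize survival against it")
    pct = 100.0 * obs.pfu_per_ml / reference.pfu_per_ml
    return SurvivalObservation(
        stressor=obs.stressor, level=obs.level, duration_min=obs.duration_min,
        stock_id=obs.stock_id, percent_survival=pct,
        log10_percent=math.log10(pct), censored=obs.censored,
        reference_id=reference.sample_id, sample_id=obs.sample_id)


def titer_table(plaque_table: pd.DataFrame,
                countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
                pre_dilution_factor: float = 1.0,
                pooled: bool = False) -> list[TiterEstimate]:
    """Per-sample titer estimates, in first-appearance order of sample_id."""
    order = plaque_table["sample_id"].drop_duplicates().tolist()
    out = []
    for sid in order:
        plates = plaque_table[plaque_table["sample_id"] == sid]
        out.append(estimate_titer(plates, countable_range,
                                  pre_dilution_factor, pooled))
    return out


@dataclass
class ReferencePolicy:
    """Which sample normalizes each stressed sample.

    The reference is the sample of the same stock (when ``per_stock``) whose
    (stressor, level, duration) match the policy; falling back to a single
    global reference when a stock-specific one is absent.
    """

    stressor: str
    ref_level: float | None
    ref_duration_min: float
    ref_stressor: str | None = None  # defaults to `stressor`; "none" for stock refs
    per_stock: bool = True

    def matches(self, t: TiterEstimate) -> bool:
        ref_stressor = self.ref_stressor or self.stressor
        if t.stressor != ref_stressor:
            return False
        if self.ref_level is not None and not np.isclose(t.level, self.ref_level):
            return False
        return np.isclose(t.duration_min, self.ref_duration_min)


# reference policies named after the experimental designs they serve
POLICIES = {
    # gradient exposures referenced to the mildest temperature; the short
    # (5 min) exposure is the default reference timepoint, a 0-min variant
    # is provided because figure and protocol conventions differ
    "heat_gradient_methods": ReferencePolicy("heat", ref_level=55.0, ref_duration_min=5.0),
    "heat_gradient_figure": ReferencePolicy("heat", ref_level=55.0, ref_duration_min=0.0),
    # long time course referenced to the unstressed source stock
    "heat_timecourse": ReferencePolicy("heat", ref_level=None,
                                       ref_duration_min=0.0, ref_stressor="none"),
    # growth-medium control (0.17 M) at time zero
    "saline": ReferencePolicy("saline", ref_level=0.17, ref_duration_min=0.0),
    "urea": ReferencePolicy("urea", ref_level=0.0, ref_duration_min=0.0),
}


def survival_table(titers: list[TiterEstimate], policy: ReferencePolicy,
                   include_references: bool = False) -> pd.DataFrame:
    """Percent survival for every titer under `policy`'s stressor.

    Censored rows are kept (flagged) so downstream fits can prove their
    exclusion; reference samples themselves are omitted unless requested.
    """
    refs = [t for t in titers if policy.matches(t)]
    if not refs:
        raise ValueError(f"no reference sample found for policy {policy}")
    by_stock = {t.stock_id: t for t in refs}
    global_ref = refs[0]

    rows = []
    for t in titers:
        if t.stressor != policy.stressor:
            continue
        is_ref = policy.matches(t)
        if is_ref and not include_references:
            continue
        ref = by_stock.get(t.stock_id, global_ref) if policy.per_stock else global_ref
        rows.append(percent_survival(t, ref).__dict__)
    return pd.DataFrame(rows)
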