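"""Growth-curve-derived phage fitness.

A phage-challenged bacterial culture rises, peaks, and declines as lysis
overtakes growth; the first local maximum of the smoothed OD600 trajectory
is a reverse proxy for phage fitness (higher peak = weaker suppression =
lower phage fitness). This module converts OD600 to cell densities via a
log-linear standard curve, plans MOI-normalized phage dosing, smooths
trajectories (moving median by default), extracts the first peak, and
compares treatments with a two-factor ANOVA (treatment + stock +
interaction), Tukey HSD letters over treatments, and a Welch t-test for
the phage-free control pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_engine as se
from .titering import TiterEstimate

__all__ = [
    "StandardCurve", "DoseSpec", "DosingPlan", "PeakStatistic",
    "od_to_cfu", "cfu_to_od", "dose_wells", "smooth_curve", "first_peak",
    "default_prominence", "peak_table", "fitness_comparison",
]


@dataclass
class StandardCurve:
    """log10 CFU/mL = intercept + slope * OD600, valid on an OD range."""

    intercept: float = 8.0
    slope: float = 1.0
    valid_od_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        lo, hi = self.valid_od_range
        if not lo < hi:
            raise ValueError("invalid OD range")


def od_to_cfu(od: float, curve: StandardCurve) -> tuple[float, bool]:
    """CFU/mL for an OD600 reading; second element flags extrapolation."""
    lo, hi = curve.valid_od_range
    extrapolated = not (lo <= od <= hi)
    return 10.0 ** (curve.intercept + curve.slope * od), extrapolated


def cfu_to_od(cfu_per_ml: float, curve: StandardCurve) -> float:
    if cfu_per_ml <= 0:
        raise ValueError("cfu_per_ml must be positive")
    return (np.log10(cfu_per_ml) - curve.intercept) / curve.slope


@dataclass
class DoseSpec:
    """Dosing targets: a fixed PFU count per well at a fixed MOI."""

    target_pfu_per_well: float = 200.0
    target_moi: float = 1e-5
    well_volume_ml: float = 0.2
    max_phage_volume_ml: float = 0.1
    min_phage_volume_ml: float = 0.001  # 1 uL, smallest pipettable addition
    dilution_step: int = 10  # serial-dilution fold used for intermediates

    def __post_init__(self):
        for name in ("target_pfu_per_well", "target_moi", "well_volume_ml",
                     "max_phage_volume_ml", "min_phage_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_phage_volume_ml > self.max_phage_volume_ml:
            raise ValueError("min_phage_volume_ml exceeds max_phage_volume_ml")


@dataclass
class DosingPlan:
    phage_dilution_factor: float
    phage_volume_ml: float
    bacteria_cells_per_well: float
    achieved_pfu: float
    achieved_moi: float
    insufficient_flag: bool


def dose_wells(titer: TiterEstimate, culture_od: float, curve: StandardCurve,
               spec: DoseSpec | None = None) -> DosingPlan:
    """Plan the phage/bacteria mix for one treatment's wells.

    Bacteria per well are set by the MOI target (target_pfu / target_moi).
    High-titer stocks get an intermediate serial dilution raising the
    required addition above the smallest pipettable volume; if even
    undiluted stock at the per-well volume cap cannot supply the target
    PFU, the plan is flagged insufficient and delivers the maximum
    attainable dose (such wells are excluded from the treatment ANOVA but
    still reported).
    """
    spec = spec or DoseSpec()
    if titer.censored:
        raise ValueError(f"sample {titer.sample_id!r} is censored; cannot dose")
    bacteria = spec.target_pfu_per_well / spec.target_moi
    cfu_per_ml, _ = od_to_cfu(culture_od, curve)
    if cfu_per_ml <= 0:
        raise ValueError("culture density must be positive")

    max_deliverable = titer.pfu_per_ml * spec.max_phage_volume_ml
    if max_deliverable < spec.target_pfu_per_well:
        return DosingPlan(1.0, spec.max_phage_volume_ml, bacteria,
                          achieved_pfu=max_deliverable,
                          achieved_moi=max_deliverable / bacteria,
                          insufficient_flag=True)

    dilution = 1.0
    vol = spec.target_pfu_per_well / titer.pfu_per_ml
    while vol < spec.min_phage_volume_ml:
        dilution *= spec.dilution_step
        vol = dilution * spec.target_pfu_per_well / titer.pfu_per_ml
    vol = min(vol, spec.max_phage_volume_ml)
    return DosingPlan(dilution, vol, bacteria,
                      achieved_pfu=(titer.pfu_per_ml / dilution) * vol,
                      achieved_moi=(titer.pfu_per_ml / dilution) * vol / bacteria,
                      insufficient_flag=False)


def smooth_curve(od: np.ndarray, method: str = "moving_median",
                 window: int = 5) -> np.ndarray:
    """Windowed smoothing; edges shrink the window symmetrically."""
    od = np.asarray(od, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > len(od):
        raise ValueError("window exceeds series length")
    if method not in ("moving_median", "moving_average"):
        raise ValueError(f"unknown smoothing method {method!r}")
    half = window // 2
    n = len(od)
    out = np.empty(n)
    agg = np.median if method == "moving_median" else np.mean
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = agg(od[i - h:i + h + 1])
    return out


def default_prominence(smoothed: np.ndarray) -> float:
    """Noise floor: 3x the median absolute successive difference."""
    d = np.abs(np.diff(np.asarray(smoothed, dtype=float)))
    return 3.0 * float(np.median(d)) if len(d) else 0.0


@dataclass
class PeakStatistic:
    well_id: str
    peak_od: float
    peak_time_min: float
    smoothing_window: int
    boundary_flag: bool
    peak_index: int = -1
    treatment: str = ""
    stock_id: str = ""
    excluded_flag: bool = False


def first_peak(smoothed: np.ndarray, time_grid: np.ndarray,
               prominence: float = 0.0, local_window: int = 5,
               well_id: str = "", smoothing_window: int = 5) -> PeakStatistic:
    """Earliest qualifying local maximum of a smoothed series.

    Index i qualifies when smoothed[i] >= every point in the (shrunken at
    the edges) window of `local_window` points centred on i, and the series
    afterwards drops to <= smoothed[i] - prominence. Ties go to the earliest
    index. With no qualifying interior maximum the global maximum is
    returned with ``boundary_flag`` set.
    """
    s = np.asarray(smoothed, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if len(s) < 3:
        raise ValueError("series must have at least 3 points")
    if len(s) != len(t):
        raise ValueError("series and time grid length mismatch")
    half = max(1, local_window // 2)
    n = len(s)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if h == 0:
            continue  # series endpoints are not interior maxima
        if s[i] < s[max(0, i - h):i + h + 1].max():
            continue
        if np.min(s[i:]) <= s[i] - prominence:
            return PeakStatistic(well_id, float(s[i]), float(t[i]),
                                 smoothing_window, boundary_flag=False,
                                 peak_index=i)
    i = int(np.argmax(s))
    return PeakStatistic(well_id, float(s[i]), float(t[i]), smoothing_window,
                         boundary_flag=True, peak_index=i)


def peak_table(plate, method: str = "moving_median", window: int = 5,
               prominence: float | None = None,
               dose_target_pfu: float | None = 200.0,
               dose_tolerance: float = 0.01) -> pd.DataFrame:
    """Peak statistics for every well of a plate-reader run.

    `plate` is an assay_io.PlateTimeSeries. Wells whose inoculated PFU
    misses ``dose_target_pfu`` by more than ``dose_tolerance`` (relative)
    are flagged ``excluded_flag`` (under-dosed) and left out of the
    downstream treatment ANOVA; phage-free control wells are never excluded
    on dose grounds.
    """
    rows = []
    for lay in plate.layout.itertuples():
        grp = plate.well_series(lay.well_id)
        od = grp["od600"].to_numpy(dtype=float)
        tt = grp["time_min"].to_numpy(dtype=float)
        sm = smooth_curve(od, method=method, window=window)
        prom = default_prominence(sm) if prominence is None else prominence
        pk = first_peak(sm, tt, prominence=prom, local_window=window,
                        well_id=lay.well_id, smoothing_window=window)
        pk.treatment = str(lay.treatment)
        pk.stock_id = str(lay.stock_id)
        ctrl = str(getattr(lay, "control_type", "") or "").strip()
        if ctrl.lower() in ("nan", "none"):
            ctrl = ""
        if dose_target_pfu is not None and not ctrl:
            pfu = getattr(lay, "inoculated_pfu", np.nan)
            pk.excluded_flag = (not np.isfinite(pfu)) or \
                abs(pfu - dose_target_pfu) > dose_tolerance * dose_target_pfu
        rows.append({**pk.__dict__, "control_type": ctrl})
    return pd.DataFrame(rows)


def fitness_comparison(peaks: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Treatment comparison of peak densities.

    Returns a dict with keys ``anova_table`` (sequential: treatment, stock,
    treatment:stock), ``tukey`` (pairwise comparisons over treatment levels
    using the model's residual mean square), ``letters`` (compact letter
    display at `alpha`), and ``welch_controls`` (Welch t-test between the
    two phage-free control groups, if present).
    """
    ctrl_col = peaks.get("control_type")
    is_ctrl = (ctrl_col.fillna("").astype(str).isin(["", "nan"]) == False) \
        if ctrl_col is not None else pd.Series(False, index=peaks.index)
    phage = peaks[~is_ctrl & ~peaks["excluded_flag"].astype(bool)]

    treatments = sorted(phage["treatment"].unique().tolist())
    if len(treatments) < 2:
        raise ValueError("need >= 2 treatments with eligible wells")
    for tr in treatments:
        if (phage["treatment"] == tr).sum() < 2:
            raise ValueError(f"treatment {tr!r} has fewer than 2 eligible wells")

    y = phage["peak_od"].to_numpy(dtype=float)
    n = len(phage)
    stocks = sorted(phage["stock_id"].unique().tolist())
    cols: dict[str, np.ndarray] = {}
    t_cols, s_cols, i_cols = [], [], []
    # treatment-contrast coding: first level of each factor is baseline
    for tr in treatments[1:]:
        cols[f"t[{tr}]"] = (phage["treatment"] == tr).to_numpy(dtype=float)
        t_cols.append(f"t[{tr}]")
    for st in stocks[1:]:
        cols[f"s[{st}]"] = (phage["stock_id"] == st).to_numpy(dtype=float)
        s_cols.append(f"s[{st}]")
    for tr in treatments[1:]:
        for st in stocks[1:]:
            cols[f"ts[{tr}|{st}]"] = cols[f"t[{tr}]"] * cols[f"s[{st}]"]
            i_cols.append(f"ts[{tr}|{st}]")
    design = pd.DataFrame(cols, index=range(n))
    terms = [("treatment", t_cols)]
    if s_cols:
        terms.append(("stock", s_cols))
    if i_cols:
        terms.append(("treatment:stock", i_cols))
    anova = se.sequential_anova(design, y, terms, include_intercept=True)

    resid = anova[anova["term"] == "Residual"].iloc[0]
    mse, df_resid = float(resid["mean_sq"]), int(resid["df"])
    means = {tr: float(phage.loc[phage["treatment"] == tr, "peak_od"].mean())
             for tr in treatments}
    ns = {tr: int((phage["treatment"] == tr).sum()) for tr in treatments}
    tukey = se.tukey_hsd(means, ns, mse, df_resid, alpha=alpha)
    letters = se.compact_letters(tukey, levels=treatments, alpha=alpha)

    welch = None
    if ctrl_col is not None:
        ctrl = peaks[is_ctrl]
        kinds = sorted(ctrl["control_type"].astype(str).unique().tolist())
        if len(kinds) == 2:
            a = ctrl.loc[ctrl["control_type"] == kinds[0], "peak_od"]
            b = ctrl.loc[ctrl["control_type"] == kinds[1], "peak_od"]
            if len(a) >= 2 and len(b) >= 2:
                try:
                    welch = {"groups": kinds, **se.welch_t(b, a)}
                except ValueError:
                    welch = None  # degenerate (noise-free) control samples

    return {"anova_table": anova, "tukey": tukey, "letters": letters,
            "welch_controls": welch, "group_means": means, "group_ns": ns}
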