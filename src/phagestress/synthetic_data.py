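"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* ``simulate_decay_assay`` — virions decay exponentially (optionally
  biphasically) on a log10 scale per stress condition; each stock carries a
  lognormal titer offset; the true titer is then observed through a serial
  dilution series as Poisson plaque counts per plate, reproducing the
  counting noise, countable-range selection and limit-of-detection
  censoring of a real plaque assay.

* ``simulate_growth_curves`` — bacterial growth under phage predation:
  logistic host growth, mass-action adsorption, an Erlang-staged latent
  period (a smooth stand-in for a fixed lysis delay), and burst release.
  A damage factor in (0, 1] multiplies the adsorption rate (or burst size)
  of heat-shocked phage, lowering per-particle fitness without changing
  the inoculated PFU. OD600 is linear in total cells plus Gaussian
  plate-reader noise. Trajectories rise, peak and decline, and the peak is
  higher when phage are fewer or damaged.

Determinism: every generator takes a seed (or Generator) and produces
identical output for identical input, using a single numpy Generator
stream per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DecayCondition", "DecaySimConfig", "simulate_decay_assay",
    "GrowthSimConfig", "growth_layout", "simulate_growth_curves",
    "make_fixture_bundle", "HEAT_GRADIENT_SLOPES",
]

# published per-temperature decay slopes (log10 percent survival per minute)
# for the heat-gradient design; used as generator defaults so simulated
# experiments match the study's observed kinetics
HEAT_GRADIENT_SLOPES = {55.0: 0.0008, 60.0: 0.0005, 65.0: -0.0028, 70.0: -0.0182}


@dataclass
class DecayCondition:
    """One stress condition: a (stressor, level) with its decay rate(s).

    ``k1``/``k2`` are log10-scale decay rates per minute (negative = decay;
    small positive values model sampling drift in no-decay conditions);
    ``fraction_fast`` = 1 gives mono-exponential decay.
    """

    label: str
    level: float
    k1: float
    stressor: str = "heat"
    k2: float | None = None
    fraction_fast: float = 1.0
    durations_min: tuple | None = None  # falls back to config durations

    def log10_survival(self, t: float) -> float:
        f = self.fraction_fast
        if f >= 1.0 or self.k2 is None:
            return self.k1 * t
        return float(np.log10(f * 10.0 ** (self.k1 * t)
                              + (1 - f) * 10.0 ** (self.k2 * t)))


@dataclass
class DecaySimConfig:
    n0_pfu_per_ml: float = 1e9
    conditions: tuple = tuple(
        DecayCondition(f"{int(temp)}C", temp, k)
        for temp, k in HEAT_GRADIENT_SLOPES.items())
    durations_min: tuple = (5.0, 30.0, 60.0, 90.0)
    stocks: tuple = ("A",)
    stock_sd: float = 0.0            # log10-scale between-stock variation
    volume_ml: float = 0.1
    dilution_exponents: tuple = tuple(range(0, 8))
    n_plates: int = 3                # triplicate titering
    poisson_noise: bool = True
    include_source_reference: bool = False  # unstressed stock samples at t=0
    seed: int = 0

    def __post_init__(self):
        if self.n0_pfu_per_ml <= 0:
            raise ValueError("n0_pfu_per_ml must be positive")
        if not self.durations_min:
            raise ValueError("durations_min must be nonempty")
        if self.stock_sd < 0 or self.n_plates < 1 or self.volume_ml <= 0:
            raise ValueError("invalid noise/plate/volume settings")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_decay_assay(config: DecaySimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plaque-count table for a simulated decay experiment."""
    rng = _rng(config.seed if rng is None else rng)
    rows = []
    offsets = {s: (10.0 ** rng.normal(0.0, config.stock_sd)
                   if config.stock_sd > 0 else 1.0) for s in config.stocks}

    def plate_rows(sample_id, stressor, level, duration, stock, true_titer):
        for exponent in config.dilution_exponents:
            mean = true_titer * config.volume_ml * 10.0 ** (-exponent)
            for _ in range(config.n_plates):
                if config.poisson_noise:
                    count = int(rng.poisson(mean)) if mean < 1e12 else int(round(mean))
                else:
                    count = int(round(mean))
                rows.append({
                    "sample_id": sample_id, "stressor": stressor,
                    "level": level, "duration_min": duration,
                    "stock_id": stock, "dilution_exponent": exponent,
                    "volume_ml": config.volume_ml, "plaques": count})

    for stock in config.stocks:
        n0 = config.n0_pfu_per_ml * offsets[stock]
        if config.include_source_reference:
            plate_rows(f"src_{stock}", "none", 0.0, 0.0, stock, n0)
        for cond in config.conditions:
            durations = cond.durations_min or config.durations_min
            for t in durations:
                titer = n0 * 10.0 ** cond.log10_survival(t)
                sid = f"{cond.stressor}_{cond.label}_t{t:g}_{stock}"
                plate_rows(sid, cond.stressor, cond.level, t, stock, titer)
    return pd.DataFrame(rows)


@dataclass
class GrowthSimConfig:
    """Phage-bacteria microplate dynamics parameters.

    Rates are per minute; densities per mL. Defaults describe a lytic
    myovirus on a fast-growing gram-negative host in rich medium at the
    study's dosing (200 PFU/well at MOI 1e-5 in 0.2 mL).
    """

    r: float = 0.025                  # host growth rate, ~28 min doubling
    K: float = 1.5e9                  # carrying capacity, cells/mL
    adsorption: float = 2.4e-9        # mL/(cell*min)
    burst: int = 150
    latent_min: float = 35.0
    n_stages: int = 5                 # Erlang stages of the latent period
    od_per_cell: float = 1e-9         # OD600 per (cell/mL)
    od_blank: float = 0.04
    od_noise_sd: float = 0.005
    damage_target: str = "adsorption"  # or "burst"
    integrator: str = "lsoda"         # stiff solver; "rk4" = fixed-step
    dose_pfu: float = 200.0
    target_moi: float = 1e-5
    well_volume_ml: float = 0.2
    duration_min: float = 720.0
    step_min: float = 5.0             # measurement interval
    seed: int = 0

    def __post_init__(self):
        for name in ("r", "K", "adsorption", "latent_min", "od_per_cell",
                     "step_min", "duration_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burst < 1 or self.n_stages < 1:
            raise ValueError("burst and n_stages must be >= 1")
        if self.damage_target not in ("adsorption", "burst"):
            raise ValueError("damage_target must be 'adsorption' or 'burst'")
        if self.integrator not in ("lsoda", "rk4"):
            raise ValueError("integrator must be 'lsoda' or 'rk4'")


def growth_layout(treatments: dict[str, float], stocks: tuple = ("A", "B"),
                  replicates: int = 3, controls: int = 6,
                  dose_pfu: float = 200.0,
                  underdosed: dict[str, float] | None = None) -> pd.DataFrame:
    """Well layout for a simulated plate.

    `treatments` maps treatment label -> damage factor (1.0 for the
    unshocked control). Two phage-free control groups (plain and shocked
    medium) are appended. ``underdosed`` maps treatment labels to the
    achievable PFU when the stressed stock could not supply the target dose.
    """
    rows = []
    idx = 0
    letters = "ABCDEFGH"

    def next_well():
        nonlocal idx
        w = f"{letters[idx // 12]}{idx % 12 + 1}"
        idx += 1
        return w

    for label, damage in treatments.items():
        pfu = (underdosed or {}).get(label, dose_pfu)
        for stock in stocks:
            for _ in range(replicates):
                rows.append({"well_id": next_well(), "treatment": label,
                             "stock_id": stock, "inoculated_pfu": pfu,
                             "target_moi": 1e-5, "control_type": "",
                             "damage_factor": damage})
    for ctrl in ("plus_ctrl", "plus_ctrl_shock"):
        for _ in range(controls):
            rows.append({"well_id": next_well(), "treatment": ctrl,
                         "stock_id": "none", "inoculated_pfu": 0.0,
                         "target_moi": np.nan, "control_type": ctrl,
                         "damage_factor": 1.0})
    return pd.DataFrame(rows)


def _integrate_well(cfg: GrowthSimConfig, b0: float, p0: float,
                    damage: float, k_mult: float = 1.0) -> np.ndarray:
    """Total cell density at each measurement time.

    The system turns stiff once free phage amplify (adsorption rates far
    exceed the measurement interval), so the default integrator is LSODA
    with tight relative tolerance; the fixed-step RK4 alternative is only
    adequate for gentle parameter ranges and raises on instability.
    """
    n = cfg.n_stages
    a = cfg.adsorption * (damage if cfg.damage_target == "adsorption" else 1.0)
    burst = cfg.burst * (damage if cfg.damage_target == "burst" else 1.0)
    mu = n / cfg.latent_min
    r = cfg.r
    K = cfg.K * k_mult

    def deriv(y):
        B, P = max(y[0], 0.0), max(y[-1], 0.0)
        infected = np.maximum(y[1:-1], 0.0)
        total = B + infected.sum()
        adsorb = a * B * P
        d = np.empty_like(y)
        d[0] = r * B * (1.0 - total / K) - adsorb
        d[1] = adsorb - mu * infected[0]
        for j in range(1, n):
            d[1 + j] = mu * (infected[j - 1] - infected[j])
        d[-1] = burst * mu * infected[-1] - adsorb
        return d

    n_meas = int(round(cfg.duration_min / cfg.step_min)) + 1
    times = np.arange(n_meas) * cfg.step_min
    y0 = np.zeros(n + 2)
    y0[0], y0[-1] = b0, p0

    if cfg.integrator == "lsoda":
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda t, y: deriv(y), (0.0, float(times[-1])), y0,
                        method="LSODA", t_eval=times, rtol=1e-8,
                        atol=1e-3 * max(1.0, b0) * 1e-6)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        cells = np.maximum(sol.y[0], 0.0) + np.maximum(sol.y[1:-1], 0.0).sum(axis=0)
        return cells

    h = cfg.step_min / 4.0
    y = y0.copy()
    out = np.empty(n_meas)
    out[0] = b0
    for m in range(1, n_meas):
        for _ in range(4):
            k1 = deriv(y)
            k2 = deriv(y + 0.5 * h * k1)
            k3 = deriv(y + 0.5 * h * k2)
            k4 = deriv(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            np.clip(y, 0.0, None, out=y)
        total = y[0] + y[1:-1].sum()
        if not np.all(np.isfinite(y)) or total > 1.05 * K:
            raise RuntimeError("unstable integration: reduce step_min or use "
                               "the 'lsoda' integrator")
        out[m] = total
    return out


def simulate_growth_curves(config: GrowthSimConfig, layout: pd.DataFrame,
                           rng: np.random.Generator | None = None):
    """OD600 trajectories for every well of `layout`.

    Returns an ``assay_io.PlateTimeSeries``. Initial bacterial density is
    set by the MOI target (dose / MOI, scaled to per-mL); phage-free
    control wells get no phage, and the shocked-medium control carries a
    slightly reduced carrying capacity (nutrient degradation by prolonged
    heating), so it peaks lower than the plain-medium control — the
    direction of the study's control contrast.
    """
    from .assay_io import PlateTimeSeries

    rng = _rng(config.seed if rng is None else rng)
    n_meas = int(round(config.duration_min / config.step_min)) + 1
    time = np.arange(n_meas) * config.step_min
    b0 = (config.dose_pfu / config.target_moi) / config.well_volume_ml
    meas_rows = []
    for lay in layout.itertuples():
        p0 = float(lay.inoculated_pfu) / config.well_volume_ml
        damage = float(getattr(lay, "damage_factor", 1.0))
        k_mult = 0.93 if lay.control_type == "plus_ctrl_shock" else 1.0
        cells = _integrate_well(config, b0, p0, damage, k_mult)
        od = config.od_blank + config.od_per_cell * cells
        if config.od_noise_sd > 0:
            od = od + rng.normal(0.0, config.od_noise_sd, size=n_meas)
        for t, v in zip(time, od):
            meas_rows.append({"well_id": lay.well_id, "time_min": float(t),
                              "od600": float(v)})
    measurements = pd.DataFrame(meas_rows).sort_values(
        ["well_id", "time_min"], kind="stable").reset_index(drop=True)
    lay_out = layout.drop(columns=["damage_factor"], errors="ignore")
    return PlateTimeSeries(layout=lay_out.reset_index(drop=True),
                           measurements=measurements)


def make_fixture_bundle(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a small, self-consistent dataset exercising every stage.

    Contents: a heat gradient (4 estimable temperatures x 4 durations x 2
    stocks, plus a hotter condition driven fully below the limit of
    detection), urea and saline series (5 levels x 2 timepoints x 3 stocks
    with 0-min reference samples), and one growth plate with shocked,
    unshocked, under-dosed and phage-free control wells.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    heat_conditions = tuple(
        DecayCondition(f"{int(t)}C", t, k) for t, k in HEAT_GRADIENT_SLOPES.items()
    ) + (DecayCondition("75C", 75.0, -2.5),)  # decays below LOD within minutes
    heat_cfg = DecaySimConfig(conditions=heat_conditions, stocks=("A", "B"),
                              stock_sd=0.1, seed=seed)
    heat = simulate_decay_assay(heat_cfg, rng)

    def chem(stressor, levels, control_level, k_of):
        conds = []
        for lev in levels:
            durs = (0.0, 45.0, 90.0) if lev == control_level else (45.0, 90.0)
            conds.append(DecayCondition(f"{lev:g}M", lev, k_of(lev),
                                        stressor=stressor, durations_min=durs))
        cfg = DecaySimConfig(conditions=tuple(conds), stocks=("F", "G", "H"),
                             stock_sd=0.1, seed=seed)
        return simulate_decay_assay(cfg, rng)

    urea = chem("urea", (0.0, 1.0, 2.0, 3.0, 4.0), 0.0,
                lambda lev: -0.012 * max(0.0, lev - 2.0))
    saline = chem("saline", (0.0, 0.17, 0.5, 3.0, 5.0), 0.17, lambda lev: 0.0)

    plaques = pd.concat([heat, urea, saline], ignore_index=True)
    plaque_path = out_dir / "plaque_counts.csv"
    plaques.drop(columns=["plate_replicate"], errors="ignore").to_csv(
        plaque_path, index=False)

    # damage saturates within minutes of heat shock: every shocked
    # treatment shares one damage factor, so shocked durations are
    # statistically indistinguishable from each other but not from 0 min
    layout = growth_layout({"0": 1.0, "5": 0.2, "90": 0.2, "180": 0.2,
                            "270": 0.2},
                           stocks=("A", "B"), replicates=3,
                           underdosed={"270": 40.0})
    growth_cfg = GrowthSimConfig(seed=seed)
    plate = simulate_growth_curves(growth_cfg, layout, rng)
    layout_path = out_dir / "layout.csv"
    meas_path = out_dir / "measurements.csv"
    plate.layout.to_csv(layout_path, index=False)
    plate.measurements.to_csv(meas_path, index=False)
    return {"plaque_counts": plaque_path, "layout": layout_path,
            "measurements": meas_path}
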