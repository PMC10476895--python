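"""Canonical validation experiments.

These functions define, in one place, the package's standard synthetic
experiments: the GA benchmark against a grid-search oracle, the
parameter-recovery experiment for the minimum growth temperature, and the
structural-recovery run of the full analysis chain on the default
synthetic study. They are used both by the test suite and by the
reproduction script, so the numbers those two report are computed by the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import GAConfig, calibrate, ga_optimize
from .climate import DailyClimateSeries
from .forcing_chilling import build_cf_table, cf_frame, select_chilling_window, slope_ratio
from .response_analysis import compare_slopes, fit_response, project_mismatch
from .synthetic_data import SynthClimateConfig, generate_climate, make_study
from .vs_growth import VSParameters, simulate_chronology

#: Climate used for the t1-recovery experiment: a very short growing
#: season (annual mean -3 degC) makes the annual increment pattern
#: genuinely sensitive to the minimum growth temperature, which a
#: correlation-only objective cannot resolve in milder climates.
RECOVERY_CLIMATE = dict(
    years=(1965, 2014),
    latitude=50.0,
    mean_annual_t=-3.0,
    seasonal_amplitude=5.5,
    seasonal_asymmetry=0.0,
    peak_doy=200,
    daily_noise_sd=2.0,
    ar1_coefficient=0.6,
    annual_anomaly_sd=1.0,
    annual_anomaly_ar1=0.5,
    spring_trend=0.0,
    winter_trend=0.0,
)

#: Ground truth for the recovery experiment; t1 = 2 degC is the quantity
#: the experiment recovers, the other thresholds are held at truth.
RECOVERY_TRUTH = dict(t1=2.0, t2=6.0, t3=18.0, t4=26.0)

RECOVERY_NOISE_SD = 0.3
RECOVERY_N_YEARS = 50


@dataclass
class RecoveryResult:
    errors: list[float]
    retained: list[bool]
    best_rs: list[float]

    @property
    def median_abs_error(self) -> float:
        return float(np.median(np.abs(self.errors)))

    @property
    def all_retained(self) -> bool:
        return all(self.retained)


def recovery_climate(seed: int) -> DailyClimateSeries:
    return generate_climate(SynthClimateConfig(seed=seed, **RECOVERY_CLIMATE),
                            site_id="recovery")


def t1_recovery_trial(seed: int, noise_sd: float = RECOVERY_NOISE_SD,
                      population_size: int = 30, generations: int = 25):
    """One recovery trial: simulate truth, add index noise, re-calibrate t1."""
    clim = recovery_climate(1000 + seed)
    truth = VSParameters(**RECOVERY_TRUTH)
    y0, y1 = RECOVERY_CLIMATE["years"]
    years = np.arange(y0, y1 + 1)
    sim = simulate_chronology(clim, years, truth)
    rng = np.random.default_rng(seed)
    observed = sim.index + rng.normal(0.0, noise_sd, len(years))
    cfg = GAConfig(bounds={"t1": (0.0, 5.5)}, population_size=population_size,
                   generations=generations, seed=seed)
    return calibrate(years, observed, clim, config=cfg, base_params=truth)


def t1_recovery_experiment(n_seeds: int = 10, base_seed: int = 0) -> RecoveryResult:
    """Median-over-seeds recovery error of the minimum growth temperature."""
    errors, retained, best_rs = [], [], []
    for k in range(n_seeds):
        seed = base_seed + k + 1
        res = t1_recovery_trial(seed)
        errors.append(float(res.best_params.t1 - RECOVERY_TRUTH["t1"]))
        retained.append(res.retained)
        best_rs.append(res.best_r)
    return RecoveryResult(errors=errors, retained=retained, best_rs=best_rs)


# ---------------------------------------------------------------------------
# GA benchmark


def quadratic_objective(center=(3.0, -1.5)):
    cx, cy = center

    def f(x: dict[str, float]) -> float:
        return -((x["a"] - cx) ** 2 + (x["b"] - cy) ** 2)

    return f


def ga_grid_benchmark(seed: int = 0, grid_n: int = 50):
    """GA versus a dense grid-search oracle on a smooth 2-parameter bowl.

    Returns (ga_best, grid_best, ga_result); a sound GA should come within
    a small margin of the grid optimum.
    """
    bounds = {"a": (-5.0, 5.0), "b": (-5.0, 5.0)}
    f = quadratic_objective()
    cfg = GAConfig(bounds=bounds, population_size=40, generations=50, seed=seed)
    ga = ga_optimize(f, cfg)
    axis_a = np.linspace(*bounds["a"], grid_n)
    axis_b = np.linspace(*bounds["b"], grid_n)
    grid_best = max(
        f({"a": a, "b": b}) for a in axis_a for b in axis_b
    )
    return ga.best_fitness, float(grid_best), ga


# ---------------------------------------------------------------------------
# structural recovery on the default synthetic study


@dataclass
class StructuralResult:
    best_window: str
    window_ranking: list[tuple[str, float]]
    interaction_sign: float
    chilling_slope_ratio: float
    shrub_days_per_degc: float
    tree_days_per_degc: float
    shrub_p: float
    tree_p: float
    contrast_t: float
    contrast_p: float
    mismatch_days: float
    n_records: int
    dropped_domain: int = 0
    fits: dict = field(default_factory=dict)


def structural_recovery(seed: int = 1, delta_t: float = 2.0) -> StructuralResult:
    """Run the full chilling/forcing + response chain on the default study.

    The generating rule uses the (-5, 0) chilling window and a shrub:tree
    chilling-slope ratio of 3.2; the analysis should select that window by
    AIC, recover a positive chilling x life-form interaction under the
    shrub-reference coding, and produce opposite-sign onset responses to
    spring temperature for the two life forms.
    """
    bundle = make_study(seed=seed)
    ranking = select_chilling_window(bundle.phenology, bundle.climates,
                                     reference="shrub")
    best_window, _, best_lmm = ranking[0]
    table = build_cf_table(bundle.phenology, bundle.climates, window=best_window)
    df = cf_frame(table)
    in_domain = df["spring_t"] < 1.0
    dropped = int((~in_domain).sum())
    df = df[in_domain]

    fits = {
        form: fit_response(grp["onset_doy"], grp["spring_t"], life_form=form)
        for form, grp in df.groupby("life_form")
    }
    shrub_df = df[df.life_form == "shrub"]
    tree_df = df[df.life_form == "tree"]
    contrast = compare_slopes(
        shrub_df["onset_doy"], shrub_df["spring_t"],
        tree_df["onset_doy"], tree_df["spring_t"],
    )
    return StructuralResult(
        best_window=str(best_window),
        window_ranking=[(str(w), float(a)) for w, a, _ in ranking],
        interaction_sign=float(np.sign(best_lmm.coef("Chilling x life form"))),
        chilling_slope_ratio=float(slope_ratio(best_lmm)),
        shrub_days_per_degc=fits["shrub"].days_per_degc,
        tree_days_per_degc=fits["tree"].days_per_degc,
        shrub_p=fits["shrub"].p_value,
        tree_p=fits["tree"].p_value,
        contrast_t=contrast.t_statistic,
        contrast_p=contrast.p_value,
        mismatch_days=project_mismatch(fits["shrub"], fits["tree"], delta_t),
        n_records=int(len(df)),
        dropped_domain=dropped,
        fits=fits,
    )
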