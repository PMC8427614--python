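"""Synthetic-study generator and the recovery/calibration harnesses.

The generator emulates the structure of a montane mast-seeding trapping
study: five sites (two basin, three slope; one elongated open site with a
larger grid), 1-3 sessions per year between May and October, 2-5
consecutive trap nights per session, two landform-level seed-rain series
(beech and pooled conifers) with strong interannual masting variation, and
AR(1) night temperatures with intermittent precipitation.

Counts are drawn from the same hierarchy the analysis assumes:
``N_i ~ Poisson(A_i exp(x_i' beta + eps_i))`` and
``C_ij ~ Binomial(N_i, logistic(z_ij' alpha))``, so parameter-recovery
experiments probe the estimator, not model misspecification.

The default truth is loosely centred on the magnitudes a field study of
this design estimates, with a spillover structure: the open sites carry a
strongly negative site effect and a *steeper* beech-seed response than the
canopy sites, so their density deficit narrows after mast years.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .covariates import DesignMatrices, build_design, counts_for_taxon
from .effects import coefficient_table
from .likelihood import ModelData
from .sampler import McmcConfig, PosteriorDraws, SamplerError, fit
from .study_data import (
    TRAP_AREA_M2,
    NightRecord,
    Site,
    Study,
    TrapSession,
)

N_SEED_TRAPS = 81


@dataclass
class MastParams:
    """Interannual seed-crop model for one species.

    Log seed density is a two-component mixture: ordinary years are
    lognormal around ``base_median`` [seeds/m^2]; mast years (probability
    ``p_mast``) multiply the median by ``mast_factor``.  Landforms share a
    Gaussian copula with correlation ``rho_landform``; species propensities
    are correlated ``rho_species``.
    """

    base_median: float = 5.0
    sigma_base: float = 1.0
    mast_factor: float = 50.0
    sigma_mast: float = 0.7
    p_mast: float = 0.3

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = norm.cdf((np.log(x) - np.log(self.base_median)) / self.sigma_base)
        hi = norm.cdf(
            (np.log(x) - np.log(self.base_median * self.mast_factor)) / self.sigma_mast
        )
        return (1 - self.p_mast) * lo + self.p_mast * hi

    def quantile(self, u: float) -> float:
        lo = self.base_median * np.exp(self.sigma_base * norm.ppf(min(u, 1 - 1e-12)))
        hi = self.base_median * self.mast_factor * np.exp(
            self.sigma_mast * norm.ppf(min(u, 1 - 1e-12))
        )
        a = min(lo, hi) * 1e-6 + 1e-300
        b = max(lo, hi) * 1e6
        return brentq(lambda x: self.cdf(x) - u, a, b, xtol=1e-12, rtol=1e-10)


@dataclass
class WeatherParams:
    """Night temperature AR(1) and intermittent precipitation defaults."""

    temp_mean: float = 8.0
    temp_sd: float = 4.0
    temp_phi: float = 0.7
    precip_prob: float = 0.4
    precip_shape: float = 1.5
    precip_scale_mm: float = 6.0


@dataclass
class TrueParams:
    """Generating parameters, in named form (assembled per design columns).

    ``beta_site`` / ``beta_site_fagus`` are keyed by site id (reference site
    omitted).  Detection coefficients follow the design order: intercept,
    night-of-session, temperature, temperature^2, precipitation,
    temperature x precipitation.
    """

    beta0: float = 3.0
    beta_site: dict = field(
        default_factory=lambda: {"PFb": 0.09, "PFs": 0.14, "WTs": -0.93, "AVs": -2.85}
    )
    beta_fagus: float = 0.20
    beta_conifer: float = 0.27
    beta_julian: float = 0.09
    beta_julian2: float = -0.22
    beta_site_fagus: dict = field(
        default_factory=lambda: {"PFb": 0.0, "PFs": 0.05, "WTs": 0.55, "AVs": 0.73}
    )
    sigma_eps: float = 0.5
    alpha: tuple = (-1.08, 0.03, -0.09, -0.10, -0.06, 0.12)

    @property
    def tau(self) -> float:
        return self.sigma_eps**-2.0

    def beta_vector(self, x_names: list[str]) -> np.ndarray:
        """Coefficient vector aligned with the abundance design columns."""
        base = {
            "intercept": self.beta0,
            "fagus_seed": self.beta_fagus,
            "conifer_seed": self.beta_conifer,
            "julian": self.beta_julian,
            "julian_sq": self.beta_julian2,
        }
        out = []
        for name in x_names:
            if name in base:
                out.append(base[name])
            elif name.startswith("site[") and name.endswith("]:fagus_seed"):
                out.append(self.beta_site_fagus[name[5 : -len("]:fagus_seed")]])
            elif name.startswith("site[") and name.endswith("]"):
                out.append(self.beta_site[name[5:-1]])
            elif name == "open_sites:fagus_seed":
                vals = [v for v in self.beta_site_fagus.values() if v != 0.0]
                out.append(float(np.mean(vals)) if vals else 0.0)
            else:
                raise KeyError(f"no true value for design column {name!r}")
        return np.array(out)

    def alpha_vector(self, z_names: list[str]) -> np.ndarray:
        if len(z_names) != len(self.alpha):
            raise ValueError("detection design shape mismatch")
        return np.array(self.alpha, dtype=float)

    def named(self) -> dict:
        """Truth keyed by the sampler's parameter names."""
        out = {
            "lambda:intercept": self.beta0,
            "lambda:fagus_seed": self.beta_fagus,
            "lambda:conifer_seed": self.beta_conifer,
            "lambda:julian": self.beta_julian,
            "lambda:julian_sq": self.beta_julian2,
            "tau": self.tau,
            "sigma_eps": self.sigma_eps,
        }
        for s, v in self.beta_site.items():
            out[f"lambda:site[{s}]"] = v
        for s, v in self.beta_site_fagus.items():
            out[f"lambda:site[{s}]:fagus_seed"] = v
        for name, v in zip(
            ["intercept", "night_of_session", "temp", "temp_sq", "precip",
             "temp_x_precip"],
            self.alpha,
        ):
            out[f"p:{name}"] = v
        return out


def default_sites() -> list[Site]:
    """The five-grid layout: 25-station square grids plus one 44-station
    elongated open site, 15 m spacing throughout."""
    mk = lambda sid, lf, n: Site(  # noqa: E731
        site_id=sid,
        landform=lf,
        n_stations=n,
        station_spacing_m=15.0,
        area_ha=n * 15.0**2 / 1e4,
        first_year=2004,
        last_year=2019,
    )
    return [
        mk("PFb", "basin", 25),
        mk("MFb", "basin", 25),
        mk("PFs", "slope", 25),
        mk("WTs", "slope", 25),
        mk("AVs", "slope", 44),
    ]


@dataclass
class ScenarioConfig:
    """Study-design knobs of the generator."""

    first_year: int = 2004
    n_years: int = 16
    sites: list = field(default_factory=default_sites)
    sessions_per_year: tuple = (1, 3)
    nights_per_session: tuple = (2, 5)
    reference_site: str = "MFb"
    taxon: str = "myodes"
    fagus: MastParams = field(default_factory=MastParams)
    conifer: MastParams = field(
        default_factory=lambda: MastParams(base_median=2.5, mast_factor=50.0)
    )
    rho_landform: float = 0.9
    rho_species: float = 0.7
    weather: WeatherParams = field(default_factory=WeatherParams)
    seed_trap_dispersion: float = 0.7  # negative-binomial k of per-trap counts
    unmonitored_periods: tuple = ()  # masting periods without seed-trap data

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_years - 1


@dataclass
class TruthBundle:
    """Everything needed to score an estimate against the generator."""

    params: TrueParams
    beta: np.ndarray
    alpha: np.ndarray
    eps: np.ndarray
    latent_N: np.ndarray
    seed: int
    scenario: ScenarioConfig
    design: DesignMatrices

    def named(self) -> dict:
        return self.params.named()


def generate_seed_series(
    years: list[int] | np.ndarray,
    fagus: MastParams | None = None,
    conifer: MastParams | None = None,
    rho_landform: float = 0.9,
    rho_species: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-landform annual seed densities [seeds/m^2] for beech and conifers.

    Returns a frame with columns ``period, landform, fagus_per_m2,
    conifer_per_m2``.  The four margins (species x landform) follow the
    mixture of :class:`MastParams` coupled by a Gaussian copula whose
    correlation is the Kronecker product of the species and landform blocks.
    """
    fagus = fagus or MastParams()
    conifer = conifer or MastParams(base_median=2.5)
    years = list(years)
    if len(years) < 2:
        raise ValueError("need >= 2 years")
    r_sp = np.array([[1.0, rho_species], [rho_species, 1.0]])
    r_lf = np.array([[1.0, rho_landform], [rho_landform, 1.0]])
    corr = np.kron(r_sp, r_lf)  # order: (fagus,basin),(fagus,slope),(con,basin),(con,slope)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    rows = []
    for y in years:
        z = chol @ rng.standard_normal(4)
        u = norm.cdf(z)
        fb, fs = fagus.quantile(u[0]), fagus.quantile(u[1])
        cb, cs = conifer.quantile(u[2]), conifer.quantile(u[3])
        rows.append(dict(period=y, landform="basin", fagus_per_m2=fb, conifer_per_m2=cb))
        rows.append(dict(period=y, landform="slope", fagus_per_m2=fs, conifer_per_m2=cs))
    return pd.DataFrame(rows)


def _seed_trap_counts(
    series: pd.DataFrame, dispersion: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-trap annual seed totals whose stratum means match the series."""
    rows = []
    for r in series.itertuples():
        for species, dens in (("fagus", r.fagus_per_m2), ("conifer", r.conifer_per_m2)):
            mean_per_trap = dens * TRAP_AREA_M2
            if species == "conifer":
                # split pooled conifer density between spruce and fir
                split = rng.beta(4.0, 2.0)
                parts = {"picea": mean_per_trap * split,
                         "abies": mean_per_trap * (1 - split)}
            else:
                parts = {"fagus": mean_per_trap}
            for sp, m in parts.items():
                if m <= 0:
                    counts = np.zeros(N_SEED_TRAPS, dtype=int)
                else:
                    p = dispersion / (dispersion + m)
                    counts = rng.negative_binomial(dispersion, p, N_SEED_TRAPS)
                for t, c in enumerate(counts, start=1):
                    rows.append(
                        dict(landform=r.landform, trap_id=t, period=int(r.period),
                             species=sp, seeds=int(c))
                    )
    return pd.DataFrame(rows)


def _session_calendar(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> list[TrapSession]:
    """Sessions for every site-year: 1-3 per year, May-October, >= 35 d apart."""
    lo_s, hi_s = scenario.sessions_per_year
    lo_n, hi_n = scenario.nights_per_session
    sessions = []
    sid = 0
    for site in scenario.sites:
        y0 = max(scenario.first_year, site.first_year)
        y1 = min(scenario.last_year, site.last_year)
        for year in range(y0, y1 + 1):
            k = int(rng.integers(lo_s, hi_s + 1))
            # anchor days over mid-May..early October, jitter +-5 d; anchors
            # are spaced so jittered sessions stay >= 35 days apart
            anchors = [210.0] if k == 1 else np.linspace(140, 280, k)
            for a in anchors:
                day = int(a + rng.integers(-5, 6))
                start = dt.date(year, 1, 1) + dt.timedelta(days=day - 1)
                sid += 1
                sessions.append(
                    TrapSession(
                        session_id=sid,
                        site_id=site.site_id,
                        start_date=start,
                        n_nights=int(rng.integers(lo_n, hi_n + 1)),
                        counts={},
                    )
                )
    return sessions


def _night_weather(
    sessions: list[TrapSession], wp: WeatherParams, rng: np.random.Generator
) -> list[NightRecord]:
    records = []
    for s in sessions:
        t = wp.temp_mean + wp.temp_sd * rng.standard_normal()
        for j in range(1, s.n_nights + 1):
            if j > 1:
                innov = wp.temp_sd * np.sqrt(1 - wp.temp_phi**2)
                t = wp.temp_mean + wp.temp_phi * (t - wp.temp_mean) + innov * rng.standard_normal()
            wet = rng.random() < wp.precip_prob
            precip = float(rng.gamma(wp.precip_shape, wp.precip_scale_mm)) if wet else 0.0
            records.append(
                NightRecord(
                    session_id=s.session_id,
                    night=j,
                    mean_night_temp_c=float(t),
                    precip_prev_day_mm=precip,
                )
            )
    return records


def generate_study(
    scenario: ScenarioConfig | None = None,
    truth: TrueParams | None = None,
    seed: int = 0,
    interaction_sites: list[str] | None = None,
) -> tuple[Study, TruthBundle]:
    """Generate a complete synthetic study plus the truth that produced it.

    Regeneration from the same (scenario, truth, seed) is bit-identical.
    """
    scenario = scenario or ScenarioConfig()
    truth = truth or TrueParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    periods = [
        y
        for y in range(scenario.first_year - 1, scenario.last_year)
        if y not in scenario.unmonitored_periods
    ]
    series = generate_seed_series(
        periods,
        scenario.fagus,
        scenario.conifer,
        scenario.rho_landform,
        scenario.rho_species,
        seed=int(rng.integers(2**31)),
    )
    seed_counts = _seed_trap_counts(
        series, scenario.seed_trap_dispersion, rng
    )
    sessions = _session_calendar(scenario, rng)
    nights = _night_weather(sessions, scenario.weather, rng)

    sites = {s.site_id: s for s in scenario.sites}
    # design needs a study; counts are filled in afterwards
    proto = Study(
        sites=sites, sessions=sessions, night_records=nights, seed_counts=seed_counts
    )
    design = build_design(
        proto, scenario.reference_site, interaction_sites=interaction_sites
    )

    beta = truth.beta_vector(design.x_names)
    alpha = truth.alpha_vector(design.z_names)
    n = design.n_sessions
    eps = truth.sigma_eps * rng.standard_normal(n)
    mu = np.exp(design.offset_log_area + design.X @ beta + eps)
    N = rng.poisson(mu)
    p = expit(design.Z @ alpha)
    C = rng.binomial(N[design.night_session], p)

    by_id = {s.session_id: s for s in sessions}
    for row, sess_id in enumerate(design.session_ids):
        mask = design.night_session == row
        by_id[int(sess_id)].counts = {scenario.taxon: C[mask].astype(int)}
    # sessions excluded from the design (no seed data) still need counts
    for s in sessions:
        if scenario.taxon not in s.counts:
            s.counts = {scenario.taxon: np.zeros(s.n_nights, dtype=int)}
    study = Study(
        sites=sites, sessions=sessions, night_records=nights, seed_counts=seed_counts
    )
    bundle = TruthBundle(
        params=truth,
        beta=beta,
        alpha=alpha,
        eps=eps,
        latent_N=N,
        seed=seed,
        scenario=scenario,
        design=design,
    )
    return study, bundle


def model_data_for(study: Study, bundle: TruthBundle) -> ModelData:
    """Flat model data for the generated taxon, aligned with the truth design."""
    counts = counts_for_taxon(study, bundle.design, bundle.scenario.taxon)
    data = ModelData.from_design(bundle.design, counts)
    return data


# ---------------------------------------------------------------------------
# recovery and calibration harnesses


@dataclass
class RecoveryReplicate:
    """One generate-fit-score cycle."""

    seed: int
    truth: dict
    table: pd.DataFrame | None
    draws: PosteriorDraws | None
    data: ModelData | None
    error: str | None = None


@dataclass
class RecoveryReport:
    """Aggregate of a parameter-recovery experiment."""

    replicates: list[RecoveryReplicate]
    params_of_interest: tuple

    def ok(self) -> list[RecoveryReplicate]:
        return [r for r in self.replicates if r.error is None]

    def coverage(self, name: str) -> float:
        """Share of replicates whose central 95% interval covers the truth."""
        hits = []
        for r in self.ok():
            row = r.table[r.table.parameter == name].iloc[0]
            hits.append(row.q2_5 <= r.truth[name] <= row.q97_5)
        return float(np.mean(hits))

    def truth_vs_estimate(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        t, e = [], []
        for r in self.ok():
            row = r.table[r.table.parameter == name].iloc[0]
            t.append(r.truth[name])
            e.append(row["mean"])
        return np.array(t), np.array(e)

    def correlation(self, name: str) -> float:
        t, e = self.truth_vs_estimate(name)
        return float(np.corrcoef(t, e)[0, 1])

    def rmse(self, name: str) -> float:
        t, e = self.truth_vs_estimate(name)
        return float(np.sqrt(np.mean((e - t) ** 2)))

    def excludes_zero_rate(self, name: str) -> float:
        flags = []
        for r in self.ok():
            row = r.table[r.table.parameter == name].iloc[0]
            flags.append(bool(row.excludes_zero))
        return float(np.mean(flags))

    def summary(self) -> dict:
        out = {"n_replicates": len(self.replicates), "n_failed": len(self.replicates) - len(self.ok())}
        for name in self.params_of_interest:
            out[name] = {
                "coverage95": self.coverage(name),
                "correlation": self.correlation(name),
                "rmse": self.rmse(name),
            }
        return out


def sample_truth(rng: np.random.Generator, base: TrueParams | None = None) -> TrueParams:
    """Truth for one recovery replicate: key effects drawn around the defaults."""
    base = base or TrueParams()
    new = dataclasses.replace(
        base,
        beta_fagus=float(rng.normal(0.5, 0.35)),
        beta_conifer=float(rng.normal(0.3, 0.2)),
    )
    a = list(base.alpha)
    a[0] = float(rng.normal(-1.0, 0.3))
    new.alpha = tuple(a)
    return new


def recovery_experiment(
    n_replicates: int = 20,
    scenario: ScenarioConfig | None = None,
    fit_config: McmcConfig | None = None,
    seed: int = 0,
    vary_truth: bool = True,
    base_truth: TrueParams | None = None,
    params_of_interest: tuple = (
        "lambda:fagus_seed",
        "lambda:conifer_seed",
        "p:intercept",
    ),
) -> RecoveryReport:
    """Generate -> fit -> score, ``n_replicates`` times.

    Each replicate draws its own truth (unless ``vary_truth`` is off), its
    own synthetic study and its own chains.  Sampler failures are recorded
    per replicate, never fatal.
    """
    scenario = scenario or ScenarioConfig(n_years=12)
    fit_config = fit_config or desk_mcmc_config()
    root = np.random.SeedSequence(seed)
    reps: list[RecoveryReplicate] = []
    for i, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        truth = (
            sample_truth(rng, base_truth) if vary_truth else (base_truth or TrueParams())
        )
        rep_seed = int(rng.integers(2**31))
        study, bundle = generate_study(scenario, truth, seed=rep_seed)
        data = model_data_for(study, bundle)
        cfg = dataclasses.replace(fit_config, seed=int(rng.integers(2**31)))
        try:
            draws = fit(
                data,
                cfg,
                meta={
                    "standardization": {
                        k: {"center": c, "scale": s}
                        for k, (c, s) in bundle.design.standardization.items()
                    },
                    "reference_site": bundle.design.reference_site,
                },
            )
            reps.append(
                RecoveryReplicate(
                    seed=rep_seed,
                    truth=truth.named(),
                    table=coefficient_table(draws),
                    draws=draws,
                    data=data,
                )
            )
        except SamplerError as exc:  # recorded, not fatal
            reps.append(
                RecoveryReplicate(
                    seed=rep_seed, truth=truth.named(), table=None, draws=None,
                    data=None, error=str(exc)
                )
            )
    return RecoveryReport(replicates=reps, params_of_interest=params_of_interest)


def desk_mcmc_config(seed: int = 0) -> McmcConfig:
    """Scaled-down protocol for desk-scale experiments: 3 x 20,000 / 4,000 / 10."""
    return McmcConfig(n_chains=3, n_iter=20_000, n_burn_adapt=4_000, thin=10, seed=seed)


def spillover_experiment(
    seed: int = 0,
    scenario: ScenarioConfig | None = None,
    fit_config: McmcConfig | None = None,
    truth: TrueParams | None = None,
    n_grid: int = 25,
):
    """Fit one study generated under the default (spillover) truth and return
    per-site marginal-effect curves of beech seed rain.

    Under the spillover structure the open site sits far below the canopy
    sites at low seed rain and its steeper seed response closes the gap as
    seed rain grows.
    """
    from .effects import default_seed_grid, marginal_effect

    scenario = scenario or ScenarioConfig(n_years=12)
    truth = truth or TrueParams()
    root = np.random.SeedSequence(seed)
    s1, s2 = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2)]
    study, bundle = generate_study(scenario, truth, seed=s1)
    data = model_data_for(study, bundle)
    cfg = dataclasses.replace(fit_config or desk_mcmc_config(), seed=s2)
    std = {
        k: {"center": c, "scale": s}
        for k, (c, s) in bundle.design.standardization.items()
    }
    draws = fit(
        data, cfg,
        meta={"standardization": std,
              "reference_site": bundle.design.reference_site},
    )
    grid = default_seed_grid(std, n_grid)
    sites = [s.site_id for s in scenario.sites]
    curves = {site: marginal_effect(draws, site, grid) for site in sites}
    return curves, draws, bundle


def gof_calibration(
    report: RecoveryReport,
    n_total: int = 50,
    seed: int = 0,
    max_draws: int = 800,
) -> pd.DataFrame:
    """Self-calibration of the posterior-predictive check under the true model.

    Every recovery fit was run on data generated from the model itself, so
    the check applied to a fit's own data must not signal misfit: Bayesian
    p-values stay away from 0 and 1 and c-hat sits near 1.  Each of
    ``n_total`` calibration replicates cycles over the fits with a fresh
    seed for the binomial replication stream (the stochastic half of the
    check), so both the across-dataset and the across-replication
    variability of the p-value are exercised.

    Checking the posterior against a *new* posterior-predictive dataset
    without refitting is deliberately not done here: the retained latent
    abundances are conditioned on the original counts, so such a comparison
    inflates the observed discrepancy and reads as spurious misfit.
    """
    from .gof import posterior_predictive_gof

    ok = report.ok()
    if not ok:
        raise ValueError("no successful fits to calibrate against")
    root = np.random.SeedSequence(seed)
    rows = []
    for k, ss in enumerate(root.spawn(n_total)):
        rep = ok[k % len(ok)]
        rng = np.random.default_rng(ss)
        res = posterior_predictive_gof(
            rep.draws, rep.data, seed=int(rng.integers(2**31)),
            max_draws=max_draws,
        )
        rows.append(dict(replicate=k, bayes_p=res.bayes_p, c_hat=res.c_hat))
    return pd.DataFrame(rows)
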