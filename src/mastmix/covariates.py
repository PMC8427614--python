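"""Covariate construction: seed rain densities, weather windows, design matrices.

The abundance submodel uses, per session: site (factor, configurable
reference level), standardized log beech seed rain, standardized log pooled
conifer seed rain, standardized Julian day and its square, a site x beech
seed rain interaction, and a log-area offset.  The detection submodel uses,
per trap night: night-of-session, standardized mean night temperature and
its square, standardized previous-day precipitation, and the
temperature x precipitation interaction.

Seed rain is measured at one monitoring plot per landform; sessions on
unmonitored sites inherit the series of their landform.  A session in
calendar year ``y`` is matched to the masting period labelled ``y - 1``
(seed fall in autumn ``y - 1`` through the following spring feeds the rodent
population trapped in year ``y``).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_data import TRAP_AREA_M2, Study, StudyError


class MissingDataError(StudyError):
    """Required seed-trap or weather records are absent (not zero)."""


#: backwards-compatible alias
MissingSeedDataError = MissingDataError


class CovariateError(StudyError):
    """Covariate construction failed (zero variance, bad reference site...)."""


def grid_area(n_stations: int, spacing_m: float) -> float:
    """Sampled area [ha] of a trapping grid: one spacing x spacing cell per station.

    >>> grid_area(25, 15.0)
    0.5625
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    if spacing_m <= 0:
        raise ValueError("spacing must be > 0")
    return n_stations * spacing_m**2 / 10_000.0


def seed_density(
    seed_counts: pd.DataFrame,
    landform: str,
    period: int,
    trap_area_m2: float = TRAP_AREA_M2,
) -> tuple[float, float]:
    """Mean seed density [seeds/m^2] for beech and pooled conifers.

    Per trap, the annual total is scaled by the trap basal area; conifers are
    pooled *per trap* (spruce + fir) before scaling.  The mean is then taken
    over all traps of the stratum.
    """
    if trap_area_m2 <= 0:
        raise ValueError("trap_area_m2 must be > 0")
    sub = seed_counts[
        (seed_counts["landform"] == landform) & (seed_counts["period"] == period)
    ]
    if not len(sub):
        raise MissingDataError(f"no seed traps for ({landform!r}, period {period})")
    per_trap = sub.pivot_table(
        index="trap_id", columns="species", values="seeds", aggfunc="sum", fill_value=0
    )
    fagus = per_trap.get("fagus", pd.Series(0, index=per_trap.index))
    conifer = per_trap.get("picea", pd.Series(0, index=per_trap.index)) + per_trap.get(
        "abies", pd.Series(0, index=per_trap.index)
    )
    return (
        float(fagus.mean()) / trap_area_m2,
        float(conifer.mean()) / trap_area_m2,
    )


def log_transform(density_per_m2):
    """log(1 + density): totality at zero-seed failure years, 0 -> 0."""
    x = np.asarray(density_per_m2, dtype=float)
    if (x < 0).any():
        raise ValueError("seed density must be >= 0")
    out = np.log1p(x)
    return float(out) if np.isscalar(density_per_m2) else out


def back_transform_seed(log_density):
    """Inverse of :func:`log_transform`, for effect-curve axes."""
    return np.expm1(log_density)


def assign_mast_period(session_date: dt.date) -> int:
    """Masting period feeding a session: the seed year before the trapping year.

    Seed fall of autumn ``y`` through spring ``y + 1`` is labelled period
    ``y``; a session trapped in calendar year ``y`` is driven by period
    ``y - 1``.
    """
    return session_date.year - 1


@dataclass(frozen=True)
class SeedRainRecord:
    """Per-landform, per-period seed rain: raw and log-transformed densities."""

    landform: str
    period: int
    fagus_per_m2: float
    conifer_per_m2: float

    @property
    def fagus_log(self) -> float:
        return log_transform(self.fagus_per_m2)

    @property
    def conifer_log(self) -> float:
        return log_transform(self.conifer_per_m2)


def seed_rain_table(seed_counts: pd.DataFrame) -> list[SeedRainRecord]:
    """All (landform, period) strata present in the seed-trap table."""
    out = []
    for (lf, per), _ in seed_counts.groupby(["landform", "period"]):
        f, c = seed_density(seed_counts, lf, per)
        out.append(SeedRainRecord(lf, int(per), f, c))
    return out


def night_covariates(
    hourly_temps: pd.Series,
    daily_precip: pd.Series,
    trap_night_date: dt.date,
) -> tuple[float, float]:
    """Weather covariates for the trap night checked on ``trap_night_date``.

    ``hourly_temps`` is indexed by timestamp; the temperature covariate is
    the mean over the 12 clock hours 19:00 (previous evening) through 06:00
    (check morning), endpoints included.  ``daily_precip`` is indexed by
    date; the precipitation covariate is the total of the previous calendar
    day.
    """
    start = pd.Timestamp(trap_night_date) - pd.Timedelta(hours=5)  # 19:00 prev day
    end = pd.Timestamp(trap_night_date) + pd.Timedelta(hours=6)  # 06:00
    window = hourly_temps.loc[start:end]
    if len(window) < 12 or window.isna().any():
        raise MissingDataError(
            f"hourly temperature window incomplete for night of {trap_night_date}"
        )
    prev = pd.Timestamp(trap_night_date) - pd.Timedelta(days=1)
    try:
        precip = daily_precip.loc[prev]
    except KeyError as exc:
        raise MissingDataError(
            f"no precipitation for previous day {prev.date()}"
        ) from exc
    if pd.isna(precip):
        raise MissingDataError(f"precipitation missing for {prev.date()}")
    return float(window.mean()), float(precip)


def standardize(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Center and scale to sample SD 1; returns (z, (center, scale)).

    The transform parameters are kept so effect axes can be back-transformed
    to the original units.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise CovariateError("standardize needs >= 2 values")
    center = float(x.mean())
    scale = float(x.std(ddof=1))
    if scale == 0.0:
        raise CovariateError("zero variance: cannot standardize a constant covariate")
    return (x - center) / scale, (center, scale)


ABUND_BASE = ["fagus_seed", "conifer_seed", "julian", "julian_sq"]
DET_COLS = ["intercept", "night_of_session", "temp", "temp_sq", "precip", "temp_x_precip"]


@dataclass
class DesignMatrices:
    """Fixed-effect design for one study, shared by all taxa.

    ``X`` (sessions x p) is the abundance design; ``Z`` (nights x q) the
    detection design; ``night_session`` maps each row of ``Z`` to its row in
    ``X``.  ``standardization`` holds (center, scale) pairs keyed by
    covariate name, needed to back-transform marginal-effect axes.
    """

    session_ids: np.ndarray
    site_ids: np.ndarray
    X: np.ndarray
    x_names: list[str]
    offset_log_area: np.ndarray
    Z: np.ndarray
    z_names: list[str]
    night_session: np.ndarray
    night_index: np.ndarray
    standardization: dict[str, tuple[float, float]]
    reference_site: str
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)

    @property
    def n_nights_total(self) -> int:
        return len(self.night_session)

    def column(self, name: str) -> int:
        return self.x_names.index(name)

    def report(self) -> dict:
        """Covariate build report: inclusion status and transform constants."""
        return {
            "n_sessions_kept": int(self.n_sessions),
            "n_sessions_excluded": len(self.excluded),
            "excluded": [
                {"session_id": int(i), "reason": r} for i, r in self.excluded
            ],
            "reference_site": self.reference_site,
            "standardization": {
                k: {"center": c, "scale": s}
                for k, (c, s) in self.standardization.items()
            },
            "x_columns": self.x_names,
            "z_columns": self.z_names,
        }


def counts_for_taxon(study: Study, design: DesignMatrices, taxon: str) -> np.ndarray:
    """Flat nightly count vector aligned with the detection design rows."""
    by_id = {s.session_id: s for s in study.sessions}
    out = np.empty(design.n_nights_total, dtype=int)
    for k, (srow, j) in enumerate(zip(design.night_session, design.night_index)):
        sess = by_id[int(design.session_ids[srow])]
        if taxon not in sess.counts:
            raise CovariateError(
                f"taxon {taxon!r} missing from session {sess.session_id}"
            )
        out[k] = sess.counts[taxon][j - 1]
    return out


def build_design(
    study: Study,
    reference_site: str,
    interaction_sites: list[str] | None = None,
) -> DesignMatrices:
    """Assemble abundance and detection design matrices for a study.

    Site enters as a factor with ``reference_site`` as the omitted level.
    The site x beech-seed interaction uses one column per non-reference site
    by default; passing ``interaction_sites`` collapses it to a single
    pooled indicator (e.g. only the open, medium-scale-disturbance sites).

    Sessions whose landform/period stratum has no seed-trap data are
    excluded and listed in ``excluded`` — never dropped silently.
    """
    if reference_site not in study.sites:
        raise CovariateError(f"reference site {reference_site!r} unknown")
    if interaction_sites is not None:
        unknown = set(interaction_sites) - set(study.sites)
        if unknown:
            raise CovariateError(f"interaction sites unknown: {sorted(unknown)}")

    seed = {(r.landform, r.period): r for r in seed_rain_table(study.seed_counts)}
    nights_by_sess: dict[int, dict[int, object]] = {}
    for r in study.night_records:
        nights_by_sess.setdefault(r.session_id, {})[r.night] = r

    kept: list = []
    excluded: list[tuple[int, str]] = []
    for s in sorted(study.sessions, key=lambda s: s.session_id):
        lf = study.sites[s.site_id].landform
        period = assign_mast_period(s.mid_date)
        if (lf, period) not in seed:
            excluded.append((s.session_id, f"no seed rain for ({lf}, {period})"))
            continue
        recs = nights_by_sess.get(s.session_id, {})
        if set(recs) != set(range(1, s.n_nights + 1)):
            excluded.append((s.session_id, "incomplete night weather records"))
            continue
        kept.append((s, seed[(lf, period)], recs))
    if not kept:
        raise CovariateError("no sessions left after exclusions")

    sessions = [k[0] for k in kept]
    session_ids = np.array([s.session_id for s in sessions])
    site_ids = np.array([s.site_id for s in sessions])
    offset = np.log([study.sites[s.site_id].area_ha for s in sessions])

    fagus_log = np.array([rec.fagus_log for _, rec, _ in kept])
    conifer_log = np.array([rec.conifer_log for _, rec, _ in kept])
    julian = np.array([s.julian for s in sessions])

    std: dict[str, tuple[float, float]] = {}
    fagus_z, std["fagus_seed"] = standardize(fagus_log)
    conifer_z, std["conifer_seed"] = standardize(conifer_log)
    julian_z, std["julian"] = standardize(julian)

    site_levels = [x for x in sorted(study.sites) if x != reference_site]
    cols = [np.ones(len(sessions))]
    names = ["intercept"]
    for lev in site_levels:
        cols.append((site_ids == lev).astype(float))
        names.append(f"site[{lev}]")
    cols += [fagus_z, conifer_z, julian_z, julian_z**2]
    names += ABUND_BASE
    if interaction_sites is None:
        for lev in site_levels:
            cols.append((site_ids == lev).astype(float) * fagus_z)
            names.append(f"site[{lev}]:fagus_seed")
    else:
        ind = np.isin(site_ids, interaction_sites).astype(float)
        cols.append(ind * fagus_z)
        names.append("open_sites:fagus_seed")
    X = np.column_stack(cols)

    # detection design: flat over nights
    night_session = []
    night_index = []
    temps = []
    precips = []
    for row, (s, _, recs) in enumerate(kept):
        for j in range(1, s.n_nights + 1):
            night_session.append(row)
            night_index.append(j)
            temps.append(recs[j].mean_night_temp_c)
            precips.append(recs[j].precip_prev_day_mm)
    night_session = np.array(night_session, dtype=int)
    night_index = np.array(night_index, dtype=int)
    temp_z, std["temp"] = standardize(np.array(temps))
    precip_z, std["precip"] = standardize(np.array(precips, dtype=float))
    night_z, std["night_of_session"] = standardize(night_index.astype(float))
    Z = np.column_stack(
        [
            np.ones(len(night_session)),
            night_z,
            temp_z,
            temp_z**2,
            precip_z,
            temp_z * precip_z,
        ]
    )

    return DesignMatrices(
        session_ids=session_ids,
        site_ids=site_ids,
        X=X,
        x_names=names,
        offset_log_area=offset,
        Z=Z,
        z_names=list(DET_COLS),
        night_session=night_session,
        night_index=night_index,
        standardization=std,
        reference_site=reference_site,
        excluded=excluded,
    )
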