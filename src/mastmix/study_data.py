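"""Canonical data model for a mast-seeding small-mammal trapping study.

A *study* bundles four tables that the downstream analysis consumes:

* sites — trapping grids with a landform stratum (``basin``/``slope``), a
  station count and spacing, and a sampled area in hectares (the offset of
  the abundance model);
* trapping sessions — primary periods of 2–5 consecutive trap nights at one
  site, with a per-taxon vector of nightly capture counts;
* night records — per trap night weather covariates (mean temperature of the
  preceding night, precipitation sum of the previous day);
* seed-trap counts — per-trap annual seed totals per tree species, collected
  at one monitoring plot per landform.

Everything is plain CSV/YAML on disk (see :func:`read_study` /
:func:`write_study`) and dataclasses + a pandas frame in memory.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

LANDFORMS = ("basin", "slope")
SEED_SPECIES = ("fagus", "picea", "abies")

#: trap basal area of one seed trap [m^2]
TRAP_AREA_M2 = 0.24

#: minimum spacing between primary periods at one site [days]
MIN_SESSION_LAG_DAYS = 35

#: live traps per station (two traps of different manufacturers)
TRAPS_PER_STATION = 2


class StudyError(Exception):
    """Base class for study data problems."""


class SchemaError(StudyError):
    """A file does not conform to the canonical schema."""


class IntegrityError(StudyError):
    """A record references an unknown site or session."""


class ValidationError(StudyError):
    """A record violates a hard invariant (e.g. negative count)."""


class StudyWarning(UserWarning):
    """Soft invariant violation (session spacing, trap saturation)."""


@dataclass(frozen=True)
class Site:
    """One trapping grid.

    ``area_ha`` is the sampled area entering the abundance model as an
    offset, so that latent abundance is expressed as density per hectare.
    """

    site_id: str
    landform: str
    n_stations: int
    station_spacing_m: float
    area_ha: float
    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.landform not in LANDFORMS:
            raise ValidationError(
                f"site {self.site_id!r}: landform must be one of {LANDFORMS}, "
                f"got {self.landform!r}"
            )
        if self.n_stations < 1:
            raise ValidationError(f"site {self.site_id!r}: n_stations must be >= 1")
        if self.area_ha <= 0:
            raise ValidationError(f"site {self.site_id!r}: area_ha must be > 0")


@dataclass
class TrapSession:
    """One primary period: consecutive trap nights at one site.

    ``counts`` maps taxon label to the vector of nightly capture totals
    ``C_ij`` (length ``n_nights``).
    """

    session_id: int
    site_id: str
    start_date: dt.date
    n_nights: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nights < 1:
            raise ValidationError(f"session {self.session_id}: n_nights must be >= 1")
        clean = {}
        for taxon, c in self.counts.items():
            arr = np.asarray(c, dtype=int)
            if arr.shape != (self.n_nights,):
                raise ValidationError(
                    f"session {self.session_id}, taxon {taxon!r}: count vector "
                    f"length {arr.shape} != n_nights {self.n_nights}"
                )
            if (arr < 0).any():
                raise ValidationError(
                    f"session {self.session_id}, taxon {taxon!r}: negative count"
                )
            clean[taxon] = arr
        self.counts = clean

    @property
    def mid_date(self) -> dt.date:
        """Midpoint date of the session (anchors the Julian-day covariate)."""
        return self.start_date + dt.timedelta(days=(self.n_nights - 1) // 2)

    @property
    def julian(self) -> float:
        """Day of year of the session midpoint (fractional for even nights)."""
        base = self.start_date.timetuple().tm_yday
        return base + (self.n_nights - 1) / 2.0

    @property
    def year(self) -> int:
        return self.start_date.year


@dataclass(frozen=True)
class NightRecord:
    """Weather covariates for one trap night of one session."""

    session_id: int
    night: int  # 1-based night-of-session index j
    mean_night_temp_c: float
    precip_prev_day_mm: float

    def __post_init__(self) -> None:
        if self.night < 1:
            raise ValidationError(
                f"session {self.session_id}: night index must be 1-based positive"
            )


@dataclass
class Study:
    """A fully cross-linked study: sites, sessions, night records, seeds.

    ``seed_counts`` is a long frame with columns
    ``landform, trap_id, period, species, seeds`` — one row per seed trap,
    masting period and tree species, holding the annual seed total.
    """

    sites: dict[str, Site]
    sessions: list[TrapSession]
    night_records: list[NightRecord]
    seed_counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def taxa(self) -> list[str]:
        out: list[str] = []
        for s in self.sessions:
            for t in s.counts:
                if t not in out:
                    out.append(t)
        return out

    def session(self, session_id: int) -> TrapSession:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)

    def validate(self) -> None:
        """Check hard invariants (raise) and soft ones (warn)."""
        seen_ids: set[int] = set()
        for s in self.sessions:
            if s.session_id in seen_ids:
                raise IntegrityError(f"duplicate session_id {s.session_id}")
            seen_ids.add(s.session_id)
            if s.site_id not in self.sites:
                raise IntegrityError(
                    f"session {s.session_id} references unknown site {s.site_id!r}"
                )
            site = self.sites[s.site_id]
            cap = site.n_stations * TRAPS_PER_STATION
            for taxon, c in s.counts.items():
                if (c > cap).any():
                    warnings.warn(
                        f"session {s.session_id}, taxon {taxon!r}: nightly count "
                        f"exceeds physical trap capacity {cap} at {s.site_id}",
                        StudyWarning,
                        stacklevel=2,
                    )
        by_sess: dict[int, set[int]] = {}
        for r in self.night_records:
            if r.session_id not in seen_ids:
                raise IntegrityError(
                    f"night record references unknown session {r.session_id}"
                )
            nights = by_sess.setdefault(r.session_id, set())
            if r.night in nights:
                raise IntegrityError(
                    f"duplicate night record (session {r.session_id}, night {r.night})"
                )
            nights.add(r.night)
            if r.night > self.session(r.session_id).n_nights:
                raise IntegrityError(
                    f"night record night {r.night} exceeds n_nights of session "
                    f"{r.session_id}"
                )
        # session spacing: soft constraint from the demographic-openness design
        by_site: dict[str, list[TrapSession]] = {}
        for s in self.sessions:
            by_site.setdefault(s.site_id, []).append(s)
        for site_id, group in by_site.items():
            group = sorted(group, key=lambda s: s.start_date)
            for a, b in zip(group, group[1:]):
                gap = (b.start_date - (a.start_date + dt.timedelta(days=a.n_nights))).days
                if gap < MIN_SESSION_LAG_DAYS - a.n_nights:
                    lag = (b.start_date - a.start_date).days
                    if lag < MIN_SESSION_LAG_DAYS:
                        warnings.warn(
                            f"sessions {a.session_id} and {b.session_id} at "
                            f"{site_id} are {lag} days apart (< "
                            f"{MIN_SESSION_LAG_DAYS})",
                            StudyWarning,
                            stacklevel=2,
                        )
        if len(self.seed_counts):
            _check_seed_frame(self.seed_counts)


SEED_COLUMNS = ["landform", "trap_id", "period", "species", "seeds"]
CAPTURE_COLUMNS = ["session_id", "site_id", "start_date", "taxon", "night", "count"]
NIGHT_COLUMNS = ["session_id", "night", "mean_night_temp_c", "precip_prev_day_mm"]


def _check_seed_frame(df: pd.DataFrame) -> None:
    missing = [c for c in SEED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"seed table missing columns {missing}")
    if (df["seeds"] < 0).any():
        bad = df.index[df["seeds"] < 0][0]
        raise ValidationError(f"seed table row {bad}: negative seed count")
    bad_lf = set(df["landform"]) - set(LANDFORMS)
    if bad_lf:
        raise ValidationError(f"seed table: unknown landform(s) {sorted(bad_lf)}")


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def load_sites(sites_config: str | Path | dict) -> dict[str, Site]:
    """Load the per-site configuration from a YAML file or an in-memory dict.

    ``area_ha`` may be omitted, in which case it is derived from the station
    grid (one spacing x spacing cell per station).
    """
    from .covariates import grid_area

    if isinstance(sites_config, (str, Path)):
        with open(sites_config) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = sites_config
    entries = raw["sites"] if isinstance(raw, dict) and "sites" in raw else raw
    sites: dict[str, Site] = {}
    for entry in entries:
        entry = dict(entry)
        sid = entry.pop("id", None) or entry.pop("site_id", None)
        if sid is None:
            raise SchemaError("sites config entry without an 'id'")
        area = entry.get("area_ha")
        if area is None:
            area = grid_area(entry["n_stations"], entry["station_spacing_m"])
        sites[sid] = Site(
            site_id=sid,
            landform=entry["landform"],
            n_stations=int(entry["n_stations"]),
            station_spacing_m=float(entry["station_spacing_m"]),
            area_ha=float(area),
            first_year=int(entry.get("first_year", 0)),
            last_year=int(entry.get("last_year", 9999)),
        )
    return sites


def read_study(
    captures_path: str | Path,
    nights_path: str | Path,
    seeds_path: str | Path,
    sites_config: str | Path | dict,
) -> Study:
    """Read and cross-validate the canonical CSV set into a :class:`Study`.

    Raises :class:`SchemaError` for malformed files, :class:`IntegrityError`
    for dangling references and :class:`ValidationError` for invariant
    violations (negative counts etc.).
    """
    sites = load_sites(sites_config)

    cap = pd.read_csv(captures_path)
    _require_columns(cap, CAPTURE_COLUMNS, captures_path)
    if len(cap) and (cap["count"] < 0).any():
        row = cap.index[cap["count"] < 0][0]
        raise ValidationError(f"{captures_path}: negative count at row {row}")

    sessions: list[TrapSession] = []
    if len(cap):
        for (sid, site_id, start), grp in cap.groupby(
            ["session_id", "site_id", "start_date"], sort=True
        ):
            nights = int(grp["night"].max())
            expected = set(range(1, nights + 1))
            counts: dict[str, np.ndarray] = {}
            for taxon, tgrp in grp.groupby("taxon"):
                got = set(tgrp["night"].astype(int))
                if got != expected:
                    raise SchemaError(
                        f"{captures_path}: session {sid} taxon {taxon!r} has "
                        f"nights {sorted(got)}, expected 1..{nights}"
                    )
                vec = tgrp.sort_values("night")["count"].to_numpy(dtype=int)
                counts[taxon] = vec
            sessions.append(
                TrapSession(
                    session_id=int(sid),
                    site_id=str(site_id),
                    start_date=dt.date.fromisoformat(str(start)),
                    n_nights=nights,
                    counts=counts,
                )
            )

    ndf = pd.read_csv(nights_path, float_precision="round_trip")
    _require_columns(ndf, NIGHT_COLUMNS, nights_path)
    night_records = [
        NightRecord(
            session_id=int(r.session_id),
            night=int(r.night),
            mean_night_temp_c=float(r.mean_night_temp_c),
            precip_prev_day_mm=float(r.precip_prev_day_mm),
        )
        for r in ndf.itertuples()
    ]

    sdf = pd.read_csv(seeds_path)
    _require_columns(sdf, SEED_COLUMNS, seeds_path)
    sdf = sdf[SEED_COLUMNS].copy()

    return Study(
        sites=sites, sessions=sessions, night_records=night_records, seed_counts=sdf
    )


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as the canonical CSV/YAML file set; lossless round-trip.

    Returns a mapping of logical names to the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cap_rows = []
    for s in study.sessions:
        for taxon, vec in s.counts.items():
            for j, c in enumerate(vec, start=1):
                cap_rows.append(
                    dict(
                        session_id=s.session_id,
                        site_id=s.site_id,
                        start_date=s.start_date.isoformat(),
                        taxon=taxon,
                        night=j,
                        count=int(c),
                    )
                )
    cap_path = out / "captures.csv"
    pd.DataFrame(cap_rows, columns=CAPTURE_COLUMNS).to_csv(cap_path, index=False)

    night_rows = [dataclasses.asdict(r) for r in study.night_records]
    nights_path = out / "nights.csv"
    pd.DataFrame(night_rows, columns=NIGHT_COLUMNS).to_csv(
        nights_path, index=False, float_format="%.17g"
    )

    seeds_path = out / "seeds.csv"
    study.seed_counts.to_csv(seeds_path, index=False)

    sites_path = out / "sites.yaml"
    payload = {
        "sites": [
            dict(
                id=s.site_id,
                landform=s.landform,
                n_stations=s.n_stations,
                station_spacing_m=s.station_spacing_m,
                area_ha=s.area_ha,
                first_year=s.first_year,
                last_year=s.last_year,
            )
            for s in study.sites.values()
        ]
    }
    with open(sites_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)

    return {
        "captures": cap_path,
        "nights": nights_path,
        "seeds": seeds_path,
        "sites": sites_path,
    }


def read_study_dir(path: str | Path) -> Study:
    """Read a study from a directory written by :func:`write_study`."""
    p = Path(path)
    return read_study(
        p / "captures.csv", p / "nights.csv", p / "seeds.csv", p / "sites.yaml"
    )
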