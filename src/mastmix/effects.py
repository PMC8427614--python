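"""Posterior summaries: coefficient tables, marginal effects, density predictions.

Mirrors the standard reporting of a fitted N-mixture analysis: a table of
posterior means/SDs/credible intervals per coefficient, marginal-effect
curves of density against back-transformed beech seed rain per site (other
covariates at their means, random effect at its median 0), and per-session
posterior density samples for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import back_transform_seed, log_transform
from .sampler import PosteriorDraws


def coefficient_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, SD, central 95% interval and sign flag per parameter.

    Chains are pooled; quantiles use linear interpolation.  A parameter
    "excludes zero" when both interval endpoints share one sign.
    """
    rows = []
    for name in draws.param_names:
        x = draws.stack(name)
        q2, q97 = np.quantile(x, [0.025, 0.975], method="linear")
        rows.append(
            dict(
                parameter=name,
                mean=float(x.mean()),
                sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                q2_5=float(q2),
                q97_5=float(q97),
                excludes_zero=bool(q2 > 0) or bool(q97 < 0),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class MarginalEffectCurve:
    """Marginal effect of beech seed rain on density for one site.

    ``seed_grid`` is on the raw scale [seeds/m^2]; density is per hectare,
    posterior mean with a central 95% band, all other covariates at their
    means and the session random effect at 0.
    """

    site_id: str
    seed_grid: np.ndarray
    mean_density: np.ndarray
    lo_density: np.ndarray
    hi_density: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                site_id=self.site_id,
                fagus_seeds_per_m2=self.seed_grid,
                density_mean=self.mean_density,
                density_lo=self.lo_density,
                density_hi=self.hi_density,
            )
        )


def _site_columns(x_names: list[str], site_id: str, reference_site: str):
    """Indices of the site dummy and its seed interaction for one site."""
    dummy = inter = None
    if site_id != reference_site:
        name = f"site[{site_id}]"
        if name in x_names:
            dummy = x_names.index(name)
        iname = f"site[{site_id}]:fagus_seed"
        if iname in x_names:
            inter = x_names.index(iname)
        elif "open_sites:fagus_seed" in x_names:
            # pooled interaction coding: applies only to the flagged sites
            inter = None
    return dummy, inter


def marginal_effect(
    draws: PosteriorDraws,
    site_id: str,
    seed_grid: np.ndarray,
    standardization: dict | None = None,
    interaction_applies: bool | None = None,
) -> MarginalEffectCurve:
    """Posterior marginal effect of beech seed rain at one site.

    ``seed_grid`` is raw seeds/m^2 (strictly increasing); it is log(1+x)
    transformed and standardized with the constants stored at fit time (or
    passed explicitly).  Per draw the density is
    ``exp(beta0 + site dummy + (beta_fagus + site interaction) * z)``; the
    curve reports the posterior mean and central 95% band.

    With the pooled ("open sites") interaction coding, pass
    ``interaction_applies`` to state whether this site carries the pooled
    interaction term.
    """
    grid = np.asarray(seed_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or (np.diff(grid) <= 0).any():
        raise ValueError("seed_grid must be strictly increasing")
    std = standardization or draws.meta.get("standardization")
    if std is None:
        raise ValueError("standardization constants unavailable")
    center, scale = std["fagus_seed"]["center"], std["fagus_seed"]["scale"]
    z = (log_transform(grid) - center) / scale

    x_names = draws.x_names()
    reference = draws.meta.get("reference_site", "")
    known_sites = {n[5:-1] for n in x_names if n.startswith("site[")}
    if site_id != reference and site_id not in known_sites:
        raise ValueError(f"unknown site {site_id!r}")
    beta = draws.beta_draws()
    b0 = beta[:, x_names.index("intercept")]
    slope = beta[:, x_names.index("fagus_seed")].copy()
    dummy_ix, inter_ix = _site_columns(x_names, site_id, reference)
    intercept = b0 if dummy_ix is None else b0 + beta[:, dummy_ix]
    if inter_ix is not None:
        slope = slope + beta[:, inter_ix]
    elif "open_sites:fagus_seed" in x_names and interaction_applies:
        slope = slope + beta[:, x_names.index("open_sites:fagus_seed")]

    log_density = intercept[:, None] + slope[:, None] * z[None, :]
    dens = np.exp(log_density)
    lo, hi = np.quantile(dens, [0.025, 0.975], axis=0)
    return MarginalEffectCurve(
        site_id=site_id,
        seed_grid=grid,
        mean_density=dens.mean(axis=0),
        lo_density=lo,
        hi_density=hi,
    )


def default_seed_grid(standardization: dict, n: int = 50) -> np.ndarray:
    """Grid over the observed beech seed-rain range, on the raw scale."""
    c, s = standardization["fagus_seed"]["center"], standardization["fagus_seed"]["scale"]
    # roughly +-2 sd around the mean of the log scale; log1p densities are
    # nonnegative, so the lower end is clamped at 0 before back-transforming
    logs = np.linspace(max(c - 2 * s, 0.0), c + 2 * s, n)
    return back_transform_seed(logs)


def predict_density(
    draws: PosteriorDraws,
    X: np.ndarray,
    offset_log_area: np.ndarray | None = None,
    n_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-session posterior density samples [ind/ha], (n_samples, sessions).

    For each retained draw, density is ``exp(x_i' beta + eps_i)`` (the area
    offset is excluded: the curve is per hectare).  A seeded subsample of
    ``n_samples`` draws is returned, mirroring the convention of plotting a
    random sample of posterior predictions per session.
    """
    total = draws.n_retained
    if n_samples > total:
        raise ValueError(f"subsample {n_samples} exceeds retained draws {total}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n_samples, replace=False)
    beta = draws.beta_draws()[idx]
    eps = draws.eps.reshape(total, -1)[idx]
    X = np.asarray(X, dtype=float)
    return np.exp(beta @ X.T + eps)
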