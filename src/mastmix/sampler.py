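"""Metropolis-within-Gibbs posterior simulation for the N-mixture model.

One sweep updates, in order:

(a) each latent abundance ``N_i`` by a symmetric integer random walk bounded
    below by the session's maximum nightly count;
(b) each session random effect ``eps_i`` by Gaussian random-walk MH;
(c) the random-effect precision ``tau`` by its conjugate Gamma draw;
(d) the abundance coefficients ``beta`` and detection coefficients ``alpha``
    coordinate-wise by adaptive Gaussian random-walk MH.

Proposal scales follow a Robbins-Monro adaptation towards a 20-40 %
acceptance rate during the burn-in/adaptation phase only and are frozen
afterwards, keeping the retained chain Markovian.  Runs are bit-reproducible
given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .likelihood import AbundanceParams, DetectionParams, ModelData, Priors

__all__ = ["McmcConfig", "PosteriorDraws", "SamplerError", "retained_samples", "fit"]


class SamplerError(Exception):
    """Sampler could not run (bad config, degenerate data, bad initials)."""


@dataclass
class McmcConfig:
    """MCMC protocol. The field-study protocol is 3 chains x 800,000
    iterations with 100,000 burn-in/adaptation draws and thinning 200
    (10,500 retained draws); desk-scale runs shrink these numbers.
    """

    n_chains: int = 3
    n_iter: int = 800_000
    n_burn_adapt: int = 100_000
    thin: int = 200
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    target_accept: float = 0.3
    target_accept_latent: float = 0.4
    adapt_step: float = 0.05
    init_headroom: float = 5.0  # Poisson mean added to max-count at init
    max_init_retries: int = 20
    n_trade_moves: int = 8  # per-sweep joint intercept moves along the N-p ridge

    def __post_init__(self):
        if self.thin < 1:
            raise SamplerError("thin must be >= 1")
        if self.n_iter <= self.n_burn_adapt:
            raise SamplerError("n_iter must exceed n_burn_adapt")
        if self.n_chains < 1:
            raise SamplerError("need at least one chain")


def retained_samples(config: McmcConfig) -> int:
    """Total retained draws: chains x floor((iters - burn) / thin)."""
    return config.n_chains * ((config.n_iter - config.n_burn_adapt) // config.thin)


@dataclass
class PosteriorDraws:
    """Retained MCMC samples for all parameters and latent abundances.

    ``params`` has shape (chains, kept, n_params) with ``param_names``
    labelling the last axis; ``latent_N`` and ``eps`` have shape
    (chains, kept, n_sessions).  ``meta`` carries whatever the fit knew that
    reporting needs (design column names, standardization constants, ...).
    """

    params: np.ndarray
    param_names: list[str]
    latent_N: np.ndarray
    eps: np.ndarray
    accept_rates: dict[str, float]
    config: McmcConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_kept_per_chain(self) -> int:
        return self.params.shape[1]

    @property
    def n_retained(self) -> int:
        return self.params.shape[0] * self.params.shape[1]

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def stack(self, name: str) -> np.ndarray:
        """All chains' draws of one parameter, flattened."""
        return self.params[:, :, self.index(name)].reshape(-1)

    def by_chain(self, name: str) -> np.ndarray:
        """(chains, kept) draws of one parameter."""
        return self.params[:, :, self.index(name)]

    def x_names(self) -> list[str]:
        return [n[len("lambda:"):] for n in self.param_names if n.startswith("lambda:")]

    def z_names(self) -> list[str]:
        return [n[len("p:"):] for n in self.param_names if n.startswith("p:")]

    def beta_draws(self) -> np.ndarray:
        """(total draws, p) abundance coefficient matrix."""
        cols = [i for i, n in enumerate(self.param_names) if n.startswith("lambda:")]
        return self.params[:, :, cols].reshape(-1, len(cols))

    def alpha_draws(self) -> np.ndarray:
        cols = [i for i, n in enumerate(self.param_names) if n.startswith("p:")]
        return self.params[:, :, cols].reshape(-1, len(cols))

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Persist draws as plain CSV plus a JSON sidecar with the config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ch, kept, _ = self.params.shape
        idx = pd.MultiIndex.from_product(
            [range(ch), range(kept)], names=["chain", "draw"]
        )
        pdf = pd.DataFrame(
            self.params.reshape(ch * kept, -1), index=idx, columns=self.param_names
        )
        p_params = out / "draws_params.csv"
        pdf.to_csv(p_params)
        ndf = pd.DataFrame(
            self.latent_N.reshape(ch * kept, -1),
            index=idx,
            columns=[f"N[{i}]" for i in range(self.latent_N.shape[2])],
        )
        p_n = out / "draws_latent_N.csv"
        ndf.to_csv(p_n)
        edf = pd.DataFrame(
            self.eps.reshape(ch * kept, -1),
            index=idx,
            columns=[f"eps[{i}]" for i in range(self.eps.shape[2])],
        )
        p_eps = out / "draws_eps.csv"
        edf.to_csv(p_eps)
        sidecar = {
            "config": {
                k: v
                for k, v in dataclasses.asdict(self.config).items()
                if not isinstance(v, dict)
            },
            "priors": dataclasses.asdict(self.config.priors),
            "accept_rates": self.accept_rates,
            "param_names": self.param_names,
            "meta": _jsonable(self.meta),
        }
        p_meta = out / "draws_meta.json"
        with open(p_meta, "w") as fh:
            json.dump(sidecar, fh, indent=2)
        return {"params": p_params, "latent_N": p_n, "eps": p_eps, "meta": p_meta}

    @classmethod
    def load(cls, out_dir: str | Path) -> "PosteriorDraws":
        out = Path(out_dir)
        pdf = pd.read_csv(out / "draws_params.csv", index_col=[0, 1])
        ndf = pd.read_csv(out / "draws_latent_N.csv", index_col=[0, 1])
        edf = pd.read_csv(out / "draws_eps.csv", index_col=[0, 1])
        with open(out / "draws_meta.json") as fh:
            sidecar = json.load(fh)
        ch = pdf.index.get_level_values(0).nunique()
        kept = pdf.index.get_level_values(1).nunique()
        cfg_kwargs = sidecar["config"]
        cfg_kwargs["priors"] = Priors(**sidecar["priors"])
        cfg = McmcConfig(**cfg_kwargs)
        return cls(
            params=pdf.to_numpy().reshape(ch, kept, -1),
            param_names=list(pdf.columns),
            latent_N=ndf.to_numpy().reshape(ch, kept, -1),
            eps=edf.to_numpy().reshape(ch, kept, -1),
            accept_rates=sidecar["accept_rates"],
            config=cfg,
            meta=sidecar["meta"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def fit(
    data: ModelData,
    config: McmcConfig,
    fixed: dict | None = None,
    meta: dict | None = None,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    ``fixed`` may pin any of ``beta``, ``alpha``, ``eps``, ``tau`` to given
    values (their updates are skipped) — used for conditional-posterior
    validation against the enumeration oracle.
    """
    fixed = fixed or {}
    if data.counts.sum() == 0 and "beta" not in fixed:
        raise SamplerError(
            "all nightly counts are zero: abundance and detection are not "
            "separately identifiable; review priors or pool more data"
        )
    kept_per_chain = (config.n_iter - config.n_burn_adapt) // config.thin
    if kept_per_chain < 1:
        raise SamplerError("config retains no draws")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(data, config, fixed, np.random.default_rng(s), kept_per_chain)
        for s in seeds
    ]

    params = np.stack([c["params"] for c in chains])
    latent = np.stack([c["N"] for c in chains])
    eps = np.stack([c["eps"] for c in chains])
    acc: dict[str, float] = {}
    for key in chains[0]["accept"]:
        acc[key] = float(np.mean([c["accept"][key] for c in chains]))
    return PosteriorDraws(
        params=params,
        param_names=chains[0]["names"],
        latent_N=latent,
        eps=eps,
        accept_rates=acc,
        config=config,
        meta=meta or {},
    )


def _session_sum(values: np.ndarray, night_session: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(night_session, weights=values, minlength=n)


_P_EPS = 1e-12


def _expit_clipped(eta: np.ndarray) -> np.ndarray:
    # keep p strictly inside (0, 1) so log p / log(1-p) stay finite
    return np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)


def _run_chain(
    data: ModelData,
    config: McmcConfig,
    fixed: dict,
    rng: np.random.Generator,
    kept_per_chain: int,
) -> dict:
    n_sess = data.n_sessions
    n_nights = len(data.counts)
    X, Z = data.X, data.Z
    C = data.counts.astype(float)
    ns = data.night_session
    J = np.bincount(ns, minlength=n_sess).astype(float)
    maxC = data.max_counts()
    priors = config.priors
    coef_var = priors.coef_sd**2

    fix_beta = "beta" in fixed
    fix_alpha = "alpha" in fixed
    fix_eps = "eps" in fixed
    fix_tau = "tau" in fixed

    p_a, p_d = X.shape[1], Z.shape[1]

    for attempt in range(config.max_init_retries):
        beta = (
            np.asarray(fixed["beta"], dtype=float).copy()
            if fix_beta
            else rng.normal(0.0, 1.0, p_a)
        )
        alpha = (
            np.asarray(fixed["alpha"], dtype=float).copy()
            if fix_alpha
            else rng.normal(0.0, 1.0, p_d)
        )
        eps = (
            np.asarray(fixed["eps"], dtype=float).copy()
            if fix_eps
            else np.zeros(n_sess)
        )
        tau = float(fixed.get("tau", 1.0))
        N = maxC + rng.poisson(config.init_headroom, n_sess)
        log_mu = data.offset_log_area + X @ beta + eps
        if np.all(np.isfinite(np.exp(log_mu))):
            break
    else:
        raise SamplerError("could not find finite initial state")

    mu = np.exp(log_mu)
    eta_d = Z @ alpha
    p = _expit_clipped(eta_d)
    log_p = np.log(p)
    log_q = np.log1p(-p)
    s_logq = _session_sum(log_q, ns, n_sess)

    Nf = N[ns].astype(float)
    glN = gammaln(N + 1.0)
    gl_night = gammaln(Nf - C + 1.0)

    # adaptive proposal scales (log scale for positivity)
    scale_N = np.full(n_sess, 3.0)
    scale_eps = np.full(n_sess, 0.5)
    scale_beta = np.full(p_a, 0.1)
    scale_alpha = np.full(p_d, 0.1)
    scale_trade = 0.2
    acc_trade = 0

    acc_N = np.zeros(n_sess)
    acc_eps = np.zeros(n_sess)
    acc_beta = np.zeros(p_a)
    acc_alpha = np.zeros(p_d)
    n_post = 0

    kept_params = np.empty((kept_per_chain, p_a + p_d + 2))
    kept_N = np.empty((kept_per_chain, n_sess), dtype=np.int64)
    kept_eps = np.empty((kept_per_chain, n_sess))
    k_out = 0

    tgt = config.target_accept
    tgt_N = config.target_accept_latent
    gam = config.adapt_step
    mu_sum = mu.sum()
    err = np.errstate(divide="ignore", invalid="ignore")
    err.__enter__()

    for it in range(config.n_iter):
        adapting = it < config.n_burn_adapt

        # ---- (a) latent N: symmetric integer random walk ------------------
        m = np.maximum(1, np.rint(scale_N).astype(np.int64))
        step = rng.integers(1, m + 1) * (2 * rng.integers(0, 2, n_sess) - 1)
        Np = N + step
        ok = Np >= maxC
        Np_safe = np.where(ok, Np, maxC)
        dN = (Np_safe - N).astype(float)
        gl_prop_sess = gammaln(Np_safe + 1.0)
        gl_prop_night = gammaln(Np_safe[ns] - C + 1.0)
        d_gl_night = _session_sum(gl_night - gl_prop_night, ns, n_sess)
        delta = (
            dN * log_mu
            + (J - 1.0) * (gl_prop_sess - glN)
            + d_gl_night
            + dN * s_logq
        )
        accept = ok & (np.log(rng.random(n_sess)) < delta)
        if accept.any():
            N = np.where(accept, Np_safe, N)
            Nf = N[ns].astype(float)
            glN = np.where(accept, gl_prop_sess, glN)
            gl_night = np.where(accept[ns], gl_prop_night, gl_night)
        N_sum = float(N.sum())
        if adapting:
            scale_N = np.clip(
                scale_N * np.exp(gam * (accept.astype(float) - tgt_N)), 0.51, 500.0
            )
        else:
            acc_N += accept

        # ---- (b) session random effects ------------------------------------
        if not fix_eps:
            d_eps = scale_eps * rng.standard_normal(n_sess)
            eps_p = eps + d_eps
            mu_p = mu * np.exp(d_eps)
            delta = (
                N * d_eps - (mu_p - mu) - 0.5 * tau * (eps_p**2 - eps**2)
            )
            accept = np.log(rng.random(n_sess)) < delta
            if accept.any():
                eps = np.where(accept, eps_p, eps)
                mu = np.where(accept, mu_p, mu)
                log_mu = np.where(accept, log_mu + d_eps, log_mu)
                mu_sum = mu.sum()
            if adapting:
                scale_eps = np.clip(
                    scale_eps * np.exp(gam * (accept.astype(float) - tgt)), 1e-3, 10.0
                )
            else:
                acc_eps += accept

        # ---- (c) tau: conjugate Gamma given eps ----------------------------
        if not fix_tau:
            shape = priors.tau_shape + 0.5 * n_sess
            rate = priors.tau_rate + 0.5 * float(eps @ eps)
            tau = rng.gamma(shape, 1.0 / rate)

        # ---- (d) coefficients: coordinate-wise adaptive RW-MH --------------
        if not fix_beta:
            for k in range(p_a):
                d = scale_beta[k] * rng.standard_normal()
                log_mu_p = log_mu + X[:, k] * d
                mu_p = np.exp(log_mu_p)
                mu_p_sum = mu_p.sum()
                delta = (
                    d * float(N @ X[:, k])
                    - (mu_p_sum - mu_sum)
                    - 0.5 * ((beta[k] + d) ** 2 - beta[k] ** 2) / coef_var
                )
                if np.log(rng.random()) < delta:
                    beta[k] += d
                    log_mu, mu = log_mu_p, mu_p
                    mu_sum = mu_p_sum
                    if adapting:
                        scale_beta[k] *= np.exp(gam * (1 - tgt))
                    else:
                        acc_beta[k] += 1
                elif adapting:
                    scale_beta[k] *= np.exp(-gam * tgt)

        if not fix_alpha:
            for k in range(p_d):
                d = scale_alpha[k] * rng.standard_normal()
                eta_p = eta_d + Z[:, k] * d
                p_prop = _expit_clipped(eta_p)
                ll_prop = float(C @ np.log(p_prop) + (Nf - C) @ np.log1p(-p_prop))
                ll_cur = float(C @ log_p + (Nf - C) @ log_q)
                delta = ll_prop - ll_cur - 0.5 * (
                    (alpha[k] + d) ** 2 - alpha[k] ** 2
                ) / coef_var
                if np.isfinite(delta) and np.log(rng.random()) < delta:
                    alpha[k] += d
                    eta_d = eta_p
                    p = p_prop
                    log_p = np.log(p)
                    log_q = np.log1p(-p)
                    if adapting:
                        scale_alpha[k] *= np.exp(gam * (1 - tgt))
                    else:
                        acc_alpha[k] += 1
                elif adapting:
                    scale_alpha[k] *= np.exp(-gam * tgt)
            s_logq = _session_sum(log_q, ns, n_sess)

        # joint intercept move: beta0 up / alpha0 down traverses the ridge of
        # posterior correlation between abundance and detection intercepts
        if not (fix_beta or fix_alpha):
            for _ in range(config.n_trade_moves):
                d = scale_trade * rng.standard_normal()
                log_mu_p = log_mu + d
                mu_p = np.exp(log_mu_p)
                mu_p_sum = mu_p.sum()
                eta_p = eta_d - d
                p_prop = _expit_clipped(eta_p)
                ll_prop = float(C @ np.log(p_prop) + (Nf - C) @ np.log1p(-p_prop))
                ll_cur = float(C @ log_p + (Nf - C) @ log_q)
                delta = (
                    d * N_sum
                    - (mu_p_sum - mu_sum)
                    + ll_prop
                    - ll_cur
                    - 0.5 * ((beta[0] + d) ** 2 - beta[0] ** 2) / coef_var
                    - 0.5 * ((alpha[0] - d) ** 2 - alpha[0] ** 2) / coef_var
                )
                if np.log(rng.random()) < delta:
                    beta[0] += d
                    alpha[0] -= d
                    log_mu, mu, mu_sum = log_mu_p, mu_p, mu_p_sum
                    eta_d, p = eta_p, p_prop
                    log_p = np.log(p)
                    log_q = np.log1p(-p)
                    if adapting:
                        scale_trade *= np.exp(gam * (1 - tgt))
                    acc_trade += 0 if adapting else 1
                elif adapting:
                    scale_trade *= np.exp(-gam * tgt)
            s_logq = _session_sum(log_q, ns, n_sess)

        if not adapting:
            n_post += 1
            if (it - config.n_burn_adapt) % config.thin == config.thin - 1:
                if k_out < kept_per_chain:
                    kept_params[k_out, :p_a] = beta
                    kept_params[k_out, p_a : p_a + p_d] = alpha
                    kept_params[k_out, p_a + p_d] = tau
                    kept_params[k_out, p_a + p_d + 1] = tau**-0.5
                    kept_N[k_out] = N
                    kept_eps[k_out] = eps
                    k_out += 1

    err.__exit__(None, None, None)
    x_names = data.x_names or [f"x{k}" for k in range(p_a)]
    z_names = data.z_names or [f"z{k}" for k in range(p_d)]
    names = (
        [f"lambda:{n}" for n in x_names]
        + [f"p:{n}" for n in z_names]
        + ["tau", "sigma_eps"]
    )
    denom = max(n_post, 1)
    return {
        "params": kept_params[:k_out],
        "N": kept_N[:k_out],
        "eps": kept_eps[:k_out],
        "names": names,
        "accept": {
            "trade": float(acc_trade / (denom * max(config.n_trade_moves, 1))),
            "latent_N": float(np.mean(acc_N) / denom),
            "eps": float(np.mean(acc_eps) / denom) if not fix_eps else np.nan,
            "beta": float(np.mean(acc_beta) / denom) if not fix_beta else np.nan,
            "alpha": float(np.mean(acc_alpha) / denom) if not fix_alpha else np.nan,
        },
    }
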