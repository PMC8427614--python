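"""Posterior-predictive goodness-of-fit: Bayesian p-value and c-hat.

Per retained draw, the expected nightly count is ``E_ij = N_i * p_ij``
(conditioning on the sampled latent abundance, the standard N-mixture
posterior-predictive construction).  A Pearson chi-squared discrepancy is
computed for the observed counts and for a fresh binomial replicate:

    D = sum_ij (C_ij - E_ij)^2 / (E_ij + guard)

The Bayesian p-value is the share of draws with ``D_rep > D_obs`` (strict;
ties count as not-exceeding); the overdispersion ratio is
``c_hat = mean(D_obs) / mean(D_rep)``.  Values of c-hat near 1 and p-values
away from 0 and 1 indicate adequate fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .likelihood import ModelData
from .sampler import PosteriorDraws

DEFAULT_GUARD = 0.5


def chi2_discrepancy(observed_counts, expected_counts, guard: float = DEFAULT_GUARD):
    """Pearson chi-squared discrepancy with a small-denominator guard."""
    C = np.asarray(observed_counts, dtype=float)
    E = np.asarray(expected_counts, dtype=float)
    if C.shape != E.shape:
        raise ValueError(f"shape mismatch: {C.shape} vs {E.shape}")
    if (E < 0).any():
        raise ValueError("expected counts must be >= 0")
    return float(np.sum((C - E) ** 2 / (E + guard)))


@dataclass
class GofResult:
    """Posterior-predictive check result.

    ``d_obs``/``d_rep`` are per-draw discrepancies; ``bayes_p`` the share of
    draws whose replicate discrepancy strictly exceeds the observed one;
    ``c_hat`` the observed/replicated mean-discrepancy ratio.
    """

    bayes_p: float
    c_hat: float
    n_draws_used: int
    d_obs: np.ndarray
    d_rep: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "bayes_p": self.bayes_p,
            "c_hat": self.c_hat,
            "n_draws_used": self.n_draws_used,
            "seed": self.seed,
        }


def posterior_predictive_gof(
    draws: PosteriorDraws,
    data: ModelData,
    seed: int = 0,
    guard: float = DEFAULT_GUARD,
    max_draws: int | None = None,
) -> GofResult:
    """Chi-squared posterior-predictive check over the retained draws.

    ``max_draws`` subsamples the retained draws (evenly across chains) to
    bound runtime; replication noise is seeded and reproducible.
    """
    total = draws.n_retained
    if total == 0:
        raise ValueError("no retained draws")
    alpha = draws.alpha_draws()
    N = draws.latent_N.reshape(total, -1)

    idx = np.arange(total)
    if max_draws is not None and max_draws < total:
        idx = np.linspace(0, total - 1, max_draws).astype(int)
    rng = np.random.default_rng(seed)

    ns = data.night_session
    C = data.counts.astype(float)
    d_obs = np.empty(len(idx))
    d_rep = np.empty(len(idx))
    for k, i in enumerate(idx):
        p = expit(data.Z @ alpha[i])
        Nf = N[i][ns]
        E = Nf * p
        d_obs[k] = np.sum((C - E) ** 2 / (E + guard))
        C_rep = rng.binomial(Nf.astype(int), p)
        d_rep[k] = np.sum((C_rep - E) ** 2 / (E + guard))

    return GofResult(
        bayes_p=float(np.mean(d_rep > d_obs)),
        c_hat=float(np.mean(d_obs) / np.mean(d_rep)),
        n_draws_used=len(idx),
        d_obs=d_obs,
        d_rep=d_rep,
        seed=seed,
    )


def replicate_counts(
    draws: PosteriorDraws, data: ModelData, seed: int = 0, draw_index: int | None = None
) -> np.ndarray:
    """One posterior-predictive replicate of the nightly count vector.

    Used for self-calibration: a replicate treated as "observed" data should
    yield a Bayesian p-value away from 0 and 1.
    """
    rng = np.random.default_rng(seed)
    total = draws.n_retained
    i = int(rng.integers(total)) if draw_index is None else draw_index
    alpha = draws.alpha_draws()[i]
    N = draws.latent_N.reshape(total, -1)[i]
    p = expit(data.Z @ alpha)
    return rng.binomial(N[data.night_session].astype(int), p)
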