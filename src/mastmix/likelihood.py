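"""Probability machinery of the Poisson-lognormal binomial N-mixture model.

Hierarchy, per trapping session i with nights j = 1..J_i:

    N_i ~ Poisson(mu_i),      mu_i = A_i * lambda_i
    log lambda_i = x_i' beta + eps_i,   eps_i ~ Normal(0, sigma_eps)
    C_ij | N_i ~ Binomial(N_i, p_ij),   logit p_ij = z_ij' alpha

lambda_i is density [individuals / ha]; A_i the sampled area [ha].  The
area offset enters the Poisson mean exactly once.  tau = sigma_eps^-2 is
the precision of the session random effect.

Besides the complete-data log posterior used by the sampler, this module
provides a brute-force enumeration of the marginal likelihood over N (the
independent oracle for sampler tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "AbundanceParams",
    "DetectionParams",
    "Priors",
    "ModelData",
    "expected_abundance",
    "detection_prob",
    "complete_data_logpost",
    "marginal_loglik_enum",
    "binom_logpmf",
    "poisson_logpmf",
]


def binom_logpmf(c, n, p):
    """log Binomial(c | n, p), vectorized, -inf outside support."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1)
            - gammaln(c + 1)
            - gammaln(n - c + 1)
            + np.where(c > 0, c * np.log(p), 0.0)
            + np.where(n - c > 0, (n - c) * np.log1p(-p), 0.0)
        )
    out = np.where((c < 0) | (c > n), -np.inf, out)
    out = np.where((p == 0) & (c > 0), -np.inf, out)
    out = np.where((p == 1) & (c < n), -np.inf, out)
    return out


def poisson_logpmf(n, mu):
    """log Poisson(n | mu), vectorized."""
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * np.log(mu) - mu - gammaln(n + 1)
        out = np.where((mu == 0) & (n == 0), 0.0, out)
    return np.where(n < 0, -np.inf, out)


@dataclass
class AbundanceParams:
    """Abundance submodel state: coefficient vector, random effects, precision.

    ``beta`` is aligned with the abundance design columns (intercept, site
    dummies, seed terms, Julian terms, interaction terms); ``eps`` holds one
    session random effect per fitted session; ``tau`` is the precision of
    eps (sigma_eps = tau**-0.5).
    """

    beta: np.ndarray
    eps: np.ndarray
    tau: float = 1.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau (precision) must be > 0")

    @property
    def sigma_eps(self) -> float:
        return float(self.tau) ** -0.5


@dataclass
class DetectionParams:
    """Detection submodel coefficients, aligned with the detection design."""

    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("detection coefficients must be finite")


@dataclass
class Priors:
    """Diffuse priors: Normal(0, coef_sd^2) coefficients, Gamma(a, b) on tau."""

    coef_sd: float = np.sqrt(1000.0)
    tau_shape: float = 0.001
    tau_rate: float = 0.001


@dataclass
class ModelData:
    """Everything the likelihood needs, in flat vectorized form.

    ``counts`` is the nightly count vector over all kept sessions
    (length = total nights); ``night_session`` maps each night row to its
    session row in ``X``.
    """

    counts: np.ndarray
    X: np.ndarray
    offset_log_area: np.ndarray
    Z: np.ndarray
    night_session: np.ndarray
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.offset_log_area = np.asarray(self.offset_log_area, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.night_session = np.asarray(self.night_session, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(self.counts) != len(self.Z):
            raise ValueError("counts and detection design misaligned")
        if len(self.X) != len(self.offset_log_area):
            raise ValueError("offset and abundance design misaligned")

    @classmethod
    def from_design(cls, design, counts) -> "ModelData":
        """Build from a :class:`~mastmix.covariates.DesignMatrices` + counts."""
        return cls(
            counts=counts,
            X=design.X,
            offset_log_area=design.offset_log_area,
            Z=design.Z,
            night_session=design.night_session,
            x_names=list(design.x_names),
            z_names=list(design.z_names),
        )

    @property
    def n_sessions(self) -> int:
        return self.X.shape[0]

    def max_counts(self) -> np.ndarray:
        """Per-session max nightly count: the support floor for latent N."""
        out = np.zeros(self.n_sessions, dtype=int)
        np.maximum.at(out, self.night_session, self.counts)
        return out


def expected_abundance(
    x_row: np.ndarray,
    offset_log_area: float | np.ndarray,
    params: AbundanceParams,
    eps: float | np.ndarray = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(density [ind/ha], expected count) for session rows.

    ``lambda = exp(x'beta + eps)`` and ``mu = A * lambda``; the area offset
    multiplies the density once.
    """
    x = np.atleast_2d(np.asarray(x_row, dtype=float))
    if x.shape[1] != len(params.beta):
        raise ValueError(
            f"design row has {x.shape[1]} columns, beta has {len(params.beta)}"
        )
    if eps is None:
        eps = params.eps if params.eps.size else 0.0
    lam = np.exp(x @ params.beta + eps)
    mu = np.exp(np.asarray(offset_log_area, dtype=float)) * lam
    if np.isscalar(offset_log_area) and x.shape[0] == 1:
        return float(lam[0]), float(mu[0])
    return lam, mu


def detection_prob(z_row: np.ndarray, params: DetectionParams) -> np.ndarray | float:
    """p = logistic(z'alpha) in (0, 1)."""
    z = np.asarray(z_row, dtype=float)
    single = z.ndim == 1
    p = expit(np.atleast_2d(z) @ params.alpha)
    return float(p[0]) if single else p


def complete_data_logpost(
    data: ModelData,
    latent_N: np.ndarray,
    abundance: AbundanceParams,
    detection: DetectionParams,
    priors: Priors | None = None,
) -> float:
    """Joint log density of counts, latent N, random effects and parameters.

    Returns -inf whenever any N_i is below its session's max nightly count
    (the binomial support constraint).
    """
    priors = priors or Priors()
    N = np.asarray(latent_N, dtype=int)
    if N.shape != (data.n_sessions,):
        raise ValueError("latent_N must have one entry per session")
    if (N < data.max_counts()).any() or (N < 0).any():
        return -np.inf

    _, mu = expected_abundance(data.X, data.offset_log_area, abundance,
                               eps=abundance.eps)
    p = expit(data.Z @ detection.alpha)
    Nf = N[data.night_session]

    ll = float(np.sum(poisson_logpmf(N, mu)))
    ll += float(np.sum(binom_logpmf(data.counts, Nf, p)))
    sd = abundance.sigma_eps
    ll += float(
        np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (abundance.eps / sd) ** 2)
    )
    # diffuse priors on coefficients and tau
    coef = np.concatenate([abundance.beta, detection.alpha])
    ll += float(
        np.sum(
            -0.5 * np.log(2 * np.pi)
            - np.log(priors.coef_sd)
            - 0.5 * (coef / priors.coef_sd) ** 2
        )
    )
    a, b = priors.tau_shape, priors.tau_rate
    tau = abundance.tau
    ll += a * np.log(b) - gammaln(a) + (a - 1) * np.log(tau) - b * tau
    return ll


def marginal_loglik_enum(
    counts_i: np.ndarray,
    mu_count_i: float,
    p_i_vector: np.ndarray,
    N_max: int,
) -> float:
    """Brute-force marginal log likelihood of one session's nightly counts.

    Sums Poisson(N | mu) * prod_j Binomial(C_j | N, p_j) over
    N = max(C)..N_max (conditional on the session random effect, which
    enters through ``mu_count_i``).  Test oracle; not used by the sampler.
    """
    C = np.asarray(counts_i, dtype=int)
    if (C < 0).any():
        raise ValueError("negative counts")
    cmax = int(C.max()) if C.size else 0
    if N_max < cmax:
        raise ValueError(f"N_max={N_max} below max count {cmax}")
    p = np.asarray(p_i_vector, dtype=float)
    if p.shape != C.shape:
        raise ValueError("counts and detection probabilities misaligned")
    Ns = np.arange(cmax, N_max + 1)
    terms = poisson_logpmf(Ns, mu_count_i)
    for j in range(len(C)):
        terms = terms + binom_logpmf(C[j], Ns, p[j])
    m = terms.max()
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(terms - m))))
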