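"""Convergence diagnostics: potential scale reduction factor and reporting.

``rhat`` implements the classic Gelman-Rubin / Brooks-Gelman potential
scale reduction factor on unsplit chains:

    W    = mean of within-chain variances
    B/n  = variance of chain means
    var+ = (n-1)/n * W + B/n
    Rhat = sqrt( var+/W + B/(n*m*W) )

where n is draws per chain and m the number of chains; the B/(n*m*W) term
is the sampling-variability correction for the mean of means.  Values below
1.1 are conventionally taken as converged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

RHAT_THRESHOLD = 1.1


def rhat(draws_by_chain: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``draws_by_chain`` has shape (chains, draws); needs >= 2 chains and
    >= 10 draws per chain.
    """
    x = np.asarray(draws_by_chain, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs draws from >= 2 chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("rhat needs >= 10 draws per chain")
    chain_means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    B_over_n = float(chain_means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W + B_over_n / (m * W)))


def ess(draws_by_chain: np.ndarray) -> float:
    """Effective sample size (delegated to arviz's standard estimator)."""
    import arviz as az

    x = np.asarray(draws_by_chain, dtype=float)
    return float(az.ess(az.convert_to_dataset(x))["x"])


@dataclass
class ConvergenceReport:
    """Per-parameter rhat/ESS table plus sampler acceptance rates."""

    table: pd.DataFrame
    accept_rates: dict[str, float]
    flagged: list[str]

    @property
    def converged(self) -> bool:
        return not self.flagged


def convergence_report(
    draws: PosteriorDraws,
    out_dir: str | Path | None = None,
    threshold: float = RHAT_THRESHOLD,
) -> ConvergenceReport:
    """Diagnose every sampled parameter; optionally write trace plots.

    Parameters with rhat >= ``threshold`` are flagged.  When ``out_dir`` is
    given, a CSV of the table and one trace-plot page are written there.
    """
    rows = []
    flagged = []
    for name in draws.param_names:
        chains = draws.by_chain(name)
        try:
            r = rhat(chains)
        except ValueError:
            r = np.nan
        try:
            neff = ess(chains)
        except Exception:
            neff = np.nan
        bad = bool(np.isfinite(r) and r >= threshold)
        if bad:
            flagged.append(name)
        rows.append(
            dict(
                parameter=name,
                mean=float(chains.mean()),
                sd=float(chains.std(ddof=1)),
                rhat=r,
                ess=neff,
                flagged=bad,
            )
        )
    table = pd.DataFrame(rows)
    report = ConvergenceReport(
        table=table, accept_rates=dict(draws.accept_rates), flagged=flagged
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "convergence.csv", index=False)
        _trace_plots(draws, out / "traceplots.pdf")
    return report


def _trace_plots(draws: PosteriorDraws, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    with PdfPages(path) as pdf:
        per_page = 6
        names = draws.param_names
        for start in range(0, len(names), per_page):
            chunk = names[start : start + per_page]
            fig, axes = plt.subplots(len(chunk), 1, figsize=(8, 2 * len(chunk)))
            axes = np.atleast_1d(axes)
            for ax, name in zip(axes, chunk):
                for c in range(draws.n_chains):
                    ax.plot(draws.by_chain(name)[c], lw=0.5)
                ax.set_ylabel(name, fontsize=7)
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
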