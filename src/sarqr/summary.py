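"""Posterior summaries, convergence diagnostics, and effect decompositions.

* :func:`summarize` — posterior mean, spread, and equal-tailed 95% credible
  interval per monitored scalar.
* :func:`gelman_rubin` — the classic two-part potential scale reduction
  factor (PSRF) from multiple chains; values below 1.2 are conventionally
  taken as convergence evidence.  No rank normalization or chain splitting.
* :func:`marginal_effects` — the LeSage–Pace decomposition of the spatial
  multiplier: per posterior draw, dy/dx_j = (I - rho W)^{-1} beta_j, with
  the direct effect the mean diagonal entry, the total effect the mean row
  sum, and the indirect effect their difference (exactly, per draw).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize", "gelman_rubin", "marginal_effects"]


def summarize(draws, level=0.95):
    """Posterior Mean, SE (posterior standard deviation), and equal-tailed
    credible interval for each named scalar.

    Parameters
    ----------
    draws : dict[str, array_like] or DataFrame
        Posterior draws per scalar, all of equal length.
    """
    if isinstance(draws, pd.DataFrame):
        draws = {c: draws[c].to_numpy() for c in draws.columns}
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = {}
    for name, x in draws.items():
        x = np.asarray(x, dtype=float).ravel()
        if x.size == 0:
            raise ValueError(f"no draws for {name!r}")
        rows[name] = {
            "Mean": x.mean(),
            "SE": x.std(ddof=1) if x.size > 1 else 0.0,
            f"{100 * lo:g}%": np.quantile(x, lo),
            f"{100 * hi:g}%": np.quantile(x, hi),
        }
    return pd.DataFrame(rows).T


def gelman_rubin(chains):
    """Classic Gelman–Rubin PSRF from m >= 2 equal-length chains.

    With W the mean within-chain variance and B/n the variance of the chain
    means, R-hat = sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be an (m, n) array of draws")
    m, n = chains.shape
    if m < 2:
        raise ValueError("at least two chains are required for the PSRF")
    if n < 2:
        raise ValueError("chains must contain at least two draws")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def marginal_effects(rho_draws, beta_draws, weights, names=None, kind="row"):
    """LeSage–Pace direct/indirect/total effect draws for each linear covariate.

    Per retained draw, M = (I - rho W)^{-1} beta_j; direct = mean diag(M),
    total = mean row sum of M, indirect = total - direct.  (Averaged over
    units, the row-sum and column-sum conventions coincide; ``kind`` is kept
    for interface parity.)

    Returns
    -------
    draws : dict[str, DataFrame]
        Per covariate, a DataFrame with columns direct, indirect, total
        (one row per posterior draw).
    """
    rho_draws = np.asarray(rho_draws, dtype=float).ravel()
    beta_draws = np.asarray(beta_draws, dtype=float)
    if beta_draws.ndim == 1:
        beta_draws = beta_draws[:, None]
    if beta_draws.shape[0] != rho_draws.size:
        raise ValueError("rho and beta draw counts differ")
    p = beta_draws.shape[1]
    names = names or [f"x{j + 1}" for j in range(p)]
    diag_mult = np.array([weights.mean_diag_inv(r) for r in rho_draws])
    total_mult = np.array([weights.mean_total_inv(r, kind=kind) for r in rho_draws])
    out = {}
    for j in range(p):
        direct = diag_mult * beta_draws[:, j]
        indirect = (total_mult - diag_mult) * beta_draws[:, j]
        # total re-assembled from the parts so the conservation identity
        # direct + indirect == total holds exactly per draw
        out[names[j]] = pd.DataFrame(
            {"direct": direct, "indirect": indirect, "total": direct + indirect}
        )
    return out
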