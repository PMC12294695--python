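"""The partially linear varying-coefficient spatial-lag quantile model.

The model for observation i at quantile level tau is

    y_i = rho * sum_j w_ij y_j + x_i' beta + z_i' alpha(u_i) + eps_i,

where the tau-th conditional quantile of eps_i is zero.  Working with an
asymmetric Laplace error law and its exponential-normal mixture, and writing
alpha_j through free-knot B-splines (D(z, u) gamma), the augmented model in
matrix form is

    A(rho) y = X beta + D(z, u) gamma + m1 e + E^{1/2} nu,
    A(rho) = I - rho W,  E = m2 delta0 diag(e),  nu ~ N(0, I).

This module holds the data container, the prior configuration, the full
chain state, and the augmented log-likelihood; the statsmodels-style
:class:`QuantileSAR` entry point delegates sampling to :mod:`sarqr.sampler`
and summarization to :mod:`sarqr.results`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ald import QuantileConstants
from .splines import SplineConfig, SplineState, build_design
from .weights import WeightMatrix

__all__ = ["Dataset", "Priors", "ChainState", "QuantileSAR", "augmented_loglik", "residual_targets"]


@dataclass
class Dataset:
    """Observed data: response, linear and varying-coefficient covariates,
    smoothing variable(s), and the spatial weight matrix."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, p); p may be 0
    Z: np.ndarray  # (n, q)
    U: np.ndarray  # (n, q); column j may repeat a shared smoothing variable
    weights: WeightMatrix

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.X is None or np.size(self.X) == 0:
            self.X = np.empty((n, 0))
        else:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim == 1:
                self.X = self.X[:, None]
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim == 1:
            self.U = np.repeat(self.U[:, None], self.Z.shape[1], axis=1)
        for name, arr in (("X", self.X), ("Z", self.Z), ("U", self.U)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.U.shape[1] != self.Z.shape[1]:
            raise ValueError("U must have one column per column of Z (or a single shared column)")
        if self.weights.n != n:
            raise ValueError(f"weight matrix is {self.weights.n} x {self.weights.n}, data has n={n}")

    @property
    def n(self):
        return self.y.size

    @property
    def p(self):
        return self.X.shape[1]

    @property
    def q(self):
        return self.Z.shape[1]


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the hierarchical prior.

    delta0 ~ IG(r0/2, s0_sq/2); tau_j ~ IG(r_tau/2, s_tau_sq/2) for
    j = 0..q; k_j ~ Poisson(poisson_mean) truncated at max_knots;
    xi_j | k_j ordered-uniform on (a_j, b_j); beta | tau0 ~ N(0, tau0 I);
    gamma_j | tau_j ~ N(0, tau_j I); rho ~ Uniform over the spectral support.
    """

    r0: float = 1.0
    s0_sq: float = 1.0
    r_tau: float = 1.0
    s_tau_sq: float = 0.005
    poisson_mean: float = 5.0

    def __post_init__(self):
        for name in ("r0", "s0_sq", "r_tau", "s_tau_sq", "poisson_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


@dataclass
class ChainState:
    """Full parameter and latent state at one MCMC iteration."""

    rho: float
    beta: np.ndarray  # (p,)
    delta0: float
    tau0: float
    splines: list  # q SplineStates
    e: np.ndarray  # (n,) positive latent mixing variables
    sigma_rho: float = 0.1  # MH proposal scales (tuning)
    sigma_move: np.ndarray = field(default_factory=lambda: np.array([]))

    def validate(self, weights=None):
        if self.delta0 <= 0 or self.tau0 <= 0:
            raise ValueError("delta0 and tau0 must be positive")
        if np.any(self.e <= 0):
            raise ValueError("latent e must be positive")
        if weights is not None and not (weights.rho_lower < self.rho < weights.rho_upper):
            raise ValueError("rho outside the spectral support")
        for s in self.splines:
            if s.tau <= 0:
                raise ValueError("spline tau must be positive")

    def copy(self):
        return ChainState(
            rho=self.rho,
            beta=self.beta.copy(),
            delta0=self.delta0,
            tau0=self.tau0,
            splines=[s.copy() for s in self.splines],
            e=self.e.copy(),
            sigma_rho=self.sigma_rho,
            sigma_move=np.asarray(self.sigma_move, dtype=float).copy(),
        )


def augmented_loglik(state, data, configs, tau):
    """Log of the augmented likelihood at a chain state.

    log|I - rho W| - (1/2) sum_i log(m2 delta0 e_i)
    - (1/2) r' E^{-1} r,  r = A(rho) y - X beta - D gamma - m1 e.
    """
    qc = QuantileConstants.from_tau(tau)
    wm = data.weights
    if not (wm.rho_lower < state.rho < wm.rho_upper):
        raise ValueError("rho outside the spectral support")
    D, _ = build_design(data.Z, data.U, configs, state.splines)
    gamma = np.concatenate([s.gamma for s in state.splines]) if state.splines else np.zeros(0)
    y_tilde = data.y - state.rho * wm.lag(data.y)
    r = y_tilde - data.X @ state.beta - D @ gamma - qc.m1 * state.e
    evar = qc.m2 * state.delta0 * state.e
    return float(wm.log_det(state.rho) - 0.5 * np.log(evar).sum() - 0.5 * np.sum(r * r / evar))


def residual_targets(state, data, configs, tau):
    """The partial-residual vectors used by the conditional updates.

    Returns a dict with ``y_tilde`` = A(rho) y (the rho-filtered response),
    ``y_hat`` = y_tilde - m1 e - D gamma (target of the beta update), and
    ``y_star`` = [y_tilde - X beta - m1 e - D_{-j} gamma_{-j}]_j (targets of
    the per-block knot/coefficient updates).
    """
    qc = QuantileConstants.from_tau(tau)
    wm = data.weights
    y_tilde = data.y - state.rho * wm.lag(data.y)
    D, blocks = build_design(data.Z, data.U, configs, state.splines)
    gamma = np.concatenate([s.gamma for s in state.splines]) if state.splines else np.zeros(0)
    fitted_spline = D @ gamma
    y_hat = y_tilde - qc.m1 * state.e - fitted_spline
    y_star = []
    for j, blk in enumerate(blocks):
        fit_j = D[:, blk] @ state.splines[j].gamma
        y_star.append(y_tilde - data.X @ state.beta - qc.m1 * state.e - (fitted_spline - fit_j))
    return {"y_tilde": y_tilde, "y_hat": y_hat, "y_star": y_star}


class QuantileSAR:
    """Bayesian quantile regression for the partially linear
    varying-coefficient spatial autoregressive model.

    Parameters
    ----------
    y : array_like, shape (n,)
        Response.
    X : array_like, shape (n, p) or None
        Linear covariates (no intercept is added automatically).
    Z : array_like, shape (n, q)
        Covariates entering through varying coefficients alpha_j(u).
    U : array_like, shape (n,) or (n, q)
        Smoothing variable(s); a single column is shared across all j.
    weights : WeightMatrix
        Spatial weight matrix (row-normalized in all benchmark designs).
    tau : float
        Quantile level in (0, 1).
    priors : Priors, optional
    spline_degree : int
        Degree of the free-knot B-splines (quadratic by default).
    max_knots : int
        Cap on the interior-knot count per coefficient.

    Examples
    --------
    >>> from sarqr import QuantileSAR, simulate
    >>> design = simulate.eq21_design(n=100, rho=0.5, tau=0.5)
    >>> data, truth = simulate.generate(design, rng=1)
    >>> model = QuantileSAR(data.y, data.X, data.Z, data.U, data.weights, tau=0.5)
    >>> res = model.fit(n_iter=6000, n_burn=3000, seed=1)
    >>> res.summary()  # doctest: +SKIP
    """

    def __init__(self, y, X, Z, U, weights, tau=0.5, priors=None,
                 spline_degree=2, max_knots=20, knot_poisson_mean=None):
        self.data = Dataset(y=y, X=X, Z=Z, U=U, weights=weights)
        if not 0 < tau < 1:
            raise ValueError(f"tau must lie in (0, 1), got {tau}")
        self.tau = float(tau)
        self.priors = priors or Priors()
        lam = knot_poisson_mean if knot_poisson_mean is not None else self.priors.poisson_mean
        self.configs = [
            SplineConfig(
                lower=float(self.data.U[:, j].min()),
                upper=float(self.data.U[:, j].max()),
                degree=spline_degree,
                poisson_mean=lam,
                max_knots=max_knots,
            )
            for j in range(self.data.q)
        ]

    @classmethod
    def from_dataframe(cls, df, weights, tau=0.5, y_col="y", x_cols=None,
                       z_cols=None, u_cols=None, **kwargs):
        """Build the model from a DataFrame with columns y, x1..xp, z1..zq, u (or u1..uq)."""
        df = pd.DataFrame(df)
        if x_cols is None:
            x_cols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                            key=lambda c: int(c[1:]))
        if z_cols is None:
            z_cols = sorted((c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
                            key=lambda c: int(c[1:]))
        if u_cols is None:
            if "u" in df.columns:
                u_cols = ["u"]
            else:
                u_cols = sorted((c for c in df.columns if c.startswith("u") and c[1:].isdigit()),
                                key=lambda c: int(c[1:]))
        missing = [c for c in [y_col, *x_cols, *z_cols, *u_cols] if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        if not z_cols:
            raise ValueError("at least one varying-coefficient column z1.. is required")
        U = df[u_cols].to_numpy()
        if U.shape[1] == 1:
            U = U[:, 0]
        return cls(df[y_col].to_numpy(), df[x_cols].to_numpy() if x_cols else None,
                   df[z_cols].to_numpy(), U, weights, tau=tau, **kwargs)

    def loglike(self, state):
        """Augmented log-likelihood at a ChainState."""
        return augmented_loglik(state, self.data, self.configs, self.tau)

    def fit(self, n_iter=6000, n_burn=3000, n_chains=1, seed=None, thin=1,
            adapt=True, target_accept=0.25, ngrid=100, monitor_points=10,
            store_splines=False, init=None):
        """Run the Metropolis–Hastings-within-Gibbs sampler.

        Returns a :class:`~sarqr.results.QuantileSARResults` with the retained
        post-burn-in draws of all chains, acceptance diagnostics, and fitted
        varying-coefficient curves.
        """
        from .results import QuantileSARResults
        from .sampler import run_chain

        if n_burn >= n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        seq = np.random.SeedSequence(seed)
        chains = [
            run_chain(
                self, n_iter=n_iter, n_burn=n_burn, seed_seq=child, thin=thin,
                adapt=adapt, target_accept=target_accept, ngrid=ngrid,
                monitor_points=monitor_points, store_splines=store_splines, init=init,
            )
            for child in seq.spawn(n_chains)
        ]
        return QuantileSARResults(self, chains)
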