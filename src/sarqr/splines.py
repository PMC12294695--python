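"""Free-knot B-spline bases for varying coefficients.

Each varying coefficient alpha_j(u) is approximated by a polynomial B-spline
of degree ``t_j`` with a random number ``k_j`` of interior knots at random
ordered positions ``xi_j``: alpha_j(u) = B_j(u)' gamma_j with
K_j = 1 + t_j + k_j basis functions.  The boundary knots are the observed
min/max of the smoothing variable.  The combined regression block for the
varying-coefficient part is the horizontal concatenation of the z_j-scaled
basis matrices, D(z, u) = [z_1 * B_1(u_1), ..., z_q * B_q(u_q)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineConfig", "SplineState", "basis_matrix", "build_design", "evaluate_alpha"]


@dataclass(frozen=True)
class SplineConfig:
    """Static configuration of one free-knot spline block.

    Parameters
    ----------
    lower, upper : float
        Boundary knots a_j < b_j (observed range of the smoothing variable).
    degree : int
        Polynomial degree t_j >= 1 (quadratic by default).
    poisson_mean : float
        Prior mean lambda_j of the Poisson law on the interior-knot count.
    max_knots : int
        Cap on k_j; guards against singular design blocks.
    min_knot_gap : float or None
        Minimal spacing between interior knots (and to the boundaries);
        defaults to (b_j - a_j) / 200.
    """

    lower: float
    upper: float
    degree: int = 2
    poisson_mean: float = 5.0
    max_knots: int = 20
    min_knot_gap: float | None = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper}]")
        if self.degree < 1:
            raise ValueError(f"spline degree must be >= 1, got {self.degree}")
        if self.max_knots < 0:
            raise ValueError("max_knots must be >= 0")
        if self.min_knot_gap is None:
            object.__setattr__(self, "min_knot_gap", (self.upper - self.lower) / 200.0)

    @property
    def span(self):
        return self.upper - self.lower

    def n_basis(self, n_knots):
        return 1 + self.degree + n_knots

    def knot_vector(self, interior):
        """Full (clamped) knot vector for the given interior knots."""
        d = self.degree
        return np.concatenate(
            [np.full(d + 1, self.lower), np.asarray(interior, dtype=float), np.full(d + 1, self.upper)]
        )

    def validate_knots(self, interior, min_gap=None):
        """True if interior knots are strictly inside, ordered, and gap-separated."""
        xi = np.asarray(interior, dtype=float)
        if xi.size == 0:
            return True
        gap = self.min_knot_gap if min_gap is None else min_gap
        aug = np.concatenate([[self.lower], xi, [self.upper]])
        return bool(np.all(np.diff(aug) >= gap))


@dataclass
class SplineState:
    """Sampled state of one varying coefficient: knots, coefficients, variance."""

    knots: np.ndarray  # ordered interior knots xi_j, possibly empty
    gamma: np.ndarray  # spline coefficients, length 1 + degree + len(knots)
    tau: float  # prior variance of gamma entries

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.knots.size and np.any(np.diff(self.knots) <= 0):
            raise ValueError("interior knots must be strictly increasing")

    @property
    def n_knots(self):
        return self.knots.size

    @property
    def n_basis(self):
        return self.gamma.size

    def copy(self):
        return SplineState(self.knots.copy(), self.gamma.copy(), self.tau)


def basis_matrix(u, config, interior_knots=()):
    """Dense n x K_j matrix of B-spline basis evaluations at the points ``u``.

    Rows form a partition of unity; entries lie in [0, 1].  Points outside
    [lower, upper] are rejected (the boundary knots are the data range).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    tol = 1e-10 * max(1.0, abs(config.lower), abs(config.upper))
    if u.min() < config.lower - tol or u.max() > config.upper + tol:
        raise ValueError(
            f"evaluation points outside the boundary knots "
            f"[{config.lower}, {config.upper}]"
        )
    u = np.clip(u, config.lower, config.upper)
    t = config.knot_vector(interior_knots)
    return BSpline.design_matrix(u, t, config.degree, extrapolate=False).toarray()


def build_design(Z, U, configs, states):
    """Assemble D(z, u): horizontally stacked z_j-scaled basis blocks.

    Parameters
    ----------
    Z : (n, q) array
        Varying-coefficient covariates.
    U : (n,) or (n, q) array
        Smoothing variable(s); a single column is shared across all j.
    configs, states : sequences of length q

    Returns
    -------
    D : (n, K_1 + ... + K_q) array
    blocks : list of slice
        Column ranges of each block D_j, for per-j extraction.
    """
    Z = np.asarray(Z, dtype=float)
    U = np.asarray(U, dtype=float)
    n, q = Z.shape
    if U.ndim == 1:
        U = np.repeat(U[:, None], q, axis=1)
    if U.shape[0] != n:
        raise ValueError(f"Z has {n} rows but U has {U.shape[0]}")
    if len(configs) != q or len(states) != q:
        raise ValueError("need one SplineConfig and SplineState per column of Z")
    mats, blocks, start = [], [], 0
    for j in range(q):
        B = basis_matrix(U[:, j], configs[j], states[j].knots)
        mats.append(Z[:, j : j + 1] * B)
        blocks.append(slice(start, start + B.shape[1]))
        start += B.shape[1]
    return np.hstack(mats), blocks


def evaluate_alpha(grid, state, config):
    """Fitted varying-coefficient values B_j(grid) @ gamma_j."""
    return basis_matrix(grid, config, state.knots) @ state.gamma
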