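"""Spatial weight matrices for spatial-lag (SAR-type) models.

A :class:`WeightMatrix` wraps an n x n array of prespecified spatial weights
``w_ij`` (zero diagonal), caches the spectrum of the matrix actually handed to
the sampler, and derives from it the admissible interval for the spatial
autocorrelation coefficient rho, ``(1/lambda_min, 1/lambda_max)``.  The cached
eigenvalues also make the log-determinant ``log|I - rho W|`` an O(n) operation
inside MCMC loops, and give O(n) scalar summaries of ``(I - rho W)^{-1}`` for
the direct/indirect/total effect decomposition.

Constructors cover the standard benchmark designs: rook contiguity on a square
lattice, the Case block (district) matrix, a row-normalized AR-decay band
matrix ``base^|i-j|``, and a negative-exponential distance kernel on (lon, lat)
coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

__all__ = [
    "WeightMatrix",
    "build_rook_lattice",
    "build_case_blocks",
    "build_ar_decay",
    "build_distance_kernel",
    "build_weights",
    "save_weights",
    "load_weights",
]

_ROW_SUM_TOL = 1e-12


class WeightMatrix:
    """An n x n spatial weight matrix with cached spectral information.

    Parameters
    ----------
    W : ndarray
        Square weight matrix with zero diagonal.
    row_normalized : bool
        Whether rows with at least one neighbor sum to one.
    meta : dict, optional
        Constructor name and parameters, for provenance round-trips.
    """

    def __init__(self, W, row_normalized=False, meta=None):
        W = np.asarray(W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        if np.any(np.abs(np.diag(W)) > 0):
            raise ValueError("weight matrix must have a zero diagonal (w_ii = 0)")
        if row_normalized:
            sums = W.sum(axis=1)
            nonzero = sums > 0
            if np.any(np.abs(sums[nonzero] - 1.0) > 1e-8):
                raise ValueError("row_normalized=True but row sums differ from 1")
        self.W = W
        self.row_normalized = bool(row_normalized)
        self.meta = dict(meta or {})
        self._eigenvalues = np.linalg.eigvals(W)
        self._effects_cache = None
        lam_re = self._eigenvalues.real
        lam_max = lam_re.max()
        lam_min = lam_re.min()
        # degenerate spectra (e.g. a zero matrix) leave the support unbounded
        # on that side; the sampler requires finite bounds and checks there
        if lam_max > 1e-12:
            self.rho_upper = 1.0 if (row_normalized and abs(lam_max - 1) < 1e-9) else 1.0 / lam_max
        else:
            self.rho_upper = np.inf
        self.rho_lower = 1.0 / lam_min if lam_min < -1e-12 else -np.inf

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self):
        return self.W.shape[0]

    @property
    def eigenvalues(self):
        return self._eigenvalues

    def __repr__(self):
        kind = self.meta.get("constructor", "custom")
        return (
            f"WeightMatrix(n={self.n}, constructor={kind!r}, "
            f"rho support=({self.rho_lower:.4f}, {self.rho_upper:.4f}))"
        )

    # -- spectral operations ----------------------------------------------
    def log_det(self, rho):
        """log|I - rho W| from the cached eigenvalues, sum_i log|1 - rho lambda_i|."""
        if not (self.rho_lower < rho < self.rho_upper):
            raise ValueError(
                f"rho={rho} outside the admissible interval "
                f"({self.rho_lower:.6g}, {self.rho_upper:.6g})"
            )
        return float(np.log(np.abs(1.0 - rho * self._eigenvalues)).sum())

    def lag(self, y):
        """The spatial lag W @ y."""
        return self.W @ np.asarray(y, dtype=float)

    def _effects_coefs(self):
        # Eigendecomposition-based O(n) summaries of M(rho) = (I - rho W)^{-1}:
        # mean diag(M) = (1/n) sum_k 1/(1-rho lam_k)   (since sum_i V_ik Vinv_ki = 1)
        # mean rowsum(M) = (1/n) sum_k d_k/(1-rho lam_k), d_k = (1'V)_k (Vinv 1)_k
        if self._effects_cache is None:
            lam, V = np.linalg.eig(self.W)
            Vinv = np.linalg.inv(V)
            one = np.ones(self.n)
            d = (one @ V) * (Vinv @ one)
            # sanity: the decomposition must reconstruct W
            if not np.allclose((V * lam) @ Vinv, self.W, atol=1e-8):
                self._effects_cache = (None, None)
            else:
                self._effects_cache = (lam, d)
        return self._effects_cache

    def mean_diag_inv(self, rho):
        """Mean diagonal entry of (I - rho W)^{-1} (per-unit direct multiplier)."""
        lam, _ = self._effects_coefs()
        if lam is None:
            M = np.linalg.inv(np.eye(self.n) - rho * self.W)
            return float(np.trace(M) / self.n)
        return float(np.mean((1.0 / (1.0 - rho * lam)).real))

    def mean_total_inv(self, rho, kind="row"):
        """Mean row (or column) sum of (I - rho W)^{-1} (total-effect multiplier).

        The two conventions coincide once averaged: both equal (1'M1)/n.
        """
        if kind not in ("row", "column"):
            raise ValueError("kind must be 'row' or 'column'")
        lam, d = self._effects_coefs()
        if lam is None:
            M = np.linalg.inv(np.eye(self.n) - rho * self.W)
            return float(M.sum() / self.n)
        return float(np.mean((d / (1.0 - rho * lam)).real))


def _row_normalize(W):
    sums = W.sum(axis=1, keepdims=True)
    out = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
    return out


def build_rook_lattice(n):
    """Row-normalized rook contiguity on an s x s square lattice (n = s^2).

    Units are laid out row-major; neighbors are the up/down/left/right cells.
    """
    s = int(round(np.sqrt(n)))
    if s < 2 or s * s != n:
        raise ValueError(f"rook lattice requires n = s^2 with integer s >= 2, got n={n}")
    W = np.zeros((n, n))
    for i in range(s):
        for j in range(s):
            k = i * s + j
            if i > 0:
                W[k, k - s] = 1.0
            if i < s - 1:
                W[k, k + s] = 1.0
            if j > 0:
                W[k, k - 1] = 1.0
            if j < s - 1:
                W[k, k + 1] = 1.0
    W = _row_normalize(W)
    return WeightMatrix(W, row_normalized=True, meta={"constructor": "rook", "n": n})


def build_case_blocks(r, m):
    """Case district matrix: r blocks of m members, within-block weights 1/(m-1)."""
    if m < 2:
        raise ValueError(f"case blocks require m >= 2 members per district, got m={m}")
    if r < 1:
        raise ValueError(f"case blocks require r >= 1 districts, got r={r}")
    block = (np.ones((m, m)) - np.eye(m)) / (m - 1)
    W = np.kron(np.eye(r), block)
    return WeightMatrix(W, row_normalized=True, meta={"constructor": "case", "r": r, "m": m})


def build_ar_decay(n, base=0.3):
    """Row-normalized band matrix w_ij = base^|i-j| (i != j), diagonal zeroed."""
    if n < 2:
        raise ValueError(f"ar_decay requires n >= 2, got n={n}")
    if not (0 < base < 1):
        raise ValueError(f"ar_decay base must lie in (0, 1), got {base}")
    idx = np.arange(n)
    W = base ** np.abs(idx[:, None] - idx[None, :])
    np.fill_diagonal(W, 0.0)
    W = _row_normalize(W)
    return WeightMatrix(W, row_normalized=True, meta={"constructor": "ar_decay", "n": n, "base": base})


def build_distance_kernel(coords):
    """Negative-exponential Euclidean distance kernel on (lon, lat) coordinates.

    w_ij = exp(-||s_i - s_j||) / sum_{k != i} exp(-||s_i - s_k||)
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an n x 2 array of (lon, lat)")
    n = coords.shape[0]
    if n < 2:
        raise ValueError(f"distance kernel requires n >= 2 locations, got n={n}")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    W = np.exp(-dist)
    np.fill_diagonal(W, 0.0)
    W = _row_normalize(W)
    return WeightMatrix(W, row_normalized=True, meta={"constructor": "distance_kernel", "n": n})


_CONSTRUCTORS = {
    "rook": build_rook_lattice,
    "case": build_case_blocks,
    "ar_decay": build_ar_decay,
    "distance_kernel": build_distance_kernel,
}


def build_weights(name, **params):
    """Dispatch to a named constructor: rook | case | ar_decay | distance_kernel."""
    if name not in _CONSTRUCTORS:
        raise ValueError(f"unknown weight constructor {name!r}; options: {sorted(_CONSTRUCTORS)}")
    return _CONSTRUCTORS[name](**params)


def save_weights(wm, path, fmt=None):
    """Write a WeightMatrix as dense CSV or Matrix Market, plus a JSON sidecar."""
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "csv")
    if fmt == "csv":
        np.savetxt(path, wm.W, delimiter=",")
    elif fmt == "mtx":
        mmwrite(str(path), csr_matrix(wm.W))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"row_normalized": wm.row_normalized, **wm.meta}, indent=1)
    )
    return path


def load_weights(path):
    """Read a weight matrix written by :func:`save_weights` (CSV or MTX)."""
    path = Path(path)
    if path.suffix == ".mtx":
        M = mmread(str(path))
        W = M.toarray() if hasattr(M, "toarray") else np.asarray(M)
    else:
        W = np.loadtxt(path, delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    row_normalized = False
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        row_normalized = bool(meta.pop("row_normalized", False))
    return WeightMatrix(W, row_normalized=row_normalized, meta=meta)
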