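"""File I/O glue: dataset CSV schema, run configuration, fit directories.

Dataset CSV contract: columns ``y``, ``x1..xp`` (optional), ``z1..zq``
(required), ``u`` or ``u1..uq``, and optional ``lon``/``lat`` coordinate
columns for distance-kernel weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Dataset
from .weights import build_weights, load_weights

__all__ = ["RunConfig", "read_dataset_csv", "write_dataset_csv", "resolve_weights"]


@dataclass
class RunConfig:
    """Self-describing run configuration (YAML round-trippable)."""

    tau: float = 0.5
    n_iter: int = 6000
    n_burn: int = 3000
    n_chains: int = 1
    seed: int = 0
    thin: int = 1
    r0: float = 1.0
    s0_sq: float = 1.0
    r_tau: float = 1.0
    s_tau_sq: float = 0.005
    knot_poisson_mean: float = 5.0
    spline_degree: int = 2
    max_knots: int = 20
    target_accept: float = 0.25
    weights: dict = field(default_factory=dict)  # {"constructor": ..., params} or {"file": path}
    outdir: str = "sarqr_fit"

    def __post_init__(self):
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def manifest(self):
        return asdict(self)


def _numbered(df, prefix):
    cols = [c for c in df.columns if c.startswith(prefix) and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def read_dataset_csv(path, weights):
    """Load a dataset CSV against the schema, reporting missing columns by name."""
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise ValueError("missing required column(s): y")
    z_cols = _numbered(df, "z")
    if not z_cols:
        raise ValueError("missing required column(s): z1 (at least one z column)")
    x_cols = _numbered(df, "x")
    u_cols = ["u"] if "u" in df.columns else _numbered(df, "u")
    if not u_cols:
        raise ValueError("missing required column(s): u (or u1..uq)")
    U = df[u_cols].to_numpy()
    if U.shape[1] == 1:
        U = U[:, 0]
    data = Dataset(
        y=df["y"].to_numpy(),
        X=df[x_cols].to_numpy() if x_cols else None,
        Z=df[z_cols].to_numpy(),
        U=U,
        weights=weights,
    )
    return data, df


def write_dataset_csv(data, path):
    from .simulate import to_frame

    to_frame(data).to_csv(path, index=False)
    return Path(path)


def resolve_weights(spec, n=None, df=None):
    """Turn a weights spec into a WeightMatrix.

    ``spec`` is a dict with either ``file`` (CSV/MTX path) or ``constructor``
    plus parameters; the constructor ``distance_kernel`` pulls lon/lat from
    the dataset frame.
    """
    spec = dict(spec or {})
    if "file" in spec:
        return load_weights(spec["file"])
    name = spec.pop("constructor", None)
    if name is None:
        raise ValueError("weights spec needs a 'constructor' or 'file' entry")
    if name == "distance_kernel":
        if "coords" in spec:
            return build_weights(name, coords=np.asarray(spec["coords"], dtype=float))
        if df is None or not {"lon", "lat"} <= set(df.columns):
            raise ValueError("distance_kernel weights need lon/lat columns in the dataset")
        return build_weights(name, coords=df[["lon", "lat"]].to_numpy())
    if name in ("rook", "ar_decay") and "n" not in spec:
        spec["n"] = n
    return build_weights(name, **spec)


def write_manifest(outdir, config, extra=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": config.manifest(), **(extra or {})}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1))
    return outdir / "manifest.json"
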