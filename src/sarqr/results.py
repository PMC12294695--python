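"""Results container for fitted quantile spatial-lag models."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .summary import gelman_rubin, marginal_effects, summarize

__all__ = ["QuantileSARResults"]


class QuantileSARResults:
    """Posterior draws and diagnostics from one or more chains.

    Draw accessors (``rho``, ``beta``, ``delta0``...) pool the retained
    post-burn-in draws of all chains; per-chain arrays remain available in
    ``.chains`` for convergence diagnostics.
    """

    def __init__(self, model, chains):
        if not chains:
            raise ValueError("no chains supplied")
        self.model = model
        self.chains = chains

    # -- pooled draw accessors --------------------------------------------
    def _pool(self, key):
        return np.concatenate([c[key] for c in self.chains], axis=0)

    @property
    def n_chains(self):
        return len(self.chains)

    @property
    def rho(self):
        return self._pool("rho")

    @property
    def beta(self):
        return self._pool("beta")

    @property
    def delta0(self):
        return self._pool("delta0")

    @property
    def tau(self):
        return self._pool("tau")

    @property
    def tau0(self):
        return self._pool("tau0")

    @property
    def n_knots(self):
        return self._pool("k")

    def alpha_draws(self, j, monitor=False):
        key = "alpha_monitor" if monitor else "alpha"
        return np.concatenate([c[key][j] for c in self.chains], axis=0)

    def alpha_grid(self, j, monitor=False):
        return self.chains[0]["monitor_grids" if monitor else "grids"][j]

    @property
    def acceptance(self):
        """Post-burn-in acceptance summaries, averaged over chains."""
        keys = self.chains[0]["acceptance"].keys()
        out = {}
        for k in keys:
            acc = sum(c["acceptance"][k]["accepted"] for c in self.chains)
            tot = sum(c["acceptance"][k]["proposed"] for c in self.chains)
            out[k] = {"accepted": acc, "proposed": tot, "rate": acc / max(tot, 1)}
        return out

    # -- fitted curves -----------------------------------------------------
    def alpha_mean(self, j):
        return self.alpha_draws(j).mean(axis=0)

    def alpha_band(self, j, level=0.95):
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        draws = self.alpha_draws(j)
        return np.quantile(draws, lo, axis=0), np.quantile(draws, hi, axis=0)

    def alpha_table(self, j, level=0.95):
        """Fitted curve export: grid, posterior mean, lower/upper band."""
        lo, hi = self.alpha_band(j, level)
        return pd.DataFrame({
            "u": self.alpha_grid(j),
            "mean": self.alpha_mean(j),
            "lower": lo,
            "upper": hi,
        })

    def made(self, truth_fns):
        """Mean absolute deviation error of each fitted coefficient curve on
        its evaluation grid, plus the global (across-j) average."""
        from .simulate import made as _made

        fitted = [self.alpha_mean(j) for j in range(self.model.data.q)]
        truth = [np.asarray(f(self.alpha_grid(j)) if callable(f) else f, dtype=float)
                 for j, f in enumerate(truth_fns)]
        return _made(fitted, truth)

    # -- summaries ---------------------------------------------------------
    def _scalar_draws(self, include_effects=True):
        d = {"rho": self.rho}
        for jj in range(self.model.data.p):
            d[f"beta{jj + 1}"] = self.beta[:, jj]
        d["delta0"] = self.delta0
        if include_effects and self.model.data.p:
            eff = self.marginal_effects()
            for name, frame in eff.items():
                d[f"total_{name}"] = frame["total"].to_numpy()
                d[f"direct_{name}"] = frame["direct"].to_numpy()
                d[f"indirect_{name}"] = frame["indirect"].to_numpy()
        return d

    def summary(self, level=0.95, include_effects=True):
        """Posterior Mean / SE / credible-interval table for the model
        parameters and (optionally) the effect decomposition."""
        return summarize(self._scalar_draws(include_effects), level=level)

    def marginal_effects(self, kind="row"):
        return marginal_effects(
            self.rho, self.beta, self.model.data.weights,
            names=[f"x{j + 1}" for j in range(self.model.data.p)], kind=kind,
        )

    def monitored_chains(self):
        """Per-chain draw matrices for every monitored scalar: rho, beta,
        delta0, and each fitted coefficient curve at the monitor grid."""
        out = {"rho": np.stack([c["rho"] for c in self.chains])}
        for jj in range(self.model.data.p):
            out[f"beta{jj + 1}"] = np.stack([c["beta"][:, jj] for c in self.chains])
        out["delta0"] = np.stack([c["delta0"] for c in self.chains])
        for j in range(self.model.data.q):
            grid = self.alpha_grid(j, monitor=True)
            for g in range(len(grid)):
                out[f"alpha{j + 1}@u={grid[g]:.3g}"] = np.stack(
                    [c["alpha_monitor"][j][:, g] for c in self.chains]
                )
        return out

    def gelman_rubin(self):
        """Classic PSRF per monitored scalar (requires >= 2 chains)."""
        if self.n_chains < 2:
            raise ValueError("Gelman–Rubin diagnostics require at least two chains")
        return pd.Series({k: gelman_rubin(v) for k, v in self.monitored_chains().items()},
                         name="rhat")

    # -- persistence and plotting ------------------------------------------
    def save(self, outdir):
        """Persist draws as CSV + JSON-lines with a metadata manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = []
        for ci, c in enumerate(self.chains):
            df = pd.DataFrame({"chain": ci, "rho": c["rho"], "delta0": c["delta0"],
                               "tau0": c["tau0"]})
            for jj in range(self.model.data.p):
                df[f"beta{jj + 1}"] = c["beta"][:, jj]
            for j in range(self.model.data.q):
                df[f"tau{j + 1}"] = c["tau"][:, j]
                df[f"k{j + 1}"] = c["k"][:, j]
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(outdir / "draws.csv", index=False)
        for j in range(self.model.data.q):
            self.alpha_table(j).to_csv(outdir / f"alpha{j + 1}.csv", index=False)
        if "splines" in self.chains[0]:
            with open(outdir / "splines.jsonl", "w") as fh:
                for c in self.chains:
                    for rec in c["splines"]:
                        fh.write(json.dumps(rec) + "\n")
        meta = {
            "tau": self.model.tau,
            "n_chains": self.n_chains,
            "n_iter": self.chains[0]["n_iter"],
            "n_burn": self.chains[0]["n_burn"],
            "thin": self.chains[0]["thin"],
            "acceptance": self.acceptance,
            "tuning": [c["tuning"] for c in self.chains],
            "seeds": [c["seed_state"] for c in self.chains],
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
        return outdir

    def plot_alpha(self, j, truth=None, ax=None):
        """Fitted coefficient curve with 95% pointwise band (optional truth overlay)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.alpha_grid(j)
        lo, hi = self.alpha_band(j)
        ax.fill_between(grid, lo, hi, alpha=0.25, label="95% band")
        ax.plot(grid, self.alpha_mean(j), label="posterior mean")
        if truth is not None:
            ax.plot(grid, truth(grid) if callable(truth) else truth, "k--", label="truth")
        ax.set_xlabel("u")
        ax.set_ylabel(f"alpha_{j + 1}(u)")
        ax.legend()
        return ax
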