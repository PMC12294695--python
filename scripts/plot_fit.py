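#!/usr/bin/env python
"""Plot the fitted varying-coefficient curves of a saved fit directory.

Usage: python scripts/plot_fit.py FITDIR [--out curves.png]
Reads the alpha*.csv tables written by `sarqr fit` and draws each posterior
mean curve with its 95% pointwise band.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("fitdir", type=Path)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()
    tables = sorted(args.fitdir.glob("alpha*.csv"))
    if not tables:
        raise SystemExit(f"no alpha*.csv curve tables found in {args.fitdir}")
    fig, axes = plt.subplots(1, len(tables), figsize=(5 * len(tables), 4), squeeze=False)
    for ax, path in zip(axes[0], tables):
        df = pd.read_csv(path)
        ax.fill_between(df["u"], df["lower"], df["upper"], alpha=0.25, label="95% band")
        ax.plot(df["u"], df["mean"], label="posterior mean")
        ax.set_xlabel("u")
        ax.set_title(path.stem)
        ax.legend()
    out = args.out or args.fitdir / "curves.png"
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
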