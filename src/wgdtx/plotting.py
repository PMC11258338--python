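"""Simple figure exports: volcano plot of the DGE results and KM curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_volcano", "plot_km"]


def plot_volcano(records: pd.DataFrame, path, *, coef=1.5, alpha=0.05) -> None:
    """WGD coefficient vs -log10 adjusted p, significant genes highlighted."""
    ok = records[records["fit_status"] == "ok"]
    logp = -np.log10(np.maximum(ok["p_adj"].to_numpy(), 1e-300))
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = ok["significant"].to_numpy()
    ax.scatter(ok.loc[~sig, "coef_wgd"], logp[~sig], s=5, c="0.7", lw=0)
    ax.scatter(ok.loc[sig, "coef_wgd"], logp[sig], s=7, c="crimson", lw=0)
    ax.axhline(-np.log10(alpha), ls=":", c="0.4")
    for x in (-coef, coef):
        ax.axvline(x, ls=":", c="0.4")
    ax.set_xlabel("WGD coefficient (log2 expression)")
    ax.set_ylabel(r"$-\log_{10}$ adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km(curves: dict[str, pd.DataFrame], path) -> None:
    """Step-function survival curves, one line per WGD timing group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in sorted(curves.items()):
        ax.step(
            curve["time"], curve["survival"], where="post",
            label=f"{group} (n={int(curve['n_at_risk'].iloc[0])})",
        )
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
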