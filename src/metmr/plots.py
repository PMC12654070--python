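"""Optional presentational plots (volcano and forest), never required.

Both take a combined result table (the columns written by
:func:`metmr.gwas_io.write_results`) and save one panel per outcome.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def volcano(results: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """MR beta (log-odds per 1-SD exposure) vs −log₁₀ p, one panel per outcome."""
    outcomes = sorted(results["outcome"].unique())
    fig, axes = plt.subplots(1, max(len(outcomes), 1), figsize=(4 * len(outcomes), 4))
    axes = np.atleast_1d(axes)
    for ax, outcome in zip(axes, outcomes):
        df = results[results["outcome"] == outcome]
        sig = df["pval"] < alpha
        ax.scatter(df.loc[~sig, "beta"], -np.log10(df.loc[~sig, "pval"]),
                   s=12, c="grey", alpha=0.6)
        ax.scatter(df.loc[sig, "beta"], -np.log10(df.loc[sig, "pval"]),
                   s=16, c="crimson")
        ax.axvline(0.0, ls="--", lw=0.8, c="k")
        ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
        ax.set_xlabel("MR beta (log-OR per 1-SD)")
        ax.set_ylabel("-log10(p)")
        ax.set_title(outcome)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def forest(results: pd.DataFrame, path: str | Path, max_rows: int = 40) -> None:
    """OR per 1-SD with 95% CI, strongest rows first (n_snv = 1 throughout)."""
    df = results.sort_values("pval").head(max_rows).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(df) + 1.5))
    y = np.arange(len(df))
    ax.errorbar(
        df["OR"], y,
        xerr=[df["OR"] - df["CI_low"], df["CI_high"] - df["OR"]],
        fmt="o", ms=4, lw=1, capsize=2, color="navy",
    )
    ax.axvline(1.0, ls="--", lw=0.8, c="k")
    ax.set_yticks(y)
    ax.set_yticklabels(df["metabolite"] + " / " + df["outcome"], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("OR per 1-SD (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
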