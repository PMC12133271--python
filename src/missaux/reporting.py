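"""Figures and tabular exports for grid results.

The headline figure mirrors the study's summary view: a panel per
(outcome mechanism, auxiliary mechanism) pair, auxiliary missingness
proportion on the x-axis, MI bias relative to CRA (%) on the y-axis, one
line per corr(Y,Z) level, a dashed reference at 100% (bias equal to CRA),
and Monte-Carlo-error ribbons.  Panels where the CRA bias is within Monte
Carlo noise of zero (the relative scale is then meaningless — e.g. the
unbiased-CRA outcome mechanism) fall back to absolute bias with a labelled
axis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_relative_bias"]


def _panel(ax, sub: pd.DataFrame) -> None:
    mi = sub[sub["model"] == "mi_incl"]
    flagged = bool(mi["cra_bias_near_zero"].any())
    for rho, grp in mi.groupby("rho_yz"):
        grp = grp.sort_values("pi_z")
        if flagged:
            yvals = grp["bias"]
            err = 1.96 * grp["mcse_bias"]
        else:
            yvals = grp["rel_bias_vs_cra_pct"]
            # delta-method MC error of the ratio, denominator treated fixed
            cra_bias = grp["bias"] / (grp["rel_bias_vs_cra_pct"] / 100.0)
            err = 196.0 * grp["mcse_bias"] / cra_bias.abs()
        ax.plot(grp["pi_z"], yvals, marker="o", ms=2.5, lw=1.0, label=f"{rho:g}")
        ax.fill_between(grp["pi_z"], yvals - err, yvals + err, alpha=0.15)
    if flagged:
        ax.axhline(0.0, color="gray", lw=0.8, ls=":")
        ax.set_ylabel("absolute bias")
    else:
        ax.axhline(100.0, color="black", lw=0.8, ls="--")
        ax.set_ylabel("bias relative to CRA (%)")


def plot_relative_bias(metrics: pd.DataFrame, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write the bias-relative-to-CRA grid figure; returns the file path."""
    required = {"outcome_mech", "aux_mech", "rho_yz", "pi_z", "model", "bias",
                "mcse_bias", "rel_bias_vs_cra_pct", "cra_bias_near_zero"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks required columns: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    oms = sorted(metrics["outcome_mech"].unique())
    ams = sorted(metrics["aux_mech"].unique())
    fig, axes = plt.subplots(
        len(oms), len(ams), figsize=(3.4 * len(ams), 2.8 * len(oms)),
        squeeze=False, sharex=True,
    )
    for i, om in enumerate(oms):
        for j, am in enumerate(ams):
            ax = axes[i][j]
            sub = metrics[(metrics["outcome_mech"] == om) & (metrics["aux_mech"] == am)]
            if sub.empty:
                ax.set_axis_off()
                continue
            _panel(ax, sub)
            ax.set_title(f"outcome mech {om}, aux mech {am}", fontsize=9)
            if i == len(oms) - 1:
                ax.set_xlabel("proportion of missing auxiliary data")
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, title="corr(Y,Z)", loc="lower center",
                   ncol=len(labels), fontsize=8)
    fig.tight_layout(rect=(0, 0.05, 1, 1))
    path = out_dir / f"bias_relative_to_cra.{fmt}"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
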