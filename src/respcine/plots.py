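"""Regression figures: volumes vs estimated tidal volume, and SVi vs EDVi."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_METRICS = ("edvi", "esvi", "svi", "ef_pct")
_GROUP_COLORS = {"rv_overload": "tab:blue", "control": "tab:green"}


def _group_of(subject: str) -> str:
    return "rv_overload" if subject.startswith("rv_overload") else "control"


def plot_tv_regressions(volumes: pd.DataFrame, path: str | Path) -> None:
    """2x4 panel of per-class mean volumes against class TVi, one row per
    respiratory phase, both ventricles overlaid."""
    fig, axes = plt.subplots(2, 4, figsize=(16, 7), sharex=True)
    for row, phase in enumerate(("inspiration", "expiration")):
        for col, metric in enumerate(_METRICS):
            ax = axes[row][col]
            sel = volumes[(volumes["resp_phase"] == phase) & (~volumes["excluded"])]
            for (ventricle, subject), sub in sel.groupby(["ventricle", "subject"]):
                color = _GROUP_COLORS.get(_group_of(subject), "gray")
                style = "-" if ventricle == "RV" else "--"
                ax.plot(sub["tvi"], sub[metric], style, color=color, alpha=0.4, lw=1)
            ax.set_title(f"{metric} ({phase})", fontsize=9)
            if row == 1:
                ax.set_xlabel("class TVi (ml/cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_starling(volumes: pd.DataFrame, path: str | Path) -> None:
    """SVi against EDVi per subject and ventricle (Frank-Starling panels)."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for ax, ventricle in zip(axes, ("RV", "LV")):
        sel = volumes[(volumes["ventricle"] == ventricle) & (~volumes["excluded"])]
        for subject, sub in sel.groupby("subject"):
            color = _GROUP_COLORS.get(_group_of(subject), "gray")
            sub = sub.sort_values("edvi")
            ax.plot(sub["edvi"], sub["svi"], "o-", color=color, alpha=0.5, ms=3, lw=1)
        ax.set_xlabel(f"{ventricle}-EDVi (ml/m$^2$)")
        ax.set_ylabel(f"{ventricle}-SVi (ml/m$^2$)")
        ax.set_title(f"{ventricle} Frank-Starling")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
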