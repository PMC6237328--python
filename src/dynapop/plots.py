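"""Diagnostic plots: within-disease risk proportions and comorbidity
ratios against age, initial population versus newborn cohort."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .ratetable import SEXES

_MARKERS = {"male": "o", "female": "^"}


def plot_risk_within_disease(
    initial: pd.DataFrame, newborn: pd.DataFrame, disease: str, out_path
) -> Path:
    """One panel per risk state: proportion of the diseased in that risk
    class by age, initial (red) vs newborn cohort (green)."""
    states = list(initial["risk_state"].unique())
    fig, axes = plt.subplots(1, len(states), figsize=(4 * len(states), 3.2), sharey=True)
    if len(states) == 1:
        axes = [axes]
    for ax, state in zip(axes, states):
        for label, table, color in (("initial", initial, "tab:red"),
                                    ("newborns", newborn, "tab:green")):
            sub = table[(table["disease"] == disease) & (table["risk_state"] == state)]
            for sex in SEXES:
                ss = sub[sub["sex"] == sex]
                ax.plot(ss["age"], ss["proportion"], color=color,
                        marker=_MARKERS[sex], markersize=2, linewidth=0.8,
                        label=f"{label}, {sex}")
        ax.set_title(state)
        ax.set_xlabel("age")
    axes[0].set_ylabel(f"proportion of {disease} cases")
    axes[0].legend(fontsize=6)
    fig.suptitle(disease)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_comorbidity(
    initial: pd.DataFrame, newborn: pd.DataFrame, pair: tuple[str, str], out_path
) -> Path:
    """Comorbidity ratio by age and sex for one disease pair."""
    a, b = pair
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, table, color in (("initial", initial, "tab:red"),
                                ("newborns", newborn, "tab:green")):
        sub = table[(table["disease_a"] == a) & (table["disease_b"] == b)]
        for sex in SEXES:
            ss = sub[sub["sex"] == sex]
            ax.plot(ss["age"], ss["ratio"], color=color, marker=_MARKERS[sex],
                    markersize=2, linewidth=0.8, label=f"{label}, {sex}")
    ax.axhline(1.0, color="grey", linewidth=0.6)
    ax.set_xlabel("age")
    ax.set_ylabel(f"comorbidity ratio {a} & {b}")
    ax.legend(fontsize=6)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
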