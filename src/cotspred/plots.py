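"""Optional figures: detection-decay curve and regional predation boxes."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .edna import DecayFit
from .predation import ConsumptionRates, _transect_totals

__all__ = ["plot_detection_decay", "plot_regional_predation"]


def plot_detection_decay(trials: pd.DataFrame, fit: DecayFit, path) -> None:
    """Fitted decay curve over the observed per-time detection fractions."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    obs = trials.groupby("hours_post_ingestion")["detected"].agg(["mean", "size"])
    ax.scatter(obs.index, obs["mean"], s=20 * obs["size"], zorder=3,
               color="tab:blue", label="observed")
    t = np.linspace(0.5, max(48.0, float(obs.index.max())), 200)
    ax.plot(t, fit.predict(t), color="tab:red", label="logistic fit")
    ax.set_xlabel("hours post-ingestion")
    ax.set_ylabel("P(detect CoTS DNA)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regional_predation(
    transects: pd.DataFrame, path, rates: ConsumptionRates | None = None
) -> None:
    """Box plots of per-transect potential predation totals by region."""
    rates = rates if rates is not None else ConsumptionRates()
    totals = _transect_totals(transects, rates)
    regions = list(dict.fromkeys(transects["region"]))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.boxplot(
        [totals[transects["region"] == r] for r in regions],
        tick_labels=regions, whis=(0, 100),
    )
    ax.set_ylabel("potential predation (ind. 100 m$^{-2}$ d$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
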