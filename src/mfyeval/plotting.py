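"""Observed-vs-predicted scatter with per-herd and overall regressions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from mfyeval.stats import grouped_regression


def plot_observed_vs_predicted(predictions: pd.DataFrame, out_path, title: str = ""):
    """One panel per DMI source: points coloured by herd, thin per-herd
    regression lines, bold black overall regression line."""
    sources = list(pd.unique(predictions["dmi_source"]))
    fig, axes = plt.subplots(
        len(sources), 1, figsize=(6, 4.5 * len(sources)), squeeze=False
    )
    for ax, source in zip(axes.ravel(), sources):
        sub = predictions[predictions["dmi_source"] == source]
        obs = sub["mfy_obs_g_d"].to_numpy()
        pred = sub["mfy_pred_g_d"].to_numpy()
        herds = sub["herd_id"].to_numpy()
        cmap = plt.get_cmap("tab20")
        herd_list = sorted(pd.unique(herds), key=str)
        for i, herd in enumerate(herd_list):
            m = herds == herd
            ax.scatter(pred[m], obs[m], s=8, color=cmap(i % 20), alpha=0.6)
        (slope, intercept), fits = grouped_regression(obs, pred, herds)
        xs = np.linspace(pred.min(), pred.max(), 2)
        for i, fit in enumerate(fits):
            if not fit.flagged:
                ax.plot(
                    xs, fit.intercept + fit.slope * xs,
                    color=cmap(i % 20), lw=0.8, alpha=0.7,
                )
        ax.plot(xs, intercept + slope * xs, color="black", lw=2.2)
        ax.set_xlabel("Predicted milk fat yield, g/d")
        ax.set_ylabel("Observed milk fat yield, g/d")
        ax.set_title(f"{title} DMI: {source}".strip())
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
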