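"""Scatter plots for clock evaluation and GAA."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .robust import RobustFit

__all__ = ["plot_predicted_vs_clinical", "plot_gaa"]


def plot_predicted_vs_clinical(obs, pred, fit: RobustFit | None = None, path=None,
                               title: str = "Predicted vs clinical GA"):
    """Predicted GA against clinical GA with identity and robust-fit lines."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(obs, pred, s=12, alpha=0.6, edgecolors="none")
    lims = [min(obs.min(), pred.min()) - 2, max(obs.max(), pred.max()) + 2]
    ax.plot(lims, lims, color="red", lw=1, label="identity")
    if fit is not None:
        xs = np.linspace(obs.min(), obs.max(), 50)
        ax.plot(xs, fit.predict(xs), color="black", lw=1, label="MM robust fit")
    ax.set_xlabel("Clinical GA (days)")
    ax.set_ylabel("Predicted GA (days)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_gaa(clinical, gaa, group=None, path=None):
    """GAA residuals against clinical GA, optionally coloured by group."""
    clinical = np.asarray(clinical, float)
    gaa = np.asarray(gaa, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if group is None:
        ax.scatter(clinical, gaa, s=12, alpha=0.6, edgecolors="none")
    else:
        group = np.asarray(group).astype(bool)
        ax.scatter(clinical[~group], gaa[~group], s=12, alpha=0.6,
                   edgecolors="none", color="red", label="non-ART")
        ax.scatter(clinical[group], gaa[group], s=12, alpha=0.6,
                   edgecolors="none", color="black", label="ART")
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Clinical GA (days)")
    ax.set_ylabel("GAA (days)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
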