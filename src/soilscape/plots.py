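"""Diagnostic figures: empirical + fitted variograms and partition bars."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .geostat import EmpiricalVariogram, VariogramModel

__all__ = ["plot_variogram", "plot_varpart"]


def plot_variogram(emp: EmpiricalVariogram, model: VariogramModel | None = None,
                   path=None, title: str = ""):
    """Empirical variogram points with the fitted model curve overlaid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = emp.counts > 0
    ax.plot(emp.bin_centers[ok], emp.gamma[ok], "o", color="k", ms=4,
            label="empirical")
    if model is not None:
        h = np.linspace(1e-6, emp.max_lag, 200)
        ax.plot(h, model.semivariance(h), "-", color="C3", label="fitted model")
    ax.set_xlabel("lag distance h (m)")
    ax.set_ylabel("semivariance γ(h)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_varpart(results: dict, path=None):
    """Stacked bars of unique and shared adjusted-R² fractions per response.

    `results` maps response name -> VarPartResult.
    """
    names = list(results)
    keys = ["soil", "management", "space", "soil_management",
            "soil_space", "management_space", "soil_management_space"]
    labels = ["soil", "management", "space", "soil∩mgmt", "soil∩space",
              "mgmt∩space", "all shared"]
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 2, 4))
    bottoms = np.zeros(len(names))
    for key, lab in zip(keys, labels):
        vals = np.array([max(results[n].fractions[key], 0.0) for n in names])
        ax.bar(names, 100 * vals, bottom=100 * bottoms, label=lab)
        bottoms += vals
    ax.set_ylabel("explained variance (adjusted R², %)")
    ax.legend(fontsize=8, frameon=False, bbox_to_anchor=(1.02, 1),
              loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
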