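"""Optional diagnostic plots (PNG); content is informational only."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def scatter_observed_predicted(observed, predicted, path: str | Path) -> Path:
    """Observed vs predicted biomass with the 1:1 line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(observed, predicted, s=18, alpha=0.7, edgecolor="none")
    lims = [min(np.min(observed), np.min(predicted)), max(np.max(observed), np.max(predicted))]
    ax.plot(lims, lims, "k--", lw=1, label="1:1")
    ax.set_xlabel("observed biomass (kg m$^{-2}$)")
    ax.set_ylabel("predicted biomass (kg m$^{-2}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return Path(path)


def residual_plot(observed, predicted, path: str | Path) -> Path:
    """Residuals (observed - predicted) against predicted values."""
    r = np.asarray(observed, float) - np.asarray(predicted, float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(predicted, r, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(0.0, color="r", ls="--", lw=1)
    ax.set_xlabel("predicted biomass (kg m$^{-2}$)")
    ax.set_ylabel("residual (kg m$^{-2}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return Path(path)
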