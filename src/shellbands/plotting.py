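"""Plots: band-ribbon projection along the last whorl.

The projection plot unrolls the last whorl: the x-axis is the distance
travelled by the aperture along the final turn, the y-axis the position on
the suture-to-umbilicus arc (percent), and each band is drawn as a shaded
ribbon between its start and end fractions at each station.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .helicospiral import ShellParams
from .banding import BandConfig, band_sectors, region_widths
from .helicospiral import visible_arc


def plot_band_projection(
    params: ShellParams,
    bands: BandConfig,
    path: str | Path,
    n_samples: int = 80,
):
    """Band ribbons versus distance along the last whorl (PNG or SVG)."""
    two_pi = 2.0 * math.pi
    thetas = np.linspace(params.theta_max - two_pi, params.theta_max, n_samples)
    # arc distance travelled by the aperture centre along the whorl
    dist = np.concatenate(
        [[0.0], np.cumsum(params.r(thetas[1:]) * np.diff(thetas))]
    )
    sectors = band_sectors(params, bands)
    fig, ax = plt.subplots(figsize=(7, 4))
    cmap = plt.get_cmap("tab10")
    for b, (phi_a, phi_b) in zip(bands.bands, sectors):
        top, bottom = [], []
        for th in thetas:
            arc = visible_arc(params, th)
            top.append(float(arc.fraction_at_phi(phi_a)) * 100.0)
            bottom.append(float(arc.fraction_at_phi(phi_b)) * 100.0)
        ax.fill_between(dist, top, bottom, color=cmap(b.index - 1), alpha=0.7,
                        label=f"band {b.index}")
    ax.set_xlabel("distance along last whorl (mm)")
    ax.set_ylabel("position on suture-umbilicus arc (%)")
    ax.set_ylim(100, 0)  # suture at the top, like the shell
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
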