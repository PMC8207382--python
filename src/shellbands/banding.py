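"""Band placement on the growing aperture and region-growth extraction.

A band is a pigmented stripe of the shell.  On the measurement arc from
the suture (fraction 0) to the umbilicus (fraction 1) a band occupies the
interval ``[p - w/2, p + w/2]`` where ``p`` is its midpoint position and
``w`` its width, both as fractions of the arc.  Bands are *material-fixed*:
their arc fractions at a reference station (by default the lip) are mapped
to aperture angles once, and those angles then travel with the generating
curve for every earlier station.  Any change in the relative width of a
region along the whorl therefore emerges purely from the geometry of the
helicospiral (drift of the suture/umbilicus endpoints under allometry),
not from band-specific growth.

With B bands the arc is partitioned into ``2B + 1`` ordered regions::

    gap 1 | band 1 | gap 2 | band 2 | ... | band B | gap B+1

where gap 1 adjoins the suture and gap B+1 the umbilicus.  Region widths
are evaluated at five stations spaced a quarter whorl apart ending at the
lip, emulating the physical protocol of sawing the last whorl off in 90
degree increments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .helicospiral import ShellParams, visible_arc, whorl_increments

__all__ = [
    "Band",
    "BandConfig",
    "RegionProfile",
    "band_sectors",
    "region_widths",
    "region_profile",
    "growth_rates",
    "allometry_increments",
    "region_names",
]

TWO_PI = 2.0 * math.pi
N_STATIONS = 5


@dataclass(frozen=True)
class Band:
    """One band on the suture-to-umbilicus arc.

    ``index`` counts 1-5 from the suture downward; ``position_frac`` and
    ``width_frac`` are the midpoint and width as fractions of the arc.
    ``pigmented=False`` models hyalozonate bands (structurally present,
    unpigmented).
    """

    index: int
    position_frac: float
    width_frac: float
    pigmented: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.position_frac < 1.0:
            raise ValueError(f"band {self.index}: position must be in (0, 1)")
        if self.width_frac <= 0.0:
            raise ValueError(f"band {self.index}: width must be positive")
        if self.start <= 0.0 or self.end >= 1.0:
            raise ValueError(
                f"band {self.index}: interval [{self.start:.4f}, {self.end:.4f}] "
                "must lie strictly inside (0, 1)"
            )

    @property
    def start(self) -> float:
        return self.position_frac - 0.5 * self.width_frac

    @property
    def end(self) -> float:
        return self.position_frac + 0.5 * self.width_frac


@dataclass(frozen=True)
class BandConfig:
    """Ordered set of bands plus optional fusion groups.

    ``fusion_groups`` lists sets of adjacent band indices that are fused on
    the shell; fused bands form a single region and are excluded from
    band-level statistics.
    """

    bands: tuple[Band, ...]
    fusion_groups: tuple[frozenset[int], ...] = ()

    def __init__(self, bands: Iterable[Band], fusion_groups: Iterable[Iterable[int]] = ()):
        bands = tuple(sorted(bands, key=lambda b: b.position_frac))
        groups = tuple(frozenset(g) for g in fusion_groups)
        fused = set().union(*groups) if groups else set()
        for b1, b2 in zip(bands, bands[1:]):
            both_fused = b1.index in fused and b2.index in fused
            if b1.end > b2.start and not both_fused:
                raise ValueError(
                    f"bands {b1.index} and {b2.index} overlap and are not fused"
                )
        for g in groups:
            idx = sorted(g)
            if len(idx) < 2 or idx != list(range(idx[0], idx[-1] + 1)):
                raise ValueError(f"fusion group {idx} must contain >=2 adjacent bands")
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "fusion_groups", groups)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def n_regions(self) -> int:
        return 2 * len(self.bands) + 1


def region_names(n_bands: int) -> list[str]:
    """Names of the ``2B + 1`` regions from the suture downward."""
    names = []
    for i in range(n_bands):
        names.append(f"gap{i + 1}")
        names.append(f"band{i + 1}")
    names.append(f"gap{n_bands + 1}")
    return names


@dataclass
class RegionProfile:
    """Region widths (mm) at the five quarter-whorl stations.

    ``stations`` holds the coiling angles in increasing order, the last one
    being the lip; ``widths`` is an array of shape (5, 2B+1) with columns
    ordered gap1, band1, gap2, ..., bandB, gapB+1.
    """

    stations: np.ndarray  # (5,)
    widths: np.ndarray  # (5, 2B+1)
    names: list[str]
    shell_id: str = "shell"

    @property
    def fractions(self) -> np.ndarray:
        """Widths normalized per station (rows sum to 1)."""
        return self.widths / self.widths.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: shell_id, station, region, width_mm."""
        rows = []
        for k, theta in enumerate(self.stations):
            for name, w in zip(self.names, self.widths[k]):
                rows.append((self.shell_id, k, name, w))
        return pd.DataFrame(rows, columns=["shell_id", "station", "region", "width_mm"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionProfile":
        names = list(dict.fromkeys(frame["region"]))
        stations = np.sort(frame["station"].unique()).astype(float)
        widths = (
            frame.pivot_table(index="station", columns="region", values="width_mm")
            .loc[:, names]
            .to_numpy()
        )
        shell_id = str(frame["shell_id"].iloc[0])
        return cls(stations=stations, widths=widths, names=names, shell_id=shell_id)


def band_sectors(
    params: ShellParams,
    bands: BandConfig,
    theta_ref: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Aperture-angle sectors of each band, anchored at the reference station.

    Maps each band's arc-fraction interval through the visible arc at
    ``theta_ref`` (the lip by default) to ``(phi_start, phi_end)`` pairs.
    These angles are fixed on the generating curve for all stations.
    """
    if theta_ref is None:
        theta_ref = params.theta_max
    arc = visible_arc(params, theta_ref)
    sectors = []
    for band in bands.bands:
        phi_start = float(arc.phi_at_fraction(band.start))
        phi_end = float(arc.phi_at_fraction(band.end))
        sectors.append((phi_start, phi_end))
    return sectors


def region_widths(
    params: ShellParams,
    bands: BandConfig,
    theta: float,
    theta_ref: Optional[float] = None,
) -> np.ndarray:
    """Widths (mm) of the 2B+1 regions at coiling angle *theta*.

    Band sectors are anchored at ``theta_ref`` (lip by default); at *theta*
    each region is the intersection of its angular interval with the
    visible arc, scaled by the aperture radius.  The outermost gaps are
    clipped by the suture/umbilicus endpoints, so the widths always sum to
    the visible-arc length.
    """
    sectors = band_sectors(params, bands, theta_ref)
    arc = visible_arc(params, theta)
    # keep endpoints on the same unwrap branch as the anchored sectors
    ref = sectors[0][0] if sectors else 0.0
    lo = arc.phi_suture + TWO_PI * np.round((ref - arc.phi_suture) / TWO_PI)
    hi = lo + arc.span

    bounds = [-np.inf]
    for phi_start, phi_end in sectors:
        bounds.extend([phi_start, phi_end])
    bounds.append(np.inf)

    a = float(params.a(theta))
    widths = np.empty(len(bounds) - 1)
    for i in range(len(bounds) - 1):
        start = max(bounds[i], lo)
        end = min(bounds[i + 1], hi)
        widths[i] = a * max(0.0, end - start)
    return widths


def region_profile(
    params: ShellParams,
    bands: BandConfig,
    lip: Optional[float] = None,
    shell_id: str = "shell",
) -> RegionProfile:
    """Region widths at the five quarter-whorl stations of the last whorl.

    Stations sit at ``lip - k*pi/2`` for k = 4..0, mirroring the physical
    sectioning of one whorl in 90 degree increments.  The earliest station
    still needs a previous whorl, so the model must span at least two
    whorls before the lip.
    """
    if lip is None:
        lip = params.theta_max
    if lip - TWO_PI < TWO_PI:
        raise ValueError(
            "region profile needs lip >= 4*pi: one whorl of stations, each "
            "with a previous whorl above it"
        )
    stations = np.array([lip - (N_STATIONS - 1 - k) * (math.pi / 2) for k in range(N_STATIONS)])
    widths = np.vstack([region_widths(params, bands, th, theta_ref=lip) for th in stations])
    return RegionProfile(
        stations=stations,
        widths=widths,
        names=region_names(len(bands)),
        shell_id=shell_id,
    )


def growth_rates(profile: RegionProfile) -> pd.DataFrame:
    """Per-region growth rates between consecutive quarter-whorl stations.

    The rate is the log-ratio ``ln(width_{k+1} / width_k)`` per quarter
    whorl; for an isometric shell every rate equals ``g_a * pi/2`` exactly.
    Regions with a non-positive width at any station are flagged missing
    (NaN rates) rather than raising.  The absolute increment per step is
    also reported for comparison.
    """
    w = profile.widths
    n_steps = w.shape[0] - 1
    ok = np.all(w > 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.log(w[1:] / w[:-1])
    rates[:, ~ok] = np.nan
    increments = w[1:] - w[:-1]
    rows = []
    for j, name in enumerate(profile.names):
        for k in range(n_steps):
            rows.append(
                (
                    profile.shell_id,
                    name,
                    k,
                    rates[k, j],
                    increments[k, j],
                    not ok[j],
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["shell_id", "region", "step", "rate", "increment_mm", "missing"],
    )
    return frame


def mean_region_rates(profile: RegionProfile) -> pd.Series:
    """Mean log-ratio growth rate per region (NaN for flagged regions)."""
    rates = growth_rates(profile)
    return rates.groupby("region", sort=False)["rate"].mean()


def allometry_increments(fits: Sequence[ShellParams]) -> pd.DataFrame:
    """Whorl height/width increments at the lip for a set of fitted shells.

    One row per shell with ``delta_height`` and ``delta_width`` (mm); the
    paired differences feed a one-sided Wilcoxon signed-rank test of
    height increase exceeding width increase (convex-spire allometry).
    """
    if len(fits) == 0:
        raise ValueError("need at least one fitted shell")
    rows = []
    for i, p in enumerate(fits):
        dh, dw = whorl_increments(p, p.theta_max)
        rows.append((i, dh, dw))
    return pd.DataFrame(rows, columns=["shell", "delta_height", "delta_width"])
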