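"""Spectral marker points: detection, binning and fit to discrimination optima.

A marker point is the wavelength of a sharp transition in a reflectance
spectrum.  The detector reconstructs the behaviour of the published settings:
the spectrum is smoothed with a centred moving-average window, the slope is
measured by a forward difference over a small look-ahead, local maxima of the
absolute slope become candidates, and a candidate survives only if the
reflectance range within a window around it reaches a minimum amplitude.
Surviving candidates closer together than half the amplitude window are
merged, keeping the steeper one.

Fit metrics against pollinator discrimination optima (400 and 500 nm for
bees): MAD is the mean distance of a spectrum's marker points to their
nearest optimum (an all-pairs variant is available); minAD is the minimum
distance of any marker point to one specific optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "MarkerSettings",
    "MarkerPointSet",
    "DiscriminationOptima",
    "BEE_OPTIMA",
    "EmptyMarkerSetError",
    "detect_marker_points",
    "bin_marker_points",
    "min_abs_deviation",
    "mean_abs_deviation",
    "metrics_table",
]


class EmptyMarkerSetError(ValueError):
    """Raised when a fit metric is requested for a spectrum without marker points."""


@dataclass(frozen=True)
class MarkerSettings:
    """Detector settings.

    min_change is in reflectance percentage points (absolute change, the
    default reading of the published ">= 10 %" criterion); set
    ``relative_change=True`` to gate on 10 % relative change instead.
    window_nm is the wavelength span of the amplitude criterion;
    smooth_halfwidth and lookahead are in grid points.
    """

    min_change: float = 10.0
    window_nm: float = 50.0
    smooth_halfwidth: int = 10
    lookahead: int = 5
    relative_change: bool = False

    def __post_init__(self) -> None:
        if self.min_change <= 0 or self.window_nm <= 0:
            raise ValueError("min_change and window_nm must be positive")
        if self.smooth_halfwidth < 1 or self.lookahead < 1:
            raise ValueError("smooth_halfwidth and lookahead must be >= 1")


@dataclass
class MarkerPointSet:
    """Detected marker points for one spectrum (possibly none)."""

    label: str
    points: np.ndarray
    settings: MarkerSettings = field(default_factory=MarkerSettings)

    def __post_init__(self) -> None:
        self.points = np.sort(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0


@dataclass(frozen=True)
class DiscriminationOptima:
    """Wavelengths of best colour discrimination for a pollinator taxon."""

    wavelengths: tuple[float, ...]
    taxon: str = ""

    def __post_init__(self) -> None:
        for w in self.wavelengths:
            if not 300.0 <= w <= 700.0:
                raise ValueError(f"optimum {w} nm outside 300-700 nm")


#: Honeybee hue-discrimination optima (nm).
BEE_OPTIMA = DiscriminationOptima((400.0, 500.0), taxon="hymenoptera")


def _moving_average(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centred moving mean with windows truncated at the spectrum edges."""
    n = len(values)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detect_marker_points(
    s: Spectrum, cfg: MarkerSettings | None = None
) -> MarkerPointSet:
    """Detect marker points (sharp reflectance transitions) in one spectrum.

    The reported wavelength of a candidate is the midpoint of its forward
    slope interval, which keeps symmetric transitions centred on their
    inflection.
    """
    cfg = cfg or MarkerSettings()
    wl = s.grid.wavelengths
    step = s.grid.step_nm
    n = len(wl)
    if n <= 2 * cfg.smooth_halfwidth + cfg.lookahead:
        raise ValueError("spectrum shorter than the smoothing window")

    smoothed = _moving_average(s.reflectance, cfg.smooth_halfwidth)
    k = cfg.lookahead
    slope = (smoothed[k:] - smoothed[:-k]) / (k * step)
    slope_wl = wl[:-k] + k * step / 2.0  # midpoint of the forward interval
    mag = np.abs(slope)

    # strict interior local maxima of |slope|, with a numerical floor
    interior = np.arange(1, len(mag) - 1)
    is_max = (mag[interior] > mag[interior - 1]) & (mag[interior] >= mag[interior + 1])
    cand = interior[is_max & (mag[interior] > 1e-9)]

    half = cfg.window_nm / 2.0
    accepted: list[tuple[float, float]] = []
    for i in cand:
        centre = slope_wl[i]
        in_win = (wl >= centre - half) & (wl <= centre + half)
        window_vals = smoothed[in_win]
        amp = float(window_vals.max() - window_vals.min())
        if cfg.relative_change:
            lo = float(window_vals.min())
            ok = lo > 0 and amp / lo >= cfg.min_change / 100.0
        else:
            ok = amp >= cfg.min_change
        if ok:
            accepted.append((centre, mag[i]))

    # merge accepted candidates closer than window_nm / 2, keeping the steeper
    merged: list[float] = []
    cluster: list[tuple[float, float]] = []
    for centre, strength in accepted:
        if cluster and centre - cluster[-1][0] < half:
            cluster.append((centre, strength))
        else:
            if cluster:
                merged.append(max(cluster, key=lambda cs: cs[1])[0])
            cluster = [(centre, strength)]
    if cluster:
        merged.append(max(cluster, key=lambda cs: cs[1])[0])

    return MarkerPointSet(s.label, np.array(merged), cfg)


def bin_marker_points(
    marker_sets: Iterable[MarkerPointSet],
    binwidth: float = 10.0,
    start_nm: float = 300.0,
    stop_nm: float = 700.0,
) -> pd.DataFrame:
    """Relative frequency of marker points in half-open wavelength bins.

    Frequencies are relative to the total number of points pooled over the
    non-empty sets and sum to 1; an input without any marker points yields an
    empty table.
    """
    span = stop_nm - start_nm
    if abs(span / binwidth - round(span / binwidth)) > 1e-9:
        raise ValueError(f"binwidth {binwidth} does not divide the {span} nm span")
    points = np.concatenate([m.points for m in marker_sets] or [np.array([])])
    if len(points) == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count", "rel_freq"])
    edges = np.arange(start_nm, stop_nm + binwidth / 2, binwidth)
    counts, _ = np.histogram(points, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "rel_freq": counts / counts.sum(),
        }
    )


def min_abs_deviation(mps: MarkerPointSet, optimum: float) -> float:
    """minAD: distance from the closest marker point to one optimum (nm)."""
    if mps.is_empty:
        raise EmptyMarkerSetError(
            f"'{mps.label}': no marker points; minAD is undefined and the "
            "spectrum is excluded from fit-metric summaries"
        )
    return float(np.min(np.abs(mps.points - optimum)))


def mean_abs_deviation(
    mps: MarkerPointSet,
    optima: DiscriminationOptima | Sequence[float],
    method: str = "nearest",
) -> float:
    """MAD: mean distance of marker points to the discrimination optima (nm).

    ``method="nearest"`` (default) averages each point's distance to its
    nearest optimum; ``method="all_pairs"`` averages over every point-optimum
    pair.
    """
    if mps.is_empty:
        raise EmptyMarkerSetError(
            f"'{mps.label}': no marker points; MAD is undefined"
        )
    opts = np.asarray(
        optima.wavelengths if isinstance(optima, DiscriminationOptima) else optima,
        dtype=float,
    )
    dists = np.abs(mps.points[:, None] - opts[None, :])
    if method == "nearest":
        return float(dists.min(axis=1).mean())
    if method == "all_pairs":
        return float(dists.mean())
    raise ValueError(f"unknown method {method!r}")


def metrics_table(
    marker_sets: Iterable[MarkerPointSet],
    optima: DiscriminationOptima = BEE_OPTIMA,
    method: str = "nearest",
) -> tuple[pd.DataFrame, list[str]]:
    """MAD/minAD table for many spectra, plus the excluded (no-point) labels.

    Returns a DataFrame with columns ``label, n_points, MAD, minAD_<w>...``
    (one minAD column per optimum) and the list of labels whose spectra
    produced no marker points and are therefore excluded.
    """
    rows = []
    excluded: list[str] = []
    for mps in marker_sets:
        if mps.is_empty:
            excluded.append(mps.label)
            continue
        row = {
            "label": mps.label,
            "n_points": len(mps),
            "MAD": mean_abs_deviation(mps, optima, method=method),
        }
        for w in optima.wavelengths:
            row[f"minAD_{w:.0f}"] = min_abs_deviation(mps, w)
        rows.append(row)
    return pd.DataFrame(rows), excluded
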