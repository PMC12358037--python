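"""Reflectance spectra: containers, I/O, smoothing, correction, aggregation.

Reflectance is stored internally on a percent scale (0--100), the convention
of FReD-style exports.  Readers auto-detect 0--1 scaled files (maximum value
at or below 1.5) and rescale, logging the decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .grid import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectra",
    "write_spectra",
    "smooth_spectrum",
    "fix_negative",
    "aggregate_spectra",
]

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """A single reflectance spectrum on a shared wavelength grid.

    Attributes
    ----------
    grid : WavelengthGrid
        Wavelength axis the values live on.
    reflectance : ndarray
        Percent reflectance (0--100 scale nominally; values may be negative
        before :func:`fix_negative` is applied).
    label : str
        Sample or species identifier.
    n_aggregated : int
        Number of raw samples averaged into this spectrum (>= 1).
    sd : ndarray or None
        Optional per-wavelength sample standard deviation.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    label: str = ""
    n_aggregated: int = 1
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (len(self.grid),):
            raise ValueError(
                f"spectrum '{self.label}': reflectance length "
                f"{self.reflectance.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError(f"spectrum '{self.label}': non-finite reflectance values")
        if self.n_aggregated < 1:
            raise ValueError("n_aggregated must be >= 1")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != (len(self.grid),):
                raise ValueError(f"spectrum '{self.label}': sd length mismatch")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one grid, with colour classes.

    ``group_labels`` maps each spectrum label to a colour-class name
    (e.g. ``green``, ``green_yellow``, ``blue_violet``).  Membership in the
    mapping is optional per spectrum; grouped operations act on the labelled
    subset.
    """

    spectra: list[Spectrum]
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectra:
            g = self.spectra[0].grid
            for s in self.spectra:
                if s.grid != g:
                    raise ValueError(
                        f"spectrum '{s.label}' is on a different grid than the set"
                    )
        unknown = set(self.group_labels) - {s.label for s in self.spectra}
        if unknown:
            raise ValueError(f"group_labels refer to absent spectra: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, label: str) -> Spectrum:
        for s in self.spectra:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def grid(self) -> WavelengthGrid:
        if not self.spectra:
            raise ValueError("empty SpectrumSet has no grid")
        return self.spectra[0].grid

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def group_of(self, label: str) -> str | None:
        return self.group_labels.get(label)

    def subset(self, labels: Iterable[str]) -> "SpectrumSet":
        keep = set(labels)
        return SpectrumSet(
            [s for s in self.spectra if s.label in keep],
            {k: v for k, v in self.group_labels.items() if k in keep},
        )

    def by_group(self) -> dict[str, "SpectrumSet"]:
        """Split the labelled subset into one SpectrumSet per colour class."""
        out: dict[str, SpectrumSet] = {}
        for cls in dict.fromkeys(self.group_labels.values()):
            members = [k for k, v in self.group_labels.items() if v == cls]
            out[cls] = self.subset(members)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: ``wavelength_nm`` column plus one column per label."""
        data = {"wavelength_nm": self.grid.wavelengths}
        for s in self.spectra:
            data[s.label] = s.reflectance
        return pd.DataFrame(data)

    def map(self, fn: Callable[[Spectrum], Spectrum]) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra], dict(self.group_labels))


def _detect_scale(values: np.ndarray, origin: str) -> np.ndarray:
    """Rescale 0--1 reflectance to percent when the data look fractional."""
    if np.nanmax(values) <= 1.5:
        logger.info(
            "%s: maximum reflectance <= 1.5, interpreting as 0-1 scale and "
            "rescaling to percent",
            origin,
        )
        return values * 100.0
    return values


def _resample(
    wl: np.ndarray, values: np.ndarray, grid: WavelengthGrid, origin: str
) -> np.ndarray:
    order = np.argsort(wl)
    wl, values = wl[order], values[order]
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{origin}: wavelength column is not strictly increasing")
    if wl[0] > grid.start_nm or wl[-1] < grid.stop_nm:
        raise ValueError(
            f"{origin}: wavelength coverage {wl[0]:g}-{wl[-1]:g} nm is narrower "
            f"than the analysis grid {grid.start_nm:g}-{grid.stop_nm:g} nm; "
            "extrapolation is refused"
        )
    return np.interp(grid.wavelengths, wl, values)


def read_spectra(
    path, dialect: str = "wide", grid: WavelengthGrid = DEFAULT_GRID
) -> SpectrumSet:
    """Read delimited-text spectra and resample onto the analysis grid.

    Two dialects are supported (comma/tab auto-detected):

    * ``long`` -- columns ``wavelength_nm, reflectance[, label]``, one row per
      wavelength per sample (FReD-style two-column export when the label
      column is absent).
    * ``wide`` -- first column ``wavelength_nm``, then one column per sample
      whose header is the sample label.

    Values outside the grid span are discarded; missing wavelengths inside it
    are filled by linear interpolation.  Coverage narrower than the grid is an
    error (no extrapolation).
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    origin = str(path)
    if df.shape[1] < 2:
        raise ValueError(f"{origin}: expected at least two columns")

    def _numeric(col: pd.Series, name: str) -> np.ndarray:
        out = pd.to_numeric(col, errors="coerce")
        bad = out.isna() & col.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{origin}: non-numeric value {col[row]!r} in column '{name}' "
                f"at data row {row}"
            )
        if out.isna().any():
            row = int(out.isna().idxmax())
            raise ValueError(f"{origin}: missing value in column '{name}' at row {row}")
        return out.to_numpy(dtype=float)

    spectra: list[Spectrum] = []
    if dialect == "long":
        wl_all = _numeric(df.iloc[:, 0], df.columns[0])
        refl_all = _numeric(df.iloc[:, 1], df.columns[1])
        refl_all = _detect_scale(refl_all, origin)
        labels = (
            df.iloc[:, 2].astype(str).to_numpy()
            if df.shape[1] >= 3
            else np.full(len(df), "sample")
        )
        for lab in dict.fromkeys(labels):
            m = labels == lab
            spectra.append(
                Spectrum(grid, _resample(wl_all[m], refl_all[m], grid, origin), str(lab))
            )
    else:
        wl = _numeric(df.iloc[:, 0], df.columns[0])
        for name in df.columns[1:]:
            vals = _detect_scale(_numeric(df[name], name), f"{origin}:{name}")
            spectra.append(Spectrum(grid, _resample(wl, vals, grid, origin), str(name)))
    return SpectrumSet(spectra)


def write_spectra(ss: SpectrumSet, path, sep: str = "\t") -> None:
    """Write a SpectrumSet in the wide dialect.

    Aggregated spectra carrying standard deviations get ``_mean``/``_sd``
    column suffixes.
    """
    data: dict[str, np.ndarray] = {"wavelength_nm": ss.grid.wavelengths}
    for s in ss:
        if s.sd is not None:
            data[f"{s.label}_mean"] = s.reflectance
            data[f"{s.label}_sd"] = s.sd
        else:
            data[s.label] = s.reflectance
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def smooth_spectrum(s: Spectrum, span: float = 0.20) -> Spectrum:
    """Smooth a spectrum with a local-regression (LOWESS) smoother.

    ``span`` is the fraction of the grid included in each local fit window
    (tricube-weighted locally linear regression, no robustness iterations).
    Constants and linear trends are preserved by construction.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    wl = s.grid.wavelengths
    smoothed = lowess(
        s.reflectance, wl, frac=span, it=0, return_sorted=False
    )
    return replace(s, reflectance=np.asarray(smoothed, dtype=float), sd=None)


def fix_negative(s: Spectrum) -> Spectrum:
    """Correct calibration artefacts by shifting the minimum up to zero.

    If the minimum reflectance is negative, its absolute value is added to
    every wavelength so the minimum becomes exactly 0; otherwise the spectrum
    is returned unchanged.  Rank order is preserved and the operation is
    idempotent.
    """
    mn = float(np.min(s.reflectance))
    if mn >= 0.0:
        return s
    return replace(s, reflectance=s.reflectance - mn)


def aggregate_spectra(
    ss: SpectrumSet,
    by: Mapping[str, str] | Callable[[str], str] | None = None,
) -> SpectrumSet:
    """Average replicate spectra into one mean (+/- sd) spectrum per group.

    ``by`` maps each spectrum label to its aggregation group (dict or
    callable); by default each distinct label forms its own group, so
    replicates sharing a label are pooled.  Groups holding a single spectrum
    pass through unchanged (preserving any existing ``sd``/``n_aggregated``),
    which makes aggregation idempotent.
    """
    if by is None:
        keyfn: Callable[[str], str] = lambda lab: lab
    elif callable(by):
        keyfn = by
    else:
        mapping = dict(by)
        keyfn = lambda lab: mapping.get(lab, lab)

    groups: dict[str, list[Spectrum]] = {}
    for s in ss:
        groups.setdefault(keyfn(s.label), []).append(s)

    out: list[Spectrum] = []
    new_groups: dict[str, str] = {}
    for key, members in groups.items():
        if len(members) == 1 and members[0].label == key:
            agg = members[0]
        else:
            stack = np.vstack([m.reflectance for m in members])
            n = sum(m.n_aggregated for m in members)
            sd = (
                stack.std(axis=0, ddof=1)
                if len(members) > 1
                else np.zeros(stack.shape[1])
            )
            agg = Spectrum(
                ss.grid, stack.mean(axis=0), label=key, n_aggregated=n, sd=sd
            )
        out.append(agg)
        classes = {ss.group_labels[m.label] for m in members if m.label in ss.group_labels}
        if len(classes) == 1:
            new_groups[key] = classes.pop()
    return SpectrumSet(out, new_groups)
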