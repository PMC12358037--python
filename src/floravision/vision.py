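"""Pollinator colour-vision models: receptor catches, bee hexagon, fly space.

The processing chain for a stimulus spectrum is

    quantum catch  ->  von Kries adaptation  ->  (hyperbolic transduction)
                   ->  colour-space locus    ->  chromatic / achromatic contrast

Two models are implemented:

* ``hexagon`` -- the trichromatic honeybee colour hexagon.  Relative catches
  are transduced hyperbolically (E = q / (q + 1), so the adapting background
  sits at E = 0.5) and projected into the plane; the hexagon is partitioned
  into six 60-degree hue sectors.
* ``fly_categorical`` -- the tetravariant blowfly (Lucilia-type) space built
  from the R7p/R7y/R8p/R8y receptor classes.  Relative catches are kept
  linear, normalised to unit sum, and combined into two opponent axes whose
  sign pair selects one of four categorical quadrants.

Chromatic contrast is the Euclidean distance (EU) of a locus from the
achromatic centre; achromatic (green) contrast is the deviation of the green
receptor's excitation from its adapted value 0.5 (bee model only).
Default discriminability thresholds: 0.11 EU (bee), 0.096 EU (fly); a
stimulus exactly at threshold counts as discriminable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import DEFAULT_GRID, WavelengthGrid
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "ReceptorSensitivity",
    "Illuminant",
    "ViewingContext",
    "ColourLocus",
    "ContrastResult",
    "visual_pigment_template",
    "make_receptor",
    "receptor_from_table",
    "quantum_catch",
    "adapt_von_kries",
    "excite_hyperbolic",
    "hexagon_locus",
    "fly_locus",
    "chromatic_contrast",
    "achromatic_contrast",
    "flag_discriminable",
    "bee_context",
    "fly_context",
    "spectrum_contrast",
    "analyse_set",
    "BEE_LAMBDA_MAX",
    "FLY_LAMBDA_MAX",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_FLY_QUADRANTS",
    "HEXAGON_SECTOR_CENTRES",
]

# Peak wavelengths (nm) of the default receptor sets.  Bee values follow the
# standard Apis mellifera trichromat (UV/blue/green); fly values follow the
# four Lucilia-type R7/R8 classes.  Both are editable conventions: tabulated
# curves can be supplied to reproduce any other sensitivity set, and all
# downstream numbers are sensitive to this choice.
BEE_LAMBDA_MAX: dict[str, float] = {"uv": 344.0, "blue": 436.0, "green": 544.0}
FLY_LAMBDA_MAX: dict[str, float] = {
    "R7p": 330.0,
    "R7y": 350.0,
    "R8p": 460.0,
    "R8y": 530.0,
}

DEFAULT_THRESHOLDS: dict[str, float] = {"hexagon": 0.11, "fly_categorical": 0.096}

# Sign pair (x >= 0, y >= 0) -> categorical fly colour.  The default places
# "yellow" in the quadrant reached by long-wavelength-dominant stimuli under
# the default curves (verified by a narrowband 580 nm smoke test).
DEFAULT_FLY_QUADRANTS: dict[tuple[bool, bool], str] = {
    (True, True): "uv",
    (True, False): "yellow",
    (False, True): "blue",
    (False, False): "purple",
}

# Hue-sector centres (degrees) in the hexagon plane; each sector spans
# [centre - 30, centre + 30) so boundary ties resolve counter-clockwise.
HEXAGON_SECTOR_CENTRES: dict[str, float] = {
    "green": -30.0,
    "blue_green": 30.0,
    "blue": 90.0,
    "uv_blue": 150.0,
    "uv": 210.0,
    "uv_green": 270.0,
}

_ACHROMATIC_EPS = 1e-9

# CIE standard daylight illuminant D65, relative spectral power distribution
# tabulated at 5 nm from 300 to 700 nm (normalised to 100 at 560 nm).
_D65_NM = np.arange(300.0, 701.0, 5.0)
_D65_SPD = np.array([
    0.0341, 1.6643, 3.2945, 11.7652, 20.2360, 28.6447, 37.0535, 38.5011,
    39.9488, 42.4302, 44.9117, 45.7750, 46.6383, 49.3637, 52.0891, 51.0323,
    49.9755, 52.3118, 54.6482, 68.7015, 82.7549, 87.1204, 91.4860, 92.4589,
    93.4318, 90.0570, 86.6823, 95.7736, 104.8650, 110.9360, 117.0080,
    117.4100, 117.8120, 116.3360, 114.8610, 115.3920, 115.9230, 112.3670,
    108.8110, 109.0820, 109.3540, 108.5780, 107.8020, 106.2960, 104.7900,
    106.2390, 107.6890, 106.0470, 104.4050, 104.2250, 104.0460, 102.0230,
    100.0000, 98.1671, 96.3342, 96.0611, 95.7880, 92.2368, 88.6856, 89.3459,
    90.0062, 89.8026, 89.5991, 88.6489, 87.6987, 85.4936, 83.2886, 83.4939,
    83.6992, 81.8630, 80.0268, 80.1207, 80.2146, 81.2462, 82.2778, 80.2810,
    78.2842, 74.0027, 69.7213, 70.6652, 71.6091,
])


def visual_pigment_template(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band).

    Standard rhodopsin nomogram parameterised only by the peak wavelength;
    returned curve is peak-normalised to 1.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lm_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


@dataclass
class ReceptorSensitivity:
    """Relative spectral sensitivity of one photoreceptor class."""

    name: str
    lambda_max: float
    curve: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.shape != (len(self.grid),):
            raise ValueError(f"receptor '{self.name}': curve length mismatch with grid")
        if np.any(self.curve < 0):
            raise ValueError(f"receptor '{self.name}': negative sensitivity values")
        peak = self.curve.max()
        if not math.isclose(peak, 1.0, rel_tol=1e-9):
            raise ValueError(f"receptor '{self.name}': curve is not peak-normalised")
        # the pigment beta band can pull the realised peak a few nm off the
        # nominal alpha-band maximum, so allow a small slack
        peak_wl = self.grid.wavelengths[int(np.argmax(self.curve))]
        tol = max(self.grid.step_nm, 5.0)
        if abs(peak_wl - self.lambda_max) > tol:
            raise ValueError(
                f"receptor '{self.name}': curve peaks at {peak_wl} nm, "
                f"not at lambda_max={self.lambda_max} nm"
            )


def make_receptor(
    lambda_max: float,
    name: str | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    template: str = "nomogram",
) -> ReceptorSensitivity:
    """Build a receptor from the visual-pigment nomogram template."""
    if template != "nomogram":
        raise ValueError(f"unknown template {template!r}")
    if not grid.start_nm <= lambda_max <= grid.stop_nm:
        raise ValueError(f"lambda_max {lambda_max} nm lies outside the grid")
    curve = visual_pigment_template(grid.wavelengths, lambda_max)
    return ReceptorSensitivity(name or f"r{lambda_max:.0f}", lambda_max, curve, grid)


def receptor_from_table(
    path, name: str, grid: WavelengthGrid = DEFAULT_GRID
) -> ReceptorSensitivity:
    """Load a tabulated sensitivity curve (wide dialect: wavelength + column)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    col = name if name in df.columns else df.columns[1]
    vals = np.interp(grid.wavelengths, wl, df[col].to_numpy(dtype=float))
    vals = vals / vals.max()
    peak_wl = float(grid.wavelengths[int(np.argmax(vals))])
    return ReceptorSensitivity(name, peak_wl, vals, grid)


@dataclass
class Illuminant:
    """Relative spectral irradiance of the light source."""

    name: str
    irradiance: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if self.irradiance.shape != (len(self.grid),):
            raise ValueError(f"illuminant '{self.name}': length mismatch with grid")
        if np.any(self.irradiance < 0):
            raise ValueError(f"illuminant '{self.name}': negative irradiance")

    @classmethod
    def d65(cls, grid: WavelengthGrid = DEFAULT_GRID) -> "Illuminant":
        """Standard daylight D65, interpolated onto the grid, unit mean.

        The absolute scale is irrelevant under von Kries adaptation (enforced
        by the illuminant-invariance tests); unit mean is a convenience.
        """
        spd = np.interp(grid.wavelengths, _D65_NM, _D65_SPD)
        return cls("D65", spd / spd.mean(), grid)


@dataclass
class ViewingContext:
    """Everything needed to map a spectrum to a colour locus.

    ``model`` is ``"hexagon"`` (3 receptors ordered UV, blue, green) or
    ``"fly_categorical"`` (4 receptors ordered R7p, R7y, R8p, R8y).
    """

    receptors: tuple[ReceptorSensitivity, ...]
    illuminant: Illuminant
    background: Spectrum
    model: str
    fly_quadrants: Mapping[tuple[bool, bool], str] = field(
        default_factory=lambda: dict(DEFAULT_FLY_QUADRANTS)
    )
    _bg_catches: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        expected = {"hexagon": 3, "fly_categorical": 4}
        if self.model not in expected:
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.receptors) != expected[self.model]:
            raise ValueError(
                f"{self.model} model needs {expected[self.model]} receptors, "
                f"got {len(self.receptors)}"
            )
        self._bg_catches = np.array(
            [quantum_catch(self.background, r, self.illuminant) for r in self.receptors]
        )
        if np.any(self._bg_catches <= 0):
            raise ValueError("background yields a non-positive catch for some receptor")

    @property
    def background_catches(self) -> np.ndarray:
        return self._bg_catches

    def relative_catches(self, s: Spectrum) -> np.ndarray:
        """Von Kries adapted catches q_i for a stimulus spectrum."""
        q = np.array(
            [quantum_catch(s, r, self.illuminant) for r in self.receptors]
        )
        return q / self._bg_catches


@dataclass
class ColourLocus:
    """Position of a stimulus in a 2-D colour space."""

    x: float
    y: float
    excitations: dict[str, float]
    sector: str
    model: str


@dataclass
class ContrastResult:
    """Chromatic and (for bees) achromatic contrast of a stimulus."""

    chromatic: float
    achromatic: float | None
    above_threshold: bool
    threshold_used: float


def quantum_catch(s: Spectrum, r: ReceptorSensitivity, i: Illuminant) -> float:
    """Receptor quantum catch Q = sum_lambda R * S * I * dlambda.

    Reflectance is taken as a fraction (percent / 100); the rectangle rule is
    applied on the shared grid.
    """
    if s.grid != r.grid or s.grid != i.grid:
        raise ValueError("spectrum, receptor and illuminant must share one grid")
    return float(
        np.sum((s.reflectance / 100.0) * r.curve * i.irradiance) * s.grid.step_nm
    )


def adapt_von_kries(q_stimulus: float, q_background: float) -> float:
    """Von Kries receptor adaptation: catch relative to the background catch."""
    if q_background <= 0:
        raise ValueError("degenerate background: non-positive background catch")
    return q_stimulus / q_background


def excite_hyperbolic(q: float | np.ndarray) -> float | np.ndarray:
    """Hyperbolic phototransduction E = q / (q + 1); background maps to 0.5."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("relative catch must be non-negative")
    e = q / (q + 1.0)
    return float(e) if e.ndim == 0 else e


def _hexagon_sector(x: float, y: float) -> str:
    if math.hypot(x, y) < _ACHROMATIC_EPS:
        return "achromatic"
    angle = math.degrees(math.atan2(y, x))
    for name, centre in HEXAGON_SECTOR_CENTRES.items():
        delta = (angle - centre + 180.0) % 360.0 - 180.0
        if -30.0 <= delta < 30.0:
            return name
    return "green"  # unreachable; sectors tile the circle


def hexagon_locus(e_uv: float, e_blue: float, e_green: float) -> ColourLocus:
    """Project three receptor excitations into the bee colour hexagon.

    x = (sqrt(3)/2) (E_g - E_uv); y = E_b - (E_uv + E_g)/2.  The adapted
    background (0.5, 0.5, 0.5) maps to the achromatic centre (0, 0).
    """
    for e in (e_uv, e_blue, e_green):
        if not 0.0 <= e < 1.0:
            raise ValueError(f"excitation {e} outside [0, 1)")
    x = (math.sqrt(3.0) / 2.0) * (e_green - e_uv)
    y = e_blue - (e_uv + e_green) / 2.0
    return ColourLocus(
        x,
        y,
        {"uv": e_uv, "blue": e_blue, "green": e_green},
        _hexagon_sector(x, y),
        "hexagon",
    )


def fly_locus(
    q7p: float,
    q7y: float,
    q8p: float,
    q8y: float,
    quadrants: Mapping[tuple[bool, bool], str] | None = None,
) -> ColourLocus:
    """Opponent locus in the categorical fly colour space.

    The four von Kries adapted catches are normalised to unit sum (the
    "signals"); the opponent axes are the direct signal differences
    x = s(R7p) - s(R8p) and y = s(R7y) - s(R8y), each bounded in [-1, 1].
    Equal adaptation (all catches equal) maps to (0, 0).
    """
    q = np.array([q7p, q7y, q8p, q8y], dtype=float)
    if np.any(q < 0):
        raise ValueError("relative catches must be non-negative")
    total = q.sum()
    if total <= 0:
        raise ValueError("all catches are zero: fly locus undefined")
    s7p, s7y, s8p, s8y = q / total
    x = s7p - s8p
    y = s7y - s8y
    qmap = dict(DEFAULT_FLY_QUADRANTS if quadrants is None else quadrants)
    sector = (
        "achromatic"
        if math.hypot(x, y) < _ACHROMATIC_EPS
        else qmap[(x >= 0, y >= 0)]
    )
    return ColourLocus(
        x, y, {"R7p": s7p, "R7y": s7y, "R8p": s8p, "R8y": s8y}, sector, "fly_categorical"
    )


def chromatic_contrast(locus: ColourLocus) -> float:
    """Euclidean distance (EU) of a locus from the achromatic centre."""
    return math.hypot(locus.x, locus.y)


def achromatic_contrast(e_green: float) -> float:
    """Green-receptor (achromatic) contrast |E_g - 0.5|."""
    if not 0.0 <= e_green < 1.0:
        raise ValueError(f"excitation {e_green} outside [0, 1)")
    return abs(e_green - 0.5)


def flag_discriminable(
    chromatic: float, model: str, threshold: float | None = None
) -> bool:
    """Whether a chromatic contrast reaches the discriminability threshold.

    Defaults: 0.11 EU (hexagon / bees) and 0.096 EU (fly).  A contrast
    exactly at threshold counts as discriminable (>=).
    """
    thr = DEFAULT_THRESHOLDS[model] if threshold is None else threshold
    return chromatic >= thr


def _default_background(grid: WavelengthGrid) -> Spectrum:
    from .synthdata import foliage_background

    return foliage_background(grid)


def bee_context(
    grid: WavelengthGrid = DEFAULT_GRID,
    background: Spectrum | None = None,
    illuminant: Illuminant | None = None,
    lambda_max: Mapping[str, float] | None = None,
) -> ViewingContext:
    """Default honeybee hexagon viewing context (D65, green-foliage background)."""
    peaks = dict(BEE_LAMBDA_MAX if lambda_max is None else lambda_max)
    receptors = tuple(
        make_receptor(peaks[k], name=k, grid=grid) for k in ("uv", "blue", "green")
    )
    return ViewingContext(
        receptors,
        illuminant or Illuminant.d65(grid),
        background or _default_background(grid),
        "hexagon",
    )


def fly_context(
    grid: WavelengthGrid = DEFAULT_GRID,
    background: Spectrum | None = None,
    illuminant: Illuminant | None = None,
    lambda_max: Mapping[str, float] | None = None,
) -> ViewingContext:
    """Default Lucilia-type categorical viewing context."""
    peaks = dict(FLY_LAMBDA_MAX if lambda_max is None else lambda_max)
    receptors = tuple(
        make_receptor(peaks[k], name=k, grid=grid)
        for k in ("R7p", "R7y", "R8p", "R8y")
    )
    return ViewingContext(
        receptors,
        illuminant or Illuminant.d65(grid),
        background or _default_background(grid),
        "fly_categorical",
    )


def spectrum_locus(s: Spectrum, ctx: ViewingContext) -> ColourLocus:
    """Map a stimulus spectrum to its colour locus under a viewing context."""
    q = ctx.relative_catches(s)
    if ctx.model == "hexagon":
        e = excite_hyperbolic(q)
        return hexagon_locus(e[0], e[1], e[2])
    return fly_locus(q[0], q[1], q[2], q[3], quadrants=ctx.fly_quadrants)


def spectrum_contrast(
    s: Spectrum, ctx: ViewingContext, threshold: float | None = None
) -> ContrastResult:
    """Chromatic (and, for bees, achromatic) contrast of a stimulus."""
    locus = spectrum_locus(s, ctx)
    chrom = chromatic_contrast(locus)
    achro = (
        achromatic_contrast(locus.excitations["green"])
        if ctx.model == "hexagon"
        else None
    )
    thr = DEFAULT_THRESHOLDS[ctx.model] if threshold is None else threshold
    return ContrastResult(chrom, achro, flag_discriminable(chrom, ctx.model, thr), thr)


def analyse_set(
    ss: SpectrumSet,
    contexts: Sequence[ViewingContext],
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Contrast table for a spectrum set under one or more viewing contexts.

    One row per spectrum per context with columns
    ``label, group, model, x, y, sector, chromatic_EU, achromatic_EU,
    above_threshold``.
    """
    rows = []
    for ctx in contexts:
        thr = None if thresholds is None else thresholds.get(ctx.model)
        for s in ss:
            locus = spectrum_locus(s, ctx)
            res = spectrum_contrast(s, ctx, threshold=thr)
            rows.append(
                {
                    "label": s.label,
                    "group": ss.group_of(s.label),
                    "model": ctx.model,
                    "x": locus.x,
                    "y": locus.y,
                    "sector": locus.sector,
                    "chromatic_EU": res.chromatic,
                    "achromatic_EU": res.achromatic,
                    "above_threshold": res.above_threshold,
                }
            )
    return pd.DataFrame(rows)
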