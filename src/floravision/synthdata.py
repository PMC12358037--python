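"""Pigment-based synthetic reflectance spectra, trees and trait datasets.

Spectra are generated by a simple absorbing-pigment model

    R(lambda) = baseline * exp(-sum_k strength_k * G(lambda; centre_k, width_k))
                + smooth correlated noise,  clipped to [0, 100] %,

where each Gaussian band G mimics the absorption of a floral/foliar pigment
(chlorophyll a/b, carotenoids, anthocyanins, plus a broad UV absorber).
Band strengths and the baseline are drawn per sample from preset-specific
ranges, so every colour class is a population of related but non-identical
spectra.  The noise is Gaussian-kernel-smoothed white noise, so at its
default amplitude it does not create spurious marker points.

Class presets emulate the study's six colour classes: ``green`` flowers
(very low UV and blue reflectance, primary peak at 500--550 nm, chlorophyll
valley near 670 nm), ``green_yellow`` flowers (carotenoid-suppressed
400--500 nm reflectance, elevated long-wavelength plateau), the comparison
classes ``blue_violet``, ``pink``, ``white`` and ``yellow``, and the
``foliage`` background.  Default class counts are 19/11/28/25/9/38, the
sample sizes of the study design being emulated.

Trees are pure-birth (Yule) trees; trait datasets are Brownian tip values
plus group mean shifts, for calibrating the phylogenetic ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .grid import DEFAULT_GRID, WavelengthGrid
from .phylostats import PhyloTree, simulate_bm
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "PigmentBand",
    "FlowerClassPreset",
    "DEFAULT_PRESETS",
    "DEFAULT_CLASS_COUNTS",
    "load_presets",
    "dump_presets",
    "make_spectrum",
    "foliage_background",
    "make_study_set",
    "make_yule_tree",
    "make_trait_dataset",
]


@dataclass(frozen=True)
class PigmentBand:
    """One Gaussian absorption band with a per-sample strength range.

    ``centre``/``width`` in nm (width is the Gaussian sd); ``strength_lo`` /
    ``strength_hi`` bound the absorbance drawn for each sample.
    """

    centre: float
    width: float
    strength_lo: float
    strength_hi: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.strength_lo < 0 or self.strength_hi < self.strength_lo:
            raise ValueError("band strengths must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class FlowerClassPreset:
    """Pigment mix and brightness range defining one colour class."""

    class_name: str
    bands: tuple[PigmentBand, ...]
    baseline_lo: float
    baseline_hi: float
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.baseline_lo <= self.baseline_hi <= 100:
            raise ValueError("baseline range must lie in (0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _bands(*specs: tuple[float, float, float, float]) -> tuple[PigmentBand, ...]:
    return tuple(PigmentBand(*s) for s in specs)


# Band centres follow literature-style pigment absorption maxima:
# chlorophyll a ~430/670 nm, chlorophyll b ~455/645 nm, a carotenoid triplet
# ~425/450/480 nm, anthocyanin ~530-560 nm, plus a broad UV absorber.  They
# are scene-setting defaults, editable via preset files.
DEFAULT_PRESETS: dict[str, FlowerClassPreset] = {
    "foliage": FlowerClassPreset(
        "foliage",
        _bands(
            (330, 55, 1.3, 1.5),
            (430, 28, 0.5, 0.7),
            (455, 28, 0.3, 0.5),
            (480, 25, 0.2, 0.4),
            (620, 60, 0.6, 0.8),
            (672, 24, 1.2, 1.4),
        ),
        baseline_lo=17.0,
        baseline_hi=19.0,
    ),
    "green": FlowerClassPreset(
        "green",
        _bands(
            (330, 55, 1.5, 2.1),
            (430, 28, 0.5, 0.9),
            (455, 28, 0.3, 0.6),
            (480, 25, 0.2, 0.5),
            (620, 60, 0.5, 0.8),
            (672, 24, 1.0, 1.8),
        ),
        baseline_lo=26.0,
        baseline_hi=48.0,
    ),
    "green_yellow": FlowerClassPreset(
        "green_yellow",
        _bands(
            (330, 55, 1.8, 2.6),
            (430, 30, 1.0, 1.4),
            (455, 30, 1.0, 1.4),
            (480, 28, 0.8, 1.2),
            (620, 60, 0.15, 0.35),
            (672, 24, 0.4, 0.8),
        ),
        baseline_lo=26.0,
        baseline_hi=38.0,
    ),
    "blue_violet": FlowerClassPreset(
        "blue_violet",
        _bands(
            (340, 45, 1.2, 2.0),
            (560, 48, 1.8, 2.8),
            (672, 24, 0.1, 0.3),
        ),
        baseline_lo=30.0,
        baseline_hi=50.0,
    ),
    "pink": FlowerClassPreset(
        "pink",
        _bands(
            (340, 50, 1.0, 1.8),
            (540, 45, 0.8, 1.4),
        ),
        baseline_lo=40.0,
        baseline_hi=65.0,
    ),
    "white": FlowerClassPreset(
        "white",
        _bands(
            (330, 50, 1.6, 2.4),
        ),
        baseline_lo=45.0,
        baseline_hi=70.0,
    ),
    "yellow": FlowerClassPreset(
        "yellow",
        _bands(
            (330, 55, 2.0, 2.8),
            (425, 30, 2.0, 3.0),
            (450, 30, 2.0, 3.0),
            (480, 28, 1.6, 2.4),
        ),
        baseline_lo=45.0,
        baseline_hi=70.0,
    ),
}

#: Default per-class sample counts of the emulated study design.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "green": 19,
    "green_yellow": 11,
    "blue_violet": 28,
    "pink": 25,
    "white": 9,
    "yellow": 38,
}


def load_presets(path) -> dict[str, FlowerClassPreset]:
    """Load class presets from a YAML file (see :func:`dump_presets`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        bands = tuple(PigmentBand(*b) for b in spec["bands"])
        out[name] = FlowerClassPreset(
            name,
            bands,
            spec["baseline_lo"],
            spec["baseline_hi"],
            spec.get("noise_sd", 0.5),
        )
    return out


def dump_presets(presets: Mapping[str, FlowerClassPreset], path) -> None:
    """Write presets as editable YAML."""
    raw = {
        name: {
            "bands": [
                [b.centre, b.width, b.strength_lo, b.strength_hi] for b in p.bands
            ],
            "baseline_lo": p.baseline_lo,
            "baseline_hi": p.baseline_hi,
            "noise_sd": p.noise_sd,
        }
        for name, p in presets.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def _smooth_noise(
    rng: np.random.Generator, n: int, sd: float, corr_nm: float, step_nm: float
) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise rescaled to target sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    half = int(3 * corr_nm / step_nm)
    x = np.arange(-half, half + 1) * step_nm
    kernel = np.exp(-(x**2) / (2 * corr_nm**2))
    kernel /= kernel.sum()
    smooth = np.convolve(white, kernel, mode="same")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def make_spectrum(
    preset: FlowerClassPreset,
    seed: int | np.random.Generator | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    label: str | None = None,
    noise_sd: float | None = None,
) -> Spectrum:
    """Draw one spectrum from a colour-class preset.

    Band strengths and the baseline are sampled uniformly within the preset
    ranges; ``noise_sd`` (percent) overrides the preset noise amplitude
    (use 0 for a deterministic pigment-only spectrum given fixed draws).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wl = grid.wavelengths
    absorbance = np.zeros(len(wl))
    for band in preset.bands:
        strength = rng.uniform(band.strength_lo, band.strength_hi)
        absorbance += strength * np.exp(
            -((wl - band.centre) ** 2) / (2 * band.width**2)
        )
    baseline = rng.uniform(preset.baseline_lo, preset.baseline_hi)
    refl = baseline * np.exp(-absorbance)
    sd = preset.noise_sd if noise_sd is None else noise_sd
    refl = refl + _smooth_noise(rng, len(wl), sd, corr_nm=15.0, step_nm=grid.step_nm)
    refl = np.clip(refl, 0.0, 100.0)
    return Spectrum(grid, refl, label or preset.class_name)


def foliage_background(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Deterministic green-foliage adaptation background.

    Midpoint band strengths and baseline of the ``foliage`` preset, no noise;
    this is the default von Kries background of the vision module (a
    user-supplied background spectrum can replace it for literature
    comparability).
    """
    p = DEFAULT_PRESETS["foliage"]
    wl = grid.wavelengths
    absorbance = np.zeros(len(wl))
    for band in p.bands:
        strength = (band.strength_lo + band.strength_hi) / 2
        absorbance += strength * np.exp(
            -((wl - band.centre) ** 2) / (2 * band.width**2)
        )
    baseline = (p.baseline_lo + p.baseline_hi) / 2
    return Spectrum(grid, baseline * np.exp(-absorbance), "foliage_background")


def make_study_set(
    n_per_class: Mapping[str, int] | None = None,
    seed: int | None = None,
    presets: Mapping[str, FlowerClassPreset] | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> SpectrumSet:
    """Generate a labelled study set with the default class counts.

    Labels are ``<class>_<index>``; ``group_labels`` records the colour
    class of every spectrum.  Reproducible under ``seed``.
    """
    counts = dict(DEFAULT_CLASS_COUNTS if n_per_class is None else n_per_class)
    presets = dict(DEFAULT_PRESETS if presets is None else presets)
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    groups: dict[str, str] = {}
    for cls, n in counts.items():
        if n < 0:
            raise ValueError(f"count for class {cls!r} must be >= 0")
        if n > 0 and cls not in presets:
            raise ValueError(f"no preset for class {cls!r}")
        for i in range(n):
            lab = f"{cls}_{i + 1:02d}"
            spectra.append(make_spectrum(presets[cls], rng, grid=grid, label=lab))
            groups[lab] = cls
    return SpectrumSet(spectra, groups)


def make_yule_tree(
    n_tips: int | None = None,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
    birth_rate: float = 1.0,
) -> PhyloTree:
    """Simulate an ultrametric pure-birth (Yule) tree.

    Either ``n_tips`` or ``labels`` must be given; labels are shuffled onto
    the tips so that tree structure is independent of label order.
    """
    if labels is not None:
        labels = list(labels)
        if n_tips is None:
            n_tips = len(labels)
        elif n_tips != len(labels):
            raise ValueError("n_tips disagrees with number of labels")
    if n_tips is None or n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    while True:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += dt
        if len(active) == n_tips:
            break
        parent = active.pop(rng.integers(len(active)))
        active.append(parent.new_child(edge_length=0.0))
        active.append(parent.new_child(edge_length=0.0))

    names = (
        labels if labels is not None else [f"t{i + 1}" for i in range(n_tips)]
    )
    order = rng.permutation(n_tips)
    for node, j in zip(active, order):
        node.taxon = taxon_namespace.new_taxon(label=str(names[j]))
    return PhyloTree(tree)


def make_trait_dataset(
    tree: PhyloTree,
    group_map: Mapping[str, str],
    sigma2: float = 1.0,
    shifts: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Brownian tip traits plus group mean shifts, as a trait table.

    ``group_map`` assigns each tip label to a group; ``shifts`` adds a mean
    offset per group (groups absent from ``shifts`` get 0; unknown groups in
    ``shifts`` are an error).  With all shifts zero this is a null dataset
    for type-I-error calibration of the phylogenetic ANOVA.
    """
    tips = tree.tip_labels
    missing = set(tips) - set(group_map)
    if missing:
        raise ValueError(f"tips without group assignment: {sorted(missing)}")
    shifts = dict(shifts or {})
    unknown = set(shifts) - set(group_map.values())
    if unknown:
        raise ValueError(f"shifts reference unknown groups: {sorted(unknown)}")
    values = simulate_bm(tree, sigma2, seed=seed)
    values = np.atleast_1d(values).astype(float)
    offsets = np.array([shifts.get(group_map[lab], 0.0) for lab in tips])
    return pd.DataFrame(
        {
            "label": tips,
            "value": values + offsets,
            "group": [group_map[lab] for lab in tips],
        }
    )
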