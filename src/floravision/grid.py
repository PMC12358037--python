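"""Shared wavelength grid for reflectance spectra and sensitivity curves.

All spectral quantities in this package live on a common, evenly spaced
wavelength grid.  The default covers the insect-relevant UV--VIS window,
300--700 nm inclusive at 1 nm resolution (401 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavelengthGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis, endpoints inclusive.

    Parameters
    ----------
    start_nm, stop_nm : float
        First and last wavelength in nanometres; ``start_nm < stop_nm``.
    step_nm : float
        Grid increment in nanometres; must divide the span evenly.
    """

    start_nm: float = 300.0
    stop_nm: float = 700.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be below stop_nm ({self.stop_nm})"
            )
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = self.stop_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"step_nm ({self.step_nm}) does not divide the span {span} evenly"
            )

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """Grid points in nm as a float array (length ``len(self)``)."""
        return self.start_nm + self.step_nm * np.arange(len(self))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest to ``wavelength_nm``."""
        idx = int(round((wavelength_nm - self.start_nm) / self.step_nm))
        if idx < 0 or idx >= len(self):
            raise ValueError(f"{wavelength_nm} nm lies outside the grid")
        return idx


DEFAULT_GRID = WavelengthGrid()
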