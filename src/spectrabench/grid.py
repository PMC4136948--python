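"""Uniform wavelength grids for discretized reflectance spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default acquisition grid: 1150 wavelengths from 350.14 to 649.98 nm,
#: i.e. steps of roughly 0.26 nm.
DEFAULT_START_NM = 350.14
DEFAULT_STOP_NM = 649.98
DEFAULT_N_POINTS = 1150


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing, uniformly spaced wavelength grid in nm."""

    start_nm: float
    stop_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if not self.stop_nm > self.start_nm:
            raise ValueError(
                f"stop_nm ({self.stop_nm}) must exceed start_nm ({self.start_nm})"
            )

    @property
    def spacing(self) -> float:
        return (self.stop_nm - self.start_nm) / (self.n_points - 1)

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.stop_nm, self.n_points)

    @property
    def column_labels(self) -> list[str]:
        """Wavelength column names, formatted with two decimals (e.g. "350.14")."""
        labels = [f"{w:.2f}" for w in self.values]
        if len(set(labels)) != len(labels):
            raise ValueError(
                "grid too dense for two-decimal column labels; points collide"
            )
        return labels

    def __len__(self) -> int:
        return self.n_points


def make_wavelength_grid(
    start_nm: float = DEFAULT_START_NM,
    stop_nm: float = DEFAULT_STOP_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> WavelengthGrid:
    """Build a uniform wavelength grid.

    Spacing is (stop - start) / (n_points - 1); the default grid reproduces
    the 1150-point acquisition range of the experimental setup.
    """
    return WavelengthGrid(float(start_nm), float(stop_nm), int(n_points))
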