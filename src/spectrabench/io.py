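"""Reading and writing the columnar spectra-table dialect and configs.

Tables are plain CSV/TSV with one reflectance column per wavelength, named
by the wavelength value with two decimals ("350.14"), plus the metadata
columns Specimen, Tissue and — for raw tables — Spot and Repetition.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import WavelengthGrid
from .synthetic import METADATA_COLUMNS, GroundTruthConfig, RawDesign, wavelength_columns


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_spectra_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_spectra_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    wl = wavelength_columns(table)
    if not wl:
        raise ValueError(f"{path} has no wavelength columns")
    table[wl] = table[wl].astype(float)
    return table


def grid_from_table(table: pd.DataFrame) -> WavelengthGrid:
    """Recover the (uniform) wavelength grid from a table's column names."""
    values = np.array([float(c) for c in wavelength_columns(table)])
    if len(values) < 2 or np.any(np.diff(values) <= 0):
        raise ValueError("wavelength columns are not strictly increasing")
    return WavelengthGrid(float(values[0]), float(values[-1]), len(values))


def load_config(path: str | Path) -> GroundTruthConfig:
    """Load a generator config from YAML or JSON.

    Recognized keys: tissue_labels, separation, base_level, animal_shift_sd,
    spot_shift_sd, rep_noise_sd, smooth_noise_length_nm,
    smooth_noise_amplitude, and grid: {start_nm, stop_nm, n_points}.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    kwargs = dict(raw)
    if "grid" in kwargs:
        kwargs["grid"] = WavelengthGrid(**kwargs["grid"])
    if "tissue_labels" in kwargs:
        kwargs["tissue_labels"] = tuple(kwargs["tissue_labels"])
    return GroundTruthConfig(**kwargs)


def save_config(config: GroundTruthConfig, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "tissue_labels": list(config.tissue_labels),
        "separation": config.separation,
        "base_level": config.base_level,
        "animal_shift_sd": config.animal_shift_sd,
        "spot_shift_sd": config.spot_shift_sd,
        "rep_noise_sd": config.rep_noise_sd,
        "smooth_noise_length_nm": config.smooth_noise_length_nm,
        "smooth_noise_amplitude": config.smooth_noise_amplitude,
        "grid": {
            "start_nm": config.grid.start_nm,
            "stop_nm": config.grid.stop_nm,
            "n_points": config.grid.n_points,
        },
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def design_from_mapping(raw: dict) -> RawDesign:
    kwargs = dict(raw)
    if "tissues" in kwargs:
        kwargs["tissues"] = tuple(kwargs["tissues"])
    return RawDesign(**kwargs)


__all__ = [
    "write_spectra_table",
    "read_spectra_table",
    "grid_from_table",
    "load_config",
    "save_config",
    "design_from_mapping",
    "METADATA_COLUMNS",
]
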