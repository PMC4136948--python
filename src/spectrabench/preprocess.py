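"""Collapse repeated measurements into one spectrum per (animal, tissue).

The raw design holds 6 spots x 30 repetitions = 180 highly redundant spectra
per animal and tissue; repetitions of one spot vary minimally and spots
differ almost only by a vertical shift.  Averaging them removes the
redundancy and avoids a downward-biased class covariance later, while the
resulting rows can be read as one spectrum per animal.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import wavelength_columns


def average_spectra(raw: pd.DataFrame) -> pd.DataFrame:
    """Average over spots and repetitions, per wavelength.

    Returns one row per (Specimen, Tissue) with the unweighted arithmetic
    mean of all that group's spectra (with a balanced design this equals the
    mean of spot means).  Rows are sorted by (Tissue, Specimen) so that
    downstream splits are reproducible.
    """
    if raw.empty:
        raise ValueError("raw table is empty")
    for col in ("Specimen", "Tissue"):
        if col not in raw.columns:
            raise ValueError(f"raw table lacks required column {col!r}")
    wl = wavelength_columns(raw)
    if not wl:
        raise ValueError("raw table has no wavelength columns")

    grouped = (
        raw.groupby(["Tissue", "Specimen"], observed=True, sort=True)[wl]
        .mean()
        .reset_index()
    )
    out = grouped[["Specimen", "Tissue"] + wl]
    return out.reset_index(drop=True)
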