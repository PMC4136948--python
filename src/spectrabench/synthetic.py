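"""Synthetic raw reflectance spectra with the ex-vivo study's design.

The original measurements (12 animals x 8 tissue types x 6 spots x 30
repetitions, 1150 wavelengths on 350-650 nm) are not publicly available, so
this module emulates their statistical structure: smooth per-tissue mean
curves, a near-constant vertical shift between animals and between spots
within an animal, a smooth per-animal deviation component, and tiny
repetition noise.  It also exposes the exact ground-truth model so that
downstream estimators can be tested against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, make_wavelength_grid

#: The eight tissue categories of the study, in canonical (alphabetical) order.
TISSUE_LABELS = (
    "Cancellous Bone",
    "Cortical Bone",
    "Fat",
    "Mucosa",
    "Muscle",
    "Nerve",
    "Salivary Gland",
    "Skin",
)

METADATA_COLUMNS = ("Specimen", "Tissue", "Spot", "Repetition")


@dataclass(frozen=True)
class TissueProfile:
    """Smooth mean reflectance curve of one tissue type.

    The curve is a baseline level plus a sum of Gaussian-shaped bumps,
    ``baseline + sum(a * exp(-(w - c)^2 / (2 s^2)))`` — smooth by
    construction and cheap to evaluate.
    """

    label: str
    baseline: float
    bumps: tuple[tuple[float, float, float], ...]  # (center nm, width nm, amplitude)

    def mean_curve(self, grid: WavelengthGrid) -> np.ndarray:
        w = grid.values
        curve = np.full(grid.n_points, self.baseline, dtype=float)
        for center, width, amplitude in self.bumps:
            curve += amplitude * np.exp(-0.5 * ((w - center) / width) ** 2)
        return curve


@dataclass(frozen=True)
class GroundTruthModel:
    """Known-parameter generative model for raw spectra.

    A spectrum of (animal a, tissue c, spot s, repetition r) is

        mean_c + animal_shift(a,c) + smooth_dev(a,c) + spot_shift(a,c,s) + noise

    where the two shifts are wavelength-constant Gaussian offsets, the smooth
    deviation is a stationary squared-exponential process shared by all spots
    of an animal, and the repetition noise is i.i.d. per wavelength.  The SDs
    default to 2.0 / 0.5 / 0.05 reflectance units, encoding that repetitions
    of one spot vary minimally and that spots within an animal differ almost
    only by a constant vertical shift.
    """

    grid: WavelengthGrid
    profiles: tuple[TissueProfile, ...]
    animal_shift_sd: float = 2.0
    spot_shift_sd: float = 0.5
    rep_noise_sd: float = 0.05
    smooth_noise_length_nm: float = 80.0
    smooth_noise_amplitude: float = 0.5

    def __post_init__(self) -> None:
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tissue labels in profiles")

    @property
    def tissue_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.profiles)

    def profile(self, label: str) -> TissueProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise KeyError(label)

    def mean_curves(self) -> dict[str, np.ndarray]:
        return {p.label: p.mean_curve(self.grid) for p in self.profiles}


@dataclass(frozen=True)
class RawDesign:
    """Factorial layout of the raw acquisition: animals x tissues x spots x reps."""

    n_animals: int = 12
    tissues: tuple[str, ...] = TISSUE_LABELS
    n_spots: int = 6
    n_repetitions: int = 30

    @property
    def n_rows(self) -> int:
        return self.n_animals * len(self.tissues) * self.n_spots * self.n_repetitions


@dataclass(frozen=True)
class GroundTruthConfig:
    """Knobs of the invented ground truth.

    ``separation`` scales the tissue-specific deviation curves away from a
    shared base curve: 0 makes all tissue means identical, and the maximum
    pairwise L2 distance between mean curves grows linearly with it.  The
    default of 6.0 reflectance units yields curves that are visually distinct
    at the 0-60 reflectance scale yet overlap partially at any single
    wavelength once the 2.0-unit animal shifts are added.
    """

    tissue_labels: tuple[str, ...] = TISSUE_LABELS
    separation: float = 6.0
    base_level: float = 25.0
    animal_shift_sd: float = 2.0
    spot_shift_sd: float = 0.5
    rep_noise_sd: float = 0.05
    smooth_noise_length_nm: float = 80.0
    smooth_noise_amplitude: float = 0.5
    grid: WavelengthGrid = field(default_factory=make_wavelength_grid)


def generate_ground_truth(
    config: GroundTruthConfig | None = None, seed: int = 0
) -> GroundTruthModel:
    """Draw a ground-truth model: one smooth mean curve per tissue.

    Each tissue's mean is a shared base curve plus ``separation`` times a
    unit-normalized tissue-specific deviation (3-6 Gaussian bumps), keeping
    all curves smooth and inside the plausible 0-60 reflectance band.
    Deterministic given ``seed``.
    """
    if config is None:
        config = GroundTruthConfig()
    labels = tuple(config.tissue_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tissue labels in config")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB45E]))

    # Shared base curve: broad features common to all tissues.
    base_bumps = []
    for _ in range(3):
        center = rng.uniform(380.0, 620.0)
        width = rng.uniform(50.0, 90.0)
        amplitude = rng.uniform(-6.0, 8.0)
        base_bumps.append((center, width, amplitude))

    grid = config.grid
    w = grid.values
    profiles = []
    accepted_devs: list[np.ndarray] = []
    for label in labels:
        # Rejection-sample a unit-RMS deviation curve that is bounded and not
        # too collinear with any previously accepted tissue's deviation, so
        # that every pairwise mean-curve distance is controlled by (and
        # scales linearly with) config.separation.
        for _ in range(500):
            n_bumps = int(rng.integers(3, 7))
            centers = rng.uniform(360.0, 640.0, n_bumps)
            widths = rng.uniform(25.0, 80.0, n_bumps)
            amplitudes = rng.uniform(-1.0, 1.0, n_bumps)
            offset = rng.uniform(-0.3, 0.3)
            dev = np.full(grid.n_points, offset)
            for c, s, a in zip(centers, widths, amplitudes):
                dev += a * np.exp(-0.5 * ((w - c) / s) ** 2)
            rms = float(np.sqrt(np.mean(dev**2)))
            if rms < 1e-9:
                continue
            dev /= rms
            if np.max(np.abs(dev)) > 2.5:
                continue  # keep mean curves inside the plausible band
            if all(float(np.mean(dev * prev)) < 0.5 for prev in accepted_devs):
                break
        else:  # pragma: no cover - 500 smooth draws always yield a candidate
            raise RuntimeError("could not draw sufficiently distinct mean curves")
        accepted_devs.append(dev)
        scale = config.separation / rms
        bumps = tuple(
            (float(c), float(s), float(a * scale))
            for c, s, a in zip(centers, widths, amplitudes)
        )
        profiles.append(
            TissueProfile(
                label=label,
                baseline=float(config.base_level + offset * scale),
                bumps=tuple(base_bumps) + bumps,
            )
        )

    return GroundTruthModel(
        grid=grid,
        profiles=tuple(profiles),
        animal_shift_sd=config.animal_shift_sd,
        spot_shift_sd=config.spot_shift_sd,
        rep_noise_sd=config.rep_noise_sd,
        smooth_noise_length_nm=config.smooth_noise_length_nm,
        smooth_noise_amplitude=config.smooth_noise_amplitude,
    )


def _smooth_basis(
    grid: WavelengthGrid, length_nm: float, amplitude: float
) -> np.ndarray:
    """Truncated eigenbasis factor of a squared-exponential covariance.

    Returns F with F @ F.T equal (up to truncation at 1e-10 of the largest
    eigenvalue) to amplitude^2 * exp(-(wi-wj)^2 / (2 length^2)); a draw is
    F @ z with z standard normal.
    """
    if amplitude == 0.0:
        return np.zeros((grid.n_points, 0))
    w = grid.values
    kernel = amplitude**2 * np.exp(-0.5 * ((w[:, None] - w[None, :]) / length_nm) ** 2)
    eigvals, eigvecs = np.linalg.eigh(kernel)
    keep = eigvals > 1e-10 * eigvals[-1]
    return eigvecs[:, keep] * np.sqrt(eigvals[keep])


def generate_raw_dataset(
    model: GroundTruthModel,
    design: RawDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the full factorial raw-spectra table.

    One row per (Specimen, Tissue, Spot, Repetition); reflectance columns are
    labelled by wavelength with two decimals.  The single seed is split into
    an independent substream per (animal, tissue), so regenerating any cell
    of the design is stable.  Reflectance is clipped at 0 from below only
    (physical non-negativity; the 0-60 band is typical, not a hard bound).
    """
    if design is None:
        design = RawDesign(tissues=model.tissue_labels)
    missing = set(design.tissues) - set(model.tissue_labels)
    if missing:
        raise ValueError(f"design tissues missing from model: {sorted(missing)}")

    grid = model.grid
    p = grid.n_points
    basis = _smooth_basis(grid, model.smooth_noise_length_nm, model.smooth_noise_amplitude)
    mean_curves = model.mean_curves()

    root = np.random.SeedSequence([int(seed), 0x5A3C])
    children = root.spawn(design.n_animals * len(design.tissues))

    n_per_cell = design.n_spots * design.n_repetitions
    blocks = []
    meta_specimen = []
    meta_tissue = []
    meta_spot = []
    meta_rep = []
    idx = 0
    for a in range(1, design.n_animals + 1):
        for tissue in design.tissues:
            rng = np.random.default_rng(children[idx])
            idx += 1
            animal_shift = rng.normal(0.0, model.animal_shift_sd)
            smooth_dev = (
                basis @ rng.standard_normal(basis.shape[1])
                if basis.shape[1]
                else np.zeros(p)
            )
            spot_shifts = rng.normal(0.0, model.spot_shift_sd, design.n_spots)
            noise = rng.normal(
                0.0, model.rep_noise_sd, (design.n_spots, design.n_repetitions, p)
            ) if model.rep_noise_sd > 0 else np.zeros(
                (design.n_spots, design.n_repetitions, p)
            )
            cell = (
                mean_curves[tissue][None, None, :]
                + animal_shift
                + smooth_dev[None, None, :]
                + spot_shifts[:, None, None]
                + noise
            )
            blocks.append(cell.reshape(n_per_cell, p))
            meta_specimen.append(np.full(n_per_cell, a))
            meta_tissue.extend([tissue] * n_per_cell)
            meta_spot.append(
                np.repeat(np.arange(1, design.n_spots + 1), design.n_repetitions)
            )
            meta_rep.append(
                np.tile(np.arange(1, design.n_repetitions + 1), design.n_spots)
            )

    spectra = np.clip(np.vstack(blocks), 0.0, None)
    frame = pd.DataFrame(spectra, columns=grid.column_labels)
    frame.insert(0, "Specimen", np.concatenate(meta_specimen))
    frame.insert(1, "Tissue", pd.Categorical(meta_tissue, categories=design.tissues))
    frame.insert(2, "Spot", np.concatenate(meta_spot))
    frame.insert(3, "Repetition", np.concatenate(meta_rep))
    return frame


def wavelength_columns(table: pd.DataFrame) -> list[str]:
    """The reflectance columns of a spectra table (everything non-metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def spectra_matrix(table: pd.DataFrame) -> np.ndarray:
    """Reflectance values of a spectra table as a float matrix."""
    return table[wavelength_columns(table)].to_numpy(dtype=float)
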