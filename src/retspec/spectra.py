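"""Ensemble absorption spectra from per-snapshot stick spectra.

Each molecular-dynamics snapshot contributes a stick spectrum: vertical
excitation energies (eV) with oscillator strengths.  Sticks are broadened
with a Gaussian band shape, per-snapshot curves are averaged pointwise on a
common energy grid, and the absorption maximum is read off the averaged
curve.  The default broadening width of 0.15 eV is interpreted as the
Gaussian σ; pass ``width_is_fwhm=True`` for the FWHM convention
(σ = FWHM / 2.3548).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import HC_EV_NM
from .errors import DegenerateSpectrumError, ValidationError

__all__ = [
    "STICK_COLUMNS",
    "BroadSpectrum",
    "SpectrumSummary",
    "nm_to_ev",
    "ev_to_nm",
    "default_grid",
    "broaden",
    "average_spectra",
    "ensemble_spectrum",
    "find_max",
    "compute_shift",
    "read_stick_table",
    "write_stick_table",
]

#: Column layout of a stick-spectrum table.
STICK_COLUMNS = ["snapshot", "state", "energy_eV", "osc_strength"]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class BroadSpectrum:
    """A broadened intensity curve on a strictly increasing energy grid."""

    grid: np.ndarray  # eV
    intensity: np.ndarray  # arbitrary units, >= 0
    width: float  # the Gaussian sigma used, eV

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise ValidationError("grid and intensity must have equal length")
        if self.grid.size == 0:
            raise ValidationError("spectrum grid is empty")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("energy grid must be strictly increasing")
        if np.any(self.intensity < -1e-12):
            raise ValidationError("intensities must be non-negative")


@dataclass
class SpectrumSummary:
    """Absorption maximum of an (ensemble-averaged) spectrum."""

    e_max: float  # eV
    lambda_max: float  # nm
    n_snapshots: int | None = None
    degenerate: bool = False


def nm_to_ev(wavelength: float) -> float:
    """Photon energy in eV for a wavelength in nm (E = hc/λ)."""
    if wavelength <= 0:
        raise ValidationError(f"wavelength must be positive, got {wavelength}")
    return HC_EV_NM / wavelength


def ev_to_nm(energy: float) -> float:
    """Wavelength in nm for a photon energy in eV (λ = hc/E)."""
    if energy <= 0:
        raise ValidationError(f"energy must be positive, got {energy}")
    return HC_EV_NM / energy


def default_grid(start: float = 1.5, stop: float = 4.0, step: float = 0.001) -> np.ndarray:
    """Default evaluation grid, 1.5–4.0 eV in 0.001-eV steps."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def broaden(
    sticks: pd.DataFrame,
    sigma: float = 0.15,
    grid: np.ndarray | None = None,
    *,
    weighted: bool = True,
    width_is_fwhm: bool = False,
) -> BroadSpectrum:
    """Gaussian-broaden one snapshot's stick spectrum onto an energy grid.

    I(E) = Σ_rows f · exp(−(E − E_row)² / (2σ²)), peak-height convention
    (no 1/(σ√2π) normalisation).  With ``weighted=False`` every stick gets
    unit weight regardless of oscillator strength.
    """
    if len(sticks) == 0:
        raise ValidationError("cannot broaden an empty stick spectrum")
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    if width_is_fwhm:
        sigma = sigma / FWHM_TO_SIGMA
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    energies = sticks["energy_eV"].to_numpy(dtype=float)
    if np.any(~np.isfinite(energies)) or np.any(energies <= 0):
        raise ValidationError("stick energies must be finite and positive")
    weights = (
        sticks["osc_strength"].to_numpy(dtype=float)
        if weighted
        else np.ones_like(energies)
    )
    diff = grid[:, None] - energies[None, :]
    intensity = (weights[None, :] * np.exp(-(diff**2) / (2.0 * sigma**2))).sum(axis=1)
    return BroadSpectrum(grid=grid, intensity=intensity, width=sigma)


def average_spectra(per_snapshot: list[BroadSpectrum]) -> BroadSpectrum:
    """Pointwise arithmetic mean of spectra sharing one grid."""
    if not per_snapshot:
        raise ValidationError("cannot average an empty list of spectra")
    grid = per_snapshot[0].grid
    for s in per_snapshot[1:]:
        if s.grid.shape != grid.shape or not np.array_equal(s.grid, grid):
            raise ValidationError("all spectra must share an identical grid")
    mean = np.mean([s.intensity for s in per_snapshot], axis=0)
    return BroadSpectrum(grid=grid, intensity=mean, width=per_snapshot[0].width)


def ensemble_spectrum(
    table: pd.DataFrame,
    sigma: float = 0.15,
    grid: np.ndarray | None = None,
    *,
    weighted: bool = True,
    width_is_fwhm: bool = False,
) -> tuple[BroadSpectrum, int]:
    """Broaden every snapshot of a stick table and average the curves.

    Returns the averaged spectrum and the number of snapshots entering it.
    """
    if grid is None:
        grid = default_grid()
    per = [
        broaden(g, sigma, grid, weighted=weighted, width_is_fwhm=width_is_fwhm)
        for _, g in table.groupby("snapshot", sort=True)
    ]
    return average_spectra(per), len(per)


def find_max(spec: BroadSpectrum, n_snapshots: int | None = None) -> SpectrumSummary:
    """Absorption maximum of a broadened spectrum.

    Ties (and flat spectra) resolve toward the lowest energy; a flat
    spectrum is flagged degenerate rather than raising.
    """
    inten = spec.intensity
    degenerate = bool(np.all(inten == inten[0]))
    idx = int(np.argmax(inten))  # first maximum = lowest-energy tie
    e_max = float(spec.grid[idx])
    return SpectrumSummary(
        e_max=e_max,
        lambda_max=ev_to_nm(e_max),
        n_snapshots=n_snapshots,
        degenerate=degenerate,
    )


def compute_shift(a: SpectrumSummary, b: SpectrumSummary) -> float:
    """Signed shift a.e_max − b.e_max in eV; positive means a is
    blue-shifted relative to b."""
    if a.degenerate or b.degenerate:
        raise DegenerateSpectrumError("cannot compute a shift from a flat spectrum")
    return a.e_max - b.e_max


def read_stick_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated stick-spectrum table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STICK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"stick table missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError("stick table has no rows")
    return df


def write_stick_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=STICK_COLUMNS)
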