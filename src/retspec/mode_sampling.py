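"""Boltzmann normal-mode sampling of harmonic initial conditions.

Each vibrational mode of a harmonic system is an independent 1-D oscillator
whose canonical (classical) energy distribution at temperature T is
exponential with mean kT.  An initial condition is drawn by sampling a
per-mode energy E ~ Exp(kT) and a uniform phase φ, splitting E into
potential and kinetic parts:

    Q  = (√(2E)/ω) sin φ        (mass-weighted coordinate)
    Q̇  = √(2E) cos φ            (mass-weighted velocity)

and mapping back to Cartesian positions (Å) and velocities (Å/ps) through
the mass-weighted displacement vectors.  This is classical sampling — no
zero-point energy — which is the regime where the mean energy per mode
satisfies equipartition ⟨E⟩ = kT (0.59616 kcal/mol at 300 K).

Internal units: amu, Å, ps; energies converted from kcal/mol via
1 kcal/mol = 418.4 amu·Å²/ps².  Rotational/translational modes must be
removed beforehand; strictly positive frequencies are enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    C_CM_PER_PS,
    KB_KCAL_MOL_K,
    KCAL_MOL_TO_AMU_A2_PS2,
)
from .errors import ValidationError
from .synthetic_data import Seed, _as_seed

__all__ = ["ModeSet", "InitialCondition", "sample_initial_conditions"]

#: cm⁻¹ → angular frequency in rad/ps
CM1_TO_RAD_PS = 2.0 * math.pi * C_CM_PER_PS


@dataclass
class ModeSet:
    """Harmonic modes: frequencies (cm⁻¹) and orthonormal mass-weighted
    displacement vectors over 3N Cartesian coordinates."""

    frequencies: np.ndarray  # (n_modes,), cm⁻¹, > 0
    displacements: np.ndarray  # (n_modes, 3N), orthonormal rows
    equilibrium: np.ndarray  # (3N,), Å
    masses: np.ndarray  # (N,), amu

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float).reshape(-1)
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float).reshape(-1)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        n_modes = len(self.frequencies)
        if np.any(self.frequencies <= 0):
            raise ValidationError(
                "all mode frequencies must be strictly positive "
                "(remove rotation/translation modes first)"
            )
        if self.displacements.shape != (n_modes, len(self.equilibrium)):
            raise ValidationError("displacements must be (n_modes, 3N)")
        if len(self.equilibrium) != 3 * len(self.masses):
            raise ValidationError("equilibrium length must be 3 × number of atoms")
        if np.any(self.masses <= 0):
            raise ValidationError("masses must be positive")
        gram = self.displacements @ self.displacements.T
        if not np.allclose(gram, np.eye(n_modes), atol=1e-6):
            raise ValidationError("displacement vectors must be orthonormal")

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


@dataclass
class InitialCondition:
    """One sampled phase-space point plus its per-mode energies."""

    positions: np.ndarray  # (3N,), Å
    velocities: np.ndarray  # (3N,), Å/ps
    mode_energies: np.ndarray  # (n_modes,), kcal/mol


def sample_initial_conditions(
    modes: ModeSet,
    temperature: float,
    n: int,
    seed: Seed | int,
) -> list[InitialCondition]:
    """Draw n initial conditions from the classical canonical ensemble.

    At T = 0 every sample sits at equilibrium with zero velocity.
    """
    if temperature < 0:
        raise ValidationError("temperature must be non-negative")
    if n < 1:
        raise ValidationError("n must be at least 1")
    rng = _as_seed(seed).rng()
    omega = CM1_TO_RAD_PS * modes.frequencies  # rad/ps
    kT = KB_KCAL_MOL_K * temperature  # kcal/mol
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(modes.masses, 3))
    out = []
    for _ in range(n):
        e_kcal = rng.exponential(kT, size=modes.n_modes) if kT > 0 else np.zeros(
            modes.n_modes
        )
        phi = rng.uniform(0.0, 2.0 * math.pi, size=modes.n_modes)
        e_int = e_kcal * KCAL_MOL_TO_AMU_A2_PS2  # amu·Å²/ps²
        amp = np.sqrt(2.0 * e_int)
        Q = amp / omega * np.sin(phi)  # amu^½·Å
        Qdot = amp * np.cos(phi)  # amu^½·Å/ps
        dx = (modes.displacements.T @ Q) * inv_sqrt_m
        vel = (modes.displacements.T @ Qdot) * inv_sqrt_m
        out.append(
            InitialCondition(
                positions=modes.equilibrium + dx,
                velocities=vel,
                mode_energies=e_kcal,
            )
        )
    return out
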