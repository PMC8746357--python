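"""Point-charge electrostatics for chromophore–environment analysis.

The environment potential is the bare Coulomb sum Φ(r) = k Σ qᵢ/|r − rᵢ|
with k = 332.0637 kcal·Å/(mol·e²) — a deliberately simple, screening-free
model that supports the sign and locality statements the analysis makes
(which end of the chromophore the environment stabilises), not absolute
solvated-potential values.

The spectral-tuning descriptor follows the external point-charge picture of
retinal proteins: on S0→S1 excitation the Schiff-base positive charge moves
toward the β-ionone ring, so an environment that is more negative at the
Schiff base than at the ring (delta = Φ_SB − Φ_ring < 0) stabilises the
ground state preferentially and predicts a blue shift relative to vacuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_K, vdw_radius
from .errors import SelectionError, SingularityError, ValidationError
from .structure_io import Frame, Selection, select

__all__ = [
    "ChargedEnvironment",
    "SurfaceMap",
    "TuningDescriptor",
    "SB_REGION_DEFAULT",
    "RING_REGION_DEFAULT",
    "coulomb_potential",
    "select_environment",
    "fibonacci_sphere",
    "vdw_surface",
    "project_potential",
    "tuning_descriptor",
]

#: Default atom-name sets for the two chromophore regions of the
#: point-charge tuning model.
SB_REGION_DEFAULT = frozenset({"C15", "N15", "H15"})
RING_REGION_DEFAULT = frozenset({"C1", "C2", "C3", "C4", "C5", "C6"})

_MIN_SEPARATION = 1e-6  # Å


@dataclass
class ChargedEnvironment:
    """Point charges with positions (Å) and source-residue labels."""

    positions: np.ndarray  # (n, 3)
    charges: np.ndarray  # (n,), e
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if self.positions.shape[0] != self.charges.shape[0]:
            raise ValidationError("positions and charges must have equal length")
        if not self.labels:
            self.labels = [""] * len(self.charges)
        if len(self.labels) != len(self.charges):
            raise ValidationError("labels must match charges in length")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise ValidationError("environment contains non-finite values")

    def __len__(self) -> int:
        return len(self.charges)


@dataclass
class SurfaceMap:
    """Coulomb potential sampled on the chromophore vdW surface."""

    points: np.ndarray  # (n, 3), Å
    potential: np.ndarray  # (n,), kcal/(mol·e)
    owner_atom: np.ndarray  # (n,), index of the hosting atom

    def __post_init__(self) -> None:
        n = len(self.potential)
        if len(self.points) != n or len(self.owner_atom) != n:
            raise ValidationError("surface map arrays must have equal length")


@dataclass
class TuningDescriptor:
    """Mean environment potential at the Schiff-base and β-ionone regions.

    delta = phi_sb − phi_ring; delta < 0 (environment more negative at the
    Schiff base) predicts a blue shift relative to vacuum.
    """

    phi_sb: float
    phi_ring: float

    @property
    def delta(self) -> float:
        return self.phi_sb - self.phi_ring

    @property
    def predicts_blue_shift(self) -> bool:
        return self.delta < 0


def coulomb_potential(point: np.ndarray, env: ChargedEnvironment) -> float:
    """Φ = k Σ qᵢ/rᵢ at a point, kcal/(mol·e)."""
    if len(env) == 0:
        return 0.0
    r = np.linalg.norm(env.positions - np.asarray(point, dtype=float), axis=1)
    if np.min(r) < _MIN_SEPARATION:
        i = int(np.argmin(r))
        raise SingularityError(
            f"evaluation point coincides with charge {i} ({env.labels[i]!r})"
        )
    return float(COULOMB_K * np.sum(env.charges / r))


def _potential_batch(points: np.ndarray, env: ChargedEnvironment) -> np.ndarray:
    r = np.linalg.norm(points[:, None, :] - env.positions[None, :, :], axis=2)
    if np.min(r) < _MIN_SEPARATION:
        raise SingularityError("a surface point coincides with an environment charge")
    return COULOMB_K * (env.charges[None, :] / r).sum(axis=1)


def select_environment(
    frame: Frame, center: Selection, cutoff: float
) -> ChargedEnvironment:
    """Whole-residue environment selection around a center selection.

    A residue (chain, resname, resid) enters the environment if any of its
    atoms lies within ``cutoff`` Å of any center atom; residues containing a
    center atom are excluded entirely.  All frame atoms must carry charges.
    """
    center_idx = select(frame, center)
    if not center_idx:
        raise SelectionError("center selection resolved to no atoms")
    charges = frame.charges  # raises ValidationError if any are missing
    coords = frame.coords
    center_xyz = coords[center_idx]

    def reskey(i: int):
        a = frame.atoms[i]
        return (a.chain, a.resname, a.resid)

    center_residues = {reskey(i) for i in center_idx}
    residues: dict[tuple, list[int]] = {}
    for i in range(len(frame)):
        residues.setdefault(reskey(i), []).append(i)

    keep: list[int] = []
    for key, idxs in residues.items():
        if key in center_residues:
            continue
        pts = coords[idxs]
        dmin = np.min(
            np.linalg.norm(pts[:, None, :] - center_xyz[None, :, :], axis=2)
        )
        if dmin <= cutoff:
            keep.extend(idxs)
    keep.sort()
    return ChargedEnvironment(
        positions=coords[keep] if keep else np.empty((0, 3)),
        charges=charges[keep] if keep else np.empty(0),
        labels=[f"{frame.atoms[i].resname}{frame.atoms[i].resid}" for i in keep],
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on a sphere (golden-spiral lattice)."""
    if n < 1:
        raise ValidationError("need at least one surface point per atom")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def vdw_surface(
    frame: Frame,
    points_per_atom: int = 200,
    *,
    scale: float = 1.0,
    indices: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Points on the (scaled) Bondi vdW surface of a set of atoms.

    Each atom's sphere is sampled on a Fibonacci lattice; points strictly
    inside any other atom's scaled sphere are discarded.  Returns
    (points (n, 3), owner atom index (n,)).
    """
    idxs = list(range(len(frame))) if indices is None else list(indices)
    if not idxs:
        raise ValidationError("no atoms to build a surface from")
    unit = fibonacci_sphere(points_per_atom)
    centers = np.array([frame.atoms[i].xyz for i in idxs])
    radii = np.array([scale * vdw_radius(frame.atoms[i].element) for i in idxs])
    pts_out, owner_out = [], []
    for k, i in enumerate(idxs):
        pts = centers[k] + radii[k] * unit
        keep = np.ones(len(pts), dtype=bool)
        for m in range(len(idxs)):
            if m == k:
                continue
            d = np.linalg.norm(pts - centers[m], axis=1)
            keep &= d >= radii[m] - 1e-9
        pts_out.append(pts[keep])
        owner_out.append(np.full(int(keep.sum()), i))
    return np.vstack(pts_out), np.concatenate(owner_out)


def project_potential(
    points: np.ndarray, owner_atom: np.ndarray, env: ChargedEnvironment
) -> SurfaceMap:
    """Evaluate the environment Coulomb potential at every surface point."""
    if len(env) == 0:
        raise ValidationError("environment is empty")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    return SurfaceMap(
        points=points,
        potential=_potential_batch(points, env),
        owner_atom=np.asarray(owner_atom),
    )


def tuning_descriptor(
    frame: Frame,
    env: ChargedEnvironment,
    sb_region: Selection | None = None,
    ring_region: Selection | None = None,
) -> TuningDescriptor:
    """Point-charge tuning descriptor: mean environment potential over the
    Schiff-base region vs. the β-ionone ring region atom centers."""
    if sb_region is None:
        sb_region = Selection(atom_names=SB_REGION_DEFAULT)
    if ring_region is None:
        ring_region = Selection(atom_names=RING_REGION_DEFAULT)
    phis = []
    for sel, what in ((sb_region, "Schiff-base"), (ring_region, "β-ionone")):
        idx = select(frame, sel)
        if not idx:
            raise SelectionError(f"{what} region selection resolved to no atoms")
        phis.append(
            float(np.mean([coulomb_potential(frame.atoms[i].xyz, env) for i in idx]))
        )
    return TuningDescriptor(phi_sb=phis[0], phi_ring=phis[1])
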