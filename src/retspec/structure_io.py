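"""Molecular structure containers and PDB / multi-frame XYZ I/O.

Coordinates are in Å throughout; no unit conversion happens at I/O
boundaries.  Atom indexing is 0-based internally; PDB serials are carried
as data and never used as indices.  Alternate locations are not supported:
the first altloc wins and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "read_pdb",
    "write_pdb",
    "read_xyz_traj",
    "write_xyz_traj",
    "select",
    "apply_template",
]


@dataclass
class AtomRecord:
    """One atom: identity fields plus a coordinate and an optional charge."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    xyz: np.ndarray
    charge: float | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValidationError(f"xyz must be a 3-vector, got shape {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValidationError(f"atom {self.name!r} has an empty element symbol")
        if self.serial <= 0:
            raise ValidationError(f"atom serial must be positive, got {self.serial}")


@dataclass
class Frame:
    """An ordered set of atoms at one time point, optionally with a box."""

    atoms: list[AtomRecord]
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError("a Frame must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValidationError("atom serials must be unique within a Frame")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValidationError("box must be a 3-vector of positive lengths")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.xyz for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        """Per-atom charges; raises if any atom is missing one."""
        missing = [a.name for a in self.atoms if a.charge is None]
        if missing:
            raise ValidationError(f"atoms missing charges: {missing[:5]}")
        return np.array([a.charge for a in self.atoms])


@dataclass
class Trajectory:
    """Frames sharing one atom layout, stored `stride` ps apart."""

    frames: list[Frame]
    stride: float = 10.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("a Trajectory must contain at least one frame")
        if self.stride <= 0:
            raise ValidationError(f"stride must be positive, got {self.stride}")
        n0 = len(self.frames[0])
        names0 = [a.name for a in self.frames[0].atoms]
        for k, fr in enumerate(self.frames):
            if len(fr) != n0 or [a.name for a in fr.atoms] != names0:
                raise ValidationError(
                    f"frame {k} does not share the atom layout of frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Selection:
    """Conjunctive atom-selection criteria; at least one must be given."""

    resnames: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    resids: frozenset[int] | None = None
    elements: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if all(
            c is None
            for c in (self.resnames, self.atom_names, self.resids, self.elements)
        ):
            raise ValidationError("a Selection needs at least one criterion")
        for attr in ("resnames", "atom_names", "elements"):
            val = getattr(self, attr)
            if val is not None:
                object.__setattr__(self, attr, frozenset(val))
        if self.resids is not None:
            object.__setattr__(self, "resids", frozenset(int(r) for r in self.resids))


def select(frame: Frame, sel: Selection) -> list[int]:
    """Indices of atoms matching all provided criteria, in frame order."""
    out = []
    for i, a in enumerate(frame.atoms):
        if sel.resnames is not None and a.resname not in sel.resnames:
            continue
        if sel.atom_names is not None and a.name not in sel.atom_names:
            continue
        if sel.resids is not None and a.resid not in sel.resids:
            continue
        if sel.elements is not None and a.element.upper() not in {
            e.upper() for e in sel.elements
        }:
            continue
        out.append(i)
    return out


# --- PDB -------------------------------------------------------------------


def _guess_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped[:1] or "X"


def read_pdb(path: str | Path) -> Frame:
    """Parse ATOM/HETATM records of a fixed-column PDB file into a Frame.

    Occupancy and B-factor columns are ignored.  The element is taken from
    columns 77–78, falling back to the leading alphabetic character of the
    atom name.  Only the first alternate location of an atom is kept.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    seen_alt: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip()
                resid = int(line[22:26])
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed record: {exc}") from None
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _guess_element(name)
            key = (name, resid, chain)
            if altloc:
                if key in seen_alt:
                    logger.warning(
                        "%s:%d: dropping alternate location %r of atom %s",
                        path.name, lineno, altloc, name,
                    )
                    continue
                seen_alt.add(key)
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, resname=resname, resid=resid,
                    chain=chain, element=element, xyz=np.array(xyz),
                )
            )
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    return Frame(atoms=atoms)


def write_pdb(frame: Frame, path: str | Path) -> None:
    """Write a Frame as fixed-column PDB (coordinates to 3 decimals)."""
    lines = []
    for a in frame.atoms:
        if len(a.name) > 4:
            raise ValidationError(f"atom name {a.name!r} exceeds 4 characters")
        # standard convention: 1–3 char names start in column 14
        name = f" {a.name:<3s}" if len(a.name) < 4 else a.name
        x, y, z = a.xyz
        lines.append(
            f"ATOM  {a.serial:>5d} {name}{'':1s}{a.resname:<3s} {a.chain:1s}"
            f"{a.resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --- multi-frame XYZ -------------------------------------------------------


def read_xyz_traj(path: str | Path, stride_ps: float = 10.0) -> Trajectory:
    """Read concatenated XYZ blocks into a Trajectory.

    Frame k gets time k × stride_ps.  Atom metadata beyond the element is
    unavailable in XYZ; use :func:`apply_template` to restore names and
    residues from a template PDB frame.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{path.name}:{i + 1}: expected an atom count") from None
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise ParseError(
                f"{path.name}:{i + 1}: inconsistent atom count "
                f"({natoms} vs {n_expected})"
            )
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(
                f"{path.name}:{i + 1}: frame declares {natoms} atoms "
                f"but only {len(body)} coordinate lines follow"
            )
        atoms = []
        for j, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"{path.name}:{i + 3 + j}: malformed coordinate line")
            try:
                xyz = np.array([float(p) for p in parts[1:4]])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{i + 3 + j}: malformed coordinate line"
                ) from None
            atoms.append(
                AtomRecord(
                    serial=j + 1, name=parts[0], resname="UNK", resid=1,
                    chain="A", element=parts[0], xyz=xyz,
                )
            )
        frames.append(Frame(atoms=atoms, time=len(frames) * stride_ps))
        i += 2 + natoms
    if not frames:
        raise EmptyInputError(f"{path}: no XYZ frames found")
    return Trajectory(frames=frames, stride=stride_ps)


def write_xyz_traj(traj: Trajectory, path: str | Path, comment: str = "") -> None:
    """Write a Trajectory as concatenated XYZ blocks."""
    chunks = []
    for k, fr in enumerate(traj.frames):
        rows = [str(len(fr)), f"{comment} frame={k} time_ps={fr.time:g}".strip()]
        for a in fr.atoms:
            x, y, z = a.xyz
            rows.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
        chunks.append("\n".join(rows))
    Path(path).write_text("\n".join(chunks) + "\n")


def apply_template(traj: Trajectory, template: Frame) -> Trajectory:
    """Copy atom identity fields (and charges) from a template Frame onto
    every frame of an element-only trajectory (e.g. one read from XYZ)."""
    if len(template) != len(traj.frames[0]):
        raise ValidationError(
            f"template has {len(template)} atoms but trajectory frames "
            f"have {len(traj.frames[0])}"
        )
    new_frames = []
    for fr in traj.frames:
        atoms = [
            replace(t, xyz=a.xyz.copy())
            for t, a in zip(template.atoms, fr.atoms)
        ]
        new_frames.append(Frame(atoms=atoms, box=fr.box, time=fr.time))
    return Trajectory(frames=new_frames, stride=traj.stride)
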