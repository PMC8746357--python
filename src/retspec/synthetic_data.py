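"""Synthetic binding-pocket ensembles with controlled statistics.

The generators produce the inputs every downstream analysis consumes —
pocket trajectories, per-snapshot stick-spectrum tables, and reference ESP
grids — as pure functions of (config, seed), bitwise reproducible.

A generated pocket frame is a geometric scaffold, not a physically relaxed
structure: a minimal retinal-like chromophore (Schiff-base N15/H15, a
polyene chain C15…C7, and a six-carbon ring C1–C6), labelled acceptor atoms
for the pocket residues (E194 carboxylate O, Y126 hydroxyl O, S199 O,
M99/M103 S), and a shell of nearby waters oriented oxygen-toward the
positively charged Schiff base.  Only the statistics the analyses measure
are controlled:

* each labelled pair distance is an independent truncated-Normal draw per
  frame along a fixed per-pair direction;
* each contact partner is a per-frame Bernoulli draw that places the
  acceptor either in hydrogen-bond geometry (D···A uniform in 2.6–3.4 Å,
  near-linear D–H···A) or clearly outside it (4.5–6.0 Å);
* per-snapshot S1 excitation energies fluctuate Normally about an
  isomer/environment-specific mean.

Packaged fixture configs for the three retinal isomers encode published
binding-pocket statistics, so recovering them downstream is a
parameter-recovery exercise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .charge_fit import EspGrid
from .constants import COULOMB_K, vdw_radius
from .errors import ValidationError
from .structure_io import AtomRecord, Frame, Trajectory

__all__ = [
    "Seed",
    "IsomerFixtureConfig",
    "generate_trajectory",
    "generate_stick_table",
    "generate_esp_grid",
    "load_fixture",
    "list_fixtures",
]

ISOMERS = ("9-cis", "11-cis", "all-trans")


@dataclass(frozen=True)
class Seed:
    """Non-negative RNG seed; identical seeds give bit-identical outputs."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("seed must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.value)


def _as_seed(seed: "Seed | int") -> Seed:
    return seed if isinstance(seed, Seed) else Seed(int(seed))


@dataclass
class IsomerFixtureConfig:
    """Statistical recipe for one isomer's synthetic pocket ensemble.

    pair_distances maps labels like ``"N15:E194_O"`` to (mean Å, sd Å);
    contact_probs maps partner labels like ``"M103"`` to per-frame
    hydrogen-bond contact probabilities.
    """

    isomer: str
    pair_distances: dict[str, tuple[float, float]]
    contact_probs: dict[str, float]
    n_waters_near: int
    excitation_mean_protein: float  # eV
    excitation_mean_vacuum: float  # eV
    excitation_sd: float = 0.08  # eV
    oscillator_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.isomer not in ISOMERS:
            raise ValidationError(f"unknown isomer {self.isomer!r}; expected {ISOMERS}")
        for label, (mean, sd) in self.pair_distances.items():
            if mean <= 0:
                raise ValidationError(f"pair {label}: mean must be positive")
            if sd < 0:
                raise ValidationError(f"pair {label}: sd must be non-negative")
        for label, p in self.contact_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"contact {label}: probability outside [0, 1]")
        if self.n_waters_near < 0:
            raise ValidationError("n_waters_near must be non-negative")
        for attr in ("excitation_mean_protein", "excitation_mean_vacuum"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")
        if self.excitation_sd < 0 or self.oscillator_mean <= 0:
            raise ValidationError("excitation_sd must be >= 0, oscillator_mean > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "IsomerFixtureConfig":
        d = dict(d)
        d["pair_distances"] = {
            k: (float(v[0]), float(v[1])) for k, v in d["pair_distances"].items()
        }
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "IsomerFixtureConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "isomer": self.isomer,
            "pair_distances": {k: list(v) for k, v in self.pair_distances.items()},
            "contact_probs": dict(self.contact_probs),
            "n_waters_near": self.n_waters_near,
            "excitation_mean_protein": self.excitation_mean_protein,
            "excitation_mean_vacuum": self.excitation_mean_vacuum,
            "excitation_sd": self.excitation_sd,
            "oscillator_mean": self.oscillator_mean,
        }


def list_fixtures() -> list[str]:
    return list(ISOMERS)


def load_fixture(isomer: str) -> IsomerFixtureConfig:
    """Load one of the packaged isomer fixture configs."""
    fname = "isomer_" + isomer.replace("-", "_") + ".json"
    ref = resources.files("retspec.fixtures").joinpath(fname)
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValidationError(
            f"no packaged fixture for isomer {isomer!r}; known: {ISOMERS}"
        ) from None
    return IsomerFixtureConfig.from_dict(json.loads(text))


# --- pocket scaffold -------------------------------------------------------

# Retinal-like chromophore: Schiff base at the origin, polyene chain along
# −x, six-membered ring at the far end.  (name, element, xyz, charge);
# charges sum to +1 (protonated Schiff base).
_CHROMOPHORE = [
    ("N15", "N", (0.0, 0.0, 0.0), -0.30),
    ("H15", "H", (1.01, 0.0, 0.0), 0.44),
    ("C15", "C", (-1.4, 0.3, 0.0), 0.30),
    ("C14", "C", (-2.6, -0.3, 0.0), -0.15),
    ("C13", "C", (-3.9, 0.3, 0.0), 0.25),
    ("C12", "C", (-5.1, -0.3, 0.0), -0.12),
    ("C11", "C", (-6.4, 0.3, 0.0), 0.20),
    ("C10", "C", (-7.6, -0.3, 0.0), -0.10),
    ("C9", "C", (-8.9, 0.3, 0.0), 0.18),
    ("C8", "C", (-10.1, -0.3, 0.0), -0.05),
    ("C7", "C", (-11.3, 0.3, 0.0), 0.05),
    ("C6", "C", (-12.5, 0.0, 0.0), 0.05),
    ("C5", "C", (-13.2, 1.1, 0.2), 0.05),
    ("C4", "C", (-14.6, 1.0, 0.3), 0.05),
    ("C3", "C", (-15.2, -0.2, -0.2), 0.05),
    ("C2", "C", (-14.5, -1.3, -0.4), 0.05),
    ("C1", "C", (-13.1, -1.2, -0.1), 0.05),
]

_RES_LETTER = {
    "A": "ALA", "D": "ASP", "E": "GLU", "K": "LYS", "M": "MET",
    "N": "ASN", "Q": "GLN", "S": "SER", "T": "THR", "Y": "TYR",
}
# acceptor atom name, element and partial charge per residue type
_ACCEPTOR_ATOM = {
    "GLU": ("OE1", "O", -1.00),
    "ASP": ("OD1", "O", -1.00),
    "TYR": ("OH", "O", -0.56),
    "SER": ("OG", "O", -0.65),
    "THR": ("OG1", "O", -0.65),
    "MET": ("SD", "S", -0.27),
    "ASN": ("OD1", "O", -0.50),
    "GLN": ("OE1", "O", -0.50),
}
_WATER_O_CHARGE = -0.834
_WATER_H_CHARGE = 0.417
_GOLDEN_DEG = 137.50776405003785


def _parse_partner(label: str) -> tuple[str, int, str, str, float]:
    """'E194_O' or 'M103' → (resname, resid, atom name, element, charge)."""
    token = label.split("_", 1)[0]
    letter, digits = token[0], token[1:]
    if letter not in _RES_LETTER or not digits.isdigit():
        raise ValidationError(f"cannot parse partner label {label!r}")
    resname = _RES_LETTER[letter]
    if resname not in _ACCEPTOR_ATOM:
        raise ValidationError(f"no acceptor atom defined for residue {resname}")
    name, elem, charge = _ACCEPTOR_ATOM[resname]
    return resname, int(digits), name, elem, charge


def _pair_partner(label: str):
    """Pair labels look like 'N15:E194_O' — donor atom name, partner token."""
    try:
        donor, partner = label.split(":", 1)
    except ValueError:
        raise ValidationError(f"pair label {label!r} must look like 'N15:E194_O'") from None
    return donor, _parse_partner(partner)


def _direction(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at `polar` from the +x donor axis, rotated by `azimuth`."""
    a, b = math.radians(polar_deg), math.radians(azimuth_deg)
    return np.array(
        [math.cos(a), math.sin(a) * math.cos(b), math.sin(a) * math.sin(b)]
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to > 1.5 Å (redraw)."""
    if sd == 0:
        return mean
    while True:
        d = rng.normal(mean, sd)
        if d > 1.5:
            return d


def generate_trajectory(
    cfg: IsomerFixtureConfig,
    n_frames: int,
    seed: Seed | int,
    *,
    stride_ps: float = 10.0,
    ar1: float = 0.0,
) -> Trajectory:
    """Generate a synthetic pocket trajectory with the configured statistics.

    ``ar1`` adds optional lag-1 autocorrelation to the labelled pair
    distances (default 0: independent draws frame-to-frame).
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be at least 1")
    if not 0.0 <= ar1 < 1.0:
        raise ValidationError("ar1 must lie in [0, 1)")
    rng = _as_seed(seed).rng()

    pair_labels = sorted(cfg.pair_distances)
    contact_labels = sorted(cfg.contact_probs)
    pair_dirs = {
        lab: _direction(90.0, 30.0 + i * _GOLDEN_DEG)
        for i, lab in enumerate(pair_labels)
    }
    contact_dirs = {
        lab: _direction(12.0, 45.0 + i * 180.0)
        for i, lab in enumerate(contact_labels)
    }
    water_base = []
    for k in range(cfg.n_waters_near):
        d = _direction(65.0 + 12.0 * (k % 5), 75.0 + k * _GOLDEN_DEG)
        water_base.append((2.9 + 0.35 * k, d))

    prev_pair: dict[str, float] = {}
    frames = []
    for k in range(n_frames):
        atoms: list[AtomRecord] = []
        serial = 1
        for name, elem, xyz, q in _CHROMOPHORE:
            atoms.append(
                AtomRecord(serial, name, "RET", 1, "A", elem, np.array(xyz), q)
            )
            serial += 1
        for lab in pair_labels:
            mean, sd = cfg.pair_distances[lab]
            d = _truncated_normal(rng, mean, sd)
            if ar1 > 0.0 and lab in prev_pair:
                d = mean + ar1 * (prev_pair[lab] - mean) + math.sqrt(1 - ar1**2) * (d - mean)
            prev_pair[lab] = d
            _, (resname, resid, aname, elem, q) = _pair_partner(lab)
            atoms.append(
                AtomRecord(serial, aname, resname, resid, "A", elem,
                           d * pair_dirs[lab], q)
            )
            serial += 1
        for lab in contact_labels:
            p = cfg.contact_probs[lab]
            contact = rng.random() < p
            d = rng.uniform(2.6, 3.4) if contact else rng.uniform(4.5, 6.0)
            resname, resid, aname, elem, q = _parse_partner(lab)
            atoms.append(
                AtomRecord(serial, aname, resname, resid, "A", elem,
                           d * contact_dirs[lab], q)
            )
            serial += 1
        for w, (r0, d0) in enumerate(water_base):
            jitter = rng.normal(0.0, 0.1, 3)
            o = r0 * d0 + jitter
            away = d0
            perp = np.cross(away, np.array([1.0, 0.0, 0.0]))
            perp /= np.linalg.norm(perp)
            h1 = o + 0.59 * away + 0.77 * perp
            h2 = o + 0.59 * away - 0.77 * perp
            resid = 401 + w
            atoms.append(AtomRecord(serial, "O", "HOH", resid, "A", "O", o,
                                    _WATER_O_CHARGE))
            atoms.append(AtomRecord(serial + 1, "H1", "HOH", resid, "A", "H", h1,
                                    _WATER_H_CHARGE))
            atoms.append(AtomRecord(serial + 2, "H2", "HOH", resid, "A", "H", h2,
                                    _WATER_H_CHARGE))
            serial += 3
        frames.append(Frame(atoms=atoms, time=k * stride_ps))
    return Trajectory(frames=frames, stride=stride_ps)


def generate_stick_table(
    cfg: IsomerFixtureConfig,
    n_snapshots: int,
    environment: str,
    seed: Seed | int,
    *,
    n_states: int = 1,
) -> pd.DataFrame:
    """Per-snapshot stick-spectrum table for one environment.

    One S1 row per snapshot with energy ~ Normal(environment mean, sd) and
    oscillator strength ~ Normal(f̄, 0.1 f̄) truncated positive; with
    ``n_states > 1``, higher states are added at larger energies with small
    strengths.
    """
    if n_snapshots < 1:
        raise ValidationError("n_snapshots must be at least 1")
    if environment == "protein":
        mean = cfg.excitation_mean_protein
    elif environment == "vacuum":
        mean = cfg.excitation_mean_vacuum
    else:
        raise ValidationError(
            f"unknown environment {environment!r}; expected 'protein' or 'vacuum'"
        )
    if n_states < 1:
        raise ValidationError("n_states must be at least 1")
    rng = _as_seed(seed).rng()
    rows = []
    for snap in range(n_snapshots):
        e1 = rng.normal(mean, cfg.excitation_sd)
        while True:
            f1 = rng.normal(cfg.oscillator_mean, 0.1 * cfg.oscillator_mean)
            if f1 > 0:
                break
        rows.append((snap, 1, e1, f1))
        for s in range(2, n_states + 1):
            es = e1 + 0.3 * (s - 1) + abs(rng.normal(0.0, 0.05))
            fs = abs(rng.normal(0.02, 0.01))
            rows.append((snap, s, es, fs))
    return pd.DataFrame(rows, columns=["snapshot", "state", "energy_eV", "osc_strength"])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def generate_esp_grid(
    atoms: Frame,
    shells: list[float],
    density: float,
    seed: Seed | int,
    *,
    conformer_id: int = 0,
) -> EspGrid:
    """Shell-based ESP sample grid with exact Coulomb reference potentials.

    Points sit on concentric shells at ``scale × vdW radius`` around every
    atom (Fibonacci lattice, randomly rotated per atom/shell), excluding
    points inside any other atom's scaled sphere; the reference potential at
    each point is the exact Coulomb sum over the frame's charges.
    """
    if not shells:
        raise ValidationError("need at least one shell scale factor")
    charges = atoms.charges
    coords = atoms.coords
    radii = np.array([vdw_radius(a.element) for a in atoms.atoms])
    rng = _as_seed(seed).rng()
    from .electrostatics import fibonacci_sphere

    pts = []
    for scale in shells:
        if scale <= 0:
            raise ValidationError("shell scale factors must be positive")
        for i in range(len(atoms)):
            r = scale * radii[i]
            n_pts = max(1, int(round(density * 4.0 * math.pi * r * r)))
            unit = fibonacci_sphere(n_pts) @ _random_rotation(rng).T
            cand = coords[i] + r * unit
            keep = np.ones(len(cand), dtype=bool)
            for j in range(len(atoms)):
                if j == i:
                    continue
                keep &= (
                    np.linalg.norm(cand - coords[j], axis=1)
                    >= scale * radii[j] - 1e-9
                )
            pts.append(cand[keep])
    points = np.vstack(pts)
    dists = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    v_ref = COULOMB_K * (charges[None, :] / dists).sum(axis=1)
    return EspGrid(points=points, v_ref=v_ref, conformer_id=conformer_id)
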