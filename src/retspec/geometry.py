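"""Trajectory geometry statistics for the chromophore binding pocket.

Covers the three summaries the pocket analysis needs: averaged pair
distances (e.g. Schiff-base nitrogen to counterion oxygen), geometric
hydrogen-bond occupancies, and the integrated radial distribution function
of pocket waters around the chromophore (a frame-averaged cumulative water
count, not a density-normalised g(r)).

No periodic minimum-image convention is applied by default: the analyses
operate on extracted pocket models.  Pass ``use_box=True`` to enable
orthorhombic minimum-image distances for boxed frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError, ValidationError
from .structure_io import Frame, Selection, Trajectory, select

__all__ = [
    "HBondCriteria",
    "IntegratedRdf",
    "pair_distance_stats",
    "integrated_rdf",
    "hbond_occupancy",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion: donor–acceptor distance cap and
    donor–hydrogen–acceptor angle floor (degrees)."""

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValidationError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValidationError("min_dha_angle must lie in (0, 180]")


@dataclass
class IntegratedRdf:
    """Mean cumulative water count within radius r of the chromophore."""

    radii: np.ndarray  # Å, increasing
    counts: np.ndarray  # frame-averaged cumulative counts

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.radii.shape != self.counts.shape:
            raise ValidationError("radii and counts must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValidationError("radius grid must be strictly increasing")
        if np.any(self.counts < 0) or np.any(np.diff(self.counts) < -1e-12):
            raise ValidationError("counts must be non-negative and non-decreasing")


def _resolve_single(frame: Frame, sel: Selection, what: str) -> int:
    idx = select(frame, sel)
    if len(idx) != 1:
        raise SelectionError(
            f"{what} selection must resolve to exactly one atom, got {len(idx)}"
        )
    return idx[0]


def _dist(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    d = a - b
    if box is not None:
        d = d - box * np.round(d / box)
    return float(np.sqrt(np.sum(d * d)))


def pair_distance_stats(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    *,
    use_box: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Per-frame distance between two single-atom selections.

    Returns (mean, sample sd with n−1 denominator, per-frame series in Å).
    """
    ia = _resolve_single(traj.frames[0], sel_a, "first")
    ib = _resolve_single(traj.frames[0], sel_b, "second")
    series = np.empty(len(traj))
    for k, fr in enumerate(traj.frames):
        box = fr.box if use_box else None
        series[k] = _dist(fr.atoms[ia].xyz, fr.atoms[ib].xyz, box)
    mean = float(series.mean())
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return mean, sd, series


def integrated_rdf(
    traj: Trajectory,
    chromophore: Selection,
    waters: Selection,
    r_max: float = 10.0,
    dr: float = 0.1,
    *,
    heavy_only: bool = True,
    use_box: bool = False,
) -> IntegratedRdf:
    """Frame-averaged cumulative count of waters within r of the chromophore.

    Each selected water atom (conventionally the oxygen) contributes at its
    minimum distance to any chromophore heavy atom; hydrogens are excluded
    from the reference set unless ``heavy_only=False``.
    """
    if dr <= 0 or r_max <= 0:
        raise ValidationError("r_max and dr must be positive")
    chrom_idx = select(traj.frames[0], chromophore)
    if heavy_only:
        chrom_idx = [
            i for i in chrom_idx if traj.frames[0].atoms[i].element.upper() != "H"
        ]
    if not chrom_idx:
        raise SelectionError("chromophore selection resolved to no (heavy) atoms")
    water_idx = select(traj.frames[0], waters)
    n_bins = int(round(r_max / dr))
    radii = dr * np.arange(1, n_bins + 1)
    counts = np.zeros(n_bins)
    for fr in traj.frames:
        box = fr.box if use_box else None
        ref = np.array([fr.atoms[i].xyz for i in chrom_idx])
        for iw in water_idx:
            w = fr.atoms[iw].xyz
            if box is None:
                dmin = float(np.min(np.linalg.norm(ref - w, axis=1)))
            else:
                dmin = min(_dist(w, r, box) for r in ref)
            counts += dmin <= radii
    counts /= len(traj)
    return IntegratedRdf(radii=radii, counts=counts)


def hbond_occupancy(
    traj: Trajectory,
    donor: Selection,
    donor_h: Selection,
    acceptor: Selection,
    crit: HBondCriteria = HBondCriteria(),
) -> float:
    """Percentage of frames satisfying the geometric H-bond criterion
    D···A ≤ max distance and D–H···A angle ≥ min angle."""
    i_d = _resolve_single(traj.frames[0], donor, "donor")
    i_h = _resolve_single(traj.frames[0], donor_h, "donor hydrogen")
    i_a = _resolve_single(traj.frames[0], acceptor, "acceptor")
    hits = 0
    for fr in traj.frames:
        d, h, a = fr.atoms[i_d].xyz, fr.atoms[i_h].xyz, fr.atoms[i_a].xyz
        if np.linalg.norm(a - d) > crit.max_da_distance:
            continue
        v1 = d - h
        v2 = a - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle >= crit.min_dha_angle:
            hits += 1
    return 100.0 * hits / len(traj)
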