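"""Restrained multi-conformer ESP charge fitting (RESP-style).

Atomic point charges are fitted to reproduce a reference electrostatic
potential sampled on grids around one or more conformers, minimising

    Σ_conf Σ_points (v_ref − Σᵢ k qᵢ/rᵢ)²  +  a Σ_{i∈restrained} (√(qᵢ²+b²) − b)

subject to a total-charge constraint, exact equality within equivalence
groups (e.g. equivalent hydrogens), and frozen charges.  The hyperbolic
restraint (b = 0.1 e) pulls restrained charges toward zero without a hard
cap; it is handled by iteratively re-linearised least squares: at each
iteration the penalty contributes a diagonal term a/√(q²+b²) evaluated at
the current charges, and the resulting linear KKT system (Lagrange
multiplier for the total charge, variable reduction for groups and frozen
atoms) is solved until the charges move by less than 1e-6 e.

This is a single-stage fit: the restrained set and equivalence groups are
supplied explicitly by the caller rather than via a two-stage refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .constants import COULOMB_K
from .errors import RankDeficiencyError, ValidationError
from .structure_io import Frame

logger = logging.getLogger(__name__)

__all__ = ["EspGrid", "ChargeFitProblem", "ChargeFitResult", "fit_charges", "esp_rrms"]


@dataclass
class EspGrid:
    """Reference electrostatic-potential samples around one conformer."""

    points: np.ndarray  # (n, 3), Å
    v_ref: np.ndarray  # (n,), kcal/(mol·e)
    conformer_id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.v_ref = np.asarray(self.v_ref, dtype=float).reshape(-1)
        if len(self.points) != len(self.v_ref):
            raise ValidationError("points and v_ref must have equal length")
        if len(self.points) == 0:
            raise ValidationError("ESP grid is empty")


@dataclass
class ChargeFitProblem:
    """Specification of a restrained multi-conformer charge fit."""

    conformers: list[Frame]
    grids: list[EspGrid]
    total_charge: float | None = 0.0
    restraint_weight: float = 0.005  # the `a` of the hyperbolic penalty
    restraint_b: float = 0.1  # e
    restrained_atoms: frozenset[int] = frozenset()
    equivalence_groups: list[frozenset[int]] = field(default_factory=list)
    frozen: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conformers or not self.grids:
            raise ValidationError("need at least one conformer with a grid")
        if len(self.conformers) != len(self.grids):
            raise ValidationError("one grid per conformer required")
        n = len(self.conformers[0])
        for c in self.conformers:
            if len(c) != n:
                raise ValidationError("all conformers must share one atom count")
        self.restrained_atoms = frozenset(self.restrained_atoms)
        self.equivalence_groups = [frozenset(g) for g in self.equivalence_groups]
        seen: set[int] = set()
        for g in self.equivalence_groups:
            if g & seen:
                raise ValidationError("an atom appears in multiple equivalence groups")
            seen |= g
        if set(self.frozen) & seen:
            raise ValidationError("frozen atoms cannot be in equivalence groups")
        for idx in list(self.restrained_atoms) + list(self.frozen) + sorted(seen):
            if not 0 <= idx < n:
                raise ValidationError(f"atom index {idx} out of range (n={n})")
        for g in self.grids:
            if len(g.points) < n:
                logger.warning(
                    "conformer %d grid has fewer points (%d) than atoms (%d)",
                    g.conformer_id, len(g.points), n,
                )

    @property
    def n_atoms(self) -> int:
        return len(self.conformers[0])


@dataclass
class ChargeFitResult:
    charges: np.ndarray  # (n_atoms,), e
    rrms: float
    iterations: int
    converged: bool


def _design_matrix(problem: ChargeFitProblem) -> tuple[np.ndarray, np.ndarray]:
    """Stacked Coulomb design matrix A (points × atoms) and target v."""
    blocks, targets = [], []
    for frame, grid in zip(problem.conformers, problem.grids):
        coords = frame.coords
        r = np.linalg.norm(grid.points[:, None, :] - coords[None, :, :], axis=2)
        if np.min(r) < 1e-6:
            raise ValidationError("a grid point coincides with an atom")
        blocks.append(COULOMB_K / r)
        targets.append(grid.v_ref)
    return np.vstack(blocks), np.concatenate(targets)


def _reduction(problem: ChargeFitProblem) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """q = T p + q0: map free variables p to atomic charges q."""
    n = problem.n_atoms
    group_of = {}
    for g in problem.equivalence_groups:
        members = sorted(g)
        for m in members:
            group_of[m] = members[0]
    free_vars: list[list[int]] = []  # atoms per free variable
    col_of_rep: dict[int, int] = {}
    q0 = np.zeros(n)
    cols = []
    for i in range(n):
        if i in problem.frozen:
            q0[i] = problem.frozen[i]
            cols.append(None)
            continue
        rep = group_of.get(i, i)
        if rep in col_of_rep:
            free_vars[col_of_rep[rep]].append(i)
            cols.append(col_of_rep[rep])
        else:
            col_of_rep[rep] = len(free_vars)
            free_vars.append([i])
            cols.append(col_of_rep[rep])
    T = np.zeros((n, len(free_vars)))
    for i, c in enumerate(cols):
        if c is not None:
            T[i, c] = 1.0
    return T, q0, free_vars


def fit_charges(
    problem: ChargeFitProblem,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ChargeFitResult:
    """Solve the restrained charge fit; see module docstring for the model."""
    A, v = _design_matrix(problem)
    T, q0, free_vars = _reduction(problem)
    n = problem.n_atoms
    m = T.shape[1]
    if m == 0:
        q = q0
        return ChargeFitResult(
            charges=q, rrms=esp_rrms(q, problem.grids, problem.conformers),
            iterations=0, converged=True,
        )
    AtA = A.T @ A
    Atv = A.T @ v
    ones = np.ones(n)
    constrained = problem.total_charge is not None
    a, b = problem.restraint_weight, problem.restraint_b
    restrained = np.zeros(n, dtype=bool)
    for i in problem.restrained_atoms:
        restrained[i] = True

    q = q0 + T @ np.zeros(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        diag = np.zeros(n)
        if a > 0:
            diag[restrained] = a / np.sqrt(q[restrained] ** 2 + b**2)
        M = AtA + np.diag(diag)
        B = T.T @ M @ T
        rhs = T.T @ (Atv - M @ q0)
        if constrained:
            # scale the constraint row to the magnitude of B so the KKT
            # condition number reflects genuine degeneracy, not units
            s = max(float(np.mean(np.abs(np.diag(B)))), 1.0)
            c = s * (T.T @ ones)
            K = np.zeros((m + 1, m + 1))
            K[:m, :m] = B
            K[:m, m] = c
            K[m, :m] = c
            kr = np.concatenate([rhs, [s * (problem.total_charge - ones @ q0)]])
        else:
            K, kr = B, rhs
        try:
            sol = np.linalg.solve(K, kr)
        except np.linalg.LinAlgError:
            raise RankDeficiencyError(_degenerate_message(B, free_vars)) from None
        if np.linalg.cond(K) > 1e10:
            raise RankDeficiencyError(_degenerate_message(B, free_vars))
        p = sol[:m] if constrained else sol
        q_new = q0 + T @ p
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        if delta < tol:
            converged = True
            break
    return ChargeFitResult(
        charges=q,
        rrms=esp_rrms(q, problem.grids, problem.conformers),
        iterations=it,
        converged=converged,
    )


def _degenerate_message(B: np.ndarray, free_vars: list[list[int]]) -> str:
    _, s, vt = np.linalg.svd(B)
    null = vt[-1]
    worst = np.argsort(-np.abs(null))[:3]
    atoms = sorted({a for w in worst for a in free_vars[int(w)]})
    return (
        "charge-fit normal equations are rank deficient; "
        f"degenerate atoms (0-based): {atoms}"
    )


def esp_rrms(
    charges: np.ndarray, grids: list[EspGrid], conformers: list[Frame]
) -> float:
    """Relative RMS ESP error √(Σ(v_ref−v_model)² / Σ v_ref²), pooled."""
    charges = np.asarray(charges, dtype=float)
    num = den = 0.0
    for frame, grid in zip(conformers, grids):
        r = np.linalg.norm(grid.points[:, None, :] - frame.coords[None, :, :], axis=2)
        v_model = COULOMB_K * (charges[None, :] / r).sum(axis=1)
        num += float(np.sum((grid.v_ref - v_model) ** 2))
        den += float(np.sum(grid.v_ref**2))
    if den == 0.0:
        raise ValidationError("reference potential is identically zero; rrms undefined")
    return float(np.sqrt(num / den))
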