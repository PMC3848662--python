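"""Slotboom change of variables and the decoupled Poisson potential solve.

The substitution Z_i = C_i * exp((m_i/d_i) * phi / V_T) symmetrizes the
drift-diffusion operator: in the Z variables every species solves a weighted
diffusion problem with the positive weight q_i = exp(-(m_i/d_i) * phi / V_T),
so the discrete systems are symmetric positive definite.

The electric potential phi satisfies the Poisson equation
-eps * Lap(phi) = sum_i z_i C_i - f with phi = 0 on the membrane.  The solve
is performed in simulation (mV-scale) units on the interior node set; the
division by the thermal voltage V_T happens only inside the Slotboom
exponents, keeping them dimensionless and numerically tame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import fem
from .mesh import TriMesh

__all__ = [
    "SlotboomFactors",
    "PotentialField",
    "slotboom_factors",
    "slotboom_transform",
    "solve_potential",
    "PoissonSolver",
]


@dataclass
class SlotboomFactors:
    """Per-species nodal factors q_i = exp(-(m_i/d_i) phi / V_T) and p_i = 1/q_i."""

    q: np.ndarray  # (n_species, n_nodes)
    p: np.ndarray


@dataclass
class PotentialField:
    """Nodal electric potential in simulation units (mV); zero on the membrane."""

    values: np.ndarray
    boundary_nodes: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def slotboom_factors(
    phi, species, v_thermal: float = 1.0, clamp: float = fem.DEFAULT_CLAMP
) -> SlotboomFactors:
    """Nodal Slotboom factors for every species.

    ``phi`` is a nodal potential (or a PotentialField) in the same units as
    ``v_thermal``; the exponent is -(m/d) * phi / v_thermal, clamped per the
    assembly policy.
    """
    if isinstance(phi, PotentialField):
        phi = phi.values
    phi = np.asarray(phi, dtype=float)
    ratios = np.array([s.ratio for s in species])
    expo = -np.outer(ratios, phi) / v_thermal
    q = fem.clamped_exp(expo, clamp)
    return SlotboomFactors(q=q, p=1.0 / q)


def slotboom_transform(
    field: np.ndarray, factors: SlotboomFactors, species_index: int, direction: str
) -> np.ndarray:
    """Convert nodally between Slotboom variable Z and concentration C.

    direction "to-C": C = q_i * Z; direction "to-Z": Z = C / q_i = p_i * C.
    """
    field = np.asarray(field, dtype=float)
    if direction == "to-C":
        return factors.q[species_index] * field
    if direction == "to-Z":
        return factors.p[species_index] * field
    raise ValueError(f"direction must be 'to-C' or 'to-Z', got {direction!r}")


class PoissonSolver:
    """Interior-node Poisson solver with a cached factorization of eps*Q_{YxY}.

    The Laplace matrix depends only on the mesh, so one LU factorization
    serves every time step.
    """

    def __init__(self, mesh: TriMesh, epsilon: float, degree: int = 2):
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if mesh.interior_nodes.size == 0:
            raise ValueError("mesh has no interior nodes; Poisson system is empty")
        self.mesh = mesh
        self.epsilon = epsilon
        self.degree = degree
        Q = fem.assemble_laplace(mesh, degree)
        Y = mesh.interior_nodes
        self._solve = spla.factorized((epsilon * Q[np.ix_(Y, Y)]).tocsc())

    def solve(self, rhs: np.ndarray) -> PotentialField:
        """Solve eps * Q_{YxY} phi_Y = rhs_Y with zero membrane values."""
        phi = np.zeros(self.mesh.n_nodes)
        phi[self.mesh.interior_nodes] = self._solve(rhs[self.mesh.interior_nodes])
        return PotentialField(values=phi, boundary_nodes=self.mesh.boundary_nodes)


def solve_potential(
    mesh: TriMesh,
    species,
    xi: np.ndarray,
    phi_prev,
    epsilon: float,
    f,
    v_thermal: float = 1.0,
    degree: int = 2,
    clamp: float = fem.DEFAULT_CLAMP,
    _solver: PoissonSolver | None = None,
) -> PotentialField:
    """One discrete Poisson step for the potential.

    Solves eps * Q_{YxY} phi_Y = [sum_i z_i M_i(phi_prev) xi_i - beta]_Y where
    M_i is the mass matrix weighted by the species' Slotboom factor evaluated
    from the previous potential, xi_i the nodal Slotboom variables, and beta
    the fixed-charge load.  Membrane values are exactly zero.
    """
    if isinstance(phi_prev, PotentialField):
        phi_prev = phi_prev.values
    solver = _solver if _solver is not None else PoissonSolver(mesh, epsilon, degree)
    rhs = -fem.assemble_charge_load(mesh, f, degree)
    for j, spec in enumerate(species):
        if spec.z == 0:
            continue
        Mj = fem.assemble_weighted_mass(
            mesh, phi_prev, spec.ratio / v_thermal, degree, clamp
        )
        rhs += spec.z * (Mj @ np.asarray(xi[j], dtype=float))
    return solver.solve(rhs)
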