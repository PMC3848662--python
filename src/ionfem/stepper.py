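"""Implicit-Euler time integration with per-model Picard fixed-point loops.

One step from t_n to t_{n+1} proceeds exactly in the algorithmic order of the
discrete system:

1. the potential solves the decoupled Poisson step with lagged charge,
   eps * Q_{YxY} phi^{n+1}_Y = [sum_i z_i M_i(phi^n) xi_i^n - beta]_Y;
2. the Slotboom factors are refreshed, q_i^{n+1} = exp(-(m_i/d_i) phi^{n+1}/V_T);
3. every species solves (A_i^{n+1} + dt R_i^{n+1}) xi_i^{n+1}
   = A_i^n xi_i^n + dt S_i^{n+1}, the weighted matrices carrying q^{n+1} on
   the left and q^n in the history term.

Nonlinear reaction terms are handled by the model's Picard pattern: the
own-species factor of each negative term multiplies the new iterate (it is
assembled into the system matrix), all other factors come from a working
vector updated species-by-species in a Gauss–Seidel sweep, so already-updated
species enter at iterate k+1 and the rest at k.  The loop stops when the
summed L2 increment over the looped species falls below ``eps``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import fem
from .electro import PoissonSolver, PotentialField
from .kinetics import KineticsModel
from .mesh import TriMesh, nearest_node

__all__ = [
    "SolverConfig",
    "SimulationState",
    "PicardDiagnostics",
    "Trajectory",
    "initialize",
    "advance",
    "simulate",
    "PicardNonConvergence",
]

log = logging.getLogger(__name__)

#: thermal voltage RT/F in mV, the natural scale of membrane potentials
DEFAULT_THERMAL_VOLTAGE = 25.693


class PicardNonConvergence(RuntimeError):
    """Picard loop failed to reach the tolerance within the iteration cap."""


@dataclass
class SolverConfig:
    """Time-integration and coupling parameters.

    dt, t_end in seconds; ``eps`` is the Picard stopping tolerance in L2
    concentration units (uM); ``epsilon`` the permittivity and
    ``fixed_charge`` the fixed-charge density f of the Poisson equation;
    ``v_thermal`` the thermal voltage in mV dividing the Slotboom exponents.
    ``on_nonconvergence`` is "warn" (accept the last iterate) or "raise".
    """

    dt: float
    t_end: float
    eps: float = 1e-4
    max_picard: int = 50
    quad_degree: int = 2
    v_thermal: float = DEFAULT_THERMAL_VOLTAGE
    clamp: float = fem.DEFAULT_CLAMP
    epsilon: float = 1.0
    fixed_charge: float = 0.0
    on_nonconvergence: str = "warn"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least dt")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_picard < 1:
            raise ValueError("max_picard must be >= 1")


@dataclass
class PicardDiagnostics:
    """Per-step Picard record: iterations, per-iteration L2 increments, flag."""

    iterations: int
    increments: np.ndarray  # (iterations, n_species); zeros for unlooped species
    converged: bool

    def max_increment_per_species(self) -> np.ndarray:
        if self.increments.size == 0:
            return np.zeros(0)
        return self.increments.max(axis=0)


@dataclass
class SimulationState:
    """Discrete state at time t_n: potential, Slotboom variables and factors."""

    n: int
    t: float
    phi: np.ndarray  # nodal potential, mV, zero on the membrane
    xi: np.ndarray  # (n_species, n_nodes) Slotboom variables
    q_nodal: np.ndarray  # (n_species, n_nodes) nodal Slotboom factors
    diagnostics: PicardDiagnostics | None = None
    min_concentration: float = math.inf
    # pointwise weights exp(-rho*phi) at quadrature points, keyed by rho
    _wpts: dict = field(default_factory=dict, repr=False)
    _A: dict = field(default_factory=dict, repr=False)

    def concentrations(self) -> np.ndarray:
        """Reconstructed nodal concentrations C_i = q_i * Z_i (uM)."""
        return self.q_nodal * self.xi


def _distinct_ratios(species, v_thermal: float) -> list[float]:
    out = []
    for s in species:
        rho = s.ratio / v_thermal
        if rho not in out:
            out.append(rho)
    return out


def _weights_at_points(mesh, phi, rhos, degree, clamp):
    eb = fem.element_basis(mesh, degree)
    phi_pts = eb.interpolate(phi)
    return {
        rho: (
            np.ones_like(phi_pts)
            if rho == 0.0
            else fem.clamped_exp(-rho * phi_pts, clamp)
        )
        for rho in rhos
    }


def _nodal_factors(phi, species, v_thermal, clamp):
    ratios = np.array([s.ratio for s in species])
    return fem.clamped_exp(-np.outer(ratios, phi) / v_thermal, clamp)


def initialize(
    mesh: TriMesh, species, config: SolverConfig, phi0
) -> SimulationState:
    """Initial state: phi^0 from phi0 (interior) and 0 (membrane); Z^0 = C_0 p^0.

    ``phi0`` is a scalar interior potential in mV or a full nodal vector.
    """
    phi = np.zeros(mesh.n_nodes)
    if np.isscalar(phi0):
        phi[mesh.interior_nodes] = float(phi0)
    else:
        phi0 = np.asarray(phi0, dtype=float)
        phi[:] = phi0
        phi[mesh.boundary_nodes] = 0.0
    for s in species:
        c0 = np.asarray(s.c0, dtype=float)
        if np.any(c0 < 0):
            raise ValueError(f"species {s.name!r}: negative initial concentration")
    q = _nodal_factors(phi, species, config.v_thermal, config.clamp)
    c0 = np.stack(
        [np.broadcast_to(np.asarray(s.c0, dtype=float), (mesh.n_nodes,)) for s in species]
    )
    xi = c0 / q  # Z^0 = C_0 * p^0 with p = 1/q
    rhos = _distinct_ratios(species, config.v_thermal)
    state = SimulationState(n=0, t=0.0, phi=phi, xi=xi, q_nodal=q)
    state._wpts = _weights_at_points(mesh, phi, rhos, config.quad_degree, config.clamp)
    for rho in rhos:
        state._A[rho] = fem.mass_from_pointwise(mesh, state._wpts[rho], config.quad_degree)
    state.min_concentration = float(np.min(c0))
    return state


def advance(
    state: SimulationState,
    mesh: TriMesh,
    species,
    kinetics: KineticsModel,
    config: SolverConfig,
    _poisson: PoissonSolver | None = None,
) -> SimulationState:
    """One implicit-Euler step with the model's Picard/Gauss–Seidel pattern."""
    ns = len(species)
    if ns != kinetics.n_species:
        raise ValueError("species list and kinetics model disagree on species count")
    dt = config.dt
    degree = config.quad_degree
    eb = fem.element_basis(mesh, degree)
    poisson = _poisson if _poisson is not None else PoissonSolver(mesh, config.epsilon, degree)

    # 1. potential from the lagged charge density
    rhs = -fem.assemble_charge_load(mesh, config.fixed_charge, degree)
    for j, spec in enumerate(species):
        if spec.z == 0:
            continue
        rho = spec.ratio / config.v_thermal
        rhs += spec.z * (state._A[rho] @ state.xi[j])
    phi_new = poisson.solve(rhs).values

    # 2. refreshed Slotboom weights (quadrature-point and nodal)
    rhos = _distinct_ratios(species, config.v_thermal)
    w_new = _weights_at_points(mesh, phi_new, rhos, degree, config.clamp)
    A_new = {rho: fem.mass_from_pointwise(mesh, w_new[rho], degree) for rho in rhos}
    K_new = {
        rho: fem.stiffness_from_weights(mesh, w_new[rho] @ eb.qw, 1.0, degree)
        for rho in rhos
    }
    q_nodal = _nodal_factors(phi_new, species, config.v_thermal, config.clamp)

    spec_rho = [s.ratio / config.v_thermal for s in species]
    A_old = [state._A[r] for r in spec_rho]
    A_n1 = [A_new[r] for r in spec_rho]
    lhs_lin = [(A_new[r] + dt * species[j].d * K_new[r]).tocsc() for j, r in enumerate(spec_rho)]
    hist = [A_old[j] @ state.xi[j] for j in range(ns)]

    Z = state.xi.copy()
    # working concentrations at quadrature points
    c_pts = np.stack([w_new[spec_rho[j]] * eb.interpolate(Z[j]) for j in range(ns)])

    M0 = fem.mass_matrix(mesh, degree)

    def norm(v):
        return float(np.sqrt(max(v @ (M0 @ v), 0.0)))

    def solve_species(j, with_reaction):
        if with_reaction:
            w = np.broadcast_to(
                np.asarray(kinetics.lhs_weight(j, c_pts), dtype=float), c_pts[j].shape
            )
            r = np.broadcast_to(
                np.asarray(kinetics.rhs_rate(j, c_pts), dtype=float), c_pts[j].shape
            )
            if not np.all(np.isfinite(r)):
                raise FloatingPointError(
                    f"non-finite reaction rate for species {species[j].name!r} "
                    f"at step {state.n + 1}"
                )
            B = fem.mass_from_pointwise(mesh, w * w_new[spec_rho[j]], degree)
            lhs = lhs_lin[j] + dt * B
            rhs_j = hist[j] + dt * fem.load_from_pointwise(mesh, r, degree)
        else:
            lhs = lhs_lin[j]
            rhs_j = hist[j]
        try:
            return spla.spsolve(lhs.tocsc(), rhs_j)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"linear solve failed for species {species[j].name!r} at step "
                f"{state.n + 1}"
            ) from exc

    # 3a. species solved before the loop (reaction-free in every preset)
    for j in kinetics.pre:
        Z[j] = solve_species(j, with_reaction=True)
        c_pts[j] = w_new[spec_rho[j]] * eb.interpolate(Z[j])

    # 3b. Picard loop with Gauss–Seidel species sweep
    increments: list[np.ndarray] = []
    converged = len(kinetics.loop) == 0
    for _k in range(config.max_picard):
        inc = np.zeros(ns)
        for j in kinetics.loop:
            z_next = solve_species(j, with_reaction=True)
            inc[j] = norm(z_next - Z[j])
            Z[j] = z_next
            c_pts[j] = w_new[spec_rho[j]] * eb.interpolate(Z[j])
        increments.append(inc)
        if float(inc.sum()) < config.eps:
            converged = True
            break
    if not converged and kinetics.loop:
        msg = (
            f"Picard loop did not converge in {config.max_picard} iterations at "
            f"step {state.n + 1} (last increment {float(increments[-1].sum()):.3e})"
        )
        if config.on_nonconvergence == "raise":
            raise PicardNonConvergence(msg)
        log.warning(msg)

    # 3c. species solved after the loop (with converged fields)
    for j in kinetics.post:
        Z[j] = solve_species(j, with_reaction=True)
        c_pts[j] = w_new[spec_rho[j]] * eb.interpolate(Z[j])

    diag = PicardDiagnostics(
        iterations=len(increments),
        increments=np.array(increments).reshape(len(increments), ns),
        converged=converged,
    )
    new = SimulationState(
        n=state.n + 1,
        t=state.t + dt,
        phi=phi_new,
        xi=Z,
        q_nodal=q_nodal,
        diagnostics=diag,
    )
    new._wpts = w_new
    new._A = A_new
    new.min_concentration = float(np.min(q_nodal * Z))
    if new.min_concentration < -1e-8:
        log.warning(
            "negative concentration %.3e uM at step %d", new.min_concentration, new.n
        )
    return new


@dataclass
class Trajectory:
    """Result of :func:`simulate`: probe series, diagnostics, snapshots."""

    times: np.ndarray
    probe_nodes: np.ndarray
    probe_concentrations: np.ndarray  # (n_times, n_probes, n_species), uM
    probe_potential: np.ndarray  # (n_times, n_probes), mV
    picard_iterations: np.ndarray
    diagnostics: list[PicardDiagnostics]
    species_names: list[str]
    snapshots: list[tuple[float, np.ndarray, np.ndarray]]  # (t, C (ns,m), phi)
    min_concentration: float
    dt: float

    def to_dataframe(self, probe: int = 0):
        """Probe series as a DataFrame: time, one column per species, phi, iters."""
        import pandas as pd

        data = {"time": self.times}
        for i, name in enumerate(self.species_names):
            data[name] = self.probe_concentrations[:, probe, i]
        data["phi_probe"] = self.probe_potential[:, probe]
        data["picard_iters"] = self.picard_iterations
        return pd.DataFrame(data)


def simulate(
    mesh: TriMesh,
    species,
    kinetics: KineticsModel,
    config: SolverConfig,
    probes=((0.0, 0.0),),
    phi0: float = 0.0,
    snapshot_every: int = 0,
) -> Trajectory:
    """Integrate to t_end, recording probe concentrations every step.

    Runs exactly ceil(t_end/dt) steps.  ``probes`` is a list of points, each
    mapped to its nearest mesh node.  ``snapshot_every`` > 0 stores full
    concentration/potential fields every that many steps (plus t=0 and the
    final step).
    """
    n_steps = math.ceil(config.t_end / config.dt - 1e-12)
    probe_nodes = np.array([nearest_node(mesh, p) for p in probes], dtype=np.int64)
    state = initialize(mesh, species, config, phi0)
    poisson = PoissonSolver(mesh, config.epsilon, config.quad_degree)

    times = np.empty(n_steps + 1)
    pc = np.empty((n_steps + 1, len(probe_nodes), len(species)))
    pp = np.empty((n_steps + 1, len(probe_nodes)))
    iters = np.zeros(n_steps + 1, dtype=np.int64)
    diags: list[PicardDiagnostics] = []
    snaps: list[tuple[float, np.ndarray, np.ndarray]] = []
    min_c = state.min_concentration

    def record(k, st):
        times[k] = st.t
        conc = st.concentrations()
        pc[k] = conc[:, probe_nodes].T
        pp[k] = st.phi[probe_nodes]
        if st.diagnostics is not None:
            iters[k] = st.diagnostics.iterations
        if snapshot_every and (k % snapshot_every == 0 or k == n_steps):
            snaps.append((st.t, conc.copy(), st.phi.copy()))

    record(0, state)
    for k in range(1, n_steps + 1):
        state = advance(state, mesh, species, kinetics, config, _poisson=poisson)
        diags.append(state.diagnostics)
        min_c = min(min_c, state.min_concentration)
        record(k, state)
        log.info(
            "step %d t=%.6g picard=%d max_inc=%.3e",
            k,
            state.t,
            state.diagnostics.iterations,
            float(state.diagnostics.increments.max(initial=0.0)),
        )

    return Trajectory(
        times=times,
        probe_nodes=probe_nodes,
        probe_concentrations=pc,
        probe_potential=pp,
        picard_iterations=iters,
        diagnostics=diags,
        species_names=[s.name for s in species],
        snapshots=snaps,
        min_concentration=min_c,
        dt=config.dt,
    )
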