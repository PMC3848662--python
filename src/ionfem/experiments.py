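"""Convergence and stability studies for the electrodiffusion solver.

The convergence error of a run is the Picard-increment functional

    E_h = dt * sum_i sum_n max_k || Z_i^{n,k+1} - Z_i^{n,k} ||_L2,

the time step tied to the mesh by dt = h * T / 16 so that space and time are
refined together.  The stability study integrates one model at dt, dt/2 and
dt/4 on a single mesh and reports pairwise relative L2 discrepancies of the
final product field.  Observed spatial order is the log-log least-squares
slope of error against mesh size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import fem
from .kinetics import KineticsModel
from .mesh import TriMesh, generate_ellipse_mesh
from .stepper import PicardDiagnostics, SolverConfig, Trajectory, simulate

__all__ = [
    "ModelSetup",
    "ConvergenceRecord",
    "StabilityResult",
    "convergence_error",
    "convergence_study",
    "stability_study",
    "observed_order",
]

log = logging.getLogger(__name__)


@dataclass
class ModelSetup:
    """Everything defining one reference model run except mesh and time grid."""

    name: str
    species: list
    kinetics: KineticsModel
    solver: SolverConfig
    phi0: float = 0.0
    a: float = 2.0
    b: float = 1.0


@dataclass
class ConvergenceRecord:
    """One row of a mesh-refinement table."""

    model: str
    h: float
    dt: float
    n_elements: int
    error: float  # E_h
    mean_picard: float

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("E_h must be nonnegative")


@dataclass
class StabilityResult:
    """Final product fields per dt and their pairwise relative discrepancies."""

    model: str
    dts: list[float]
    final_fields: list[np.ndarray]
    discrepancies: list[float]  # between consecutive dt pairs, relative L2

    @property
    def max_discrepancy(self) -> float:
        return max(self.discrepancies) if self.discrepancies else 0.0


def convergence_error(diagnostics: list[PicardDiagnostics], dt: float) -> float:
    """E_h = dt * sum over species and steps of the max-over-k L2 increment."""
    if diagnostics is None:
        raise ValueError("run did not record Picard diagnostics")
    total = 0.0
    for diag in diagnostics:
        if diag.increments.size:
            total += float(diag.increments.max(axis=0).sum())
    return dt * total


def convergence_study(
    setup: ModelSetup, h_list=(0.3, 0.1, 0.05), T: float | None = None
) -> list[ConvergenceRecord]:
    """Run the model on a mesh ladder with dt = h*T/16; report E_h per mesh.

    Initial conditions are the model's constant initial concentrations.
    Output is sorted by decreasing h (coarse to fine).
    """
    T = setup.solver.t_end if T is None else T
    records = []
    for h in sorted(h_list, reverse=True):
        mesh = generate_ellipse_mesh(setup.a, setup.b, h)
        dt = h * T / 16.0
        cfg = _replace(setup.solver, dt=dt, t_end=T)
        traj = simulate(mesh, setup.species, setup.kinetics, cfg, phi0=setup.phi0)
        err = convergence_error(traj.diagnostics, dt)
        iters = [d.iterations for d in traj.diagnostics]
        records.append(
            ConvergenceRecord(
                model=setup.name,
                h=h,
                dt=dt,
                n_elements=mesh.n_elements,
                error=err,
                mean_picard=float(np.mean(iters)) if iters else 0.0,
            )
        )
        log.info("convergence %s h=%g dt=%g E_h=%.6e", setup.name, h, dt, err)
    return records


def stability_study(
    setup: ModelSetup, dt_list, T: float | None = None, h: float = 0.2
) -> StabilityResult:
    """Integrate to a common T at several dt on one mesh; compare product fields.

    Each dt is rounded to the nearest exact divisor of T (with a logged note)
    so all runs land on the same final time.  Discrepancies are relative L2
    distances between final product fields of consecutive dt pairs.
    """
    T = setup.solver.t_end if T is None else T
    mesh = generate_ellipse_mesh(setup.a, setup.b, h)
    M0 = fem.mass_matrix(mesh)

    def l2(v):
        return float(np.sqrt(max(v @ (M0 @ v), 0.0)))

    fields = []
    dts = []
    for dt in sorted(dt_list, reverse=True):
        n = max(1, round(T / dt))
        dt_eff = T / n
        if not math.isclose(dt_eff, dt, rel_tol=1e-12):
            log.info("stability %s: dt %g rounded to %g (T/%d)", setup.name, dt, dt_eff, n)
        cfg = _replace(setup.solver, dt=dt_eff, t_end=T)
        traj = simulate(
            mesh, setup.species, setup.kinetics, cfg, phi0=setup.phi0,
            snapshot_every=10**9,
        )
        _, conc, _phi = traj.snapshots[-1]
        fields.append(conc[setup.kinetics.product_index])
        dts.append(dt_eff)
    disc = []
    for u, v in zip(fields, fields[1:]):
        ref = max(l2(u), l2(v))
        disc.append(l2(u - v) / ref if ref > 0 else 0.0)
    return StabilityResult(
        model=setup.name, dts=dts, final_fields=fields, discrepancies=disc
    )


def observed_order(h_list, errors) -> float:
    """Least-squares slope of log(error) against log(h); needs >= 2 points."""
    h = np.asarray(h_list, dtype=float)
    e = np.asarray(errors, dtype=float)
    if h.size < 2:
        raise ValueError("observed order needs at least two mesh sizes")
    if np.any(e <= 0) or np.any(h <= 0):
        raise ValueError("observed order is undefined for non-positive errors")
    slope, _ = np.polyfit(np.log(h), np.log(e), 1)
    return float(slope)


def _replace(cfg: SolverConfig, **kw) -> SolverConfig:
    import dataclasses

    return dataclasses.replace(cfg, **kw)
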