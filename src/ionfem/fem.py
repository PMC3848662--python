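"""P1 finite-element assembly on triangular meshes.

Assembles the matrices and vectors of the discretised electrodiffusion
system: exponentially weighted mass and stiffness matrices (the weight
exp(-(m/d) * phi) comes from the Slotboom change of variables), the Laplace
stiffness matrix of the Poisson solve, fixed-charge and reaction load
vectors, and the L2 norm used by the Picard stopping criterion.

All integrals are evaluated by symmetric Gauss quadrature on each triangle:
a 3-point degree-2 rule by default (exact for products of two P1 functions)
with an optional 6-point degree-4 rule for the smooth exponential weights.
Assembly is vectorised element-major with ascending local indices, so the
sparse matrices are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import TriMesh

__all__ = [
    "ElementBasis",
    "element_basis",
    "assemble_weighted_mass",
    "assemble_weighted_stiffness",
    "assemble_laplace",
    "assemble_charge_load",
    "assemble_reaction_load",
    "mass_matrix",
    "l2_norm",
    "clamped_exp",
    "clamp_counter",
    "DEFAULT_CLAMP",
]

#: symmetric bound on Slotboom exponents before exponentiation
DEFAULT_CLAMP = 50.0

#: global counter of clamped exponent evaluations (diagnostic)
clamp_counter = {"count": 0}

# Degree-2 rule: edge midpoints, weights 1/3 (times element area).
_QP2 = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
_QW2 = np.array([1.0, 1.0, 1.0]) / 3.0

# Degree-4 symmetric 6-point rule (Dunavant), barycentric points and weights.
_a1, _b1 = 0.816847572980459, 0.091576213509771
_a2, _b2 = 0.108103018168070, 0.445948490915965
_QP4 = np.array(
    [
        [_a1, _b1, _b1],
        [_b1, _a1, _b1],
        [_b1, _b1, _a1],
        [_a2, _b2, _b2],
        [_b2, _a2, _b2],
        [_b2, _b2, _a2],
    ]
)
_QW4 = np.array(
    [0.109951743655322] * 3 + [0.223381589678011] * 3
)

_RULES = {2: (_QP2, _QW2), 4: (_QP4, _QW4)}


def clamped_exp(x: np.ndarray, clamp: float = DEFAULT_CLAMP) -> np.ndarray:
    """exp with the argument clipped to [-clamp, clamp]; counts clamp events."""
    x = np.asarray(x, dtype=float)
    n_out = int(np.count_nonzero((x > clamp) | (x < -clamp)))
    if n_out:
        clamp_counter["count"] += n_out
    return np.exp(np.clip(x, -clamp, clamp))


@dataclass
class ElementBasis:
    """Precomputed per-element geometry and quadrature data for a mesh.

    Attributes
    ----------
    areas : (nel,) element areas
    grads : (nel, 3, 2) constant gradients of the three P1 shape functions
    qp : (nq, 3) barycentric quadrature points (shape-function values)
    qw : (nq,) quadrature weights summing to 1 (scaled by area on use)
    points : (nel, nq, 2) physical quadrature point coordinates
    """

    mesh: TriMesh
    degree: int
    areas: np.ndarray
    grads: np.ndarray
    qp: np.ndarray
    qw: np.ndarray
    points: np.ndarray

    def interpolate(self, v: np.ndarray) -> np.ndarray:
        """Nodal P1 field -> values at quadrature points, shape (nel, nq)."""
        vloc = np.asarray(v, dtype=float)[self.mesh.triangles]  # (nel, 3)
        return vloc @ self.qp.T


_basis_cache: dict[tuple[int, int], ElementBasis] = {}


def element_basis(mesh: TriMesh, degree: int = 2) -> ElementBasis:
    """Element geometry + quadrature for ``mesh`` (cached per mesh object)."""
    key = (id(mesh), degree)
    cached = _basis_cache.get(key)
    if cached is not None and cached.mesh is mesh:
        return cached
    if degree not in _RULES:
        raise ValueError(f"unsupported quadrature degree {degree}; use 2 or 4")
    qp, qw = _RULES[degree]
    p = mesh.nodes[mesh.triangles]  # (nel, 3, 2)
    x1, x2, x3 = p[:, 0], p[:, 1], p[:, 2]
    det = (x2[:, 0] - x1[:, 0]) * (x3[:, 1] - x1[:, 1]) - (
        x3[:, 0] - x1[:, 0]
    ) * (x2[:, 1] - x1[:, 1])
    areas = 0.5 * det
    # grad N_i = rot(opposite edge) / (2 * area)
    grads = np.empty((mesh.n_elements, 3, 2))
    grads[:, 0, 0] = x2[:, 1] - x3[:, 1]
    grads[:, 0, 1] = x3[:, 0] - x2[:, 0]
    grads[:, 1, 0] = x3[:, 1] - x1[:, 1]
    grads[:, 1, 1] = x1[:, 0] - x3[:, 0]
    grads[:, 2, 0] = x1[:, 1] - x2[:, 1]
    grads[:, 2, 1] = x2[:, 0] - x1[:, 0]
    grads /= det[:, None, None]
    points = np.einsum("qi,kid->kqd", qp, p)
    basis = ElementBasis(
        mesh=mesh, degree=degree, areas=areas, grads=grads, qp=qp, qw=qw, points=points
    )
    if len(_basis_cache) > 64:
        _basis_cache.clear()
    _basis_cache[key] = basis
    return basis


def _scatter(mesh: TriMesh, local: np.ndarray) -> sp.csr_matrix:
    """Scatter (nel, 3, 3) element matrices into a global sparse matrix."""
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    mat = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return mat.tocsr()


def _scatter_vector(mesh: TriMesh, local: np.ndarray) -> np.ndarray:
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.triangles.ravel(), local.ravel())
    return out


def mass_from_pointwise(mesh: TriMesh, w_pts: np.ndarray, degree: int = 2) -> sp.csr_matrix:
    """Weighted mass matrix from weight values at quadrature points (nel, nq)."""
    eb = element_basis(mesh, degree)
    # local[k, l, s] = area_k * sum_q qw_q * w[k, q] * N_l(q) * N_s(q)
    nn = eb.qp[:, :, None] * eb.qp[:, None, :]  # (nq, 3, 3)
    local = np.einsum("q,kq,qls->kls", eb.qw, w_pts, nn) * eb.areas[:, None, None]
    return _scatter(mesh, local)


def load_from_pointwise(mesh: TriMesh, r_pts: np.ndarray, degree: int = 2) -> np.ndarray:
    """Load vector from integrand values at quadrature points (nel, nq)."""
    eb = element_basis(mesh, degree)
    local = np.einsum("q,kq,qs->ks", eb.qw, r_pts, eb.qp) * eb.areas[:, None]
    return _scatter_vector(mesh, local)


def stiffness_from_weights(
    mesh: TriMesh, w_elem: np.ndarray, d: float = 1.0, degree: int = 2
) -> sp.csr_matrix:
    """Weighted stiffness from element-averaged weights (nel,).

    The P1 gradients are constant per element, so the elementwise integral of
    w * grad(N_l) . grad(N_s) equals (quadrature average of w) * area *
    grad(N_l) . grad(N_s).
    """
    eb = element_basis(mesh, degree)
    gg = np.einsum("kld,ksd->kls", eb.grads, eb.grads)
    local = d * (w_elem * eb.areas)[:, None, None] * gg
    return _scatter(mesh, local)


def _exp_weight(
    mesh: TriMesh, phi, ratio: float, degree: int, clamp: float
) -> np.ndarray:
    """exp(-ratio * phi) interpolated to quadrature points, shape (nel, nq)."""
    eb = element_basis(mesh, degree)
    if phi is None or (np.isscalar(phi) and phi == 0) or ratio == 0.0:
        return np.ones((mesh.n_elements, eb.qw.size))
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(mesh.n_nodes, float(phi))
    return clamped_exp(-ratio * eb.interpolate(phi), clamp)


def assemble_weighted_mass(
    mesh: TriMesh,
    phi,
    ratio: float,
    degree: int = 2,
    clamp: float = DEFAULT_CLAMP,
) -> sp.csr_matrix:
    """Mass matrix weighted by exp(-ratio * phi), entries by quadrature.

    ``ratio`` is the mobility-to-diffusivity ratio m/d (already divided by the
    thermal voltage if phi is in mV).  With phi == 0 this is the standard
    P1 mass matrix.
    """
    if not np.isfinite(ratio):
        raise ValueError("ratio must be finite")
    w = _exp_weight(mesh, phi, ratio, degree, clamp)
    return mass_from_pointwise(mesh, w, degree)


def assemble_weighted_stiffness(
    mesh: TriMesh,
    phi,
    d: float,
    ratio: float,
    degree: int = 2,
    clamp: float = DEFAULT_CLAMP,
) -> sp.csr_matrix:
    """Stiffness matrix d * integral of exp(-ratio*phi) grad(N_l).grad(N_s)."""
    if d <= 0:
        raise ValueError("diffusion coefficient d must be positive")
    eb = element_basis(mesh, degree)
    w = _exp_weight(mesh, phi, ratio, degree, clamp)
    w_elem = w @ eb.qw
    return stiffness_from_weights(mesh, w_elem, d, degree)


def assemble_laplace(mesh: TriMesh, degree: int = 2) -> sp.csr_matrix:
    """Laplace stiffness matrix Q (unweighted, unit diffusivity)."""
    return stiffness_from_weights(mesh, np.ones(mesh.n_elements), 1.0, degree)


def assemble_charge_load(mesh: TriMesh, f, degree: int = 2) -> np.ndarray:
    """Load vector beta_i = integral of f * N_i for the fixed-charge density f.

    ``f`` may be a constant, a nodal vector, or a callable f(x, y).
    """
    eb = element_basis(mesh, degree)
    if callable(f):
        f_pts = f(eb.points[..., 0], eb.points[..., 1])
        f_pts = np.broadcast_to(f_pts, (mesh.n_elements, eb.qw.size))
    else:
        f_arr = np.asarray(f, dtype=float)
        if f_arr.ndim == 0:
            f_pts = np.full((mesh.n_elements, eb.qw.size), float(f_arr))
        else:
            f_pts = eb.interpolate(f_arr)
    return load_from_pointwise(mesh, f_pts, degree)


def assemble_reaction_load(
    mesh: TriMesh,
    rate,
    phi_next,
    Z_fields: np.ndarray,
    species,
    species_index: int,
    v_thermal: float = 1.0,
    degree: int = 2,
    clamp: float = DEFAULT_CLAMP,
) -> np.ndarray:
    """Reaction load: integral of F_i evaluated at reconstructed concentrations.

    Concentrations are reconstructed at quadrature points as
    c_j = exp(-(m_j/d_j) * phi/V_T) * Z_j with phi and Z interpolated nodally.
    ``rate`` maps a (n_species, ...) concentration array to rates of the same
    shape; the row ``species_index`` is integrated against the P1 basis.
    """
    eb = element_basis(mesh, degree)
    c = np.empty((len(species), mesh.n_elements, eb.qw.size))
    for j, spec in enumerate(species):
        q = _exp_weight(mesh, phi_next, spec.ratio / v_thermal, degree, clamp)
        c[j] = q * eb.interpolate(Z_fields[j])
    rates = np.asarray(rate(c))
    r_i = rates[species_index]
    if not np.all(np.isfinite(r_i)):
        bad = int(np.argwhere(~np.isfinite(r_i))[0][0])
        raise FloatingPointError(
            f"non-finite reaction rate for species {species_index} on element {bad}"
        )
    return load_from_pointwise(mesh, r_i, degree)


def mass_matrix(mesh: TriMesh, degree: int = 2) -> sp.csr_matrix:
    """The standard (unweighted) P1 mass matrix."""
    return assemble_weighted_mass(mesh, None, 0.0, degree)


def l2_norm(mesh: TriMesh, v: np.ndarray, _mass: sp.csr_matrix | None = None) -> float:
    """L2(Omega) norm of the P1 field with nodal values v: sqrt(v' M v)."""
    M = mass_matrix(mesh) if _mass is None else _mass
    v = np.asarray(v, dtype=float)
    return float(np.sqrt(max(v @ (M @ v), 0.0)))
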