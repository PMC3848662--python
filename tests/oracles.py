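"""Independent reference computations used as test oracles.

These deliberately avoid the finite-element code paths: the scalar stepper
below is a plain backward-Euler loop on numbers, and the quadrature oracle
integrates with scipy's adaptive routine.
"""

import numpy as np
from scipy.integrate import dblquad


def scalar_backward_euler(c0, n_steps, dt, model, eps, domain_area, max_picard=50):
    """Well-mixed backward-Euler trajectory with the model's Picard pattern.

    Mirrors the species ordering (pre / loop / post) and the own-species
    implicit factor of the PDE scheme, but on scalars:
    c^{k+1} = (c^n + dt*rhs) / (1 + dt*w).  The loop stopping criterion uses
    the L2 norm of a constant field, |increment| * sqrt(area), to match the
    field solver's eps exactly.
    """
    c = np.array(c0, dtype=float)
    history = [c.copy()]
    sqrt_area = np.sqrt(domain_area)
    for _ in range(n_steps):
        cn = c.copy()
        work = c.copy()

        def solve(j):
            w = float(model.lhs_weight(j, work))
            r = float(model.rhs_rate(j, work))
            return (cn[j] + dt * r) / (1.0 + dt * w)

        for j in model.pre:
            work[j] = solve(j)
        for _k in range(max_picard):
            inc = 0.0
            for j in model.loop:
                new = solve(j)
                inc += abs(new - work[j]) * sqrt_area
                work[j] = new
            if inc < eps:
                break
        for j in model.post:
            work[j] = solve(j)
        c = work
        history.append(c.copy())
    return np.array(history)


def triangle_integral(f, vertices, tol=1e-12):
    """Adaptive integral of f(x, y) over a triangle via a reference-square map."""
    (x1, y1), (x2, y2), (x3, y3) = vertices
    jac = abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))

    def integrand(v, u):
        # collapsed-square map: (u, v) in [0,1]^2 -> barycentric (1-u, u(1-v), uv)
        l1, l2, l3 = 1 - u, u * (1 - v), u * v
        x = l1 * x1 + l2 * x2 + l3 * x3
        y = l1 * y1 + l2 * y2 + l3 * y3
        return f(x, y) * u  # extra u from the collapsed map

    val, _err = dblquad(integrand, 0, 1, 0, 1, epsabs=tol, epsrel=tol)
    return val * jac


def p1_shape_functions(vertices):
    """Barycentric coordinate functions of a triangle as callables of (x, y)."""
    (x1, y1), (x2, y2), (x3, y3) = vertices
    det = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)

    def lam(i):
        if i == 0:
            return lambda x, y: ((x2 * y3 - x3 * y2) + (y2 - y3) * x + (x3 - x2) * y) / det
        if i == 1:
            return lambda x, y: ((x3 * y1 - x1 * y3) + (y3 - y1) * x + (x1 - x3) * y) / det
        return lambda x, y: ((x1 * y2 - x2 * y1) + (y1 - y2) * x + (x2 - x1) * y) / det

    return [lam(0), lam(1), lam(2)]
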