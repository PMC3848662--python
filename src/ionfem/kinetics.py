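"""Enzyme reaction kinetics: rate laws and their Picard linearization patterns.

Three presets are provided.

* ``basic`` — the Michaelis–Menten mechanism S + E <-> SE -> P + E after the
  quasi-steady-state reduction of the complex, acting on three transported
  species (enzyme, substrate, product) with rate k2 * C1_0 * S / (S + k_M).
* ``suicide`` — the mechanism-based (suicide-substrate) inhibitor scheme
  E + S <-> X -> Y, Y -> E + P (rate k3) or Y -> Ei (rate k4), six species
  (E, S, X, Y, Ei, P) with full mass-action rates.
* ``cooperative`` — a two-binding-site allosteric mechanism
  S + E <-> X -> E + P, S + X <-> Y -> X + P, five species (E, S, X, Y, P).

Besides the pointwise rate vector F(c), each model carries the linearization
used inside the implicit-Euler Picard loop: for every species the rate is
split as F_i(c) = -w_i(c) * c_i + r_i(c) with w_i >= 0 for nonnegative c.
During a Gauss–Seidel sweep the own-species factor c_i is taken at the new
iterate (it multiplies the system matrix) while w_i and r_i are evaluated on
the working concentration vector, which mixes already-updated species (k+1)
and not-yet-updated species (k) exactly as the per-model algorithms specify.

Concentration unit is uM throughout; time unit is seconds.  Second-order rate
constants are per uM per second, and a Michaelis constant given in M must be
converted (see :func:`molar_to_micromolar`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesSpec",
    "KineticsModel",
    "BasicParams",
    "SuicideParams",
    "CooperativeParams",
    "basic_model",
    "suicide_model",
    "cooperative_model",
    "custom_model",
    "mm_reduced_rate",
    "suicide_rates",
    "cooperative_rates",
    "partition_metrics",
    "michaelis_constant",
    "equilibrium_constants",
    "rate_constants_from_equilibrium",
    "molar_to_micromolar",
]


def molar_to_micromolar(x: float) -> float:
    """Convert a concentration-like quantity from M to uM (or M^-1 to uM^-1 inverted)."""
    return x * 1e6


@dataclass(frozen=True)
class SpeciesSpec:
    """One transported ion species.

    Parameters
    ----------
    name : species label.
    d : diffusion coefficient, simulation area units per second; must be > 0.
    z : integer valence (charge number).
    c0 : initial concentration in uM (>= 0), constant over the domain.
    m : mobility; ``None`` selects the Einstein-relation default m = z * d,
        which makes m/d equal to the valence in thermal-voltage units.
    """

    name: str
    d: float
    z: int
    c0: float
    m: float | None = None

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError(f"species {self.name!r}: diffusion coefficient must be > 0")
        if self.c0 < 0:
            raise ValueError(f"species {self.name!r}: initial concentration must be >= 0")

    @property
    def mobility(self) -> float:
        return self.z * self.d if self.m is None else self.m

    @property
    def ratio(self) -> float:
        """m/d, the Slotboom exponent coefficient (valence under the default)."""
        return self.mobility / self.d


# ---------------------------------------------------------------------------
# Rate-constant containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasicParams:
    """Michaelis–Menten reduced model: rate k2 * c1_0 * S / (S + km).

    km is the Michaelis constant (k_-1 + k2)/k1 in uM; c1_0 the (constant)
    total enzyme concentration in uM.
    """

    k2: float
    km: float
    c1_0: float

    def __post_init__(self):
        if self.k2 <= 0 or self.km <= 0:
            raise ValueError("k2 and km must be positive")
        if self.c1_0 < 0:
            raise ValueError("c1_0 must be nonnegative")


@dataclass(frozen=True)
class SuicideParams:
    """Suicide-substrate scheme constants (k1 in uM^-1 s^-1, others s^-1)."""

    k1: float
    km1: float
    k2: float
    k3: float
    k4: float
    e0: float = 0.0
    s0: float = 0.0

    def __post_init__(self):
        for name in ("k1", "km1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.e0 < 0 or self.s0 < 0:
            raise ValueError("initial concentrations must be >= 0")


@dataclass(frozen=True)
class CooperativeParams:
    """Two-site cooperative scheme constants (k1, k3 in uM^-1 s^-1)."""

    k1: float
    km1: float
    k2: float
    k3: float
    km3: float
    k4: float
    e0: float = 0.0
    s0: float = 0.0

    def __post_init__(self):
        for name in ("k1", "km1", "k2", "k3", "km3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.e0 < 0 or self.s0 < 0:
            raise ValueError("initial concentrations must be >= 0")


# ---------------------------------------------------------------------------
# Pointwise rate laws
# ---------------------------------------------------------------------------


def mm_reduced_rate(c2, params: BasicParams):
    """Michaelis–Menten conversion velocity k2 * c1_0 * c2 / (c2 + km) (uM/s).

    The substrate equation carries the negative of this, the product equation
    the positive, and the free enzyme is unaffected.
    """
    c2 = np.asarray(c2, dtype=float)
    return params.k2 * params.c1_0 * c2 / (c2 + params.km)


def suicide_rates(c, params: SuicideParams):
    """Mass-action rates for (E, S, X, Y, Ei, P); c has shape (6, ...)."""
    c = np.asarray(c, dtype=float)
    _warn_negative(c)
    c1, c2, c3, c4 = c[0], c[1], c[2], c[3]
    k1, km1, k2, k3, k4 = params.k1, params.km1, params.k2, params.k3, params.k4
    F = np.empty_like(c)
    F[0] = -k1 * c1 * c2 + km1 * c3 + k3 * c4
    F[1] = -k1 * c1 * c2 + km1 * c3
    F[2] = k1 * c1 * c2 - (km1 + k2) * c3
    F[3] = k2 * c3 - (k3 + k4) * c4
    F[4] = k4 * c4
    F[5] = k3 * c4
    return F


def cooperative_rates(c, params: CooperativeParams):
    """Mass-action rates for (E, S, X, Y, P); c has shape (5, ...)."""
    c = np.asarray(c, dtype=float)
    _warn_negative(c)
    c1, c2, c3, c4 = c[0], c[1], c[2], c[3]
    k1, km1, k2 = params.k1, params.km1, params.k2
    k3, km3, k4 = params.k3, params.km3, params.k4
    F = np.empty_like(c)
    F[0] = -k1 * c2 * c1 + (km1 + k2) * c3
    F[1] = -k1 * c2 * c1 + km1 * c3 - k3 * c2 * c3 + km3 * c4
    F[2] = k1 * c2 * c1 - (km1 + k2 + k3 * c2) * c3 + (km3 + k4) * c4
    F[3] = k3 * c2 * c3 - (km3 + k4) * c4
    F[4] = k2 * c3 + k4 * c4
    return F


def _warn_negative(c: np.ndarray, tol: float = 1e-8) -> None:
    if np.any(c < -tol):
        import warnings

        warnings.warn(
            f"concentration below -{tol:g} uM passed to a rate law "
            f"(min {float(np.min(c)):.3e})",
            RuntimeWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Derived kinetic quantities
# ---------------------------------------------------------------------------


def partition_metrics(k3: float, k4: float, e0: float, s0: float):
    """Partition ratio r = k3/k4, mu = e0/s0, and the determining factor (1+r)mu.

    The factor classifies the long-time outcome of a suicide-substrate run:
    > 1 the substrate is exhausted, < 1 all enzyme is inactivated, = 1 both.
    Returns (r, mu, factor, label).
    """
    if k4 == 0 or s0 == 0:
        raise ValueError("k4 and s0 must be nonzero")
    r = k3 / k4
    mu = e0 / s0
    factor = (1.0 + r) * mu
    if factor > 1.0:
        label = "exhausted"
    elif factor < 1.0:
        label = "enzyme-inactivated"
    else:
        label = "both"
    return r, mu, factor, label


def michaelis_constant(k1: float, km1: float, k2: float) -> float:
    """k_M = (k_-1 + k2) / k1."""
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    return (km1 + k2) / k1


def equilibrium_constants(params: CooperativeParams) -> tuple[float, float]:
    """The per-binding-step pseudo-equilibrium constants (K1, K2).

    K1 = (k_-1 + k2)/k1 and K2 = (k4 + k_-3)/k3.
    """
    return (params.km1 + params.k2) / params.k1, (params.k4 + params.km3) / params.k3


def rate_constants_from_equilibrium(
    K1: float, K2: float, km1: float = 1.0, k2: float = 1.0, km3: float = 1.0, k4: float = 1.0
) -> tuple[float, float]:
    """Invert K1, K2 for k1, k3 given the four first-order constants."""
    if K1 <= 0 or K2 <= 0:
        raise ValueError("K1 and K2 must be positive")
    return (km1 + k2) / K1, (k4 + km3) / K2


# ---------------------------------------------------------------------------
# The model container and its Picard split
# ---------------------------------------------------------------------------


@dataclass
class KineticsModel:
    """A reaction system together with its Picard linearization pattern.

    ``rates(c)`` is the full pointwise rate vector.  ``lhs_weight(i, c)`` and
    ``rhs_rate(i, c)`` give the split F_i(c) = -lhs_weight * c_i + rhs_rate
    used by the implicit solver: the own-species factor is taken at the new
    Picard iterate, everything inside lhs_weight/rhs_rate on the working
    (mixed k+1 / k) vector.  ``pre``, ``loop`` and ``post`` list the species
    solved before, inside and after the Picard loop, in sweep order.

    ``product_index`` marks the product species used by the stability study.
    """

    name: str
    n_species: int
    params: object
    pre: tuple[int, ...]
    loop: tuple[int, ...]
    post: tuple[int, ...]
    product_index: int
    _rates: object = field(repr=False)
    _lhs: object = field(repr=False)
    _rhs: object = field(repr=False)

    def rates(self, c):
        return self._rates(c)

    def lhs_weight(self, i: int, c):
        return self._lhs(i, c)

    def rhs_rate(self, i: int, c):
        return self._rhs(i, c)


def basic_model(params: BasicParams) -> KineticsModel:
    """Michaelis–Menten reduced system on (enzyme, substrate, product).

    The enzyme and product equations are linear and solved outside the Picard
    loop (the product with the converged substrate); only the substrate
    iterates, with the saturation denominator lagged:
    -k2*c1_0*c2^{k+1} / (km + c2^k).
    """
    k2, km, c10 = params.k2, params.km, params.c1_0

    def rates(c):
        c = np.asarray(c, dtype=float)
        v = mm_reduced_rate(c[1], params)
        F = np.zeros_like(c)
        F[1] = -v
        F[2] = v
        return F

    def lhs(i, c):
        if i == 1:
            return k2 * c10 / (c[1] + km)
        return np.zeros_like(c[i])

    def rhs(i, c):
        if i == 2:
            return mm_reduced_rate(c[1], params)
        return np.zeros_like(c[i])

    return KineticsModel(
        name="basic",
        n_species=3,
        params=params,
        pre=(0,),
        loop=(1,),
        post=(2,),
        product_index=2,
        _rates=rates,
        _lhs=lhs,
        _rhs=rhs,
    )


def suicide_model(params: SuicideParams) -> KineticsModel:
    """Suicide-substrate system on (E, S, X, Y, Ei, P), all species in one loop."""
    k1, km1, k2, k3, k4 = params.k1, params.km1, params.k2, params.k3, params.k4

    def rates(c):
        return suicide_rates(c, params)

    def lhs(i, c):
        if i == 0:
            return k1 * c[1]
        if i == 1:
            return k1 * c[0]
        if i == 2:
            return np.full_like(c[2], km1 + k2)
        if i == 3:
            return np.full_like(c[3], k3 + k4)
        return np.zeros_like(c[i])

    def rhs(i, c):
        if i == 0:
            return km1 * c[2] + k3 * c[3]
        if i == 1:
            return km1 * c[2]
        if i == 2:
            return k1 * c[0] * c[1]
        if i == 3:
            return k2 * c[2]
        if i == 4:
            return k4 * c[3]
        return k3 * c[3]

    return KineticsModel(
        name="suicide",
        n_species=6,
        params=params,
        pre=(),
        loop=(0, 1, 2, 3, 4, 5),
        post=(),
        product_index=5,
        _rates=rates,
        _lhs=lhs,
        _rhs=rhs,
    )


def cooperative_model(params: CooperativeParams) -> KineticsModel:
    """Two-site cooperative system on (E, S, X, Y, P), all species in one loop."""
    k1, km1, k2 = params.k1, params.km1, params.k2
    k3, km3, k4 = params.k3, params.km3, params.k4

    def rates(c):
        return cooperative_rates(c, params)

    def lhs(i, c):
        if i == 0:
            return k1 * c[1]
        if i == 1:
            return k1 * c[0] + k3 * c[2]
        if i == 2:
            return km1 + k2 + k3 * c[1]
        if i == 3:
            return np.full_like(c[3], km3 + k4)
        return np.zeros_like(c[i])

    def rhs(i, c):
        if i == 0:
            return (km1 + k2) * c[2]
        if i == 1:
            return km1 * c[2] + km3 * c[3]
        if i == 2:
            return k1 * c[0] * c[1] + (km3 + k4) * c[3]
        if i == 3:
            return k3 * c[1] * c[2]
        return k2 * c[2] + k4 * c[3]

    return KineticsModel(
        name="cooperative",
        n_species=5,
        params=params,
        pre=(),
        loop=(0, 1, 2, 3, 4),
        post=(),
        product_index=4,
        _rates=rates,
        _lhs=lhs,
        _rhs=rhs,
    )


def custom_model(
    terms: list[list[tuple[float, dict[int, int]]]],
    product_index: int | None = None,
) -> KineticsModel:
    """Mass-action model from explicit term lists.

    ``terms[i]`` lists the monomials of F_i as (coefficient, exponents) pairs
    where ``exponents`` maps species index -> integer power.  Negative terms
    with a positive power of the own species are treated implicitly (their
    own-species factor moves to the system matrix), everything else is lagged.
    """
    n = len(terms)

    def monomial(c, exponents, skip=None, reduce_skip_by=0):
        out = None
        for j, p in exponents.items():
            pw = p - reduce_skip_by if j == skip else p
            if pw == 0:
                continue
            factor = c[j] ** pw if pw != 1 else c[j]
            out = factor if out is None else out * factor
        if out is None:
            return np.ones_like(np.asarray(c[0], dtype=float))
        return out

    def rates(c):
        c = np.asarray(c, dtype=float)
        F = np.zeros_like(c)
        for i, tl in enumerate(terms):
            for coef, exps in tl:
                F[i] = F[i] + coef * monomial(c, exps)
        return F

    def lhs(i, c):
        w = np.zeros_like(np.asarray(c[i], dtype=float))
        for coef, exps in terms[i]:
            if coef < 0 and exps.get(i, 0) >= 1:
                w = w + (-coef) * monomial(c, exps, skip=i, reduce_skip_by=1)
        return w

    def rhs(i, c):
        r = np.zeros_like(np.asarray(c[i], dtype=float))
        for coef, exps in terms[i]:
            if not (coef < 0 and exps.get(i, 0) >= 1):
                r = r + coef * monomial(c, exps)
        return r

    return KineticsModel(
        name="custom",
        n_species=n,
        params=terms,
        pre=(),
        loop=tuple(range(n)),
        post=(),
        product_index=n - 1 if product_index is None else product_index,
        _rates=rates,
        _lhs=lhs,
        _rhs=rhs,
    )
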