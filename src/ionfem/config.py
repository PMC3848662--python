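"""Run configuration: TOML schema, validation, units and model building.

A run is described by a TOML file with the sections

* top level: ``epsilon`` (permittivity), ``fixed_charge`` (fixed-charge
  density f), ``phi0`` (initial interior potential, mV);
* ``[domain]`` — ellipse semi-axes ``a``, ``b`` and mesh size ``h``, or a
  ``mesh`` file path (Gmsh MSH 2.2 ASCII);
* ``[[species]]`` — name, diffusion coefficient ``d``, valence ``z``, initial
  concentration ``c0`` (uM unless ``c0_unit = "M"``), optional mobility ``m``;
* ``[model]`` — kinetics ``preset`` (basic | suicide | cooperative | custom),
  a ``constants`` table and an optional ``units`` table annotating constants
  given in M or M^-1 s^-1 (converted to the uM-based internal units);
* ``[solver]`` — dt, T, eps, max_picard, quadrature_degree, v_thermal, ...;
* ``[probes]`` — probe points; ``[output]`` — directory, snapshot cadence.

Three bundled reference configurations reproduce the printed parameter sets
of the basic, suicide-substrate and cooperative runs.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import kinetics as kin
from .experiments import ModelSetup
from .mesh import TriMesh, generate_ellipse_mesh, read_msh
from .stepper import SolverConfig

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "dump_config",
    "bundled_config_path",
    "build_mesh",
    "build_setup",
    "convert_constant",
]


class ConfigError(ValueError):
    """Configuration file violates the schema; message lists every violation."""


_UNIT_FACTORS = {
    "uM": 1.0,
    "µM": 1.0,
    "M": 1e6,  # molar concentration -> uM
    "mM": 1e3,
    "s": 1.0,
    "s^-1": 1.0,
    "1/s": 1.0,
    "mV": 1.0,
    "M^-1 s^-1": 1e-6,  # second-order rate constant -> uM^-1 s^-1
    "1/M/s": 1e-6,
    "uM^-1 s^-1": 1.0,
    "1/uM/s": 1.0,
}


def convert_constant(value: float, unit: str | None) -> float:
    """Convert a constant annotated with a unit to internal (uM, s, mV) units."""
    if unit is None:
        return value
    try:
        return value * _UNIT_FACTORS[unit]
    except KeyError:
        raise ConfigError(
            f"unknown unit {unit!r}; allowed: {sorted(_UNIT_FACTORS)}"
        ) from None


class DomainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: float | None = None
    b: float | None = None
    h: float | None = None
    mesh: str | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.mesh is None:
            if self.a is None or self.b is None or self.h is None:
                raise ValueError("domain needs either a/b/h or a mesh file path")
            if self.a <= 0 or self.b <= 0 or self.h <= 0:
                raise ValueError("domain a, b, h must be positive")
        return self


class SpeciesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    d: float
    z: int
    c0: float
    c0_unit: Literal["uM", "M", "mM"] = "uM"
    m: float | None = None

    def to_spec(self) -> kin.SpeciesSpec:
        return kin.SpeciesSpec(
            name=self.name,
            d=self.d,
            z=self.z,
            c0=convert_constant(self.c0, self.c0_unit),
            m=self.m,
        )


class CustomTerm(BaseModel):
    model_config = ConfigDict(extra="forbid")
    coef: float
    exponents: list[int]


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["basic", "suicide", "cooperative", "custom"]
    constants: dict[str, float] = {}
    units: dict[str, str] = {}
    terms: list[list[CustomTerm]] | None = None  # custom preset only
    product_index: int | None = None

    def converted_constants(self) -> dict[str, float]:
        return {
            k: convert_constant(v, self.units.get(k)) for k, v in self.constants.items()
        }


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt: float
    T: float
    eps: float = 1e-4
    max_picard: int = 50
    quadrature_degree: int = 2
    v_thermal: float = 25.693
    clamp: float = 50.0
    on_nonconvergence: Literal["warn", "raise"] = "warn"


class ProbesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    points: list[list[float]] = [[0.0, 0.0]]


class OutputSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: str = "out"
    snapshot_every: int = 0
    formats: list[Literal["csv", "vtk", "mtx"]] = ["csv", "vtk"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epsilon: float = 1.0
    fixed_charge: float = 0.0
    phi0: float = 0.0
    domain: DomainSection
    species: list[SpeciesSection]
    model: ModelSection
    solver: SolverSection
    probes: ProbesSection = ProbesSection()
    output: OutputSection = OutputSection()

    @model_validator(mode="after")
    def _check(self):
        n = len(self.species)
        expected = {"basic": 3, "suicide": 6, "cooperative": 5}.get(self.model.preset)
        if expected is not None and n != expected:
            raise ValueError(
                f"preset {self.model.preset!r} needs {expected} species, got {n}"
            )
        if self.model.preset == "custom":
            if self.model.terms is None:
                raise ValueError("custom preset requires model.terms")
            if len(self.model.terms) != n:
                raise ValueError("model.terms must list one term list per species")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        return self


def loads_config(text: str) -> RunConfig:
    """Parse and validate a TOML configuration string."""
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"TOML syntax error: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(lines)
        ) from exc


def load_config(path) -> RunConfig:
    """Load and validate a TOML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    return loads_config(path.read_text())


def bundled_config_path(name: str) -> Path:
    """Path to a bundled reference configuration: basic | suicide | cooperative
    | cooperative_negative."""
    ref = resources.files("ionfem") / "configs" / f"{name}.toml"
    with resources.as_file(ref) as p:
        return Path(p)


# ---------------------------------------------------------------------------
# Building runnable objects from a config
# ---------------------------------------------------------------------------


def build_mesh(cfg: RunConfig) -> TriMesh:
    d = cfg.domain
    if d.mesh is not None:
        return read_msh(d.mesh)
    return generate_ellipse_mesh(d.a, d.b, d.h)


def _build_kinetics(cfg: RunConfig) -> kin.KineticsModel:
    c = cfg.model.converted_constants()
    preset = cfg.model.preset
    try:
        if preset == "basic":
            return kin.basic_model(
                kin.BasicParams(k2=c["k2"], km=c["k_M"], c1_0=c["c1_0"])
            )
        if preset == "suicide":
            return kin.suicide_model(
                kin.SuicideParams(
                    k1=c["k1"], km1=c["km1"], k2=c["k2"], k3=c["k3"], k4=c["k4"],
                    e0=c.get("e0", 0.0), s0=c.get("s0", 0.0),
                )
            )
        if preset == "cooperative":
            if "K1" in c:
                k1, k3 = kin.rate_constants_from_equilibrium(
                    c["K1"], c["K2"],
                    km1=c.get("km1", 1.0), k2=c.get("k2", 1.0),
                    km3=c.get("km3", 1.0), k4=c.get("k4", 1.0),
                )
            else:
                k1, k3 = c["k1"], c["k3"]
            return kin.cooperative_model(
                kin.CooperativeParams(
                    k1=k1, km1=c.get("km1", 1.0), k2=c.get("k2", 1.0),
                    k3=k3, km3=c.get("km3", 1.0), k4=c.get("k4", 1.0),
                    e0=c.get("e0", 0.0), s0=c.get("s0", 0.0),
                )
            )
        terms = [
            [(t.coef, {j: p for j, p in enumerate(t.exponents) if p}) for t in tl]
            for tl in cfg.model.terms
        ]
        return kin.custom_model(terms, cfg.model.product_index)
    except KeyError as exc:
        raise ConfigError(
            f"model.constants is missing {exc.args[0]!r} for preset {preset!r}"
        ) from None


def build_setup(cfg: RunConfig, name: str | None = None) -> ModelSetup:
    """Turn a validated RunConfig into a runnable ModelSetup."""
    solver = SolverConfig(
        dt=cfg.solver.dt,
        t_end=cfg.solver.T,
        eps=cfg.solver.eps,
        max_picard=cfg.solver.max_picard,
        quad_degree=cfg.solver.quadrature_degree,
        v_thermal=cfg.solver.v_thermal,
        clamp=cfg.solver.clamp,
        epsilon=cfg.epsilon,
        fixed_charge=cfg.fixed_charge,
        on_nonconvergence=cfg.solver.on_nonconvergence,
    )
    return ModelSetup(
        name=name or cfg.model.preset,
        species=[s.to_spec() for s in cfg.species],
        kinetics=_build_kinetics(cfg),
        solver=solver,
        phi0=cfg.phi0,
        a=cfg.domain.a if cfg.domain.a is not None else 2.0,
        b=cfg.domain.b if cfg.domain.b is not None else 1.0,
    )


# ---------------------------------------------------------------------------
# Deterministic serialization (round-trip support)
# ---------------------------------------------------------------------------


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, int):
        return str(v)
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to TOML; reloading yields an equal config."""
    d = cfg.model_dump(exclude_none=True)
    out = []
    for key in ("epsilon", "fixed_charge", "phi0"):
        out.append(f"{key} = {_toml_value(d[key])}")
    out.append("")

    def emit_table(name, table):
        out.append(f"[{name}]")
        for k, v in table.items():
            if isinstance(v, dict):
                continue
            out.append(f"{k} = {_toml_value(v)}")
        for k, v in table.items():
            if isinstance(v, dict):
                out.append(f"[{name}.{k}]")
                for kk, vv in v.items():
                    out.append(f"{kk} = {_toml_value(vv)}")
        out.append("")

    emit_table("domain", d["domain"])
    for sp in d["species"]:
        out.append("[[species]]")
        for k, v in sp.items():
            out.append(f"{k} = {_toml_value(v)}")
        out.append("")
    model = dict(d["model"])
    terms = model.pop("terms", None)
    out.append("[model]")
    for k, v in model.items():
        if not isinstance(v, dict):
            out.append(f"{k} = {_toml_value(v)}")
    if terms is not None:
        # nested arrays of inline tables: one inner list per species
        rows = []
        for tl in terms:
            inner = ", ".join(
                "{coef = %s, exponents = %s}"
                % (_toml_value(t["coef"]), _toml_value(t["exponents"]))
                for t in tl
            )
            rows.append("[" + inner + "]")
        out.append("terms = [" + ", ".join(rows) + "]")
    for k, v in model.items():
        if isinstance(v, dict):
            out.append(f"[model.{k}]")
            for kk, vv in v.items():
                out.append(f"{kk} = {_toml_value(vv)}")
    out.append("")
    emit_table("solver", d["solver"])
    emit_table("probes", d["probes"])
    emit_table("output", d["output"])
    return "\n".join(out)
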