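"""Physical parameters and the dimensionless groups of the interfacial model.

A catalytic particle of radius ``R`` converts substrate M into product N in a
first-order surface reaction with kinetic constant ``k_r`` on a catalytic cap
of half-angle ``phi0``.  The interfacial balance equations are controlled by
five dimensionless groups:

``alpha2 = k_r R^2 / D_s``
    reaction vs. interfacial diffusion,
``beta2 = U R^2 / D_s``
    bulk exchange (adsorption) vs. interfacial diffusion,
``lambda2 = R^2 |dH_r| k_r C0 / (kappa T0)``
    reaction-heat generation vs. conduction,
``omega2 = U_q R / kappa``
    interfacial cooling vs. conduction,
``xi2 ∝ R^2 C0 N_A q0^2 / (k_B T0 eps0 eps_r)``
    electrostatic coupling of the charged species to the surface potential.

The coefficient of ``xi2`` carries a per-system multiplicative prefactor
(``xi2_prefactor``): the electrostatic coupling of a real interface is a
fitted quantity and is specified for each preset as the value matching the
model's reported operating range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields, asdict, replace
from importlib import resources
from typing import Iterable

import yaml

from .constants import K_B, N_A, Q0, EPS0, EPS_R_WATER

__all__ = [
    "PhysicalParams",
    "DimensionlessGroups",
    "compute_dimensionless_groups",
    "load_preset",
    "available_presets",
    "load_config",
    "save_config",
]

#: Fields that may be negative (signed thermodynamic quantities and charges).
_SIGNED = {"dH_r", "dmu_r0", "gamma_CM", "gamma_CN", "gamma_T", "z_M", "z_N"}
#: Fields that may be zero.
_ZERO_OK = {"D0", "k_r", "U", "U_q", "z_M", "z_N"} | _SIGNED

_TAU_MODES = ("kr", "kr_beta2")


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional description of one particle/fluid system (SI units).

    Surface-tension derivatives ``gamma_CM``/``gamma_CN`` are per volumetric
    concentration, [J m/mol] (the tabulated mJ/(m^2 M) equals 1e-6 J m/mol);
    ``gamma_T`` is [J/(m^2 K)].
    """

    C0: float            # bulk substrate concentration [mol/m^3]
    T0: float            # bath temperature [K]
    k_r: float           # first-order surface kinetic constant [1/s]
    D_s: float           # interfacial diffusivity [m^2/s]
    eta_s: float         # interfacial viscosity [Pa s]
    U: float             # mass-transfer (bulk exchange) coefficient [1/s]
    dH_r: float          # reaction enthalpy, signed, exothermic < 0 [J/mol]
    dmu_r0: float        # standard reaction free energy [J/mol]
    kappa: float         # thermal conductivity [W/(K m)]
    U_q: float           # heat-transfer coefficient [W/(K m^2)]
    eps_thick: float     # interfacial thickness [m]
    z_M: int             # substrate valence
    z_N: int             # product valence
    gamma_CM: float      # d(gamma)/d(C_M) [J m/mol]
    gamma_CN: float      # d(gamma)/d(C_N) [J m/mol]
    gamma_T: float       # d(gamma)/d(T) [J/(m^2 K)]
    D0: float            # passive diffusivity [m^2/s]
    R: float             # particle radius [m]
    w0: float = 0.5      # interfacial composition constant, in (0, 1)
    phi0: float = math.pi / 2  # catalytic-cap half-angle [rad]
    eps_r: float = EPS_R_WATER  # relative permittivity of the solvent
    xi2_prefactor: float = 1.0  # fitted electrostatic-coupling prefactor
    tau_mode: str = "kr"  # characteristic time: "kr" -> 1/k_r,
    #                      "kr_beta2" -> 1/(k_r beta^2)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name == "tau_mode":
                if v not in _TAU_MODES:
                    raise ValueError(
                        f"tau_mode must be one of {_TAU_MODES}, got {v!r}")
                continue
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if f.name in _SIGNED:
                continue
            if f.name in _ZERO_OK:
                if v < 0:
                    raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")
        if not 0.0 < self.w0 < 1.0:
            raise ValueError(f"w0 must lie in (0, 1), got {self.w0}")
        if not 0.0 < self.phi0 <= math.pi:
            raise ValueError(f"phi0 must lie in (0, pi], got {self.phi0}")

    # -- characteristic time --------------------------------------------
    def tau(self) -> float:
        """Characteristic time of the dissipative route [s]."""
        if self.k_r == 0:
            raise ValueError("tau undefined for k_r = 0")
        if self.tau_mode == "kr":
            return 1.0 / self.k_r
        beta2 = self.U * self.R**2 / self.D_s
        if beta2 == 0:
            raise ValueError("tau_mode 'kr_beta2' requires U > 0")
        return 1.0 / (self.k_r * beta2)

    def area(self) -> float:
        """Particle surface area 4*pi*R^2 [m^2]."""
        return 4.0 * math.pi * self.R**2

    def with_(self, **kw) -> "PhysicalParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DimensionlessGroups:
    """The BVP coefficients derived from a :class:`PhysicalParams`."""

    alpha2: float
    beta2: float
    lambda2: float
    omega2: float
    xi2: float
    phi0: float
    w0: float
    z_M: int = 0
    z_N: int = 0
    That_b: float = 1.0
    Chat_Mb: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha2", "beta2", "lambda2", "omega2", "xi2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_dimensionless_groups(p: PhysicalParams) -> DimensionlessGroups:
    """Map dimensional parameters onto the five dimensionless groups.

    Pure and deterministic; raises for the degenerate denominators
    (nonpositive ``R``, ``D_s``, ``kappa``, ``T0``) with the parameter named.
    """
    for name in ("R", "D_s", "kappa", "T0"):
        if getattr(p, name) <= 0:
            raise ValueError(f"parameter {name} must be > 0 to form the groups")
    alpha2 = p.k_r * p.R**2 / p.D_s
    beta2 = p.U * p.R**2 / p.D_s
    lambda2 = p.R**2 * abs(p.dH_r) * p.k_r * p.C0 / (p.kappa * p.T0)
    omega2 = p.U_q * p.R / p.kappa
    xi2 = (p.xi2_prefactor * p.R**2 * p.C0 * N_A * Q0**2
           / (K_B * p.T0 * EPS0 * p.eps_r))
    return DimensionlessGroups(
        alpha2=alpha2, beta2=beta2, lambda2=lambda2, omega2=omega2, xi2=xi2,
        phi0=p.phi0, w0=p.w0, z_M=p.z_M, z_N=p.z_N,
    )


# ---------------------------------------------------------------------------
# configuration files and presets
# ---------------------------------------------------------------------------

import dataclasses as _dc  # noqa: E402

_PARAM_KEYS = tuple(f.name for f in dc_fields(PhysicalParams))
_REQUIRED = tuple(
    f.name for f in dc_fields(PhysicalParams)
    if f.default is _dc.MISSING and f.default_factory is _dc.MISSING
)


def _params_from_mapping(d: dict, source: str) -> PhysicalParams:
    unknown = sorted(set(d) - set(_PARAM_KEYS))
    missing = sorted(set(_REQUIRED) - set(d))
    problems = []
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    if missing:
        problems.append(f"missing keys: {', '.join(missing)}")
    if problems:
        raise ValueError(f"invalid parameter config {source}: "
                         + "; ".join(problems))
    kw = dict(d)
    for k in ("z_M", "z_N"):
        kw[k] = int(kw[k])
    return PhysicalParams(**kw)


def load_config(path) -> PhysicalParams:
    """Read a YAML parameter file (strict schema: unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"parameter config {path} must be a mapping")
    if "params" in data and isinstance(data["params"], dict):
        data = data["params"]
    return _params_from_mapping(data, str(path))


def save_config(p: PhysicalParams, path) -> None:
    """Write a parameter set as YAML; round-trips through :func:`load_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump({"params": p.to_dict()}, fh, sort_keys=False)


def available_presets() -> list[str]:
    root = resources.files("actidiff") / "presets"
    return sorted(r.name[:-5] for r in root.iterdir() if r.name.endswith(".yaml"))


def load_preset(name: str) -> PhysicalParams:
    """Load one of the packaged parameter presets.

    ``case1_janus_nano``: nanometric catalytic Janus particles consuming a
    charged salt substrate.  ``case2_vesicle``: phospholipid vesicles with
    membrane-embedded enzymes hydrolyzing ATP.
    """
    root = resources.files("actidiff") / "presets"
    res = root / f"{name}.yaml"
    if not res.is_file():
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}")
    data = yaml.safe_load(res.read_text())
    if "params" in data:
        data = data["params"]
    return _params_from_mapping(data, f"preset {name}")


def groups_frame(items: Iterable[tuple[str, PhysicalParams]]):
    """Tabulate derived dimensionless groups for several parameter sets.

    Returns a pandas DataFrame (one row per named parameter set); used by the
    CLI for CSV export.
    """
    import pandas as pd

    rows = []
    for name, p in items:
        g = compute_dimensionless_groups(p)
        row = {"name": name}
        row.update(g.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
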