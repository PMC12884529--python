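"""Active diffusivity: from excess energy to D(ṙ) curves and their extrema.

The long-time diffusivity of an active particle exceeds its passive value
because the surface excess energy adds to the thermal energy per degree of
freedom:

    D = D0 (1 + |E_s| / k_B T_b)

Activity sweeps vary the bulk substrate concentration C0 (as in experiments),
recomputing the concentration-dependent groups (λ² ∝ C0, ξ² ∝ C0) at every
point, and report the mean reaction rate ṙ = k_r C0 ⟨Ĉ_M⟩ in nM/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import K_B
from .params import PhysicalParams, compute_dimensionless_groups
from .surface_fields import AzimuthalGrid, solve_fields, mean_reaction_rate
from .excess_energy import (EnergyBreakdown, energy_from_fields,
                            dissipative_energy, total_excess_energy)

__all__ = [
    "ActivityCurve",
    "active_diffusivity",
    "evaluate_point",
    "sweep_activity",
    "find_extrema",
    "Extremum",
]

#: 1 nM/s in SI volumetric rate units [mol/(m^3 s)]
NM_PER_S = 1e-6


def active_diffusivity(D0: float, E_abs: float, T_b: float) -> float:
    """D = D0 (1 + |E_s|/k_B T_b); units of D follow D0.

    ``E_abs`` is the magnitude of the surface excess energy [J].
    """
    if T_b <= 0:
        raise ValueError(f"bath temperature must be > 0, got {T_b}")
    if D0 < 0 or E_abs < 0:
        raise ValueError("D0 and E_abs must be >= 0")
    return D0 * (1.0 + E_abs / (K_B * T_b))


@dataclass
class ActivityCurve:
    """Result of a bulk-concentration sweep.

    ``rdot`` in nM/s, energies in J (signed totals), diffusivities in the
    units of the preset's ``D0`` (SI, m²/s) — helper properties convert to
    μm²/s and k_BT.
    """

    C0_values: np.ndarray
    rdot: np.ndarray                  # [nM/s], strictly increasing
    E_nd: np.ndarray                  # signed nondissipative total [J]
    E_d: np.ndarray                   # signed dissipative total [J]
    D_nd: np.ndarray                  # [m^2/s]
    D_d: np.ndarray                   # [m^2/s]
    T0: float
    D0: float
    breakdowns: list[EnergyBreakdown] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.rdot) > 0):
            raise ValueError("rdot must be strictly increasing along the sweep")

    @property
    def kT(self) -> float:
        return K_B * self.T0

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "C0": self.C0_values,
            "rdot_nMps": self.rdot,
            "E_nd_J": self.E_nd,
            "E_nd_kT": self.E_nd / self.kT,
            "E_d_J": self.E_d,
            "E_d_kT": self.E_d / self.kT,
            "D_nd_um2ps": self.D_nd * 1e12,
            "D_d_um2ps": self.D_d * 1e12,
        })
        if self.breakdowns:
            terms = pd.DataFrame([b.to_dict() for b in self.breakdowns])
            df = pd.concat([df, terms], axis=1)
        return df


def evaluate_point(p: PhysicalParams, C0: float, n_points: int = 512,
                   tau: float | None = None) -> dict:
    """Full pipeline at one bulk concentration.

    Returns rdot [nM/s], the signed totals, both diffusivities and the
    breakdown; groups are re-derived at the given C0.
    """
    pc = p.with_(C0=float(C0))
    g = compute_dimensionless_groups(pc)
    f = solve_fields(g, AzimuthalGrid(n_points))
    nd = energy_from_fields(pc, g, f)
    dd = dissipative_energy(pc, g, f, tau=tau)
    b = nd.merged_with(dd)
    rdot = mean_reaction_rate(pc, f) / NM_PER_S
    return {
        "C0": float(C0),
        "rdot": rdot,
        "breakdown": b,
        "E_nd": b.total_nd,
        "E_d": b.total_d,
        "D_nd": active_diffusivity(p.D0, abs(b.total_nd), p.T0),
        "D_d": active_diffusivity(p.D0, abs(b.total_d), p.T0),
    }


def sweep_activity(p: PhysicalParams, C0_grid, route: str = "both",
                   n_points: int = 512, tau: float | None = None,
                   keep_breakdowns: bool = True) -> ActivityCurve:
    """Sweep bulk concentration and assemble the activity curve.

    ``route`` selects which diffusivity columns are meaningful downstream
    ('nd', 'd' or 'both'); both are always computed (the dissipative pentad
    is cheap once the fields are solved).
    """
    if route not in ("nd", "d", "both"):
        raise ValueError(f"route must be 'nd', 'd' or 'both', got {route!r}")
    C0_grid = np.asarray(C0_grid, dtype=float)
    if C0_grid.ndim != 1 or C0_grid.size < 1:
        raise ValueError("C0_grid must be a 1-D array of concentrations")
    if np.any(C0_grid <= 0) or not np.all(np.diff(C0_grid) > 0):
        raise ValueError("C0_grid must be positive and strictly increasing")
    rows = []
    for C0 in C0_grid:
        try:
            rows.append(evaluate_point(p, C0, n_points=n_points, tau=tau))
        except Exception as exc:
            raise RuntimeError(f"sweep failed at C0 = {C0:g} mol/m^3: {exc}"
                               ) from exc
    return ActivityCurve(
        C0_values=C0_grid,
        rdot=np.array([r["rdot"] for r in rows]),
        E_nd=np.array([r["E_nd"] for r in rows]),
        E_d=np.array([r["E_d"] for r in rows]),
        D_nd=np.array([r["D_nd"] for r in rows]),
        D_d=np.array([r["D_d"] for r in rows]),
        T0=p.T0, D0=p.D0,
        breakdowns=[r["breakdown"] for r in rows] if keep_breakdowns else [],
    )


@dataclass(frozen=True)
class Extremum:
    rdot: float          # [nM/s]
    kind: str            # 'min' | 'max' | 'zero_crossing_of_E'
    C0: float            # [mol/m^3]
    D: float | None = None


def find_extrema(curve: ActivityCurve, route: str = "nd",
                 p: PhysicalParams | None = None, n_points: int = 512,
                 rel_tol: float = 1e-3) -> list[Extremum]:
    """Locate interior extrema of D(ṙ) and sign changes of the signed total E.

    Candidates are bracketed on the sweep grid; when the parameter set ``p``
    is given each candidate is refined by golden-section (extrema) or
    bisection (zero crossings) on the continuous pipeline to ``rel_tol``
    relative accuracy in ṙ.  A monotone curve yields an empty list.
    """
    if route not in ("nd", "d"):
        raise ValueError("route must be 'nd' or 'd'")
    if curve.rdot.size < 5:
        raise ValueError("need at least 5 sweep points to bracket extrema")
    D = curve.D_nd if route == "nd" else curve.D_d
    E = curve.E_nd if route == "nd" else curve.E_d
    out: list[Extremum] = []

    dD = np.diff(D)
    for i in range(1, dD.size):
        if dD[i - 1] > 0 and dD[i] < 0:
            out.append(_refine_extremum(curve, p, i, "max", route, n_points,
                                        rel_tol))
        elif dD[i - 1] < 0 and dD[i] > 0:
            out.append(_refine_extremum(curve, p, i, "min", route, n_points,
                                        rel_tol))
    for i in range(E.size - 1):
        if E[i] == 0.0:
            # exact zero on a node is itself the crossing when the
            # neighbors change sign around it
            if 0 < i and np.sign(E[i - 1]) * np.sign(E[i + 1]) < 0:
                out.append(Extremum(rdot=float(curve.rdot[i]),
                                    kind="zero_crossing_of_E",
                                    C0=float(curve.C0_values[i]),
                                    D=float(D[i])))
            continue
        if np.sign(E[i]) * np.sign(E[i + 1]) < 0:
            out.append(_refine_zero(curve, p, i, route, n_points, rel_tol))
    out.sort(key=lambda e: e.rdot)
    return out


def _point_fn(p: PhysicalParams, route: str, n_points: int):
    def f(C0: float) -> dict:
        return evaluate_point(p, C0, n_points=n_points)
    return f


def _refine_extremum(curve, p, i, kind, route, n_points, rel_tol) -> Extremum:
    D = curve.D_nd if route == "nd" else curve.D_d
    if p is None:
        return Extremum(rdot=float(curve.rdot[i]), kind=kind,
                        C0=float(curve.C0_values[i]), D=float(D[i]))
    f = _point_fn(p, route, n_points)
    key = "D_nd" if route == "nd" else "D_d"
    sign = -1.0 if kind == "max" else 1.0
    a, b = curve.C0_values[i - 1], curve.C0_values[i + 1]
    # golden-section on log-C0 (the sweep is typically geometric)
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    la, lb = math.log(a), math.log(b)
    lc = lb - gr * (lb - la)
    ld = la + gr * (lb - la)
    fc = sign * f(math.exp(lc))[key]
    fd = sign * f(math.exp(ld))[key]
    while (lb - la) > rel_tol / 2:
        if fc < fd:
            lb, ld, fd = ld, lc, fc
            lc = lb - gr * (lb - la)
            fc = sign * f(math.exp(lc))[key]
        else:
            la, lc, fc = lc, ld, fd
            ld = la + gr * (lb - la)
            fd = sign * f(math.exp(ld))[key]
    C0s = math.exp((la + lb) / 2)
    r = f(C0s)
    return Extremum(rdot=r["rdot"], kind=kind, C0=C0s, D=r[key])


def _refine_zero(curve, p, i, route, n_points, rel_tol) -> Extremum:
    E = curve.E_nd if route == "nd" else curve.E_d
    if p is None:
        # linear interpolation on the grid
        w = abs(E[i]) / (abs(E[i]) + abs(E[i + 1]))
        rd = curve.rdot[i] + w * (curve.rdot[i + 1] - curve.rdot[i])
        C0 = curve.C0_values[i] + w * (curve.C0_values[i + 1]
                                       - curve.C0_values[i])
        return Extremum(rdot=float(rd), kind="zero_crossing_of_E",
                        C0=float(C0))
    from scipy.optimize import brentq

    f = _point_fn(p, route, n_points)
    key = "E_nd" if route == "nd" else "E_d"
    a, b = curve.C0_values[i], curve.C0_values[i + 1]
    C0s = brentq(lambda c: f(c)[key], a, b, rtol=rel_tol / 2)
    r = f(C0s)
    dkey = "D_nd" if route == "nd" else "D_d"
    return Extremum(rdot=r["rdot"], kind="zero_crossing_of_E", C0=float(C0s),
                    D=r[dkey])


# ---------------------------------------------------------------------------
# operating windows of the two case studies
# ---------------------------------------------------------------------------

def default_C0_window(p: PhysicalParams, rdot_min: float = 1.0,
                      rdot_max: float = 100.0, n: int = 41,
                      n_points: int = 512) -> np.ndarray:
    """Geometric C0 grid spanning a target ṙ window [nM/s].

    ṙ is proportional to C0 (the dimensionless profiles do not depend on
    C0), so the window maps exactly onto a C0 interval through one solve.
    """
    g = compute_dimensionless_groups(p)
    f = solve_fields(g, AzimuthalGrid(n_points))
    slope = p.k_r * f.cap_mean_Chat_M  # rdot_SI = slope * C0
    if slope <= 0:
        raise ValueError("reaction rate vanishes for this parameter set")
    c_lo = rdot_min * NM_PER_S / slope
    c_hi = rdot_max * NM_PER_S / slope
    return np.geomspace(c_lo, c_hi, n)
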