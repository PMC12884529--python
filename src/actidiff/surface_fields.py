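"""Azimuthal boundary-value problems at the particle interface.

The interfacial steady state of a catalytic Janus sphere reduces, under polar
symmetry, to four linear ODEs in the azimuthal angle ϕ on the periodic domain
[−π, π]: dimensionless substrate Ĉ_M, product Ĉ_N, temperature T̂, and
electric potential ψ̂,

    0 = Ĉ_M'' − α² Ĉ_M Θ_cap(ϕ) − β² (Ĉ_M − 1)
    0 = Ĉ_N'' + α² Ĉ_M Θ_cap(ϕ) − β² Ĉ_N
    0 = T̂''  + λ² Ĉ_M Θ_cap(ϕ) − ω² (T̂ − 1)
    ψ̂'' = −ξ² (z_M Ĉ_M + z_N Ĉ_N)

with Θ_cap the indicator of the catalytic cap |ϕ| ≤ ϕ0.  All four are solved
with second-order central differences on a uniform periodic grid; the cap
indicator is cell-averaged so a node on the cap edge carries weight 1/2 and
the discretization stays second-order.  The potential (and the temperature
when ω² = 0) is gauged to zero mean with the incompatible mean of its source
projected out and recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import K_B, N_A, Q0, EPS0
from .params import PhysicalParams, DimensionlessGroups, compute_dimensionless_groups

__all__ = [
    "AzimuthalGrid",
    "SurfaceFields",
    "DegenerateProblemError",
    "solve_substrate",
    "solve_product",
    "solve_temperature",
    "solve_potential",
    "solve_fields",
    "mean_reaction_rate",
]


class DegenerateProblemError(ValueError):
    """Raised when the discretized BVP is singular for the given groups."""


@dataclass(frozen=True)
class AzimuthalGrid:
    """Uniform periodic grid on [−π, π).

    Nodes are ϕ_j = −π + j·h with h = 2π/n; the node at +π is identified
    with the one at −π and not duplicated.
    """

    n_points: int = 512

    def __post_init__(self) -> None:
        if self.n_points < 64:
            raise ValueError("n_points must be >= 64")
        if self.n_points % 2:
            raise ValueError("n_points must be even (node at phi=0 required)")

    @property
    def h(self) -> float:
        return 2.0 * math.pi / self.n_points

    @property
    def phi(self) -> np.ndarray:
        return -math.pi + self.h * np.arange(self.n_points)

    def cap_weights(self, phi0: float) -> np.ndarray:
        """Cell-averaged indicator of the catalytic cap |ϕ| <= ϕ0.

        Each node owns the cell [ϕ_j − h/2, ϕ_j + h/2]; the weight is the
        fraction of the cell inside the cap, so an edge node gets 1/2.
        """
        phi = self.phi
        h = self.h
        lo = np.abs(phi) - h / 2.0
        w = np.clip((phi0 - lo) / h, 0.0, 1.0)
        # the node at −π owns the wrap-around cell [π−h/2, π] ∪ [−π, −π+h/2],
        # on which |ϕ| ∈ [π−h/2, π] is attained twice: the covered fraction
        # is twice the one-sided value (and exactly 1 at ϕ0 = π)
        w[0] = min(max(2.0 * (phi0 - (math.pi - h / 2.0)) / h, 0.0), 1.0)
        return w

    def laplacian(self) -> sp.csc_matrix:
        n, h = self.n_points, self.h
        main = -2.0 * np.ones(n)
        off = np.ones(n - 1)
        lap = sp.diags([off, main, off], [-1, 0, 1], format="lil")
        lap[0, n - 1] = 1.0
        lap[n - 1, 0] = 1.0
        return (lap / h**2).tocsc()

    def ddphi(self, y: np.ndarray) -> np.ndarray:
        """Periodic central first derivative dy/dϕ (second order)."""
        return (np.roll(y, -1) - np.roll(y, 1)) / (2.0 * self.h)

    def arc_mean(self, y: np.ndarray) -> float:
        """Mean over the periodic domain (trapezoid, exact on this grid)."""
        return float(np.mean(y))


@dataclass
class SurfaceFields:
    """Solved interfacial profiles and their tangential gradients (per rad)."""

    grid: AzimuthalGrid
    groups: DimensionlessGroups
    Chat_M: np.ndarray
    Chat_N: np.ndarray
    theta_mean: float          # uniform part of T̂ − T̂_b, = λ²⟨Θ_cap Ĉ_M⟩/ω²
    theta_fluct: np.ndarray    # zero-mean part of T̂ − T̂_b (well scaled)
    psihat: np.ndarray
    cap: np.ndarray
    psi_source_offset: float = 0.0
    theta: np.ndarray = field(init=False)
    That: np.ndarray = field(init=False)
    grad_Chat_M: np.ndarray = field(init=False)
    grad_Chat_N: np.ndarray = field(init=False)
    grad_That: np.ndarray = field(init=False)
    grad_psihat: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.theta = self.theta_mean + self.theta_fluct
        self.That = self.groups.That_b + self.theta
        self.grad_Chat_M = self.grid.ddphi(self.Chat_M)
        self.grad_Chat_N = self.grid.ddphi(self.Chat_N)
        # gradient taken on the zero-mean deviation: constants drop out of
        # d/dϕ, and differentiating T̂_b + θ directly would lose the tiny
        # fluctuation to the machine epsilon of the larger uniform parts
        self.grad_That = self.grid.ddphi(self.theta_fluct)
        self.grad_psihat = self.grid.ddphi(self.psihat)

    @property
    def mean_Chat_M(self) -> float:
        return self.grid.arc_mean(self.Chat_M)

    @property
    def mean_Chat_N(self) -> float:
        return self.grid.arc_mean(self.Chat_N)

    @property
    def cap_mean_Chat_M(self) -> float:
        """Cap-restricted surface mean ⟨Ĉ_M Θ_cap⟩ (sets the reaction rate)."""
        return self.grid.arc_mean(self.cap * self.Chat_M)

    def to_frame(self):
        """Profiles as a pandas DataFrame (CSV-ready)."""
        import pandas as pd

        return pd.DataFrame({
            "phi": self.grid.phi,
            "Chat_M": self.Chat_M,
            "Chat_N": self.Chat_N,
            "That": self.That,
            "theta": self.theta,
            "psihat": self.psihat,
        })


def _require_same_grid(grid: AzimuthalGrid, y: np.ndarray, name: str) -> None:
    if y.shape != (grid.n_points,):
        raise ValueError(f"{name} was solved on a different grid "
                         f"({y.shape[0]} vs {grid.n_points} nodes)")


def solve_substrate(g: DimensionlessGroups, grid: AzimuthalGrid) -> np.ndarray:
    """Solve the substrate balance; returns Ĉ_M on the grid nodes."""
    if g.alpha2 == 0.0 and g.beta2 == 0.0:
        raise DegenerateProblemError(
            "alpha2 = beta2 = 0: substrate equation is pure Laplace on a "
            "periodic domain (solution undetermined)")
    if g.alpha2 == 0.0:
        return np.full(grid.n_points, g.Chat_Mb)
    w = grid.cap_weights(g.phi0)
    lap = grid.laplacian()
    A = lap - sp.diags(g.alpha2 * w + g.beta2)
    b = -g.beta2 * g.Chat_Mb * np.ones(grid.n_points)
    if g.beta2 == 0.0:
        # no bulk exchange: all substrate is consumed in steady state
        return np.zeros(grid.n_points)
    return spla.spsolve(A.tocsc(), b)


def solve_product(g: DimensionlessGroups, grid: AzimuthalGrid,
                  Chat_M: np.ndarray) -> np.ndarray:
    """Solve the product balance given the substrate profile."""
    _require_same_grid(grid, Chat_M, "Chat_M")
    if g.alpha2 == 0.0:
        return np.zeros(grid.n_points)
    if g.beta2 == 0.0:
        raise DegenerateProblemError(
            "beta2 = 0 with alpha2 > 0: the periodic product equation has no "
            "steady state (net source cannot leave the interface)")
    w = grid.cap_weights(g.phi0)
    A = grid.laplacian() - sp.diags(np.full(grid.n_points, g.beta2))
    b = -g.alpha2 * w * Chat_M
    out = spla.spsolve(A.tocsc(), b)
    # clip FD undershoot at the roundoff level only
    return np.where(np.abs(out) < 1e-14, np.maximum(out, 0.0), out)


def solve_temperature(g: DimensionlessGroups, grid: AzimuthalGrid,
                      Chat_M: np.ndarray) -> tuple[float, np.ndarray]:
    """Solve the interfacial heat balance in deviation form.

    Returns ``(theta_mean, theta_fluct)`` with T̂ = T̂_b + θ_mean + θ_fluct.
    The deviation form keeps the solution well scaled when λ² is tiny, and
    the mean mode ⟨θ⟩ = λ²⟨Θ_cap Ĉ_M⟩/ω² is split off analytically: the
    zero-mean remainder is solved with a mean-constrained (bordered) system,
    which stays well conditioned even for ω² ≪ h⁻² where a direct solve of
    the nearly singular operator loses ~ω⁻²·ε_mach of accuracy.  Keeping the
    two parts separate also preserves the full precision of the fluctuation
    when the uniform heating term dominates (λ²/ω² ≫ λ²).
    """
    _require_same_grid(grid, Chat_M, "Chat_M")
    if g.lambda2 == 0.0:
        return 0.0, np.zeros(grid.n_points)
    w = grid.cap_weights(g.phi0)
    src = g.lambda2 * w * Chat_M
    src_mean = float(src.mean())
    if g.omega2 == 0.0:
        warnings.warn(
            "omega2 = 0 with lambda2 > 0: no cooling, the periodic heat "
            "equation fixes T̂ only up to a constant; gauging <T̂> = T̂_b "
            "after projecting the source mean",
            RuntimeWarning, stacklevel=2)
        return 0.0, _solve_gauged_poisson(grid, src_mean - src)
    theta_mean = src_mean / g.omega2
    theta_fluct = _solve_mean_constrained_helmholtz(grid, g.omega2,
                                                    src_mean - src)
    return theta_mean, theta_fluct


def _solve_mean_constrained_helmholtz(grid: AzimuthalGrid, omega2: float,
                                      rhs: np.ndarray) -> np.ndarray:
    """Solve y'' − ω²y = rhs with ⟨y⟩ = 0 for zero-mean rhs (bordered)."""
    n = grid.n_points
    A = grid.laplacian() - sp.diags(np.full(n, omega2))
    ones = np.ones((n, 1))
    K = sp.bmat([[A, ones], [ones.T, None]], format="csc")
    b = np.append(rhs, 0.0)
    sol = spla.spsolve(K, b)
    return sol[:n]


def solve_potential(g: DimensionlessGroups, grid: AzimuthalGrid,
                    Chat_M: np.ndarray, Chat_N: np.ndarray
                    ) -> tuple[np.ndarray, float]:
    """Solve the surface Poisson equation for ψ̂, gauge ⟨ψ̂⟩ = 0.

    Returns ``(psihat, offset)`` where ``offset`` is the (projected-out) mean
    of the charge source −ξ²Σz_iĈ_i, nonzero whenever the interface carries a
    net charge; on a periodic domain only the fluctuating part of the source
    admits a solution, and the offset is reported for bookkeeping.
    """
    _require_same_grid(grid, Chat_M, "Chat_M")
    _require_same_grid(grid, Chat_N, "Chat_N")
    if g.xi2 == 0.0 or (g.z_M == 0 and g.z_N == 0):
        return np.zeros(grid.n_points), 0.0
    src = -g.xi2 * (g.z_M * Chat_M + g.z_N * Chat_N)
    offset = float(src.mean())
    psi = _solve_gauged_poisson(grid, src - offset)
    return psi, offset


def _solve_gauged_poisson(grid: AzimuthalGrid, rhs: np.ndarray) -> np.ndarray:
    """Solve y'' = rhs on the periodic grid with ⟨y⟩ = 0 (bordered system)."""
    n = grid.n_points
    lap = grid.laplacian().tolil()
    ones = np.ones((n, 1))
    K = sp.bmat([[lap, ones], [ones.T, None]], format="csc")
    b = np.append(rhs, 0.0)
    sol = spla.spsolve(K, b)
    return sol[:n]


def residual_norm(g: DimensionlessGroups, grid: AzimuthalGrid,
                  f: "SurfaceFields") -> dict[str, float]:
    """Relative ∞-norm residuals of the discretized equations (diagnostics)."""
    w = f.cap
    lap = grid.laplacian()
    out = {}
    rM = lap @ f.Chat_M - g.alpha2 * w * f.Chat_M - g.beta2 * (f.Chat_M - g.Chat_Mb)
    out["Chat_M"] = _rel_inf(rM, g.beta2 * g.Chat_Mb)
    rN = lap @ f.Chat_N + g.alpha2 * w * f.Chat_M - g.beta2 * f.Chat_N
    out["Chat_N"] = _rel_inf(rN, g.alpha2 * np.max(w * f.Chat_M))
    # mean and fluctuating channels of the heat balance are checked
    # separately: the discrete Laplacian annihilates the mean mode, and
    # feeding the (much larger) mean through it would bury the fluctuation
    # residual under ~ε_mach·⟨θ⟩/h² of roundoff
    src_T = g.lambda2 * w * f.Chat_M
    rT = lap @ f.theta_fluct + (src_T - src_T.mean()) \
        - g.omega2 * f.theta_fluct
    r_mean = src_T.mean() - g.omega2 * f.theta_mean
    out["That"] = max(_rel_inf(rT, g.lambda2 * np.max(w * f.Chat_M)),
                      _rel_inf(np.array([r_mean]),
                               g.lambda2 * np.max(w * f.Chat_M)))
    src = -g.xi2 * (g.z_M * f.Chat_M + g.z_N * f.Chat_N)
    rP = lap @ f.psihat - (src - f.psi_source_offset)
    out["psihat"] = _rel_inf(rP, np.max(np.abs(src)) if np.any(src) else 0.0)
    return out


def _rel_inf(r: np.ndarray, scale: float) -> float:
    s = abs(scale)
    return float(np.max(np.abs(r)) / (s if s > 0 else 1.0))


def solve_fields(g: DimensionlessGroups | PhysicalParams,
                 grid: AzimuthalGrid | int | None = None) -> SurfaceFields:
    """Solve all four interfacial profiles.

    Accepts either precomputed dimensionless groups or a dimensional
    parameter set (converted internally).
    """
    if isinstance(g, PhysicalParams):
        g = compute_dimensionless_groups(g)
    if grid is None:
        grid = AzimuthalGrid()
    elif isinstance(grid, int):
        grid = AzimuthalGrid(grid)
    Chat_M = solve_substrate(g, grid)
    Chat_N = solve_product(g, grid, Chat_M)
    theta_mean, theta_fluct = solve_temperature(g, grid, Chat_M)
    psihat, offset = solve_potential(g, grid, Chat_M, Chat_N)
    return SurfaceFields(grid=grid, groups=g, Chat_M=Chat_M, Chat_N=Chat_N,
                         theta_mean=theta_mean, theta_fluct=theta_fluct,
                         psihat=psihat, cap=grid.cap_weights(g.phi0),
                         psi_source_offset=offset)


def mean_reaction_rate(p: PhysicalParams, fields: SurfaceFields) -> float:
    """Mean surface reaction rate ṙ = k_r C0 ⟨Ĉ_M Θ_cap⟩ [mol/(m³ s)].

    The rate is the surface average of the local reaction rate, nonzero only
    on the catalytic cap; for a fully catalytic surface (ϕ0 = π, small
    groups) this reduces to the classical k_r C0 β²/(α²+β²).  In steady
    state it equals the net substrate uptake k_r C0 β²(1−⟨Ĉ_M⟩)/α².
    Multiply by 1e6 for nM/s.
    """
    return p.k_r * p.C0 * fields.cap_mean_Chat_M


def mean_substrate_closed_form(alpha2: float, beta2: float,
                               phi0: float = math.pi) -> float:
    """Small-α²,β² closed form for ⟨Ĉ_M⟩, β²/((ϕ0/π)α² + β²).

    With a fully catalytic surface (ϕ0 = π) this is the classical
    β²/(α²+β²); a partial cap rescales the reaction group by the covered
    arc fraction ϕ0/π.
    """
    frac = phi0 / math.pi
    denom = frac * alpha2 + beta2
    if denom == 0.0:
        raise ValueError("alpha2 and beta2 cannot both vanish")
    return beta2 / denom
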