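"""Parameter estimation against D(ṙ) activity data.

The interfacial thickness ε is the model's principal fitting parameter;
the surface-tension derivatives (γ_CM, γ_CN, γ_T) and the composition
constant w0 may additionally be freed within bounds (literature values are
trusted to within tens of percent).  Synthetic noisy curves generated from
the model itself provide the parameter-recovery test bed standing in for
experimental data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .params import PhysicalParams
from .diffusivity import sweep_activity, NM_PER_S

__all__ = ["FitSpec", "SyntheticCurve", "FitResult", "generate_synthetic",
           "fit", "model_curve", "quadratic_vs_linear"]

_FREEABLE = ("eps_thick", "gamma_CM", "gamma_CN", "gamma_T", "w0")


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are free, their bounds, the route and the loss."""

    free_params: tuple[str, ...] = ("eps_thick",)
    bounds: dict = field(default_factory=dict)  # name -> (lo, hi)
    route: str = "nd"
    weighted: bool = True       # 1/sigma^2 weights when sigma_D available

    def __post_init__(self) -> None:
        unknown = [f for f in self.free_params if f not in _FREEABLE]
        if unknown:
            raise ValueError(f"cannot free {unknown}; allowed: {_FREEABLE}")
        if self.route not in ("nd", "d"):
            raise ValueError("route must be 'nd' or 'd'")

    def bounds_for(self, name: str, p0: PhysicalParams) -> tuple[float, float]:
        if name in self.bounds:
            lo, hi = self.bounds[name]
        elif name == "eps_thick":
            v = p0.eps_thick
            lo, hi = v / 10.0, v * 10.0
        elif name == "w0":
            lo, hi = 0.05, 0.95
        else:
            # gamma derivatives: within ±50% of the reference value
            v = getattr(p0, name)
            lo, hi = sorted((0.5 * v, 1.5 * v))
        if name == "eps_thick" and lo <= 0:
            raise ValueError("eps_thick bounds must be positive")
        if not lo < hi:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        return lo, hi


@dataclass
class SyntheticCurve:
    """Noisy model curve: D_obs = model(ṙ) · (1 + cv·η), η ~ N(0,1)."""

    rdot: np.ndarray         # [nM/s]
    D_obs: np.ndarray        # [m^2/s]
    sigma_D: np.ndarray      # [m^2/s]
    C0_values: np.ndarray
    true_params: PhysicalParams
    seed: int
    noise_cv: float


@dataclass
class FitResult:
    params: dict             # fitted values
    se: dict                 # approximate standard errors
    r2: float
    rss: float
    n_obs: int
    success: bool
    message: str
    quad_vs_lin: dict        # quadratic/linear trend comparison of the data


def model_curve(p: PhysicalParams, C0_values: np.ndarray, route: str = "nd",
                n_points: int = 256) -> np.ndarray:
    """Model diffusivity [m²/s] at the given bulk concentrations."""
    curve = sweep_activity(p, C0_values, route="both", n_points=n_points,
                           keep_breakdowns=False)
    return curve.D_nd if route == "nd" else curve.D_d


def generate_synthetic(p: PhysicalParams, C0_grid, noise_cv: float,
                       seed: int, route: str = "nd",
                       n_points: int = 256) -> SyntheticCurve:
    """Model curve plus multiplicative Gaussian noise, reproducible by seed."""
    if not 0.0 <= noise_cv <= 0.5:
        raise ValueError("noise_cv must lie in [0, 0.5]")
    C0_grid = np.asarray(C0_grid, dtype=float)
    curve = sweep_activity(p, C0_grid, route="both", n_points=n_points,
                           keep_breakdowns=False)
    D_model = curve.D_nd if route == "nd" else curve.D_d
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=D_model.size) if noise_cv > 0 else 0.0
    D_obs = D_model * (1.0 + noise_cv * noise)
    sigma = noise_cv * D_model if noise_cv > 0 else np.full_like(D_model,
                                                                 1e-30)
    return SyntheticCurve(rdot=curve.rdot.copy(), D_obs=D_obs,
                          sigma_D=np.asarray(sigma), C0_values=C0_grid,
                          true_params=p, seed=seed, noise_cv=noise_cv)


def quadratic_vs_linear(rdot: np.ndarray, D: np.ndarray) -> dict:
    """Compare linear and quadratic least-squares trends of D(ṙ).

    Returns RSS of both fits, their ratio, the quadratic coefficient and
    R² values — the descriptive model comparison used for activity curves.
    """
    lin = np.polyfit(rdot, D, 1)
    quad = np.polyfit(rdot, D, 2)
    rss_lin = float(np.sum((D - np.polyval(lin, rdot)) ** 2))
    rss_quad = float(np.sum((D - np.polyval(quad, rdot)) ** 2))
    tss = float(np.sum((D - D.mean()) ** 2))
    return {
        "rss_linear": rss_lin,
        "rss_quadratic": rss_quad,
        "rss_ratio": rss_quad / rss_lin if rss_lin > 0 else math.nan,
        "quad_coeff": float(quad[0]),
        "r2_linear": 1.0 - rss_lin / tss if tss > 0 else math.nan,
        "r2_quadratic": 1.0 - rss_quad / tss if tss > 0 else math.nan,
    }


def fit(spec: FitSpec, data: SyntheticCurve, p0: PhysicalParams,
        n_starts: int = 5, seed: int = 0, n_points: int = 256) -> FitResult:
    """Bounded weighted least squares of the model against a D(ṙ) curve.

    Multi-start (``n_starts`` seeded log-uniform initial points within the
    bounds) guards against nonmonotonic-landscape local minima.  The fit is
    invariant to the ordering of the data points (the loss is a sum).
    """
    names = list(spec.free_params)
    if data.rdot.size < 2 * len(names):
        raise ValueError("need at least 2x more data points than free "
                         "parameters")
    bounds = [spec.bounds_for(n, p0) for n in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    C0_values = np.asarray(data.C0_values, dtype=float)

    if spec.weighted and np.all(data.sigma_D > 0):
        w = 1.0 / data.sigma_D
    else:
        w = np.ones_like(data.D_obs)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = p0.with_(**dict(zip(names, theta)))
        D = model_curve(p, C0_values, route=spec.route, n_points=n_points)
        return w * (D - data.D_obs)

    rng = np.random.default_rng(seed)
    starts = [np.array([np.clip(getattr(p0, n), lo[i], hi[i])
                        for i, n in enumerate(names)])]
    for _ in range(n_starts - 1):
        u = rng.uniform(size=len(names))
        if np.all(lo > 0):
            starts.append(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        else:
            starts.append(lo + u * (hi - lo))

    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("least-squares failed from every start")

    rss = float(np.sum((residuals(best.x) / w) ** 2))
    tss = float(np.sum((data.D_obs - data.D_obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    se = _standard_errors(best, names)
    return FitResult(
        params=dict(zip(names, best.x.tolist())),
        se=se, r2=r2, rss=rss, n_obs=int(data.rdot.size),
        success=bool(best.success),
        message=str(best.message),
        quad_vs_lin=quadratic_vs_linear(data.rdot, data.D_obs),
    )


def _standard_errors(res, names) -> dict:
    try:
        J = res.jac
        dof = max(J.shape[0] - J.shape[1], 1)
        s2 = 2.0 * res.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        return {n: float(math.sqrt(max(cov[i, i], 0.0)))
                for i, n in enumerate(names)}
    except Exception:
        return {n: math.nan for n in names}
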