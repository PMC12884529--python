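import math
import warnings

import numpy as np
import pytest

from actidiff import (AzimuthalGrid, compute_dimensionless_groups,
                      solve_fields, energy_from_fields, energy_closed_form,
                      closed_form_leading_order, dissipative_energy,
                      total_excess_energy, full_breakdown)
from actidiff.excess_energy import _I, _J


def _small_groups(p):
    """Rescale the kinetic parameters so that α² = β² = 1e-4."""
    target = 1e-4 * p.D_s / p.R**2
    return p.with_(k_r=target, U=target)


def _nd_pair(p, n_points=512):
    g = compute_dimensionless_groups(p)
    f = solve_fields(g, AzimuthalGrid(n_points))
    quad = energy_from_fields(p, g, f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        closed = energy_closed_form(p, g)
    return quad.to_dict(), closed.to_dict()


def test_brackets_on_known_functions():
    grid = AzimuthalGrid(512)
    phi = grid.phi
    # I[X] = (X(π) − X(0)) / π on the half meridian
    assert _I(grid, np.cos(phi)) == pytest.approx(-2.0 / math.pi, rel=1e-6)
    assert _I(grid, np.ones_like(phi)) == pytest.approx(0.0, abs=1e-14)
    # J[g] = (1/π) ∫_0^π g dϕ
    assert _J(grid, np.ones_like(phi)) == pytest.approx(1.0, rel=1e-12)
    assert _J(grid, np.cos(phi)) == pytest.approx(0.0, abs=1e-8)
    assert _J(grid, np.cos(phi) ** 2) == pytest.approx(0.5, rel=1e-8)


@pytest.mark.parametrize("preset", ["case1_janus_nano", "case2_vesicle"])
def test_closed_form_matches_quadrature_small_groups(preset):
    """Exact analytic rows vs quadrature, term by term, at α² = β² = 1e-4."""
    from actidiff import load_preset

    p = _small_groups(load_preset(preset))
    quad, closed = _nd_pair(p)
    for term in ("e_reaction", "e_entropic", "e_electro", "e_diffusio",
                 "e_thermo"):
        scale = max(abs(quad[term]), abs(closed[term]))
        assert abs(quad[term] - closed[term]) <= 5e-3 * scale, term


def test_closed_form_matches_quadrature_native_case2(case2):
    quad, closed = _nd_pair(case2)
    for term in ("e_reaction", "e_entropic", "e_electro", "e_diffusio",
                 "e_thermo"):
        scale = max(abs(quad[term]), abs(closed[term]))
        assert abs(quad[term] - closed[term]) <= 1e-3 * scale, term


def test_energy_linear_in_concentration_like_terms(case2):
    """e_reaction, e_entropic, e_diffusio, e_thermo scale ∝ C0;
    e_electro ∝ C0² (the potential itself carries a factor ξ² ∝ C0)."""
    g = compute_dimensionless_groups(case2)
    f = solve_fields(g, AzimuthalGrid(512))
    b1 = energy_from_fields(case2, g, f).to_dict()
    p2 = case2.with_(C0=2.0 * case2.C0)
    g2 = compute_dimensionless_groups(p2)
    f2 = solve_fields(g2, AzimuthalGrid(512))
    b2 = energy_from_fields(p2, g2, f2).to_dict()
    for term in ("e_reaction", "e_diffusio", "e_thermo"):
        assert b2[term] == pytest.approx(2.0 * b1[term], rel=1e-9)
    assert b2["e_electro"] == pytest.approx(4.0 * b1["e_electro"], rel=1e-9)


def test_totals_are_sums(case2):
    b = full_breakdown(case2, n_points=256)
    d = b.to_dict()
    assert d["total_nd"] == pytest.approx(
        sum(d[k] for k in ("e_reaction", "e_entropic", "e_electro",
                           "e_diffusio", "e_thermo")), rel=1e-14)
    assert d["total_d"] == pytest.approx(
        sum(d[k] for k in ("d_mixing", "d_diffusion", "d_heat",
                           "d_reaction", "d_viscous")), rel=1e-14)
    assert total_excess_energy(b, "nd") == abs(d["total_nd"])
    assert total_excess_energy(b, "d") == abs(d["total_d"])
    with pytest.raises(ValueError):
        total_excess_energy(b, "bogus")


def test_dissipative_linear_in_tau(case2):
    g = compute_dimensionless_groups(case2)
    f = solve_fields(g, AzimuthalGrid(256))
    b1 = dissipative_energy(case2, g, f, tau=1.0).to_dict()
    b3 = dissipative_energy(case2, g, f, tau=3.0).to_dict()
    for term in ("d_mixing", "d_diffusion", "d_heat", "d_reaction",
                 "d_viscous"):
        assert b3[term] == pytest.approx(3.0 * b1[term], rel=1e-12)


def test_dissipative_entropy_production_signs(case1, case2):
    """The entropy-production channels of σ_s are nonnegative by
    construction (squared gradients / squared tensions)."""
    for p in (case1, case2):
        d = full_breakdown(p, n_points=256).to_dict()
        assert d["d_diffusion"] >= 0.0
        assert d["d_heat"] >= 0.0
        assert d["d_viscous"] >= 0.0


def test_inconsistent_groups_rejected(case2):
    g = compute_dimensionless_groups(case2.with_(k_r=2.0 * case2.k_r))
    f = solve_fields(g, AzimuthalGrid(256))
    with pytest.raises(ValueError, match="inconsistent"):
        energy_from_fields(case2, g, f)


def test_closed_form_warns_outside_small_group_regime(case2):
    # the vesicle preset has α² ≈ 3, beyond the historical validity regime
    with pytest.warns(RuntimeWarning, match="validity"):
        energy_closed_form(case2)


def test_leading_order_tracks_closed_form(case1):
    """The leading-order rows approach the exact analytic values as the
    kinetic groups shrink (both ∝ α² at fixed ratio)."""
    p = _small_groups(case1)
    lead = closed_form_leading_order(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        closed = energy_closed_form(p).to_dict()
    for lead_key, term in (("reaction", "e_reaction"),
                           ("diffusio", "e_diffusio")):
        assert lead[lead_key] == pytest.approx(closed[term], rel=0.05)
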