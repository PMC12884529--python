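import numpy as np
import pytest

from actidiff import (active_diffusivity, evaluate_point, sweep_activity,
                      find_extrema, ActivityCurve)
from actidiff.constants import K_B
from actidiff.diffusivity import default_C0_window, NM_PER_S


def test_active_diffusivity_formula():
    kT = K_B * 300.0
    assert active_diffusivity(1e-12, 0.0, 300.0) == 1e-12
    assert active_diffusivity(1e-12, 2.0 * kT, 300.0) == pytest.approx(3e-12)
    with pytest.raises(ValueError):
        active_diffusivity(1e-12, 1e-21, -1.0)
    with pytest.raises(ValueError):
        active_diffusivity(-1e-12, 0.0, 300.0)


def test_evaluate_point_consistency(case2):
    r = evaluate_point(case2, case2.C0, n_points=256)
    kT = K_B * case2.T0
    assert r["D_nd"] == pytest.approx(
        case2.D0 * (1.0 + abs(r["E_nd"]) / kT), rel=1e-12)
    assert r["D_d"] == pytest.approx(
        case2.D0 * (1.0 + abs(r["E_d"]) / kT), rel=1e-12)
    assert r["rdot"] > 0


def test_default_window_maps_rdot_exactly(case2):
    C0_grid = default_C0_window(case2, rdot_min=1.0, rdot_max=100.0, n=11,
                                n_points=256)
    curve = sweep_activity(case2, C0_grid, n_points=256,
                           keep_breakdowns=False)
    assert curve.rdot[0] == pytest.approx(1.0, rel=1e-6)
    assert curve.rdot[-1] == pytest.approx(100.0, rel=1e-6)


def test_sweep_rdot_proportional_to_C0(case2):
    """The dimensionless profiles do not depend on C0, so ṙ ∝ C0."""
    C0_grid = np.geomspace(1e-8, 1e-6, 7)
    curve = sweep_activity(case2, C0_grid, n_points=256,
                           keep_breakdowns=False)
    ratio = curve.rdot / curve.C0_values
    np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)


def test_sweep_validation(case2):
    with pytest.raises(ValueError):
        sweep_activity(case2, [1e-6, 1e-7], n_points=256)  # not increasing
    with pytest.raises(ValueError):
        sweep_activity(case2, [-1.0, 1.0], n_points=256)
    with pytest.raises(ValueError):
        sweep_activity(case2, [1e-7], route="bogus", n_points=256)


def test_to_frame_columns(case2):
    C0_grid = default_C0_window(case2, n=6)
    curve = sweep_activity(case2, C0_grid, n_points=256)
    df = curve.to_frame()
    for col in ("C0", "rdot_nMps", "E_nd_J", "E_nd_kT", "E_d_J", "E_d_kT",
                "D_nd_um2ps", "D_d_um2ps", "e_electro", "d_reaction"):
        assert col in df.columns
    assert len(df) == 6
    np.testing.assert_allclose(df["D_nd_um2ps"], curve.D_nd * 1e12)


def _synthetic_curve(D):
    n = len(D)
    rdot = np.linspace(1.0, 100.0, n)
    E = np.linspace(-1e-21, 1e-21, n)  # one sign change
    return ActivityCurve(C0_values=np.geomspace(1e-8, 1e-6, n),
                         rdot=rdot, E_nd=E, E_d=E,
                         D_nd=np.asarray(D, dtype=float),
                         D_d=np.asarray(D, dtype=float),
                         T0=300.0, D0=1e-12)


def test_find_extrema_on_grid_candidates():
    x = np.linspace(-1.0, 1.0, 21)
    D = 1e-12 * (2.0 + np.sin(2.5 * x))  # interior max then min
    curve = _synthetic_curve(D)
    kinds = [e.kind for e in find_extrema(curve)]
    assert "max" in kinds and "min" in kinds
    assert "zero_crossing_of_E" in kinds


def test_find_extrema_monotone_has_no_extrema():
    D = np.linspace(1.0, 2.0, 21) * 1e-12
    curve = _synthetic_curve(D)
    curve.E_nd = np.linspace(1e-22, 1e-21, 21)  # no sign change either
    assert find_extrema(curve) == []


def test_nM_unit():
    assert NM_PER_S == 1e-6  # 1 nmol/(L s) in mol/(m^3 s)
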