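"""Unit and property tests of the three-compartment disposition model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from nrf2pk import DosingSchedule, PKParameters, PKState, pk_rhs, simulate_pk
from nrf2pk.pk import fraction_metabolized, simulate_pk_fast
from nrf2pk.units import DAY_S, DEFAULT_GEOMETRY as G


def test_rhs_zero_state_is_absorbing(mode_pk):
    assert np.all(pk_rhs(PKState(), mode_pk) == 0.0)


def test_rhs_empty_wall_has_no_unbinding(mode_pk):
    """With nothing on the wall, the wall flux is exactly +k1*ext."""
    s = PKState(csa_extracellular=1e6)
    dy = pk_rhs(s, mode_pk)
    assert dy[2] == pytest.approx(mode_pk.k1 * 1e6, rel=1e-12)


def test_rhs_matches_term_by_term_arithmetic(mode_pk):
    """Mode parameters, hand-picked state, spreadsheet-style evaluation."""
    cyt, ext, wall = 2.0e6, 5.0e6, 4.0e5
    s = PKState(cyt, ext, wall, 0.0)
    # independent term-by-term arithmetic
    c_ext = ext / G.V_extracellular
    c_cyt = cyt / G.V_cytosol
    uptake = 99.6 * c_ext
    efflux = (0.581 * 2965.0) * c_cyt / (2965.0 + c_cyt)
    metab = 40.0 * cyt / (2.18e6 + cyt)
    won = 3.55e-5 * ext
    woff = 6.01e-4 * wall ** 0.921
    expected = np.array([uptake - efflux - metab,
                         -uptake + efflux - won + woff,
                         won - woff, metab])
    np.testing.assert_allclose(pk_rhs(s, mode_pk), expected, rtol=1e-12)
    # mass balance: compartment derivatives sum to -metabolism
    assert np.sum(pk_rhs(s, mode_pk)[:3]) == pytest.approx(-metab, rel=1e-10)


def test_invalid_inputs_rejected(mode_pk):
    with pytest.raises(ValueError):
        PKState(csa_cytosol=-1.0)
    with pytest.raises(ValueError):
        PKParameters(k3=0.0)
    with pytest.raises(ValueError):
        PKParameters(k3=0.96)
    with pytest.raises(ValueError):
        PKParameters(CLin1=-5.0)


@given(cyt=st.floats(0, 1e8), ext=st.floats(0, 1e8), wall=st.floats(0, 1e8))
@settings(max_examples=100, deadline=None)
def test_mass_balance_property(cyt, ext, wall):
    """Sum of compartment derivatives equals minus the metabolism flux."""
    p = PKParameters()
    dy = pk_rhs(PKState(cyt, ext, wall), p)
    assert np.sum(dy[:3]) == pytest.approx(-dy[3], rel=1e-9, abs=1e-12)


def test_mass_conserved_between_doses(mode_pk):
    """Total mass + metabolized integral is constant within an interval."""
    sch = DosingSchedule(dose_uM=5.0, n_doses=1)
    tr = simulate_pk(mode_pk, G, sch,
                     times=np.linspace(0, DAY_S, 500))
    total = tr.y.sum(axis=0)
    assert np.max(np.abs(total - total[0])) / total[0] < 1e-6


def test_uptake_only_monotonicity(mode_pk):
    """With efflux/metabolism/wall binding negligible, cytosolic drug is
    non-decreasing, extracellular non-increasing, and the sum constant."""
    p = PKParameters(CLout1_over_Kmout1=1e-12, vmax=0.0, k1=1e-15)
    sch = DosingSchedule(dose_uM=5.0, n_doses=1)
    tr = simulate_pk(p, G, sch, times=np.linspace(0, DAY_S, 300))
    cyt, ext = tr["csa_cytosol"], tr["csa_extracellular"]
    assert np.all(np.diff(cyt) >= -1e-6 * cyt.max())
    assert np.all(np.diff(ext) <= 1e-6 * ext.max())
    total = cyt + ext
    assert np.max(np.abs(total - total[0])) / total[0] < 1e-6


def test_linear_limit_matches_matrix_exponential(mode_pk):
    """Far below both Michaelis constants and with the wall decoupled, the
    cell-medium exchange is linear and matches the closed-form solution."""
    p = PKParameters(Kmout1=1e9, Km2=1e12, k1=1e-15, k2=1e-12, k3=0.5)
    sch = DosingSchedule(dose_uM=5.0, n_doses=1)
    times = np.linspace(0, DAY_S, 50)
    tr = simulate_pk(p, G, sch, times=times, rtol=1e-10, atol=1e-12)
    # linear rates: uptake a*ext, efflux b*cyt, metabolism c*cyt
    a = p.CLin1 / G.V_extracellular
    b = p.CLout1 / (G.V_cytosol * p.Kmout1)
    c = p.vmax / p.Km2
    A = np.array([[-(b + c), a], [b, -a]])
    y0 = np.array([0.0, 5.0 * G.V_extracellular])
    for i, t in enumerate(times):
        y = expm(A * t) @ y0
        np.testing.assert_allclose(
            [tr["csa_cytosol"][i], tr["csa_extracellular"][i]], y,
            rtol=1e-3, atol=1e-6)


def _rk4_oracle(p, g, y0, t_end, dt):
    """Test-local fixed-step classical Runge-Kutta integrator."""
    def f(y):
        cyt, ext, wall = np.maximum(y[:3], 0.0)
        up = p.CLin1 * ext / g.V_extracellular
        ce = cyt / g.V_cytosol
        ef = p.CLout1 * ce / (p.Kmout1 + ce)
        me = p.vmax * cyt / (p.Km2 + cyt)
        won = p.k1 * ext
        woff = p.k2 * wall ** p.k3 if wall > 0 else 0.0
        return np.array([up - ef - me, -up + ef - won + woff,
                         won - woff, me])
    y = y0.astype(float).copy()
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = f(y); k2 = f(y + dt / 2 * k1)
        k3 = f(y + dt / 2 * k2); k4 = f(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def test_adaptive_solution_matches_rk4_oracle(mode_pk):
    """Single interval: adaptive solver vs fine fixed-step oracle < 0.1%."""
    sch = DosingSchedule(dose_uM=5.0, n_doses=1)
    tr = simulate_pk(mode_pk, G, sch, times=np.array([0.0, DAY_S]))
    y_oracle = _rk4_oracle(mode_pk, G,
                           np.array([0.0, 5.0 * G.V_extracellular, 0.0, 0.0]),
                           DAY_S, 10.0)
    np.testing.assert_allclose(tr.y[:, -1], y_oracle, rtol=1e-3)


def test_fast_path_matches_adaptive(mode_pk):
    sch = DosingSchedule(dose_uM=15.0, n_doses=14)
    obs = np.array([0.5, 1, 3, 6, 24, 72, 120, 240, 24 * 13.5, 336.0]) * 3600.0
    Yf = simulate_pk_fast(mode_pk, G, sch, obs)
    tr = simulate_pk(mode_pk, G, sch, times=obs)
    np.testing.assert_allclose(Yf, tr.y, rtol=1e-3)


def test_zero_dose_trajectory_is_zero(mode_pk):
    sch = DosingSchedule(dose_uM=0.0, n_doses=3)
    tr = simulate_pk(mode_pk, G, sch)
    assert np.all(tr.y == 0.0)


def test_fraction_metabolized_zero_without_metabolism():
    p = PKParameters(vmax=0.0)
    sch = DosingSchedule(dose_uM=5.0, n_doses=3)
    tr = simulate_pk(p, G, sch)
    assert fraction_metabolized(tr) == 0.0


def test_full_protocol_mass_audit(pk_traj_5):
    """Dosed = remaining in compartments + metabolized + discarded medium."""
    tr = pk_traj_5
    dosed = tr.schedule.total_dosed_quantity(G.V_extracellular)
    remaining = tr.y[:3, -1].sum()
    metabolized = tr["csa_metabolized"][-1]
    discarded = tr.audit.total_discarded
    assert dosed == pytest.approx(remaining + metabolized + discarded,
                                  rel=1e-5)
    assert 0.0 <= fraction_metabolized(tr) <= 1.0


def test_fraction_metabolized_requires_dose(mode_pk):
    sch = DosingSchedule(dose_uM=0.0, n_doses=3)
    tr = simulate_pk(mode_pk, G, sch)
    with pytest.raises(ValueError):
        fraction_metabolized(tr)
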