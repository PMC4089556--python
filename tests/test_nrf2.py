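"""Unit and invariant tests of the coupled pathway model."""

import numpy as np
import pytest

from nrf2pk import (DosingSchedule, NrfParameters, PKParameters,
                    baseline_state, nrf2_rhs, simulate_coupled)
from nrf2pk.nrf2 import NRF_STATE_NAMES, _IX, ahr_binding_fluxes
from nrf2pk.units import DAY_S, DEFAULT_GEOMETRY as G

IX = _IX


def _free_indices():
    book = {IX["csa_metabolized"], IX["ros_cleared"]}
    csa = {IX[n] for n in ("csa_cytosol", "csa_extracellular", "csa_wall",
                           "csa_nucleus")}
    return [i for i in range(len(NRF_STATE_NAMES)) if i not in book | csa]


def test_no_oxidant_source_means_no_oxidation(mode_pk):
    """Without basal or drug-driven ROS formation the ROS balance and every
    oxidation flux vanish."""
    p = NrfParameters(k_ros_basal=0.0, k_ros_csa=0.0)
    y = np.ones(len(NRF_STATE_NAMES))
    y[IX["ros"]] = 0.0
    dy = nrf2_rhs(y, p, mode_pk)
    assert dy[IX["ros"]] == 0.0
    assert dy[IX["ros_cleared"]] == 0.0
    # no new oxidation: the oxidized complex only drains by release
    rel = p.krel_nrf2_keap1_ox * y[IX["nrf2_keap1_ox"]]
    assert dy[IX["nrf2_keap1_ox"]] == pytest.approx(-rel, rel=1e-12)
    red = p.kred_keap1 * y[IX["keap1_ox"]]
    deg = p.kdeg_keap1 * y[IX["keap1_ox"]]
    assert dy[IX["keap1_ox"]] == pytest.approx(rel - red - deg, rel=1e-12)


def test_ahr_branch_is_inert(mode_nrf, mode_pk):
    """CsA is not an AhR ligand: its receptor-binding fluxes are zero for
    any state, and nonzero binding constants are rejected for simulation."""
    y = np.full(len(NRF_STATE_NAMES), 7.0)
    fluxes = ahr_binding_fluxes(y, mode_nrf)
    assert all(v == 0.0 for v in fluxes.values())
    bad = mode_nrf.replace(kb_ahr=1e-3)
    with pytest.raises(ValueError):
        simulate_coupled(bad, mode_pk)


def test_rhs_term_by_term_arithmetic(mode_nrf, mode_pk):
    """Posterior-mode parameters, hand-set state: key derivative components
    match an independent evaluation of the stated rate laws."""
    p, q = mode_nrf, mode_pk
    y = np.zeros(len(NRF_STATE_NAMES))
    y[IX["csa_cytosol"]] = 1.0e6
    y[IX["ros"]] = 50.0
    y[IX["gsh"]] = 8.0e6
    y[IX["ggc"]] = 2000.0
    y[IX["prot_gpx"]] = 150.0
    y[IX["prot_gs"]] = 100.0
    y[IX["prot_gcl"]] = 120.0
    y[IX["prot_gclc"]] = 3.0
    y[IX["prot_gclm"]] = 200.0
    y[IX["prot_cyp3a5"]] = 214.0
    y[IX["keap1"]] = 70.0
    y[IX["nrf2_maf"]] = 0.02
    y[IX["are_gclc"]] = 0.004
    y[IX["mrna_gclc"]] = 100.0
    dy = nrf2_rhs(y, p, q)
    # ROS balance: basal + drug-driven formation minus GPx clearance
    clear = (2.67 * 150.0 * (50.0 / (p.km_ros_gpx + 50.0))
             * (8.0e6 / (p.km_gsh_gpx + 8.0e6)))
    prod = 79.1 + 6.55e-5 * 1.0e6
    assert dy[IX["ros"]] == pytest.approx(prod - clear, rel=1e-12)
    # GCLC transcription: basal + ARE-occupancy induction, minus decay
    tx = (1.28 + 22.1 * 0.004) * p.gene_dose - p.kdeg_mrna * 100.0
    assert dy[IX["mrna_gclc"]] == pytest.approx(tx, rel=1e-12)
    # glutathione: synthesis by GS minus degradation minus 2x clearance
    gsh_syn = 8.57 * 100.0 * 2000.0 / (p.km_ggc_gs + 2000.0)
    gsh_deg = 283.0 * 8.0e6 / (1.62e8 + 8.0e6)
    assert dy[IX["gsh"]] == pytest.approx(gsh_syn - gsh_deg - 2 * clear,
                                          rel=1e-12)
    # gamma-GC: GCL + free-GCLC synthesis under GSH feedback, minus GS use
    fb = p.ki_gsh_gcl / (p.ki_gsh_gcl + 8.0e6)
    ggc_syn = (83.4 * 120.0 + 1.64 * 3.0) * fb
    assert dy[IX["ggc"]] == pytest.approx(ggc_syn - gsh_syn, rel=1e-12)
    # drug metabolism scaled by CYP3A5 protein
    metab = 0.187 * 214.0 * 1.0e6 / (p.km_csa_metabolism + 1.0e6)
    assert dy[IX["csa_metabolized"]] == pytest.approx(metab, rel=1e-12)


def test_baseline_is_a_fixed_point(mode_nrf, mode_pk):
    """At the drug-free baseline every free-state derivative is < 1e-9 of
    the state scale."""
    y0 = baseline_state(mode_nrf, mode_pk)
    dy = nrf2_rhs(y0, mode_nrf, mode_pk)
    free = _free_indices()
    scale = np.maximum(np.abs(y0[free]), 1e-3)
    assert np.max(np.abs(dy[free]) / scale) < 1e-9


def test_control_equals_control(mode_nrf, mode_pk):
    """Zero dosing keeps the trajectory at baseline: all observed species
    stay within solver tolerance of their starting values."""
    sch = DosingSchedule(dose_uM=0.0, n_doses=3)
    tr = simulate_coupled(mode_nrf, mode_pk, G, sch)
    y0 = baseline_state(mode_nrf, mode_pk)
    free = _free_indices()
    rel = np.abs(tr.y[free] - y0[free, None]) / np.maximum(y0[free, None],
                                                           1e-12)
    assert rel.max() < 1e-4


def test_nonnegative_states_along_trajectory(coupled_traj_5):
    assert coupled_traj_5.y.min() >= 0.0


def test_keap1_and_maf_moiety_conservation(mode_nrf, mode_pk):
    """With Keap1 synthesis/degradation disabled, total Keap1 across free,
    oxidized and complexed forms is conserved; the Maf pool always is."""
    p = mode_nrf.replace(ksyn_keap1=0.0, kdeg_keap1=0.0)
    sch = DosingSchedule(dose_uM=5.0, n_doses=2)
    tr = simulate_coupled(p, mode_pk, G, sch,
                          initial_state=baseline_state(mode_nrf, mode_pk))
    keap1_total = (tr["keap1"] + tr["keap1_ox"] + tr["nrf2_keap1"]
                   + tr["nrf2_keap1_ox"])
    assert np.max(np.abs(keap1_total - keap1_total[0])) / keap1_total[0] < 1e-6
    are = sum(tr[f"are_{g}"] for g in
              ("nrf2", "cyp3a5", "gs", "gclc", "gclm", "gst", "gpx", "mrp2"))
    maf_total = tr["maf"] + tr["nrf2_maf"] + are
    assert np.max(np.abs(maf_total - maf_total[0])) / maf_total[0] < 1e-6


def test_ros_sink_audit(mode_nrf, mode_pk):
    """Cumulative ROS produced equals eliminated plus the net pool change."""
    sch = DosingSchedule(dose_uM=5.0, n_doses=3)
    times = np.linspace(0, 3 * DAY_S, 2000)
    tr = simulate_coupled(mode_nrf, mode_pk, G, sch, times)
    prod_rate = (mode_nrf.k_ros_basal
                 + mode_nrf.k_ros_csa * tr["csa_cytosol"])
    produced = np.trapezoid(prod_rate, tr.t)
    eliminated = tr["ros_cleared"][-1] - tr["ros_cleared"][0]
    d_ros = tr["ros"][-1] - tr["ros"][0]
    assert produced == pytest.approx(eliminated + d_ros, rel=1e-3)


def test_unstressed_limit_reduces_to_autonomous_baseline(mode_nrf, mode_pk):
    """With the drug-coupling terms switched off and no dose, the system is
    the autonomous stress-response network at its fixed point."""
    p = mode_nrf.replace(k_ros_csa=0.0)
    y0 = baseline_state(p, mode_pk)
    sch = DosingSchedule(dose_uM=0.0, n_doses=3)
    tr = simulate_coupled(p, mode_pk, G, sch)
    free = _free_indices()
    rel = np.abs(tr.y[free, -1] - y0[free]) / np.maximum(y0[free], 1e-12)
    assert rel.max() < 1e-5


def test_parameter_table_roundtrips_through_csv(tmp_path, mode_nrf, mode_pk):
    import pandas as pd
    from nrf2pk import parameter_table
    table = parameter_table(mode_nrf, mode_pk)
    assert set(table["kind"]) == {"calibrated", "fixed", "initial_state"}
    assert (table["kind"] == "calibrated").sum() == 27
    path = tmp_path / "params.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, table)


def test_coupled_transport_consistent_with_disposition_model(
        coupled_traj_5, pk_traj_5):
    """At baseline CYP3A5 levels the coupled model's drug kinetics match the
    standalone disposition model (whose lumped vmax it replaces)."""
    a = coupled_traj_5.at("csa_cytosol", np.array([5.0, 10.0]) * DAY_S)
    b = pk_traj_5.at("csa_cytosol", np.array([5.0, 10.0]) * DAY_S)
    np.testing.assert_allclose(a, b, rtol=0.05)
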