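"""Synthetic data generators: reproducibility, noise law, composition."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from nrf2pk import (DosingSchedule, ObservationDesign, SyntheticScenario,
                    generate_omics_dataset, generate_pk_dataset,
                    generate_viability_dataset, predict_fold_changes,
                    simulate_coupled, simulate_pk)
from nrf2pk.experiment import PK_COMPARTMENTS, sample_time_s
from nrf2pk.nrf2 import NRF_STATE_NAMES, baseline_state
from nrf2pk.trajectory import Trajectory
from nrf2pk.units import DAY_S, DEFAULT_GEOMETRY as G
from nrf2pk.viability import ViabilityParams, loglogistic_viability


def test_noise_free_limit_equals_model_truth(scenario, mode_pk):
    df = generate_pk_dataset(scenario.with_noise_free())
    sub = df[(df.dose_uM == 5.0) & (df.compartment == "medium")]
    t = np.sort(sample_time_s(sub["day"], sub["hour"]).astype(float))
    tr = simulate_pk(mode_pk, G, DosingSchedule(dose_uM=5.0),
                     times=np.unique(t))
    truth = tr.at("csa_extracellular", np.unique(t))
    got = sub.groupby(["day", "hour"])["quantity"].mean().to_numpy()
    np.testing.assert_allclose(np.sort(got), np.sort(truth), rtol=1e-6)


def test_same_seed_reproduces_identical_tables(scenario):
    a = generate_pk_dataset(scenario, seed=5)
    b = generate_pk_dataset(scenario, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = generate_pk_dataset(scenario, seed=6)
    assert not a["quantity"].equals(c["quantity"])


def test_empirical_gsd_matches_generating_gsd(scenario):
    """Residual geometric SD over many replicates converges to the
    generating value (law of large numbers, within 2%)."""
    design = ObservationDesign(doses_uM=(5.0,), replicates=3000,
                               pk_fine_days=(1,), pk_trough_days=())
    from dataclasses import replace
    sc = replace(scenario, design=design)
    df = generate_pk_dataset(sc, seed=12)
    noisefree = generate_pk_dataset(replace(sc.with_noise_free(),
                                            design=replace(design,
                                                           replicates=1)),
                                    seed=12)
    merged = df.merge(noisefree, on=["day", "hour", "dose_uM", "compartment"],
                      suffixes=("", "_truth"))
    for comp, gsd in (("medium", 1.2), ("cell", 1.3)):
        r = merged[merged.compartment == comp]
        resid = np.log(r["quantity"] / r["quantity_truth"])
        assert math.exp(resid.std()) == pytest.approx(gsd, rel=0.02)


def test_control_fold_changes_cluster_around_one(mode_nrf, mode_pk):
    sc = SyntheticScenario(design=ObservationDesign(doses_uM=(0.0,)),
                           seed=3)
    df = generate_omics_dataset(sc)
    gm = math.exp(np.mean(np.log(df["fold_change"])))
    assert gm == pytest.approx(1.0, rel=0.1)


def test_noise_free_omics_equals_predicted_fold_changes(scenario, mode_nrf,
                                                        mode_pk):
    """Composition identity: the generator reproduces the fold-change
    observable exactly when noise is switched off."""
    sc = scenario.with_noise_free()
    df = generate_omics_dataset(sc)
    y0 = baseline_state(mode_nrf, mode_pk)
    control = Trajectory(np.array([0.0, 14 * DAY_S]),
                         np.column_stack([y0, y0]), NRF_STATE_NAMES, None, G)
    tr = simulate_coupled(mode_nrf, mode_pk, G, DosingSchedule(dose_uM=5.0))
    fc = predict_fold_changes(tr, control)
    merged = df[df.dose_uM == 5.0].merge(fc, on=["species", "day"],
                                         suffixes=("", "_pred"))
    np.testing.assert_allclose(merged["fold_change"],
                               merged["fold_change_pred"], rtol=1e-6)


def test_omics_count_matches_design_combinatorics(scenario):
    df = generate_omics_dataset(scenario)
    d = scenario.design
    assert len(df) == (len(d.omics_species) * len(d.omics_days)
                       * len(d.doses_uM) * d.replicates)
    assert len(generate_omics_dataset(scenario, drop=7)) == len(df) - 7


def test_viability_truncation_flag(scenario):
    """With truncation on, every renal-line dose sits below its EC50."""
    df = generate_viability_dataset(scenario)
    truth = scenario.viability_truth["RPTEC"]
    assert df[df.cell_line == "RPTEC"]["dose_uM"].max() < truth.ec50
    from dataclasses import replace
    full = generate_viability_dataset(replace(scenario,
                                              truncate_rptec=False))
    assert full[full.cell_line == "RPTEC"]["dose_uM"].max() > truth.ec50


def test_full_curve_line_recovers_params_by_direct_fit(scenario):
    df = generate_viability_dataset(scenario, seed=9)
    sub = df[df.cell_line == "HepaRG"]

    def f(d, top, ec50, slope):
        return top / (1 + (d / ec50) ** slope)

    popt, _ = curve_fit(f, sub["dose_uM"], sub["viability"],
                        p0=[1.0, 10.0, 2.0],
                        bounds=([0.5, 0.5, 0.1], [1.2, 2000, 10]))
    truth = scenario.viability_truth["HepaRG"]
    assert popt[0] == pytest.approx(truth.top, rel=0.1)
    assert popt[1] == pytest.approx(truth.ec50, rel=0.2)
    assert popt[2] == pytest.approx(truth.slope, rel=0.3)


def test_gsd_below_one_rejected():
    with pytest.raises(ValueError):
        SyntheticScenario(gsd={"medium": 0.9, "cell": 1.3, "wall": 1.3,
                               "omics": 1.35})
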