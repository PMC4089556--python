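"""Synthetic data generation.

No public accession holds the study's raw measurements, so every pipeline
stage is exercised on synthetic data carrying the statistical structure the
analysis assumes: ODE-model truths observed at the study's sampling design
under multiplicative lognormal measurement noise (per-measurement-type
geometric SDs), fold-changes referenced to the first control observation
time, and log-logistic viability curves.  All generators are pure functions
of (scenario, seed).

Default generating values are the published posterior modes, so generated
tables resemble the study's data scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dosing import DosingSchedule
from .experiment import (OBSERVED_SPECIES, PK_COMPARTMENTS, ObservationDesign,
                         predict_fold_changes, sample_time_s)
from .nrf2 import NrfParameters, baseline_state, simulate_coupled
from .pk import PKParameters, simulate_pk
from .trajectory import Trajectory
from .units import DAY_S, DEFAULT_GEOMETRY, CultureGeometry
from .viability import CELL_LINES, ViabilityParams, loglogistic_viability

#: default measurement-error geometric SDs by measurement type
DEFAULT_GSD = {"medium": 1.2, "cell": 1.3, "wall": 1.3, "omics": 1.35}


@dataclass(frozen=True)
class SyntheticScenario:
    """Generating truth + observation design + noise specification."""

    pk_params: PKParameters = PKParameters()
    nrf_params: NrfParameters = NrfParameters()
    geometry: CultureGeometry = DEFAULT_GEOMETRY
    design: ObservationDesign = ObservationDesign()
    n_doses: int = 14
    gsd: dict = field(default_factory=lambda: dict(DEFAULT_GSD))
    viability_truth: dict = field(default_factory=lambda: {
        "RPTEC": ViabilityParams(top=1.0, ec50=38.5, slope=2.0),
        "3T3": ViabilityParams(top=1.0, ec50=6.0, slope=1.8),
        "HepaRG": ViabilityParams(top=1.0, ec50=12.0, slope=2.2),
    })
    viability_doses: tuple = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0,
                              50.0, 100.0)
    truncate_rptec: bool = True
    viability_sd: float = 0.05
    seed: int = 20140625

    def __post_init__(self) -> None:
        for k, g in self.gsd.items():
            if g <= 1.0:
                raise ValueError(f"geometric SD for {k!r} must exceed 1")

    def with_noise_free(self) -> "SyntheticScenario":
        eps = 1.0 + 1e-12
        return replace(self, gsd={k: eps for k in self.gsd}, viability_sd=0.0)


def _rng(scenario: SyntheticScenario, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(scenario.seed if seed is None else seed)


def _lognoise(rng, gsd: float, size) -> np.ndarray:
    return np.exp(math.log(gsd) * rng.standard_normal(size))


def generate_pk_dataset(scenario: SyntheticScenario,
                        seed: int | None = None) -> pd.DataFrame:
    """Drug-quantity measurement table under the study's sampling design.

    Truth comes from the disposition model at the scenario parameters;
    observations are truth times lognormal noise with the compartment's
    geometric SD.  Quantities are zmol per cell.
    """
    rng = _rng(scenario, seed)
    d = scenario.design
    samples = d.pk_sample_times()
    rows = []
    for dose in d.doses_uM:
        sch = DosingSchedule(dose_uM=float(dose), n_doses=scenario.n_doses)
        times = np.sort(np.unique(sample_time_s(samples["day"], samples["hour"])))
        tr = simulate_pk(scenario.pk_params, scenario.geometry, sch, times)
        for _, s in samples.iterrows():
            t = float(sample_time_s(s["day"], s["hour"]))
            truth = float(tr.at(PK_COMPARTMENTS[s["compartment"]], [t])[0])
            noise = _lognoise(rng, scenario.gsd[s["compartment"]],
                              d.replicates)
            for rep in range(d.replicates):
                rows.append((int(s["day"]), float(s["hour"]), float(dose),
                             s["compartment"], rep + 1,
                             truth * noise[rep], "zmol"))
    return pd.DataFrame(rows, columns=["day", "hour", "dose_uM",
                                       "compartment", "replicate",
                                       "quantity", "unit"])


def generate_omics_dataset(scenario: SyntheticScenario,
                           seed: int | None = None,
                           drop: int = 0) -> pd.DataFrame:
    """Fold-change table at the omics design (days 1/3/14, two doses).

    Truths are coupled-model fold-changes referenced to the first control
    observation time; noise is multiplicative lognormal with the shared
    omics geometric SD.  ``drop`` removes that many trailing values to
    mimic incomplete designs (the study reports 227 of the nominal 234).
    """
    rng = _rng(scenario, seed)
    d = scenario.design
    y0 = baseline_state(scenario.nrf_params, scenario.pk_params,
                        scenario.geometry)
    # control trajectory: the unexposed system stays at its baseline state
    from .nrf2 import NRF_STATE_NAMES
    t_ctrl = np.array([0.0, scenario.n_doses * DAY_S])
    control = Trajectory(t_ctrl, np.column_stack([y0, y0]), NRF_STATE_NAMES,
                         None, scenario.geometry)
    rows = []
    for dose in d.doses_uM:
        sch = DosingSchedule(dose_uM=float(dose), n_doses=scenario.n_doses)
        tr = simulate_coupled(scenario.nrf_params, scenario.pk_params,
                              scenario.geometry, sch)
        fc = predict_fold_changes(tr, control, d)
        for _, s in fc.iterrows():
            noise = _lognoise(rng, scenario.gsd["omics"], d.replicates)
            for rep in range(d.replicates):
                rows.append((s["species"], float(dose), float(s["day"]),
                             rep + 1, float(s["fold_change"]) * noise[rep]))
    df = pd.DataFrame(rows, columns=["species", "dose_uM", "day",
                                     "replicate", "fold_change"])
    if drop:
        df = df.iloc[:len(df) - drop].reset_index(drop=True)
    return df


def generate_viability_dataset(scenario: SyntheticScenario,
                               seed: int | None = None,
                               replicates: int = 3) -> pd.DataFrame:
    """Cell-viability dose-response table for the EC50 meta-analysis.

    With ``truncate_rptec`` the renal line is only observed at doses below
    its generating EC50, mimicking the identifiability limitation that the
    hierarchical fit is designed to overcome.  Noise is additive normal on
    the viability fraction, truncated at zero.
    """
    rng = _rng(scenario, seed)
    rows = []
    for line, truth in scenario.viability_truth.items():
        doses = np.asarray(scenario.viability_doses, dtype=float)
        if line == "RPTEC" and scenario.truncate_rptec:
            doses = doses[doses < truth.ec50]
        for dose in doses:
            mu = float(loglogistic_viability(dose, truth))
            for rep in range(replicates):
                v = mu + scenario.viability_sd * rng.standard_normal()
                rows.append((line, float(dose), max(v, 0.0), rep + 1))
    return pd.DataFrame(rows, columns=["cell_line", "dose_uM", "viability",
                                       "replicate"])
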