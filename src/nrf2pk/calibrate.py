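"""Model-specific Bayesian calibrations.

Two-step protocol: (1) the disposition model is calibrated against drug
quantities measured in medium, cells and on the vial wall (8 kinetic + 3
measurement-error parameters); (2) the coupled pathway model is calibrated
against omics fold-changes with the disposition parameters frozen at their
joint posterior mode (27 structural + 1 shared error parameter).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .bayes import (LikelihoodSpec, PosteriorSamples, PriorSpec,
                    log_likelihood, log_prior, metropolis_sample)
from .dosing import DosingSchedule
from .experiment import (OBSERVED_SPECIES, PK_COMPARTMENTS,
                         ObservationDesign, predict_fold_changes,
                         sample_time_s)
from .nrf2 import NRF_STATE_NAMES, NrfParameters, baseline_state, \
    simulate_coupled
from .pk import PKParameters, simulate_pk_fast
from .tables import (NRF2_POSTERIOR_MODE, NRF2_PRIORS, PK_ERROR_TYPES,
                     PK_POSTERIOR_MODE, PK_PRIORS, error_sigma_prior)
from .trajectory import Trajectory
from .units import DAY_S, DEFAULT_GEOMETRY, CultureGeometry

_COMP_ROW = {"medium": 1, "cell": 0, "wall": 2}


def pk_priors_with_errors() -> dict[str, PriorSpec]:
    priors = dict(PK_PRIORS)
    for t in PK_ERROR_TYPES:
        priors[f"sigma_{t}"] = error_sigma_prior(f"sigma_{t}")
    return priors


def make_pk_log_posterior(pk_data: pd.DataFrame,
                          geometry: CultureGeometry = DEFAULT_GEOMETRY,
                          n_doses: int = 14, dt: float = 120.0):
    """Closure evaluating the disposition-model log-posterior.

    Predictions use the fixed-step fast integrator (the system is
    non-stiff); the likelihood is lognormal with one geometric SD per
    measurement type (medium / cell / wall).
    """
    priors = pk_priors_with_errors()
    groups = []
    for dose, g in pk_data.groupby("dose_uM"):
        t = sample_time_s(g["day"], g["hour"])
        order = np.argsort(t, kind="stable")
        g = g.iloc[order]
        t = np.asarray(t)[order]
        rows = np.array([_COMP_ROW[c] for c in g["compartment"]])
        groups.append((float(dose), t, rows, g["quantity"].to_numpy(),
                       list(g["compartment"])))

    def log_post(theta: dict) -> float:
        lp = log_prior(theta, priors)
        if not math.isfinite(lp):
            return -math.inf
        try:
            params = PKParameters(**{k: theta[k] for k in PK_POSTERIOR_MODE})
        except ValueError:
            return -math.inf
        lik = LikelihoodSpec({t: theta[f"sigma_{t}"] for t in PK_ERROR_TYPES})
        for dose, t, rows, obs, comps in groups:
            sch = DosingSchedule(dose_uM=dose, n_doses=n_doses)
            Y = simulate_pk_fast(params, geometry, sch, t, dt=dt)
            pred = Y[rows, np.arange(len(rows))]
            if np.any(pred <= 0):
                return -math.inf
            lp += log_likelihood(obs, pred, comps, lik)
        return lp

    return log_post, priors


def calibrate_pk(pk_data: pd.DataFrame,
                 geometry: CultureGeometry = DEFAULT_GEOMETRY,
                 n_chains: int = 5, n_iter: int = 20_000, thin: int = 10,
                 seed: int = 0, update: str = "vector",
                 **kw) -> PosteriorSamples:
    """Reduced-protocol MCMC calibration of the disposition model.

    The full study protocol (5 chains x 200,000 iterations, thin 100,
    first half discarded) is available by passing ``n_iter=200_000,
    thin=100``.
    """
    log_post, priors = make_pk_log_posterior(pk_data, geometry)
    return metropolis_sample(log_post, priors, n_chains=n_chains,
                             n_iter=n_iter, thin=thin, seed=seed,
                             update=update, **kw)


def pk_mode_parameters(samples: PosteriorSamples) -> PKParameters:
    """Disposition parameters at the joint posterior mode of a sample."""
    mode = samples.mode()
    return PKParameters(**{k: mode[k] for k in PK_POSTERIOR_MODE})


# ---------------------------------------------------------------------------
# coupled-model calibration (omics fold-changes)
# ---------------------------------------------------------------------------

def nrf2_priors_with_errors() -> dict[str, PriorSpec]:
    priors = dict(NRF2_PRIORS)
    priors["sigma_omics"] = error_sigma_prior("sigma_omics")
    return priors


def make_nrf2_log_posterior(omics_data: pd.DataFrame,
                            pk_mode: PKParameters,
                            base_params: NrfParameters = NrfParameters(),
                            geometry: CultureGeometry = DEFAULT_GEOMETRY,
                            design: ObservationDesign = ObservationDesign(),
                            n_doses: int = 14,
                            calibrated: tuple[str, ...] | None = None):
    """Closure evaluating the coupled-model log-posterior.

    ``calibrated`` restricts which structural parameters are sampled (all
    27 by default); the rest stay at ``base_params``.  Disposition
    parameters are frozen at ``pk_mode`` per the two-step protocol.
    """
    calibrated = calibrated or NrfParameters.CALIBRATED
    priors = {k: NRF2_PRIORS[k] for k in calibrated}
    priors["sigma_omics"] = error_sigma_prior("sigma_omics")
    doses = sorted(omics_data["dose_uM"].unique())
    obs_by_dose = {d: omics_data[omics_data.dose_uM == d] for d in doses}
    out_times = np.unique(np.concatenate([
        [0.0], np.asarray(design.omics_days, dtype=float) * DAY_S]))

    def log_post(theta: dict) -> float:
        lp = log_prior(theta, priors)
        if not math.isfinite(lp):
            return -math.inf
        try:
            params = base_params.replace(
                **{k: theta[k] for k in calibrated})
        except ValueError:
            return -math.inf
        lik = LikelihoodSpec({"omics": theta["sigma_omics"]})
        try:
            y0 = baseline_state(params, pk_mode, geometry)
        except RuntimeError:
            return -math.inf
        control = Trajectory(np.array([0.0, n_doses * DAY_S]),
                             np.column_stack([y0, y0]), NRF_STATE_NAMES,
                             None, geometry)
        for dose in doses:
            sch = DosingSchedule(dose_uM=float(dose), n_doses=n_doses)
            try:
                tr = simulate_coupled(params, pk_mode, geometry, sch,
                                      out_times, rtol=1e-6, atol=1e-8)
            except RuntimeError:
                return -math.inf
            fc = predict_fold_changes(tr, control, design)
            merged = obs_by_dose[dose].merge(fc, on=["species", "day"],
                                             suffixes=("", "_pred"))
            pred = merged["fold_change_pred"].to_numpy()
            if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
                return -math.inf
            lp += log_likelihood(merged["fold_change"].to_numpy(), pred,
                                 ["omics"] * len(merged), lik)
        return lp

    return log_post, priors


def calibrate_nrf2(omics_data: pd.DataFrame, pk_mode: PKParameters,
                   n_chains: int = 5, n_iter: int = 20_000, thin: int = 10,
                   seed: int = 0, **kw) -> PosteriorSamples:
    """MCMC calibration of the coupled model (PK frozen at its mode)."""
    log_post, priors = make_nrf2_log_posterior(omics_data, pk_mode,
                                               **{k: kw.pop(k) for k in
                                                  ("base_params", "geometry",
                                                   "design", "n_doses",
                                                   "calibrated")
                                                  if k in kw})
    return metropolis_sample(log_post, priors, n_chains=n_chains,
                             n_iter=n_iter, thin=thin, seed=seed, **kw)


def nrf2_mode_parameters(samples: PosteriorSamples,
                         base: NrfParameters = NrfParameters()) -> NrfParameters:
    mode = samples.mode()
    return base.replace(**{k: v for k, v in mode.items()
                           if k in NrfParameters.CALIBRATED})


def prediction_discrepancy(observed: pd.DataFrame,
                           predicted: pd.DataFrame,
                           keys=("species", "dose_uM", "day")) -> float:
    """Mean absolute relative difference |pred - obs| / obs between an
    observation table and a prediction table sharing key columns."""
    merged = observed.merge(predicted, on=list(keys), suffixes=("", "_pred"))
    if merged.empty:
        raise ValueError("no overlapping observations and predictions")
    return float(np.mean(np.abs(merged["fold_change_pred"]
                                - merged["fold_change"])
                         / merged["fold_change"]))
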