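"""Published parameter values and prior specifications.

Two calibrations are supported:

* the disposition (PK) model — 8 kinetic constants with vague priors, plus
  one measurement-error geometric SD per measurement type (medium, cell
  lysate, plastic wall);
* the coupled pathway model — 27 structural parameters with priors either
  vague log-uniform/uniform or lognormal centred on the literature values of
  the parent stress-response model with a geometric SD of 3, plus a single
  shared omics measurement-error geometric SD.

Posterior modes below are the published point estimates used for all
deterministic predictions.
"""

from __future__ import annotations

import math

from .bayes import PriorSpec

# --- disposition model ------------------------------------------------------

#: joint posterior mode of the disposition-model calibration
PK_POSTERIOR_MODE: dict[str, float] = {
    "CLin1": 99.6,
    "Kmout1": 2965.0,
    "CLout1_over_Kmout1": 0.581,
    "k1": 3.55e-5,
    "k3": 0.921,
    "k2": 6.01e-4,
    "vmax": 40.0,
    "Km2": 2.18e6,
}

#: vague priors of the disposition-model calibration
PK_PRIORS: dict[str, PriorSpec] = {
    "CLin1": PriorSpec("CLin1", "loguniform", lower=1e-1, upper=1e4),
    "Kmout1": PriorSpec("Kmout1", "loguniform", lower=100.0, upper=5e4),
    "CLout1_over_Kmout1": PriorSpec("CLout1_over_Kmout1", "loguniform",
                                    lower=1e-2, upper=20.0),
    "k1": PriorSpec("k1", "loguniform", lower=1e-6, upper=5e-4),
    "k3": PriorSpec("k3", "uniform", lower=0.0, upper=0.95),
    "k2": PriorSpec("k2", "loguniform", lower=1e-4, upper=0.5),
    "vmax": PriorSpec("vmax", "loguniform", lower=0.1, upper=5000.0),
    "Km2": PriorSpec("Km2", "loguniform", lower=5e5, upper=5e7),
}

# Measurement-error log-scale SDs (sigma = ln GSD).  The vague prior spans
# coefficients of variation from 1% up to a factor of 2.
_SIGMA_LO = math.sqrt(math.log(1.0 + 0.01 ** 2))   # CV 1%
_SIGMA_HI = math.log(2.0)                          # factor 2


def error_sigma_prior(name: str) -> PriorSpec:
    """Log-uniform prior on a lognormal measurement-error log-SD."""
    return PriorSpec(name, "loguniform", lower=_SIGMA_LO, upper=_SIGMA_HI)


#: measurement types of the PK data, each with its own error GSD
PK_ERROR_TYPES = ("medium", "cell", "wall")

# --- coupled pathway model --------------------------------------------------

# name -> (posterior mode, prior)
_LN = lambda n, med: PriorSpec(n, "lognormal", median=med, gsd=3.0)

NRF2_POSTERIOR_MODE: dict[str, float] = {
    "vmax_csa_metabolism": 0.187,
    "k_ros_basal": 79.1,
    "vmax_ros_clearance": 2.67,
    "k_keap1_oxidation": 3.02e-6,
    "k_ros_csa": 6.55e-5,
    "kb_nrf2_maf": 0.0124,
    "ktsp_cyp3a5": 1.29,
    "ktsp_nrf2": 0.087,
    "ktsp_gs": 1.07,
    "ktsp_gclc": 1.28,
    "ktsp_gclm": 3.95,
    "ktsp_gst": 0.021,
    "ktsp_gpx": 0.098,
    "ktsp_mrp2": 1.22,
    "kb_gcl_assembly": 4.33e-6,
    "kind_nrf2": 150.0,
    "kind_gs": 2.17,
    "kind_gclc": 22.1,
    "kind_gclm": 3.28,
    "kind_gst": 8.46,
    "kind_gpx": 1.37,
    "kind_mrp2": 6.43,
    "vmax_ggc_gcl": 83.4,
    "vmax_ggc_gclc": 1.64,
    "vmax_gsh_synthesis": 8.57,
    "vmax_gsh_degradation": 283.0,
    "km_gsh_degradation": 1.62e8,
}

NRF2_PRIORS: dict[str, PriorSpec] = {
    "vmax_csa_metabolism": _LN("vmax_csa_metabolism", 0.2),
    "k_ros_basal": _LN("k_ros_basal", 12.0),
    "vmax_ros_clearance": _LN("vmax_ros_clearance", 8.0),
    "k_keap1_oxidation": PriorSpec("k_keap1_oxidation", "uniform",
                                   lower=1e-8, upper=1e-2),
    "k_ros_csa": PriorSpec("k_ros_csa", "uniform", lower=1e-8, upper=1e-2),
    "kb_nrf2_maf": _LN("kb_nrf2_maf", 0.003),
    "ktsp_cyp3a5": _LN("ktsp_cyp3a5", 1.07),
    "ktsp_nrf2": _LN("ktsp_nrf2", 0.00611),
    "ktsp_gs": _LN("ktsp_gs", 1.15),
    "ktsp_gclc": _LN("ktsp_gclc", 1.98),
    "ktsp_gclm": _LN("ktsp_gclm", 3.22),
    "ktsp_gst": _LN("ktsp_gst", 0.242),
    # GPx priors are structurally cloned from GST (no literature value exists
    # for GPx in the parent model)
    "ktsp_gpx": _LN("ktsp_gpx", 0.242),
    "ktsp_mrp2": _LN("ktsp_mrp2", 0.9),
    "kb_gcl_assembly": _LN("kb_gcl_assembly", 2e-5),
    "kind_nrf2": _LN("kind_nrf2", 100.0),
    "kind_gs": _LN("kind_gs", 5.95),
    "kind_gclc": _LN("kind_gclc", 8.7),
    "kind_gclm": _LN("kind_gclm", 1.6),
    "kind_gst": _LN("kind_gst", 11.9),
    "kind_gpx": _LN("kind_gpx", 11.9),
    "kind_mrp2": _LN("kind_mrp2", 16.0),
    "vmax_ggc_gcl": _LN("vmax_ggc_gcl", 8.2),
    "vmax_ggc_gclc": _LN("vmax_ggc_gclc", 1.9),
    "vmax_gsh_synthesis": _LN("vmax_gsh_synthesis", 6.5),
    "vmax_gsh_degradation": _LN("vmax_gsh_degradation", 1845.0),
    "km_gsh_degradation": _LN("km_gsh_degradation", 2e7),
}

#: single shared omics measurement-error type
OMICS_ERROR_TYPES = ("omics",)
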