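"""Monte Carlo sensitivity screen: which kinetic constants matter?

Draws disposition-model parameters from their priors, maps each draw to
scalar output summaries (mean accumulation ratio, fraction metabolized)
and ranks parameters by |Spearman correlation| -- the screen used to decide
which structural parameters deserve calibration.
"""

import numpy as np

from nrf2pk import DosingSchedule, PKParameters, concentration_ratio, \
    mc_sensitivity
from nrf2pk.pk import fraction_metabolized, simulate_pk_fast
from nrf2pk.tables import PK_PRIORS
from nrf2pk.units import DAY_S, DEFAULT_GEOMETRY as G


def summaries(theta: dict) -> dict:
    try:
        p = PKParameters(**theta)
    except ValueError:
        return {"mean_ratio": 0.0, "frac_metabolized": 0.0}
    sch = DosingSchedule(dose_uM=5.0, n_doses=7)
    t = np.linspace(0.25 * DAY_S, 7 * DAY_S, 28)
    Y = simulate_pk_fast(p, G, sch, t, dt=300.0)
    ratio = np.mean((Y[0] / G.V_cytosol)
                    / np.maximum(Y[1] / G.V_extracellular, 1e-300))
    frac = Y[3, -1] / sch.total_dosed_quantity(G.V_extracellular)
    return {"mean_ratio": float(ratio), "frac_metabolized": float(frac)}


table = mc_sensitivity(summaries, PK_PRIORS, n_samples=300, seed=0)
print(table.round(3).to_string())
print("""
High-ranking parameters (uptake and efflux clearances) dominate the
accumulation ratio; vmax/Km2 drive the metabolized fraction.  Parameters
with near-zero indices could be fixed without hurting the fit.""")
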