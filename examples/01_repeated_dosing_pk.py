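"""Repeated-dosing disposition of cyclosporine A in a renal cell culture.

Simulates the 3-compartment model (cytosol / medium / vial wall) at its
posterior-mode parameters for 14 daily doses with medium renewal, and
prints the headline kinetics: how strongly the lipophilic drug accumulates
in cells (intracellular/extracellular concentration ratio), how long the
daily cycle takes to repeat itself (dynamic steady state), and what part
of the administered dose is metabolized.
"""

from nrf2pk import (DosingSchedule, PKParameters, concentration_ratio,
                    simulate_pk, steady_state_time)
from nrf2pk.pk import fraction_metabolized
from nrf2pk.units import DAY_S, DEFAULT_GEOMETRY

params = PKParameters()   # posterior-mode kinetic constants
for dose in (5.0, 15.0):
    schedule = DosingSchedule(dose_uM=dose, n_doses=14)
    traj = simulate_pk(params, DEFAULT_GEOMETRY, schedule)
    print(f"\n{dose:g} uM daily dosing, 14 days")
    print(f"  mean conc. ratio (cell/medium): "
          f"{concentration_ratio(traj):7.1f}")
    print(f"  day-14 conc. ratio:             "
          f"{concentration_ratio(traj, window=(13 * DAY_S, 14 * DAY_S)):7.1f}")
    print(f"  steady state reached (days):    "
          f"{steady_state_time(traj, 'csa_cytosol'):7.1f}")
    print(f"  fraction of dose metabolized:   "
          f"{fraction_metabolized(traj):7.3f}")

print("""
A ratio of ~200 means the cell concentrates the drug two-hundred-fold over
the medium; at the high dose the efflux transporter saturates, so the ratio
climbs further (~650 by day 14) and steady state takes twice as long.""")
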