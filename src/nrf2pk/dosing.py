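"""Repeated-dosing protocol with medium renewal.

The in vitro protocol doses the culture daily for 14 days; the assay medium
is renewed immediately before each dose.  Renewal discards whatever drug is
left in the medium (recorded in an audit trail so mass balances can still be
closed) and replaces it with fresh medium at the nominal dose concentration.
Cell-associated and wall-bound drug persist through renewals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import DAY_S


@dataclass(frozen=True)
class DosingSchedule:
    """Daily bolus dosing with medium renewal.

    Attributes
    ----------
    dose_uM:
        Nominal concentration of each fresh medium change, umol/L.
    n_doses:
        Number of daily doses (14 in the study protocol).
    period_s:
        Time between doses in seconds (24 h).
    renewal:
        If True the extracellular pool is *replaced* at each dose (old
        medium discarded); if False the dose is added on top.
    start_s:
        Time of the first dose.
    """

    dose_uM: float = 5.0
    n_doses: int = 14
    period_s: float = DAY_S
    renewal: bool = True
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("dosing period must be positive")
        if self.dose_uM < 0:
            raise ValueError("dose must be non-negative")
        if self.n_doses < 1:
            raise ValueError("need at least one dose")

    @property
    def dose_times(self) -> np.ndarray:
        """Times (s) at which a dose / medium renewal occurs."""
        return self.start_s + self.period_s * np.arange(self.n_doses)

    @property
    def end_s(self) -> float:
        """End of the last dosing interval."""
        return self.start_s + self.period_s * self.n_doses

    def total_dosed_quantity(self, V_extracellular: float) -> float:
        """Total quantity of drug administered over the protocol, zmol per cell."""
        return self.dose_uM * V_extracellular * self.n_doses


@dataclass
class RenewalAudit:
    """Record of drug removed from the balance at each medium renewal."""

    times_s: list = field(default_factory=list)
    discarded_zmol: list = field(default_factory=list)

    def record(self, t: float, discarded: float) -> None:
        self.times_s.append(t)
        self.discarded_zmol.append(discarded)

    @property
    def total_discarded(self) -> float:
        return float(np.sum(self.discarded_zmol)) if self.discarded_zmol else 0.0
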