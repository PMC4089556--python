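"""Named trajectory container shared by the PK and coupled pathway models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dosing import DosingSchedule, RenewalAudit
from .units import CultureGeometry


@dataclass
class Trajectory:
    """A simulated time course of named state components.

    ``y`` has shape (n_states, n_times); components are addressed by name
    through ``__getitem__``.  Quantities are zmol, time is seconds.
    """

    t: np.ndarray
    y: np.ndarray
    names: Sequence[str]
    schedule: Optional[DosingSchedule] = None
    geometry: Optional[CultureGeometry] = None
    audit: Optional[RenewalAudit] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.names), self.t.size):
            raise ValueError(
                f"shape mismatch: y {self.y.shape} vs ({len(self.names)}, {self.t.size})"
            )
        self._index = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[self._index[name]]

    @property
    def t_days(self) -> np.ndarray:
        return self.t / 86_400.0

    def at(self, name: str, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of one component at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.t, self[name])

    def window(self, t0_s: float, t1_s: float) -> "Trajectory":
        """Sub-trajectory restricted to ``t0_s <= t <= t1_s``."""
        m = (self.t >= t0_s) & (self.t <= t1_s)
        return Trajectory(self.t[m], self.y[:, m], self.names,
                          self.schedule, self.geometry, self.audit, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: {time_s, species, quantity_zmol[, dose_uM]}."""
        frames = []
        dose = self.schedule.dose_uM if self.schedule is not None else np.nan
        for name in self.names:
            frames.append(pd.DataFrame({
                "time_s": self.t,
                "species": name,
                "quantity_zmol": self[name],
                "dose_uM": dose,
            }))
        return pd.concat(frames, ignore_index=True)
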