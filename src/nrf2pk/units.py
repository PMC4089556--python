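"""Unit system and culture geometry.

Internal quantities are zeptomoles (zmol, 1e-21 mol), volumes are cubic
micrometres and time is in seconds.  With those choices 1 umol/L equals
exactly 1 zmol/um^3, so micromolar dose concentrations convert to per-cell
quantities by a single multiplication with the per-cell medium volume.
All unit conversion happens at the I/O boundary; the ODE right-hand sides
never convert.
"""

from __future__ import annotations

from dataclasses import dataclass

#: seconds per day (the dosing period of the repeated-exposure protocol)
DAY_S = 86_400.0

#: 1 mL expressed in um^3
ML_TO_UM3 = 1.0e12

#: 1 umol/L expressed in zmol/um^3 (exact in this unit system)
UM_TO_ZMOL_PER_UM3 = 1.0


def concentration_to_quantity(conc_uM: float, volume_um3: float) -> float:
    """Convert a concentration in umol/L to a quantity in zmol for a volume in um^3."""
    return conc_uM * UM_TO_ZMOL_PER_UM3 * volume_um3


@dataclass(frozen=True)
class CultureGeometry:
    """Per-cell bookkeeping geometry of the culture well.

    The model tracks one representative cell together with its share of the
    assay medium and vial wall.  Defaults follow the study system: renal
    proximal tubule epithelial cells of 2000 um^3 (electron microscopy /
    stereology), 2.1 million cells per well, cultured in 3 mL of serum-free
    medium.

    Attributes
    ----------
    V_cytosol:
        Cell volume in um^3.
    n_cells:
        Cells per assay well.
    V_medium_total_mL:
        Medium volume per well in mL.
    """

    V_cytosol: float = 2000.0
    n_cells: float = 2.1e6
    V_medium_total_mL: float = 3.0

    def __post_init__(self) -> None:
        if self.V_cytosol <= 0 or self.n_cells <= 0 or self.V_medium_total_mL <= 0:
            raise ValueError("geometry values must be strictly positive")

    @property
    def V_extracellular(self) -> float:
        """Medium volume per cell in um^3 (~1.43e6 um^3 for the defaults)."""
        return self.V_medium_total_mL * ML_TO_UM3 / self.n_cells


DEFAULT_GEOMETRY = CultureGeometry()
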