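"""Observation design, fold-change observables and measurement I/O.

The omics data enter the analysis as dimensionless fold-changes: every
species value is divided by the value measured at the first observation
time of the *control* (unexposed) experiment.  Model-predicted fold-changes
are computed the same way, from a treated and a control trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory
from .units import DAY_S

#: observed omics species -> model state component
OBSERVED_SPECIES: dict[str, str] = {
    "Nrf2 mRNA": "mrna_nrf2",
    "CYP3A5 mRNA": "mrna_cyp3a5",
    "GS mRNA": "mrna_gs",
    "GCLC mRNA": "mrna_gclc",
    "GCLM mRNA": "mrna_gclm",
    "GST mRNA": "mrna_gst",
    "GPx mRNA": "mrna_gpx",
    "ABCC2 mRNA": "mrna_mrp2",
    "GCLM protein": "prot_gclm",
    "GS protein": "prot_gs",
    "MRP2 protein": "prot_mrp2",
    "gamma-GC": "ggc",
    "GSH": "gsh",
}

PK_COMPARTMENTS: dict[str, str] = {
    "medium": "csa_extracellular",
    "cell": "csa_cytosol",
    "wall": "csa_wall",
}

PK_SCHEMA = ("day", "hour", "dose_uM", "compartment", "replicate",
             "quantity", "unit")
OMICS_SCHEMA = ("species", "dose_uM", "day", "replicate", "fold_change")


@dataclass(frozen=True)
class ObservationDesign:
    """Sampling design of the 14-day repeated-dosing study.

    Omics samples are taken at the end of days 1, 3 and 14; drug quantities
    are measured in the medium on days 1/3/5/7/10/14 (with a fine intra-day
    grid on days 1 and 14) and in cells / on the wall on days 1 and 14.
    """

    doses_uM: tuple = (5.0, 15.0)
    replicates: int = 3
    omics_days: tuple = (1.0, 3.0, 14.0)
    omics_species: tuple = tuple(OBSERVED_SPECIES)
    pk_fine_days: tuple = (1, 14)
    pk_fine_hours: tuple = (0.5, 1.0, 3.0, 6.0, 24.0)
    pk_trough_days: tuple = (3, 5, 7, 10)

    def pk_sample_times(self) -> pd.DataFrame:
        """Long table of PK sampling points: {day, hour, compartment}."""
        rows = []
        for day in self.pk_fine_days:
            for hour in self.pk_fine_hours:
                for comp in PK_COMPARTMENTS:
                    rows.append((day, hour, comp))
        for day in self.pk_trough_days:
            rows.append((day, 24.0, "medium"))
        return pd.DataFrame(rows, columns=["day", "hour", "compartment"])

    @property
    def reference_day(self) -> float:
        """First observation time of the control experiment (days)."""
        return self.omics_days[0]


def sample_time_s(day, hour) -> np.ndarray:
    """Absolute sampling time: 'day d at h hours' is (d-1)*24h + h."""
    return ((np.asarray(day, dtype=float) - 1.0) * 24.0
            + np.asarray(hour, dtype=float)) * 3600.0


def predict_fold_changes(trajectory: Trajectory,
                         control_trajectory: Trajectory,
                         design: ObservationDesign = ObservationDesign(),
                         times_days: np.ndarray | None = None) -> pd.DataFrame:
    """Model fold-changes for each observed species.

    value(species, t) = treated(species, t) / control(species, t_ref) with
    t_ref the first omics observation time of the control run.  The result
    is invariant under rescaling of a species' absolute units.
    """
    days = np.asarray(design.omics_days if times_days is None else times_days,
                      dtype=float)
    t_ref = design.reference_day * DAY_S
    dose = trajectory.schedule.dose_uM if trajectory.schedule else np.nan
    rows = []
    for label, comp in OBSERVED_SPECIES.items():
        if label not in design.omics_species:
            continue
        ref = float(control_trajectory.at(comp, [t_ref])[0])
        if ref <= 0:
            raise ValueError(f"zero control reference quantity for {label!r}")
        vals = trajectory.at(comp, days * DAY_S) / ref
        for d, v in zip(days, vals):
            rows.append((label, dose, float(d), float(v)))
    return pd.DataFrame(rows, columns=["species", "dose_uM", "day",
                                       "fold_change"])


# ---------------------------------------------------------------------------
# measurement file I/O with validation
# ---------------------------------------------------------------------------

class ValidationError(ValueError):
    """Raised with an itemized list of schema violations."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid observation table:\n  - "
                         + "\n  - ".join(self.problems))


def _check_schema(df: pd.DataFrame, schema, path) -> list[str]:
    missing = [c for c in schema if c not in df.columns]
    return [f"{path}: missing column {c!r}" for c in missing]


def load_pk_measurements(path) -> pd.DataFrame:
    """Load and validate a drug-quantity measurement table."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty measurement file")
        return pd.DataFrame(columns=PK_SCHEMA)
    problems = _check_schema(df, PK_SCHEMA, path)
    if problems:
        raise ValidationError(problems)
    bad = ~df["compartment"].isin(PK_COMPARTMENTS)
    if bad.any():
        problems.append(f"{path}: unknown compartments "
                        f"{sorted(df.loc[bad, 'compartment'].unique())}")
    if (df["quantity"] <= 0).any():
        n = int((df["quantity"] <= 0).sum())
        problems.append(f"{path}: {n} non-positive quantities")
    keys = ["day", "hour", "dose_uM", "compartment", "replicate"]
    if df.duplicated(keys).any():
        problems.append(f"{path}: duplicated measurement keys")
    if problems:
        raise ValidationError(problems)
    return df


def load_fold_changes(path) -> pd.DataFrame:
    """Load and validate an omics fold-change table."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty fold-change file")
        return pd.DataFrame(columns=OMICS_SCHEMA)
    problems = _check_schema(df, OMICS_SCHEMA, path)
    if problems:
        raise ValidationError(problems)
    if (df["fold_change"] <= 0).any():
        n = int((df["fold_change"] <= 0).sum())
        problems.append(f"{path}: {n} non-positive fold-changes")
    unknown = set(df["species"]) - set(OBSERVED_SPECIES)
    if unknown:
        problems.append(f"{path}: unknown species {sorted(unknown)}")
    keys = ["species", "dose_uM", "day", "replicate"]
    if df.duplicated(keys).any():
        problems.append(f"{path}: duplicated observation keys")
    if problems:
        raise ValidationError(problems)
    return df


def load_observations(pk_files=(), omics_files=()) -> tuple[pd.DataFrame,
                                                            pd.DataFrame]:
    """Load PK and omics observation sets; reports the total omics count."""
    pk = (pd.concat([load_pk_measurements(f) for f in pk_files],
                    ignore_index=True)
          if pk_files else pd.DataFrame(columns=PK_SCHEMA))
    om = (pd.concat([load_fold_changes(f) for f in omics_files],
                    ignore_index=True)
          if omics_files else pd.DataFrame(columns=OMICS_SCHEMA))
    om.attrs["n_values"] = len(om)
    return pk, om


def write_pk_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(PK_SCHEMA))


def write_fold_changes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(OMICS_SCHEMA))
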