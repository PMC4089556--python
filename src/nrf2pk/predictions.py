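"""Post-calibration analytics.

Steady-state timing of the daily dosing cycle, intracellular/extracellular
concentration ratios, dose-time response surfaces and classification of
trajectory tails into oscillating / plateau / unbounded-growth regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dosing import DosingSchedule
from .nrf2 import NrfParameters, simulate_coupled
from .pk import PKParameters
from .trajectory import Trajectory
from .units import DAY_S, DEFAULT_GEOMETRY, CultureGeometry

REGIMES = ("oscillating", "plateau", "unbounded-growth")


@dataclass(frozen=True)
class RegimeReport:
    """Classification of one species' long-run behaviour at one dose."""

    species: str
    dose_uM: float
    regime: str
    period_days: Optional[float] = None
    amplitude: float = 0.0          # peak prominence relative to signal level
    steady_state_day: Optional[float] = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "oscillating" and not (self.period_days or 0) > 0:
            raise ValueError("oscillating regime requires a positive period")


def steady_state_time(trajectory: Trajectory, component: str,
                      period_s: float = DAY_S, tol: float = 0.05,
                      n_grid: int = 96) -> float:
    """First day whose dosing cycle matches the next one within ``tol``.

    Consecutive cycles are resampled on a common intra-cycle grid and
    compared by maximum pointwise relative deviation; returns the 0-based
    day index (a constant trajectory converges at day 0) or ``inf`` when
    the trajectory never settles.
    """
    n_cycles = int(np.floor((trajectory.t[-1] - trajectory.t[0]) / period_s))
    if n_cycles < 3:
        raise ValueError("trajectory must span at least 3 dosing periods")
    t0 = trajectory.t[0]
    phase = np.linspace(0.0, period_s, n_grid, endpoint=False)
    cycles = np.array([trajectory.at(component, t0 + d * period_s + phase)
                       for d in range(n_cycles)])
    for d in range(n_cycles - 1):
        a, b = cycles[d], cycles[d + 1]
        dev = np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12))
        if dev < tol:
            return float(d)
    return float("inf")


def classify_regime(t_days: np.ndarray, y: np.ndarray,
                    min_relative_amplitude: float = 0.05,
                    growth_threshold: float = 0.05,
                    species: str = "", dose_uM: float = float("nan"),
                    min_tail_days: float = 10.0) -> RegimeReport:
    """Classify a trajectory tail as oscillating, plateau or growing.

    The tail is linearly detrended; peaks with prominence of at least
    ``min_relative_amplitude`` times the mean signal level count as
    oscillation.  A relative trend above ``growth_threshold`` per day that
    persists to the end of the tail is classified as unbounded growth.
    The classification is invariant under uniform scaling of the signal.
    """
    t_days = np.asarray(t_days, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_days[-1] - t_days[0] < min_tail_days:
        raise ValueError(f"tail must span >= {min_tail_days} days")
    scale = float(np.mean(np.abs(y)))
    if scale == 0.0:
        return RegimeReport(species, dose_uM, "plateau")
    slope, intercept = np.polyfit(t_days, y, 1)
    rel_slope = slope / scale
    # persistent growth: significant positive trend and the signal keeps
    # rising through the second half of the tail
    half = t_days > (t_days[0] + t_days[-1]) / 2
    second_half_rise = np.mean(y[half]) > np.mean(y[~half])
    if rel_slope > growth_threshold and second_half_rise:
        return RegimeReport(species, dose_uM, "unbounded-growth",
                            amplitude=float(rel_slope))
    detrended = y - (slope * t_days + intercept)
    peaks, props = find_peaks(detrended,
                              prominence=min_relative_amplitude * scale)
    if peaks.size >= 3:
        period = float(np.median(np.diff(t_days[peaks])))
        amp = float(np.median(props["prominences"]) / scale)
        return RegimeReport(species, dose_uM, "oscillating",
                            period_days=period, amplitude=amp)
    amp = float((y.max() - y.min()) / (2 * scale))
    return RegimeReport(species, dose_uM, "plateau", amplitude=amp)


def classify_trajectory(trajectory: Trajectory, component: str,
                        tail_start_day: float = 4.0, **kw) -> RegimeReport:
    """Convenience wrapper classifying one component of a trajectory."""
    tail = trajectory.window(tail_start_day * DAY_S, trajectory.t[-1])
    dose = trajectory.schedule.dose_uM if trajectory.schedule else float("nan")
    return classify_regime(tail.t_days, tail[component],
                           species=component, dose_uM=dose, **kw)


def concentration_ratio(trajectory: Trajectory,
                        geometry: CultureGeometry | None = None,
                        window: tuple[float, float] | None = None,
                        numerator: str = "csa_cytosol",
                        denominator: str = "csa_extracellular") -> float:
    """Time-averaged intracellular-to-extracellular concentration ratio.

    ``window`` is (start, end) in seconds; defaults to the whole trajectory.
    The average is the trapezoidal time integral of the pointwise ratio of
    concentrations (quantity / compartment volume), divided by the window
    length; the ratio is invariant under simultaneous rescaling of both
    quantities.
    """
    g = geometry or trajectory.geometry or DEFAULT_GEOMETRY
    tr = trajectory if window is None else trajectory.window(*window)
    if tr.t.size < 2:
        raise ValueError("window contains fewer than 2 samples")
    num = tr[numerator] / g.V_cytosol
    den = tr[denominator] / g.V_extracellular
    ratio = num / np.maximum(den, 1e-300)
    return float(np.trapezoid(ratio, tr.t) / (tr.t[-1] - tr.t[0]))


SURFACE_SPECIES = ("ros", "nrf2_nuc", "gsh", "prot_gcl", "csa_cytosol")


def dose_response_surface(doses_uM: Sequence[float],
                          horizon_days: int = 14,
                          species: Sequence[str] = SURFACE_SPECIES,
                          params: NrfParameters = NrfParameters(),
                          pk_params: PKParameters = PKParameters(),
                          geometry: CultureGeometry = DEFAULT_GEOMETRY,
                          samples_per_day: int = 48) -> pd.DataFrame:
    """Simulate the coupled model across a dose grid.

    Returns a tidy frame {dose_uM, time_d, species, quantity} suitable for
    regime mapping and surface plots.
    """
    frames = []
    for dose in doses_uM:
        sch = DosingSchedule(dose_uM=float(dose), n_doses=horizon_days)
        times = np.linspace(0.0, horizon_days * DAY_S,
                            horizon_days * samples_per_day + 1)
        tr = simulate_coupled(params, pk_params, geometry, sch, times)
        for sp in species:
            frames.append(pd.DataFrame({
                "dose_uM": float(dose), "time_d": tr.t_days,
                "species": sp, "quantity": tr[sp]}))
    return pd.concat(frames, ignore_index=True)


def regime_map(surface: pd.DataFrame, species: str = "ros",
               tail_start_day: float = 4.0, **kw) -> pd.DataFrame:
    """Classify one species' regime at every dose of a response surface."""
    rows = []
    for dose, g in surface[surface["species"] == species].groupby("dose_uM"):
        tail = g[g["time_d"] >= tail_start_day]
        rep = classify_regime(tail["time_d"].to_numpy(),
                              tail["quantity"].to_numpy(),
                              species=species, dose_uM=float(dose), **kw)
        rows.append({"dose_uM": float(dose), "species": species,
                     "regime": rep.regime, "period_days": rep.period_days,
                     "amplitude": rep.amplitude})
    return pd.DataFrame(rows).sort_values("dose_uM", ignore_index=True)


def transition_dose(regimes: pd.DataFrame) -> float:
    """Midpoint of the single oscillating -> growth switch of a regime map.

    Raises if the map is not piecewise constant with exactly one switch.
    """
    r = regimes.sort_values("dose_uM")
    growing = (r["regime"] == "unbounded-growth").to_numpy()
    switches = np.flatnonzero(np.diff(growing.astype(int)) != 0)
    if switches.size != 1 or not growing[-1] or growing[0]:
        raise ValueError("regime map does not show a single low-dose to "
                         "high-dose transition")
    i = switches[0]
    return float((r["dose_uM"].iloc[i] + r["dose_uM"].iloc[i + 1]) / 2)


def oscillation_extinction_day(trajectory: Trajectory, component: str,
                               min_relative_amplitude: float = 0.05) -> float:
    """First day after which a component's daily oscillation stays below
    the detection threshold (relative cycle amplitude), or ``inf``."""
    n_days = int(np.floor(trajectory.t_days[-1]))
    amps = []
    for d in range(n_days):
        w = trajectory.window(d * DAY_S, (d + 1) * DAY_S)
        y = w[component]
        level = max(float(np.mean(np.abs(y))), 1e-300)
        amps.append((y.max() - y.min()) / level)
    amps = np.asarray(amps)
    below = amps < min_relative_amplitude
    for d in range(n_days):
        if below[d:].all():
            return float(d)
    return float("inf")
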