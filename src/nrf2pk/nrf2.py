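"""Coupled disposition / Nrf2-pathway model.

The cell-stress module is an oxidative-stress gene-regulation network in the
lineage of generic Keap1–Nrf2–ARE kinetic models: drug in the cytosol drives
production of a lumped reactive-oxygen-species (ROS) pool; ROS oxidize the
sensor Keap1 and the Nrf2–Keap1 complex, sparing Nrf2 from Keap1-mediated
degradation; free Nrf2 enters the nucleus, dimerizes with small Maf proteins
and the dimer occupies antioxidant-response elements (AREs) in the promoters
of its target genes (Nrf2 itself, CYP3A5, GS, GCLC, GCLM, GST, GPx,
MRP2/ABCC2), adding an induced term to their basal transcription.  GCLC and
GCLM assemble into the GCL holoenzyme; GCL (and free GCLC) synthesize
gamma-glutamylcysteine under feedback inhibition by glutathione; GS converts
gamma-GC to GSH; GPx clears ROS into a non-reactive sink using GSH as
co-substrate (2 GSH per ROS); GSH is also turned over by a Michaelis-Menten
degradation pathway.  Drug transport (uptake, efflux, wall exchange) is
identical in form to the standalone disposition model, with additional
nuclear partitioning, and drug metabolism is scaled by the CYP3A5 protein
level instead of a lumped vmax.

The aryl-hydrocarbon-receptor branch of the parent model is carried with its
drug-binding constants fixed at zero: cyclosporine A is not an AhR ligand.

Quantities are zmol per cell throughout.  The published values of the 27
calibrated parameters are in :mod:`nrf2pk.tables`; the remaining fixed
constants below are this package's reconstruction of baseline cell
physiology (see docs/methods.md for the design calculations).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .dosing import DosingSchedule, RenewalAudit
from .pk import PKParameters, _integrate_intervals
from .trajectory import Trajectory
from .units import DEFAULT_GEOMETRY, CultureGeometry

GENES = ("nrf2", "cyp3a5", "gs", "gclc", "gclm", "gst", "gpx", "mrp2")

NRF_STATE_NAMES = (
    "csa_cytosol", "csa_extracellular", "csa_wall", "csa_nucleus",
    "csa_metabolized",
    "ros", "ros_cleared",
    "keap1", "keap1_ox",
    "nrf2_cyt", "nrf2_keap1", "nrf2_keap1_ox", "nrf2_nuc",
    "maf", "nrf2_maf",
    *(f"are_{g}" for g in GENES),
    *(f"mrna_{g}" for g in GENES),
    "prot_cyp3a5", "prot_gs", "prot_gclc", "prot_gclm", "prot_gcl",
    "prot_gst", "prot_gpx", "prot_mrp2",
    "ggc", "gsh",
)

_IX = {n: i for i, n in enumerate(NRF_STATE_NAMES)}
N_STATES = len(NRF_STATE_NAMES)

# index blocks used by the RHS
_I_ARE0 = _IX["are_nrf2"]
_I_MRNA0 = _IX["mrna_nrf2"]
_I_PROT = {g: _IX[f"prot_{g}"] for g in GENES if g != "nrf2"}
_I_PROT["gcl"] = _IX["prot_gcl"]
# bookkeeping integrals excluded from fixed-point searches
_BOOKKEEPING = (_IX["csa_metabolized"], _IX["ros_cleared"])
_CSA_IDX = tuple(_IX[n] for n in
                 ("csa_cytosol", "csa_extracellular", "csa_wall", "csa_nucleus"))


@dataclass(frozen=True)
class NrfParameters:
    """All rate constants of the coupled model.

    The first block holds the 27 calibrated parameters (defaults are the
    published posterior modes); the second block holds the fixed baseline
    physiology.  Units: first-order rates 1/s, bimolecular rates 1/(zmol s),
    capacities zmol/s per zmol of enzyme (written as 1/s), pools and
    Michaelis constants zmol.
    """

    # --- calibrated (posterior-mode defaults) ---
    vmax_csa_metabolism: float = 0.187    # 1/s per zmol CYP3A5
    k_ros_basal: float = 79.1             # zmol/s basal ROS formation
    vmax_ros_clearance: float = 2.67      # 1/s per zmol GPx
    k_keap1_oxidation: float = 3.02e-6    # 1/(zmol ROS s)
    k_ros_csa: float = 6.55e-5            # 1/s per zmol cytosolic drug
    kb_nrf2_maf: float = 0.0124           # 1/(zmol s)
    ktsp_cyp3a5: float = 1.29             # 1/s basal transcription (per gene dose)
    ktsp_nrf2: float = 0.087
    ktsp_gs: float = 1.07
    ktsp_gclc: float = 1.28
    ktsp_gclm: float = 3.95
    ktsp_gst: float = 0.021
    ktsp_gpx: float = 0.098
    ktsp_mrp2: float = 1.22
    kb_gcl_assembly: float = 4.33e-6      # 1/(zmol s)
    kind_nrf2: float = 150.0              # 1/(zmol s) ARE-bound induction
    kind_gs: float = 2.17
    kind_gclc: float = 22.1
    kind_gclm: float = 3.28
    kind_gst: float = 8.46
    kind_gpx: float = 1.37
    kind_mrp2: float = 6.43
    vmax_ggc_gcl: float = 83.4            # 1/s per zmol GCL
    vmax_ggc_gclc: float = 1.64           # 1/s per zmol free GCLC
    vmax_gsh_synthesis: float = 8.57      # 1/s per zmol GS
    vmax_gsh_degradation: float = 283.0   # zmol/s
    km_gsh_degradation: float = 1.62e8    # zmol

    # --- fixed baseline physiology (reconstruction, see docs/methods.md) ---
    gene_dose: float = 0.01               # zmol of promoter per gene (~6 copies)
    kdeg_mrna: float = 1e-4               # 1/s (t1/2 ~ 2 h)
    kdeg_protein: float = 1e-5            # 1/s (t1/2 ~ 19 h)
    ktl: float = 1e-5                     # 1/s generic translation per mRNA
    ktl_gpx: float = 2e-4                 # GPx translation (sets clearance capacity)
    ktl_cyp3a5: float = 1.66e-5           # matches the lumped PK vmax at baseline
    ktl_nrf2: float = 1e-4
    ku_gcl: float = 1e-5                  # 1/s GCL disassembly
    km_ggc_gs: float = 1e4                # zmol, gamma-GC Michaelis of GS
    ki_gsh_gcl: float = 2e5               # zmol, GSH feedback on GCL
    km_ros_gpx: float = 150.0             # zmol
    km_gsh_gpx: float = 2e6               # zmol
    ksyn_keap1: float = 1e-3              # zmol/s
    kdeg_keap1: float = 1e-5              # 1/s
    kred_keap1: float = 3e-4              # 1/s, reduction of oxidized Keap1
    kb_nrf2_keap1: float = 0.2            # 1/(zmol s)
    ku_nrf2_keap1: float = 1e-4           # 1/s
    kdeg_nrf2_keap1: float = 1e-3         # 1/s, Keap1-mediated Nrf2 degradation
    krel_nrf2_keap1_ox: float = 1e-3      # 1/s, Nrf2 release from oxidized complex
    k_nrf2_import: float = 0.01           # 1/s nuclear import
    k_nrf2_export: float = 1e-3           # 1/s nuclear export
    kdeg_nrf2_cyt: float = 1e-4           # 1/s Keap1-independent degradation
    kdeg_nrf2_nuc: float = 1e-4
    ku_nrf2_maf: float = 1e-4             # 1/s
    kdeg_nma: float = 1e-4                # 1/s (degrades Nrf2 part, recycles Maf)
    maf_total: float = 1.0                # zmol, conserved pool
    kb_are: float = 0.02                  # 1/(zmol s)
    ku_are: float = 1e-3                  # 1/s
    k_csa_nuc_in: float = 1e-4            # 1/s
    k_csa_nuc_out: float = 1e-3           # 1/s
    km_csa_metabolism: float = 2.18e6     # zmol (shared with the PK fit)
    kb_ahr: float = 0.0                   # AhR branch carried at zero
    kb_dre: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    CALIBRATED = (
        "vmax_csa_metabolism", "k_ros_basal", "vmax_ros_clearance",
        "k_keap1_oxidation", "k_ros_csa", "kb_nrf2_maf",
        "ktsp_cyp3a5", "ktsp_nrf2", "ktsp_gs", "ktsp_gclc", "ktsp_gclm",
        "ktsp_gst", "ktsp_gpx", "ktsp_mrp2", "kb_gcl_assembly",
        "kind_nrf2", "kind_gs", "kind_gclc", "kind_gclm", "kind_gst",
        "kind_gpx", "kind_mrp2", "vmax_ggc_gcl", "vmax_ggc_gclc",
        "vmax_gsh_synthesis", "vmax_gsh_degradation", "km_gsh_degradation",
    )

    def replace(self, **kw) -> "NrfParameters":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "NrfParameters":
        return cls(**{k: float(v) for k, v in d.items()})


def ahr_binding_fluxes(state, params: NrfParameters) -> dict[str, float]:
    """Drug–AhR association fluxes; identically zero for CsA (non-ligand)."""
    y = _as_array(state)
    return {"csa_ahr_binding": params.kb_ahr * y[_IX["csa_nucleus"]],
            "xaa_dre_binding": params.kb_dre * y[_IX["csa_nucleus"]]}


def _as_array(state) -> np.ndarray:
    if isinstance(state, Mapping):
        return np.array([state.get(n, 0.0) for n in NRF_STATE_NAMES], dtype=float)
    arr = np.asarray(state, dtype=float)
    if arr.size != N_STATES:
        raise ValueError(f"state must have {N_STATES} components")
    return arr


def nrf2_rhs(state, params: NrfParameters, pk_params: PKParameters,
             geometry: CultureGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Full derivative vector (zmol/s) of the coupled model."""
    y = np.maximum(_as_array(state), 0.0)   # guard solver micro-undershoot
    p, q = params, pk_params
    dy = np.zeros(N_STATES)

    cyt, ext, wall, nuc = (y[i] for i in _CSA_IDX)
    ros = y[_IX["ros"]]
    keap1, keap1_ox = y[_IX["keap1"]], y[_IX["keap1_ox"]]
    nrf2c, nk, nk_ox, nrf2n = (y[_IX["nrf2_cyt"]], y[_IX["nrf2_keap1"]],
                               y[_IX["nrf2_keap1_ox"]], y[_IX["nrf2_nuc"]])
    maf, nma = y[_IX["maf"]], y[_IX["nrf2_maf"]]
    ggc, gsh = y[_IX["ggc"]], y[_IX["gsh"]]

    # --- drug transport and metabolism ---
    c_ext = ext / geometry.V_extracellular
    c_cyt = cyt / geometry.V_cytosol
    uptake = q.CLin1 * c_ext
    efflux = q.CLout1 * c_cyt / (q.Kmout1 + c_cyt)
    metab = (p.vmax_csa_metabolism * y[_I_PROT["cyp3a5"]]
             * cyt / (p.km_csa_metabolism + cyt))
    wall_on = q.k1 * ext
    wall_off = q.k2 * wall ** q.k3 if wall > 0.0 else 0.0
    nuc_in = p.k_csa_nuc_in * cyt
    nuc_out = p.k_csa_nuc_out * nuc
    dy[_IX["csa_cytosol"]] = uptake - efflux - metab - nuc_in + nuc_out
    dy[_IX["csa_extracellular"]] = -uptake + efflux - wall_on + wall_off
    dy[_IX["csa_wall"]] = wall_on - wall_off
    dy[_IX["csa_nucleus"]] = nuc_in - nuc_out
    dy[_IX["csa_metabolized"]] = metab

    # --- ROS balance ---
    ros_prod = p.k_ros_basal + p.k_ros_csa * cyt
    ros_clear = (p.vmax_ros_clearance * y[_I_PROT["gpx"]]
                 * ros / (p.km_ros_gpx + ros)
                 * gsh / (p.km_gsh_gpx + gsh))
    dy[_IX["ros"]] = ros_prod - ros_clear
    dy[_IX["ros_cleared"]] = ros_clear

    # --- Keap1 redox cycle and Nrf2-Keap1 complexes ---
    ox_k = p.k_keap1_oxidation * ros * keap1
    red_k = p.kred_keap1 * keap1_ox
    bind = p.kb_nrf2_keap1 * nrf2c * keap1
    unbind = p.ku_nrf2_keap1 * nk
    deg_cx = p.kdeg_nrf2_keap1 * nk            # Nrf2 degraded, Keap1 recycled
    ox_cx = p.k_keap1_oxidation * ros * nk
    rel = p.krel_nrf2_keap1_ox * nk_ox         # -> free Nrf2 + oxidized Keap1
    dy[_IX["keap1"]] = (p.ksyn_keap1 - p.kdeg_keap1 * keap1 - ox_k + red_k
                        - bind + unbind + deg_cx)
    dy[_IX["keap1_ox"]] = ox_k - red_k - p.kdeg_keap1 * keap1_ox + rel
    dy[_IX["nrf2_keap1"]] = bind - unbind - deg_cx - ox_cx
    dy[_IX["nrf2_keap1_ox"]] = ox_cx - rel

    # --- Nrf2 nuclear signalling ---
    syn_nrf2 = p.ktl_nrf2 * y[_I_MRNA0 + 0]
    imp = p.k_nrf2_import * nrf2c
    exp_ = p.k_nrf2_export * nrf2n
    bind_m = p.kb_nrf2_maf * nrf2n * maf
    unbind_m = p.ku_nrf2_maf * nma
    dy[_IX["nrf2_cyt"]] = (syn_nrf2 - bind + unbind + rel - imp + exp_
                           - p.kdeg_nrf2_cyt * nrf2c)
    dy[_IX["nrf2_nuc"]] = (imp - exp_ - bind_m + unbind_m
                           - p.kdeg_nrf2_nuc * nrf2n)

    # --- Maf, Nrf2-Maf dimer, ARE occupancy, transcription, translation ---
    are = y[_I_ARE0:_I_ARE0 + 8]
    on = p.kb_are * nma * np.maximum(p.gene_dose - are, 0.0)
    off = p.ku_are * are
    dy[_IX["maf"]] = -bind_m + unbind_m + p.kdeg_nma * nma
    dy[_IX["nrf2_maf"]] = (bind_m - unbind_m - p.kdeg_nma * nma
                           - on.sum() + off.sum())
    dy[_I_ARE0:_I_ARE0 + 8] = on - off

    ktsp = np.array([p.ktsp_nrf2, p.ktsp_cyp3a5, p.ktsp_gs, p.ktsp_gclc,
                     p.ktsp_gclm, p.ktsp_gst, p.ktsp_gpx, p.ktsp_mrp2])
    kind = np.array([p.kind_nrf2, 0.0, p.kind_gs, p.kind_gclc,
                     p.kind_gclm, p.kind_gst, p.kind_gpx, p.kind_mrp2])
    mrna = y[_I_MRNA0:_I_MRNA0 + 8]
    dy[_I_MRNA0:_I_MRNA0 + 8] = ((ktsp + kind * are) * p.gene_dose
                                 - p.kdeg_mrna * mrna)

    ktl = {g: p.ktl for g in GENES}
    ktl["gpx"] = p.ktl_gpx
    ktl["cyp3a5"] = p.ktl_cyp3a5
    for j, g in enumerate(GENES):
        if g == "nrf2":
            continue  # Nrf2 protein handled through the signalling block
        i = _I_PROT[g]
        dy[i] = ktl[g] * y[_I_MRNA0 + j] - p.kdeg_protein * y[i]

    # --- GCL holoenzyme assembly ---
    gclc, gclm, gcl = (y[_I_PROT["gclc"]], y[_I_PROT["gclm"]],
                       y[_I_PROT["gcl"]])
    asm = p.kb_gcl_assembly * gclc * gclm
    dis = p.ku_gcl * gcl
    dy[_I_PROT["gclc"]] += -asm + dis
    dy[_I_PROT["gclm"]] += -asm + dis
    dy[_I_PROT["gcl"]] = asm - dis - p.kdeg_protein * gcl

    # --- glutathione branch ---
    fb = p.ki_gsh_gcl / (p.ki_gsh_gcl + gsh)
    ggc_syn = (p.vmax_ggc_gcl * gcl + p.vmax_ggc_gclc * gclc) * fb
    gsh_syn = (p.vmax_gsh_synthesis * y[_I_PROT["gs"]]
               * ggc / (p.km_ggc_gs + ggc))
    gsh_deg = (p.vmax_gsh_degradation * gsh
               / (p.km_gsh_degradation + gsh))
    dy[_IX["ggc"]] = ggc_syn - gsh_syn
    dy[_IX["gsh"]] = gsh_syn - gsh_deg - 2.0 * ros_clear
    return dy


# ---------------------------------------------------------------------------
# baseline (unexposed) steady state
# ---------------------------------------------------------------------------

def _baseline_seed(p: NrfParameters) -> np.ndarray:
    y = np.zeros(N_STATES)
    y[_IX["keap1"]] = 75.0
    y[_IX["keap1_ox"]] = 25.0
    y[_IX["nrf2_cyt"]] = 1e-4
    y[_IX["nrf2_keap1"]] = 1.0
    y[_IX["nrf2_nuc"]] = 1e-4
    y[_IX["maf"]] = p.maf_total
    y[_IX["nrf2_maf"]] = 1e-3
    ktsp = np.array([p.ktsp_nrf2, p.ktsp_cyp3a5, p.ktsp_gs, p.ktsp_gclc,
                     p.ktsp_gclm, p.ktsp_gst, p.ktsp_gpx, p.ktsp_mrp2])
    y[_I_MRNA0:_I_MRNA0 + 8] = ktsp * p.gene_dose / p.kdeg_mrna
    for j, g in enumerate(GENES):
        if g == "nrf2":
            continue
        k = p.ktl_gpx if g == "gpx" else p.ktl_cyp3a5 if g == "cyp3a5" else p.ktl
        y[_I_PROT[g]] = k * y[_I_MRNA0 + j] / p.kdeg_protein
    y[_I_PROT["gcl"]] = y[_I_PROT["gclc"]]
    y[_IX["ros"]] = 30.0
    y[_IX["ggc"]] = 2.5e3
    y[_IX["gsh"]] = 1.2e7
    return y


@lru_cache(maxsize=8)
def baseline_state(params: NrfParameters,
                   pk_params: PKParameters = PKParameters(),
                   geometry: CultureGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Drug-free steady state of the cell-physiology subsystem.

    Found by relaxing the autonomous system for 400 days and polishing with
    a Newton solve (bookkeeping integrals and drug pools pinned at zero).
    This state is the initial condition of every exposure simulation and the
    reference ("control") trajectory is constant at it.
    """
    y = _baseline_seed(params)
    sol = solve_ivp(lambda t, yy: nrf2_rhs(yy, params, pk_params, geometry),
                    (0.0, 400 * 86400.0), y, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"baseline relaxation failed: {sol.message}")
    y = np.maximum(sol.y[:, -1], 0.0)
    free = [i for i in range(N_STATES)
            if i not in _BOOKKEEPING and i not in _CSA_IDX]

    def residual(sub):
        full = np.zeros(N_STATES)
        full[free] = sub
        return nrf2_rhs(full, params, pk_params, geometry)[free]

    sub, info, ier, _ = fsolve(residual, y[free], full_output=True)
    if ier == 1 and np.all(sub >= -1e-9):
        y = np.zeros(N_STATES)
        y[free] = np.maximum(sub, 0.0)
    else:  # fall back on the relaxed state
        y[list(_BOOKKEEPING)] = 0.0
        y[list(_CSA_IDX)] = 0.0
    y.setflags(write=False)
    return y


def parameter_table(params: NrfParameters = NrfParameters(),
                    pk_params: PKParameters = PKParameters(),
                    geometry: CultureGeometry = DEFAULT_GEOMETRY):
    """Tidy table of all rate constants and baseline initial state values.

    Columns: symbol, value, kind ('calibrated' | 'fixed' | 'initial_state'),
    suitable for CSV/JSON export and run provenance.
    """
    import pandas as pd
    rows = [{"symbol": f.name, "value": getattr(params, f.name),
             "kind": ("calibrated" if f.name in NrfParameters.CALIBRATED
                      else "fixed")}
            for f in fields(params)]
    y0 = baseline_state(params, pk_params, geometry)
    rows += [{"symbol": name, "value": float(y0[i]), "kind": "initial_state"}
             for i, name in enumerate(NRF_STATE_NAMES)]
    return pd.DataFrame(rows, columns=["symbol", "value", "kind"])


def simulate_coupled(params: NrfParameters,
                     pk_params: PKParameters = PKParameters(),
                     geometry: CultureGeometry = DEFAULT_GEOMETRY,
                     schedule: DosingSchedule = DosingSchedule(),
                     times: np.ndarray | None = None,
                     rtol: float = 1e-6, atol: float = 1e-9,
                     initial_state: np.ndarray | None = None) -> Trajectory:
    """Simulate repeated dosing of the coupled model.

    Starts from the drug-free baseline steady state with the first dose at
    ``schedule.start_s``; medium renewal resets the extracellular drug pool
    at every dosing event exactly as in the disposition model.
    """
    if params.kb_ahr != 0.0 or params.kb_dre != 0.0:
        raise ValueError("the AhR branch must stay at zero for CsA simulations")
    if times is None:
        times = np.linspace(schedule.start_s, schedule.end_s,
                            int(schedule.n_doses * 96) + 1)
    y0 = (baseline_state(params, pk_params, geometry)
          if initial_state is None else np.asarray(initial_state, dtype=float))
    audit = RenewalAudit()
    rhs = lambda y: nrf2_rhs(y, params, pk_params, geometry)
    t, Y = _integrate_intervals(rhs, y0, schedule, times, rtol, atol, "LSODA",
                                geometry, _IX["csa_extracellular"], audit)
    return Trajectory(t, Y, NRF_STATE_NAMES, schedule, geometry, audit)
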