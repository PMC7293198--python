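"""Reduced whole-patient model of TCE monotherapy in a solid tumor.

Four compartments -- central (blood), peripheral, tumor and tumor-draining
lymph node (TDLN) -- carry effector (Teff) and regulatory (Treg) T cells.
The TDLN primes T cells from constant naive pools at a rate proportional to
the tumor mutational burden (TMB, represented as the number of activated
T-cell clones) and a saturating decreasing function of the antigen-MHC II
dissociation constant.  Primed cells enter the blood, recirculate through
the peripheral compartment, and infiltrate the tumor once it is large
enough to be vascularised.

The tumor grows logistically from a single cell.  Cancer-cell killing by
tumor Teff is gated by effector availability (a saturating function of the
Teff:cancer ratio) and enhanced by TCE ternary complexes through a Hill
function of the per-synapse biTTC density; TCE-activated Tregs exhaust
tumor Teff through a second, distinct Hill function.  Drug in the tumor is
the plasma concentration scaled by a partition coefficient (analytic PK).

A virtual patient is simulated in two phases: growth from one cell until
the tumor reaches the preset initial diameter (that instant becomes day 0),
then treatment under a dosing regimen.  Patients whose tumor never reaches
the initial diameter within the growth cap are flagged as non-patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .binding import BindingParams, clamped_equilibrium
from .invitro import HillParams, REFERENCE_HILL, hill_response
from .pk import PKParams, Regimen, plasma_concentration

__all__ = ["PatientParams", "Trajectory", "tumor_diameter", "cells_for_diameter",
           "patient_odes", "grow_to_baseline", "simulate_patient"]

#: MHC II affinity (Kd, molar) at which T-cell priming efficiency is halved.
MHC_KD50 = 1e-7

#: state vector layout
STATE = ("n_cancer", "teff_central", "teff_peripheral", "teff_tumor",
         "treg_central", "treg_peripheral", "treg_tumor")


def tumor_diameter(n_cells: float, cell_volume: float = 1e-9, packing: float = 0.8) -> float:
    """Spherical-equivalent tumor diameter (cm) for ``n_cells`` cells.

    ``cell_volume`` is in cm^3 (default 1e-9, a ~12 um cell), ``packing``
    the cell volume fraction of the lesion.
    """
    if n_cells < 0 or cell_volume <= 0 or not (0 < packing <= 1):
        raise ValueError("need n_cells >= 0, cell_volume > 0 and packing in (0, 1]")
    return (6.0 * n_cells * cell_volume / (math.pi * packing)) ** (1.0 / 3.0)


def cells_for_diameter(diameter_cm: float, cell_volume: float = 1e-9, packing: float = 0.8) -> float:
    """Inverse of :func:`tumor_diameter`."""
    if diameter_cm < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * packing * diameter_cm ** 3 / (6.0 * cell_volume)


@dataclass(frozen=True)
class PatientParams:
    """One virtual patient's parameter vector.

    Counts per cell, rates in 1/day, diameters in cm, MHC affinity in M.
    """

    tmb: float = 100.0                   # activated T-cell clones
    growth_rate: float = 0.012
    capacity: float = 1e12               # logistic carrying capacity (cells)
    initial_diameter: float = 3.0
    cea_sites: float = 5e4
    cd3_sites_teff: float = 6.1e4
    cd3_sites_treg: float = 6.1e4
    mhc_affinity: float = 5e-8           # antigen-MHC II Kd (M)
    k_kill_base: float = 0.15            # max baseline (checkpoint-suppressed)
    #                                      killing by Teff without TCE (1/day)
    teff_death: float = 0.1
    treg_death: float = 0.1
    treg_activation: float = 0.3         # Treg/Teff priming ratio
    k_prime: float = 1.2e6               # primed cells/day per clone at ideal MHC
    antigen_n50: float = 3e9             # tumor cells at half-maximal antigen supply
    k_central_peripheral: float = 0.1
    k_peripheral_central: float = 0.05
    k_central_tumor: float = 0.02
    tumor_entry_n50: float = 3e10        # cells at half-maximal vascular entry
    et_half_tumor: float = 1.0           # Teff:cancer ratio at half-max killing
    treg_half_tumor: float = 1.0         # Treg:cancer ratio at half-max exhaustion
    effector_offset: float = 1e5         # cells; contact inefficiency floor
    cancer_teff_death: float = 1.0       # extra Teff death from cancer cells (1/day)
    cancer_teff_n50: float = 3e9
    cell_volume: float = 1e-9            # cm^3
    packing: float = 0.8
    growth_cap_days: float = 4000.0
    binding: BindingParams = field(default_factory=BindingParams)
    hill_kill: HillParams = HillParams(d50=REFERENCE_HILL.d50, n_hill=3.0, k_max=10.0)
    hill_exhaust: HillParams = HillParams(d50=REFERENCE_HILL.d50, n_hill=3.0, k_max=1.0)

    def __post_init__(self) -> None:
        scalars = {k: v for k, v in self.__dict__.items()
                   if isinstance(v, (int, float))}
        for k, v in scalars.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"PatientParams.{k} must be finite and >= 0")
        if not (self.initial_diameter > 0):
            raise ValueError("initial_diameter must be > 0")

    def mhc_priming_factor(self) -> float:
        """Saturating decrease of priming with weaker antigen-MHC II binding."""
        return MHC_KD50 / (MHC_KD50 + self.mhc_affinity)

    def synapse_binding(self, pool: str) -> BindingParams:
        """Per-synapse binding parameters for the Teff or Treg pool."""
        cd3 = self.cd3_sites_teff if pool == "teff" else self.cd3_sites_treg
        return replace(self.binding, cea_sites=self.cea_sites, cd3_sites=cd3,
                       tcell_density=self.binding.cancer_cell_density)


def _bittc_interpolators(params: PatientParams, conc_max: float):
    """Per-patient log-log interpolators for biTTC(tumor TCE conc), one per pool.

    The per-synapse equilibrium is smooth in concentration, so an 80-point
    monotone spline reproduces it to well below solver tolerance while
    keeping the right-hand side cheap.
    """
    grid = np.logspace(-6, math.log10(max(conc_max * 2.0, 1e-3)), 80)
    out = {}
    for pool in ("teff", "treg"):
        bp = params.synapse_binding(pool)
        vals = np.array([clamped_equilibrium(c, bp).biTTC for c in grid])
        logv = np.log(np.clip(vals, 1e-300, None))
        interp = PchipInterpolator(np.log(grid), logv, extrapolate=False)
        lo, hi = grid[0], grid[-1]
        v_lo, v_hi = vals[0], vals[-1]

        def f(conc, interp=interp, lo=lo, hi=hi, v_lo=v_lo, v_hi=v_hi):
            if conc <= 0.0:
                return 0.0
            if conc < lo:
                return v_lo * conc / lo  # linear regime below the grid
            if conc > hi:
                return v_hi
            return math.exp(float(interp(math.log(conc))))
        out[pool] = f
    return out["teff"], out["treg"]


def patient_odes(state, params: PatientParams, tce_conc: float,
                 bittc_teff: float | None = None, bittc_treg: float | None = None):
    """Time derivatives (1/day) of the 7 cellular states.

    ``tce_conc`` is the tumor-compartment TCE concentration (nM); the
    per-synapse biTTC densities are computed from it by quasi-equilibrium
    unless supplied.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (7,):
        raise ValueError("state must have 7 entries " + str(STATE))
    if np.any(y < 0):
        raise ValueError("state must be non-negative")
    if tce_conc < 0:
        raise ValueError("tce_conc must be >= 0")
    p = params
    if bittc_teff is None:
        bittc_teff = clamped_equilibrium(tce_conc, p.synapse_binding("teff")).biTTC if tce_conc > 0 else 0.0
    if bittc_treg is None:
        bittc_treg = clamped_equilibrium(tce_conc, p.synapse_binding("treg")).biTTC if tce_conc > 0 else 0.0
    return _rhs(0.0, y, p, lambda t: tce_conc,
                lambda c: bittc_teff, lambda c: bittc_treg)


def _rhs(t, y, p: PatientParams, conc_fn, bittc_teff_fn, bittc_treg_fn):
    N, TeC, TeP, TeT, TrC, TrP, TrT = (max(v, 0.0) for v in y)
    conc = conc_fn(t)
    hr_kill = hill_response(bittc_teff_fn(conc), p.hill_kill) if conc > 0 else 0.0
    hr_exh = hill_response(bittc_treg_fn(conc), p.hill_exhaust) if conc > 0 else 0.0

    # cancer cells; the absolute offset keeps trace infiltrates from
    # controlling microscopic (pre-vascular) lesions
    f_eff = TeT / (TeT + p.et_half_tumor * N + p.effector_offset)
    kill = f_eff * (p.k_kill_base + p.hill_kill.k_max * hr_kill)
    dN = p.growth_rate * N * (1.0 - N / p.capacity) - kill * N

    # TDLN priming from constant naive pools, gated by antigen supply
    # (released by the tumor, saturating in tumor burden)
    g_mhc = p.mhc_priming_factor()
    antigen = N / (N + p.antigen_n50) if N > 0 else 0.0
    q_eff = p.k_prime * p.tmb * g_mhc * antigen
    q_reg = p.k_prime * p.treg_activation * p.tmb * g_mhc * antigen

    entry = N / (N + p.tumor_entry_n50) if N > 0 else 0.0
    k_ct = p.k_central_tumor * entry

    # Teff: priming -> central <-> peripheral, central -> tumor
    dTeC = q_eff + p.k_peripheral_central * TeP \
        - (p.k_central_peripheral + k_ct + p.teff_death) * TeC
    dTeP = p.k_central_peripheral * TeC - (p.k_peripheral_central + p.teff_death) * TeP
    f_reg = TrT / (TrT + p.treg_half_tumor * N + p.effector_offset)
    exhaustion = p.teff_death \
        + p.cancer_teff_death * (N / (N + p.cancer_teff_n50)) \
        + p.hill_exhaust.k_max * hr_exh * f_reg
    dTeT = k_ct * TeC - exhaustion * TeT

    # Treg mirror
    dTrC = q_reg + p.k_peripheral_central * TrP \
        - (p.k_central_peripheral + k_ct + p.treg_death) * TrC
    dTrP = p.k_central_peripheral * TrC - (p.k_peripheral_central + p.treg_death) * TrP
    dTrT = k_ct * TrC - p.treg_death * TrT

    return np.array([dN, dTeC, dTeP, dTeT, dTrC, dTrP, dTrT])


@dataclass
class Trajectory:
    """Time course of one simulated patient (time in days from treatment start)."""

    t: np.ndarray
    n_cancer: np.ndarray
    diameter: np.ndarray
    teff_central: np.ndarray
    teff_peripheral: np.ndarray
    teff_tumor: np.ndarray
    treg_central: np.ndarray
    treg_peripheral: np.ndarray
    treg_tumor: np.ndarray
    plasma_conc: np.ndarray
    tumor_conc: np.ndarray
    bittc_teff: np.ndarray
    bittc_treg: np.ndarray
    pretreatment_days: float
    non_patient: bool
    params: PatientParams

    @property
    def baseline_diameter(self) -> float:
        return float(self.diameter[0])

    def percent_change(self) -> np.ndarray:
        return 100.0 * (self.diameter - self.baseline_diameter) / self.baseline_diameter

    def to_frame(self) -> pd.DataFrame:
        cols = {name: getattr(self, name) for name in
                ("t", "n_cancer", "diameter", "teff_central", "teff_peripheral",
                 "teff_tumor", "treg_central", "treg_peripheral", "treg_tumor",
                 "plasma_conc", "tumor_conc", "bittc_teff", "bittc_treg")}
        return pd.DataFrame(cols)


_SOLVER = dict(method="LSODA", rtol=1e-6, atol=1e-3)


def grow_to_baseline(params: PatientParams):
    """Untreated growth phase from a single cell.

    Returns ``(reached, t_reach_days, state)``: whether the tumor reached
    the preset initial diameter within the growth cap, the time it took
    (or the cap), and the state vector at that instant.
    """
    p = params
    n_target = cells_for_diameter(p.initial_diameter, p.cell_volume, p.packing)
    zero = lambda c: 0.0
    y0 = np.array([1.0, 0, 0, 0, 0, 0, 0], dtype=float)

    def reached(t, y, *args):
        return y[0] - n_target
    reached.terminal = True
    reached.direction = 1.0

    grow = solve_ivp(_rhs, (0.0, p.growth_cap_days), y0,
                     args=(p, zero, zero, zero), events=reached, **_SOLVER)
    if not grow.t_events[0].size:
        return False, float(grow.t[-1]), grow.y[:, -1].copy()
    y_start = grow.y_events[0][0].copy()
    y_start[0] = n_target  # land exactly on the event surface
    return True, float(grow.t_events[0][0]), y_start


def simulate_patient(params: PatientParams, regimen: Regimen | None = None,
                     t_end: float = 400.0, pk: PKParams | None = None,
                     save_every: float = 1.0, growth=None) -> Trajectory:
    """Simulate one virtual patient: untreated growth to the preset initial
    diameter, then ``t_end`` days of treatment under ``regimen``.

    Deterministic for fixed inputs.  If the tumor never reaches the initial
    diameter within ``growth_cap_days`` the trajectory is returned with
    ``non_patient=True`` (no treatment phase).  ``growth`` may carry a
    precomputed :func:`grow_to_baseline` result to avoid repeating phase 1.
    """
    if not (t_end > 0):
        raise ValueError("t_end must be > 0")
    p = params
    pk = pk or PKParams()
    regimen = regimen if regimen is not None else Regimen()

    ok, t_reach, y_start = growth if growth is not None else grow_to_baseline(p)
    if not ok:
        t0 = np.array([0.0])
        y_end = y_start
        d = np.array([tumor_diameter(max(y_end[0], 0.0), p.cell_volume, p.packing)])
        z = np.zeros(1)
        return Trajectory(t0, np.array([y_end[0]]), d, *[np.array([v]) for v in y_end[1:]],
                          z, z, z, z, pretreatment_days=t_reach,
                          non_patient=True, params=p)
    y_start = np.asarray(y_start, dtype=float).copy()

    bittc_te, bittc_tr = _bittc_interpolators(
        p, conc_max=pk.tumor_partition * plasma_concentration(0.0, regimen, pk)
        * max(regimen.n_doses, 1))

    def tumor_conc(t):
        return pk.tumor_partition * plasma_concentration(t, regimen, pk)

    # integrate piecewise between dose times (concentration jumps at boluses)
    dose_times = [float(td) for td in regimen.dose_times if 0.0 < td < t_end]
    edges = [0.0] + dose_times + [t_end]
    t_out = [np.array([0.0])]
    y_out = [y_start.reshape(-1, 1)]
    y_cur = y_start
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 0:
            continue
        t_eval = np.arange(a + save_every, b, save_every)
        t_eval = np.append(t_eval, b)
        seg = solve_ivp(_rhs, (a, b), y_cur, t_eval=t_eval,
                        args=(p, tumor_conc, bittc_te, bittc_tr), **_SOLVER)
        if not seg.success:
            raise RuntimeError(f"patient integration failed on [{a}, {b}]: {seg.message}")
        t_out.append(seg.t)
        y_out.append(seg.y)
        y_cur = seg.y[:, -1]
    t = np.concatenate(t_out)
    y = np.clip(np.concatenate(y_out, axis=1), 0.0, None)

    n = y[0]
    diam = np.array([tumor_diameter(v, p.cell_volume, p.packing) for v in n])
    plasma = plasma_concentration(t, regimen, pk)
    tumor = pk.tumor_partition * plasma
    bi_te = np.array([bittc_te(c) for c in tumor])
    bi_tr = np.array([bittc_tr(c) for c in tumor])
    return Trajectory(t, n, diam, y[1], y[2], y[3], y[4], y[5], y[6],
                      np.asarray(plasma, dtype=float), tumor, bi_te, bi_tr,
                      pretreatment_days=t_reach, non_patient=False, params=p)
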