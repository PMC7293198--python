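"""Ternary-complex formation between a bivalent-CEA x monovalent-CD3 T-cell
engager (TCE), tumor-surface CEA and T-cell CD3.

The reaction network (mass action, concentrations in nM, time in seconds):

1. ``T + A  <-> AT``      at (2*kon_CEA, koff_CEA)   -- first anti-CEA arm
2. ``AT + A <-> AAT``     at (lambda*kon_CEA, 2*koff_CEA) -- intramolecular
   second-arm (cross-arm) binding, scaled by the intrinsic cross-arm binding
   efficiency ``lambda``
3. ``T + C  <-> TC``      at (kon_CD3, koff_CD3)
4. ``TC + A <-> moTTC``   at (2*kon_CEA, koff_CEA)
5. ``moTTC + A <-> biTTC`` at (lambda*kon_CEA, 2*koff_CEA)
6. ``AT + C <-> moTTC``   at (kon_CD3, koff_CD3)
7. ``AAT + C <-> biTTC``  at (kon_CD3, koff_CD3)
8. ``T + S  <-> sAT``     at (2*kon_CEA, koff_CEA)   -- soluble-CEA sink

``biTTC`` (TCE bound to two CEA and one CD3) is the efficacy-driving species;
``moTTC`` (one CEA, one CD3) is assumed non-functional, and soluble-CEA
complexes are inert.  The network satisfies detailed balance, so the closed
equilibrium is unique.

Surface receptors are treated as well-mixed volumetric species.  The
sites-per-cell to nM conversion uses interface-effective cell densities
(bulk density times ``interface_enrichment``), reflecting that binding takes
place in the cell-cell interface region rather than the full bulk volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constants import BIVALENT_ON, BIVALENT_OFF, sites_to_nM

__all__ = [
    "BindingParams",
    "SpeciesState",
    "EquilibriumError",
    "sites_to_concentration",
    "binding_odes",
    "solve_equilibrium",
    "clamped_equilibrium",
    "concentration_scan",
]

SPECIES = ("T_free", "A_free", "C_free", "AT", "AAT", "TC", "moTTC", "biTTC", "sAT")

#: Column order required for species tables written to CSV.
SCAN_COLUMNS = ("T_free", "AT", "AAT", "TC", "moTTC", "biTTC", "sAT")


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


@dataclass(frozen=True)
class BindingParams:
    """Kinetic and avidity constants plus receptor/cell densities.

    Rates are in 1/(nM s) and 1/s; densities in cells per litre.  The
    defaults describe a cibisatamab-like molecule: Kd(CEA) = 130 nM,
    cross-arm efficiency lambda = 1000, CD3 = 6.1e4 sites/cell.
    """

    kon_ceatce: float = 1e-4
    koff_ceatce: float = 1.3e-2  # Kd(CEA) = 130 nM
    kon_cd3tce: float = 1e-4
    koff_cd3tce: float = 1e-4    # Kd(CD3) = 1 nM
    lambda_crossarm: float = 1000.0
    cea_sites: float = 5e4
    cd3_sites: float = 6.1e4
    cancer_cell_density: float = 3e11  # cells/L (bulk tumor cellularity 3e8/mL)
    tcell_density: float = 3e10        # cells/L
    interface_enrichment: float = 30.0
    reaction_volume: float = 1.0       # litres (volume basis of the densities)
    soluble_cea: float = 0.0           # nM

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"BindingParams.{f.name} must be finite and >= 0, got {v!r}")
        if self.kon_ceatce <= 0 or self.kon_cd3tce <= 0:
            raise ValueError("association rates must be positive (Kd would be infinite)")
        if self.reaction_volume <= 0:
            raise ValueError("reaction_volume must be positive")

    @property
    def kd_cea(self) -> float:
        return self.koff_ceatce / self.kon_ceatce

    @property
    def kd_cd3(self) -> float:
        return self.koff_cd3tce / self.kon_cd3tce

    @property
    def cea_total_nM(self) -> float:
        """Interface-effective total CEA concentration (nM)."""
        return sites_to_nM(
            self.cea_sites,
            self.cancer_cell_density * self.interface_enrichment,
            self.reaction_volume,
        )

    @property
    def cd3_total_nM(self) -> float:
        """Interface-effective total CD3 concentration (nM)."""
        return sites_to_nM(
            self.cd3_sites,
            self.tcell_density * self.interface_enrichment,
            self.reaction_volume,
        )

    def with_(self, **kwargs) -> "BindingParams":
        return replace(self, **kwargs)


@dataclass
class SpeciesState:
    """Concentrations (nM-equivalent) of free and TCE-containing species."""

    T_free: float = 0.0
    A_free: float = 0.0
    C_free: float = 0.0
    AT: float = 0.0
    AAT: float = 0.0
    TC: float = 0.0
    moTTC: float = 0.0
    biTTC: float = 0.0
    sAT: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"SpeciesState.{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "SpeciesState":
        return cls(**{n: max(float(v), 0.0) for n, v in zip(SPECIES, y)})

    @property
    def total_tce(self) -> float:
        return self.T_free + self.AT + self.AAT + self.TC + self.moTTC + self.biTTC + self.sAT

    @property
    def total_cea(self) -> float:
        return self.A_free + self.AT + 2 * self.AAT + self.moTTC + 2 * self.biTTC

    @property
    def total_cd3(self) -> float:
        return self.C_free + self.TC + self.moTTC + self.biTTC


def sites_to_concentration(sites_per_cell: float, cell_density: float,
                           reaction_volume: float = 1.0) -> float:
    """nM-equivalent concentration of ``sites_per_cell`` receptors on cells at
    ``cell_density`` (cells/L, or a count if ``reaction_volume`` is in litres)."""
    return sites_to_nM(sites_per_cell, cell_density, reaction_volume)


def _rates(y: np.ndarray, p: BindingParams) -> np.ndarray:
    """Net forward rates of reactions 1-8 (nM/s)."""
    T, A, C, AT, AAT, TC, mo, bi, sAT = y
    S = max(p.soluble_cea - sAT, 0.0)
    kon_a, koff_a = p.kon_ceatce, p.koff_ceatce
    kon_c, koff_c = p.kon_cd3tce, p.koff_cd3tce
    lam = p.lambda_crossarm
    return np.array([
        BIVALENT_ON * kon_a * T * A - koff_a * AT,
        lam * kon_a * AT * A - BIVALENT_OFF * koff_a * AAT,
        kon_c * T * C - koff_c * TC,
        BIVALENT_ON * kon_a * TC * A - koff_a * mo,
        lam * kon_a * mo * A - BIVALENT_OFF * koff_a * bi,
        kon_c * AT * C - koff_c * mo,
        kon_c * AAT * C - koff_c * bi,
        BIVALENT_ON * kon_a * T * S - koff_a * sAT,
    ])


# stoichiometry: rows = species in SPECIES order, columns = reactions 1-8
_STOICH = np.array([
    # r1  r2  r3  r4  r5  r6  r7  r8
    [-1,  0, -1,  0,  0,  0,  0, -1],  # T_free
    [-1, -1,  0, -1, -1,  0,  0,  0],  # A_free
    [0,   0, -1,  0,  0, -1, -1,  0],  # C_free
    [1,  -1,  0,  0,  0, -1,  0,  0],  # AT
    [0,   1,  0,  0,  0,  0, -1,  0],  # AAT
    [0,   0,  1, -1,  0,  0,  0,  0],  # TC
    [0,   0,  0,  1, -1,  1,  0,  0],  # moTTC
    [0,   0,  0,  0,  1,  0,  1,  0],  # biTTC
    [0,   0,  0,  0,  0,  0,  0,  1],  # sAT
], dtype=float)


def binding_odes(state: SpeciesState, params: BindingParams) -> SpeciesState:
    """Mass-action time derivatives (nM/s) of all species.

    The derivatives conserve total TCE, total CEA and total CD3 exactly by
    construction of the stoichiometry matrix.
    """
    y = state.as_array()
    dy = _STOICH @ _rates(y, params)
    out = SpeciesState.__new__(SpeciesState)
    for name, v in zip(SPECIES, dy):
        object.__setattr__(out, name, float(v))
    return out


def _complexes(T: float, A: float, C: float, S: float, p: BindingParams) -> SpeciesState:
    """Assemble a SpeciesState from free concentrations at equilibrium."""
    k1 = BIVALENT_ON * p.kon_ceatce / p.koff_ceatce            # AT / (T*A)
    k2 = p.lambda_crossarm * p.kon_ceatce / (BIVALENT_OFF * p.koff_ceatce)  # AAT/(AT*A)
    k3 = p.kon_cd3tce / p.koff_cd3tce                           # TC / (T*C)
    AT = k1 * T * A
    AAT = k2 * AT * A
    TC = k3 * T * C
    mo = k3 * AT * C
    bi = k3 * AAT * C
    sAT = k1 * T * S
    return SpeciesState(T, A, C, AT, AAT, TC, mo, bi, sAT)


def _equilibrium_constants(p: BindingParams):
    k1 = BIVALENT_ON * p.kon_ceatce / p.koff_ceatce
    k2 = p.lambda_crossarm * p.kon_ceatce / (BIVALENT_OFF * p.koff_ceatce)
    k3 = p.kon_cd3tce / p.koff_cd3tce
    return k1, k2, k3


def clamped_equilibrium(free_tce: float, params: BindingParams,
                        tol: float = 1e-12, max_iter: int = 500) -> SpeciesState:
    """Equilibrium species for a *clamped* free-TCE concentration (bath mode).

    The free drug level is held at ``free_tce`` (set externally, e.g. by
    plasma PK or a large medium reservoir); CEA, CD3 and soluble CEA obey
    their conservation totals.  Solved by alternating the closed-form
    conditional solutions for free CEA (quadratic) and free CD3.
    """
    if free_tce < 0:
        raise ValueError("free_tce must be >= 0")
    p = params
    A_tot, C_tot, S_tot = p.cea_total_nM, p.cd3_total_nM, p.soluble_cea
    k1, k2, k3 = _equilibrium_constants(p)
    T = free_tce
    S = S_tot / (1.0 + k1 * T)
    if T == 0.0 or (A_tot == 0.0 and C_tot == 0.0):
        return _complexes(T, A_tot, C_tot, S, p)
    def C_of(A: float) -> float:
        return C_tot / (1.0 + k3 * T * (1.0 + k1 * A + k1 * k2 * A * A))

    def A_of(C: float) -> float:
        fac = 1.0 + k3 * C
        a = 2.0 * k1 * k2 * T * fac
        b = 1.0 + k1 * T * fac
        if a == 0.0:
            return A_tot / b
        return (-b + math.sqrt(b * b + 4.0 * a * A_tot)) / (2.0 * a)

    A, C = A_tot, C_tot
    converged = False
    for _ in range(max_iter):
        A_new = A_of(C)
        C_new = C_of(A_new)
        done = (abs(A_new - A) <= tol * max(A_tot, 1.0)
                and abs(C_new - C) <= tol * max(C_tot, 1.0))
        A, C = A_new, C_new
        if done:
            converged = True
            break
    if not converged:
        # the alternating iteration can cycle for extreme avidity; fall back
        # to a bracketed 1-D root in free CEA (monotone residual)
        from scipy.optimize import brentq

        def resid(A_: float) -> float:
            C_ = C_of(A_)
            fac = 1.0 + k3 * C_
            return A_tot - A_ * (1.0 + k1 * T * fac) - 2.0 * k1 * k2 * T * fac * A_ * A_
        if A_tot == 0.0:
            A = 0.0
        else:
            A = brentq(resid, 0.0, A_tot, xtol=1e-18, rtol=8.9e-16, maxiter=300)
        C = C_of(A)
    return _complexes(T, A, C, S, p)


def solve_equilibrium(total_tce: float, params: BindingParams,
                      tol: float = 1e-9) -> SpeciesState:
    """Equilibrium species of the closed system at a given *total* TCE.

    Solves the three conservation equations (total TCE, CEA, CD3) for the
    free concentrations by a damped fixed point polished with a Newton-type
    root solve in log space; falls back to stiff ODE integration to steady
    state when the root solve stalls.  Residual tolerance ``tol`` is absolute
    on the conservation equations scaled by each total.
    """
    if total_tce < 0:
        raise ValueError("total_tce must be >= 0")
    p = params
    T_tot = total_tce
    A_tot, C_tot, S_tot = p.cea_total_nM, p.cd3_total_nM, p.soluble_cea
    k1, k2, k3 = _equilibrium_constants(p)

    if T_tot == 0.0:
        return SpeciesState(0.0, A_tot, C_tot, 0, 0, 0, 0, 0, 0)

    def free_S(T: float) -> float:
        return S_tot / (1.0 + k1 * T)

    def residuals(logx: np.ndarray) -> np.ndarray:
        T, A, C = np.exp(logx)
        S = free_S(T)
        bound_T = 1.0 + k1 * A + k1 * k2 * A * A + k3 * C \
            + k1 * k3 * A * C + k1 * k2 * k3 * A * A * C + k1 * S
        bound_A = 1.0 + k1 * T + 2 * k1 * k2 * T * A + k1 * k3 * T * C \
            + 2 * k1 * k2 * k3 * T * A * C
        bound_C = 1.0 + k3 * T + k1 * k3 * T * A + k1 * k2 * k3 * T * A * A
        return np.array([
            (T * bound_T - T_tot) / max(T_tot, 1e-30),
            (A * bound_A - A_tot) / max(A_tot, 1e-30) if A_tot > 0 else math.log(A) + 60.0,
            (C * bound_C - C_tot) / max(C_tot, 1e-30) if C_tot > 0 else math.log(C) + 60.0,
        ])

    # damped fixed point for a warm start
    T = T_tot
    A = A_tot if A_tot > 0 else 1e-26
    C = C_tot if C_tot > 0 else 1e-26
    for _ in range(200):
        S = free_S(T)
        T_new = T_tot / (1.0 + k1 * A + k1 * k2 * A * A + k3 * C
                         + k1 * k3 * A * C + k1 * k2 * k3 * A * A * C + k1 * S)
        if A_tot > 0:
            fac = 1.0 + k3 * C
            a = 2.0 * k1 * k2 * T * fac
            b = 1.0 + k1 * T * fac
            A_new = A_tot / b if a == 0.0 else (
                (-b + math.sqrt(b * b + 4.0 * a * A_tot)) / (2.0 * a))
        else:
            A_new = A
        if C_tot > 0:
            C_new = C_tot / (1.0 + k3 * T * (1.0 + k1 * A_new + k1 * k2 * A_new ** 2))
        else:
            C_new = C
        # geometric damping keeps the iteration stable for stiff avidity
        T = math.sqrt(T * T_new)
        A = math.sqrt(A * A_new) if A_tot > 0 else A
        C = math.sqrt(C * C_new) if C_tot > 0 else C

    sol = root(residuals, np.log([T, A, C]), method="hybr", tol=1e-13)
    res = np.max(np.abs(residuals(sol.x)))
    if res > tol:
        # fall back to stiff integration to steady state
        y0 = np.array([T_tot, A_tot, C_tot, 0, 0, 0, 0, 0, 0], dtype=float)
        ode = solve_ivp(lambda t, y: _STOICH @ _rates(y, p), (0.0, 1e8), y0,
                        method="LSODA", rtol=1e-12, atol=1e-14)
        yss = ode.y[:, -1]
        S = free_S(max(yss[0], 1e-30))
        sol = root(residuals, np.log(np.clip(yss[:3], 1e-30, None)),
                   method="hybr", tol=1e-13)
        res = np.max(np.abs(residuals(sol.x)))
        if res > tol:
            raise EquilibriumError(
                f"equilibrium solver (hybr root + LSODA fallback) failed: "
                f"max scaled residual {res:.3e} > {tol:.1e}")
    T, A, C = np.exp(sol.x)
    if A_tot == 0:
        A = 0.0
    if C_tot == 0:
        C = 0.0
    return _complexes(float(T), float(A), float(C), free_S(float(T)), p)


def concentration_scan(conc_grid, params: BindingParams, mode: str = "bath") -> pd.DataFrame:
    """Equilibrium species table across a grid of TCE concentrations.

    ``mode="bath"`` (default) clamps the *free* TCE concentration at each
    grid value -- the physiological reading of a concentration-response scan,
    where drug level is set by plasma PK or a large medium reservoir.
    ``mode="closed"`` interprets grid values as *total* TCE in a closed
    compartment and uses :func:`solve_equilibrium`.

    Returns a DataFrame with one row per concentration (column ``conc_nM``)
    and species columns including ``T_free, AT, AAT, TC, moTTC, biTTC, sAT``.
    """
    grid = np.asarray(list(conc_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("conc_grid must not be empty")
    if np.any(grid < 0):
        raise ValueError("conc_grid values must be >= 0")
    if np.any(np.diff(grid) < 0):
        raise ValueError("conc_grid must be sorted ascending")
    if mode not in ("bath", "closed"):
        raise ValueError(f"unknown scan mode {mode!r}")
    solver = clamped_equilibrium if mode == "bath" else solve_equilibrium
    rows = []
    for c in grid:
        st = solver(float(c), params)
        rows.append({"conc_nM": float(c), **{n: getattr(st, n) for n in SPECIES}})
    df = pd.DataFrame(rows)
    return df[["conc_nM", *SPECIES]]


def peak_concentration(scan: pd.DataFrame, species: str = "biTTC") -> float:
    """Concentration at which ``species`` is maximal, refined by log-parabolic
    interpolation around the grid argmax."""
    x = scan["conc_nM"].to_numpy()
    y = scan[species].to_numpy()
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1 or x[i - 1] <= 0:
        return float(x[i])
    lx = np.log(x[i - 1:i + 2])
    ly = y[i - 1:i + 2]
    denom = (ly[0] - 2 * ly[1] + ly[2])
    if denom >= 0:
        return float(x[i])
    shift = 0.5 * (ly[0] - ly[2]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(np.exp(lx[1] + shift * (lx[2] - lx[1])))
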