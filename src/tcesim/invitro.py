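"""In-vitro cytotoxicity mini-model and Hill-translation calibration.

Reproduces the standard TCE killing assay: cancer cells co-cultured with
effector cells (PBMC or purified CD8 T cells) at a fixed effector-to-target
(E/T) ratio, treated with TCE, with percent tumor lysis read out after
``readout_time`` hours (LDH-release style).

The biTTC density on the co-culture interface is translated into an
additional cancer-cell death rate through a Hill function; percent lysis is
measured against an untreated control, so the TCE-independent baseline
killing cancels:

    lysis% = 100 * (1 - exp(-k_max * hill(biTTC) * t))

Calibration fits the Hill parameters (and optionally the cross-arm
efficiency lambda) to dose-response data by least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .binding import BindingParams, clamped_equilibrium

__all__ = [
    "AssaySetup",
    "HillParams",
    "CalibrationResult",
    "hill_response",
    "simulate_cytotoxicity",
    "calibrate_hill",
    "lysis_scan",
    "lysis_threshold",
    "synthetic_dose_response",
    "CELL_LINE_CEA_SITES",
    "REFERENCE_HILL",
]

#: CEA expression (sites/cell) of the reference cell-line panel, spanning the
#: published high-to-negative expression range.
CELL_LINE_CEA_SITES = {
    "MKN45": 5e5,
    "LS174T": 5e4,
    "HT-29": 2e4,
    "CCD-841": 1e3,
}


@dataclass(frozen=True)
class HillParams:
    """Hill translation of biTTC density into TCE-enhanced killing.

    d50 is the biTTC density (nM-equivalent) for half-maximal effect,
    n_hill the Hill coefficient and k_max the maximal TCE-enhanced killing
    rate (1/day).
    """

    d50: float
    n_hill: float
    k_max: float

    def __post_init__(self) -> None:
        if not (self.d50 > 0):
            raise ValueError("d50 must be > 0")
        if not (self.n_hill > 0):
            raise ValueError("n_hill must be > 0")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")


#: Reference calibration for the cibisatamab-like molecule.  d50 was chosen
#: so that, at 20 nM TCE and E/T 10:1, percent lysis crosses 5% of its
#: maximum at the published expression threshold of 1.0e4 CEA sites/cell.
REFERENCE_HILL = HillParams(d50=248.2, n_hill=3.0, k_max=1.5)


@dataclass(frozen=True)
class AssaySetup:
    """One cytotoxicity assay condition.

    The co-culture interface is modelled with the same interface-effective
    density conversion as the tumor compartment; effector coverage of the
    cancer-cell surface saturates with the E/T ratio with half-saturation
    ``et_half`` (killing activity is reported to saturate near E/T 10:1).
    """

    n_cancer: float = 1e4
    n_effector: float = 1e5          # E/T 10:1
    tce_conc: float = 20.0           # nM
    cea_sites: float = 5e4
    cd3_sites: float = 6.1e4
    readout_time: float = 48.0       # hours
    base_kill_rate: float = 0.1      # 1/day, TCE-independent killing
    et_half: float = 2.0             # E/T ratio at half-maximal coverage
    params: BindingParams = field(default_factory=BindingParams)

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_effector < 0:
            raise ValueError("cell counts must be >= 0")
        if not (self.readout_time > 0):
            raise ValueError("readout_time must be > 0")
        if self.tce_conc < 0 or self.cea_sites < 0 or self.cd3_sites < 0:
            raise ValueError("tce_conc, cea_sites and cd3_sites must be >= 0")

    @property
    def et_ratio(self) -> float:
        return self.n_effector / self.n_cancer if self.n_cancer > 0 else math.inf

    def effector_coverage(self) -> float:
        """Saturating fraction of the cancer-cell interface engaged by effectors."""
        et = self.et_ratio
        if math.isinf(et):
            return 1.0
        return et / (et + self.et_half)

    def binding_params(self) -> BindingParams:
        """Binding parameters for this assay's interface.

        biTTC is a per-synapse quantity: each synapse pairs one effector
        with one target cell, so the interface T-cell density equals the
        cancer-cell density.  How many targets are engaged (the E/T
        coverage) gates the killing rate, not the synapse chemistry.
        """
        return replace(
            self.params,
            cea_sites=self.cea_sites,
            cd3_sites=self.cd3_sites,
            tcell_density=self.params.cancer_cell_density,
        )


def hill_response(x: float, h: HillParams) -> float:
    """Hill function x^n / (x^n + d50^n); monotone, 0 at 0, 0.5 at d50."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if x == 0.0:
        return 0.0
    # compute in log space to avoid overflow for large n
    z = h.n_hill * (math.log(h.d50) - math.log(x))
    if z > 700.0:
        return 0.0
    if z < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def bittc_density(setup: AssaySetup) -> float:
    """Interface biTTC density (nM-equivalent) at the assay's TCE concentration."""
    if setup.tce_conc == 0.0:
        return 0.0
    return clamped_equilibrium(setup.tce_conc, setup.binding_params()).biTTC


def simulate_cytotoxicity(setup: AssaySetup, h: HillParams) -> float:
    """Percent tumor lysis at the readout time, relative to untreated control.

    Cancer cells die at ``coverage * (base_kill_rate + k_max * hill(biTTC))``
    where coverage is the saturating E/T term; the control shares the
    baseline, so lysis reduces to the closed form
    ``100 * (1 - exp(-coverage * k_max * hill(biTTC) * t))`` in [0, 100].
    """
    t_days = setup.readout_time / 24.0
    enhanced = setup.effector_coverage() * h.k_max * hill_response(bittc_density(setup), h)
    return 100.0 * (1.0 - math.exp(-enhanced * t_days))


def lysis_scan(cea_grid, setup: AssaySetup, h: HillParams) -> pd.DataFrame:
    """Percent lysis across CEA expression levels, all else per ``setup``."""
    rows = []
    for cea in cea_grid:
        s = replace(setup, cea_sites=float(cea))
        rows.append({"cea_sites": float(cea), "lysis_pct": simulate_cytotoxicity(s, h)})
    return pd.DataFrame(rows)


def lysis_threshold(scan: pd.DataFrame, frac_of_max: float = 0.05) -> float:
    """CEA expression at which lysis first exceeds ``frac_of_max`` of its
    maximum, log-linearly interpolated between grid points."""
    cea = scan["cea_sites"].to_numpy()
    lys = scan["lysis_pct"].to_numpy()
    target = frac_of_max * float(lys.max())
    above = np.nonzero(lys > target)[0]
    if above.size == 0:
        return float("inf")
    i = int(above[0])
    if i == 0:
        return float(cea[0])
    x0, x1 = math.log(cea[i - 1]), math.log(cea[i])
    y0, y1 = lys[i - 1], lys[i]
    w = (target - y0) / (y1 - y0)
    return float(math.exp(x0 + w * (x1 - x0)))


def synthetic_dose_response(h: HillParams = REFERENCE_HILL,
                            setup: AssaySetup = AssaySetup(),
                            cea_grid=None, conc_grid=(20.0,),
                            noise_cv: float = 0.0, seed: int | None = None) -> pd.DataFrame:
    """Synthetic dose-response table shaped like the published experiments.

    Defaults mirror the reference assay: 20 nM TCE, E/T 10:1, CEA expression
    log-spaced over 1e3-1e6 sites/cell.  ``noise_cv`` applies multiplicative
    lognormal-free noise (1 + cv*eps) to the lysis readout.

    Columns: tce_conc_nM, cea_sites, lysis_pct.
    """
    if cea_grid is None:
        cea_grid = np.logspace(3, 6, 10)
    rng = np.random.default_rng(seed)
    rows = []
    for conc in conc_grid:
        for cea in cea_grid:
            s = replace(setup, tce_conc=float(conc), cea_sites=float(cea))
            lys = simulate_cytotoxicity(s, h)
            if noise_cv > 0:
                lys = float(np.clip(lys * (1.0 + noise_cv * rng.standard_normal()), 0.0, 100.0))
            rows.append({"tce_conc_nM": float(conc), "cea_sites": float(cea),
                         "lysis_pct": lys})
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    hill: HillParams
    lambda_crossarm: float
    residual_norm: float
    converged: bool
    n_obs: int
    free_params: tuple


_FREE_PARAMS = ("d50", "n_hill", "k_max", "lambda_crossarm")


def calibrate_hill(dose_response: pd.DataFrame, fixed: BindingParams | None = None,
                   free_params=("d50", "n_hill", "k_max"),
                   setup: AssaySetup | None = None,
                   x0: dict | None = None) -> CalibrationResult:
    """Least-squares calibration of the Hill translation to dose-response data.

    ``dose_response`` needs columns tce_conc_nM, cea_sites, lysis_pct (in
    [0, 100]).  ``free_params`` is a subset of {d50, n_hill, k_max,
    lambda_crossarm}; positive parameters are fitted in log space.
    Non-convergence is flagged on the result, not raised; an under-determined
    system (fewer observations than free parameters, or no data) raises.
    """
    if dose_response is None or len(dose_response) == 0:
        raise ValueError("dose_response is empty")
    free_params = tuple(free_params)
    for name in free_params:
        if name not in _FREE_PARAMS:
            raise ValueError(f"unknown free parameter {name!r}")
    if len(dose_response) < len(free_params):
        raise ValueError(
            f"under-determined calibration: {len(dose_response)} observations "
            f"for {len(free_params)} free parameters")
    lys = dose_response["lysis_pct"].to_numpy(dtype=float)
    if np.any(lys < 0) or np.any(lys > 100):
        raise ValueError("observed lysis must be within [0, 100]")
    base = setup or AssaySetup()
    if fixed is not None:
        base = replace(base, params=fixed)

    conc = dose_response["tce_conc_nM"].to_numpy(dtype=float)
    cea = dose_response["cea_sites"].to_numpy(dtype=float)
    t_days = base.readout_time / 24.0

    def bittc_all(lam: float) -> np.ndarray:
        s0 = replace(base, params=replace(base.params, lambda_crossarm=lam))
        return np.array([
            bittc_density(replace(s0, tce_conc=c, cea_sites=a))
            for c, a in zip(conc, cea)
        ])

    lam_free = "lambda_crossarm" in free_params
    lam0 = base.params.lambda_crossarm
    b0 = bittc_all(lam0)

    # data-driven start values: k_max from the plateau, d50 from the biTTC
    # level nearest half-maximal lysis
    lys_max = float(lys.max())
    kmax0 = max(-math.log(max(1.0 - min(lys_max, 99.0) / 100.0, 1e-6)) / t_days, 1e-3)
    half_idx = int(np.argmin(np.abs(lys - 0.5 * lys_max)))
    d50_0 = max(float(b0[half_idx]), 1e-6)
    start = {"d50": d50_0, "n_hill": 1.5, "k_max": kmax0, "lambda_crossarm": lam0}
    if x0:
        start.update(x0)

    bounds_lo = {"d50": 1e-8, "n_hill": 0.1, "k_max": 1e-4, "lambda_crossarm": 1e-2}
    bounds_hi = {"d50": 1e8, "n_hill": 30.0, "k_max": 1e3, "lambda_crossarm": 1e7}

    cache = {}

    def unpack(theta):
        vals = dict(start)
        for name, v in zip(free_params, theta):
            vals[name] = math.exp(v)
        h = HillParams(d50=vals["d50"], n_hill=vals["n_hill"], k_max=vals["k_max"])
        return h, vals["lambda_crossarm"]

    def residuals(theta):
        h, lam = unpack(theta)
        if lam_free:
            if lam not in cache:
                if len(cache) > 256:
                    cache.clear()
                cache[lam] = bittc_all(lam)
            b = cache[lam]
        else:
            b = b0
        cov = base.effector_coverage()
        pred = 100.0 * (1.0 - np.exp(-cov * h.k_max * t_days
                                     * np.array([hill_response(x, h) for x in b])))
        return pred - lys

    theta0 = np.log([start[name] for name in free_params])
    lo = np.log([bounds_lo[name] for name in free_params])
    hi = np.log([bounds_hi[name] for name in free_params])
    fit = least_squares(residuals, np.clip(theta0, lo, hi), bounds=(lo, hi),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    h, lam = unpack(fit.x)
    return CalibrationResult(
        hill=h, lambda_crossarm=lam,
        residual_norm=float(np.linalg.norm(fit.fun)),
        converged=bool(fit.success), n_obs=len(lys), free_params=free_params,
    )
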