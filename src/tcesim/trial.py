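"""Virtual clinical trial engine: LHS cohort generation, plausibility
screening, treatment simulation, RECIST v1.1 classification and response
statistics.

A cohort is generated by Latin hypercube sampling of patient parameters
(uniform on a linear or log scale per parameter).  Each virtual patient
grows a tumor from a single cell; patients whose tumor never reaches the
preset initial diameter within the growth cap -- or who fail a plausibility
rule -- are screened out as non-patients before any denominator is formed.
The remaining patients are treated (default: 60 mg weekly for 400 days) and
classified CR/PR/SD/PD from percent diameter change at scheduled
assessments, single-lesion proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc
from statsmodels.stats.proportion import proportion_confint

from .binding import BindingParams
from .patient import (PatientParams, Trajectory, grow_to_baseline,
                      simulate_patient, tumor_diameter)
from .pk import PKParams, Regimen

__all__ = [
    "ParameterRange", "ParameterRanges", "CohortResult",
    "default_parameter_ranges", "lhs_sample", "build_patient",
    "screen_cohort", "classify_recist", "response_rate_ci",
    "subgroup_response", "run_trial",
]

#: CR detectability floor (cm); a single lesion smaller than 2 mm is
#: considered disappeared.
CR_FLOOR_CM = 0.2

#: RECIST absolute-increase guard for PD (cm on the single-lesion proxy).
PD_ABSOLUTE_GUARD_CM = 0.5

ASSESSMENT_INTERVAL_DAYS = 14.0


@dataclass(frozen=True)
class ParameterRange:
    name: str
    lower: float
    upper: float
    scale: str = "log"  # "linear" | "log"

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map uniform [0,1) samples onto this range on its scale."""
        if self.scale == "linear":
            return self.lower + u * (self.upper - self.lower)
        return np.exp(np.log(self.lower) + u * (np.log(self.upper) - np.log(self.lower)))


class ParameterRanges:
    """Ordered collection of :class:`ParameterRange`."""

    def __init__(self, ranges):
        self.ranges = [r if isinstance(r, ParameterRange) else ParameterRange(*r)
                       for r in ranges]
        names = [r.name for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def names(self):
        return [r.name for r in self.ranges]

    def __len__(self):
        return len(self.ranges)

    def __iter__(self):
        return iter(self.ranges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"name": r.name, "lower": r.lower, "upper": r.upper,
                              "scale": r.scale} for r in self.ranges])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterRanges":
        return cls([ParameterRange(row["name"], float(row["lower"]),
                                   float(row["upper"]), str(row["scale"]))
                    for _, row in df.iterrows()])


def default_parameter_ranges() -> ParameterRanges:
    """Sampling ranges of the virtual cohort.

    Chosen to span the physiologically plausible inter-patient variability
    for metastatic colorectal cancer: TMB as activated T-cell clones, tumor
    growth rate, presentation diameter, CEA expression across the published
    cell-line span, CD3 within the measured range, antigen-MHC II affinity,
    baseline and TCE-enhanced killing, T-cell turnover, Treg priming and
    the anti-CD3 arm off-rate (kon fixed, so koff sets Kd).
    """
    return ParameterRanges([
        ("tmb", 10.0, 2000.0, "log"),
        ("growth_rate", 0.005, 0.03, "log"),
        ("initial_diameter", 2.0, 5.0, "linear"),
        ("cea_sites", 1e3, 1e6, "log"),
        ("cd3_sites_teff", 3e4, 1.2e5, "log"),
        ("cd3_sites_treg", 3e4, 1.2e5, "log"),
        ("mhc_affinity", 1e-9, 1e-6, "log"),
        ("k_kill_base", 0.01, 0.1, "log"),
        ("teff_death", 0.05, 0.3, "log"),
        ("treg_activation", 0.1, 1.0, "log"),
        ("lambda_crossarm", 1e1, 1e4, "log"),
        ("koff_cd3tce", 1e-5, 1e-3, "log"),
    ])


def lhs_sample(ranges: ParameterRanges, n: int, seed: int) -> pd.DataFrame:
    """Latin hypercube sample: one draw per equal-probability stratum per
    parameter (on the parameter's scale), reproducible for a given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(ranges), seed=int(seed))
    u = sampler.random(n)
    cols = {r.name: r.transform(u[:, j]) for j, r in enumerate(ranges)}
    df = pd.DataFrame(cols)
    df.insert(0, "patient_id", np.arange(n))
    return df


_BINDING_FIELDS = {f for f in BindingParams.__dataclass_fields__}


def build_patient(row, base: PatientParams | None = None) -> PatientParams:
    """Construct a PatientParams from one sampled row (dict or Series).

    Sampled names matching BindingParams fields (e.g. ``lambda_crossarm``,
    ``koff_cd3tce``) go into the nested binding parameters; the rest must be
    PatientParams fields.
    """
    base = base or PatientParams()
    d = dict(row)
    d.pop("patient_id", None)
    patient_fields = PatientParams.__dataclass_fields__
    patient_kwargs = {k: float(v) for k, v in d.items() if k in patient_fields}
    binding_kwargs = {k: float(v) for k, v in d.items()
                      if k not in patient_fields and k in _BINDING_FIELDS}
    unknown = [k for k in d if k not in patient_fields and k not in _BINDING_FIELDS]
    if unknown:
        raise ValueError(f"unknown patient parameters: {unknown}")
    binding = replace(base.binding, **binding_kwargs) if binding_kwargs else base.binding
    return replace(base, binding=binding, **patient_kwargs)


def classify_recist(baseline_d: float, diameters, cr_floor: float = CR_FLOOR_CM,
                    pd_guard: float = PD_ABSOLUTE_GUARD_CM) -> str:
    """RECIST v1.1 category from a series of assessed diameters (cm).

    Best-response semantics on the single-lesion proxy: CR if the lesion
    falls below the detectability floor, PR if the best change from baseline
    is <= -30 % (and not CR), PD if the change from nadir at the final
    assessment is >= +20 % with an absolute increase of at least ``pd_guard``
    cm, otherwise SD.
    """
    if not (baseline_d > 0):
        raise ValueError("baseline_d must be > 0")
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        raise ValueError("diameter series is empty")
    best = float(d.min())
    if best <= cr_floor:
        return "CR"
    if (best - baseline_d) / baseline_d <= -0.30:
        return "PR"
    nadir = min(float(np.minimum.accumulate(d)[-1]), baseline_d)
    final = float(d[-1])
    if nadir > 0 and (final - nadir) / nadir >= 0.20 and (final - nadir) >= pd_guard:
        return "PD"
    return "SD"


def response_rate_ci(responders: int, n: int, conf: float = 0.95):
    """Agresti-Coull interval for a response proportion; returns
    (rate, lower, upper), all in [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= responders <= n):
        raise ValueError("responders must be within [0, n]")
    lo, hi = proportion_confint(responders, n, alpha=1.0 - conf, method="agresti_coull")
    return responders / n, float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


@dataclass
class CohortResult:
    """Virtual-trial outcome: one row per *plausible* patient plus exclusions."""

    patients: pd.DataFrame            # params, endpoints, category
    excluded: pd.DataFrame            # sampled rows screened out, with reason
    assessments: pd.DataFrame         # long table: patient_id, t, diameter, pct_change
    regimen: Regimen
    seed: int

    @property
    def n_plausible(self) -> int:
        return len(self.patients)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def category_counts(self) -> dict:
        c = self.patients["recist"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("CR", "PR", "SD", "PD")}

    def orr(self, conf: float = 0.95):
        """Overall response rate (CR+PR) with Agresti-Coull CI."""
        cc = self.category_counts()
        resp = cc["CR"] + cc["PR"]
        return response_rate_ci(resp, self.n_plausible, conf)

    def waterfall(self) -> pd.DataFrame:
        return (self.patients[["patient_id", "best_pct_change"]]
                .sort_values("best_pct_change", ascending=False)
                .reset_index(drop=True))


def subgroup_response(cohort: CohortResult | pd.DataFrame, parameter: str,
                      split: str | int = "median", conf: float = 0.95) -> pd.DataFrame:
    """ORR with Agresti-Coull CI per subgroup of a parameter.

    ``split="median"`` makes below/above-median groups; an integer makes
    that many equal-count bins (sizes differing by at most one).
    """
    df = cohort.patients if isinstance(cohort, CohortResult) else cohort
    if len(df) == 0:
        raise ValueError("empty cohort")
    x = df[parameter].to_numpy(dtype=float)
    resp = df["recist"].isin(["CR", "PR"]).to_numpy()
    if np.all(x == x[0]):
        raise ValueError(f"parameter {parameter!r} is constant; no subgroups")
    order = np.argsort(x, kind="mergesort")
    if split == "median":
        med = float(np.median(x))
        groups = [(f"{parameter} <= median", x <= med), (f"{parameter} > median", x > med)]
        idx_groups = [np.nonzero(m)[0] for _, m in groups]
        labels = [g[0] for g in groups]
    else:
        k = int(split)
        idx_groups = [order[chunk] for chunk in np.array_split(np.arange(len(x)), k)]
        labels = [f"bin {i + 1}/{k}" for i in range(k)]
    rows = []
    for label, idx in zip(labels, idx_groups):
        n = len(idx)
        r = int(resp[idx].sum())
        rate, lo, hi = response_rate_ci(r, max(n, 1), conf)
        rows.append({"subgroup": label, "n": n, "responders": r,
                     "median_value": float(np.median(x[idx])) if n else math.nan,
                     "orr": rate, "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


DEFAULT_PLAUSIBILITY = {
    "max_baseline_diameter": 10.0,   # cm
    "min_tumor_teff": 1.0,           # cells at treatment start
}


def screen_cohort(samples: pd.DataFrame, base: PatientParams | None = None,
                  rules: dict | None = None):
    """Run the untreated growth phase for each sampled patient and split the
    cohort into plausible patients and screened-out non-patients.

    A patient is excluded iff the tumor fails to reach the preset initial
    diameter within the growth cap (typically immune-controlled or too slow)
    or a plausibility rule fails.  Returns ``(plausible_rows, excluded_rows,
    grown)`` where ``grown`` maps patient_id to the end-of-growth Trajectory
    for reuse by the treatment phase.
    """
    rules = {**DEFAULT_PLAUSIBILITY, **(rules or {})}
    plausible, excluded, grown = [], [], {}
    for _, row in samples.iterrows():
        params = build_patient(row, base)
        ok, t_reach, y_start = grow_to_baseline(params)
        baseline_d = tumor_diameter(max(float(y_start[0]), 0.0),
                                    params.cell_volume, params.packing)
        reason = None
        if not ok:
            reason = "tumor did not reach initial diameter"
        elif baseline_d > rules["max_baseline_diameter"]:
            reason = "baseline diameter out of bounds"
        elif y_start[3] < rules["min_tumor_teff"]:
            reason = "no tumor T-cell infiltrate"
        if reason is None:
            plausible.append(row)
            grown[int(row["patient_id"])] = (ok, t_reach, y_start)
        else:
            excluded.append({**dict(row), "reason": reason})
    plausible_df = pd.DataFrame(plausible).reset_index(drop=True)
    excluded_df = pd.DataFrame(excluded).reset_index(drop=True)
    return plausible_df, excluded_df, grown


def run_trial(n: int = 2000, seed: int = 0, regimen: Regimen | None = None,
              ranges: ParameterRanges | None = None, t_end: float = 400.0,
              base: PatientParams | None = None, pk: PKParams | None = None,
              rules: dict | None = None, progress: bool = False) -> CohortResult:
    """Generate, screen, treat and classify a virtual cohort.

    Deterministic for a given seed.  Assessments every 14 days plus the
    end-of-treatment day; RECIST classification uses all assessments.
    """
    regimen = regimen or Regimen()
    ranges = ranges or default_parameter_ranges()
    pk = pk or PKParams()
    samples = lhs_sample(ranges, n, seed)
    sampled_names = [c for c in samples.columns if c != "patient_id"]

    assess_t = np.arange(0.0, t_end, ASSESSMENT_INTERVAL_DAYS)
    if assess_t[-1] != t_end:
        assess_t = np.append(assess_t, t_end)

    plausible, excluded, grown = screen_cohort(samples, base, rules)
    rows, assess_rows = [], []
    for i, (_, row) in enumerate(plausible.iterrows()):
        params = build_patient(row, base)
        traj = simulate_patient(params, regimen, t_end=t_end, pk=pk,
                                save_every=ASSESSMENT_INTERVAL_DAYS / 2.0,
                                growth=grown[int(row["patient_id"])])
        pid = int(row["patient_id"])
        d_at = np.interp(assess_t, traj.t, traj.diameter)
        pct = 100.0 * (d_at - traj.baseline_diameter) / traj.baseline_diameter
        cat = classify_recist(traj.baseline_diameter, d_at)
        n_final = float(traj.n_cancer[-1])
        vol = n_final * params.cell_volume / params.packing  # cm^3
        teff_density = traj.teff_tumor[-1] / max(vol, 1e-12)
        treg_density = traj.treg_tumor[-1] / max(vol, 1e-12)
        rows.append({
            "patient_id": pid,
            **{k: float(row[k]) for k in sampled_names},
            "pretreatment_days": traj.pretreatment_days,
            "baseline_diameter_cm": traj.baseline_diameter,
            "best_pct_change": float(pct.min()),
            "final_pct_change": float(pct[-1]),
            "recist": cat,
            "final_tumor_cells": n_final,
            "final_tumor_volume_cm3": vol,
            "teff_density": float(teff_density),
            "treg_density": float(treg_density),
            "teff_treg_ratio": float(traj.teff_tumor[-1] / max(traj.treg_tumor[-1], 1.0)),
        })
        for t_, d_, p_ in zip(assess_t, d_at, pct):
            assess_rows.append({"patient_id": pid, "t": float(t_),
                                "diameter": float(d_), "pct_change": float(p_)})
        if progress and (i + 1) % 50 == 0:
            print(f"  treated {i + 1}/{len(plausible)}")
    patients = pd.DataFrame(rows)
    assessments = pd.DataFrame(assess_rows)
    return CohortResult(patients=patients, excluded=excluded,
                        assessments=assessments, regimen=regimen, seed=seed)
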