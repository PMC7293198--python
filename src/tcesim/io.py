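"""Configuration and parameter-table I/O, run orchestration and manifests.

Parameter tables are flat key-value mappings (JSON or YAML) validated
against the package's parameter dataclasses; tabular outputs are CSV.
Every experiment writes a manifest recording the seed, package version and
a hash of the effective configuration so outputs can be regenerated
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import BindingParams, concentration_scan
from .invitro import (AssaySetup, REFERENCE_HILL, calibrate_hill, lysis_scan,
                      synthetic_dose_response)
from .patient import PatientParams, simulate_patient
from .pk import PKParams, Regimen, plasma_concentration
from .stats import biomarker_report, prcc
from .trial import default_parameter_ranges, run_trial, subgroup_response

log = logging.getLogger("tcesim")

__all__ = ["load_parameter_table", "save_parameter_table", "run_experiment"]

SCHEMAS = {
    "binding": BindingParams,
    "pk": PKParams,
    "patient": PatientParams,
    "regimen": Regimen,
}


def _read_mapping(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return data


def load_parameter_table(path, schema):
    """Load and validate a flat parameter file against a schema.

    ``schema`` is one of "binding", "pk", "patient", "regimen" or a
    dataclass type.  Unknown keys raise; missing keys fall back to the
    documented defaults with a logged notice.  Nested dataclass fields
    (e.g. the patient's binding block) may be given as sub-mappings.
    """
    cls = SCHEMAS.get(schema, schema) if isinstance(schema, str) else schema
    if not dataclasses.is_dataclass(cls):
        raise ValueError(f"unknown schema {schema!r}")
    data = _read_mapping(path)
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = [k for k in data if k not in field_map]
    if unknown:
        raise ValueError(f"{path}: unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        f = field_map[k]
        if isinstance(v, dict):
            sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
            subcls = type(sub) if sub is not None else None
            if subcls is None or not dataclasses.is_dataclass(subcls):
                raise ValueError(f"{path}: key {k!r} does not accept a mapping")
            kwargs[k] = dataclasses.replace(sub, **v)
        else:
            kwargs[k] = v
    missing = [k for k in field_map if k not in data]
    if missing:
        log.info("%s: %d keys missing, using defaults: %s",
                 path, len(missing), sorted(missing))
    return cls(**kwargs)


def save_parameter_table(obj, path) -> None:
    """Write a parameter dataclass as a flat JSON/YAML mapping (round-trips
    exactly through :func:`load_parameter_table`)."""
    d = dataclasses.asdict(obj)
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, workflow: str, seed, config: dict, files) -> None:
    manifest = {
        "workflow": workflow,
        "seed": seed,
        "tcesim_version": __version__,
        "config_hash": _config_hash(config),
        "config": config,
        "outputs": sorted(str(f.name) for f in files),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


WORKFLOWS = ("invitro_scan", "invitro_calibrate", "pk_simulate",
             "patient_simulate", "cohort", "sensitivity")


def run_experiment(workflow: str, outdir, seed: int = 0, **options) -> dict:
    """Execute a named workflow and write its CSV/JSON outputs plus a manifest.

    Returns a dict of the main result objects.  Raises ValueError for an
    unknown workflow name.
    """
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {"workflow": workflow, "seed": seed, **options}
    files, results = [], {}

    if workflow == "invitro_scan":
        grid = np.logspace(options.get("log_lo", -3), options.get("log_hi", 4),
                           options.get("n_points", 141))
        scan = concentration_scan(grid, BindingParams())
        f = outdir / "concentration_scan.csv"
        scan.to_csv(f, index=False)
        files.append(f)
        results["scan"] = scan
    elif workflow == "invitro_calibrate":
        data = synthetic_dose_response(noise_cv=options.get("noise_cv", 0.0), seed=seed)
        fit = calibrate_hill(data)
        f = outdir / "calibration.json"
        f.write_text(json.dumps({
            "d50": fit.hill.d50, "n_hill": fit.hill.n_hill, "k_max": fit.hill.k_max,
            "lambda_crossarm": fit.lambda_crossarm,
            "residual_norm": fit.residual_norm, "converged": fit.converged,
        }, indent=2))
        files.append(f)
        results["calibration"] = fit
    elif workflow == "pk_simulate":
        regimen = Regimen(dose_mg=options.get("dose_mg", 60.0),
                          interval_days=options.get("interval_days", 7.0),
                          n_doses=options.get("n_doses", 58))
        t = np.arange(0.0, options.get("t_end", 400.0) + 0.25, 0.25)
        conc = plasma_concentration(t, regimen, PKParams())
        df = pd.DataFrame({"t_days": t, "conc_nM": conc})
        f = outdir / "plasma_concentration.csv"
        df.to_csv(f, index=False)
        files.append(f)
        results["pk"] = df
    elif workflow == "patient_simulate":
        regimen = Regimen(dose_mg=options.get("dose_mg", 60.0))
        params = options.get("patient_params") or PatientParams()
        traj = simulate_patient(params, regimen,
                                t_end=options.get("t_end", 400.0))
        f = outdir / "trajectory.csv"
        traj.to_frame().to_csv(f, index=False)
        files.append(f)
        results["trajectory"] = traj
    elif workflow == "cohort":
        regimen = Regimen(dose_mg=options.get("dose_mg", 60.0),
                          interval_days=options.get("interval_days", 7.0))
        res = run_trial(n=options.get("n", 200), seed=seed, regimen=regimen,
                        t_end=options.get("t_end", 400.0))
        f1 = outdir / "cohort.csv"
        res.patients.to_csv(f1, index=False)
        f2 = outdir / "excluded.csv"
        res.excluded.to_csv(f2, index=False)
        f3 = outdir / "assessments.csv"
        res.assessments.to_csv(f3, index=False)
        f4 = outdir / "waterfall.csv"
        res.waterfall().to_csv(f4, index=False)
        files += [f1, f2, f3, f4]
        rate, lo, hi = res.orr()
        summary = {"n_sampled": options.get("n", 200),
                   "n_plausible": res.n_plausible, "n_excluded": res.n_excluded,
                   "categories": res.category_counts(),
                   "orr": rate, "orr_ci": [lo, hi]}
        f5 = outdir / "summary.json"
        f5.write_text(json.dumps(summary, indent=2))
        files.append(f5)
        if len(res.patients):
            try:
                bm = biomarker_report(res)
                f6 = outdir / "biomarkers.csv"
                bm.to_csv(f6, index=False)
                files.append(f6)
            except ValueError:
                pass
        results["cohort"] = res
    elif workflow == "sensitivity":
        res = options.get("cohort")
        if res is None:
            res = run_trial(n=options.get("n", 200), seed=seed)
        params = [r.name for r in default_parameter_ranges()]
        X = res.patients[params]
        y = np.log(res.patients["final_tumor_volume_cm3"].to_numpy())
        s = prcc(X, y)
        df = pd.DataFrame({"parameter": s.index, "output": "log_final_tumor_volume",
                           "prcc": s.to_numpy()})
        f = outdir / "prcc.csv"
        df.to_csv(f, index=False)
        files.append(f)
        results["prcc"] = s

    _write_manifest(outdir, workflow, seed, config, files)
    return results
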