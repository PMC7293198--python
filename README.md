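# tcesim

Quantitative systems pharmacology of CEA×CD3 T-cell engagers (TCEs) in
solid tumors — from ternary-complex chemistry to virtual clinical trials.

Bispecific T-cell engagers such as cibisatamab bind carcinoembryonic
antigen (CEA) on cancer cells bivalently and CD3 on T cells monovalently.
Efficacy is driven by the **bivalent ternary complex** (biTTC: two CEA, one
TCE, one CD3), which crosslinks a T cell to a tumor cell; the monovalent
ternary complex (moTTC) is treated as non-functional. `tcesim` is aimed at
modelers in immuno-oncology drug development who want to explore how
binding parameters (affinities, the intrinsic cross-arm binding efficiency
λ), target expression, and patient immunology shape response to TCE
monotherapy.

## What's in the box

| Module | Contents |
|---|---|
| `tcesim.binding` | Mass-action network of TCE–CEA–CD3 binding with cross-arm avidity; closed and bath-mode equilibrium solvers; concentration scans |
| `tcesim.invitro` | Cytotoxicity-assay mini-model (percent lysis vs CEA expression, E/T ratio, dose) and Hill-translation calibration |
| `tcesim.pk` | Two-compartment antibody PK with bolus superposition and fitting |
| `tcesim.patient` | Reduced whole-patient ODE model: four compartments, TMB-driven priming, Teff/Treg trafficking, TCE-enhanced killing and Treg-mediated exhaustion |
| `tcesim.trial` | Virtual cohorts: Latin hypercube sampling, plausibility screening, RECIST v1.1 classification, Agresti–Coull response rates, subgroup tables |
| `tcesim.stats` | PRCC global sensitivity, Wilcoxon rank-sum biomarker comparisons |
| `tcesim.io` / `tcesim.cli` | Parameter tables (JSON/YAML), workflow orchestration with manifests, `tcesim` command line |

The core model quantities:

- binding: reactions `T+A⇌AT`, `AT+A⇌AAT` (rate λ·kon, the intramolecular
  cross-arm step), `T+C⇌TC`, and the ternary closures `TC+A⇌moTTC`,
  `moTTC+A⇌biTTC`, `AT+C⇌moTTC`, `AAT+C⇌biTTC`;
- efficacy: Hill translation `E = biTTC^n / (biTTC^n + d50^n)` of the
  per-synapse biTTC density into enhanced cancer-cell killing;
- tumor: logistic growth minus killing `k·f(Teff:cancer)·(1 + k_max·E)`,
  with TMB (number of activated T-cell clones) driving T-cell priming.

## Worked example

```python
import numpy as np
from tcesim import BindingParams, concentration_scan
from tcesim.binding import peak_concentration

params = BindingParams()          # cibisatamab-like: Kd(CEA)=130 nM, λ=1000
scan = concentration_scan(np.logspace(-3, 4, 141), params)
print(f"peak biTTC {scan['biTTC'].max():.1f} nM-equivalent "
      f"at {peak_concentration(scan):.3f} nM TCE")
```

prints

```
peak biTTC 90.5 nM-equivalent at 0.098 nM TCE
```

i.e. the bell-shaped avidity curve: biTTC rises with drug until free TCE
begins to out-compete the cross-arm step for CEA (~0.1 nM), then declines
slowly over several decades before collapsing at very high concentration —
the kinetic basis of the wide therapeutic plateau of avid TCEs.

A scaled-down virtual trial from the command line:

```bash
tcesim cohort run --n 200 --seed 1 --dose-mg 60 --out trial_out
```

```
181 plausible / 19 excluded; ORR 7.2% (95% CI 4.1-12.0)
```

Nineteen of 200 sampled patients never present (their tumor is too slow or
immune-controlled); of the rest, ~7% reach PR/CR by RECIST after 400 days
of weekly dosing, all of them above the cohort's median TMB and above
1e4 CEA sites/cell. `trial_out/` contains per-patient parameters and
endpoints, the assessment time series, a waterfall table, a biomarker
report and a manifest for exact replay.

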