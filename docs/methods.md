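# Methods

This note documents the model equations, the provenance and meaning of the
default parameters, the design decisions taken where the design was open,
and what the synthetic data used for calibration and testing can and
cannot establish.

## Ternary-complex binding

Species: free TCE (`T_free`), free CEA (`A_free`), free CD3 (`C_free`),
the dimers `AT` (one CEA arm bound), `TC` (CD3 bound), the avid dimer
`AAT` (both CEA arms on one cell), the ternary complexes `moTTC`
(CEA–TCE–CD3) and `biTTC` (CEA–CEA–TCE–CD3), and the soluble-CEA sink
`sAT`. Mass action with these rate conventions, stated once in
`constants.py`:

| step | on-rate | off-rate |
|---|---|---|
| T + A ⇌ AT | 2·kon_CEA (two free arms) | koff_CEA |
| AT + A ⇌ AAT | λ·kon_CEA (intramolecular) | 2·koff_CEA (two bound arms) |
| T + C ⇌ TC | kon_CD3 | koff_CD3 |
| TC + A ⇌ moTTC | 2·kon_CEA | koff_CEA |
| moTTC + A ⇌ biTTC | λ·kon_CEA | 2·koff_CEA |
| AT/AAT + C ⇌ moTTC/biTTC | kon_CD3 | koff_CD3 |
| T + sCEA ⇌ sAT | 2·kon_CEA | koff_CEA |

λ, the intrinsic cross-arm binding efficiency, multiplies only the
intramolecular second-arm association; it never alters off-rates. The
network satisfies detailed balance, so the closed-system equilibrium is
unique and path-independent:
`biTTC = λ·Kd_CEA⁻²·Kd_CD3⁻¹·T·A²·C` (up to the statistical factors
above). Soluble CEA is an inert sink (default 0).

Two equilibrium views are provided. `solve_equilibrium` conserves all
three totals (closed compartment); `concentration_scan`'s default "bath"
mode clamps *free* TCE at the scanned value, because physiologically the
tumor's drug level is set by plasma PK (a reservoir) and in vitro the
medium volume dwarfs the settled cell layer. The closed solver is a damped
fixed point polished by a Newton-type root solve in log space (residual
tolerance 1e-9, scaled), with a stiff-ODE fallback; the bath solver
alternates the closed-form conditional solutions for free CEA (quadratic)
and free CD3, falling back to a bracketed 1-D root when extreme avidity
makes the alternation cycle.

### Sites → concentration, and the interface convention

Surface receptors are converted to volumetric nM via Avogadro's number at
*interface-effective* cell densities: bulk density (cancer 3e8 cells/mL,
T cells 3e7 cells/mL) times an enrichment factor (default 30) expressing
that binding happens in the cell–cell interface region, not the bulk
volume. biTTC is treated as a *per-synapse* quantity: a synapse pairs one
T cell with one target cell, so the interface CD3 density uses the
cancer-cell density. The enrichment factor and the CD3 arm Kd (default
1 nM, the midpoint of the published affinity scan; the reported
quantity is koff with kon fixed at 1e-4 nM⁻¹s⁻¹) were calibrated
*jointly, once*, so that the reference scan reproduces the published
location of the biTTC maximum (~0.1 nM) and the published λ-sensitivity
pattern across CEA expression (strong effect at 5e3–5e4 sites/cell,
near-insensitivity at 5e5 where the TCE itself is the limiting reagent).

### A known, deliberate discrepancy

The published scans report that *weaker* CD3 binding yields *more* biTTC
at low/moderate CEA expression. In this reaction network that ordering is
thermodynamically impossible: detailed balance makes equilibrium biTTC
monotonically increasing in CD3 affinity, and finite-time kinetics
equilibrate through association-only paths (verified by direct ODE
integration at 1 h–48 h readouts). The inversion presumably requires
mechanisms outside this module — e.g. a whole-body CD3 sink in lymphoid
tissue that sequesters high-affinity drug. The corresponding test is left
failing rather than weakened; treat CD3-affinity *rankings* from this
package as module-level chemistry only.

## In-vitro cytotoxicity and Hill calibration

The assay model mirrors LDH-release killing assays: cancer cells plus
effectors at an E/T ratio, TCE at a nominal concentration (clamped — the
medium is a reservoir), readout at 48 h. Effector coverage of targets
saturates in the E/T ratio with half-saturation 2 (killing is reported to
saturate near E/T 10:1). Percent lysis relative to the untreated control
reduces to `100·(1 − exp(−cov·k_max·E(biTTC)·t))` with
`E = biTTC^n/(biTTC^n + d50^n)`.

Reference calibration (`REFERENCE_HILL`): n = 3, k_max = 1.5/day, and
d50 = 248.2 nM-equivalent chosen so that, at 20 nM TCE and E/T 10:1, lysis
first exceeds 5 % of its maximum at 1.0e4 CEA sites/cell — the published
expression threshold. Because the underlying cell-line dose–response data
exist only as figures, calibration correctness is established by
*parameter recovery*: `calibrate_hill` refits the generating parameters
from synthetic dose–response tables exactly (noiseless) and to ~20 %
(5 % multiplicative noise, 20 points). The four-cell-line panel
(MKN45 > LS174T > HT-29 > CCD-841 in CEA) reproduces the published lysis
ordering.

## Pharmacokinetics

Two-compartment linear disposition, analytic biexponential with bolus
superposition. Vc = 3.45 L is the clinically reported central volume; the
remaining defaults (k_el 0.25/day, k12 0.30, k21 0.35, MW 194 kDa for an
IgG-based 2+1 format) are package choices giving an antibody-like
terminal half-life of about a week. Tumor exposure is
`tumor_partition × plasma` (quasi-steady state) with default 0.03, in the
low range of antibody tumor:plasma ratios; it places the 60–600 mg weekly
window on the flat plateau of the biTTC curve, which is what makes the
simulated response dose-insensitive across that span. The partition is a
single isolated function so a transport ODE can replace it. Fitting is
validated by synthetic recovery (within 15 % under 10 % noise).

## Whole-patient model

Seven ODE states: cancer cells and Teff/Treg in central, peripheral and
tumor compartments; the TDLN appears as a priming source with constant
naive pools.

- Priming: `k_prime · TMB · g(Kd_MHC) · N/(N + antigen_n50)` into central.
  TMB is the number of activated T-cell clones. `g(Kd) = Kd50/(Kd50+Kd)`
  with Kd50 = 1e-7 M expresses poorer priming above 1e-7 M antigen–MHC II
  affinity; the antigen gate ties priming to tumor burden (no antigen, no
  activation), which both lets microscopic tumors escape surveillance and
  stabilises partial responses.
- Trafficking: central ⇌ peripheral (0.1 / 0.05 per day); entry into the
  tumor scales with tumor (vascular) volume, `k_ct·N/(N + 3e10)`, keeping
  the Teff:cancer ratio roughly size-independent.
- Killing: `f·(k_kill_base + k_max·E_kill(biTTC_Teff))` with
  `f = Teff/(Teff + N + offset)` the effector-availability factor. The
  baseline rate (0.05/day) is deliberately small: pre-treatment
  cytotoxicity is checkpoint-suppressed in this disease setting (the
  checkpoint is not modelled explicitly), while the TCE redirects T cells
  at up to k_max = 10/day — serial killing of redirected lysis.
- Exhaustion: Teff die at `teff_death + cancer-dependent death
  (1.0·N/(N+3e9)) + k_exh·E_exh(biTTC_Treg)·f_reg` — the two Hill
  translations (killing from biTTC on Teff, exhaustion from biTTC on Treg)
  are distinct; both use the calibrated d50/n. With realistic Treg
  infiltrates the exhaustion term is numerically negligible, matching the
  published conclusion that the Treg effect on outcome can be ignored.
- biTTC inside the ODEs is quasi-equilibrium (binding seconds vs cellular
  days), evaluated per pool (Teff vs Treg CD3 densities) through an
  80-point monotone log-log spline in drug concentration (error well below
  solver tolerance).

Simulation is two-phase: growth from one cell to the preset initial
diameter (event-detected; cap 4000 days ≈ 11 years — tumors slower than
that are non-patients), then 400 days of treatment integrated piecewise
between boluses (LSODA, rtol 1e-6). Diameter is the spherical equivalent
of the cell count at 1e-9 cm³/cell and packing 0.8.

## Virtual trial

Twelve parameters are sampled by Latin hypercube, uniform on a linear or
log scale (`default_parameter_ranges`): TMB 10–2000 clones (log), growth
rate 0.005–0.03/day, presentation diameter 2–5 cm (linear), CEA 1e3–1e6
sites/cell, CD3 on Teff and Treg 3e4–1.2e5 sites/cell (the measured
range), MHC II Kd 1e-9–1e-6 M, baseline killing 0.01–0.1/day, Teff death
0.05–0.3/day, Treg/Teff priming ratio 0.1–1, λ 10–1e4, CD3 koff
1e-5–1e-3 s⁻¹ (kon fixed). Ranges are package choices spanning the
physiologically plausible inter-patient variability; k_prime
(1.2e6 cells/day/clone) was calibrated once so the cohort composition
approximates the published trial (≈7 % PR/CR, ≈86 % PD, ≈12 % screened
out).

Screening excludes patients whose tumor never reaches the initial
diameter within the cap (too slow, or immune-controlled) plus configurable
plausibility rules (baseline diameter ≤ 10 cm, a non-empty tumor T-cell
infiltrate). RECIST v1.1 on the single-lesion proxy with best-response
semantics: CR below a 2 mm detectability floor; PR at best change ≤ −30 %;
PD at ≥ +20 % from nadir at the final assessment with a 5 mm absolute
guard; otherwise SD; assessments every 14 days plus day 400. Response
rates carry Agresti–Coull 95 % intervals; subgroups split at the median or
into equal-count bins.

PRCC follows standard LHS practice: rank-transform everything, residualise
each parameter and the output against the other parameters by OLS with
intercept, correlate the residuals. Wilcoxon rank-sum comparisons use
exact enumeration for small tie-free samples and the tie-corrected normal
approximation otherwise; comparisons are reported unadjusted (a
Benjamini–Hochberg flag exists).

## What the synthetic data do and do not show

All fixtures are generated by the package itself (the in-vitro
dose–response generator, the LHS cohort engine); no clinical or cell-line
measurements ship with the code. Passing tests therefore demonstrate
internal consistency — solver correctness against independent ODE/
enumeration/closed-form oracles, recovery of known generating parameters,
and reproduction of the published qualitative structure (expression
threshold, bell-shaped avidity curve, λ-sensitivity pattern, TMB/CEA
response gating, dose insensitivity). They do not demonstrate predictive
accuracy for real patients: cohort percentages depend on sampling ranges
that are package choices, the single-lesion RECIST proxy ignores
multi-lesion bookkeeping, naive T-cell pools are constant (responses in
large tumors are likely overestimated), Tregs do not kill cancer cells,
and no checkpoint drug, cytokine release or ADA is modelled.

## Numerical choices

- Equilibrium residual tolerance 1e-9 (scaled); equilibrium–ODE agreement
  verified to <1e-5 relative on random parameter draws.
- Hill function evaluated in log space (no overflow at extreme
  coefficients); calibration fits positive parameters in log space with
  data-driven starts and box bounds (trf).
- LSODA everywhere; patient rtol 1e-6, atol 1e-3 cells; binding oracle
  integrations rtol 1e-12.
- Peak location on scans refined by log-parabolic interpolation around the
  grid argmax; the lysis threshold by log-linear interpolation between
  grid points.
- Cohort runs are deterministic given the master seed (scipy's seeded
  Latin hypercube; no other randomness), so scaled-down tests use a fixed
  seed and n = 200 — the size that keeps a full screening + treatment +
  dose-comparison sweep within a few minutes on one CPU; the same code
  runs n = 2000 unchanged.
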