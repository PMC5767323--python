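# Methods

## The equilibrium model

A protein P (here a transcription-factor dimer, the DNA-binding unit) binds
a double-stranded DNA fragment X with dissociation constant K_d and,
independently of DNA, an effector ligand L with dissociation constant
K_d,oxo. The two binding events are coupled by the cooperativity interaction
constant α: the ternary complex P·L·X is favored by a factor α over what the
two independent affinities predict. Averaging over the effector-bound and
effector-free protein states gives the apparent DNA affinity measured at a
fixed effector concentration,

    K_d,app([L]) = K_d (1 + [L]/K_d,oxo) / (1 + α[L]/K_d,oxo).

The curve runs monotonically from K_d at [L] = 0 to K_d/α at saturating
effector. Two derived constants are reported alongside the three fitted
ones:

* **K_d,eff = K_d/α** — the limiting DNA affinity at saturating effector.
* **K_d,oxo,eff = K_d,oxo/α** — the effector concentration at which the
  change in K_d,app is half-maximal. The linkage is reciprocal: the same
  quantity is the protein–effector dissociation constant at saturating DNA.
  The identity K_d,app(K_d,oxo/α) = (K_d + K_d/α)/2 holds exactly and is
  asserted in the property suite.

`classify_cooperativity` labels α > 1 as positive, α < 1 as negative, and
treats a configurable band around 1 (default ±0.05) as "none".

## Units

Units are split, not converted: the K_d family is µM, the K_d,oxo family and
effector concentrations mM, volumes µL, raw heats µcal, molar enthalpies
kcal/mol. Operations validate rather than silently rescale; the only
conversion in the package is `normalize_heats` (µcal → kcal per mol of
injectant).

## Single-site thermogram model

The bound-complex concentration is the physical root of
[MX]² − (Mₜ+Xₜ+K_d)[MX] + MₜXₜ = 0, computed in the numerically stable form
2MₜXₜ/(b + √(b² − 4MₜXₜ)) with the discriminant expanded as
(Mₜ−Xₜ)² + K_d² + 2K_d(Mₜ+Xₜ) to avoid cancellation; for
K_d < 10⁻⁶·min(Mₜ,Xₜ) the stoichiometric (tight-binding) limit is returned
directly. An exact-arithmetic bisection oracle in the test suite pins this
to 10⁻⁹ relative over six concentration decades.

Incremental dilution follows the overfill/displacement convention of
commercial ITC analysis: after injection *i*, species initially in the cell
are diluted by (1 − dV/V₀)ⁱ and the titrant has accumulated to
X_syr(1 − (1 − dV/V₀)ⁱ). The measured heat of injection *i* is

    q_i = Q_i − Q_{i−1} + (dV/V₀)(Q_i + Q_{i−1})/2 + q_offset,

with Q_i = V₀·ΔH·[MX]_i the cell's heat content and the middle term the
mean-concentration correction for complex carried out with the displaced
volume. q_offset is a constant per-injection background (heat of dilution);
no separate blank-titration subtraction is modelled. A step-by-step
brute-force oracle pins this convention to 10⁻⁸ relative.

Protein concentrations may be given on a monomer basis with
`monomer_per_site` (default 2: dimer binding unit), so the quoted 5 and
10 µM monomer loadings become 2.5 and 5 µM binding sites.

## Fitting

**Stage 1 — per titration.** `fit_single_site` minimizes squared residuals
between observed and modelled heats over (log K_d,app, ΔH, log n, q_offset);
n and/or q_offset can be fixed. Initial ΔH comes from the total evolved
heat; a four-point ladder of K_d starts (sites × {10⁻², 10⁻¹, 1, 10}) guards
against the shallow optima of low-c isotherms. The c-value
(n·[sites]/K_d,app) is recorded and fits with c outside [1, 1000] are
flagged non-identifiable — they converge, but the affinity rests on the
gentle curvature of a nearly featureless isotherm. Flat thermograms (heat
variance below a noise floor) raise "binding signal absent" rather than
returning a spurious fit. Standard errors are asymptotic (Jacobian at the
optimum, delta method for log-parameters).

**Stage 2 — across effector levels.** `fit_linkage` fits the linkage
equation to (effector, K_d,app) points by least squares in
(log K_d, log K_d,oxo, log α). Residuals are taken on log K_d,app by default:
the curve spans an order of magnitude and log residuals keep the
zero-effector point from dominating; inverse-variance weighting and linear
residuals are options (weighted and unweighted fits coincide when all SEs
are equal). Initialization is a multi-start grid — K_d⁰ from the
lowest-effector point, α⁰ from the empirical span
K_d,app(min)/K_d,app(max) plus fixed starts {0.5, 2, 10, 30} (the fixed
values cover negative-cooperativity truths), K_d,oxo⁰ ∈ {1, 10, 100} mM —
with the best final residual winning and ties broken toward smaller α.
Convergence tolerances are 10⁻¹⁴ (relative), 10⁴ evaluations per start.
Datasets whose K_d,app spread is below 10⁻⁶ relative — or below twice the
points' median relative SE when SEs are provided — return α = 1 with a
`no_detectable_linkage` flag instead of a degenerate three-parameter fit;
`fix_alpha=1.0` supports the mutated-promoter case explicitly. Fewer than
three distinct effector levels raises "underdetermined".

**Uncertainty.** Asymptotic SEs by default. `bootstrap_linkage` gives
percentile intervals: parametric (lognormal around the fitted curve with the
points' SE-implied CVs) when every point has an SE, residual resampling on
the log scale otherwise; replicate fits warm-start from the full-data
optimum. Deterministic under a fixed seed.

**Two-stage rather than global.** Each titration is reduced to one K_d,app
first, then the K_d,app series is fit — mirroring how such experiments are
analysed in practice (each titration is an independent instrument run). A
global fit across all thermograms is a possible extension, not the default.

## Synthetic data

No public raw data exists for this system, so the generator reproduces the
experimental design: 200 µL cell (nominal small-cell geometry; the 2 µL
injection volume and 150 s spacing are as specified, cell volume and the
19-injection count are conventional defaults and remain protocol fields),
25 °C, protein at 5 µM monomer (SS120, MED4) or 10 µM (MIT9313), dsDNA at
50 or 100 µM respectively, effector at {0, 1, 5, 10} mM. Ground-truth
linkage constants are the six fitted parameter sets (three wild-type
promoters, three mutated promoters with α = 1; the mutated presets carry a
nominal K_d,oxo = 1 mM, inert when α = 1). The assumed enthalpy is
−10 kcal/mol — none is reported for these interactions, the value is typical
for protein–DNA association, and it is a visible parameter, never baked in.

Noise is placed where the two data types acquire it: additive Gaussian on
per-injection heats (instrument-like) and multiplicative lognormal on
K_d,app points (fit-error-like), the latter with σ_log = √log(1+cv²) so the
linear-scale CV equals the nominal value; simulated SEs are cv·K_d,app.
Every stochastic call requires a seed and is bit-reproducible. What the
generator does **not** emulate: baseline drift, injection-peak integration
from raw power traces, titrant heat-of-dilution structure beyond a constant
offset, and replicate-to-replicate protocol variation — so passing tests
demonstrate correctness of the inference chain under the stated noise model,
not robustness to every artifact of real thermograms.

## Problem sizes in the recovery study

The stochastic recovery experiment uses 200 replicate datasets of 8 effector
levels on [0, 10] mM with 3 % CV noise, and 200-replicate bootstraps per
dataset — sizes at which the medians and the coverage proportion are stable
to a couple of percentage points while the whole study completes in about a
minute on one CPU.

## Known limitations

* With ~4 effector levels and realistic noise, K_d,oxo and α are only
  jointly identified: their ratio (the half-effect concentration) is well
  pinned while each factor alone can drift by orders of magnitude, with the
  asymptotic SEs blowing up accordingly. The recovery suite asserts this
  asymmetry rather than hiding it; denser effector grids or effector
  concentrations past the half-effect point restore identifiability.
* Low-c titrations (e.g. 2.5 µM sites against a ~7 µM K_d) cannot determine
  stoichiometry and affinity jointly once heat noise is present; fixing
  n at its design value is the supported remedy and the c-value flag marks
  every such fit.
* Reported ± values are this package's own asymptotic SEs (or bootstrap
  intervals); published ± values for this system have unstated provenance
  and are not reproduced numerically.
* Single-site binding only: no multi-site, sequential or kinetic models,
  no ΔCp/temperature dependence, no enthalpy–entropy decomposition.
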