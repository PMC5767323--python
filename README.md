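# itclink

Isothermal-titration-calorimetry (ITC) analysis of effector-modulated
transcription-factor/DNA binding: per-titration single-site fits yielding
apparent dissociation constants, and a heterotropic ternary-linkage model
that converts the Kd_app-vs-effector curve into an intrinsic affinity, an
effector affinity, and a cooperativity constant.

The package was built around a concrete system — the cyanobacterial nitrogen
regulator NtcA from three *Prochlorococcus* strains (MIT9313, SS120, MED4)
binding the *glnA* promoter, with 2-oxoglutarate (2OG) as the effector that
signals carbon/nitrogen imbalance — but the machinery applies to any
protein–ligand interaction allosterically coupled to a second ligand.

## The model

Each titration (protein in the cell, dsDNA titrant in the syringe, effector
at a fixed concentration) is fit with the standard single-site incremental
heat model (1:1 dsDNA : protein-dimer stoichiometry): the bound-complex
concentration after injection *i* is the stable root of

```
[MX]² − (Mₜ + Xₜ + K_d)[MX] + Mₜ·Xₜ = 0
```

and the injection heat is the dilution-corrected increment of
V₀·ΔH·[MX]. Each run yields one apparent dissociation constant
K_d,app at its effector concentration.

The ternary linkage between protein P, DNA and effector L is summarized by
three constants — the intrinsic K_d (no effector), the effector dissociation
constant K_d,oxo (no DNA), and the cooperativity interaction constant α —
through

```
K_d,app([L]) = K_d · (1 + [L]/K_d,oxo) / (1 + α[L]/K_d,oxo)
```

α > 1 is positive heterotropic cooperativity (effector tightens DNA
binding), α < 1 negative, α = 1 no linkage. Two derived constants carry the
biology: **K_d,eff = K_d/α**, the limiting DNA affinity at saturating
effector, and **K_d,oxo,eff = K_d,oxo/α**, the effector concentration at
which half the maximal change in K_d,app is reached (by reciprocity, also
the effector affinity at saturating DNA).

Both stages use nonlinear least squares (`scipy.optimize.least_squares`,
log-parameterized for positivity, multi-start initialization), with
asymptotic standard errors and an optional bootstrap.

## Worked example

```python
from itclink import (LinkageParameters, effective_constants, kdapp_linkage,
                     classify_cooperativity)

params = LinkageParameters(kd_intrinsic=0.97, kd_oxo=19.0, alpha=17.0)  # MIT9313
for oxo in (0.0, 1.0, 5.0, 10.0):
    print(f"[2OG] = {oxo:4.1f} mM  ->  Kd_app = {kdapp_linkage(oxo, params):.3f} uM")
eff = effective_constants(params)
print(classify_cooperativity(params.alpha), eff.kd_eff, eff.kd_oxo_eff)
```

prints

```
[2OG] =  0.0 mM  ->  Kd_app = 0.970 uM
[2OG] =  1.0 mM  ->  Kd_app = 0.539 uM
[2OG] =  5.0 mM  ->  Kd_app = 0.224 uM
[2OG] = 10.0 mM  ->  Kd_app = 0.149 uM
positive 0.057058823529411766 1.1176470588235294
```

— i.e. 2OG drives this transcription factor from ~1 µM to ~60 nM promoter
affinity (17-fold), with half of that change reached at ~1.1 mM 2OG.
`examples/` contains five narrative scripts covering the linkage curve,
single-titration simulation + refit, the noisy linkage fit with bootstrap
intervals, the cross-strain comparison (SS120 and MED4 bind ~7× and ~5×
more weakly than MIT9313), and the full pipeline.

A thin CLI mirrors the library:

```
itclink simulate --preset MIT9313 --out-dir sim/
itclink fit-titration sim/MIT9313_oxo0mM.csv
itclink fit-linkage sim/MIT9313_kdapp.csv --bootstrap 500 --seed 1
itclink report --config config.yaml --out results.json
```

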