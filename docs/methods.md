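# Methods

This note records the model, the conventions and the genuinely open design
choices behind `cholmech`, in the package's own words.

## The mechanistic chain

The engine predicts cholestatic liability by comparing a compound's
therapeutic exposure with the exposure needed to inhibit hepatic
transporters in vivo:

IC50 (in vitro, per transporter) → plasma concentration (mg/L) →
equivalent oral dose (QIVIVE) → correction by K → rule-based comparison
with the therapeutic dose T_D.

All four stages are deliberately linear or monotone, which gives the
pipeline strong testable invariants (dose linearity, K-monotonicity,
rule monotonicity) that the test suite and the acceptance script verify.

## PBTK model

Six flow-limited compartments — gut, liver, lungs, arteries, veins,
kidneys — plus a gut-lumen depot. Oral administration adds
`f_abs × dose` to the depot; absorption is first-order (`ka`). The liver
receives the portal (gut) outflow plus hepatic arterial flow, so oral
input is subject to first-pass extraction. Elimination is:

- hepatic: `fub · CLint_scaled · C_liver/P_liver` (well-stirred liver,
  clearance applied to the venous liver concentration);
- renal: `GFR · fub · C_art` (filtration of free drug from arterial
  blood).

Cardiac output not assigned to gut, liver or kidneys passes through a
direct artery→vein shunt so the circulation closes; that "rest of body"
is not a distribution volume, which keeps the model fully determined by
the two compound inputs the schema provides (FUB, CLint).

**CLint scaling.** CLint in µL/min/10⁶ hepatocytes × hepatocellularity
(110×10⁶ cells/g) × liver mass (1800 g) gives µL/min; ×60/10⁶ converts to
L/h. E.g. CLint = 10 → 118.8 L/h.

**Closed form.** Every term is linear, so the average steady-state plasma
concentration under a repeated oral dose rate D (mg/kg/day) is exactly

```
Css = F_h · (D · BW · f_abs / 24) / (CL_h + GFR·fub) / Rbp
F_h  = Q_L / (Q_L + fub·CLint_scaled)      (hepatic availability)
CL_h = F_h · fub · CLint_scaled            (well-stirred hepatic clearance)
```

with Q_L the total liver blood flow (portal + arterial). This is the
standard oral well-stirred result, including first-pass loss; it is the
algebraic steady state of the ODE system, and the suite checks ODE ↔
closed-form agreement at the 5% level (observed: solver precision).
In the renal-only limit (CLint = 0, fub = 1) it reduces to
`D·BW·f_abs/(24·GFR)`.

**Css definition.** Css is the *time average* of the plasma concentration
over the final dosing interval, not the trough or peak — the quantity the
closed form returns. It is computed from a co-integrated AUC state, not
by quadrature over sampled output, so sharply peaked profiles (fast
absorption, fast clearance) do not bias it.

**Numerics.** LSODA, rtol 1e-8, atol 1e-10, 48 output points per dosing
interval; each administration restarts the integrator with a bolus added
to the depot. Cumulative hepatic and renal elimination are co-integrated
and the maximum relative mass-balance error is reported on every
simulation (observed ≤ 1e-12; the contract is 0.1%). Simulation length
for steady-state work is chosen per compound as ~7 terminal half-lives
(`days_to_steady_state`, capped at 40 days in the tests), since low-
clearance compounds accumulate slowly.

**Default physiology** (one YAML file, `cholmech/data/`): 70 kg adult,
cardiac output 350 L/h, liver flow 90 L/h (67.5 portal + 22.5 arterial),
kidney flow 66 L/h, GFR 6.7 L/h, liver 1800 g, hepatocellularity
110×10⁶ cells/g, ka 2.16 h⁻¹, f_abs 1, blood:plasma ratio 1. Tissue
partition coefficients default to 1 — steady-state plasma levels are
clearance-dominated, and no per-compound partition inputs exist in the
schema; partitions only shift the transient shape and Vss, both
overridable.

## QIVIVE and the correction factor

`qivive_dose(IC50, MW, params) = (IC50·MW/1000) / Css(1 mg/kg/day)` —
valid by linearity; simulating the returned dose reproduces the IC50 as
the steady-state plasma level (checked at 5%, observed ~1e-6).

K **divides** the extrapolated dose. The field uses uncertainty factors
in both directions, so the convention is stated prominently: with
division, K > 1 lowers the dose threshold and flags *more* compounds
(conservative). `invert_k=True` multiplies instead. The positive set is
provably non-shrinking in K under all three rules.

## Decision rules and score

Votes are strict: a transporter votes positive iff T_D (mg/kg/day) is
*higher than* its corrected in vivo dose; a tie votes negative. OR = ≥1
vote, AND = all votes, MAJORITY = strictly more than half. T_D arrives as
mg/day and is divided by body weight to share units with the QIVIVE dose.
For every vote pattern AND ⇒ MAJORITY ⇒ OR (verified exhaustively for
panels of 1–8).

The continuous ranking score for AUC is the positive-vote fraction — the
natural graded version of the rules; it is isolated in one place and easy
to replace.

## QSAR panel

Features: 2048-bit Morgan fingerprint (radius 2) + MW, logP, TPSA, HBD,
HBA, rotatable bonds; largest fragment kept, canonicalization first, so
any SMILES spelling of a structure maps to one vector. The recipe is
stamped (`feature_spec_id`) into trained panels and checked at predict
time.

Targets are pIC50 (−log₁₀ molar); predictions return to µM via
`10^(6−pIC50)`, which guarantees positive IC50s. Hyperparameters are
fixed, recorded defaults: RF 500 trees; SVR (RBF) with a small 5-fold CV
grid over C ∈ {10, 100, 1000} and γ ∈ {scale, 1e-3, 1e-4} behind a
standard scaler; XGBoost 300 rounds, depth 6, learning rate 0.05. All are
single-threaded and seeded, so RF/XGBoost refits are bit-identical and
SVM fits deterministic. Panels persist as one joblib file per transporter
plus a JSON manifest (algorithm map, seeds, feature spec).

No applicability-domain filter is applied; that is a known limitation.

## Synthetic data generator

The generator emulates the shape of a curated cholestasis reference set:
drug-like structures (a frozen, validated library of ~214 real drug
SMILES), FUB log-uniform in [0.01, 1], CLint log-uniform in
[1, 100] µL/min/10⁶ cells, maximum doses log-uniform in
[5, 1000] mg/day (all spanning orders of magnitude, as real data do), and
a default size of 426 compounds.

Each transporter's "true" pIC50 surface is a linear function of the
standardized physchem block with seed-derived weights, centred at
pIC50 = 5 and scaled so the signal explains `signal_strength` of the
target variance given `noise_sd` (signal SD = noise_sd·√(s/(1−s));
defaults 0.8 and 0.5 → signal SD 1). Labels are produced by *running the
generative rule*: OR over all eight transporters at K = 1 against the
sampled T_D, using the noise-free surfaces. Consequently a pipeline
holding the exact oracle models reproduces the labels with accuracy 1.0 —
the end-to-end identity the tests assert — and with the defaults the
classes split roughly evenly (~50–60% positive).

What passing these tests shows: the mechanistic chain is internally
consistent and the learners recover a learnable signal. What it does not
show: performance on real chemistry — the planted surface is far simpler
than real transporter pharmacology, real labels are noisy, and the
library's chemical space is small.

## Problem sizes

Unit tests use 60–200-compound batches; QSAR skill checks train on 426
compounds per transporter with a fixed 80/20 split; PBTK property checks
use 20 randomized parameter sets (fub ∈ [0.01, 1],
CLint ∈ [0, 100]). The acceptance script mirrors these sizes.

## Known limitations

- Human physiology only; no population variability; linear clearance only.
- Partition coefficients default to 1 (transient shape approximate).
- The transporter models are regressors on a pluggable descriptor set;
  no claim of parity with any previously published trained models.
- Comma-decimal input files are not supported (period decimal only).
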