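# Methods

This note documents the models implemented in `neonoxy`, the choices made
where the underlying physiology admits more than one defensible
formulation, and what the synthetic-data tests do and do not demonstrate.

## Gas exchange and the shunt/V:Q forward model

The alveolar gas equation is used in its simplified clinical form,
PAO2 = FiO2·(Pb − PH2O) − PaCO2/RQ, with Pb = 760 mmHg, PH2O = 47 mmHg and
RQ = 0.8 by default (all configurable via `PhysioConstants`). The
correction term FiO2·PaCO2·(1 − RQ)/RQ is omitted; at the FiO2 and PaCO2
ranges of a step-down protocol it changes PAO2 by a few mmHg and none of
the downstream inferences.

The oxyhemoglobin dissociation curve is the Severinghaus closed form
S(P) = 1/(1 + 23400/(P³ + 150P)). It was chosen because it is a single
invertible expression (the inverse is the real Cardano root of
P³ + 150P = 23400·S/(1 − S), exact to machine precision) and is accurate
to about 0.005 saturation against tabulated adult human data over
20–150 mmHg. No temperature, pH or fetal-hemoglobin corrections are
applied; the curve is a configurable hook, and a left-shifted neonatal
curve would change the absolute fitted V:Q displacement but not the
recovery properties that the tests establish.

Oxygen content is CO2 = 1.34·Hb·S + 0.003·P mL/dL. Hemoglobin defaults to
10 g/dL, typical for a 5-day-old piglet, and can be set per analysis.

The FiO2–SaO2 forward model has two free parameters. A rightward
displacement ΔVQ (mmHg) of the effective end-capillary PO2,
Pc = max(PAO2 − ΔVQ, 0), is a deliberately coarse one-parameter summary of
ventilation:perfusion inhomogeneity: it reproduces the characteristic
rightward slide of the FiO2–SaO2 curve without attempting multi-compartment
recovery (a MIGET-style distribution is unidentifiable from four FiO2
steps and is an explicit non-goal). Shunt mixes venous blood into arterial
by the Berggren relation; the venous side is closed by a fixed assumed
arteriovenous content difference avDO2 = 2.3 mL/dL (configurable), i.e.
Cv = max(Ca − avDO2, 0), solved by damped fixed-point iteration on Ca
(damping 0.7, tolerance 1e-8 mL/dL, at most 100 iterations — the map is a
contraction with rate Qs/Qt, so for any shunt below 1 this converges far
inside the budget). Arterial saturation is then recovered by inverting the
content relation for PaO2 with a fixed-count vectorized bisection (90
iterations on [0, max(700, Ca/0.003)]), which keeps the whole forward
model array-oriented and free of per-point root-finder state.

The fit minimizes the sum of squared SaO2 residuals over a deterministic
exhaustive grid (Qs/Qt from 0 to 0.6 in steps of 0.01; ΔVQ from 0 to
200 mmHg in steps of 2) followed by Nelder–Mead refinement from the best
cell. There is no random restart; the two-parameter surface is smooth and
the grid is fine enough that refinement is local polishing. When every
measured SaO2 equals 1.0 the shunt parameter is unidentifiable and the fit
returns Qs/Qt = 0 with a warning rather than an arbitrary interior value.
SaO2 inputs are accepted as fractions or percent; values in (1, 2] are
rejected as ambiguous rather than guessed at.

## Regional NIRS processing

FOE is computed on fractions and reported as a fraction. Deltas from
baseline are relative, (value − baseline)/baseline, with each animal as
its own control; a missing baseline is an error naming the animal and
site, never silently imputed. The cerebral risk flags use strict
inequalities — rcSO2 < 45% and a relative drop > 20% — so readings exactly
at threshold are not flagged.

SaO2-range binning uses half-open intervals [lower, upper) with the top
bin closed at 100, so a reading at exactly 95.0% falls in 95–100. The
four-row scheme (95–100, 90–95, 85–90, < 85) is the default. Bin
percentages are rounded half-up to integer percent. One caveat documented
here deliberately: in the published summary table this package ships as a
fixture, the control 95–100 cell prints "1 (5%)" although 1/17 = 5.9%
rounds to 6% under the same rule every other cell obeys; the packaged
observation-level reconstruction therefore reproduces that cell's count
but computes 6%.

## Autoregulation nomogram and attribution

The cited clinical nomograms for cerebral flow regulation are not
reproduced numerically anywhere we could extract them from, so the
expectation model is a transparent piecewise-linear multiplicative form
with fully exposed parameters: an autoregulatory plateau between 40 and
90 mmHg mean BP with pressure-passive decline of 1% of expected rcSO2 per
mmHg below the plateau; CO2 vasoreactivity of 3% per mmHg PaCO2 deviation
from 40; and hypoxic flow augmentation of 1.2% per mmHg PaO2 below
50 mmHg. These defaults are physiologically plausible for neonates but are
*defaults*, not calibrated constants — every quantitative guarantee in the
test suite is a closed-form identity or a ground-truth-recovery statement
that holds for any admissible parameterization, not a claim about these
numbers.

Impairment is declared only for negative deviations (measured rcSO2 more
than `deviation_cut` = 20% *below* expectation); elevated rcSO2 is logged
as intact, since the clinical concern is desaturation. Two readings of
"20% change from the trendline" are possible — relative to the nomogram
expectation or to the raw baseline — and both are implemented behind
`deviation_reference`, defaulting to the expectation. Attribution goes to
the largest standardized excursion among: BP (the larger of the
below-plateau shortfall normalized by the plateau limit and the relative
drop from baseline mBP), oxygen (PaO2 shortfall below threshold, or SaO2
below 0.90 when `hypox_driver="sao2"`), and CO2 (absolute PaCO2 deviation
from 40, kept symmetric so the label exists even in cohorts where nobody
is hypocapnic). Exact ties break deterministically in the order
O2 > BP > CO2, configurable. An observation impaired with no excursion at
all is labelled `impaired_unattributed` with a warning. Group comparison
is Pearson chi-squared without continuity correction.

## Respiratory mechanics

The single-compartment fit regresses Paw on [V, V̇, 1] by ordinary least
squares, preferred over loop-geometry constructions because it uses every
sample, has a closed-form solution and makes rank deficiency (constant
flow or volume) an explicit, testable failure mode. Units are fixed at
mL, L/s and cmH2O, so the coefficients are elastance 1/C (cmH2O/mL),
resistance R (cmH2O·s/L) and end-expiratory pressure P0. A non-positive
fitted elastance is rejected as unidentifiable rather than returned.
Quasi-static compliance VT/(Pplat − PEEP) is provided alongside, since
both conventions are in clinical use; on a waveform with zero flow at the
measurement instants the two coincide.

The synthetic breath generator delivers the set tidal volume with a
half-sine inspiratory flow over Ti = 0.3 s, then passive exponential
expiration with time constant R·C; pressure is computed exactly from the
equation of motion, with optional Gaussian noise (SD 0.2 cmH2O by
default) on the pressure channel only.

## Synthetic cohort generator

`generate_cohort` composes the three forward models above. Defaults encode
the study design the package targets: 6 control and 7 oleic-acid-injured
animals of 2.1 kg, five measurement periods (baseline, 1 h post
injury/sham, then FiO2 40, 30, 21%) at FiO2 0.5/0.5/0.4/0.3/0.21, PaCO2
held near 40 mmHg (45 in the injured group, whose CO2 runs slightly high),
and group-level mBP trajectories taken from the published hemodynamics
table. Injury is expressed as Qs/Qt rising from 0.05 to 0.30 with the V:Q
displacement rising from 20 to 35 mmHg (a modest baseline displacement is
given to both groups: anesthetized supine animals are not perfectly
matched, and this is what lets control animals drift below 95% SaO2 at
room air, as observed), compliance halving from 2.0 to 1.0 mL/cmH2O and
resistance rising from 50 to 80 cmH2O·s/L. Published figures give the
direction and rough magnitude of these changes but not animal-level
values; the numbers above were fixed once as a representative moderate
injury and are exported per animal as ground truth.

Cerebral NIRS is generated as the nomogram expectation times
(1 − deficit), with period-wise deficit schedules matched to the relative
rcSO2 drops of the published NIRS table (up to 18% in controls at room
air, up to ~49% in injury); gut and kidney channels use analogous
baseline-times-(1 − deficit) schedules. Regional venous saturations equal
the noiseless regional NIRS value (NIRS is venous-weighted), which is also
what makes the NIRS-derived and blood-gas-derived FOE series agree in
slope. Noise is independent Gaussian per channel: SD 0.01 on SaO2
(fraction), 2 percentage points on rSO2, 0.2 cmH2O on airway pressure —
within-animal dispersion consistent with the between-animal standard
errors printed in the study tables. Per-animal randomness derives from
`numpy.random.SeedSequence([master_seed, animal_index])`, making cohorts
bit-reproducible.

What the generator does *not* emulate: temporal autocorrelation within a
measurement period, NIRS ambient-light artifacts, hemodynamic reflex
coupling (mBP is exogenous), hemoglobin drift, or any pharmacokinetics of
the injury agent. Passing recovery tests therefore demonstrate that the
estimators invert the package's own forward physiology under realistic
noise — a necessary correctness property — not that they are robust to
every pathology of real recordings.

## Problem sizes and numerical tolerances

The test suite exercises: the forward model against an independently coded
scalar fixed-point oracle on a 5 × 5 × 3 (FiO2 × shunt × shift) grid at
1e-8 absolute agreement; noiseless shunt inversion to ±0.01 in Qs/Qt and
±2 mmHg in ΔVQ; 100-replicate noisy recovery at 1% SaO2 noise to ±0.05;
mechanics recovery to machine precision noiseless and 5% under noise over
100 replicates; dissociation-curve round-trips to 1e-6 relative on
1–600 mmHg; and byte-identical report output across repeated runs on the
same seed. Cohort sizes in the tests (3 + 3 or 6 + 7 animals) mirror the
study scale, where each fit uses only four FiO2 steps per animal.

## Known limitations

- The two-parameter shunt/V:Q model is a summary, not a physiological
  inversion; fitted ΔVQ conflates diffusion limitation, low-V:Q regions
  and dissociation-curve misspecification.
- The assumed avDO2 closure ignores cardiac-output and metabolic-rate
  changes across FiO2 steps.
- The autoregulation nomogram defaults are plausible rather than
  calibrated; attribution between co-occurring excursions depends on the
  standardization choices documented above.
- Echocardiographic indices are consumed as pass-through numbers; the
  package computes nothing from images.
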