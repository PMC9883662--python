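# Methods

`pbpkddi` is a reduced, open reimplementation of a physiologically-based
pharmacokinetic (PBPK) drug–drug-interaction workflow for two oral
anticoagulants — dabigatran etexilate (DABE, prodrug of dabigatran, DAB)
and rivaroxaban — co-administered with reversible P-gp/CYP3A4 inhibitors
(verapamil, clarithromycin, fluconazole, ketoconazole) in virtual
Caucasian and Chinese adults and older adults.  This note records the
model, its assumptions, the calibration strategy, and what the package's
tests do and do not demonstrate.

## Model structure

**Absorption.** Oral drug transits a chain of 7 lumen segments (total
small-intestinal residence 3.32 h).  Each segment feeds an enterocyte
compartment at a first-order rate `ka`; enterocyte drug either passes to
the portal inflow (`k_ent`) or is pumped back into the same lumen
segment by P-glycoprotein, modelled as Michaelis–Menten efflux in the
enterocyte concentration, `J = a · Jmax · C/(Km + C)`, where `a` is the
competitive-inhibition activity factor.  Effluxed drug re-enters the
transit stream and can be recaptured downstream or lost fecally.  A
1-segment mode exists for analytic tests.  This replaces a commercial
dissolution/absorption model; there is no mechanistic dissolution,
so a dose-threshold rule on fraction released reproduces rivaroxaban's
dose-dependent bioavailability (≤10 mg vs above).

**Disposition.** The dosed parent has an explicit well-stirred liver
compartment (venous-equilibrium convention, elimination
`CLint · fu · C_liver/Kp`), so first-pass extraction and metabolite
formation emerge from mass balance.  Distribution is lumped: central +
peripheral compartments calibrated to Vss.  Metabolites (DAB from DABE
via hepatic carboxylesterase; dabigatran glucuronide, DAB-G, from DAB
via UGT2B15) form directly into their central compartments; their own
hepatic elimination uses the well-stirred clearance applied to systemic
plasma.  Renal elimination is unbound filtration `fu · GFR` plus
inhibitable active secretion (rivaroxaban: renal P-gp 70% / OAT3 30%),
scaled to subject renal function (GFR relative to a 100 mL/min
reference).  Hepatic intrinsic clearances scale with subject liver
volume (reference 1.8 L) and the per-enzyme abundance scalar.

**Perpetrators** are 1–2-compartment oral models with first-order gut
transit/absorption and a fixed first-pass availability; only their
concentrations at the interaction sites matter.  Competitive inhibition
multiplies the targeted activity by `1/(1 + I/Ki)` at every integration
step, using: the perpetrator's lumen concentration in the *same gut
segment* (times a luminal free fraction) for intestinal P-gp; the
unbound hepatic-inlet concentration `fu·(C_p + rate_abs/Q_h)` for CYP3A4
and CYP2J2; and unbound systemic plasma for renal transporters.  The
segment-resolved gut inhibition is what makes staggered dosing
mechanistically different from concomitant dosing: two hours after a
verapamil dose its luminal bolus has migrated to distal segments, so a
freshly dosed victim absorbs mostly from proximal segments with little
inhibitor present.

**Victims and perpetrators are integrated as one coupled stiff ODE
system** (LSODA; rtol 1e-8 / atol 1e-10 mg by default, 1e-6/1e-9 for
population-scale trial runs; doses are state discontinuities at event
times; reporting grid 0.1 h, 0.25 h in trial runs).  Mass balance
(remaining + eliminated per route = administered, per analyte) is
checked at every reported time with a 0.1 % gate.

## Virtual populations

Subjects are sampled per ethnicity (Chinese, Caucasian) with sex-
specific height/BMI, Du Bois body surface area, cardiac output from a
linearly declining cardiac index, serum creatinine rising linearly with
age, and GFR as Cockcroft–Gault creatinine clearance (female factor
0.85).  Aging covariates: height declines 0.1 cm/y after 60; cardiac
index declines 0.011 L/min/m²/y after 25; creatinine rises 0.65 %/y of
the sex-specific reference and *plateaus at age 71* — a deliberate
sarcopenia approximation (muscle mass falls roughly in step with
filtration in the very old, so creatinine stops tracking the decline);
liver volume declines 0.3 %/y after 40.  Inter-individual variability
is lognormal on weight (CV 13–15 %), creatinine (CV 10 %) and
enzyme/transporter abundances (CV 22 %); abundances are mean 1.0 at all
ages (aging declines are an opt-in scenario used by the sensitivity
sweep).  The aging coefficients are *reconstructions calibrated* so that
monotherapy exposure of older groups rises in the clinically reported
ranges (dabigatran ≈ +40 %/+86 %, rivaroxaban ≈ +23 %/+44 % for 60–74 /
75–99 vs 20–59); they are not fitted to individual-level physiology
data.

## Compound parameterization and calibration

The bundled parameter files are reconstructions, not transcriptions:
structural values (molecular weights, fu, Vss, fm, transit time) come
from literature-typical ranges; the absorption/P-gp/Ki values were
calibrated, at the reference adult physiology, against clinical
anchors, in this order:

1. DABE gut parameters (`ka`, `Jmax`) so the net dabigatran
   bioavailability is a few percent, with P-gp efflux removing ~40 % of
   enterocyte drug — giving full-inhibition headroom of ≈1.8-fold;
2. verapamil `ka` and its gut P-gp Ki so the single-dose AUC ratio is
   ≈1.65 concomitant and ≈1.19 with a 2-h stagger;
3. clarithromycin's gut Ki for the ≈1.31 ratio on dabigatran, and its
   CYP3A4/renal-P-gp Ki for ≈1.52 on rivaroxaban;
4. fluconazole's CYP3A4 Ki (≈1.39 on rivaroxaban) and ketoconazole's
   CYP3A4/CYP2J2/renal-P-gp Ki (≈2.58);
5. dabigatran Vss and DABE `ka` (exposure level) against the 10-day
   steady-state trough medians.

Because clarithromycin and verapamil are not purely reversible
inhibitors in vivo, their Ki values are *competitive equivalents*; gut
P-gp Ki values are referenced to the luminal concentration after the
perpetrator's `gut_free_fraction` and are not comparable to in-vitro
unbound Ki.  Every file value carries a `source` annotation.

Two global conventions: "total dabigatran" sums DAB and DAB-G in DAB
mass equivalents (the clinical assay cleaves the conjugate before
quantification); and the glucuronide's disposition parameters are cloned
from dabigatran (`derive_dabg_model`), with its formation fixed at 20 %
of dabigatran elimination at the reference adult physiology.

A deliberate trade-off: the lumped distribution yields a flatter
steady-state profile (higher trough/Cavg) than a full PBPK model, so
absolute exposure was anchored to the steady-state trough medians rather
than to single-dose AUC, which consequently sits at the low edge of its
clinical range (≈450–550 ng·h/mL for a 150 mg adult dose).  Ratio-type
outputs (DDI ratios, aging increases, normalized ratios, sensitivity
percentages) are insensitive to this choice.  The 75–99 verapamil trough
runs high relative to its published value — the published 60–74 and >75
troughs are nearly equal although the same source reports ~30 % higher
exposure in the oldest group, which no shape-preserving kinetics can
reproduce; we calibrate to the 60–74 value and report the discrepancy.

## Trial design and statistics

Studies use 10 trials × 10 subjects per demographic group; every subject
is simulated twice (victim alone, victim + perpetrator) with identical
physiology, so exposure ratios are paired within subject.  AUC is linear
trapezoidal (optional terminal log-linear extrapolation gated on
adjusted R² ≥ 0.9 over ≥3 points); ratios are pooled as geometric means
(arithmetic mode available); prediction acceptance uses the
variability-adjusted Guest interval with δ = 1.25 (20 % variability),
`L = (δ + 2(R−1))/R`, interval `[R/L, R·L]`, reciprocal-symmetric below
R = 1; fold errors are symmetric `max(p/o, o/p)`; visual-predictive-
check bands are 5th–95th percentiles with linear interpolation between
order statistics.  Age normalization divides each group's DDI ratio by
the 20–59 group's and checks the 1.25-fold bioequivalence band.

The 10-day safety simulation doses DABE BID with the perpetrator q12h
co-timed (the concomitant maintenance scenario) and reads each subject's
total-dabigatran trough at 216 h after the first dose, summarized as
median and IQR against configured bleeding thresholds (122.1 and
74.9 ng/mL).

The abundance sensitivity sweep applies, to a reference 70-year-old
Chinese subject, an 8 %-per-decade CYP3A4 decline accumulated from the
adult reference age of 40 (the age whose abundance the base model
carries) together with a 25.5 % decrease of intestinal P-gp (the site
the aging expression data concern), and reports percent AUC changes.
Other readings of that scenario (decline from age 20; renal P-gp
included) give larger rivaroxaban changes and are not used.

## Synthetic observations and what the tests show

There is no clinical data in this package.  "Observed" studies are
generated by the engine itself plus multiplicative lognormal residual
error (configurable CV; additive floors are not modelled), and the
parameter-recovery fixture refits a known abundance scalar from such
data by 1-D grid least squares on log concentrations.  Passing tests
therefore demonstrate internal consistency — conservation, closed-form
limits, correct statistics, reproduction of the published summary
quantities under the reconstructed parameterization — not predictive
validity against real patients.  In particular, the synthetic residual
model has no structured bias, no below-quantification censoring, and no
correlation across time points, all of which real concentration data
have.

## Problem sizes and numerical choices

Default suites run 10×10 subjects per group; the acceptance script's
age-normalization panel uses 10×5 per group across all six
scenario/age-group combinations — the package's chosen reporting size
for that sweep.  Percentile and geometric-mean estimates at these sizes
carry a few percent of sampling noise; acceptance checks on bounded
quantities allow 10 % relative slack for it.  Degenerate inputs are
rejected, not coerced: non-positive physiology, fm sums above 1,
unsorted time grids, reference-free normalization, perpetrators without
interaction tables, and simulations shorter than their dosing schedules
all raise named errors.  Negative solver states beyond −1e−6 mg abort
the run; smaller transients are clipped to zero.

## Known limitations

Time-dependent/mechanism-based inhibition, induction, enterohepatic
recirculation, mechanistic dissolution, per-organ partition (Kp) maps,
disease states (renal impairment), pediatrics and pharmacodynamics are
out of scope.  The perpetrator models are deliberately minimal: their
plasma profiles are plausible but not validated, and only their
interaction-site concentrations influence results.  The intestinal
model's luminal concentrations are operational quantities (dose over a
fixed fluid volume), not measured chyme concentrations.
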