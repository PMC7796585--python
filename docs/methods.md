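# Methods

## The screening model

Targeted UHPLC-MS/MS with multiple-reaction-monitoring (MRM) acquisition
monitors, for each storage disorder, a small panel of precursor > product
(Q1 > Q3) transitions of the oligosaccharides (OS) that accumulate when a
lysosomal or autophagy pathway is defective.  The assay is semi-quantitative
by design: no calibration to absolute concentrations is attempted.  Instead,
each analyte peak area `A_t` is converted to a dimensionless response

    r_t = A_t / A_IS(polarity of t)

against the maltoheptaose (Glc7) internal standard acquired in the same
polarity, and a sample's score on a transition is its multiple of the median
(MoM)

    MoM_t = r_t / median({r_t of >= 10 matrix-matched controls}).

A disorder panel calls **positive** when *every* one of its transitions
(qualifiers and quantifiers alike) reaches the matrix threshold: MoM >= 5 in
fresh urine, MoM >= 2 in dried urine spots (DUS, which carry less background
and therefore separate at a lower multiple).  Both comparisons are inclusive.
A panel whose quantifiable transitions sit uniformly in the borderline band
[1.5, threshold) is **borderline**; a panel with more than half of its
transitions unquantifiable is **not assessable**; anything else — including
discordant panels where only some transitions clear the threshold — is
**negative**.

Sample-level interpretation applies, in order: one specific panel positive
(Glc4 not positive) → a specific profile naming the disorder; two or more
specific panels positive → a mixed non-specific profile (the pattern of
mucolipidosis II/III, e.g. α-mannosidosis plus GM1 transitions together);
Glc4 positive → the Glc4 group with a fixed differential (Pompe disease, Vici
syndrome, Yunis-Varon syndrome, Danon disease, other glycogenoses), which
Glc4 alone cannot rank; Glc4 borderline only → a borderline-Glc4 flag (the
mucopolysaccharidosis-IVB pattern); otherwise negative.  GM2 calls refer to
the Sandhoff type — the Tay-Sachs variant does not alter urinary OS and every
report carries that caveat plus a confirmatory-testing disclaimer.

## Creatinine normalization

Urinary concentration is removed by normalizing the analyzed fluid to 1 mM
creatinine.  Samples at >= 1 mM are physically diluted to 1 mM before the
run; samples below 1 mM are run neat and corrected *after* the run by the
factor `1 / creatinine_mM` (always >= 1).  The central modelling assumption is
that the internal standard is spiked into the *already normalized* fluid, so
its area is creatinine-independent and the post-hoc factor can be applied
directly to analyte/IS ratios.  A sample recorded at >= 1 mM without a
dilution flag is treated as a data-entry inconsistency (warning, factor 1)
rather than silently down-scaled, because a factor below 1 has no physical
counterpart in this protocol.  The same rule applies to urine and to DUS
extracts.  Adjustment is applied exactly once; re-adjusting an adjusted
profile is an error.

## The panel registry

Only eight m/z pairs of this assay are published (the most characteristic
transition of each disorder, e.g. 1200.4 > 1099.4 for the sialyl-OS of
sialidosis and 665 > 179 for Glc4); the remaining entries are shipped as
synthetic placeholders (`placeholder: true` in `data/panels_default.yaml`)
whose *counts* per panel and polarity are faithful: sialidosis 3(−);
α-mannosidosis 8(+); β-mannosidosis 9(+)/8(−); fucosidosis 6(+);
aspartylglucosaminuria 5(+)/10(−); GM1 5(+); GM2 7(+); Glc4 2(−); IS
7(+)/7(−).  Quantitative-transition counts are likewise fixed (1, 4, 5, 3,
3+3, 3, 4, 1); which placeholders are quantitative is configurable, defaults
mark the leading ones.  Transition keys are equal when their m/z match after
rounding to one decimal, the precision at which they are reported.
`validate_registry` audits any registry against these defaults and flags
deviations instead of failing, so broken registries can still be described.

Glc4 and its linear isomer maltotetraose (M4) share the same MRM transitions
and are separated chromatographically; the registry encodes this as a
retention-window annotation (Glc4 at 6.8 ± 0.25 min, M4 near 7.6 min) rather
than as duplicate keys.

## Chromatogram integration

Vendor software normally performs peak integration; here it is an explicit
operator so the whole chain is testable.  Within a configured retention
window, the baseline is the straight line joining the signal values at the
window edges, the area is the trapezoidal integral of the corrected signal on
the native time grid (no resampling), negative net areas clip to zero, and
the apex is the time of the maximum corrected intensity (earliest on ties).
This is the simplest defensible baseline model and is exactly testable: the
trapezoid matches the closed-form Gaussian area `A·σ·√(2π)` within 1% for
σ >= 0.02 min at 0.01-min sampling over ±5σ windows.  Transitions with no
acquired trace yield *absent* areas, distinct from zero, so downstream stages
can distinguish non-acquired from non-detected.  The gradient program
(27.50 min total, 15.50 min detection + 12.00 min reconditioning) is kept as
package constants and bounds all retention windows.

## Assay-validation statistics

Linearity per transition is the squared Pearson correlation between the
relative concentration levels 1/2/3 (50/100/150 µL urine in a constant final
volume) and the measured area ratios — identical to the coefficient of
determination of the unweighted least-squares line, not forced through the
origin (whether the original fits were weighted is unknown; recorded as a
limitation).  Zero-variance responses return an explicit *undefined* flag.
Precision is CV% = 100·SD/mean over all replicates pooled (10 for intra-day,
30 across three days for inter-day); pooling is the more conservative choice
where day-mean CV is the flagged alternative (`per_day_mean=True`).  Batch
acceptance requires the mixed positive internal QC — equal parts of urine
from eight disorders — to call positive on all eight panels; failures name
the missing panels and flag, but do not suppress, the batch's sample reports.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis assumes,
not mass-spectrometric physics:

- **Controls** — analyte/IS ratios log-normal around a per-transition baseline
  (mean-1 multiplier with configurable CV; default CV 0.15, the mid-range of
  the 5–25% replicate CVs observed for these analytes).  DUS baselines are
  0.25× the urine background, encoding the lower DUS interference.  Baselines
  themselves are arbitrary positive constants (spread deterministically over
  [0.5, 2]× a scalar): true control ratios are unpublished, and MoM scoring
  makes their values immaterial.  Cohort sizes default to 75 urine / 12 DUS.
- **Creatinine** — log-normal around 6 mM (σ_log 0.9), giving a small sub-1 mM
  tail; >= 1 mM samples are generated as physically diluted, < 1 mM samples as
  neat with analyte areas scaled by the creatinine, so both normalization
  paths are exercised and agree.
- **Age** — 16% of controls below 6 months, matching the reported control mix;
  an optional age effect multiplies baselines of young controls by a
  configurable factor (default 2).  Age stratification is off by default (the
  main analysis uses one control set); scoring an under-6-month sample
  against an unstratified reference emits a warning.
- **Patients** — the disorder's panel transitions are multiplied by a fold
  drawn from the per-disorder, per-matrix reported ranges (e.g. fucosidosis
  220–470× urine, GM1 9–1160× urine, Pompe 10–72× urine); explicit folds are
  supported and, at zero dispersion, are recovered exactly by the pipeline.
  Matrices without a reported profile (e.g. Yunis-Varon in fresh urine) are
  refused rather than invented; Tay-Sachs carries explicit unit folds.
  Mucolipidosis II is encoded as above-threshold α-mannosidosis + GM1 folds,
  mucolipidosis III as GM1 folds between the threshold and GM1's minimum, and
  MPS IVB as a sub-threshold Glc4 fold in (1, 2).
- **QC mix** — equal-part (1/8) dilution of eight constituent disorders,
  using each disorder's maximum reported urine fold ÷ 8 floored at 1; the
  minimum folds of the weakest excretors (GM1 9×, Pompe 10×) would not
  survive an eight-fold dilution, so the mix is modelled on the strong
  positive control a QC scheme actually provides.
- **Chromatograms** — Gaussian peaks (σ 0.05 min) centred in each transition's
  retention window on a flat baseline, with peak area equal to the table's
  area; the integrator recovers areas within 1%.  No isotope patterns, ion
  suppression or raw spectra are simulated.

Noise is independent per transition.  Real replicate errors are partly
correlated across transitions (shared injection and source conditions), so
the synthetic setting is *harder* than reality for all-transition conjunction
calls: passing separation tests here understates real-data separation, but
equally, passing tests here says nothing about matrix effects, interferences
or retention drift, which are not modelled.

All randomness flows from a single seed; every generator call derives an
independent, purpose-keyed stream from it, so outputs are byte-identical
under a fixed seed regardless of call order.

## Numerical choices

- Medians are the standard 50th percentile (mean of the two middle values for
  even cohorts), computed only over controls with a quantifiable ratio; a
  reference needs >= 10 controls, and transitions quantifiable in fewer than
  10 are flagged.
- A zero control median makes the transition *not quantifiable* rather than
  an infinite MoM — background-free transitions (common in DUS) must not
  create spurious positives.
- MoMs are reported with 3 significant figures in TSV output; statuses and
  interpretations round-trip exactly through the report files.
- Thresholds (5 urine / 2 DUS / 1.5 borderline floor) are configurable but
  must satisfy urine > DUS > floor > 1.  The borderline floor is an artifact
  constant: the reported sub-threshold pattern gives no number, only
  "less than the positivity threshold".

## Known limitations

- Placeholder m/z values are synthetic; users with the full transition list
  should override the shipped registry.
- The borderline band and the not-assessable rule (> half unquantifiable) are
  robustness conventions of this implementation, not published rules.
- Separation at the *minimum* reported folds with worst-case 25% CV noise is
  not perfect by construction: a 9-fold GM1 elevation against a 5× threshold
  with five independent noisy transitions misses in a few percent of
  replicates (the test suite measures this honestly; at the default 15% CV
  separation is clean).
- Simulated problem sizes (cohorts of 75/12, 200-replicate separation sweeps,
  1000-seed CV recovery) were chosen to mirror the reported cohort scale
  while keeping the whole suite in a few minutes on one CPU.
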