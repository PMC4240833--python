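# Methods

## Statistical model and procedure

The package analyses a binary-outcome diagnostic marker measured once
per patient. The outcome is fluid responsiveness, ΔSV ≥ 15% after a
standardized fluid challenge; the boundary is inclusive, read literally
from the clinical definition, and implemented with a 1e-9 relative
slack so that `sv_post = 1.15 * sv_pre` classifies as a responder under
floating-point arithmetic.

**ROC.** Candidate thresholds are the unique observed marker values
plus a sentinel one unit outside the data range (the "call everyone
positive" rule). The call rule is value ≥ threshold for markers where
higher values predict responsiveness (PPV) and value ≤ threshold for
the opposite orientation (CVP; orientation can be auto-detected from
group means). Observed values rather than midpoints are used as
candidates so that integer-valued clinical markers yield the integer
cut-offs clinicians actually quote; a midpoint rule would report e.g.
7.5% where devices display 7%. AUC is the Mann–Whitney statistic with
ties counted ½, which equals the trapezoidal area under the empirical
ROC polyline exactly; both are implemented and the equivalence is a
test, not an assumption.

**Youden threshold.** The candidate maximizing J = Se + Sp − 1. Ties
are resolved toward higher sensitivity (for a positive-orientation
marker, the smallest tied threshold): the clinical use of the low
cut-off is to *exclude* responsiveness, which favours sensitivity. The
tie rule is deterministic and shared by the cost-weighted scan.

**Two-step grey zone.**
*Step 1* draws B patient-level bootstrap resamples (default B = 1000),
records each resample's Youden threshold and AUC, and summarizes the
threshold distribution by its 2.5th/97.5th percentiles and the AUC
distribution by median and percentile CI. Plain percentile intervals
are used; BCa corrections are out of scope. Resamples that lose an
outcome class entirely are redrawn, keeping B fixed; the redraw count
is reported (it is zero at realistic n and prevalence).
*Step 2* computes, on the original sample (not on bootstrap-averaged
curves), the interval between the largest threshold with Se ≥ 1 − τ
and the smallest with Sp ≥ 1 − τ, default tolerance τ = 0.10. Values
strictly inside satisfy neither target, i.e. cannot support a decision
with ≤ 10% error in either direction. When no threshold reaches a
target the corresponding data extreme is substituted and a warning is
raised. The final grey zone is whichever interval is wider, with its
provenance recorded; equal widths resolve to the tolerance zone.
Membership (the fraction of complete-case patients inside the zone)
uses closed bounds — open vs closed is unidentifiable on continuous
data and matters only for integer markers at the exact bounds.

**Comparing markers.** Correlated AUCs on the same patients are
compared with DeLong's placement-value estimator (midrank
implementation); the comparison runs on the paired subset of patients
carrying both markers, since a variance of a difference of AUCs is
defined only on paired data. Grey-zone memberships of two markers are
compared as independent proportions with an uncorrected two-proportion
chi-square; there is no consensus paired test for grey zones, and the
chi-square reproduces the published significance call at the published
counts. Disjoint subgroups (e.g. VT/IBW strata) are compared with an
independent-samples z-test on the DeLong variances of the two AUCs.

**Cost-weighted thresholds.** The objective is total misclassification
cost Σᵢ cFPᵢ·[false positive] + Σᵢ cFNᵢ·[false negative], scanned over
the same candidate grid with the same tie rule. Uniform costs with
balanced classes reduce exactly to Youden maximization (property
tested); the threshold is non-decreasing in R = cFP/cFN, so raising the
false-positive cost in severe hypoxemia always raises the cut-off. The
default R map is 2 / 1 / 0.5 for severe / moderate / mild strata
(PaO2/FiO2 < 100 / < 200 / ≥ 200; 100 belongs to moderate, 200 to
mild). The pooled analysis gives each patient the R of their own
stratum; patients without a PaO2/FiO2 ratio are excluded from it. The
cost-weighted grey zone is reconstructed as the wider of the bootstrap
CI of *cost-optimal* thresholds and the unweighted tolerance zone; no
published construction exists for this object, and reports flag it as a
reconstruction.

## Synthetic-cohort generator

The generator emulates the statistical shadow of a pooled 556-patient
multicentre ICU population; it is not a cardiovascular simulator.

- **Outcome.** Responder labels are Bernoulli(0.48).
- **Markers.** Each continuous variable is drawn per group from a
  lower-truncated normal. The configured (location, scale) are the
  *target mean and SD of the truncated variable*; the underlying normal
  parameters are solved by moment matching (`truncated_normal_params`),
  so physiologic floors (0 for pressures, 40 mmHg for PaO2/FiO2) do not
  bias the group summaries the cohort is calibrated to. Naive
  truncation would inflate e.g. the non-responder PPV mean from 9 to
  ≈ 10.4%. The truncation bound is part of the config, so sensitivity
  to it is testable.
- **ΔSV.** The source population is characterized only by the responder
  dichotomy, so ΔSV distributions are invented, config-exposed choices:
  responders N(25, 10) restricted to ≥ 15%, non-responders N(5, 6)
  restricted to < 15% (parent parameters, one-sided cuts). `sv_post` is
  set from `sv_pre` and ΔSV, with a nudge guarding the 15% float
  boundary, so re-deriving labels from stroke volumes reproduces the
  drawn labels exactly.
- **Plateau pressure** is drawn from its configured truncated normal
  with the lower bound raised to each patient's PEEP, guaranteeing
  pplat ≥ peep; its marginal mean therefore sits slightly above the
  configured location (≈ +1 cmH2O), which is the price of respecting
  the physical constraint.
- **PPV and CVP are rounded to integers** by default, as bedside
  monitors report them; this is why the pipeline recovers integer
  grey-zone bounds. Rounding shifts the group means by < 0.1 units;
  calibration tests allow a 0.3-unit margin on top of 3 SE for it.
- **Missingness** is applied independently per variable at the
  published per-variable rates (CVP 150/556, PaO2/FiO2 306/556, Pplat
  126/556, RR 63/556, VT 37/556, PEEP 36/556) and independently of the
  outcome.
- **Within-group independence.** Variables are sampled independently
  within outcome group; the published summaries carry no covariance
  information. An optional Gaussian-copula hook (`copula_corr`) exists
  to inject correlation, making the limitation explicit. One
  consequence: the ventilator-variable subgroups genuinely share one
  marker distribution, so subgroup AUC differences on default synthetic
  cohorts are null by construction — passing subgroup tests demonstrate
  the partitioning and comparison machinery, not a ventilation effect.
  Likewise the PPV–ΔSV correlation arises only through the group
  mixture (≈ 0.35 at n = 556), not from a per-patient dose-response.
- **Streams.** Every column draws from its own generator seeded by
  (seed, CRC32 of the column name): adding a variable never perturbs
  existing columns, and cohorts are bit-reproducible under a fixed
  seed.
- **Centres.** A nine-centre mixture with three small centres; the
  per-centre analysis pools centres under 70 patients as "others".

What passing tests show — and don't. Calibration tests at n = 10⁴
verify the generator hits the configured moments and AUC (the
truncation-adjusted expected PPV AUC is ≈ 0.70, checked against a
10⁶-draw Monte-Carlo oracle; the untruncated closed form
Φ(6/√130) = 0.701 is nearly identical here). Pipeline tests on n = 556
replicates verify the recovered grey zones centre on the analytic
tolerance zone of the generating distributions (≈ 3.5–18% before
rounding). None of this validates PPV clinically; real cohorts have
correlated variables, centre effects on the marker itself, and
measurement heterogeneity the generator deliberately omits.

## Numerical choices

- Tie-breaks: Youden and cost scans prefer the smallest candidate
  (highest Se) under positive orientation, mirrored under negative; an
  uninformative marker returns the sentinel ("call everyone positive").
- Bootstrap CIs: percentile 2.5/97.5; AUC summarized by median.
- Tolerance comparisons use a 1e-12 slack so Se = 0.9 computed as
  0.8999999… still counts as reaching the target.
- Degenerate inputs: one-class outcomes raise; fewer than 5 patients
  per class refuse to bootstrap; strata under 10 (cost) / 20
  (subgroups) complete cases are reported as insufficient/skipped, not
  computed. LR+ at Sp = 1 and LR− at Sp = 0 return flagged infinities.
- Reporting rounds PPV/CVP thresholds and zone bounds to integer
  resolution at serialization only; internal computation keeps full
  precision, and regenerating a report from in-memory results is
  bit-identical.
- Normality screen for the group-comparison table: Shapiro-Wilk at
  α = 0.05 per group on an evenly spaced subsample capped at 500;
  failures fall back to Mann–Whitney. Categorical comparisons use the
  uncorrected chi-square, or Fisher's exact test when an expected cell
  is below 5.

## Problem sizes used by the test suite

Monte-Carlo checks are sized to finish in minutes while keeping their
error bars meaningful: DeLong type-I calibration uses 2000 replicates
at n = 500 (binomial 2-SE band ≈ ±0.01 around 0.05); bootstrap coverage
uses 100 outer replicates × B = 1000 at n = 500; closed-form binormal
recovery uses n = 10⁵; generator calibration n = 10⁴; grey-zone
parameter recovery 25 replicates at the study size n = 556 with B = 500.

## Known limitations

- The generator reproduces first and second moments per group, not
  joint structure, tails, or centre-level heterogeneity of the marker.
- The cost-weighted grey zone is a reconstruction (see above).
- Percentile bootstrap CIs can undercover for heavily discretized
  markers at small n; the coverage test pins behaviour only for the
  continuous equal-variance binormal case.
- The membership comparison treats the two markers' grey-zone fractions
  as independent although they are measured on overlapping patients; a
  paired alternative would need patient-level joint membership, for
  which no standard test exists.
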