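# Methods

## Engraftment definition

Engraftment is operationalized purely on presence/absence in a filtered
OTU table: an OTU engrafts in a recipient at a post-FMT timepoint when it
is present in the donor material, present in the recipient's post-FMT
stool, and absent from the recipient's baseline stool collected before any
antibiotic exposure. The baseline sample — never the during-antibiotics
sample — is the reference, so antibiotic-driven suppression of a
resident taxon followed by its return is not mistaken for engraftment.
Presence means at least one read after filtering. An optional
relative-abundance presence floor (default 0) is available for noise
robustness; it was not needed on the synthetic validation data.

Set logic does not fix a denominator for "percent engraftment"; three are
implemented and the choice is explicit in every output:

- **abundance** (default): share of the post-FMT sample's reads carried by
  engrafted OTUs. Scale-free, robust to sequencing depth, and directly
  comparable to a generative transfer fraction.
- **donor_richness**: engrafted OTUs over donor OTUs. Sensitive to donor
  richness and depth; undefined for an empty donor set (returned as
  missing with a warning).
- **post_richness**: engrafted OTUs over OTUs present post-FMT.

Per-subject values at week 1 and week 10 are averaged; when only one
timepoint exists the single value stands in and is flagged
(`single_timepoint`). Subjects with no baseline sample are excluded from
engraftment (the definition is vacuous without it) with a logged reason
code, but still contribute clinical outcomes — per-protocol semantics.

**Donor pooling.** A trial using capsules manufactured from a fixed donor
panel does not record which donor colonized which recipient, so the
default donor set is the union of all listed donor samples (`union`
policy); a per-subject `listed` policy supports trials with known
single-donor assignment. Pooling widens the donor set, which can only
raise the false-engraftment floor; the placebo arm quantifies that floor
as a negative control (median ≈ 0.04% at depth 10,000 in the default
simulation).

## OTU filtering

OTUs observed in fewer than 2 distinct samples or with fewer than 10 reads
in total are discarded before any analysis. Boundaries are inclusive for
retention (exactly 2 samples, exactly 10 reads are kept), reading "fewer
than" literally. The 10-read rule is interpreted as a total across all
samples (per-sample thresholds are expressible via the arguments); the
operation is idempotent and never drops samples. No rarefaction or depth
normalization is applied by default — engraftment percentages in abundance
mode are depth-robust and the diversity comparisons are within-subject — 
but a seeded without-replacement `rarefy` step is available.

## Diversity

Shannon diversity uses natural logarithms (nats); the base affects only
the scale, never a test decision. Timepoint contrasts are two-sided paired
t-tests on within-subject differences, with incomplete subjects excluded
and counted. An all-zero difference vector has no defined t statistic and
is reported as non-significant with a `zero_variance` flag. No minimum
depth is imposed by default; `min_samples`-style depth filtering is left
to the caller because a single shallow during-antibiotics sample is
biologically informative (antibiotics suppress load).

## Statistics

All p-values are two-sided; no multiplicity adjustment is applied unless
requested (the Dunn posttest exposes Bonferroni). Choices that matter:

- **Summary-statistics ANOVA/t.** One-way ANOVA and two-sample t-tests are
  reconstructed exactly from per-group (n, mean, sd), since trial reports
  print only summaries. The combined-arms t-test defaults to pooled
  variance, which is the form that reproduces the published combined-arm
  p-values on the validation tables.
- **Kruskal–Wallis** uses the tie-corrected H with a chi-square reference
  (k−1 df); an exact permutation p over all group assignments is available
  for total n ≤ 10. Calibration under the null (three groups of 10
  normals, 1,000 replicates) keeps the empirical type-I error near the
  nominal 5%.
- **Dunn's posttest** standardizes mean-rank differences by the pooled
  tie-corrected rank variance, z = (R̄ᵢ − R̄ⱼ) / √[(N(N+1)/12 −
  T/(12(N−1)))(1/nᵢ + 1/nⱼ)] with T = Σ(t³ − t) over tie groups.
- **Mann–Whitney U** is exact when the smaller group has ≤ 8 observations
  and no ties, otherwise normal-approximate with tie correction.
- **Exact contingency tests.** 2×2 uses the probability-mass two-sided
  rule (sum of hypergeometric masses ≤ the observed table's). R×C uses the
  Freeman–Halton generalization by exhaustive enumeration over tables with
  the observed margins, with log-gamma probabilities and a relative
  tolerance of 1e-10 on the ≤-observed comparison to absorb float
  round-off; a seeded Patefield Monte-Carlo estimator covers margins
  beyond the enumeration budget.
- **Tukey HSD** wraps the studentized-range test and reduces to the pooled
  t-test for two groups.

One published validation value resists recomputation: the four-arm exact
test on the adequate-relief counts (2/8, 4/9, 4/7, 4/11) yields p = 0.71
under the conventional Freeman–Halton rule (0.62 under strict inequality,
0.67 mid-p), not the printed 0.66. The neighbouring printed values on the
same table (0.95, 0.29, 0.21) all reproduce exactly, so the package keeps
the conventional definition and documents the discrepancy rather than
special-casing it.

## Clinical scoring

The 34-item quality-of-life instrument is scored with its published linear
transform: items are 1–5 Likert responses, raw sum ∈ [34, 170], score =
100 × (170 − raw) / 136 ∈ [0, 100], higher is better. Item orientation is
configurable because administrations differ in anchor direction. Severity
(IBS-SSS) is consumed as a precomputed 0–500 score. Responder boundaries
are inclusive: severity decrease ≥ 50 points, quality-of-life gain ≥ 12
points, global improvement ≥ 6 (moderately improved), adequate relief =
yes. Missing inputs propagate missing flags; no imputation anywhere.

## Synthetic trial generator

The generator emulates the features of a four-arm antibiotic-pretreatment
FMT trial that the pipeline must detect, not the full biology:

- **Abundance model**: log-normal relative-abundance profiles
  (σ default 1.5), a standard heavy-tailed community null. Defaults: 150
  shared taxa, 60 donor-unique taxa split across 6 donors, 10 subjects per
  arm, 10,000 reads per sample (multinomial).
- **Identifiability**: donor-unique taxa are absent from every recipient
  baseline by construction, so the expected share of post-FMT reads on
  transferred taxa equals the configured transfer fraction *f* exactly;
  the abundance-mode estimator converges to *f* with depth. Donors also
  draw from the shared pool, so the donor ∩ baseline → not-engraftable
  exclusion is exercised.
- **Arms**: transfer fractions default to 0.15 (FMT alone), 0.05
  (rifaximin pretreatment), 0.02 (ciprofloxacin + metronidazole), 0
  (placebo) — the regime where antibiotic pretreatment suppresses
  engraftment.
- **Antibiotics**: in the two antibiotic arms, a configurable fraction
  (default 50%) of baseline taxa is multiplied by a depletion factor
  (default 0.1) at the during-antibiotics timepoint and renormalized,
  which strictly lowers expected Shannon diversity. Recovery at weeks 1
  and 10 is full by default, with a configurable permanently-lost
  fraction for studying incomplete recovery.
- **Clinical records** are arm-independent by default (a null for the
  engraftment-vs-response comparison), with optional per-arm severity
  shifts.

What the generator does **not** model — compositional correlation between
taxa, strain-level donor/recipient sharing, time-varying engraftment,
index-hopping or other sequencing artifacts, donor-specific engraftability
— bounds what passing tests show: they validate the measurement logic and
statistical machinery under a clean generative truth, not performance on
real stool sequencing data.

Problem sizes in the test suite and acceptance script (10–20 subjects per
arm, depth 10³–10⁵, 1,000 null replicates for calibration) were chosen to
match the pilot-trial scale the package targets while keeping every run
reproducible from a single seed.

## Known limitations

- Engraftment is OTU-level presence/absence; a recipient strain replaced
  by a donor strain of the same OTU is invisible (strain tracking and
  probabilistic source attribution are out of scope).
- The union-donor policy is conservative for multi-donor capsule products;
  with known donor assignment the `listed` policy is strictly sharper.
- The Freeman–Halton enumeration is exponential in table size; beyond the
  budget it falls back to seeded Monte Carlo rather than asymptotics.
- Summary-statistics ANOVA assumes the printed sd is the sample standard
  deviation (ddof = 1), the near-universal convention in trial tables.
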