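# Methods

This note documents the models, rules, and numerical choices behind
`tmn`, and what the synthetic-data experiments do and do not
demonstrate about real panel data.

## Consensus calling

Each sample is called by several tools (three pseudo-callers in the
simulator: `gatk`, `snver`, `lofreq`). A consensus call requires
`min_callers` observers; the default is 2-of-N because requiring all
callers is unusually strict in practice, but the threshold is a single
config value (`min_callers: 3` restores the strict reading). Variant
keys are `(chrom, pos, ref, alt)` after allele trimming (shared suffix
then prefix removed, position advanced), so callers that emit padded
indel representations agree on the key without needing the reference
sequence. VAF and depth come from the designated primary caller when it
observed the variant, otherwise the per-field median across observers —
the median is robust to one outlier caller and reduces to the mean for
two observers.

## Filtering cascade

Stage order: quality gate → strand bias → origin partition. Every
variant carries an ordered `filter_trail` of `(stage, pass/fail,
reason)` so a triage decision is always auditable.

* **Quality gate** — depth ≥ `min_depth` (default 20) and VAF ≥
  `min_vaf_somatic` (default 0.02). On ~200× panels, 2% VAF is roughly
  the floor at which 4 supporting reads are expected.
* **Strand bias** — a call fails when
  `min(alt_fwd, alt_rev) / (alt_fwd + alt_rev) ≤ 0.2`. This
  generalizes the classical "2:8 or 8:2" alternate-count rule: those
  ratios sit exactly at the 0.2 boundary and anything more
  one-sided (1:9, 0:10) is also rejected. Calls without stranded
  counts pass with a logged "not evaluated" — absence of metadata is
  not evidence of artifact.
* **Population frequency** — for somatic candidacy a variant fails
  when any of the six database frequencies (gnomAD exome/genome,
  global and East-Asian, KOVA, KRGDB) is ≥ `common_maf_threshold`
  (default 0.01, the conventional polymorphism cut-off). For germline
  candidacy the filter only annotates; rarity of germline variants is
  enforced downstream by PM2, which has its own, much stricter
  cut-offs.
* **Panel of normals** — somatic candidates recurring in ≥ 5% of the
  normal panel (inclusive boundary) fail; variants absent from the PoN
  pass.
* **Origin partition** — (a) a germline-panel variant confirmed in the
  patient's matched non-malignant sample at VAF ≥ 0.30 is *presumed
  germline*; (b) without a matched normal, a germline-panel variant
  with VAF in [0.30, 0.70] or ≥ 0.90 is *potential germline*; (c) a
  somatic-panel variant passing the population and PoN filters is
  *somatic*; (b)∧(c) is *dual* and is forwarded to both downstream
  paths; none of the above is *unresolved*. The heterozygous band
  [0.30, 0.70] is wide enough to contain observed germline VAFs from
  0.35 to 0.68 on real panels while excluding typical subclonal
  somatic VAFs; all cut-offs are config values.

## ACMG/AMP engine

Criteria are tokens with an *effective strength*; modified strengths
render as `CODE_Strength` (e.g. `PVS1_Strong`).

* **PVS1** — null variants (nonsense, frameshift, canonical ±1/2
  splice, initiation loss) in genes whose disease mechanism is loss of
  function (an extra column of the germline panel file). Very strong
  when NMD is predicted or for canonical splice sites; downgraded one
  level to `PVS1_Strong` when the transcript is predicted to escape
  NMD, and also when NMD status is unknown for a truncating variant
  (the conservative reading). NMD prediction is consumed from
  annotation (a 50-nt-rule flag), not recomputed from transcript
  structure.
* **PM2** — gnomAD exome global frequency strictly below 1e-5 for
  dominant/X-linked disease and 1e-4 for recessive disease; missing
  frequency counts as 0 (absent); unknown inheritance uses the
  stricter dominant cut-off.
* **PP3** — requires concordance of all three predictors: SIFT `D`,
  PolyPhen2-HVAR `D` or `P`, and CADD phred strictly > 20; a missing
  predictor vetoes the criterion.
* **PP5** — ClinVar P/LP assertion with ≥ 1 review star, or HGMD DM
  (high confidence). ClinVar VUS or conflicting records do not qualify
  regardless of stars, and low-confidence DM does not qualify. PP5 is
  retained although later guidance deprecates it, because curated
  clinical panels still use assertion-based evidence; removing it is a
  one-line change in `classify_germline_variant`.
* **PM1** — consumed as a hotspot/benign-variation-free-domain flag
  from annotation; the engine does not attempt domain inference.

`combine_criteria` implements the standard combining table over
effective strengths (so a downgraded PVS1 counts as strong). When both
a pathogenic-side and a benign-side rule fire the verdict is VUS
(conflicting evidence); otherwise the strongest applicable class wins.
The engine is checked exhaustively against an independently written
brute-force rule table over all criterion subsets of size ≤ 5 from a
10-token alphabet, and against seven curated worked-example variants
(`tmn.examples`) that must reproduce verdict *and* criterion set
exactly.

## Somatic tiering

Tier assignment is a lookup in a user-supplied evidence table
(gene-level rows, optionally variant-level rows matched by an fnmatch
pattern on the protein change; the variant-level match wins):
guideline/FDA evidence → I, clinical trials or strong studies → II,
otherwise III, demoted to IV when any population MAF reaches the
common-polymorphism threshold or the entry is explicitly benign. A
static table was chosen over a live knowledge-base query so runs are
reproducible offline; a toy table covering the simulator's gene set is
bundled. Tiers I–III are reportable; selection is idempotent.

## Cohort summary

The landscape matrix counts *distinct* variants per gene per sample
(multi-hit counting), so per-sample variant totals are column sums.
Gene frequencies are reported per patient (longitudinal pairs are one
patient, two samples); per-sample tallies are available separately.
Association statistics: phi = Pearson correlation of 0/1 vectors with
the t-transform p (n−2 df), undefined (reported missing) for
zero-variance features; chi-square on 2×2 tables with optional Yates
correction (zero marginals are an error); Mann–Whitney with exact
enumeration for combined n ≤ 20 without ties and the tie-corrected
normal approximation otherwise.

## Survival

Kaplan–Meier, log-rank, and Cox fitting are delegated to `lifelines`
behind this module's API. Efron tie handling is the default because
survival recorded in 0.1-month resolution is tie-heavy and Efron is
markedly less biased than Breslow there. Before the multivariate fit a
greedy collinearity screen removes, among each pair of covariates with
|association| ≥ 0.7 (phi for binary covariates), the one with the
weaker univariate log-rank significance — keeping a designated anchor
covariate (del(5q) by default, which in T-MN cohorts travels with
−7/del(7q), complex karyotype, and somatic TP53 status). Pairs are
processed in descending association order with alphabetical
tie-breaks, so the screen is deterministic. Continuous variables are
dichotomized by a strict greater-than rule at configured cut-points
(50 years for age, 15.8 months for therapy duration cohort-wide; the
cut-point selection method is not derivable from the data we emulate,
so the values are plain config inputs).

## Synthetic cohort generator

The generator's defaults are the study conditions of the cohort the
pipeline is designed around: 53 patients, 7 pediatric, 20 matched
non-malignant samples, 4 longitudinal pairs; sex, subtype, therapy and
cytogenetic prevalences as configured (`SimulationConfig.prevalences`);
del(5q)/del(7q) drawn jointly under an odds ratio (default 6) solved
against the two marginals — an OR parameterization matches the 2×2
chi-square framing in which the co-occurrence of these lesions is
usually reported. The germline carrier count is deterministic,
`round(rate × n)` (7 of 53 at the default 13.2%), with carrier
identity randomized; a Binomial draw would make the realized rate
itself noisy at n = 53. Carrier variants follow four archetypes
(nonsense+NMD, frameshift escaping NMD, canonical splice, hotspot
missense) whose annotations are constructed to fire P/LP criterion
sets; null-variant archetypes are only assigned in loss-of-function-
mechanism genes. Somatic counts follow a zero-inflated shifted Poisson
truncated at 7 for adults (median 3) and a truncated Poisson for
pediatric samples (median 2, max 2), with TP53-dominant gene weights.
Injected noise: strand-biased calls (minority fraction ≤ 0.12), common
polymorphisms (MAF 0.02–0.3, restricted to somatic-only genes so they
cannot masquerade as germline candidates), PoN-recurrent calls, and
single-caller calls that fail consensus. Every call carries its truth
label and a `boundary` flag for draws adjacent to a filter threshold,
for which origin recovery is not claimed.

Survival times are exponential with rate
`baseline_hazard · exp(Σ log(HRₖ)·xₖ)` over five binary covariates
(male sex 2.99, radiotherapy 4.80, therapy duration above cut 3.75,
age above cut 10.79, del(5q) 3.99 by default). The baseline rate
0.0011/month is calibrated so the median observed survival under the
default prevalences is ≈ 10.6 months. Censoring is an independent
exponential whose rate is solved numerically (Brent) so the expected
censored fraction equals the configured 20% — censoring at a uniform
fraction of the event time would correlate censor and event times and
bias the hazard-ratio recovery. Times are reported in months rounded
to 0.1 (minimum 0.1), which deliberately reproduces the tie structure
of monthly clinical follow-up.

### What the simulator does not emulate

Variants are independent draws: no linkage or haplotype structure, no
clonal phylogenies beyond a simple persist/gain/loss longitudinal
model, no sequence-level read simulation, and pseudo-loci rather than
real gene coordinates. Passing the end-to-end recovery tests therefore
shows that the *decision logic* is correct under the generated
annotation patterns — it does not validate caller behaviour, alignment
artifacts, or annotation quality on real data.

## Problem sizes and numerical choices

The test suite exercises the full 53-patient cohort in memory and a
14-patient cohort on disk for byte-level determinism checks; the Cox
recovery experiments use 5,000 subjects, where the Wald relative
standard error of each hazard ratio is ~4–6%, comfortably inside the
10% recovery criterion. Cox convergence follows `lifelines` defaults
(Newton–Raphson on the Efron partial likelihood); zero-variance
covariates and event-free datasets are rejected before fitting, and
non-convergence is surfaced as an error rather than a silent result.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seed and inputs give
byte-identical pipeline output trees (hash-stamped in the run
manifest).

## Known limitations

* Only the criteria exercised by curated panel data are implemented as
  evaluators (PVS1, PM1, PM2, PP3, PP5); the combiner accepts any
  token, so externally asserted PS/BS/BP evidence can be supplied, but
  the engine will not derive it.
* The strand-bias rule assumes stranded alternate counts are available
  from at least one caller; without them the filter abstains rather
  than guessing.
* The collinearity screen is greedy and pairwise; it does not detect
  higher-order multicollinearity that leaves all pairwise associations
  below threshold.
* Tiering is only as good as the supplied evidence table; no therapy
  matching or knowledge-base integration is attempted.
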