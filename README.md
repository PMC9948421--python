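# tmn — variant triage and prognosis for therapy-related myeloid neoplasm panels

`tmn` is a Python toolkit for interpreting targeted-panel sequencing of
therapy-related myeloid neoplasm (T-MN) — AML, MDS, or MDS/MPN arising
after cytotoxic therapy for a prior condition. It is aimed at molecular
hematopathology and translational research groups who run multi-caller
panel pipelines and need a reproducible, testable path from per-caller
VCFs to clinical-grade variant interpretation and cohort-level
prognostic modelling.

The pipeline implements, as importable library modules and a thin CLI:

1. **Consensus merging** (`tmn.variant_io`) — per-caller VCFs are
   merged per sample; a variant is kept when at least `min_callers`
   (default 2) of the configured callers report it, with VAF/depth from
   a designated primary caller or the per-field median.
2. **Filtering cascade** (`tmn.filters`) — quality gate (depth ≥ 20,
   VAF ≥ 0.02), a strand-bias filter rejecting calls whose
   minority-strand alternate fraction is ≤ 0.2 (the classical 2:8 / 8:2
   rule and anything more extreme), then an origin partition into
   *presumed germline* (confirmed in the matched non-malignant sample),
   *potential germline* (predisposition-panel gene, VAF in the
   heterozygous band [0.30, 0.70] or ≥ 0.90), *somatic* (somatic-panel
   gene passing population-frequency and panel-of-normals filters),
   *dual*, or *unresolved* — with a full per-variant filter trail.
3. **ACMG/AMP germline classification** (`tmn.acmg`) — evidence
   criteria (PVS1 with ClinGen-style NMD downgrade to PVS1_Strong,
   PM1, PM2 with inheritance-specific gnomAD cut-offs 1e-5/1e-4, PP3
   three-predictor concordance, PP5) combined by the standard rules
   into P / LP / VUS / LB / B.
4. **AMP/ASCO/CAP somatic tiering** (`tmn.tiering`) — evidence-table
   driven tiers I–IV; tiers I–III are reportable.
5. **Cohort summary** (`tmn.summary`) — gene × sample landscape with
   multi-hit counting, gene-category flags, phi/chi-square/Mann–Whitney
   association statistics, and cross-cohort frequency comparison.
6. **Survival** (`tmn.survival`) — Kaplan–Meier, log-rank, a greedy
   collinearity screen (|phi| ≥ 0.7, anchored at del(5q) by default),
   and multivariate Cox proportional hazards with Efron tie handling:
   λ(t | x) = λ₀(t) · exp(βᵀx), hazard ratios HRₖ = exp(βₖ) with Wald
   95% CIs.
7. **Synthetic cohorts** (`tmn.simulate`) — fully labelled cohorts
   (clinical records, per-caller calls, annotations, matched normals,
   injected artifacts, survival times) so every stage is testable
   without patient data.

## Worked example

Generate a labelled 10-patient cohort and run the full pipeline:

```bash
tmn simulate --seed 5 --n-patients 10 --out-dir cohort
tmn run-all --cohort-dir cohort --out-dir out --seed 5
```

which prints

```json
{
  "stages": ["triage", "classify_germline", "tier_somatic", "summarize", "survival"],
  "n_variants_triaged": 39,
  "n_germline_deleterious": 3,
  "n_somatic_reportable": 29
}
```

39 consensus calls survived caller merging and entered the cascade;
29 somatic/dual calls were tier I–III reportable; 3 germline-candidate
calls classified P/LP. The first lines of `out/germline.tsv`:

```
patient_id  sample_id  gene  hgvs_p      origin             vaf     depth  verdict  criteria
tmn03       tmn03-B    TP53  p.Arg190*   dual               0.3975  213    VUS      PM2
tmn05       tmn05-A    ETV6  p.Trp531*   presumed_germline  0.5174  235    LP       PVS1 + PM2
```

The ETV6 nonsense variant was confirmed in the patient's non-malignant
sample (presumed germline) and combines PVS1 (null variant, NMD
expected, loss-of-function gene) with PM2 (absent from gnomAD) to
*likely pathogenic*. `out/` also contains the triage report with filter
trails, the somatic tier table, the mutation landscape, per-patient
gene-category flags, the Cox forest-plot JSON, and a manifest with
input digests — reruns on identical inputs are byte-identical.

The classification engine can also be used directly:

```python
>>> from tmn.acmg import classify_germline_variant
>>> from tmn.examples import GERMLINE_EXAMPLES
>>> # ... wrap an AnnotationBundle in a germline-candidate AnnotatedVariant
>>> cls.verdict, cls.criteria_string
('P', 'PVS1 + PM2 + PP5')
```

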