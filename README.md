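# adcscreen

Target discovery for antibody-drug conjugates (ADCs) from antibody-based
tissue proteomics tables.

An ADC delivers a cytotoxic payload to cells displaying its target antigen,
so a good target must be (i) strongly and broadly overexpressed in tumors,
(ii) absent or weak in normal tissues whose damage would be intolerable, and
(iii) located at the cell surface where an antibody can reach it.
`adcscreen` implements a screening funnel over immunohistochemistry (IHC)
expression tables of the kind distributed by large antibody-based tissue
atlases, together with the statistics used to check the resulting scores
against experimental IHC readings.

## The funnel and its score

Starting from a gene table annotated with membrane-protein class membership
and per-(tissue, cell type) ordinal staining levels (*not detected / low /
medium / high*, weighted 0-3), the pipeline applies in order:

1. **membrane class** — keep predicted membrane proteins;
2. **protein evidence** — drop genes without IHC tissue data;
3. **critical normal tissues** — drop genes staining *high* (maximum over
   cell types) in any of 13 critical tissues: lung, the seven
   gastrointestinal sub-tissues (oral mucosa, esophagus, stomach, duodenum,
   small intestine, colon, rectum), liver, kidney, heart muscle, skin and
   bone marrow;
4. **quasi H-score threshold** — for each tumor-type cohort with patient
   counts (n₀, n₁, n₂, n₃) in the four staining categories, compute

       quasi H-score = 100 · (1·n₁ + 2·n₂ + 3·n₃) / (n₀+n₁+n₂+n₃)  ∈ [0, 300]

   and keep genes reaching ≥ 150 in at least one of the 20 tumor types
   (a cohort with zero assayed patients has an *undefined* score and never
   passes);
5. **surfaceome** — intersect with the predicted cell-surface proteome.

Survivors ("potential targets") then face a three-flag validation — RNA
consistency with matched FPKM values, literature conformity, and a
predominantly membranous staining pattern — and only genes passing all
three become **candidate targets**, ranked by maximum score, breadth of
tumor types at threshold, and narrowness of normal-tissue expression.

The experimental counterpart is the per-core H-score
(intensity 0-3 × percent positive cells, averaged over the three cores of
each tumor, cores without tumor cells excluded), compared with the
atlas-derived quasi H-score by a one-sample t-test, and with transcript
abundance by Pearson correlation per tumor type.

Because the upstream atlas tables are large, versioned downloads, the
package ships a seeded generator of atlas-shaped synthetic datasets in
which every gene is planted to fail exactly one named funnel stage (or
validation flag), so the entire pipeline is testable offline against known
ground truth.

## Worked example

```sh
adcscreen simulate --out-dir demo/data --seed 42
adcscreen run-all  --in-dir demo/data --out-dir demo/out
```

prints `wrote 138 genes to demo/data` and `23 candidate targets; outputs in
demo/out`.  The funnel audit (`demo/out/audit.tsv`) shows each planted decoy
cohort of 20 genes leaving at its stage:

```
stage            n_in  n_out
membrane_class   138   118
protein_evidence 118    98
critical_normal   98    78
score_threshold   78    58
surfaceome        58    38
```

and the 38 potential targets shrink to the 23 planted candidates after
validation.  `candidates.tsv` ranks them; the top row

```
gene_id          gene_symbol  is_candidate  max_quasi_h  n_tumors_ge_cutoff  n_normal_high_or_medium
ENSG00000000004  G0004        1             291.6667     4                   20
```

reads: this gene's strongest cohort score is 291.7 of a possible 300, it
reaches the 150 threshold in 4 of 20 tumor types, and it shows medium-or-high
staining in 20 of 45 normal tissues.  `score_heatmap.png` /
`normal_heatmap.png` (with exact TSV sidecars) render the candidate ×
tumor-type score matrix and the candidate × 45-normal-tissue level matrix;
`correlations.tsv` gives the per-tumor-type Pearson correlation of candidate
scores with FPKM.

The statistics layer is also available directly:

```sh
adcscreen ihc-stats --mean 214.4 --sd 86.7 --n 68 --mu0 200 --out-dir demo/stats
# mean difference 14.40 (95% CI -6.59 to 35.39), p = 0.175
```

— a one-sample t-test of 68 experimental tumor H-scores (mean 214.4,
SD 86.7) against an atlas-derived quasi H-score of 200: no significant
difference, i.e. the atlas score is experimentally supported.

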