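# clonepitope

Clonal somatic mutation analysis and MHC class II neoantigen candidate
prediction for tumor sequencing cohorts.

Tumor-specific mutant peptides (neo-antigens) presented by HLA molecules are
targets for cancer vaccines and markers of checkpoint-blockade response.
Candidates are most useful when the underlying mutation is **clonal**
(present in every cancer cell) and **expressed**. `clonepitope` implements
the desk-scale analysis chain that turns a cohort of somatic mutation calls
into ranked class II (HLA-DRB1) neo-antigen candidates:

1. **Sample QC** — drop samples with purity < 20% or ploidy > 6; one tumor
   sample per patient.
2. **Mutation filters** — remove calls seen at > 1% in a panel of normals,
   flagged in dbSNP or 1000 Genomes, or covered by fewer than 10 reads.
3. **Clonality** — for each mutation with alt/ref read counts, purity α and
   local total copy number q, the cancer cell fraction (CCF) posterior is

   ```
   pdf(CCF) ∝ Beta( CCF·α / (2(1−α) + α·q) ;  alt+1, ref+1 )
   ```

   normalized over CCF ∈ [0, 1] on a grid. A mutation is called clonal when
   the upper end of its 95% credible interval reaches 0.95. A simplified
   grid-MLE purity estimator on the same beta model is included.
4. **Expression gate** — genes with ≥ 3 RNA-seq reads count as expressed.
5. **Peptide windows** — mutant proteins are built from HGVS-p descriptions
   (substitutions, in-frame indels, frameshifts translated to the first
   stop), and every 15-mer (class II) or 8–11-mer (class I) window inside
   the 29-residue context that overlaps a mutant residue is enumerated.
6. **Binding** — a pluggable predictor scores (peptide, allele) pairs in
   IC50 nM; < 50 nM is a strong binder, < 500 nM weak. A deterministic toy
   position-weight-matrix scorer keeps the pipeline runnable offline; an
   adapter contract wraps external predictors.
7. **Cohort statistics** — per-patient neo-antigen burden, per-gene
   frequencies, and per-allele enrichment (one-sided Mann–Whitney U with
   Benjamini–Hochberg correction).

A synthetic-cohort generator with a full ground-truth manifest makes every
stage testable end to end without any data downloads.

## Worked example

```bash
clonepitope simulate --outdir bundle --seed 7 --n-patients 12 --mean-mutations 40
clonepitope run-all --mutations bundle/mutations.tsv --samples bundle/samples.tsv \
    --segments bundle/segments.seg --expression bundle/expression.tsv \
    --proteome bundle/proteome.fasta --cds bundle/cds.fasta \
    --outdir out --allele-mode panel
```

The run summary (also written to `out/summary.json`) reports the funnel and
binding totals; with the 8-allele panel used here:

```
"stages": {
  "samples_in": 12, "samples_qc": 12,
  "mutations_in": 476, "mutations_filtered": 445,
  "mutations_clonal": 246, "mutations_expressed_clonal": 167,
  "mutations_with_candidates": 106
},
"neo_peptides": {"strong": 0, "weak": 2924, "total": 2924}
```

476 simulated mutations shrink to 445 after artifact/germline/depth
filtering, 246 are clonal, 167 of those are expressed, and 106 yield
mutant peptide windows; scoring every window against the panel leaves 2,924
distinct (peptide, allele) binders. `out/per_patient.tsv` is the
waterfall-style burden table (mutation-level, strongest category per
mutation):

```
patient_id  smoker  n_strong  n_weak  n_other_mutations
    PT0009    True         0      15                 11
    PT0005   False         0      12                  3
    PT0008    True         0      11                  2
```

and `out/per_allele.tsv` ranks alleles by enrichment p-value. The same
steps are available as library calls (`generate_cohort`, `filter_mutations`,
`ccf_posterior`, `enumerate_windows`, `score_candidates`,
`allele_enrichment`) and as sklearn-style estimators (`MutationFilter`,
`ClonalityModel`, `PurityGridMLE`, `ToyPSSMPredictor`).

Library snippet — the CCF posterior of a mutation with 10 alt / 30 ref
reads in a pure diploid tumor peaks at CCF 0.5 (VAF 0.25 → half the cells):

```python
>>> from clonepitope import ccf_posterior, MutationRecord
>>> m = MutationRecord("P1", "KRAS", "12", 25245350, "C", "A",
...                    "missense", alt_count=10, ref_count=30)
>>> post = ccf_posterior(m, purity=1.0, local_cn=2)
>>> post.mode, post.is_clonal
(0.5, False)
```

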