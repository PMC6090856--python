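# Methods

## Scope and data model

The package analyzes cohorts of somatic mutation calls at desk scale. All
coordinates are 1-based inclusive (MAF/SEG convention). The seven variant
classes tracked are missense, silent, nonsense, splice site,
non-stop/read-through, frameshift indel and in-frame indel; standard MAF
`Variant_Classification` strings are mapped through an explicit alias table
and anything unrecognized errors loudly. Panel-of-normals evidence is
consumed as a precomputed per-site frequency column (no live database
access), and dbSNP/1000 Genomes evidence as boolean membership flags.

## Sample and mutation gates

Samples are dropped when purity < 0.20 or ploidy > 6 (both strict, i.e. the
boundary values 0.20 and 6.0 are kept); duplicate samples per patient keep
the first occurrence with a warning, since no principled tie-break exists
in the data model. Mutations are removed when PoN frequency > 1% (strict),
when flagged in dbSNP or 1000 Genomes, or when tumor depth (alt + ref) < 10
reads. "Covered reads" is interpreted as tumor depth because only tumor
counts exist in the data model. The cascade order
(PoN → dbSNP → 1000G → coverage) only affects the attribution of removals,
never membership, which is order-invariant and tested as such. The
database-membership removal is boolean by default; an optional
`germline_af_max` ceiling retains flagged records whose site frequency is
at or below the ceiling, for pipelines whose annotations encode population
frequency rather than bare membership.

## Clonality model

A mutation carried by a fraction CCF of tumor cells, in a sample of purity
α with local total copy number q, has expected variant allele fraction

    E[VAF](CCF) = CCF · α / (2(1 − α) + α·q),

assuming a diploid normal contaminant and mutation multiplicity 1 (one
mutated copy per carrying cell; the model deliberately has no multiplicity
term). The read counts define a Beta(alt+1, ref+1) density over VAF;
evaluating it at E[VAF](CCF) and renormalizing over CCF ∈ [0, 1] yields the
CCF posterior.

Numerical choices: grid resolution 0.01 (101 points); the density is
computed in log space and exponentiated after subtracting the maximum, so
deep-coverage posteriors do not underflow; normalization and moments use
the trapezoid rule; the credible interval is central (equal-tail) at 95%,
read off the cumulative trapezoid; the mode tie-break takes the smallest
CCF. A mutation in a segment of copy number 0 cannot be modeled and raises
an error; a mutation with no covering segment defaults to q = 2 with a
warning. A posterior that vanishes on the whole grid raises an error naming
the record.

**Clonal call.** A mutation is clonal when the upper CI bound reaches
`clonal_ccf_min` (default 0.95). "Close to 1" admits several formalizations
(point-estimate threshold, posterior-mass rule); the CI-overlap rule was
chosen because it is monotone in evidence — deep subclonal mutations are
confidently excluded while shallow, uninformative mutations remain clonal-
compatible — and the threshold is configurable.

**Purity grid MLE.** As a desk-scale stand-in for joint
purity/ploidy/segment inference (which is out of scope; purity and ploidy
normally arrive as inputs), purity can be estimated by maximizing

    Σ_m log [ w·BetaPDF(E[VAF](1; α, q_m); alt+1, ref+1)
              + (1−w)·∫₀¹ BetaPDF(E[VAF](c; α, q_m)) dc ]

over α ∈ {0.05, 0.06, …, 1.00}, i.e. each mutation is clonal with prior
weight w = 0.8 and otherwise uniform in CCF. The clonal point mass is what
identifies α (clonal mutations at q = 2 sit at VAF α/2); the uniform
component absorbs subclonal contamination. Fewer than 10 mutations trigger
a low-confidence warning.

## Expression gate and peptide windows

A (patient, gene) pair is expressed when its RNA read count is ≥ 3; absent
pairs count as 0. Note the gate is gene-level: expression of the mutant
allele itself is not verified, and truncating variants subject to
nonsense-mediated decay may pass the gate while the mutant transcript is
absent.

Mutant proteins are built from HGVS-p. Supported dialects: `p.G12C`
substitutions (a `*` alternate is a stop gain and yields no peptide),
`p.V73fs` frameshifts, `p.ELREA746del` deletions, `p.773_774insH`
insertions and `p.709_710ET>D` deletion-insertions; embedded whitespace is
ignored; reference residues are checked against the protein and mismatches
error with position and residues. Frameshift descriptions do not carry the
nucleotide event, so frameshifts are modeled canonically as a 1-bp deletion
at the first base of the stated codon, translated in the shifted frame to
the first stop; the novel span runs from the first residue that differs
from wild type to the new C-terminus. The CDS must be in frame with the
wild-type protein.

Window enumeration unifies the 29-mer scanning context with the
requirement that candidate peptides contain a mutant residue: for each
length L (15 for class II, 8–11 for class I), every L-mer inside the
mutant span padded by 14 residues per side (truncated at the termini) that
overlaps the span is emitted, deduplicated by (sequence, length). For an
interior substitution this yields exactly 15 fifteen-mers and 38 class I
windows; windows without a mutant residue are wild-type self peptides and
are never emitted. For frameshifts the span covers the whole novel tail, so
the enumeration reduces to "last L−1 wild-type residues plus the tail".
Splice-site and non-stop variants have no defined protein product in this
data model and are skipped with a logged reason; silent and nonsense
variants yield no candidates.

## Binding scores

Binding calls carry IC50 in nM with strict thresholds: strong < 50,
weak < 500. The built-in scorer derives a 9×20 position weight matrix per
allele from a seeded generator (SHA-256 of `namespace|allele`), scores a
peptide as the minimum over its 9-mer cores of the mean per-position
weight, and maps the raw score s ∈ [0, 1] to IC50 = 50000^(1−s) nM — the
50,000 nM ceiling matching the convention of the neural predictor family
the adapter contract targets. The toy scorer exists to make the pipeline
and its statistics runnable and testable offline; it models no
immunochemistry, and its name is recorded on every call. With uniform
random matrices, raw scores concentrate well below the strong-binder
threshold, so toy runs produce predominantly weak binders; that is a
property of the stand-in, not of the pipeline. External predictors plug in
through an adapter that writes peptide lists, invokes a configured
executable and parses a `peptide/allele/ic50_nm` TSV; a missing executable
is a hard error, never a silent fallback.

Allele handling: `typed` scores each candidate against its patient's typed
alleles, `panel` scores every candidate against the full configured panel
(the all-alleles assumption used when typing is unavailable — note this
overstates per-patient burden by design), and `auto` (default) uses typed
alleles when present. The mode is recorded in the run summary.

## Cohort statistics

Two counting units coexist and both are reported: *neo-antigen mutations*
(a mutation counts once per patient, at the strongest category any of its
windows/alleles achieves) drive the per-patient burden waterfall, and
*neo-peptides* (distinct (patient, mutation, peptide, allele) binder calls)
drive per-allele totals. Per-gene rows carry binder-peptide counts, the
count of mutations with no binder, and the fraction of patients with ≥ 1
neo-antigen in the gene.

The Mann–Whitney U statistic is computed from midrank sums; p-values are
exact (full enumeration over rank assignments) when n+m ≤ 12 with no ties,
otherwise a normal approximation with tie correction and 0.5 continuity
correction. Benjamini–Hochberg adjustment is the step-up
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1. Both are cross-checked against
independent reference implementations in the tests.

Allele enrichment contrasts, for each allele, its per-patient neo-peptide
counts against one count per (patient, other allele) pair, one-sided
(greater), BH-adjusted across alleles. The contrast is a design choice —
the table structure it reproduces (one p per allele) does not pin down the
comparison groups — and per-patient counts across alleles are not
independent, so the test is interpreted as a ranking device; its null
calibration is nevertheless verified by simulation with exchangeable
alleles. An allele with no evaluable data is emitted with p = 1 and
flagged.

## Synthetic cohorts

`generate_cohort` emulates exactly the structure the model assumes: purity
uniform in a configurable range (default 0.3–0.9); per-mutation true CCF 1
(clonal, default fraction 0.54) or a fixed subclonal value (default 0.4);
depth negative-binomial (mean 80, dispersion 10); alt counts binomial at
E[VAF]; one whole-chromosome copy-number segment per patient and
chromosome with q ∈ {1, 2, 3, 4} weighted toward diploid; zero-inflated
negative-binomial expression; 1–2 DRB1 alleles per patient from a
31-allele panel; and class proportions matching a large lung
adenocarcinoma cohort (~274 mutations per patient, ~4.7% indels split
~91:9 frameshift:in-frame). Proteins are uniform random 100–600-mers with
a deterministic reverse-translated CDS, and every mutation carries a valid
HGVS-p (splice/non-stop records carry an empty description, documented
above). Determinism: one root seed; per-patient and per-gene streams are
derived from `SeedSequence([seed, stream, index])`, so the same seed gives
byte-identical files and adding patients never changes earlier patients.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: mutational signatures and hotspot recurrence,
realistic genome coordinates and segment structure, correlated
expression/copy-number, subclonal population structure beyond a single
subclonal CCF, HLA linkage disequilibrium, and any true immunogenicity.
Recovery results (purity, clonality, enrichment) demonstrate correctness
of the inference under its own model, not field performance.

A planted allele enrichment multiplies one allele's raw toy scores by a
configurable factor (default 1.5, capped at 1), giving the enrichment
statistics a controllable effect size.

## Problem sizes and defaults

Acceptance-style checks run at: 100 random instances for the posterior
oracle (tolerance 1e-8); 20 simulations × purities {0.3, 0.5, 0.8} × 200
mutations at depth 80 for purity recovery (median error ≤ 0.05); 300
clonal + 300 subclonal mutations at depth 80, purity 0.9 for
classification (sensitivity and specificity ≥ 0.9); 200 random instances
for window enumeration; 50 seeds × 8 alleles × 60 patients for null
calibration (within 3 binomial SEs of 0.05); and 20 simulations of 100
patients × ~20 mutations for planted-enrichment detection (≥ 18/20). The
end-to-end cohort in `scripts/acceptance.py` uses 147 patients at ~60
mutations per patient with the full 31-allele panel — the package's
desk-scale working size for a cohort of that many patients.

## Known limitations

- Mutation multiplicity is fixed at 1; amplified mutant alleles bias CCF
  downward-of-truth in the model's own terms.
- The purity MLE assumes a predominantly clonal mutation set and a correct
  local copy number; it is a convenience estimator, not a replacement for
  joint purity/ploidy callers.
- The germline filter is membership-based; without population allele
  frequencies it cannot distinguish rare germline variants from somatic
  calls present in databases.
- Mutation identity for burden/enrichment uses (patient, gene, protein
  change); two distinct genomic events producing the same protein change in
  the same patient would merge.
- HGVS-p coverage is the dialect set above; complex rearrangements and
  extension variants are rejected rather than guessed.
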