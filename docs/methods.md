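# Methods

## Scope and data model

The package implements the computational core of a bulk RNA-seq comparison
of adipogenic (Adi) and myogenic (Myo) precursor cells: novel-lncRNA
discovery from assembled candidate transcripts, two-group differential
expression, cis-target inference, shared-miRNA ceRNA networks, and generic
term enrichment. Transcripts are modeled as ordered, non-overlapping exon
intervals on a chromosome strand, held 0-based half-open internally; GTF
I/O converts from the 1-based closed convention at the boundary. Interval
queries go through per-(chromosome, strand) interval trees and are tested
against brute-force scans.

## Discovery cascade

Candidates pass, in order: duplicate collapse → length → background →
known-overlap → coding-potential consensus. The survivor *set* is
order-independent (each rule is a per-transcript predicate once duplicates
are collapsed); the order only determines which rule an audit record blames.
Choices that were genuinely open:

- **Duplicate collapse** keys multi-exon transcripts on (chromosome, strand,
  intron chain) and monoexonic ones on exact exon coordinates; the survivor
  is the longest by exonic length, ties broken lexicographically by id.
- **Background filter.** The filter removes a transcript when its maximal
  expression is below 2.0 *and* it is sparse (detected in < 2 samples or
  monoexonic). The conjunctive reading was chosen because published DE
  lncRNA sets of this design contain monoexonic, well-expressed entries
  that a disjunctive monoexon rule would have removed; the disjunctive mode
  is available via `mode="disjunctive"`. "Expression" is RPKM by
  convention (configurable to counts by passing a counts frame).
- **Coding potential.** The built-in predictor calls a transcript coding
  when its longest forward-strand ORF (ATG through stop, any frame, stop
  required, length including the stop codon) is ≥ 300 nt or covers ≥ 50% of
  the transcript. These are conventional lncRNA-calling thresholds, not
  derived from any particular dataset. External predictors (CPC, CNCI,
  Pfam-scan, …) are not reimplemented; their output merges in via a
  tab-delimited call file and the consensus is the strict intersection:
  every predictor must say noncoding. Adding a predictor can therefore only
  shrink the lncRNA set.
- **Classification.** Same-strand exonic overlap ⇒ `sense_overlap`;
  otherwise opposite-strand exonic overlap ⇒ `antisense`; otherwise fully
  inside an intron of a known transcript on either strand ⇒ `intronic`;
  else `intergenic`. A candidate on a chromosome absent from the reference
  is intergenic (logged).

## Differential expression

RPKM_ij = 10⁹·c_ij/(N_j·L_i) with N_j the column sum and L_i the feature
length. Size factors are plain median-of-ratios over features positive in
every sample. The test is a per-feature negative-binomial Wald test on
normalized counts:

- **Dispersion.** At 2–3 samples per group a per-feature dispersion is far
  too noisy to test against, so a single dispersion φ is estimated for the
  whole matrix by Cox–Reid-adjusted profile likelihood (group means
  profiled out; the adjustment −½ log(n·w) per fitted mean removes the
  downward plug-in bias). A second pass drops features whose
  method-of-moments dispersion exceeds 10× the first estimate — e.g.
  transcripts with strong extra-NB covariation — and refits, so a handful
  of wild features cannot inflate φ. `prior_df` optionally shrinks
  per-feature method-of-moments estimates toward the common value in log
  space (weight df/(df+prior_df)) for data where dispersions genuinely
  vary; the default is the common value, which is what keeps the test's
  size at its nominal level in the regime this package targets (measured
  ≈ 0.05 at the 0.035–0.065 level on 2,000 null NB features, 3 vs 3,
  φ = 0.1).
- **Statistic.** log₂FC = log₂(μ̂_Myo/μ̂_Adi), SE from the delta method
  (Var(log μ̂) ≈ (1/μ + φ)/n per group), two-sided normal p-value. A group
  that is all zero contributes a pseudo-mean of 0.5 to the fold change
  only; all-zero features are reported (log₂FC 0, p 1) and flagged.
- **Calling rule.** up iff fold change ≥ 2 and BH-adjusted q < 0.05; down
  iff fold change ≤ 0.5 and q < 0.05; else ns. Fold changes are reported
  Myo/Adi on the natural scale. BH adjustment is the standard step-up
  procedure (statsmodels), verified against a brute-force implementation.
- A paired t-test on log₂(RPKM+1), pairing samples by animal, is provided
  as an alternative (`paired_log_ratio_test`) for designs where the paired
  analysis is preferred. Full DESeq2 behaviour (dispersion trends, Cook's
  filtering, independent filtering, shrinkage) is deliberately out of
  scope; the calling thresholds, not the engine, are the contract.

## Cis targets

Neighbour search returns protein-coding genes with exonic overlap, genes
whose body contains the lncRNA ("Intron" relation), and genes whose span
gap lies within [window_min, window_max]. window_max defaults to 100 kb;
window_min defaults to 0 rather than 10 kb because published cis tables of
this design include overlap, intron and sub-10-kb relations, which a strict
lower bound would exclude. Up/downstream is oriented by the *gene's* strand
(upstream = toward the gene's 5′); `orientation="genomic"` switches to
coordinate order. Acceptance requires |Pearson r| > 0.6 strictly, computed
across all samples' RPKM (Adi and Myo pooled — with three samples per
group this is the only construction with enough points). Gene-level
expression is the sum over the gene's transcript rows when no gene-level
row exists. The homology screen (k = 11 anchors, ungapped X-drop extension,
+1/−2 scoring, Karlin–Altschul E with K = 0.71, λ = 1.37, both strands) is
off by default: its role in the original workflow is ambiguous, so it is
exposed as an optional pre-filter rather than wired into the main path.

## ceRNA network

miRanda-style thermodynamic scoring is replaced by canonical seed classes:
7mer-m8 (target matches the reverse complement of miRNA nt 2–8), 8mer
(7mer-m8 followed by A), 7mer-A1 (reverse complement of nt 2–7 followed by
A). Each target position is reported once under its strongest class. The
network links a lncRNA and an mRNA iff their bound-miRNA sets intersect;
the edge label is the exact intersection, verified against a brute-force
double loop. SIF export carries no node types, so a SIF round trip
preserves edge sets but re-types targets generically; GraphML preserves
everything.

## Enrichment and qPCR arithmetic

Term enrichment is the upper-tail hypergeometric test P(X ≥ k) for k DE
genes among n, in a term covering K of N universe genes, BH-corrected
across terms. No transcript-length bias correction (goseq-style Wallenius
weighting) is applied, so term lists from length-aware tools will differ;
the universe is a required user input because results depend strongly on
it. 2^−ΔΔCt is computed exactly as defined; platform concordance is the
Pearson correlation of log₂ fold changes over features shared between
RNA-seq and qPCR.

## Synthetic data generator

The generator emulates the study conditions end to end: one synthetic
chromosome; 80 known protein-coding genes (3–5 exons of 160–300 nt) and 10
known lncRNAs; 50 planted novel lncRNAs (20 intergenic, 15 intronic inside
enlarged first introns, 15 antisense overlapping a known first exon on the
opposite strand); 50 decoys, one kind per filter — too short (< 200 nt),
monoexonic low expression, same-strand exonic overlap, long-ORF coding
(ORF ≫ 300 nt). The chromosome background is scrubbed of ATG (and CAT, its
reverse-strand image) so non-coding transcripts have no ORF by
construction; coding sequences (short ATG-free leader, stop-free codon
body, stop) are pasted into mRNA and coding-decoy exons, strand-aware.

Counts follow the DE caller's model: NB with dispersion 0.1 around
base·FC^[Myo]·animal, where base means are log-normal (coding genes median
20,000 reads — putting library sizes in the low millions so RPKM is on a
realistic scale — lncRNAs and candidates lower), FC = 4 or ¼ for the 20
planted DE mRNAs and 16 planted DE lncRNAs, and the paired animal effect
is a log-normal factor (σ = 0.2) shared by the two samples of an animal.

Planted cis pairs draw a single shared standard-normal per-sample profile
z, entering each member's log-mean with amplitude σ_i² = ρ·u_i/(1−ρ),
where u_i ≈ φ + 1/base_i is that member's residual log-scale noise; this
makes the pair's log-expression correlation equal the target ρ (default
0.95) in expectation. Cis-pair members are *not* planted differentially
expressed: realizing r ≈ 0.95 at six samples requires per-sample
covariation large enough that a 3 vs 3 group comparison of those same
features would have essentially no power, so the DE and cis plantings
probe disjoint feature sets by design. miRNA seed sites are planted by
in-place substitution of the exact 8mer complement (transcript lengths
unchanged), re-checking that no planted lncRNA's coding call flips; only
transcripts whose exons are not shared with other features are wired, so a
substitution cannot silently rewrite a second transcript.

What the generator does **not** emulate: splice-isoform complexity,
read-level error or positional bias (counts are drawn, not aligned), GC or
length bias in quantification, dispersion variation across features,
multi-chromosome structure, and real miRNA target-site context
(conservation, AU content, 3′-supplementary pairing). Passing tests on
this data therefore demonstrates the correctness of the pipeline's logic
and its statistical calibration under its own model — not robustness to
the full messiness of real libraries.

## Problem sizes and numerics

The default synthetic study is 190 features × 6 samples; the test suite and
the acceptance script use it directly, plus 2,000-feature null matrices for
calibration, 200 replicate count draws for cis-pair recovery, 1,000 random
vectors for the BH oracle, 500 random candidates for the classification
oracle, and exhaustive hypergeometric enumeration for N ≤ 25 — the whole
suite runs in well under a minute. Determinism: every random draw flows
from a single integer seed through per-stage `numpy` generator streams, so
identical configurations yield byte-identical output files. Numerical
edge cases: zero-variance expression vectors yield a skipped-pair sentinel
rather than NaN correlations; zero column sums and missing feature lengths
are errors; dispersion estimates are floored at 10⁻⁸; fold-change
reporting for half-zero features uses a 0.5 pseudo-mean; strict
inequalities follow the stated rules exactly (expression < 2.0 removes,
|r| > 0.6 accepts, q < 0.05 calls).

## Known limitations

- The NB test's common dispersion is a deliberate simplification; data with
  strongly feature-dependent dispersion should use `prior_df` or an
  external engine, and the package makes no attempt to reproduce DESeq2's
  exact numbers.
- The |r| > 0.6 cis rule at n = 6 admits ~20% of null neighbour pairs;
  cis-target lists at this design size are hypothesis generators, not
  validated targets.
- Seed matching ignores binding energetics and site context, so site lists
  are a superset of what an energy-scored predictor would return; the
  network-construction logic downstream is unaffected.
- The enrichment test ignores transcript-length selection bias.
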