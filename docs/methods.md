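# Methods

## Model and assumptions

`transhit` searches for compound-heterozygous coding/noncoding diagnoses in
recessive disease genes using trio genome data. The underlying genetic model
is simple: a gene acting recessively needs both copies damaged; when a
proband carries a single heterozygous high-impact coding variant, a rare
noncoding variant on the *other* haplotype may be the missing second allele.
Phase is inferred from transmission, which assumes:

* both parents are genotyped and correctly assigned (no sample swaps,
  non-paternity handled upstream);
* a heterozygous proband allele carried by exactly one parent was
  transmitted by that parent. When both parents carry the allele the
  transmitting haplotype is undecidable without read-backed phasing, so the
  variant is classed *ambiguous* and excluded from trans determination
  rather than guessed. De novo variants are likewise excluded: a variant
  absent from both parents has no informative transmission, and the
  compound-het model under study is specifically the inherited one;
* sites are autosomal-diploid. Hemizygous/chrX handling is not specialized;
  chrX genes should be interpreted with care.

Two variants are **in trans** when their resolved transmissions differ.
This is symmetric and is asserted for every reported candidate.

## Filter cascade

Coding hits must be heterozygous pLoF (stop gained, splice donor/acceptor,
frameshift; LOFTEE low-confidence excluded) or ClinVar P/LP with review
status in {criteria_provided,_multiple_submitters,_no_conflicts;
reviewed_by_expert_panel; practice_guideline}, in a listed recessive gene,
with resolved transmission, cohort AF ≤ 0.5%, gnomAD popmax AF ≤ 0.5%, and
genotype QC (FILTER PASS, depth ≥ 6, proband VAF in [0.25, 0.75]).
Noncoding candidates must lie in the gene's region set, pass the same
genotype QC, be transmitted by the alternative parent, have gnomAD
filtering AF ≤ 0.5% in **every** continental population (implemented as a
max-over-populations column), cohort AF ≤ 0.5%, not intersect any
representative-transcript CDS, and carry no benign ClinVar assertion.

Boundary conventions, chosen once and applied everywhere: thresholds phrased
as exclusions ("> 0.5%", "< 25% or > 75%", "< 6") retain equality, so AF of
exactly 0.005, VAF of exactly 0.25 or 0.75 and depth of exactly 6 all pass;
rule thresholds phrased as inclusions (SpliceAI ≥ 0.1, CADD ≥ 15/20,
PhyloP ≥ 5) fire at equality. The retention filters are a pure conjunction;
tests verify the retained set is independent of evaluation order.

One deliberate reading: the QC sentence for noncoding variants, taken
literally, would *retain* only allele-imbalanced calls; the coding-variant
convention (retain VAF 25–75%) is applied uniformly, since keeping only
imbalanced calls would select precisely the least trustworthy genotypes.

When two qualifying variants in one gene of one proband are in trans, the
pair is flagged `possible_coding_diagnosis` and excluded from the noncoding
search (a coding compound het should be resolved as such). The one
exception is handled by the fast path: two ClinVar P/LP variants in trans,
one protein-altering and one noncoding, are reported immediately with
`fast_path_clinvar=True` and bypass the rule engine.

## Regions

Coordinates are 0-based half-open internally; GTF (1-based closed) and VCF
(1-based) are converted at the boundary, BED is native. Per transcript:
introns are exon gaps (introns lying entirely on a UTR side of the CDS are
flagged `utr_intron` but keep class `intron`, and remain eligible for the
intronic SpliceAI rule); UTRs are exonic sequence outside the CDS, 5′ on the
TSS side; the promoter is the 5000 bp strictly upstream of the TSS on the
transcript strand, split 200 bp core + 4800 bp extended, clipped at contig
boundaries rather than erroring. With multiple transcripts per gene, regions
are built per transcript and carry transcript provenance. A position in
several classes resolves by precedence core_promoter > extended_promoter >
utr5 > utr3 > intron > atac_coaccessible.

Accessibility peaks are kept when accessible in ≥ 5% of cells **or** at or
above the empirical 95th percentile of the supplied peak set's specificity
scores (the percentile is computed over the input set globally — per-cell-
type scoring would require the raw single-cell data). Candidate enhancers
are kept peaks overlapping a listed gene's promoter window plus peaks
linked to such a peak by a coaccessibility edge, expanded **one hop only**
(both link directions); transitive multi-hop expansion is intentionally not
performed, and the hop count is not currently a parameter of the public
API. Links naming unknown peaks are warned about and ignored.

## Prioritization rules

Per region: intron — SpliceAI ≥ 0.1; core promoter — always; extended
promoter — (TFBS or accessibility-peak overlap) and CADD ≥ 15; 5′UTR —
SpliceAI ≥ 0.1, TFBS overlap, a UTR-annotator consequence, or IRES overlap;
3′UTR — SpliceAI ≥ 0.1, miRNA-site overlap, or a polyadenylation signal
(annotated feature or canonical AATAAA motif covering the variant, scanned
on the transcript-orientation sequence since AATAAA is a transcript-strand
motif); any region including candidate enhancers — PhyloP ≥ 5 or
CADD ≥ 20. The SpliceAI score is the maximum of the four delta scores,
consumed precomputed.

Two rule-design decisions were genuinely open. First, whether the CADD ≥ 15
condition of the promoter rule also applies to core-promoter variants: it
is attached only to the TFBS/accessibility branch, so core-promoter
variants are prioritized unconditionally — deleteriousness scores are poor
predictors in core promoters, and a known diagnostic core-promoter variant
(GAA, CADD 5.88) would otherwise be missed; the worked-example regression
test pins this behavior. Second, missing scores never satisfy a threshold
(they fail the comparison, with the rejection logged), so candidates are
never prioritized on absent evidence.

Prioritization is monotone in each score (raising SpliceAI, CADD or PhyloP
can only add fired rules), a property the suite checks with randomized
inputs.

## Fisher exact test with conditional-MLE odds ratio

Green-gene enrichment among probable candidates is tested on a 2×2 table
(a = probable ∧ green, b = probable ∧ not, c = other ∧ green, d = other ∧
not). The two-sided p-value sums hypergeometric probabilities of all tables
with the observed margins whose probability is ≤ the observed table's
("minimum-likelihood" convention, with a 1+1e−7 relative tolerance against
floating-point ties; a tail-doubling alternative is exposed as an option).
The odds ratio is the conditional MLE: the ψ of Fisher's noncentral
hypergeometric distribution with E<sub>ψ</sub>[X] = a. E<sub>ψ</sub>[X] is
strictly increasing in ψ (asserted numerically in the suite), so the root
is unique; it is found by Brent's method on log ψ with an expanding bracket
to near machine precision, with weights evaluated via log-gamma and a
max-shift for stability. Edge cases: a at the support minimum/maximum gives
OR 0/∞; a degenerate margin gives p = 1 with undefined OR (NaN). The
implementation is cross-checked in tests against exhaustive enumeration,
a grid-search likelihood maximizer, and SciPy's independent routines. The
CMLE is reported (alongside the sample cross-product ratio) because it is
what standard exact-test software prints and, for small unbalanced tables
like (6,1;12,35), the two differ visibly (16.5 vs 17.5).

Percentages are computed exactly in decimal arithmetic and rounded to one
decimal, half away from zero.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes — not
sequence realism. Defaults describe the study conditions used throughout
the end-to-end tests: 200 trios, 30 genes (one contig of 20 kb per gene),
AF thresholds of 0.5%, and 25 planted trans pairs plus 25 decoys of each
class. Each gene gets one transcript with 3–5 exons (200–400 bp), introns
of 0.5–1.5 kb, non-empty UTRs (5′ 20–80 bp, 3′ 60–150 bp), random strand,
and ≥ 5 kb of clear flank so the promoter window fits; half the genes carry
an AATAAA motif in the 3′UTR so the polyA scanner has positives. Planted
trans pairs cycle the noncoding variant through intron, core promoter,
5′UTR, 3′UTR and extended promoter, each with annotation values that fire
exactly the intended region rule. Decoys differ from a reportable pair in
exactly one respect (same-parent transmission, de novo, common in cohort or
in one gnomAD population at 0.73%, failed depth/VAF/FILTER QC, ClinVar
benign, or CDS placement), so each exercises one filter. Optional fast-path
pairs plant two ClinVar P/LP variants in trans. Variants are private SNVs
(reference base from the generated sequence, transition alternate); cohort
AF is therefore 2/(6·n) for a planted pair and is *computed from the emitted
genotypes*, never stored independently, which makes the AF filter testable
end to end — and implies that in cohorts smaller than ~67 trios even a
perfect trans pair is unreportable (2/(6·67) > 0.5%); the truth table
accounts for this.

What the generator does **not** emulate: mutation-rate heterogeneity,
linkage disequilibrium, sequencing error, read-level evidence,
multi-transcript genes, shared chromosomes between genes, or
sequence-derived scores (SpliceAI/CADD/PhyloP values are assigned).
Passing the recovery tests therefore demonstrates the correctness of the
filter logic, phasing and bookkeeping under the assumed data model — not
calibration of the annotations themselves on real genomes.

All randomness flows through one seeded NumPy generator; identical
(config, seed) yields byte-identical GTF/FASTA/VCF/TSV/BED outputs, which
the suite checks by hashing the output tree.

## RNA helpers

`allele_balance` returns the alternate-read fraction with an integer
percent (half-up), matching how allele-specific expression at an
NMD-degraded allele is read off an alignment. `normalized_intron_coverage`
divides per-intron read counts by the gene's total count and flags a sample
whose value **strictly** exceeds every comparison sample for that intron —
ties flag nobody and at most one sample can be flagged per intron. More
elaborate outlier statistics (z-scores, negative-binomial models) are out
of scope; the helper mirrors the strict visual comparison used when
inspecting intron retention against batch controls.

## Problem sizes and numerical settings

End-to-end tests run 200 trios × 30 genes per seed (20 seeds in the
acceptance suite, 5 replicate seeds in `scripts/acceptance.py`), roughly
0.4 s per cohort including file I/O. The CMLE root is solved to near
machine precision; the oracle-equivalence test requires |Δp| < 1e−10
against enumeration and |Δlog OR| < 1e−4 against a grid maximizer on 500
random tables of total ≤ 30.

## Known limitations

* No read-backed or population phasing: both-parent-carrier sites are
  dropped, losing some true compound hets.
* Second hits are sought only in the coding hit's own gene's regions;
  distal enhancers beyond supplied coaccessible peaks are out of reach.
* Structural variants are out of scope entirely (a real second hit that is
  an exonic deletion will be missed).
* The internal cohort AF is an allele frequency over called alleles;
  unlisted sites are assumed homozygous reference.
* The one-hop coaccessibility expansion and the global specificity
  percentile are simplifications of cell-type-resolved accessibility
  analysis.
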