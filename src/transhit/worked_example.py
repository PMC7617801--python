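"""Worked example: seven published coding/noncoding candidate pairs.

A curated set of compound-heterozygous coding/noncoding candidate pairs from
rare-disease diagnostics (genes GAA, NPHP3, ALMS1, LAMA2, IGHMBP2, PKHD1 and
PAH), with the noncoding variant's region class and its published SpliceAI,
PhyloP and CADD annotations.  Feeding these through the prioritization rule
engine must prioritize all seven and reproduce the published rule
assignments: the GAA promoter variant (182 bp upstream of the TSS) fires the
core-promoter rule despite unimpressive deleteriousness scores; NPHP3 and
ALMS1 fire only the conservation/deleteriousness catch-all; the four
intronic splice candidates fire the intronic SpliceAI rule (PAH also clears
the CADD catch-all).
"""

from __future__ import annotations

from transhit.coding_hits import ProbandVariantPair
from transhit.noncoding_hits import CandidateSecondHit
from transhit.prioritization import (
    NoncodingAnnotationRecord,
    PrioritizationResult,
    Thresholds,
    prioritize,
)
from transhit.trio_genotypes import Transmission, VariantKey

# gene -> (region_class, noncoding key, spliceai_max, phylop, cadd)
WORKED_EXAMPLE_CANDIDATES: dict[str, tuple[str, VariantKey, float | None, float | None, float]] = {
    "GAA": ("core_promoter", VariantKey("chr17", 80101399, "C", "G"), None, -0.19, 5.88),
    "NPHP3": ("intron", VariantKey("chr3", 132684549, "C", "T"), 0.04, 6.15, 21.0),
    "ALMS1": ("intron", VariantKey("chr2", 73573562, "G", "A"), 0.01, 3.84, 20.2),
    "LAMA2": ("intron", VariantKey("chr6", 129475360, "G", "GT"), 0.10, None, 8.48),
    "IGHMBP2": ("intron", VariantKey("chr11", 68929807, "G", "A"), 0.12, -1.91, 0.21),
    "PKHD1": ("intron", VariantKey("chr6", 51882440, "T", "C"), 0.95, -0.30, 8.22),
    "PAH": ("intron", VariantKey("chr12", 102843790, "C", "T"), 0.98, 0.88, 23.5),
}

EXPECTED_RULES: dict[str, frozenset[str]] = {
    "GAA": frozenset({"promoter_core"}),
    "NPHP3": frozenset({"global_conservation"}),
    "ALMS1": frozenset({"global_conservation"}),
    "LAMA2": frozenset({"intronic_spliceai"}),
    "IGHMBP2": frozenset({"intronic_spliceai"}),
    "PKHD1": frozenset({"intronic_spliceai"}),
    "PAH": frozenset({"intronic_spliceai", "global_conservation"}),
}


def prioritize_worked_example(
    thresholds: Thresholds = Thresholds(),
) -> dict[str, PrioritizationResult]:
    """Run the rule engine over the seven-candidate worked example."""
    results: dict[str, PrioritizationResult] = {}
    for gene, (region, key, spliceai, phylop, cadd) in WORKED_EXAMPLE_CANDIDATES.items():
        pair = ProbandVariantPair(
            proband_id=f"example_{gene}",
            gene_id=gene,
            coding_variant=VariantKey(key.chrom, 1, "N", "A"),
            coding_transmission=Transmission.MATERNAL,
            hit_class="plof",
        )
        candidate = CandidateSecondHit(
            pair=pair,
            noncoding_variant=key,
            region_class=region,
            noncoding_transmission=Transmission.PATERNAL,
            gnomad_faf=0.0,
            cohort_af=0.0,
        )
        record = NoncodingAnnotationRecord(
            key=key, spliceai_max=spliceai, cadd=cadd, phylop=phylop
        )
        results[gene] = prioritize(candidate, record, thresholds)
    return results
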