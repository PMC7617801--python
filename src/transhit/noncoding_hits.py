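"""Candidate noncoding second-hit discovery.

For each proband-variant pair the gene's noncoding regions are searched for
rare heterozygous variants transmitted by the alternative parent to the
coding hit (i.e. in trans, completing the expected recessive inheritance).
Retention requires: genotype QC pass, resolved opposite transmission, gnomAD
filtering allele frequency <= 0.5% in every major continental population
(modeled as a max-over-populations column), internal cohort AF <= 0.5%, no
overlap with any representative-transcript CDS, and no benign ClinVar
assertion.  Pairs of ClinVar pathogenic/likely-pathogenic variants in trans
(one protein-altering, one noncoding) take a fast path that bypasses the
prioritization rule engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from transhit.coding_hits import (
    CodingAnnotation,
    ProbandVariantPair,
    is_clinvar_qualifying,
)
from transhit.region_builder import NoncodingRegion
from transhit.trio_genotypes import (
    Genotype,
    Transmission,
    TrioGenotype,
    VariantKey,
    classify_transmission,
    in_trans,
    passes_genotype_qc,
)

log = logging.getLogger(__name__)

# precedence when a position falls in several region classes
REGION_PRECEDENCE = (
    "core_promoter",
    "extended_promoter",
    "utr5",
    "utr3",
    "intron",
    "atac_coaccessible",
)

BENIGN_CLNSIG = frozenset({"benign", "likely_benign", "benign/likely_benign"})

PROTEIN_ALTERING_CONSEQUENCES = frozenset({
    "missense_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "frameshift",
    "inframe_insertion",
    "inframe_deletion",
    "splice_acceptor_variant",
    "splice_acceptor",
    "splice_donor_variant",
    "splice_donor",
    "synonymous_variant",
    "coding_sequence_variant",
})


@dataclass(frozen=True)
class CandidateSecondHit:
    """A noncoding variant in trans with a pair's coding hit."""

    pair: ProbandVariantPair
    noncoding_variant: VariantKey
    region_class: str | None
    noncoding_transmission: Transmission
    gnomad_faf: float
    cohort_af: float
    utr_intron: bool = False
    fast_path_clinvar: bool = False


def assign_region(
    v: VariantKey, regions: Sequence[NoncodingRegion]
) -> tuple[str, bool] | None:
    """Region class containing a variant position, with utr_intron flag.

    A position in several classes resolves by the fixed precedence
    core_promoter > extended_promoter > utr5 > utr3 > intron >
    atac_coaccessible.  Returns None for a position outside all regions
    (e.g. inside coding sequence).
    """
    pos0 = v.pos - 1
    hits = [r for r in regions if r.chrom == v.chrom and r.contains(pos0)]
    if not hits:
        return None
    best = min(hits, key=lambda r: REGION_PRECEDENCE.index(r.region_class))
    return best.region_class, best.utr_intron


def _is_benign(clnsig: str | None) -> bool:
    if clnsig is None:
        return False
    return clnsig.strip().replace(" ", "_").lower() in BENIGN_CLNSIG


def _overlaps_cds(v: VariantKey, mane_cds: Sequence[tuple[str, int, int]]) -> bool:
    s, e = v.span0
    return any(c == v.chrom and s < ce and cs < e for c, cs, ce in mane_cds)


def retention_filters(
    pair: ProbandVariantPair,
    regions: Sequence[NoncodingRegion],
    annotations: Mapping[VariantKey, CodingAnnotation],
    faf_by_key: Mapping[VariantKey, float],
    faf_threshold: float,
    cohort_threshold: float,
    mane_cds: Sequence[tuple[str, int, int]],
) -> list[tuple[str, Callable[[TrioGenotype], bool]]]:
    """Named retention predicates for one pair's second-hit search.

    Exposed separately so the retained set can be shown to be independent of
    filter order.  Every predicate is total over heterozygous proband
    genotypes of the pair's gene.
    """

    def in_region(g: TrioGenotype) -> bool:
        return assign_region(g.key, regions) is not None

    def qc(g: TrioGenotype) -> bool:
        return passes_genotype_qc(g)

    def trans(g: TrioGenotype) -> bool:
        tr = classify_transmission(g)
        if tr not in (Transmission.MATERNAL, Transmission.PATERNAL):
            return False
        return in_trans(pair.coding_transmission, tr)

    def faf(g: TrioGenotype) -> bool:
        return faf_by_key.get(g.key, 0.0) <= faf_threshold

    def cohort_af(g: TrioGenotype) -> bool:
        ann = annotations.get(g.key)
        return ann is not None and ann.cohort_af <= cohort_threshold

    def not_cds(g: TrioGenotype) -> bool:
        return not _overlaps_cds(g.key, mane_cds)

    def not_benign(g: TrioGenotype) -> bool:
        ann = annotations.get(g.key)
        return ann is None or not _is_benign(ann.clnsig)

    return [
        ("in_region", in_region),
        ("genotype_qc", qc),
        ("in_trans", trans),
        ("gnomad_faf", faf),
        ("cohort_af", cohort_af),
        ("mane_cds_overlap", not_cds),
        ("clinvar_benign", not_benign),
    ]


def find_second_hits(
    pair: ProbandVariantPair,
    regions: Sequence[NoncodingRegion],
    trio_genotypes: Sequence[TrioGenotype],
    annotations: Mapping[VariantKey, CodingAnnotation],
    faf_by_key: Mapping[VariantKey, float],
    faf_threshold: float = 0.005,
    cohort_threshold: float = 0.005,
    mane_cds: Sequence[tuple[str, int, int]] = (),
) -> list[CandidateSecondHit]:
    """Retain noncoding variants in trans with a pair's coding hit.

    ``trio_genotypes`` are the proband's trio records restricted (by the
    caller or not) to the pair's gene neighborhood; the coding variant itself
    is excluded.  ``faf_by_key`` carries the gnomAD filtering allele
    frequency maximized over continental populations; a frequency of exactly
    the threshold is retained.  Each rejection is logged with its first
    failing filter.
    """
    filters = retention_filters(
        pair, regions, annotations, faf_by_key,
        faf_threshold, cohort_threshold, mane_cds,
    )
    out: list[CandidateSecondHit] = []
    for g in sorted(trio_genotypes, key=lambda t: t.key):
        if g.key == pair.coding_variant or g.proband_gt != Genotype.HET:
            continue
        failed = next((name for name, pred in filters if not pred(g)), None)
        if failed is not None:
            log.debug("second-hit reject %s for pair %s/%s: %s",
                      g.key, pair.proband_id, pair.gene_id, failed)
            continue
        region_class, utr_intron = assign_region(g.key, regions)
        ann = annotations.get(g.key)
        out.append(CandidateSecondHit(
            pair=pair,
            noncoding_variant=g.key,
            region_class=region_class,
            noncoding_transmission=classify_transmission(g),
            gnomad_faf=faf_by_key.get(g.key, 0.0),
            cohort_af=ann.cohort_af if ann is not None else 0.0,
            utr_intron=utr_intron,
        ))
    return out


def detect_clinvar_trans_fast_path(
    genotypes_by_proband: Mapping[str, Sequence[TrioGenotype]],
    annotations: Mapping[VariantKey, CodingAnnotation],
    faf_by_key: Mapping[VariantKey, float] | None = None,
    regions_by_gene: Mapping[str, Sequence[NoncodingRegion]] | None = None,
    af_threshold: float = 0.005,
) -> list[CandidateSecondHit]:
    """Immediately prioritize trans pairs of ClinVar P/LP variants.

    For each proband and gene, emits a candidate when two ClinVar-qualifying
    variants are in trans with one protein-altering and the other noncoding.
    Both variants must pass genotype QC and the allele-frequency filters.
    These candidates carry ``fast_path_clinvar=True`` and bypass the
    prioritization rule engine.
    """
    faf_by_key = faf_by_key or {}
    out: list[CandidateSecondHit] = []
    for proband_id in sorted(genotypes_by_proband):
        by_gene: dict[str, list[tuple[TrioGenotype, CodingAnnotation, Transmission]]] = {}
        for g in genotypes_by_proband[proband_id]:
            if g.proband_gt != Genotype.HET:
                continue
            ann = annotations.get(g.key)
            if ann is None or not is_clinvar_qualifying(ann):
                continue
            if not passes_genotype_qc(g):
                continue
            if ann.cohort_af > af_threshold:
                continue
            tr = classify_transmission(g)
            if tr not in (Transmission.MATERNAL, Transmission.PATERNAL):
                continue
            by_gene.setdefault(ann.gene_id, []).append((g, ann, tr))
        for gene_id, recs in sorted(by_gene.items()):
            for i, (g1, a1, t1) in enumerate(recs):
                for g2, a2, t2 in recs[i + 1:]:
                    coding, noncoding = None, None
                    for (g, a, t) in ((g1, a1, t1), (g2, a2, t2)):
                        if a.consequence & PROTEIN_ALTERING_CONSEQUENCES:
                            coding = (g, a, t)
                        else:
                            noncoding = (g, a, t)
                    if coding is None or noncoding is None:
                        continue
                    if not in_trans(coding[2], noncoding[2]):
                        continue
                    gnc, anc, tnc = noncoding
                    if faf_by_key.get(gnc.key, 0.0) > af_threshold:
                        continue
                    region = None
                    utr_intron = False
                    if regions_by_gene is not None:
                        hit = assign_region(gnc.key, regions_by_gene.get(gene_id, ()))
                        if hit is not None:
                            region, utr_intron = hit
                    pair = ProbandVariantPair(
                        proband_id=proband_id,
                        gene_id=gene_id,
                        coding_variant=coding[0].key,
                        coding_transmission=coding[2],
                        hit_class="clinvar_pathogenic",
                    )
                    out.append(CandidateSecondHit(
                        pair=pair,
                        noncoding_variant=gnc.key,
                        region_class=region,
                        noncoding_transmission=tnc,
                        gnomad_faf=faf_by_key.get(gnc.key, 0.0),
                        cohort_af=anc.cohort_af,
                        utr_intron=utr_intron,
                        fast_path_clinvar=True,
                    ))
    return out
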