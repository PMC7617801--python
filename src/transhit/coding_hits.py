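"""Qualifying single heterozygous coding variants.

A proband-variant pair is a proband carrying a single heterozygous qualifying
coding variant — a high-confidence predicted loss-of-function (pLoF), or a
ClinVar (likely) pathogenic variant with a strong review status — in a gene
from the recessive-disease gene list.  Six exclusion filters apply: de novo
variants, cohort allele frequency > 0.5%, gnomAD popmax AF > 0.5%, proband
allele fraction outside 25-75%, non-PASS FILTER, and depth < 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

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

PLOF_CONSEQUENCES = frozenset({
    "stop_gained",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "frameshift_variant",
    # short VEP-style aliases
    "splice_acceptor",
    "splice_donor",
    "frameshift",
})

CLNSIG_PATHOGENIC = frozenset({
    "Pathogenic",
    "Likely_pathogenic",
    "Pathogenic/Likely_pathogenic",
})

CLNREVSTAT_ACCEPTED = frozenset({
    "criteria_provided,_multiple_submitters,_no_conflicts",
    "reviewed_by_expert_panel",
    "practice_guideline",
})


@dataclass(frozen=True)
class CodingAnnotation:
    """Per-variant annotation consumed from precomputed sources."""

    key: VariantKey
    gene_id: str
    consequence: frozenset[str]
    loftee_confidence: str = "absent"  # high | low | absent
    clnsig: str | None = None
    clnrevstat: str | None = None
    cohort_af: float = 0.0
    gnomad_popmax_af: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cohort_af", "gnomad_popmax_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


@dataclass(frozen=True)
class ProbandVariantPair:
    """The unit of the downstream second-hit search."""

    proband_id: str
    gene_id: str
    coding_variant: VariantKey
    coding_transmission: Transmission
    hit_class: str  # plof | clinvar_pathogenic
    possible_coding_diagnosis: bool = False


def is_plof(a: CodingAnnotation) -> bool:
    """High-confidence predicted loss-of-function.

    Requires a LoF consequence (stop gained, splice acceptor/donor,
    frameshift); calls classed low-confidence by LOFTEE are excluded.
    """
    return bool(a.consequence & PLOF_CONSEQUENCES) and a.loftee_confidence != "low"


def is_clinvar_qualifying(a: CodingAnnotation) -> bool:
    """ClinVar pathogenic / likely pathogenic with accepted review status."""
    if a.clnsig is None or a.clnrevstat is None:
        return False
    clnsig, clnrevstat = a.clnsig.strip(), a.clnrevstat.strip()
    if clnsig in CLNSIG_PATHOGENIC and clnrevstat in CLNREVSTAT_ACCEPTED:
        return True
    if clnsig not in CLNSIG_PATHOGENIC and clnsig not in (
        "", "Benign", "Likely_benign", "Benign/Likely_benign",
        "Uncertain_significance", "Conflicting_interpretations_of_pathogenicity",
        "not_provided",
    ):
        log.warning("unrecognized CLNSIG %r treated as non-qualifying", clnsig)
    return False


def find_single_coding_hits(
    genotypes_by_proband: Mapping[str, Sequence[TrioGenotype]],
    annotations: Mapping[VariantKey, CodingAnnotation],
    gene_list: Iterable[str],
    af_threshold: float = 0.005,
) -> list[ProbandVariantPair]:
    """Identify qualifying single heterozygous coding hits per proband.

    A variant qualifies when it is heterozygous in the proband, lies in a
    listed gene, is a pLoF or ClinVar-qualifying variant, passes genotype QC,
    has cohort AF and gnomAD popmax AF <= ``af_threshold`` (a frequency of
    exactly the threshold is retained), and has resolved parental
    transmission (de novo, ambiguous and untyped variants are excluded).

    When two qualifying coding variants in the same gene of one proband are
    in trans, both pairs are flagged ``possible_coding_diagnosis`` — a likely
    coding compound heterozygote that should be excluded from the noncoding
    second-hit search.  A proband may contribute pairs in several genes.
    """
    genes = set(gene_list)
    pairs: list[ProbandVariantPair] = []
    for proband_id in sorted(genotypes_by_proband):
        per_gene: dict[str, list[ProbandVariantPair]] = {}
        for g in genotypes_by_proband[proband_id]:
            if g.proband_gt != Genotype.HET:
                continue
            ann = annotations.get(g.key)
            if ann is None:
                log.warning("variant %s missing from annotation table; skipped", g.key)
                continue
            if ann.gene_id not in genes:
                continue
            if is_plof(ann):
                hit_class = "plof"
            elif is_clinvar_qualifying(ann):
                hit_class = "clinvar_pathogenic"
            else:
                continue
            if not passes_genotype_qc(g):
                continue
            if ann.cohort_af > af_threshold or ann.gnomad_popmax_af > af_threshold:
                continue
            tr = classify_transmission(g)
            if tr not in (Transmission.MATERNAL, Transmission.PATERNAL):
                continue
            per_gene.setdefault(ann.gene_id, []).append(ProbandVariantPair(
                proband_id=proband_id,
                gene_id=ann.gene_id,
                coding_variant=g.key,
                coding_transmission=tr,
                hit_class=hit_class,
            ))
        for gene_id, gene_pairs in sorted(per_gene.items()):
            flagged = len(gene_pairs) >= 2 and any(
                in_trans(p.coding_transmission, q.coding_transmission)
                for i, p in enumerate(gene_pairs)
                for q in gene_pairs[i + 1:]
            )
            for p in gene_pairs:
                pairs.append(
                    ProbandVariantPair(**{
                        **p.__dict__, "possible_coding_diagnosis": flagged,
                    })
                )
    return pairs
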