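"""Region-specific prioritization of candidate second hits.

Candidates are prioritized when any region-appropriate rule fires:

* intron (including UTR introns): SpliceAI >= 0.1
* core promoter: always (the 200 bp directly upstream of the TSS)
* extended promoter: overlap of a TFBS or accessibility peak, with CADD >= 15
* 5' UTR: SpliceAI >= 0.1, TFBS overlap, a UTR-annotator consequence, or an
  internal ribosome entry site overlap
* 3' UTR: SpliceAI >= 0.1, an experimental miRNA binding-site overlap, or a
  polyadenylation signal (annotated feature or canonical AATAAA motif)
* any region (including accessibility-linked candidate enhancers):
  PhyloP >= 5 and/or CADD >= 20
* ClinVar P/LP trans pairs fire the fast-path rule unconditionally.

The SpliceAI score is the maximum of the four delta scores; the core-promoter
rule carries no CADD condition (deleteriousness scores are poor predictors in
core promoters, and prioritizing all core-promoter variants keeps hypomorphic
regulatory alleles such as weak promoter SNVs in view).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from transhit.noncoding_hits import CandidateSecondHit
from transhit.trio_genotypes import VariantKey

log = logging.getLogger(__name__)

RULES = (
    "intronic_spliceai",
    "promoter_core",
    "promoter_regulatory_cadd",
    "utr5_spliceai",
    "utr5_tfbs",
    "utr5_utrannotator",
    "utr5_ires",
    "utr3_spliceai",
    "utr3_mirna",
    "utr3_polya",
    "global_conservation",
    "clinvar_fast_path",
)

POLYA_MOTIF = "AATAAA"


@dataclass(frozen=True)
class NoncodingAnnotationRecord:
    """Precomputed annotation for one noncoding variant.

    Scores may be missing (None): a missing score never satisfies a
    threshold.  Overlap flags are computed against the corresponding
    interval resources (TFBS, accessibility peaks, miRNA sites, IRES,
    annotated polyA features).
    """

    key: VariantKey
    spliceai_max: float | None = None
    cadd: float | None = None
    phylop: float | None = None
    tfbs_overlap: bool = False
    atac_overlap: bool = False
    utrannotator_consequence: str | None = None
    ires_overlap: bool = False
    mirna_site_overlap: bool = False
    polya_feature_overlap: bool = False

    def __post_init__(self) -> None:
        if self.spliceai_max is not None and not 0.0 <= self.spliceai_max <= 1.0:
            raise ValueError(f"spliceai_max out of [0,1]: {self.spliceai_max}")


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff of the filter cascade, with defaults."""

    spliceai_min: float = 0.1
    cadd_promoter_min: float = 15.0
    cadd_global_min: float = 20.0
    phylop_min: float = 5.0
    core_promoter_bp: int = 200
    upstream_bp: int = 5000
    af_max: float = 0.005
    min_depth: int = 6
    vaf_low: float = 0.25
    vaf_high: float = 0.75


@dataclass(frozen=True)
class PrioritizationResult:
    candidate: CandidateSecondHit
    fired_rules: frozenset[str]

    @property
    def prioritized(self) -> bool:
        return bool(self.fired_rules)


def scan_polya(utr3_sequence: str, variant_offset: int) -> bool:
    """True when an AATAAA occurrence covers the variant offset.

    The sequence must be supplied in transcript orientation (minus-strand
    genes reverse-complemented), since the polyadenylation signal is a
    transcript-strand motif.
    """
    if not 0 <= variant_offset < len(utr3_sequence):
        raise ValueError(
            f"variant offset {variant_offset} outside sequence of length {len(utr3_sequence)}"
        )
    seq = utr3_sequence.upper()
    start = 0
    while True:
        i = seq.find(POLYA_MOTIF, start)
        if i < 0:
            return False
        if i <= variant_offset < i + len(POLYA_MOTIF):
            return True
        start = i + 1


def _ge(value: float | None, threshold: float) -> bool:
    return value is not None and value >= threshold


def prioritize(
    c: CandidateSecondHit,
    a: NoncodingAnnotationRecord,
    t: Thresholds = Thresholds(),
    utr3_sequence: str | None = None,
    utr3_offset: int | None = None,
) -> PrioritizationResult:
    """Evaluate all region-specific rules for one candidate.

    ``utr3_sequence``/``utr3_offset`` enable the motif-based polyA scan for
    3' UTR candidates; when absent, only the annotated polyA feature flag can
    fire that rule.
    """
    fired: set[str] = set()
    rc = c.region_class

    if c.fast_path_clinvar:
        fired.add("clinvar_fast_path")

    if rc == "intron" and _ge(a.spliceai_max, t.spliceai_min):
        fired.add("intronic_spliceai")
    elif rc == "core_promoter":
        fired.add("promoter_core")
    elif rc == "extended_promoter":
        if (a.tfbs_overlap or a.atac_overlap) and _ge(a.cadd, t.cadd_promoter_min):
            fired.add("promoter_regulatory_cadd")
    elif rc == "utr5":
        if _ge(a.spliceai_max, t.spliceai_min):
            fired.add("utr5_spliceai")
        if a.tfbs_overlap:
            fired.add("utr5_tfbs")
        if a.utrannotator_consequence:
            fired.add("utr5_utrannotator")
        if a.ires_overlap:
            fired.add("utr5_ires")
    elif rc == "utr3":
        if _ge(a.spliceai_max, t.spliceai_min):
            fired.add("utr3_spliceai")
        if a.mirna_site_overlap:
            fired.add("utr3_mirna")
        polya = a.polya_feature_overlap
        if not polya and utr3_sequence is not None and utr3_offset is not None:
            polya = scan_polya(utr3_sequence, utr3_offset)
        if polya:
            fired.add("utr3_polya")

    # catch-all over every region class, including candidate enhancers
    if _ge(a.phylop, t.phylop_min) or _ge(a.cadd, t.cadd_global_min):
        fired.add("global_conservation")

    return PrioritizationResult(candidate=c, fired_rules=frozenset(fired))
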