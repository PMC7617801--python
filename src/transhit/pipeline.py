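"""End-to-end orchestration over an on-disk cohort directory.

Expected inputs (as produced by :mod:`transhit.synthetic_data`, or assembled
from real data in the same layout): ``genes.gtf``, ``reference.fa``,
``trios.ped.tsv`` with per-trio VCFs, ``annotations.tsv``, interval BEDs
(``tfbs.bed``, ``atac_peaks.bed``, ``mirna.bed``, ``ires.bed``),
``coaccessibility.tsv`` and ``recessive_genes.txt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from transhit.coding_hits import CodingAnnotation, ProbandVariantPair, find_single_coding_hits
from transhit.cohort_stats import CohortSummary, summarize
from transhit.noncoding_hits import (
    CandidateSecondHit,
    detect_clinvar_trans_fast_path,
    find_second_hits,
)
from transhit.prioritization import (
    NoncodingAnnotationRecord,
    PrioritizationResult,
    Thresholds,
    prioritize,
)
from transhit.region_builder import (
    GeneModel,
    NoncodingRegion,
    build_regions,
    filter_atac_peaks,
    link_enhancer_candidates,
    read_atac_bed,
    read_gene_models_gtf,
    read_links_tsv,
)
from transhit.trio_genotypes import (
    TrioGenotype,
    VariantKey,
    read_pedigree,
    read_trio_vcf,
)

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class PipelineResult:
    pairs: list[ProbandVariantPair]
    flagged_pairs: list[ProbandVariantPair]
    candidates: list[CandidateSecondHit]
    fastpath_candidates: list[CandidateSecondHit]
    prioritization: list[PrioritizationResult]
    summary: CohortSummary
    regions_by_gene: dict[str, list[NoncodingRegion]]
    models: list[GeneModel]

    @property
    def all_candidates(self) -> list[CandidateSecondHit]:
        return self.candidates + self.fastpath_candidates

    @property
    def reported_set(self) -> set[tuple[str, str, VariantKey, VariantKey]]:
        """(proband, gene, coding key, noncoding key) of every reported combination."""
        return {
            (c.pair.proband_id, c.pair.gene_id, c.pair.coding_variant, c.noncoding_variant)
            for c in self.all_candidates
        }

    @property
    def prioritized_set(self) -> set[tuple[str, str, VariantKey, VariantKey]]:
        return {
            (r.candidate.pair.proband_id, r.candidate.pair.gene_id,
             r.candidate.pair.coding_variant, r.candidate.noncoding_variant)
            for r in self.prioritization if r.prioritized
        }


def load_annotations(
    path: str | Path,
    cohort_af: Mapping[VariantKey, float],
) -> tuple[dict[VariantKey, CodingAnnotation], dict[VariantKey, float], pd.DataFrame]:
    """Read the annotation TSV, injecting computed cohort allele frequencies.

    Returns the annotation map, the gnomAD filtering-AF map (max over
    continental populations) and the raw frame (for score lookups).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    anns: dict[VariantKey, CodingAnnotation] = {}
    fafs: dict[VariantKey, float] = {}
    faf_cols = [c for c in df.columns if c.startswith("faf_")]
    for r in df.itertuples(index=False):
        key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        consequence = frozenset(str(r.consequence).split("&"))
        anns[key] = CodingAnnotation(
            key=key,
            gene_id=r.gene_id,
            consequence=consequence,
            loftee_confidence=r.loftee if isinstance(r.loftee, str) else "absent",
            clnsig=r.clnsig if isinstance(r.clnsig, str) else None,
            clnrevstat=r.clnrevstat if isinstance(r.clnrevstat, str) else None,
            cohort_af=float(cohort_af.get(key, 0.0)),
            gnomad_popmax_af=float(r.gnomad_popmax_af),
        )
        pops = [getattr(r, c) for c in faf_cols]
        pops = [p for p in pops if pd.notna(p)]
        fafs[key] = float(max(pops)) if pops else float(getattr(r, "gnomad_faf", 0.0))
    return anns, fafs, df


def _interval_trees(rows: Sequence[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in rows:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def _read_bed3(path: Path) -> list[tuple[str, int, int]]:
    if not path.exists():
        return []
    out = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        c, s, e = line.split("\t")[:3]
        out.append((c, int(s), int(e)))
    return out


def _overlaps_tree(trees: Mapping[str, IntervalTree], key: VariantKey) -> bool:
    t = trees.get(key.chrom)
    if t is None:
        return False
    s, e = key.span0
    return bool(t.overlap(s, e))


def _utr3_pieces(m: GeneModel) -> list[tuple[int, int]]:
    """Genomic (ascending) exonic 3'UTR intervals of a gene model."""
    pieces = []
    for s, e in m.exons:
        if m.strand == "+":
            lo, hi = max(s, m.cds_end), e
        else:
            lo, hi = s, min(e, m.cds_start)
        if lo < hi:
            pieces.append((lo, hi))
    return pieces


def utr3_sequence_and_offset(
    m: GeneModel, fasta, pos0: int
) -> tuple[str, int] | None:
    """Transcript-orientation 3'UTR sequence and the offset of a position.

    Returns None when the position is not inside the exonic 3'UTR.  The
    polyA motif is a transcript-strand signal, so minus-strand sequence is
    reverse-complemented before scanning.
    """
    pieces = _utr3_pieces(m)
    if not pieces:
        return None
    seq_asc = "".join(str(fasta[m.chrom][s:e]) for s, e in pieces).upper()
    off_asc = None
    cum = 0
    for s, e in pieces:
        if s <= pos0 < e:
            off_asc = cum + (pos0 - s)
            break
        cum += e - s
    if off_asc is None:
        return None
    if m.strand == "+":
        return seq_asc, off_asc
    return _revcomp(seq_asc), len(seq_asc) - 1 - off_asc


def run_pipeline(
    cohort_dir: str | Path,
    faf_threshold: float = 0.005,
    cohort_threshold: float = 0.005,
    coding_af_threshold: float = 0.005,
    thresholds: Thresholds = Thresholds(),
) -> PipelineResult:
    """Run the full second-hit search over a cohort directory."""
    from pyfaidx import Fasta

    d = Path(cohort_dir)
    trios = read_pedigree(d / "trios.ped.tsv")
    genotypes_by_proband: dict[str, list[TrioGenotype]] = {}
    for t in trios:
        genotypes_by_proband[t.proband_id] = read_trio_vcf(
            d / t.vcf_path, t.proband_id, t.father_id, t.mother_id
        )

    # internal cohort allele frequency from the emitted genotypes
    an = 6 * len(trios)
    ac: dict[VariantKey, int] = {}
    dosage = {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": 0}
    for recs in genotypes_by_proband.values():
        for g in recs:
            ac[g.key] = ac.get(g.key, 0) + (
                dosage[g.proband_gt.value] + dosage[g.mother_gt.value]
                + dosage[g.father_gt.value]
            )
    cohort_af = {k: v / an for k, v in ac.items()}

    annotations, faf_by_key, ann_df = load_annotations(d / "annotations.tsv", cohort_af)

    models = read_gene_models_gtf(d / "genes.gtf")
    gene_list = [
        line.strip() for line in (d / "recessive_genes.txt").read_text().splitlines()
        if line.strip()
    ]

    regions_by_gene: dict[str, list[NoncodingRegion]] = {}
    promoter_regions: list[NoncodingRegion] = []
    mane_cds: list[tuple[str, int, int]] = []
    for m in models:
        regs = build_regions(m, upstream_bp=thresholds.upstream_bp,
                             core_bp=thresholds.core_promoter_bp)
        regions_by_gene[m.gene_id] = regs
        promoter_regions += [
            r for r in regs if r.region_class in ("core_promoter", "extended_promoter")
        ]
        for s, e in m.exons:
            lo, hi = max(s, m.cds_start), min(e, m.cds_end)
            if lo < hi:
                mane_cds.append((m.chrom, lo, hi))

    peaks = read_atac_bed(d / "atac_peaks.bed") if (d / "atac_peaks.bed").exists() else []
    kept_peaks = filter_atac_peaks(peaks) if peaks else []
    links = read_links_tsv(d / "coaccessibility.tsv") if (d / "coaccessibility.tsv").exists() else []
    gene_ids = {m.gene_id for m in models}
    for enh in link_enhancer_candidates(kept_peaks, links, promoter_regions):
        if enh.gene_id in gene_ids:
            regions_by_gene[enh.gene_id].append(enh)

    pairs_all = find_single_coding_hits(
        genotypes_by_proband, annotations, gene_list, af_threshold=coding_af_threshold
    )
    pairs = [p for p in pairs_all if not p.possible_coding_diagnosis]
    flagged = [p for p in pairs_all if p.possible_coding_diagnosis]

    candidates: list[CandidateSecondHit] = []
    for pair in pairs:
        candidates += find_second_hits(
            pair,
            regions_by_gene[pair.gene_id],
            genotypes_by_proband[pair.proband_id],
            annotations,
            faf_by_key,
            faf_threshold=faf_threshold,
            cohort_threshold=cohort_threshold,
            mane_cds=mane_cds,
        )

    fastpath = detect_clinvar_trans_fast_path(
        genotypes_by_proband, annotations, faf_by_key,
        regions_by_gene, af_threshold=coding_af_threshold,
    )

    # annotation overlays for prioritization
    tfbs_trees = _interval_trees(_read_bed3(d / "tfbs.bed"))
    mirna_trees = _interval_trees(_read_bed3(d / "mirna.bed"))
    ires_trees = _interval_trees(_read_bed3(d / "ires.bed"))
    atac_trees = _interval_trees([(p.chrom, p.start, p.end) for p in kept_peaks])

    score_cols = {}
    for r in ann_df.itertuples(index=False):
        key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        score_cols[key] = (
            None if pd.isna(r.spliceai_max) else float(r.spliceai_max),
            None if pd.isna(r.cadd) else float(r.cadd),
            None if pd.isna(r.phylop) else float(r.phylop),
        )

    fasta = Fasta(str(d / "reference.fa")) if (d / "reference.fa").exists() else None
    model_by_gene = {m.gene_id: m for m in models}

    results: list[PrioritizationResult] = []
    for c in candidates + fastpath:
        spliceai, cadd, phylop = score_cols.get(c.noncoding_variant, (None, None, None))
        rec = NoncodingAnnotationRecord(
            key=c.noncoding_variant,
            spliceai_max=spliceai,
            cadd=cadd,
            phylop=phylop,
            tfbs_overlap=_overlaps_tree(tfbs_trees, c.noncoding_variant),
            atac_overlap=_overlaps_tree(atac_trees, c.noncoding_variant),
            mirna_site_overlap=_overlaps_tree(mirna_trees, c.noncoding_variant),
            ires_overlap=_overlaps_tree(ires_trees, c.noncoding_variant),
        )
        utr3_seq = utr3_off = None
        if c.region_class == "utr3" and fasta is not None:
            hit = utr3_sequence_and_offset(
                model_by_gene[c.pair.gene_id], fasta, c.noncoding_variant.pos - 1
            )
            if hit is not None:
                utr3_seq, utr3_off = hit
        results.append(prioritize(c, rec, thresholds, utr3_seq, utr3_off))

    summary = summarize(pairs + [c.pair for c in fastpath], candidates + fastpath,
                        n_trios=len(trios))
    return PipelineResult(
        pairs=pairs,
        flagged_pairs=flagged,
        candidates=candidates,
        fastpath_candidates=fastpath,
        prioritization=results,
        summary=summary,
        regions_by_gene=regions_by_gene,
        models=models,
    )


def candidates_frame(result: PipelineResult) -> pd.DataFrame:
    """One row per proband-variant-second-hit combination."""
    rows = []
    fired = {
        (id(r.candidate)): sorted(r.fired_rules) for r in result.prioritization
    }
    for c in result.all_candidates:
        rows.append({
            "proband_id": c.pair.proband_id,
            "gene_id": c.pair.gene_id,
            "coding_variant": str(c.pair.coding_variant),
            "hit_class": c.pair.hit_class,
            "coding_transmission": c.pair.coding_transmission.value,
            "noncoding_variant": str(c.noncoding_variant),
            "region_class": c.region_class,
            "utr_intron": c.utr_intron,
            "noncoding_transmission": c.noncoding_transmission.value,
            "gnomad_faf": c.gnomad_faf,
            "cohort_af": c.cohort_af,
            "fast_path_clinvar": c.fast_path_clinvar,
            "fired_rules": ",".join(fired.get(id(c), [])),
        })
    return pd.DataFrame(rows)
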