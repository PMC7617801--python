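"""Noncoding search-space construction per gene.

For each recessive gene (one representative transcript) the search space is:
all introns, the 5' and 3' UTRs, a 5000 bp upstream promoter window split into
a 200 bp core promoter and the remaining extended promoter, and candidate
enhancer regions: chromatin-accessibility peaks overlapping the promoter
window plus peaks coaccessible (one hop) with such a promoter-overlapping
peak.

Coordinates are 0-based half-open internally; GTF (1-based closed) and VCF
positions (1-based) are converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

REGION_CLASSES = (
    "core_promoter",
    "extended_promoter",
    "utr5",
    "utr3",
    "intron",
    "atac_coaccessible",
)


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single representative transcript.

    exons are sorted non-overlapping 0-based half-open intervals; the CDS
    (``cds_start``..``cds_end``, genomic orientation) is contained in the exon
    union.  The TSS is the transcript start on the + strand and the transcript
    end on the - strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.gene_id}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"exons unsorted/overlapping in {self.gene_id}")
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValueError(f"CDS outside transcript span in {self.gene_id}")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """TSS as a 0-based position (on '-' strand: tx_end, i.e. the base at tx_end-1 is the first transcribed base)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))


@dataclass(frozen=True)
class NoncodingRegion:
    """A typed noncoding interval owned by a gene+transcript."""

    gene_id: str
    transcript_id: str
    region_class: str
    chrom: str
    start: int
    end: int
    source_peak_id: str | None = None
    utr_intron: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.region_class} ({self.start},{self.end})")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class AtacPeak:
    """Chromatin-accessibility peak with cell-level support and specificity."""

    peak_id: str
    chrom: str
    start: int
    end: int
    cell_fraction: float
    specificity_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise ValueError(f"cell_fraction out of [0,1]: {self.cell_fraction}")


def build_regions(
    model: GeneModel,
    upstream_bp: int = 5000,
    core_bp: int = 200,
    contig_length: int | None = None,
) -> list[NoncodingRegion]:
    """Construct intron, UTR and promoter regions for one gene model.

    Introns are the gaps between consecutive exons; an intron lying entirely
    on the UTR side of the CDS carries the ``utr_intron`` flag (it remains
    class "intron").  UTRs are exonic sequence outside the CDS, with utr5 on
    the TSS side.  The promoter is the ``upstream_bp`` window strictly
    upstream of the TSS on the transcript strand, split into a ``core_bp``
    core abutting the TSS and the remaining extended promoter; it is clipped
    at position 0 (and at ``contig_length`` when given) rather than erroring.
    Single-exon transcripts yield no introns; a CDS spanning the whole
    transcript yields no UTRs.
    """

    def reg(cls: str, s: int, e: int, utr_intron: bool = False) -> NoncodingRegion:
        return NoncodingRegion(
            gene_id=model.gene_id,
            transcript_id=model.transcript_id,
            region_class=cls,
            chrom=model.chrom,
            start=s,
            end=e,
            utr_intron=utr_intron,
        )

    out: list[NoncodingRegion] = []

    # 5'UTR is upstream of the CDS in transcript orientation: genomically left
    # of cds_start on '+', right of cds_end on '-'.
    for (s, e) in model.exons:
        left = (max(s, model.tx_start), min(e, model.cds_start))  # genomic-left UTR part
        right = (max(s, model.cds_end), min(e, model.tx_end))
        for (us, ue), side in ((left, "left"), (right, "right")):
            if us >= ue:
                continue
            if model.strand == "+":
                cls = "utr5" if side == "left" else "utr3"
            else:
                cls = "utr3" if side == "left" else "utr5"
            out.append(reg(cls, us, ue))

    for (s, e) in model.introns:
        utr_intron = e <= model.cds_start or s >= model.cds_end
        out.append(reg("intron", s, e, utr_intron=utr_intron))

    # promoter windows, strand-aware, clipped at contig bounds
    if model.strand == "+":
        core = (model.tss - core_bp, model.tss)
        ext = (model.tss - upstream_bp, model.tss - core_bp)
    else:
        core = (model.tss, model.tss + core_bp)
        ext = (model.tss + core_bp, model.tss + upstream_bp)
    hi = contig_length if contig_length is not None else np.inf
    for cls, (s, e) in (("core_promoter", core), ("extended_promoter", ext)):
        s, e = max(0, s), int(min(hi, e))
        if s < e:
            out.append(reg(cls, s, e))
    return out


def filter_atac_peaks(
    peaks: Sequence[AtacPeak],
    min_cell_fraction: float = 0.05,
    specificity_quantile: float = 0.95,
) -> list[AtacPeak]:
    """Keep peaks accessible in >=5% of cells or in the top 5% by specificity.

    The specificity cutoff is the empirical ``specificity_quantile`` of the
    supplied peak set's scores (kept when score >= cutoff).
    """
    if not peaks:
        return []
    scores = np.array([p.specificity_score for p in peaks], dtype=float)
    cutoff = float(np.quantile(scores, specificity_quantile))
    return [
        p for p in peaks
        if p.cell_fraction >= min_cell_fraction or p.specificity_score >= cutoff
    ]


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def link_enhancer_candidates(
    peaks: Sequence[AtacPeak],
    links: Iterable[tuple[str, str]],
    promoter_regions: Sequence[NoncodingRegion],
) -> list[NoncodingRegion]:
    """Candidate enhancer regions from promoter-overlapping and linked peaks.

    A peak qualifies for a gene when it overlaps one of that gene's promoter
    regions (core or extended), or when a coaccessibility link (in either
    direction, one hop) connects it to such a promoter-overlapping peak.
    Returned regions carry class ``atac_coaccessible`` with the anchoring
    gene and the source peak id.  Links naming unknown peak ids are ignored
    with a warning.
    """
    by_id = {p.peak_id: p for p in peaks}
    promoters = [r for r in promoter_regions
                 if r.region_class in ("core_promoter", "extended_promoter")]

    # gene -> set of anchor peak ids
    anchors: dict[tuple[str, str], set[str]] = {}
    for p in peaks:
        for r in promoters:
            if p.chrom == r.chrom and _overlaps(p.start, p.end, r.start, r.end):
                anchors.setdefault((r.gene_id, r.transcript_id), set()).add(p.peak_id)

    selected: dict[tuple[str, str], set[str]] = {k: set(v) for k, v in anchors.items()}
    for a, b in links:
        if a not in by_id or b not in by_id:
            log.warning("coaccessibility link (%s, %s) references unknown peak id; ignored", a, b)
            continue
        for gene_key, anchor_ids in anchors.items():
            if a in anchor_ids:
                selected[gene_key].add(b)
            if b in anchor_ids:
                selected[gene_key].add(a)

    out: list[NoncodingRegion] = []
    for (gene_id, transcript_id), peak_ids in sorted(selected.items()):
        for pid in sorted(peak_ids):
            p = by_id[pid]
            out.append(NoncodingRegion(
                gene_id=gene_id,
                transcript_id=transcript_id,
                region_class="atac_coaccessible",
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                source_peak_id=pid,
            ))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_models_gtf(gtf_path: str | Path) -> list[GeneModel]:
    """Parse gene models (one transcript per gene) from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        keep_order=True, merge_strategy="error", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript", order_by="start"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
        if not cds:
            raise ValueError(f"transcript {tx.id} has no CDS feature")
        models.append(GeneModel(
            gene_id=tx.attributes["gene_id"][0],
            transcript_id=tx.attributes["transcript_id"][0],
            chrom=tx.seqid,
            strand=tx.strand,
            exons=tuple(exons),
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
        ))
    return models


def read_atac_bed(path: str | Path) -> list[AtacPeak]:
    """Read peaks from BED (chrom, start, end, peak_id, cell_fraction, specificity)."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "peak_id", "cell_fraction", "specificity"],
        dtype={"chrom": str, "peak_id": str},
    )
    return [
        AtacPeak(r.peak_id, r.chrom, int(r.start), int(r.end),
                 float(r.cell_fraction), float(r.specificity))
        for r in df.itertuples(index=False)
    ]


def read_links_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read coaccessibility links (peak_id_a, peak_id_b) from TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(r.peak_id_a, r.peak_id_b) for r in df.itertuples(index=False)]


def write_regions_bed(regions: Sequence[NoncodingRegion], path: str | Path) -> None:
    """Write regions as BED with name field ``gene|transcript|region_class``."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.gene_id}|{r.transcript_id}|{r.region_class}"
            if r.utr_intron:
                name += "|utr_intron"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
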