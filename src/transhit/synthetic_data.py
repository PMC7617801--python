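"""Self-contained synthetic trio cohort with planted truth.

The generator emits everything the pipeline consumes — gene models (GTF),
reference sequence (FASTA), per-trio VCFs, annotation tables (TSV), interval
resources (BED), coaccessibility links and gene lists — together with a truth
table of planted variant configurations:

* ``trans``          — coding hit + noncoding variant from the other parent;
                       passes every filter and fires a prioritization rule.
* ``cis``            — both variants transmitted by the same parent.
* ``de_novo``        — noncoding variant absent from both parents.
* ``common_af``      — noncoding variant too common (cohort AF or gnomAD
                       filtering AF above threshold).
* ``qc_fail``        — noncoding variant failing genotype QC (low depth,
                       allele imbalance, or non-PASS FILTER).
* ``benign_clinvar`` — noncoding variant asserted Benign in ClinVar.
* ``cds_overlap``    — "second hit" that actually falls in coding sequence.

Only ``trans`` configurations (including ClinVar fast-path pairs) should be
reported; every decoy must be rejected by exactly the filter it targets.
All randomness flows through one seeded generator; a fixed (config, seed)
yields byte-identical output files.  Mutation-rate realism, linkage and
read-level simulation are out of scope: scores are assigned, not predicted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from transhit.region_builder import GeneModel

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
POLYA_MOTIF = "AATAAA"

TRANS_REGION_CYCLE = ("intron", "core_promoter", "utr5", "utr3", "extended_promoter")

_CONSEQUENCE_BY_REGION = {
    "intron": "intron_variant",
    "core_promoter": "upstream_gene_variant",
    "extended_promoter": "upstream_gene_variant",
    "utr5": "5_prime_UTR_variant",
    "utr3": "3_prime_UTR_variant",
    "cds": "synonymous_variant",
}

FAF_POPULATIONS = ("afr", "amr", "eas", "nfe", "sas")


class ConfigurationError(ValueError):
    """Requested cohort cannot be realized (infeasible geometry or counts)."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_trios: int = 200
    n_genes: int = 30
    genome_length_per_gene: int = 20_000
    planted_trans_pairs: int = 25
    planted_cis_decoys: int = 25
    planted_denovo_decoys: int = 25
    planted_common_decoys: int = 25
    planted_qcfail_decoys: int = 25
    planted_benign_decoys: int = 0
    planted_cds_overlap_decoys: int = 0
    planted_fastpath_pairs: int = 0
    coding_af_threshold: float = 0.005
    noncoding_af_threshold: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_trios, self.n_genes, self.genome_length_per_gene,
            self.planted_trans_pairs, self.planted_cis_decoys,
            self.planted_denovo_decoys, self.planted_common_decoys,
            self.planted_qcfail_decoys, self.planted_benign_decoys,
            self.planted_cds_overlap_decoys, self.planted_fastpath_pairs,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be non-negative")
        for thr in (self.coding_af_threshold, self.noncoding_af_threshold):
            if not 0.0 < thr < 1.0:
                raise ConfigurationError(f"threshold out of (0,1): {thr}")

    @property
    def total_plants(self) -> int:
        return (self.planted_trans_pairs + self.planted_cis_decoys
                + self.planted_denovo_decoys + self.planted_common_decoys
                + self.planted_qcfail_decoys + self.planted_benign_decoys
                + self.planted_cds_overlap_decoys + self.planted_fastpath_pairs)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted coding/noncoding pair."""

    proband_id: str
    gene_id: str
    coding_variant: "VariantKey"
    noncoding_variant: "VariantKey"
    configuration: str
    should_be_reported: bool
    should_be_prioritized: bool
    fast_path: bool = False


from transhit.trio_genotypes import VariantKey  # noqa: E402  (after TruthRecord docstring use)


@dataclass
class _Site:
    """One emitted variant site with its annotation and trio genotypes."""

    key: VariantKey
    gene_id: str
    consequence: str
    loftee: str = "absent"
    clnsig: str | None = None
    clnrevstat: str | None = None
    spliceai: float | None = None
    cadd: float | None = None
    phylop: float | None = None
    gnomad_popmax_af: float = 0.0
    pop_fafs: tuple[float, ...] = (0.0,) * 5
    # trio_index -> (proband, father, mother) alt dosages
    genotypes: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    # trio_index -> dict of proband FORMAT overrides {dp, ad_ref, ad_alt}
    qc_overrides: dict[int, dict[str, int]] = field(default_factory=dict)
    filter_status: str = "PASS"

    @property
    def gnomad_faf(self) -> float:
        return max(self.pop_fafs)


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort, ready to be written to disk."""

    config: CohortConfig
    models: list[GeneModel]
    sequences: dict[str, np.ndarray]  # chrom -> uint8 base indices
    sites: list[_Site]
    truth: list[TruthRecord]
    tfbs: list[tuple[str, int, int]]
    atac_peaks: list[tuple[str, str, int, int, float, float]]  # id, chrom, s, e, cellfrac, spec
    links: list[tuple[str, str]]
    mirna: list[tuple[str, int, int]]
    ires: list[tuple[str, int, int]]
    green_genes: list[str]

    @property
    def proband_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.config.n_trios)]

    def cohort_allele_counts(self) -> dict[VariantKey, int]:
        """Alt allele count per site over all trio members (AN = 6 * n_trios)."""
        return {
            s.key: sum(sum(g) for g in s.genotypes.values()) for s in self.sites
        }

    def write(self, outdir: str | Path) -> Path:
        return _write_cohort(self, Path(outdir))


# ---------------------------------------------------------------------------
# gene models and sequence
# ---------------------------------------------------------------------------

def generate_gene_models(
    config: CohortConfig,
) -> tuple[list[GeneModel], dict[str, np.ndarray]]:
    """Generate one single-transcript gene model plus sequence per gene.

    Each gene has 3-5 exons, a CDS strictly inside the transcript (non-empty
    UTRs on both sides in transcript orientation) and a random strand, with
    at least 5000 bp of clear sequence on both flanks so the full promoter
    window fits on the contig.  Half of the genes carry a canonical AATAAA
    polyadenylation motif in the 3' UTR (transcript orientation) so that the
    motif scanner has positives.
    """
    if config.n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng([config.seed, 0])
    models: list[GeneModel] = []
    seqs: dict[str, np.ndarray] = {}
    L = config.genome_length_per_gene
    for g in range(config.n_genes):
        chrom = f"chr{g + 1}"
        n_exons = int(rng.integers(3, 6))
        exon_lens = rng.integers(200, 401, n_exons)
        intron_lens = rng.integers(500, 1501, n_exons - 1)
        tx_len = int(exon_lens.sum() + intron_lens.sum())
        tx_start = 5000 + int(rng.integers(0, 200))
        if tx_start + tx_len + 5000 > L:
            raise ConfigurationError(
                f"gene span {tx_len} bp does not fit in {L} bp with 5000 bp clearance"
            )
        exons = []
        pos = tx_start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = int(rng.integers(20, 81))
        utr3_len = int(rng.integers(60, 151))
        if strand == "+":
            cds_start = exons[0][0] + utr5_len
            cds_end = exons[-1][1] - utr3_len
        else:
            cds_start = exons[0][0] + utr3_len
            cds_end = exons[-1][1] - utr5_len
        model = GeneModel(
            gene_id=f"GENE{g + 1:04d}",
            transcript_id=f"TX{g + 1:04d}",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        seq = rng.integers(0, 4, L).astype(np.uint8)
        if g % 2 == 0:  # plant a polyA motif in the 3' UTR
            motif = POLYA_MOTIF if strand == "+" else _revcomp(POLYA_MOTIF)
            if strand == "+":
                lo, hi = cds_end, exons[-1][1]
            else:
                lo, hi = exons[0][0], cds_start
            off = int(rng.integers(lo + 5, hi - len(motif) - 5))
            for j, b in enumerate(motif):
                seq[off + j] = BASES.index(b)
        models.append(model)
        seqs[chrom] = seq
    return models, seqs


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _gene_intervals(m: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Independent (generator-side) region arithmetic for position sampling."""
    left_utr = (m.tx_start, m.cds_start)
    right_utr = (m.cds_end, m.tx_end)
    if m.strand == "+":
        utr5, utr3 = left_utr, right_utr
        core = (m.tx_start - 200, m.tx_start)
        ext = (m.tx_start - 5000, m.tx_start - 200)
    else:
        utr5, utr3 = right_utr, left_utr
        core = (m.tx_end, m.tx_end + 200)
        ext = (m.tx_end + 200, m.tx_end + 5000)
    ext = (max(0, ext[0]), ext[1])
    introns = [(e1, s2) for (_, e1), (s2, _) in zip(m.exons, m.exons[1:])]
    cds = [(max(s, m.cds_start), min(e, m.cds_end)) for s, e in m.exons
           if min(e, m.cds_end) > max(s, m.cds_start)]
    return {
        "intron": introns,
        "utr5": [utr5],
        "utr3": [utr3],
        "core_promoter": [core],
        "extended_promoter": [ext],
        "cds": cds,
    }


def _sample_pos(
    rng: np.random.Generator,
    intervals: Sequence[tuple[int, int]],
    used: set[int],
    margin: int = 12,
) -> int:
    """Sample an unused 0-based position from intervals, away from edges."""
    pools = [(s + margin, e - margin) for s, e in intervals if e - s > 2 * margin + 1]
    if not pools:
        pools = [(s, e) for s, e in intervals if e > s]
    if not pools:
        raise ConfigurationError("no region space left for planting a variant")
    lens = np.array([e - s for s, e in pools], dtype=float)
    for _ in range(200):
        i = int(rng.choice(len(pools), p=lens / lens.sum()))
        pos = int(rng.integers(pools[i][0], pools[i][1]))
        if pos not in used:
            used.add(pos)
            return pos
    raise ConfigurationError("could not find a free position after 200 draws")


def _mk_key(seqs: Mapping[str, np.ndarray], chrom: str, pos0: int) -> VariantKey:
    ref = BASES[seqs[chrom][pos0]]
    return VariantKey(chrom, pos0 + 1, ref, _TRANSITION[ref])


_NONCODING_SCORES = {
    # region -> (spliceai, cadd, phylop); chosen so that exactly the intended
    # region rule fires for planted trans variants
    "intron": (0.4, 3.0, 0.5),
    "core_promoter": (None, 5.0, 0.2),
    "utr5": (0.2, 4.0, 1.0),
    "utr3": (0.2, 4.0, 1.0),
    "extended_promoter": (None, 16.0, 1.0),
    "cds": (0.4, 3.0, 0.5),
}


def generate_trio_cohort(
    config: CohortConfig,
    models: Sequence[GeneModel],
    sequences: Mapping[str, np.ndarray],
) -> SyntheticCohort:
    """Plant all configured variant pairs and decoys into trio genotypes."""
    rng = np.random.default_rng([config.seed, 1])
    n_trios, n_genes = config.n_trios, config.n_genes
    if config.total_plants > 0 and n_trios < 1:
        raise ConfigurationError("cannot plant variants into an empty cohort")

    plan: list[tuple[str, str]] = []  # (configuration, noncoding region)
    for i in range(config.planted_trans_pairs):
        plan.append(("trans", TRANS_REGION_CYCLE[i % len(TRANS_REGION_CYCLE)]))
    plan += [("cis", "intron")] * config.planted_cis_decoys
    plan += [("de_novo", "intron")] * config.planted_denovo_decoys
    plan += [("common_af", "intron")] * config.planted_common_decoys
    plan += [("qc_fail", "intron")] * config.planted_qcfail_decoys
    plan += [("benign_clinvar", "intron")] * config.planted_benign_decoys
    plan += [("cds_overlap", "cds")] * config.planted_cds_overlap_decoys
    plan += [("fastpath", "intron")] * config.planted_fastpath_pairs

    if len(plan) > n_trios * n_genes:
        raise ConfigurationError(
            f"{len(plan)} plants exceed {n_trios} trios x {n_genes} genes"
        )

    intervals = {m.gene_id: _gene_intervals(m) for m in models}
    model_by_gene = {m.gene_id: m for m in models}
    used_pos: dict[str, set[int]] = {m.chrom: set() for m in models}

    genes_by_proband: dict[int, set[str]] = {}
    sites: list[_Site] = []
    truth: list[TruthRecord] = []
    tfbs: list[tuple[str, int, int]] = []
    used_probands: set[int] = set()

    n_common = 0
    n_qcfail = 0
    n_trans = 0

    for i, (configuration, region) in enumerate(plan):
        p = i % n_trios
        used_probands.add(p)
        taken = genes_by_proband.setdefault(p, set())
        gene_idx = None
        for k in range(n_genes):
            cand = (i + k) % n_genes
            if models[cand].gene_id not in taken:
                gene_idx = cand
                break
        if gene_idx is None:
            raise ConfigurationError(f"proband {p} has plants in every gene already")
        m = models[gene_idx]
        taken.add(m.gene_id)
        iv = intervals[m.gene_id]
        used = used_pos[m.chrom]

        coding_parent = "M" if rng.random() < 0.5 else "F"
        fastpath = configuration == "fastpath"

        # --- coding hit ---
        cpos = _sample_pos(rng, iv["cds"], used)
        ckey = _mk_key(sequences, m.chrom, cpos)
        clinvar_coding = fastpath or (configuration == "trans" and i % 3 == 2)
        csite = _Site(
            key=ckey, gene_id=m.gene_id,
            consequence="missense_variant" if clinvar_coding else "stop_gained",
            loftee="absent" if clinvar_coding else "high",
            clnsig="Pathogenic" if clinvar_coding else None,
            clnrevstat=("reviewed_by_expert_panel" if clinvar_coding else None),
            cadd=float(np.round(rng.uniform(20, 40), 2)),
            phylop=float(np.round(rng.uniform(1, 8), 2)),
            gnomad_popmax_af=float(np.round(rng.uniform(0, 2e-4), 7)),
            pop_fafs=tuple(np.round(rng.uniform(0, 2e-4, 5), 7)),
        )
        # dosage tuple order is (proband, father, mother)
        csite.genotypes[p] = (1, 1, 0) if coding_parent == "F" else (1, 0, 1)
        sites.append(csite)

        # --- noncoding second hit / decoy ---
        npos = _sample_pos(rng, iv[region], used)
        nkey = _mk_key(sequences, m.chrom, npos)
        spliceai, cadd, phylop = _NONCODING_SCORES[region]
        nsite = _Site(
            key=nkey, gene_id=m.gene_id,
            consequence=_CONSEQUENCE_BY_REGION[region],
            spliceai=spliceai, cadd=cadd, phylop=phylop,
            pop_fafs=tuple(np.round(rng.uniform(0, 2e-4, 5), 7)),
        )
        if fastpath:
            nsite.clnsig = "Pathogenic"
            nsite.clnrevstat = "criteria_provided,_multiple_submitters,_no_conflicts"
            nsite.spliceai = 0.9
        if configuration == "benign_clinvar":
            nsite.clnsig = "Benign"
            nsite.clnrevstat = "criteria_provided,_multiple_submitters,_no_conflicts"
        if region == "extended_promoter":
            tfbs.append((m.chrom, npos - 10, npos + 11))

        other = "F" if coding_parent == "M" else "M"
        nc_parent = {"trans": other, "fastpath": other, "cis": coding_parent,
                     "de_novo": None}.get(configuration, other)
        if nc_parent is None:
            nsite.genotypes[p] = (1, 0, 0)
        elif nc_parent == "F":
            nsite.genotypes[p] = (1, 1, 0)
        else:
            nsite.genotypes[p] = (1, 0, 1)

        if configuration == "common_af":
            if n_common % 2 == 1:
                # common in gnomAD: one continental population above threshold
                fafs = list(nsite.pop_fafs)
                fafs[FAF_POPULATIONS.index("amr")] = 0.0073
                nsite.pop_fafs = tuple(fafs)
            else:
                # common in the cohort itself: plant extra carrier trios
                an = 6 * n_trios
                ac_needed = math.floor(config.noncoding_af_threshold * an) + 1
                extra = max(0, math.ceil((ac_needed - 2) / 2))
                for k in range(1, extra + 1):
                    q = (p + 7 * k) % n_trios
                    if q in nsite.genotypes:
                        q = (q + 1) % n_trios
                    nsite.genotypes[q] = (1, 1, 0)
            n_common += 1
        if configuration == "qc_fail":
            mode = n_qcfail % 3
            if mode == 0:
                nsite.qc_overrides[p] = {"dp": 5, "ad_ref": 3, "ad_alt": 2}
            elif mode == 1:
                nsite.qc_overrides[p] = {"dp": 20, "ad_ref": 16, "ad_alt": 4}
            else:
                nsite.filter_status = "LowQual"
            n_qcfail += 1
        sites.append(nsite)

        # a private variant (carrier parent + proband) has cohort AF
        # 2/(6*n_trios); in a cohort too small for that to clear the AF
        # threshold, even a perfect trans pair is not plantable/reportable
        private_af = 2 / (6 * n_trios)
        passable = (private_af <= config.coding_af_threshold
                    and private_af <= config.noncoding_af_threshold)
        reported = configuration in ("trans", "fastpath") and passable
        truth.append(TruthRecord(
            proband_id=f"P{p:04d}",
            gene_id=m.gene_id,
            coding_variant=ckey,
            noncoding_variant=nkey,
            configuration="trans" if fastpath else configuration,
            should_be_reported=reported,
            should_be_prioritized=reported,
            fast_path=fastpath,
        ))
        if configuration == "trans":
            n_trans += 1

    # background rare noncoding variants in probands without planted pairs:
    # non-firing annotations, never joined to a coding hit
    free = [p for p in range(n_trios) if p not in used_probands]
    for j, p in enumerate(free[:10]):
        m = models[j % n_genes]
        pos = _sample_pos(rng, intervals[m.gene_id]["intron"], used_pos[m.chrom])
        site = _Site(
            key=_mk_key(sequences, m.chrom, pos), gene_id=m.gene_id,
            consequence="intron_variant",
            spliceai=0.01, cadd=2.0, phylop=0.0,
            pop_fafs=tuple(np.round(rng.uniform(0, 2e-4, 5), 7)),
        )
        site.genotypes[p] = (1, 0, 1) if rng.random() < 0.5 else (1, 1, 0)
        sites.append(site)

    # interval resources: a qualifying promoter peak + linked distal peak per
    # gene, decoy peaks that fail the accessibility filter, and miRNA/IRES
    # intervals inside some UTRs
    atac: list[tuple[str, str, int, int, float, float]] = []
    links: list[tuple[str, str]] = []
    mirna: list[tuple[str, int, int]] = []
    ires: list[tuple[str, int, int]] = []
    L = config.genome_length_per_gene
    for g, m in enumerate(models):
        iv = intervals[m.gene_id]
        ext_s, ext_e = iv["extended_promoter"][0]
        mid = (ext_s + ext_e) // 2
        spec = float(np.round(rng.uniform(0, 0.8), 4))
        atac.append((f"peak_{g + 1:03d}_prom", m.chrom, mid - 150, mid + 150,
                     float(np.round(rng.uniform(0.06, 0.3), 4)), spec))
        atac.append((f"peak_{g + 1:03d}_dist", m.chrom,
                     L - 500 if m.strand == "+" else 100,
                     L - 200 if m.strand == "+" else 400,
                     float(np.round(rng.uniform(0.05, 0.2), 4)),
                     float(np.round(rng.uniform(0, 0.8), 4))))
        links.append((f"peak_{g + 1:03d}_prom", f"peak_{g + 1:03d}_dist"))
        if g % 2 == 0:  # decoy peak over the promoter that fails the filter
            atac.append((f"peak_{g + 1:03d}_lowq", m.chrom, ext_s + 10, ext_s + 210,
                         0.01, float(np.round(rng.uniform(0, 0.5), 4))))
        if g % 3 == 0:
            u3s, u3e = iv["utr3"][0]
            mirna.append((m.chrom, u3s + 1, u3s + 9))
            u5s, u5e = iv["utr5"][0]
            ires.append((m.chrom, u5s + 1, min(u5s + 9, u5e)))

    green = sorted({t.gene_id for t in truth if t.should_be_reported})
    return SyntheticCohort(
        config=config, models=list(models), sequences=dict(sequences),
        sites=sites, truth=truth, tfbs=tfbs, atac_peaks=atac, links=links,
        mirna=mirna, ires=ires, green_genes=green,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x: float | None) -> str:
    return "NA" if x is None else format(x, "g")


def write_gtf(models: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            rows = [("gene", m.tx_start, m.tx_end), ("transcript", m.tx_start, m.tx_end)]
            rows += [("exon", s, e) for s, e in m.exons]
            rows += [
                ("CDS", max(s, m.cds_start), min(e, m.cds_end))
                for s, e in m.exons
                if min(e, m.cds_end) > max(s, m.cds_start)
            ]
            for feat, s, e in rows:
                fh.write(
                    f"{m.chrom}\tsynthetic\t{feat}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_fasta(sequences: Mapping[str, np.ndarray], path: Path) -> None:
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom, idx in sequences.items():
            fh.write(f">{chrom}\n")
            seq = base_arr[idx].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_trio_vcf(
    path: Path,
    trio_index: int,
    cohort: SyntheticCohort,
    contig_order: Sequence[str],
) -> None:
    cfg = cohort.config
    pid, fid, mid = (f"P{trio_index:04d}", f"F{trio_index:04d}", f"M{trio_index:04d}")
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=LowQual,Description="Low quality site">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    for chrom in contig_order:
        lines.append(f"##contig=<ID={chrom},length={cfg.genome_length_per_gene}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{pid}\t{fid}\t{mid}")

    order = {c: i for i, c in enumerate(contig_order)}
    trio_sites = [s for s in cohort.sites if trio_index in s.genotypes]
    trio_sites.sort(key=lambda s: (order[s.key.chrom], s.key.pos))
    for s in trio_sites:
        dos = s.genotypes[trio_index]  # (proband, father, mother)
        cols = []
        for role, d in enumerate(dos):
            gt = ("0/0", "0/1", "1/1")[d]
            dp, ad_ref, ad_alt = 30, (30, 15, 0)[d], (0, 15, 30)[d]
            if role == 0 and trio_index in s.qc_overrides:
                ov = s.qc_overrides[trio_index]
                dp, ad_ref, ad_alt = ov["dp"], ov["ad_ref"], ov["ad_alt"]
            cols.append(f"{gt}:{dp}:{ad_ref},{ad_alt}")
        lines.append(
            f"{s.key.chrom}\t{s.key.pos}\t.\t{s.key.ref}\t{s.key.alt}\t.\t"
            f"{s.filter_status}\t.\tGT:DP:AD\t" + "\t".join(cols)
        )
    path.write_text("\n".join(lines) + "\n")


def _write_cohort(cohort: SyntheticCohort, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    contigs = [m.chrom for m in cohort.models]

    write_gtf(cohort.models, outdir / "genes.gtf")
    write_fasta(cohort.sequences, outdir / "reference.fa")
    # pyfaidx index files from earlier runs would go stale
    fai = outdir / "reference.fa.fai"
    if fai.exists():
        fai.unlink()

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    ped_rows = ["proband_id\tfather_id\tmother_id\tvcf_path"]
    for t in range(cfg.n_trios):
        name = f"trio_P{t:04d}.vcf"
        _write_trio_vcf(vcf_dir / name, t, cohort, contigs)
        ped_rows.append(f"P{t:04d}\tF{t:04d}\tM{t:04d}\tvcf/{name}")
    (outdir / "trios.ped.tsv").write_text("\n".join(ped_rows) + "\n")

    faf_cols = "\t".join(f"faf_{p}" for p in FAF_POPULATIONS)
    ann_rows = [
        "chrom\tpos\tref\talt\tgene_id\tconsequence\tloftee\tclnsig\tclnrevstat\t"
        f"spliceai_max\tcadd\tphylop\tgnomad_popmax_af\t{faf_cols}\tgnomad_faf"
    ]
    order = {c: i for i, c in enumerate(contigs)}
    for s in sorted(cohort.sites, key=lambda s: (order[s.key.chrom], s.key.pos)):
        fafs = "\t".join(format(f, "g") for f in s.pop_fafs)
        ann_rows.append(
            f"{s.key.chrom}\t{s.key.pos}\t{s.key.ref}\t{s.key.alt}\t{s.gene_id}\t"
            f"{s.consequence}\t{s.loftee}\t{s.clnsig or 'NA'}\t{s.clnrevstat or 'NA'}\t"
            f"{_fmt(s.spliceai)}\t{_fmt(s.cadd)}\t{_fmt(s.phylop)}\t"
            f"{format(s.gnomad_popmax_af, 'g')}\t{fafs}\t{format(s.gnomad_faf, 'g')}"
        )
    (outdir / "annotations.tsv").write_text("\n".join(ann_rows) + "\n")

    an = 6 * cfg.n_trios
    ac = cohort.cohort_allele_counts()
    count_rows = ["chrom\tpos\tref\talt\tAC\tAN\tAF"]
    for s in sorted(cohort.sites, key=lambda s: (order[s.key.chrom], s.key.pos)):
        k = s.key
        count_rows.append(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{ac[k]}\t{an}\t"
                          f"{format(ac[k] / an, 'g')}")
    (outdir / "cohort_counts.tsv").write_text("\n".join(count_rows) + "\n")

    def write_bed(rows: Iterable[tuple[str, int, int]], name: str) -> None:
        (outdir / name).write_text(
            "".join(f"{c}\t{s}\t{e}\n" for c, s, e in rows)
        )

    write_bed(cohort.tfbs, "tfbs.bed")
    write_bed(cohort.mirna, "mirna.bed")
    write_bed(cohort.ires, "ires.bed")
    (outdir / "atac_peaks.bed").write_text("".join(
        f"{c}\t{s}\t{e}\t{pid}\t{format(cf, 'g')}\t{format(sp, 'g')}\n"
        for pid, c, s, e, cf, sp in cohort.atac_peaks
    ))
    (outdir / "coaccessibility.tsv").write_text(
        "peak_id_a\tpeak_id_b\n"
        + "".join(f"{a}\t{b}\n" for a, b in cohort.links)
    )
    (outdir / "recessive_genes.txt").write_text(
        "".join(m.gene_id + "\n" for m in cohort.models)
    )
    (outdir / "green_genes.txt").write_text(
        "".join(g + "\n" for g in cohort.green_genes)
    )

    truth_rows = [
        "proband_id\tgene_id\tcoding_chrom\tcoding_pos\tcoding_ref\tcoding_alt\t"
        "noncoding_chrom\tnoncoding_pos\tnoncoding_ref\tnoncoding_alt\t"
        "configuration\tfast_path\tshould_be_reported\tshould_be_prioritized"
    ]
    for t in cohort.truth:
        c, n = t.coding_variant, t.noncoding_variant
        truth_rows.append(
            f"{t.proband_id}\t{t.gene_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t"
            f"{n.chrom}\t{n.pos}\t{n.ref}\t{n.alt}\t{t.configuration}\t"
            f"{int(t.fast_path)}\t{int(t.should_be_reported)}\t{int(t.should_be_prioritized)}"
        )
    (outdir / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    return outdir


def simulate_cohort(config: CohortConfig, outdir: str | Path) -> SyntheticCohort:
    """Generate a cohort and write every pipeline input plus truth to disk."""
    models, seqs = generate_gene_models(config)
    cohort = generate_trio_cohort(config, models, seqs)
    cohort.write(outdir)
    return cohort
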