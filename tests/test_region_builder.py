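import numpy as np

from transhit.region_builder import (
    AtacPeak,
    GeneModel,
    NoncodingRegion,
    build_regions,
    filter_atac_peaks,
    link_enhancer_candidates,
    read_gene_models_gtf,
)
from transhit.synthetic_data import write_gtf


def random_model(rng, chrom="chrR"):
    n_exons = int(rng.integers(1, 6))
    pos = int(rng.integers(6000, 8000))
    exons = []
    for _ in range(n_exons):
        e = pos + int(rng.integers(100, 400))
        exons.append((pos, e))
        pos = e + int(rng.integers(200, 1200))
    strand = "+" if rng.random() < 0.5 else "-"
    tx_start, tx_end = exons[0][0], exons[-1][1]
    cds_start = tx_start + int(rng.integers(10, exons[0][1] - exons[0][0]))
    cds_end = tx_end - int(rng.integers(10, exons[-1][1] - exons[-1][0]))
    if cds_end <= cds_start:
        cds_start, cds_end = tx_start + 5, tx_end - 5
    return GeneModel("G", "T", chrom, strand, tuple(exons), cds_start, cds_end)


def by_class(regions, cls):
    return sorted((r.start, r.end) for r in regions if r.region_class == cls)


class TestBuildRegions:
    def test_plus_strand_worked_example(self):
        m = GeneModel("G", "T", "chr1", "+", ((100, 200), (300, 400)), 150, 350)
        regs = build_regions(m)
        assert by_class(regs, "intron") == [(200, 300)]
        assert by_class(regs, "utr5") == [(100, 150)]
        assert by_class(regs, "utr3") == [(350, 400)]
        assert by_class(regs, "core_promoter") == [(0, 100)]  # clipped at contig start
        assert by_class(regs, "extended_promoter") == []      # fully clipped away

    def test_minus_strand_promoter_upstream_of_transcript_end(self):
        m = GeneModel("G", "T", "chr1", "-", ((1000, 2000),), 1100, 1900)
        regs = build_regions(m)
        assert by_class(regs, "core_promoter") == [(2000, 2200)]
        assert by_class(regs, "extended_promoter") == [(2200, 7000)]
        # on the minus strand the 5'UTR is at the high-coordinate end
        assert by_class(regs, "utr5") == [(1900, 2000)]
        assert by_class(regs, "utr3") == [(1000, 1100)]

    def test_single_exon_has_no_introns(self):
        m = GeneModel("G", "T", "chr1", "+", ((500, 900),), 600, 800)
        assert by_class(build_regions(m), "intron") == []

    def test_cds_spanning_transcript_has_no_utrs(self):
        m = GeneModel("G", "T", "chr1", "+", ((500, 900),), 500, 900)
        regs = build_regions(m)
        assert by_class(regs, "utr5") == [] and by_class(regs, "utr3") == []

    def test_utr_intron_flag(self):
        # intron entirely within the 5'UTR span (CDS starts in exon 2)
        m = GeneModel("G", "T", "chr1", "+", ((100, 200), (300, 400), (500, 600)), 350, 550)
        introns = {(r.start, r.end): r.utr_intron
                   for r in build_regions(m) if r.region_class == "intron"}
        assert introns == {(200, 300): True, (400, 500): False}

    def test_random_models_intron_exon_partition(self):
        """Introns and exons tile the transcript span without overlap."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = random_model(rng)
            pieces = sorted(list(m.exons) + [
                (r.start, r.end) for r in build_regions(m) if r.region_class == "intron"
            ])
            assert pieces[0][0] == m.tx_start and pieces[-1][1] == m.tx_end
            for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                assert e1 == s2  # contiguous, disjoint

    def test_random_models_regions_avoid_own_cds(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            m = random_model(rng)
            cds_pieces = [(max(s, m.cds_start), min(e, m.cds_end))
                          for s, e in m.exons
                          if min(e, m.cds_end) > max(s, m.cds_start)]
            for r in build_regions(m):
                if r.region_class in ("intron", "utr5", "utr3"):
                    assert not any(cs < r.end and r.start < ce
                                   for cs, ce in cds_pieces)

    def test_promoter_split_is_contiguous_200_plus_4800(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            m = random_model(rng)
            regs = build_regions(m)
            core = by_class(regs, "core_promoter")
            ext = by_class(regs, "extended_promoter")
            assert len(core) == 1 and len(ext) == 1
            (cs, ce), (es, ee) = core[0], ext[0]
            assert ce - cs == 200 and ee - es == 4800
            assert sorted([core[0], ext[0]])[0][1] == sorted([core[0], ext[0]])[1][0]
            if m.strand == "+":
                assert ce == m.tx_start
            else:
                assert cs == m.tx_end

    def test_mirror_symmetry(self):
        """Reflecting a model through a coordinate mirror and flipping strand
        yields exactly mirrored regions."""
        rng = np.random.default_rng(10)
        M = 100_000
        for _ in range(200):
            m = random_model(rng)
            flipped = GeneModel(
                m.gene_id, m.transcript_id, m.chrom,
                "-" if m.strand == "+" else "+",
                tuple(sorted((M - e, M - s) for s, e in m.exons)),
                M - m.cds_end, M - m.cds_start,
            )
            orig = {(r.region_class, r.start, r.end) for r in build_regions(m)}
            mirrored = {(r.region_class, M - r.end, M - r.start)
                        for r in build_regions(flipped)}
            assert orig == mirrored


class TestAtacFilter:
    def test_cell_fraction_keeps_peak(self):
        peaks = [AtacPeak("a", "chr1", 0, 100, 0.06, 0.5),
                 AtacPeak("b", "chr1", 200, 300, 0.04, 0.5)]
        kept = filter_atac_peaks(peaks)
        assert [p.peak_id for p in kept] == ["a", "b"]  # b kept: score ties max

    def test_top_specificity_keeps_rare_peak(self):
        peaks = [AtacPeak(f"p{i}", "chr1", i * 10, i * 10 + 5, 0.01, float(i))
                 for i in range(40)]
        kept = filter_atac_peaks(peaks)
        assert "p39" in {p.peak_id for p in kept}

    def test_exactly_five_of_hundred_distinct_scores(self):
        peaks = [AtacPeak(f"p{i}", "chr1", i, i + 1, 0.01, float(i))
                 for i in range(100)]
        kept = filter_atac_peaks(peaks)
        assert {p.peak_id for p in kept} == {f"p{i}" for i in range(95, 100)}

    def test_empty_input(self):
        assert filter_atac_peaks([]) == []


class TestEnhancerLinking:
    def promoter(self):
        return [NoncodingRegion("G1", "T1", "core_promoter", "chr1", 1000, 1200)]

    def test_overlapping_and_linked_peaks_returned(self):
        peaks = [AtacPeak("A", "chr1", 1100, 1300, 0.1, 0.5),
                 AtacPeak("B", "chr1", 9000, 9200, 0.1, 0.5)]
        regs = link_enhancer_candidates(peaks, [("A", "B")], self.promoter())
        assert {(r.source_peak_id, r.gene_id) for r in regs} == {("A", "G1"), ("B", "G1")}
        assert all(r.region_class == "atac_coaccessible" for r in regs)

    def test_isolated_peak_not_returned(self):
        peaks = [AtacPeak("X", "chr1", 9000, 9200, 0.1, 0.5)]
        assert link_enhancer_candidates(peaks, [], self.promoter()) == []

    def test_one_hop_only(self):
        peaks = [AtacPeak("A", "chr1", 1100, 1300, 0.1, 0.5),
                 AtacPeak("B", "chr1", 5000, 5200, 0.1, 0.5),
                 AtacPeak("C", "chr1", 9000, 9200, 0.1, 0.5)]
        regs = link_enhancer_candidates(peaks, [("A", "B"), ("B", "C")], self.promoter())
        # oracle: explicit one-hop closure from the promoter-overlapping anchor
        anchor = {"A"}
        one_hop = anchor | {b for a, b in [("A", "B"), ("B", "C")] if a in anchor} \
                         | {a for a, b in [("A", "B"), ("B", "C")] if b in anchor}
        assert {r.source_peak_id for r in regs} == one_hop == {"A", "B"}

    def test_unknown_peak_id_ignored(self, caplog):
        peaks = [AtacPeak("A", "chr1", 1100, 1300, 0.1, 0.5)]
        regs = link_enhancer_candidates(peaks, [("A", "ZZZ")], self.promoter())
        assert {r.source_peak_id for r in regs} == {"A"}


class TestGtfRoundTrip:
    def test_write_then_read_preserves_models(self, tmp_path):
        rng = np.random.default_rng(11)
        models = []
        for i in range(5):
            m = random_model(rng, chrom=f"chr{i + 1}")
            models.append(GeneModel(f"G{i}", f"T{i}", m.chrom, m.strand,
                                    m.exons, m.cds_start, m.cds_end))
        path = tmp_path / "x.gtf"
        write_gtf(models, path)
        back = {m.gene_id: m for m in read_gene_models_gtf(path)}
        for m in models:
            b = back[m.gene_id]
            assert (b.exons, b.cds_start, b.cds_end, b.strand) == \
                (m.exons, m.cds_start, m.cds_end, m.strand)
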