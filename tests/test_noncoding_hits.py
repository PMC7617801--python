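import itertools

import pytest

from transhit.coding_hits import CodingAnnotation, ProbandVariantPair
from transhit.noncoding_hits import (
    assign_region,
    detect_clinvar_trans_fast_path,
    find_second_hits,
    retention_filters,
)
from transhit.region_builder import GeneModel, NoncodingRegion, build_regions
from transhit.trio_genotypes import Genotype, Transmission, TrioGenotype, VariantKey

# gene on chr1: exons (10000,10400), (11000,11400), (12000,12400); CDS 10200-12200
MODEL = GeneModel("GENE1", "TX1", "chr1", "+",
                  ((10000, 10400), (11000, 11400), (12000, 12400)), 10200, 12200)
REGIONS = build_regions(MODEL)
MANE_CDS = [("chr1", 10200, 10400), ("chr1", 11000, 11400), ("chr1", 12000, 12200)]

PAIR = ProbandVariantPair("P1", "GENE1", VariantKey("chr1", 10250, "C", "T"),
                          Transmission.MATERNAL, "plof")


def het(key, mother="hom_ref", father="het", **kw):
    defaults = dict(proband_dp=30, proband_ad_ref=15, proband_ad_alt=15,
                    filter_status="PASS")
    defaults.update(kw)
    return TrioGenotype(key=key, proband_gt=Genotype.HET,
                        mother_gt=Genotype(mother), father_gt=Genotype(father),
                        **defaults)


def ann(key, gene="GENE1", clnsig=None, cohort_af=0.0001, consequence=("intron_variant",),
        clnrevstat=None):
    return CodingAnnotation(key=key, gene_id=gene, consequence=frozenset(consequence),
                            clnsig=clnsig, clnrevstat=clnrevstat, cohort_af=cohort_af)


INTRONIC = VariantKey("chr1", 10501, "A", "G")   # inside intron 1 (10400-11000)


class TestAssignRegion:
    @pytest.mark.parametrize("pos, expected", [
        (10000 - 182, ("core_promoter", False)),  # 182 bp upstream of the TSS
        (10000 - 201, ("extended_promoter", False)),
        (10101, ("utr5", False)),
        (12301, ("utr3", False)),
        (10501, ("intron", False)),
        (10250, None),                            # inside the CDS
        (99, None),                               # beyond the promoter window
    ])
    def test_assignment(self, pos, expected):
        got = assign_region(VariantKey("chr1", pos, "A", "G"), REGIONS)
        assert got == expected

    def test_utr_intron_flag(self):
        m = GeneModel("G", "T", "chr2", "+", ((100, 200), (300, 400)), 350, 390)
        got = assign_region(VariantKey("chr2", 251, "A", "G"), build_regions(m))
        assert got == ("intron", True)

    def test_precedence_core_promoter_over_enhancer_peak(self):
        regs = list(REGIONS) + [NoncodingRegion(
            "GENE1", "TX1", "atac_coaccessible", "chr1", 9700, 10000, "pk1")]
        got = assign_region(VariantKey("chr1", 9901, "A", "G"), regs)
        assert got == ("core_promoter", False)


class TestFindSecondHits:
    def run(self, genotype, annotation=None, faf=0.0, **kw):
        key = genotype.key
        annotations = {key: annotation if annotation is not None else ann(key)}
        return find_second_hits(PAIR, REGIONS, [genotype], annotations,
                                {key: faf}, mane_cds=MANE_CDS, **kw)

    def test_trans_rare_intronic_variant_retained(self):
        hits = self.run(het(INTRONIC))
        assert len(hits) == 1
        h = hits[0]
        assert h.region_class == "intron"
        assert h.noncoding_transmission == Transmission.PATERNAL

    def test_faf_0073_rejected_by_half_percent_filter(self):
        """A 0.73% population frequency (the classic leaky splice allele
        scenario) fails the 0.5% filtering-AF cutoff."""
        assert self.run(het(INTRONIC), faf=0.0073) == []

    def test_faf_exactly_at_threshold_retained(self):
        assert len(self.run(het(INTRONIC), faf=0.005)) == 1

    def test_cohort_af_above_threshold_rejected(self):
        assert self.run(het(INTRONIC), ann(INTRONIC, cohort_af=0.0067)) == []

    def test_cis_variant_rejected(self):
        # same transmitting parent as the coding hit (maternal)
        assert self.run(het(INTRONIC, mother="het", father="hom_ref")) == []

    def test_de_novo_variant_rejected(self):
        assert self.run(het(INTRONIC, mother="hom_ref", father="hom_ref")) == []

    def test_ambiguous_transmission_rejected(self):
        assert self.run(het(INTRONIC, mother="het", father="het")) == []

    def test_qc_fail_rejected(self):
        assert self.run(het(INTRONIC, proband_dp=5, proband_ad_ref=3,
                            proband_ad_alt=2)) == []
        assert self.run(het(INTRONIC, filter_status="LowQual")) == []

    def test_cds_overlap_rejected(self):
        key = VariantKey("chr1", 11101, "A", "G")  # inside exon 2 CDS
        assert self.run(het(key), ann(key)) == []

    @pytest.mark.parametrize("clnsig", ["Benign", "Likely_benign",
                                        "Benign/Likely_benign", "Likely benign"])
    def test_benign_clinvar_rejected(self, clnsig):
        assert self.run(het(INTRONIC), ann(INTRONIC, clnsig=clnsig)) == []

    def test_pathogenic_clinvar_not_rejected(self):
        assert len(self.run(het(INTRONIC), ann(INTRONIC, clnsig="Pathogenic"))) == 1

    def test_filter_order_independence(self):
        """Retention is a pure conjunction: any filter order yields the same set."""
        genotypes = [
            het(INTRONIC),
            het(VariantKey("chr1", 10451, "A", "G"), mother="het", father="hom_ref"),
            het(VariantKey("chr1", 11501, "A", "G"), proband_dp=4),
            het(VariantKey("chr1", 11601, "A", "G")),
        ]
        annotations = {g.key: ann(g.key) for g in genotypes}
        fafs = {g.key: 0.0 for g in genotypes}
        fafs[VariantKey("chr1", 11601, "A", "G")] = 0.02
        filters = retention_filters(PAIR, REGIONS, annotations, fafs,
                                    0.005, 0.005, MANE_CDS)
        baseline = None
        for perm in itertools.permutations(filters):
            retained = {
                g.key for g in genotypes
                if g.proband_gt == Genotype.HET and all(p(g) for _, p in perm)
            }
            if baseline is None:
                baseline = retained
            assert retained == baseline
        assert baseline == {INTRONIC}


class TestClinvarFastPath:
    CODING = VariantKey("chr1", 10250, "C", "T")

    def annotations(self, noncoding_clnsig="Pathogenic"):
        rev = "criteria_provided,_multiple_submitters,_no_conflicts"
        return {
            self.CODING: ann(self.CODING, consequence=("missense_variant",),
                             clnsig="Pathogenic", clnrevstat=rev),
            INTRONIC: ann(INTRONIC, consequence=("intron_variant",),
                          clnsig=noncoding_clnsig,
                          clnrevstat=rev if noncoding_clnsig else None),
        }

    def test_trans_pl_pair_emitted_with_flag(self):
        gts = {"P1": [het(self.CODING, mother="het", father="hom_ref"),
                      het(INTRONIC, mother="hom_ref", father="het")]}
        out = detect_clinvar_trans_fast_path(gts, self.annotations(),
                                             regions_by_gene={"GENE1": REGIONS})
        assert len(out) == 1
        c = out[0]
        assert c.fast_path_clinvar
        assert c.noncoding_variant == INTRONIC
        assert c.region_class == "intron"
        assert c.pair.coding_variant == self.CODING

    def test_cis_pair_not_emitted(self):
        gts = {"P1": [het(self.CODING, mother="het", father="hom_ref"),
                      het(INTRONIC, mother="het", father="hom_ref")]}
        assert detect_clinvar_trans_fast_path(gts, self.annotations()) == []

    def test_vus_noncoding_not_emitted(self):
        gts = {"P1": [het(self.CODING, mother="het", father="hom_ref"),
                      het(INTRONIC, mother="hom_ref", father="het")]}
        anns = self.annotations(noncoding_clnsig="Uncertain_significance")
        assert detect_clinvar_trans_fast_path(gts, anns) == []

    def test_two_protein_altering_pl_variants_not_emitted(self):
        k2 = VariantKey("chr1", 12100, "G", "A")
        rev = "reviewed_by_expert_panel"
        gts = {"P1": [het(self.CODING, mother="het", father="hom_ref"),
                      het(k2, mother="hom_ref", father="het")]}
        anns = {
            self.CODING: ann(self.CODING, consequence=("missense_variant",),
                             clnsig="Pathogenic", clnrevstat=rev),
            k2: ann(k2, consequence=("stop_gained",),
                    clnsig="Pathogenic", clnrevstat=rev),
        }
        assert detect_clinvar_trans_fast_path(gts, anns) == []
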