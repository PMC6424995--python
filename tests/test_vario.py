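import math
import warnings

import numpy as np
import pytest
from Bio.Seq import Seq

from bsahopper import simdata, vario
from bsahopper.errors import DataError, NonCodingError
from conftest import make_truth

CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]
STOPS = ("TAA", "TAG", "TGA")


def build_cds(n_codons, rng, start="ATG"):
    """Random CDS of n_codons coding codons plus a stop (no internal stops)."""
    body = [start] + [CODONS[rng.integers(len(CODONS))] for _ in range(n_codons - 1)]
    return "".join(body) + STOPS[rng.integers(3)]


def single_exon_gene(cds, gene_id="g1", chrom="chr4", start=1001, strand="+"):
    end = start + len(cds) - 1
    return vario.GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_segments=((start, end),),
        cds_seq=cds,
    )


class TestSnpSite:
    def test_validation(self):
        with pytest.raises(DataError):
            vario.SnpSite("c", 0, "A", "G", {})
        with pytest.raises(DataError):
            vario.SnpSite("c", 5, "A", "A", {})
        with pytest.raises(DataError):
            vario.SnpSite("c", 5, "A", "G", {"s": (-1, 2)})


class TestVcfIO:
    def test_ad_field_parse(self, tmp_path):
        vcf = tmp_path / "one.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            "##contig=<ID=chr4>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpoolS\n"
            "chr4\t6968050\t.\tA\tG\t60\t.\t.\tAD\t3,17\n"
        )
        sites = vario.read_variants(vcf)
        assert len(sites) == 1
        assert sites[0].depths["poolS"] == (3, 17)
        assert sites[0].pos == 6968050

    def test_empty_file_empty_collection(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        assert vario.read_variants(vcf) == []

    def test_round_trip_preserves_simulated_sites(self, tmp_path):
        truth = make_truth(np.random.default_rng(0).integers(0, 3, size=(8, 40)))
        sites = simdata.simulate_pool_seq(
            truth, {"R": truth.line_ids[:4], "S": truth.line_ids[4:]}, seed=5
        )
        path = tmp_path / "sim.vcf"
        vario.write_variants(path, sites, contig_lengths={"chr1": 100_000})
        back = vario.read_variants(path)
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert (a.chrom, a.pos, a.ref_allele, a.donor_allele) == (
                b.chrom,
                b.pos,
                b.ref_allele,
                b.donor_allele,
            )
            assert a.depths == b.depths

    def test_multiallelic_skip_and_split(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tG,T\t50\t.\t.\tAD\t5,6,7\n"
        )
        assert vario.read_variants(vcf, multiallelic="skip") == []
        split = vario.read_variants(vcf, multiallelic="split")
        assert [(s.donor_allele, s.depths["s1"]) for s in split] == [
            ("G", (5, 6)),
            ("T", (5, 7)),
        ]


def make_site(pos, depths=None, sq=60.0, bq=37.0, ref="A", donor="G", chrom="chr4"):
    return vario.SnpSite(chrom, pos, ref, donor, depths or {"p": (10, 10)}, sq, bq)


class TestFilterSites:
    def test_low_depth_pool_removed(self):
        site = make_site(10, depths={"p1": (3, 2), "p2": (10, 10)})
        assert vario.filter_sites([site]) == []

    def test_zero_thresholds_identity(self):
        sites = [make_site(i, sq=0, bq=0, depths={"p": (0, 1)}) for i in range(1, 6)]
        kept = vario.filter_sites(
            sites, min_site_quality=0, min_base_quality=0, min_depth=0
        )
        assert kept == sites

    def test_one_rule_each(self):
        good = [make_site(i) for i in range(1, 7)]
        bad = [
            make_site(10, sq=10.0),  # site quality
            make_site(11, bq=15.0),  # base quality
            make_site(12, depths={"p": (2, 3)}),  # depth
            make_site(13, depths={"p": (0, 5)}),  # depth again
        ]
        kept = vario.filter_sites(good + bad)
        assert kept == good

    def test_subset_and_order_independent(self):
        rng = np.random.default_rng(1)
        sites = [
            make_site(
                int(p),
                sq=float(rng.uniform(0, 40)),
                bq=float(rng.uniform(0, 40)),
                depths={"p": (int(rng.integers(0, 10)), int(rng.integers(0, 10)))},
            )
            for p in range(1, 40)
        ]
        kept = vario.filter_sites(sites)
        assert set(id(s) for s in kept) <= set(id(s) for s in sites)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        assert {s.pos for s in vario.filter_sites(shuffled)} == {s.pos for s in kept}


class TestGeneModel:
    def test_length_must_be_codon_multiple(self):
        with pytest.raises(DataError):
            single_exon_gene("ATGAA")

    def test_overlapping_segments_rejected(self):
        with pytest.raises(DataError):
            vario.GeneModel("g", "c", "+", ((1, 6), (4, 9)), "ATG" * 4)

    def test_missing_start_codon_warns_only(self):
        with pytest.warns(UserWarning):
            single_exon_gene("CTGAAATAA")


class TestCdsCoordinate:
    def test_single_exon_plus(self):
        gene = single_exon_gene("ATG" + "AAA" * 18 + "TAA", start=101)
        assert vario.cds_coordinate(gene, 101) == 1
        assert vario.cds_coordinate(gene, 160) == 60

    def test_two_exons_plus(self):
        gene = vario.GeneModel(
            "g", "c", "+", ((101, 150), (201, 249)), "ATG" + "A" * 93 + "TAA"
        )
        assert vario.cds_coordinate(gene, 201) == 51
        assert vario.cds_coordinate(gene, 249) == 99

    def test_two_exons_minus(self):
        gene = vario.GeneModel(
            "g", "c", "-", ((201, 249), (101, 150)), "ATG" + "A" * 93 + "TAA"
        )
        assert vario.cds_coordinate(gene, 249) == 1
        assert vario.cds_coordinate(gene, 101) == 99

    def test_intronic_position_signals_non_coding(self):
        gene = vario.GeneModel(
            "g", "c", "+", ((101, 150), (201, 249)), "ATG" + "A" * 93 + "TAA"
        )
        with pytest.raises(NonCodingError):
            vario.cds_coordinate(gene, 175)


class TestAnnotateEffect:
    def test_missense_coordinates_1527bp_cds(self):
        # codon 190 (CDS 568-570) GCT -> CCT is Ala -> Pro
        rng = np.random.default_rng(42)
        cds = build_cds(508, rng)
        cds = cds[:567] + "GCT" + cds[570:]
        gene = single_exon_gene(cds, start=1001)
        assert gene.cds_length == 1527
        site = make_site(1001 + 567, ref="G", donor="C")
        eff = vario.annotate_effect(gene, site)
        assert eff.effect_class == "missense"
        assert (eff.codon_index, eff.protein_length) == (190, 508)
        assert (eff.ref_aa, eff.alt_aa) == ("A", "P")
        assert eff.cds_pos == 568 and eff.cds_length == 1527

    def test_stop_gained_216bp_cds(self):
        # codon 67 (CDS 199-201) TAC -> TAG gains a stop
        rng = np.random.default_rng(43)
        cds = build_cds(71, rng)
        cds = cds[:198] + "TAC" + cds[201:]
        gene = single_exon_gene(cds, start=501)
        assert gene.cds_length == 216
        site = make_site(501 + 200, ref="C", donor="G")
        eff = vario.annotate_effect(gene, site)
        assert eff.effect_class == "stop_gained"
        assert (eff.codon_index, eff.protein_length) == (67, 71)

    def test_synonymous_fourfold_site(self):
        # GGA -> GGC stays glycine
        cds = "ATG" + "GGA" + "TAA"
        gene = single_exon_gene(cds, start=11)
        eff = vario.annotate_effect(gene, make_site(16, ref="A", donor="C"))
        assert eff.effect_class == "synonymous"

    def test_minus_strand_substitution(self):
        # minus-strand gene: genomic REF/ALT are reverse-complemented
        cds = "ATG" + "GCT" + "TAA"  # Ala at codon 2
        start = 101
        gene = vario.GeneModel(
            "g", "c", "-", ((start, start + 8),), cds
        )
        # CDS pos 4 (the G of GCT) is genomic position start+8-3 = 106;
        # genomic REF is complement C, ALT G -> CDS G->C: GCT -> CCT (A->P)
        eff = vario.annotate_effect(gene, make_site(106, ref="C", donor="G"))
        assert eff.effect_class == "missense"
        assert (eff.ref_aa, eff.alt_aa) == ("A", "P")

    def test_site_outside_cds_is_non_coding(self):
        gene = single_exon_gene("ATGGCTTAA", start=101)
        eff = vario.annotate_effect(gene, make_site(50))
        assert eff.effect_class == "non_coding"

    def test_inframe_and_frameshift_indels(self):
        gene = single_exon_gene("ATG" + "AAA" * 10 + "TAA", start=1)
        ins21 = vario.SnpSite("chr4", 6, "T", "T" + "TTATGCCTCTGGTGTGACCAA", {"p": (5, 5)})
        eff = vario.annotate_effect(gene, ins21)
        assert eff.effect_class == "inframe_indel"
        assert eff.inserted_aa == 7  # 21-bp in-frame insertion adds 7 residues
        fs = vario.SnpSite("chr4", 6, "TGA", "T", {"p": (5, 5)})
        assert vario.annotate_effect(gene, fs).effect_class == "frameshift"

    def test_agrees_with_full_cds_translation_oracle(self):
        """Codon-wise annotation equals a whole-protein diff on fuzzed genes."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(300):
            n_codons = int(rng.integers(5, 60))
            cds = build_cds(n_codons, rng)
            strand = "+" if rng.integers(2) else "-"
            start = int(rng.integers(1, 10_000))
            segs = ((start, start + len(cds) - 1),)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gene = vario.GeneModel("g", "c", strand, segs, cds)
            cds_pos = int(rng.integers(1, len(cds) + 1))
            old = cds[cds_pos - 1]
            new = "ACGT"[rng.integers(4)]
            if new == old:
                continue
            if strand == "+":
                genomic = start + cds_pos - 1
                ref, donor = old, new
            else:
                genomic = start + len(cds) - cds_pos
                comp = dict(zip("ACGT", "TGCA"))
                ref, donor = comp[old], comp[new]
            eff = vario.annotate_effect(gene, make_site(genomic, ref=ref, donor=donor))
            # oracle: translate the whole mutated CDS and diff the proteins
            mutated = cds[: cds_pos - 1] + new + cds_pos * "" + cds[cds_pos:]
            prot_ref = str(Seq(cds).translate())
            prot_alt = str(Seq(mutated).translate())
            if prot_ref == prot_alt:
                expected = "synonymous"
            else:
                diffs = [
                    i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b
                ]
                assert len(diffs) == 1
                expected = "stop_gained" if prot_alt[diffs[0]] == "*" else "missense"
                assert eff.codon_index == diffs[0] + 1
            assert eff.effect_class == expected, (cds, cds_pos, new, strand)
            assert eff.codon_index == math.ceil(cds_pos / 3)
            n_checked += 1
        assert n_checked > 200


# (cds_pos, cds_length, codon_index, protein_length) for every published
# coding substitution whose printed coordinates are internally consistent
TABLE_COORDS = [
    (568, 1527, 190, 508),
    (201, 216, 67, 71),
    (154, 216, 52, 71),
    (131, 216, 44, 71),
    (922, 1203, 308, 400),
    (892, 1203, 298, 400),
    (811, 1203, 271, 400),
    (837, 1137, 279, 378),
    (759, 1137, 253, 378),
    (1112, 1998, 371, 665),
    (1131, 1998, 377, 665),
    (1132, 1998, 378, 665),
    (1177, 1998, 393, 665),
    (1193, 1998, 398, 665),
    (1203, 1998, 401, 665),
    (1770, 1839, 590, 612),
    (1769, 1839, 590, 612),
    (1742, 1839, 581, 612),
    (1741, 1839, 581, 612),
    (1730, 1839, 577, 612),
    (1699, 1839, 567, 612),
    (404, 612, 135, 203),
    (1161, 1518, 387, 505),
    (795, 867, 265, 288),
]


@pytest.mark.parametrize("cds_pos, cds_length, codon, protein", TABLE_COORDS)
def test_codon_and_protein_length_conventions(cds_pos, cds_length, codon, protein):
    """codon = ceil(cds_pos / 3); protein length excludes the stop codon."""
    assert math.ceil(cds_pos / 3) == codon
    assert cds_length // 3 - 1 == protein
    rng = np.random.default_rng(cds_pos)
    cds = build_cds(cds_length // 3 - 1, rng)
    gene = single_exon_gene(cds, start=1)
    old = cds[cds_pos - 1]
    new = next(b for b in "ACGT" if b != old)
    eff = vario.annotate_effect(gene, make_site(cds_pos, ref=old, donor=new))
    assert eff.codon_index == codon
    assert eff.protein_length == protein


class TestGeneModelIO:
    def test_gff3_and_fasta_round_trip(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr4\tsrc\tgene\t101\t249\t.\t+\t.\tID=gene1\n"
            "chr4\tsrc\tmRNA\t101\t249\t.\t+\t.\tID=mRNA1;Parent=gene1\n"
            "chr4\tsrc\tCDS\t101\t150\t.\t+\t0\tID=cds1;Parent=mRNA1\n"
            "chr4\tsrc\tCDS\t201\t249\t.\t+\t.\tID=cds1b;Parent=mRNA1\n"
        )
        cds = "ATG" + "AAA" * 31 + "TGA"
        fasta = tmp_path / "cds.fa"
        fasta.write_text(f">mRNA1\n{cds}\n")
        models = vario.read_gene_models(gff, fasta)
        assert list(models) == ["mRNA1"]
        model = models["mRNA1"]
        assert model.cds_segments == ((101, 150), (201, 249))
        assert vario.cds_coordinate(model, 201) == 51
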