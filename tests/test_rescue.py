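import pytest

from sporesig.architectures import default_registry
from sporesig.context import RCKOTable
from sporesig.io_formats import GeneRecord
from sporesig.pipeline import predict_pos
from sporesig.rescue import (
    IntergenicRegion,
    find_intergenic_gaps,
    rescue_scan,
    six_frame_translate,
)
from sporesig.synth import (
    MOTIF_STRINGS,
    PROFILE_TAGS,
    MockProfileBackend,
    reverse_translate,
)


def gene(gid, start, end, sp="sp1", contig="c1", ko=None, strand="+"):
    return GeneRecord(sp, gid, contig, start, end, strand, ko, "")


class TestGapFinding:
    def test_interval_arithmetic(self):
        regions = find_intergenic_gaps(
            [gene("a", 1, 100), gene("b", 401, 500)], {("sp1", "c1"): 500}, 200
        )
        assert [(r.start, r.end, r.length) for r in regions] == [(101, 400, 300)]
        assert regions[0].flank_left == "a" and regions[0].flank_right == "b"

    def test_adjacent_genes_leave_no_gap(self):
        assert find_intergenic_gaps(
            [gene("a", 1, 100), gene("b", 101, 200)], {("sp1", "c1"): 200}, 1
        ) == []

    def test_min_gap_boundary(self):
        regions = find_intergenic_gaps(
            [gene("a", 1, 100), gene("b", 401, 500)], {("sp1", "c1"): 500}, 301
        )
        assert regions == []

    def test_gene_beyond_contig_errors(self):
        with pytest.raises(ValueError, match="beyond contig"):
            find_intergenic_gaps([gene("a", 1, 600)], {("sp1", "c1"): 500})

    def test_regions_disjoint_from_genes_and_each_other(self):
        genes = [gene("a", 300, 700), gene("b", 650, 1000), gene("c", 2000, 2400)]
        regions = find_intergenic_gaps(genes, {("sp1", "c1"): 3000}, 100)
        intervals = [(r.start, r.end) for r in regions]
        assert intervals == [(1, 299), (1001, 1999), (2401, 3000)]
        for r in regions:
            for g in genes:
                assert r.end < g.start or r.start > g.end


class TestSixFrame:
    def test_codon_table(self):
        frames = six_frame_translate("ATGGCC")
        assert frames[1] == "MA"

    def test_reverse_complement_symmetry(self):
        s = "ATGGCCTTAGACCAT"
        rc = str.maketrans("ACGT", "TGCA")
        revcomp = s.translate(rc)[::-1]
        assert six_frame_translate(s)[-1] == six_frame_translate(revcomp)[1]

    def test_empty_input(self):
        assert all(v == "" for v in six_frame_translate("").values())

    def test_n_translates_to_x(self):
        assert six_frame_translate("ATGNNN")[1] == "MX"

    def test_bad_character_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("ATGU")


def _hidden_gene_fixture(strand="+"):
    """A 1-contig genome with one unannotated SpoIIIAH-like ORF in a gap."""
    tag = PROFILE_TAGS["PLH_SpoIIIAH"]
    aa = "M" + "AGTK" * 5 + tag + "LVNQ" * 5
    cds = reverse_translate(aa)
    if strand == "-":
        cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    left = gene("left", 1, 300, ko=None)
    right = gene("right", 1201, 1500, ko="K01961")
    start = 601  # frame of the gap translation depends on gap offset
    contig = "A" * 600 + cds + "G" * (1200 - 600 - len(cds)) + "C" * 300
    genes = [left, right]
    rckos = {"SpoIIIAH": RCKOTable("SpoIIIAH", {"K01961": 8}, 8)}
    return genes, contig, rckos, aa, strand


class TestRescueScan:
    def test_planted_orf_with_rcko_neighbor_recovered(self):
        genes, contig, rckos, aa, _ = _hidden_gene_fixture("+")
        regions = find_intergenic_gaps(genes, {("sp1", "c1"): len(contig)}, 200)
        rescued = rescue_scan(
            regions, MockProfileBackend(), default_registry(),
            {("sp1", "c1"): contig}, genes=genes, rckos=rckos,
        )
        accepted = [r for r in rescued if r.accepted]
        assert len(accepted) == 1
        assert accepted[0].architecture_call.target_protein == "SpoIIIAH"
        assert accepted[0].context_support == {"K01961"}
        assert accepted[0].frame > 0

    def test_minus_strand_orf_recovered_in_negative_frame(self):
        genes, contig, rckos, aa, _ = _hidden_gene_fixture("-")
        regions = find_intergenic_gaps(genes, {("sp1", "c1"): len(contig)}, 200)
        rescued = rescue_scan(
            regions, MockProfileBackend(), default_registry(),
            {("sp1", "c1"): contig}, genes=genes, rckos=rckos,
        )
        accepted = [r for r in rescued if r.accepted]
        assert len(accepted) == 1 and accepted[0].frame < 0

    def test_spoiiiaa_without_walker_b_rejected(self):
        tag = PROFILE_TAGS["PF03266"]
        aa = ("M" + MOTIF_STRINGS["WalkerA"] + MOTIF_STRINGS["HisBox"]
              + tag + "AAAA" + tag + MOTIF_STRINGS["AspBox"])  # no Walker B
        cds = reverse_translate(aa)
        contig = "A" * 600 + cds + "G" * 300
        genes = [gene("left", 1, 300, ko="K07000")]
        rckos = {"SpoIIIAA": RCKOTable("SpoIIIAA", {"K07000": 8}, 8)}
        regions = find_intergenic_gaps(genes, {("sp1", "c1"): len(contig)}, 200)
        rescued = rescue_scan(
            regions, MockProfileBackend(), default_registry(),
            {("sp1", "c1"): contig}, genes=genes, rckos=rckos,
        )
        aa_calls = [r for r in rescued
                    if r.architecture_call.target_protein == "SpoIIIAA"]
        assert aa_calls and not any(r.accepted for r in aa_calls)
        assert not aa_calls[0].motif_report["WalkerB"]

    def test_empty_region_list(self):
        assert rescue_scan([], MockProfileBackend(), default_registry(), {}) == []

    def test_synthetic_hidden_genes_all_recovered(self, bundle, pipeline_result):
        """End-to-end: every hidden planted gene is rescued, nothing else."""
        truth = bundle.truth.hidden_genes
        assert truth, "fixture must plant hidden genes"
        sub_genes = [
            g for g in bundle.genes
            if (g.species_id, g.contig_id) in bundle.contig_seqs
        ]
        regions = find_intergenic_gaps(sub_genes, bundle.contig_lengths, 200)
        _, rckos = predict_pos(bundle.genes, bundle.hits, default_registry())
        rescued = rescue_scan(
            regions, MockProfileBackend(), default_registry(),
            bundle.contig_seqs, genes=sub_genes, rckos=rckos,
        )
        accepted = {
            (r.region.species_id, r.architecture_call.target_protein)
            for r in rescued if r.accepted
        }
        expected = {(h["species_id"], h["target"]) for h in truth}
        assert accepted == expected  # precision = recall = 1 at noise 0
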