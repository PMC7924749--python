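import numpy as np
import pandas as pd
import pytest

from sporesig.context import PhyleticMatrix
from sporesig.io_formats import Taxonomy, read_newick
from sporesig.megalign import (
    OrthologGroup,
    PairHit,
    assemble_megaalignment,
    bdbh_orthologs,
    core_groups,
    nj_tree,
    select_representatives,
    simple_pair_hits,
)


def _matrix(profiles, families):
    df = pd.DataFrame(profiles)
    tax = {s: Taxonomy(s, "C", families[s], "G") for s in df.index}
    return PhyleticMatrix(df, taxonomy=tax)


class TestRepresentatives:
    def test_two_distinct_profiles_two_reps(self):
        m = _matrix(
            pd.DataFrame(
                {"A": [1, 1, 0]}, index=["s1", "s2", "s3"]
            ),
            {"s1": "F1", "s2": "F1", "s3": "F1"},
        )
        assert select_representatives(m) == ["s1", "s3"]

    def test_identical_profiles_one_rep(self):
        m = _matrix(
            pd.DataFrame({"A": [1, 1]}, index=["s1", "s2"]),
            {"s1": "F1", "s2": "F1"},
        )
        assert select_representatives(m) == ["s1"]

    def test_singleton_family_kept(self):
        m = _matrix(
            pd.DataFrame({"A": [1, 1]}, index=["s1", "s2"]),
            {"s1": "F1", "s2": "F2"},
        )
        assert select_representatives(m) == ["s1", "s2"]

    def test_size_equals_sum_of_distinct_profiles(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 2, size=(12, 3)),
            index=[f"s{i}" for i in range(12)],
        )
        fams = {f"s{i}": f"F{i % 3}" for i in range(12)}
        m = _matrix(df, fams)
        expected = sum(
            len({tuple(df.loc[s]) for s in df.index if fams[s] == f})
            for f in {"F0", "F1", "F2"}
        )
        assert len(select_representatives(m)) == expected


def _mutual(qs, qg, ss, sg, e=1e-10, aln=60):
    return [
        PairHit(qs, qg, ss, sg, e, aln),
        PairHit(ss, sg, qs, qg, e, aln),
    ]


class TestBDBH:
    LEN = {"a1": 100, "b1": 100, "b2": 100}

    def test_mutual_best_with_coverage_accepted(self):
        groups = bdbh_orthologs(_mutual("A", "a1", "B", "b1", aln=60), self.LEN)
        assert len(groups) == 1 and groups[0].members == {"A": "a1", "B": "b1"}

    def test_one_directional_best_not_orthologous(self):
        hits = [
            PairHit("A", "a1", "B", "b1", 1e-10, 60),
            # B's best hit points elsewhere
            PairHit("B", "b1", "A", "a1", 1e-3, 60),
            PairHit("B", "b2", "A", "a1", 1e-20, 60),
            PairHit("A", "a1", "B", "b2", 1e-2, 60),
        ]
        groups = bdbh_orthologs(hits, self.LEN)
        assert groups == []

    def test_low_coverage_rejected(self):
        groups = bdbh_orthologs(_mutual("A", "a1", "B", "b1", aln=40), self.LEN)
        assert groups == []

    def test_evalue_threshold_is_strict(self):
        groups = bdbh_orthologs(_mutual("A", "a1", "B", "b1", e=1e-4), self.LEN)
        assert groups == []

    def test_missing_length_errors(self):
        with pytest.raises(KeyError):
            bdbh_orthologs(_mutual("A", "x", "B", "y"), {"x": 10})

    def test_planted_families_recovered_exactly(self):
        rng = np.random.default_rng(1)
        aa = list("ACDEFGHIKLMNPQRSTVWY")

        def mutate(seq, n):
            seq = list(seq)
            for i in rng.choice(len(seq), size=n, replace=False):
                seq[i] = rng.choice(aa)
            return "".join(seq)

        bases = ["".join(rng.choice(aa, 60)) for _ in range(3)]
        proteomes = {
            f"sp{i}": {f"sp{i}_f{j}": mutate(bases[j], 3) for j in range(3)}
            for i in range(4)
        }
        hits, lengths = simple_pair_hits(proteomes)
        groups = bdbh_orthologs(hits, lengths)
        recovered = {
            frozenset(g.members.values()) for g in groups
        }
        planted = {
            frozenset(f"sp{i}_f{j}" for i in range(4)) for j in range(3)
        }
        assert recovered == planted


class TestCoreGroups:
    def _grp(self, n):
        return OrthologGroup("g", {f"s{i}": f"s{i}_x" for i in range(n)})

    def test_ninety_percent_rule(self):
        species = [f"s{i}" for i in range(10)]
        assert core_groups([self._grp(9)], species) == [self._grp(9)]
        assert core_groups([self._grp(8)], species) == []
        assert len(core_groups([self._grp(10)], species)) == 1


class TestMegaAlignment:
    def test_missing_species_dash_padded(self):
        aln = {"og1": {"A": "MKLV" * 30}}
        mega = assemble_megaalignment(aln, ["A", "B"], col_frac=0.4)
        assert mega.sequences["B"] == "-" * 120

    def test_column_informative_fraction_rule(self):
        # 17/20 = 85% informative column removed at 0.90, kept at 0.80
        rows = {f"s{i}": ("A" if i < 17 else "-") + "C" for i in range(20)}
        mega = assemble_megaalignment({"og": rows}, list(rows), col_frac=0.90)
        assert mega.length == 1
        mega = assemble_megaalignment({"og": rows}, list(rows), col_frac=0.80)
        assert mega.length == 2

    def test_all_gap_column_removed(self):
        rows = {"a": "-M", "b": "-M"}
        mega = assemble_megaalignment({"og": rows}, ["a", "b"])
        assert mega.length == 1

    def test_duplicate_handling_and_partitions(self):
        alns = {"og1": {"a": "MK", "b": "MK"}, "og2": {"a": "VVV", "b": "VVV"}}
        mega = assemble_megaalignment(alns, ["a", "b"])
        assert mega.partitions == {"og1": (0, 2), "og2": (2, 5)}
        assert mega.length == 5

    def test_every_retained_column_satisfies_rule_exhaustively(self):
        rng = np.random.default_rng(7)
        species = [f"s{i}" for i in range(10)]
        alns = {}
        for g in range(3):
            width = int(rng.integers(5, 15))
            alns[f"og{g}"] = {
                sp: "".join(rng.choice(["A", "-"], size=width, p=[0.85, 0.15]))
                for sp in rng.choice(species, size=8, replace=False)
            }
        mega = assemble_megaalignment(alns, species, col_frac=0.9)
        arr = np.array([list(mega.sequences[sp]) for sp in species])
        if mega.length:
            assert ((arr != "-").mean(axis=0) >= 0.9).all()
        total_width = sum(len(next(iter(a.values()))) for a in alns.values())
        assert mega.length <= total_width


class TestNJTree:
    def test_three_taxon_additive_topology(self):
        # additive distances: A,B sisters at depth 1, C distant
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = read_newick(nj_tree(d))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(4.0)

    def test_two_taxa_single_edge(self):
        assert nj_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["A", "B"]) == "(A:1.5,B:1.5);"

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["A", "B"])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])
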