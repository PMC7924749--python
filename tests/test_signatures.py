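import itertools

import numpy as np
import pandas as pd
import pytest

from sporesig.context import PhyleticMatrix
from sporesig.datasets import desulfitobacterium_profiles, geobacillus_profiles
from sporesig.io_formats import Taxonomy
from sporesig.signatures import (
    CONSISTENT,
    DEVIATES,
    NO_CALL,
    SignatureResult,
    c_score,
    call_signatures,
    compact_signature,
    predict_phenotype,
    sim9_swap_null,
)


def brute_c_score(m):
    """Independent O(R^2 C) oracle: explicit loop over row pairs."""
    m = np.asarray(m)
    rows = m.shape[0]
    total, pairs = 0, 0
    for i, j in itertools.combinations(range(rows), 2):
        ri, rj = m[i].sum(), m[j].sum()
        s = int(np.sum((m[i] == 1) & (m[j] == 1)))
        total += (ri - s) * (rj - s)
        pairs += 1
    return total / pairs


class TestCScore:
    def test_identical_rows_score_zero(self):
        assert c_score([[1, 0, 1], [1, 0, 1], [1, 0, 1]]) == 0.0

    def test_perfect_checkerboard_scores_one(self):
        assert c_score([[1, 0], [0, 1]]) == 1.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = rng.integers(0, 2, size=(6, 8))
            assert c_score(m) == pytest.approx(brute_c_score(m))

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            c_score([[1, 0, 1]])

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            c_score([[2, 0], [0, 1]])

    def test_nonnegative_and_zero_iff_no_checkerboard(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = rng.integers(0, 2, size=(4, 5))
            s = c_score(m)
            assert s >= 0
            has_checker = any(
                ((m[i] == 1) & (m[j] == 0)).any() and ((m[i] == 0) & (m[j] == 1)).any()
                for i, j in itertools.combinations(range(4), 2)
            )
            assert (s > 0) == has_checker


class TestCuratedGenera:
    def test_desulfitobacterium_scores_04_with_species_rows(self):
        assert c_score(desulfitobacterium_profiles().values) == pytest.approx(0.4)

    def test_geobacillus_identical_profiles_score_zero(self):
        assert c_score(geobacillus_profiles().values) == 0.0

    def test_geobacillus_signature_string(self):
        df = geobacillus_profiles()
        present = frozenset(df.columns[df.iloc[0] == 1])
        assert compact_signature(present) == "Spo0A-Q:AH-DMP-GerM"


class TestSim9:
    def test_all_ones_matrix_is_frozen(self):
        samples = sim9_swap_null(np.ones((3, 3), dtype=int), 10, rng_seed=1)
        assert set(samples) == {0.0}

    def test_two_by_two_checkerboard_constant_score(self):
        samples = sim9_swap_null([[1, 0], [0, 1]], 20, rng_seed=5)
        assert set(samples) == {1.0}

    def test_margins_preserved_exactly(self):
        rng = np.random.default_rng(9)
        m = rng.integers(0, 2, size=(5, 7))
        _, mats = sim9_swap_null(m, 30, rng_seed=2, return_matrices=True)
        for sampled in mats:
            assert (sampled.sum(axis=0) == m.sum(axis=0)).all()
            assert (sampled.sum(axis=1) == m.sum(axis=1)).all()

    def test_three_by_three_chain_reaches_every_state(self):
        # margins (1,1,1)x(1,1,1): the 6 permutation matrices
        m = np.eye(3, dtype=int)
        _, mats = sim9_swap_null(m, 3000, burn_in=0, thin=1, rng_seed=0,
                                 return_matrices=True)
        seen = {tuple(s.flatten()) for s in mats}
        assert len(seen) == 6

    def test_n_samples_validated(self):
        with pytest.raises(ValueError):
            sim9_swap_null(np.eye(2, dtype=int), 0)


def _matrix_for_genus(profiles, genus="GX"):
    df = pd.DataFrame(profiles)
    df.index = [f"{genus}_s{i}" for i in range(len(df))]
    tax = {s: Taxonomy(s, "C", "F", genus) for s in df.index}
    pheno = {s: "sporulating" for s in df.index}
    return PhyleticMatrix(df, taxonomy=tax, phenotype=pheno)


class TestCallSignatures:
    def test_identical_profiles_significant_with_full_signature(self):
        m = _matrix_for_genus({"A": [1] * 4, "B": [1] * 4, "C": [0] * 4})
        (res,) = call_signatures(m)
        assert res.significant and res.c_score == 0.0
        assert res.signature_set == {"A", "B"}

    def test_segregated_genus_not_significant(self):
        m = _matrix_for_genus({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1], "C": [1, 1, 1, 1]})
        (res,) = call_signatures(m)
        assert not res.significant and res.signature_set == frozenset()

    def test_singleton_genus_gets_no_signature(self):
        m = _matrix_for_genus({"A": [1]})
        (res,) = call_signatures(m)
        assert res.n_species == 1 and not res.significant and res.c_score is None

    def test_prevalence_excludes_rare_proteins(self):
        # 19/20 present -> kept at 0.95; 17/20 -> dropped
        profiles = {"common": [1] * 19 + [0], "rare": [1] * 17 + [0] * 3}
        m = _matrix_for_genus(profiles)
        (res,) = call_signatures(m, prevalence=0.95)
        assert res.signature_set == {"common"}

    def test_planted_synthetic_signatures_recovered(self, bundle, pipeline_result):
        results = call_signatures(pipeline_result.matrix)
        by_genus = {r.genus: r for r in results}
        for genus, planted in bundle.truth.planted_signatures.items():
            res = by_genus[genus]
            if genus in bundle.truth.checkerboard_genera:
                assert not res.significant
            else:
                assert res.significant and res.signature_set == planted

    def test_unknown_species_in_taxonomy_errors(self):
        df = pd.DataFrame({"A": [1, 1]}, index=["s1", "s2"])
        m = PhyleticMatrix(df, phenotype={"s1": "sporulating", "s2": "sporulating"})
        with pytest.raises(KeyError):
            call_signatures(m, taxonomy={})


class TestPredictPhenotype:
    SIG = SignatureResult("G", 3, 0.0, True, frozenset({"A", "B"}))

    def test_superset_profile_consistent(self):
        assert predict_phenotype({"A": 1, "B": 1, "C": 1}, self.SIG) == CONSISTENT

    def test_missing_signature_protein_deviates(self):
        assert predict_phenotype({"A": 1, "B": 0}, self.SIG) == DEVIATES

    def test_no_signature_no_call(self):
        nosig = SignatureResult("G", 1, None, False, frozenset())
        assert predict_phenotype({"A": 1}, nosig) == NO_CALL

    def test_planted_deviant_detected(self, bundle, pipeline_result):
        results = call_signatures(pipeline_result.matrix)
        by_genus = {r.genus: r for r in results}
        matrix = pipeline_result.matrix
        for sp in bundle.truth.deviant_species:
            sig = by_genus[matrix.genus_of(sp)]
            verdict = predict_phenotype(matrix.df.loc[sp].to_dict(), sig)
            assert verdict == DEVIATES
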