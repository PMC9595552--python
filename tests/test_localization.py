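"""Per-source reduction, consensus voting and agreement scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from funhop import (
    agreement,
    build_consensus,
    consensus_vote,
    map_busca,
    mean_agreement,
    read_busca,
    read_combined,
    read_hpa,
    read_subcell,
    reduce_hpa,
    reduce_subcell,
    simplify_hpa,
)
from funhop.localization import ALL_CATEGORIES, CATEGORIES, UNCERTAIN, UNKNOWN

from _oracles import confusion_oracle, consensus_oracle

categories = st.sampled_from(ALL_CATEGORIES)


class TestReduceSubcell:
    def test_plurality_after_unassign_exclusion(self):
        labels = ["Mitochondria", "Mitochondria", "Unassign", "Cytosol", "Mitochondria"]
        assert reduce_subcell(labels) == "mitochondria"

    def test_exact_tie_is_uncertain(self):
        assert reduce_subcell(["Mitochondria", "Cytosol"]) == UNCERTAIN

    def test_all_unassign_is_unknown(self):
        assert reduce_subcell(["Unassign"] * 5) == UNKNOWN

    def test_unanimous(self):
        assert reduce_subcell(["Secretory"] * 5) == "secretory"

    @given(st.lists(st.sampled_from(
        ["Mitochondria", "Cytosol", "Nuclear", "Secretory", "Unassign"]),
        min_size=1, max_size=5))
    def test_permutation_invariant(self, labels):
        results = {reduce_subcell(list(p)) for p in itertools.permutations(labels)}
        assert len(results) == 1


class TestHpa:
    def test_nuclear_organelles_map_to_nucleus(self):
        assert simplify_hpa(["Nucleoplasm", "Nucleoli"]) == ["nucleus", "nucleus"]

    def test_mitochondria_identity(self):
        assert simplify_hpa(["Mitochondria"]) == ["mitochondria"]

    def test_cytosol_and_mitochondria(self):
        assert simplify_hpa(["Cytosol", "Mitochondria"]) == ["cytoplasm", "mitochondria"]

    def test_unmapped_label_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="Atlantis"):
            assert simplify_hpa(["Atlantis", "Cytosol"]) == ["cytoplasm"]

    def test_empty_label_set_is_error(self):
        with pytest.raises(ValueError):
            simplify_hpa([])

    def test_reduce_plurality(self):
        assert reduce_hpa(["nucleus", "nucleus", "cytoplasm"]) == "nucleus"

    def test_reduce_tie_uncertain(self):
        assert reduce_hpa(["mitochondria", "cytoplasm"]) == UNCERTAIN

    def test_reduce_singleton(self):
        assert reduce_hpa(["secretory"]) == "secretory"


class TestBusca:
    @pytest.mark.parametrize(
        ("label", "expected"),
        [
            ("mitochondrion", "mitochondria"),
            ("extracellular space", "secretory"),
            ("plasma membrane", "secretory"),
            ("endomembrane system", "secretory"),
            ("cytoplasm", "cytoplasm"),
            ("nucleus", "nucleus"),
        ],
    )
    def test_class_mapping(self, label, expected):
        assert map_busca(label) == expected

    def test_unknown_class_warns(self):
        with pytest.warns(UserWarning):
            assert map_busca("flux capacitor") == UNKNOWN


class TestConsensusVote:
    def test_two_experimental_agree(self):
        assert consensus_vote("mitochondria", "mitochondria", "cytoplasm") == (
            "mitochondria", "majority")

    def test_experimental_pair_beats_predictor(self):
        # consistent experimental evidence overrides the prediction
        assert consensus_vote("cytoplasm", "cytoplasm", "mitochondria")[0] == "cytoplasm"

    def test_all_three_differ_predictor_casts_vote(self):
        assert consensus_vote("mitochondria", "cytoplasm", "nucleus") == (
            "nucleus", "busca_casting_vote")

    def test_predictor_alone(self):
        final, rule = consensus_vote(UNKNOWN, UNKNOWN, "mitochondria")
        assert final == "mitochondria" and rule == "busca_casting_vote"

    def test_single_experimental_vote_stands(self):
        assert consensus_vote("nucleus", UNKNOWN, UNKNOWN) == ("nucleus", "single_source")

    def test_no_usable_votes(self):
        assert consensus_vote(UNCERTAIN, UNKNOWN, UNCERTAIN) == (UNKNOWN, "none")

    def test_prefer_experimental_flips_one_vs_one(self):
        args = ("cytoplasm", UNKNOWN, "mitochondria")
        assert consensus_vote(*args)[0] == "mitochondria"
        assert consensus_vote(*args, prefer_experimental=True)[0] == "cytoplasm"

    def test_full_truth_table_matches_oracle(self):
        for sc, hp, bu in itertools.product(ALL_CATEGORIES, repeat=3):
            final, _rule = consensus_vote(sc, hp, bu)
            assert final == consensus_oracle(sc, hp, bu), (sc, hp, bu)

    @given(categories, categories, categories, st.sampled_from(ALL_CATEGORIES))
    def test_majority_dominance(self, a, b, third, replacement):
        """Two agreeing usable votes fix the outcome whatever the third says."""
        if a not in CATEGORIES:
            return
        base = consensus_vote(a, a, third)[0]
        assert base == a
        assert consensus_vote(a, a, replacement)[0] == a

    @given(categories, categories)
    def test_uncertain_behaves_like_unknown(self, a, b):
        for pos in range(3):
            votes_unc = [a, b, a]
            votes_unk = [a, b, a]
            votes_unc[pos] = UNCERTAIN
            votes_unk[pos] = UNKNOWN
            assert consensus_vote(*votes_unc) == consensus_vote(*votes_unk)

    def test_consensus_never_uncertain(self):
        for votes in itertools.product(ALL_CATEGORIES, repeat=3):
            assert consensus_vote(*votes)[0] != UNCERTAIN


class TestBuildConsensus:
    def test_table_columns_and_rules(self):
        df = build_consensus(
            {"ACACA": "cytoplasm", "CS": "mitochondria"},
            {"ACACA": "cytoplasm"},
            {"ACACA": "mitochondria", "CS": "mitochondria", "ONLY": "nucleus"},
        )
        assert df.loc["ACACA", "consensus"] == "cytoplasm"
        assert df.loc["ACACA", "rule"] == "majority"
        assert df.loc["CS", "consensus"] == "mitochondria"
        assert df.loc["ONLY", "rule"] == "busca_casting_vote"


class TestAgreement:
    def test_hand_enumerated_confusion_matrix(self):
        truth = {"g1": "mitochondria", "g2": "mitochondria",
                 "g3": "cytoplasm", "g4": "nucleus"}
        pred = {"g1": "mitochondria", "g2": "cytoplasm",
                "g3": "cytoplasm", "g4": "nucleus"}
        rep = agreement(pred, truth)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (1, 1, 2, 0)
        assert rep.sensitivity == 0.5 and rep.specificity == 1.0
        assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n_shared == 4

    def test_perfect_agreement(self):
        cats = {"a": "mitochondria", "b": "cytoplasm"}
        rep = agreement(cats, cats)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_no_predicted_mito_gives_zero_sensitivity(self):
        truth = {"a": "mitochondria", "b": "cytoplasm"}
        pred = {"a": "cytoplasm", "b": "cytoplasm"}
        assert agreement(pred, truth).sensitivity == 0.0

    def test_no_shared_genes_is_error(self):
        with pytest.raises(ValueError):
            agreement({"a": "mitochondria"}, {"b": "cytoplasm"})

    def test_uncertain_and_unknown_excluded(self):
        truth = {"a": "mitochondria", "b": UNCERTAIN, "c": "cytoplasm"}
        pred = {"a": "mitochondria", "b": "mitochondria", "c": UNKNOWN}
        assert agreement(pred, truth).n_shared == 1

    @pytest.mark.parametrize("n", [10, 200, 1000])
    def test_matches_sklearn_oracle_on_random_vectors(self, n):
        rng = np.random.default_rng(n)
        genes = [f"g{i}" for i in range(n)]
        truth = {g: str(rng.choice(ALL_CATEGORIES)) for g in genes}
        pred = {g: str(rng.choice(ALL_CATEGORIES)) for g in genes}
        rep = agreement(pred, truth)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == confusion_oracle(pred, truth)

    def test_mean_agreement(self):
        r1 = agreement({"a": "mitochondria"}, {"a": "mitochondria"})
        r2 = agreement({"a": "cytoplasm", "b": "mitochondria"},
                       {"a": "mitochondria", "b": "mitochondria"})
        sens, _spec = mean_agreement([r1, r2])
        assert sens == pytest.approx(0.75)


class TestReaders:
    def test_subcell_reader_votes_per_gene(self, tmp_path):
        path = tmp_path / "subcell.tsv"
        path.write_text(
            "gene\tcell_line\tneighborhood\n"
            "aco2\tA431\tMitochondria\naco2\tMCF7\tMitochondria\n"
            "aco2\tH322\tUnassign\naco2\tU251\tCytosol\naco2\tHCC827\tMitochondria\n"
            "GAPDH\tA431\tCytosol\n"
        )
        out = read_subcell(path)
        assert out == {"ACO2": "mitochondria", "GAPDH": "cytoplasm"}

    def test_hpa_reader_multilabel(self, tmp_path):
        path = tmp_path / "hpa.tsv"
        path.write_text(
            "gene\tlocations\treliability\n"
            "FOXA1\tNucleoplasm;Nucleoli\tApproved\n"
            "TIE1\tPlasma membrane;Cytosol\tSupported\n"
        )
        out = read_hpa(path)
        assert out["FOXA1"] == "nucleus"
        assert out["TIE1"] == UNCERTAIN

    def test_busca_reader(self, tmp_path):
        path = tmp_path / "busca.tsv"
        path.write_text(
            "sequence_id\tpredicted_class\tscore\nCS\tmitochondrion\t0.9\n"
            "ALB\textracellular space\t0.8\n"
        )
        assert read_busca(path) == {"CS": "mitochondria", "ALB": "secretory"}

    def test_combined_reader_matches_separate_sources(self, tmp_path):
        path = tmp_path / "combined.tsv"
        path.write_text(
            "gene\tsubcell\thpa\tbusca\n"
            "ACACA\tCytosol\tCytosol\tmitochondrion\n"
            "CS\tMitochondria\t\tmitochondrion\n"
        )
        subcell, hpa, busca = read_combined(path)
        df = build_consensus(subcell, hpa, busca)
        assert df.loc["ACACA", "consensus"] == "cytoplasm"
        assert df.loc["CS", "consensus"] == "mitochondria"
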