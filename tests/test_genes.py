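import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from domainspot.catalog import classify_mutation
from domainspot.genes import (
    GeneMutationProfile,
    build_feature_matrix,
    cross_validate,
    gene_profiles,
    rank_auc,
    score_unlabelled,
    twenty_twenty,
)
from domainspot.io import DomainInstance, MutationRecord


def profile(total=10, trunc=0.0, max_mis=0.0, gene="G"):
    return GeneMutationProfile(gene, total, trunc, max_mis)


def muts(gene, changes):
    return [classify_mutation(MutationRecord(f"S{i}", gene, c, ""))
            for i, c in enumerate(changes)]


class TestTwentyTwenty:
    def test_thirty_percent_truncations_is_ts(self):
        assert twenty_twenty(profile(10, trunc=0.3)) == "TS"

    def test_all_missense_at_one_position_is_og(self):
        assert twenty_twenty(profile(10, max_mis=1.0)) == "OG"

    def test_dispersed_missense_is_neither(self):
        assert twenty_twenty(profile(10, max_mis=0.1)) == "neither"

    def test_both(self):
        assert twenty_twenty(profile(10, trunc=0.5, max_mis=0.5)) == "both"

    def test_zero_mutations_neither_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert twenty_twenty(profile(total=0)) == "neither"
        assert "no mutations" in caplog.text

    def test_monotone_in_truncations(self):
        # adding a truncation never demotes a TS call
        rng = np.random.default_rng(0)
        for _ in range(50):
            total = int(rng.integers(1, 50))
            n_trunc = int(rng.integers(0, total + 1))
            before = twenty_twenty(profile(total, n_trunc / total))
            after = twenty_twenty(profile(total + 1, (n_trunc + 1) / (total + 1)))
            if before in ("TS", "both"):
                assert after in ("TS", "both")

    def test_profiles_from_catalog(self):
        catalog = muts("G1", ["V600E", "V600K", "A10C", "E80*"])
        (p,) = gene_profiles(catalog)
        assert p.total_mutations == 4
        assert p.truncation_fraction == pytest.approx(0.25)
        # 2 of 3 missense at position 600
        assert p.max_missense_fraction == pytest.approx(2 / 3)
        assert twenty_twenty(p) == "both"


class TestFeatureMatrix:
    def test_counts_instances(self):
        insts = [DomainInstance("G1", "Pkinase", 1, 50),
                 DomainInstance("G1", "Pkinase", 60, 110),
                 DomainInstance("G2", "SH2", 1, 40)]
        matrix = build_feature_matrix(["G1", "G2"], insts)
        assert matrix.loc["G1", "Pkinase"] == 2
        assert matrix.loc["G2", "Pkinase"] == 0
        # disjoint families give a block-diagonal 2x2
        assert matrix.to_numpy().tolist() == [[2, 0], [0, 1]]

    def test_zero_row_kept(self):
        matrix = build_feature_matrix(["G1", "G2"],
                                      [DomainInstance("G1", "F", 1, 10)])
        assert matrix.loc["G2"].sum() == 0

    def test_binary_mode(self):
        insts = [DomainInstance("G1", "F", 1, 10),
                 DomainInstance("G1", "F", 20, 30)]
        assert build_feature_matrix(["G1"], insts,
                                    binary=True).loc["G1", "F"] == 1


class TestRankAuc:
    def test_matches_trapezoidal_integral(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.choice(np.round(rng.normal(size=40), 1), size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_constant_scores_give_half(self):
        assert rank_auc([1.0] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc([1.0, 2.0], [1, 1])


def separable_matrix(n_per_class=15):
    genes = [f"TS{i}" for i in range(n_per_class)] + \
            [f"OG{i}" for i in range(n_per_class)]
    labels = {g: ("TS" if g.startswith("TS") else "OG") for g in genes}
    insts = []
    for g in genes:
        fam = "HELICASE" if g.startswith("TS") else "PKINASE"
        insts.append(DomainInstance(g, fam, 1, 50))
    return build_feature_matrix(genes, insts), labels


class TestCrossValidate:
    def test_separable_features_reach_auc_one(self):
        matrix, labels = separable_matrix()
        report = cross_validate(matrix, labels, k_folds=10, seed=0)
        assert report.pooled_auc == pytest.approx(1.0)

    def test_reproducible_from_seed(self):
        matrix, labels = separable_matrix()
        a = cross_validate(matrix, labels, k_folds=10, seed=3)
        b = cross_validate(matrix, labels, k_folds=10, seed=3)
        assert a.fold_aucs == b.fold_aucs
        assert a.scores.equals(b.scores)
        assert a.fold_assignment == b.fold_assignment

    def test_rank_auc_equals_trapezoid_internally(self):
        matrix, labels = separable_matrix()
        report = cross_validate(matrix, labels, k_folds=10, seed=1)
        assert report.pooled_auc == pytest.approx(report.trap_auc, abs=1e-12)

    def test_too_few_genes_per_class_rejected(self):
        matrix, labels = separable_matrix(n_per_class=5)
        with pytest.raises(ValueError, match=">= 10"):
            cross_validate(matrix, labels, k_folds=10)

    def test_dual_labelled_genes_excluded_from_training(self):
        matrix, labels = separable_matrix()
        labels["TS0"] = "both"
        report = cross_validate(matrix, labels, k_folds=10, seed=0)
        assert "TS0" not in report.scores["gene"].tolist()


class TestScoreUnlabelled:
    def test_clone_of_training_gene_scores_deterministically(self):
        # a gene with a training gene's exact features gets that gene's
        # rank-calibrated score, identically on every call
        matrix, labels = separable_matrix()
        clone = matrix.loc[["TS0"]].rename(index={"TS0": "DUAL"})
        full = pd.concat([matrix, clone])
        a = score_unlabelled(full, labels, ["DUAL"])
        b = score_unlabelled(full, labels, ["DUAL"])
        assert a.loc[0, "prob_ts"] == b.loc[0, "prob_ts"]
        assert 0.0 <= a.loc[0, "prob_ts"] <= 1.0

    def test_strongly_ts_typical_gene_called_ts(self):
        # three TS-typical domains where training genes carry one:
        # outranks every training score, clearing the 0.78 cut
        matrix, labels = separable_matrix()
        dual = matrix.loc[["TS0"]].rename(index={"TS0": "DUAL"}) * 3
        full = pd.concat([matrix, dual])
        frame = score_unlabelled(full, labels, ["DUAL"])
        assert frame.loc[0, "call"] == "TS"
        assert frame.loc[0, "prob_ts"] > 0.78

    def test_strongly_og_typical_gene_called_og(self):
        matrix, labels = separable_matrix()
        dual = matrix.loc[["OG0"]].rename(index={"OG0": "DUAL"}) * 3
        full = pd.concat([matrix, dual])
        frame = score_unlabelled(full, labels, ["DUAL"])
        assert frame.loc[0, "call"] == "OG"

    def test_empty_unlabelled_set(self):
        matrix, labels = separable_matrix()
        assert score_unlabelled(matrix, labels, []).empty
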