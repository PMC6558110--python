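import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from orthoess.evaluation import (
    ConfusionCounts,
    confusion,
    curate_reference_set,
    loocv,
    metrics,
    roc_auc,
)
from orthoess.io import LabelTable
from orthoess.orthology import AlignmentParams
from orthoess.synthetic import CladeParams, generate_clade

from oracles import pairwise_auc

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 50),
    fp=st.integers(0, 50),
    tn=st.integers(0, 50),
    fn=st.integers(0, 50),
)


class TestConfusion:
    truth = LabelTable("t", {"a": True, "b": True, "c": False, "d": False})

    def test_perfect_predictions(self):
        c = confusion({"a": True, "b": True, "c": False, "d": False}, self.truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_inverted_predictions(self):
        c = confusion({"a": False, "b": False, "c": True, "d": True}, self.truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 2, 2)

    def test_all_negative_predictions(self):
        c = confusion({g: False for g in "abcd"}, self.truth)
        assert c.tp == 0 and c.fn == 2

    def test_unlabeled_genes_excluded(self):
        c = confusion({"a": True, "zz": True}, self.truth)
        assert c.total == 1

    def test_no_labeled_genes_rejected(self):
        with pytest.raises(ValueError, match="no labeled"):
            confusion({"zz": True}, self.truth)


class TestMetrics:
    def test_all_correct_gives_mcc_one(self):
        assert metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0)).mcc == 1.0

    def test_all_wrong_gives_mcc_minus_one(self):
        assert metrics(ConfusionCounts(tp=0, fp=1, tn=0, fn=1)).mcc == -1.0

    def test_sensitivity_by_direct_substitution(self):
        assert metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=1)).sensitivity == 0.75

    def test_zero_denominators_reported_undefined(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.precision is None and r.sensitivity is None and r.f_measure is None
        assert r.mcc is None

    def test_f_measure_is_harmonic_mean(self):
        r = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert r.f_measure == pytest.approx(
            2 * r.sensitivity * r.precision / (r.sensitivity + r.precision)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    @given(counts_st)
    def test_class_swap_exchanges_sensitivity_and_specificity(self, c):
        swapped = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
        r, rs = metrics(c), metrics(swapped)
        assert r.sensitivity == rs.specificity
        assert r.specificity == rs.sensitivity
        if r.mcc is not None:
            assert rs.mcc == pytest.approx(r.mcc)

    @given(counts_st)
    def test_mcc_bounded(self, c):
        r = metrics(c)
        if r.mcc is not None:
            assert -1.0 <= r.mcc <= 1.0


class TestRocAuc:
    truth = LabelTable("t", {"a": True, "b": True, "c": False, "d": False})

    def test_perfect_separation(self):
        assert roc_auc({"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}, self.truth) == 1.0

    def test_full_tie_gives_half(self):
        assert roc_auc({g: 0.5 for g in "abcd"}, self.truth) == 0.5

    def test_six_gene_instance_matches_pair_enumeration(self):
        truth = LabelTable("t", dict(zip("abcdef", [True, True, True, False, False, False])))
        scores = {"a": 0.9, "b": 0.4, "c": 0.4, "d": 0.4, "e": 0.2, "f": 0.95}
        genes = sorted(scores)
        expected = pairwise_auc(
            [scores[g] for g in genes], [truth.labels[g] for g in genes]
        )
        assert roc_auc(scores, truth) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_pair_enumeration(self, seed):
        rng = random.Random(seed)
        genes = [f"g{i}" for i in range(10)]
        labels = {g: rng.random() < 0.4 for g in genes}
        labels[genes[0]], labels[genes[1]] = True, False  # both classes present
        scores = {g: rng.choice([0.0, 0.25, 0.5, 0.75]) for g in genes}
        truth = LabelTable("t", labels)
        expected = pairwise_auc([scores[g] for g in genes], [labels[g] for g in genes])
        assert roc_auc(scores, truth) == pytest.approx(expected)

    def test_complement_scores_sum_to_one(self):
        scores = {"a": 0.9, "b": 0.3, "c": 0.3, "d": 0.1}
        neg = {g: -s for g, s in scores.items()}
        assert roc_auc(scores, self.truth) + roc_auc(neg, self.truth) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        scores = {"a": 0.9, "b": 0.3, "c": 0.5, "d": 0.1}
        cubed = {g: s**3 + 2 for g, s in scores.items()}
        assert roc_auc(scores, self.truth) == roc_auc(cubed, self.truth)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc({"a": 0.5, "b": 0.4}, LabelTable("t", {"a": True, "b": True}))


class TestLoocv:
    def test_identical_genome_pair_scores_perfectly(self, loose_params):
        clade = generate_clade(
            CladeParams(
                n_genomes=2, n_genes=12, mean_protein_length=60,
                substitution_rate=0.0, gene_loss_prob=0.0, label_flip_prob=0.0,
                seed=4,
            )
        )
        aucs = loocv(clade, k=3, params=loose_params)
        assert set(aucs.values()) == {1.0}

    def test_invariant_under_collection_permutation(self, loose_params):
        clade = generate_clade(
            CladeParams(
                n_genomes=3, n_genes=15, mean_protein_length=60,
                substitution_rate=0.1, gene_loss_prob=0.0, label_flip_prob=0.1,
                seed=5,
            )
        )
        assert loocv(clade, 3, loose_params) == loocv(clade[::-1], 3, loose_params)

    def test_matches_direct_pipeline_run(self, loose_params):
        """The fold cache must reproduce a from-scratch scoring run."""
        from orthoess.scoring import score_query
        from orthoess.evaluation import roc_auc as auc_fn

        clade = generate_clade(
            CladeParams(
                n_genomes=3, n_genes=15, mean_protein_length=60,
                substitution_rate=0.1, gene_loss_prob=0.1, label_flip_prob=0.1,
                seed=6,
            )
        )
        aucs = loocv(clade, 3, loose_params)
        query, truth = clade[0]
        table = score_query(query, clade[1:], params=loose_params, k=3)
        direct = auc_fn(table.as_mapping("raw"), truth)
        assert aucs[query.genome_id] == pytest.approx(direct)

    def test_single_genome_rejected(self, loose_params):
        clade = generate_clade(
            CladeParams(n_genomes=2, n_genes=12, mean_protein_length=60, seed=7)
        )
        with pytest.raises(ValueError):
            loocv(clade[:1], 3, loose_params)

    def test_single_class_genome_rejected(self, loose_params):
        clade = generate_clade(
            CladeParams(n_genomes=2, n_genes=12, mean_protein_length=60, seed=8)
        )
        proteome, _ = clade[0]
        broken = LabelTable(proteome.genome_id, {g: True for g in proteome.gene_ids})
        with pytest.raises(ValueError, match="label class"):
            loocv([(proteome, broken), clade[1]], 3, loose_params)


class TestCuration:
    def test_rule_application(self):
        kept, dropped = curate_reference_set({"a": 0.55, "b": 0.70, "c": 0.90})
        assert kept == ["b", "c"]
        assert dropped == {"a": 0.55}

    def test_boundary_auc_dropped(self):
        kept, dropped = curate_reference_set({"a": 0.60, "b": 0.61})
        assert kept == ["b"] and "a" in dropped

    def test_custom_cutoff(self):
        kept, _ = curate_reference_set({"a": 0.7, "b": 0.96}, cutoff=0.95)
        assert kept == ["b"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            curate_reference_set({})
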