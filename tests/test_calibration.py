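import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metlike as ml


def scores_from(pairs):
    return [ml.LabeledScore(drug_id=f"d{i}", enzyme_label="E",
                            score=s, label=bool(l))
            for i, (s, l) in enumerate(pairs)]


def concordant_pair_auc(scores):
    """Oracle: fraction of (positive, negative) pairs ranked correctly,
    with half credit for ties (the Mann-Whitney statistic)."""
    pos = [s.score for s in scores if s.label]
    neg = [s.score for s in scores if not s.label]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLabelRelations:
    def test_cardinality(self):
        m = ml.SimilarityMatrix(
            drug_ids=["d1", "d2"], metabolite_ids=["s1"],
            values=np.array([[0.9], [0.2]]), scheme="synthetic-test")
        gsp = [ml.GSPRelation("d1", "E", "s1", 0.9)]
        labeled = ml.label_relations(m, gsp)
        assert len(labeled) == 2
        assert labeled[0].score == 0.9 and labeled[0].label
        assert labeled[1].score == 0.2 and not labeled[1].label

    def test_gsp_drug_score_matches_selection(self, fixture_matrix,
                                              fixture_gsp, bundle):
        labeled = ml.label_relations(fixture_matrix, fixture_gsp,
                                     enzymes=bundle.enzymes)
        by_pair = {(s.drug_id, s.enzyme_label): s for s in labeled}
        for r in fixture_gsp:
            s = by_pair[(r.drug_id, r.enzyme_label)]
            assert s.label
            assert s.score == pytest.approx(r.similarity)

    def test_universe_is_drugs_times_gsp_enzymes(self, fixture_matrix,
                                                 fixture_gsp):
        labeled = ml.label_relations(fixture_matrix, fixture_gsp)
        n_enzymes = len({r.enzyme_label for r in fixture_gsp})
        assert len(labeled) == fixture_matrix.shape[0] * n_enzymes

    def test_sorted_descending_with_deterministic_ties(self, fixture_matrix,
                                                       fixture_gsp):
        labeled = ml.label_relations(fixture_matrix, fixture_gsp)
        keys = [(-s.score, s.drug_id, s.enzyme_label) for s in labeled]
        assert keys == sorted(keys)

    def test_unknown_substrate_raises(self):
        m = ml.SimilarityMatrix(
            drug_ids=["d1", "d2"], metabolite_ids=["s1"],
            values=np.array([[0.9], [0.2]]), scheme="synthetic-test")
        gsp = [ml.GSPRelation("d1", "E", "ghost", 0.9)]
        with pytest.raises(ml.UnknownCompoundError):
            ml.label_relations(m, gsp)

    def test_planted_separation(self):
        """Positives planted above 0.7, negatives below 0.6: scores and
        labels separate perfectly by construction."""
        cfg = ml.SyntheticConfig(
            n_drugs=20, n_metabolites=5, fp_length=2048, bit_density=0.1,
            planted_pairs=[(i, i % 5, 0.8) for i in range(5)], seed=7)
        matrix, truth = ml.synthetic_matrix(cfg)
        gsp = [ml.GSPRelation(matrix.drug_ids[d], f"E{m}",
                              matrix.metabolite_ids[m],
                              matrix.values[d, m])
               for d, m, _ in truth.itertuples(index=False)]
        labeled = ml.label_relations(matrix, gsp)
        pos = [s.score for s in labeled if s.label]
        neg = [s.score for s in labeled if not s.label]
        assert min(pos) > 0.7 > 0.6 > max(neg)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = ml.roc_curve(scores_from([(0.9, 1), (0.8, 1), (0.3, 0),
                                        (0.2, 0)]))
        assert roc.auc == 1.0

    def test_constant_score_is_chance(self):
        roc = ml.roc_curve(scores_from([(0.5, 1), (0.5, 0), (0.5, 1),
                                        (0.5, 0)]))
        assert roc.auc == pytest.approx(0.5)

    def test_interleaved_example(self):
        # concordant pairs: 3 of 4 -> AUC 0.75
        roc = ml.roc_curve(scores_from([(0.9, 1), (0.8, 0), (0.7, 1),
                                        (0.6, 0)]))
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ml.SingleClassError):
            ml.roc_curve(scores_from([(0.9, 1), (0.8, 1)]))

    def test_curve_shape(self, fixture_matrix, fixture_gsp):
        roc = ml.roc_curve(ml.label_relations(fixture_matrix, fixture_gsp))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()
        assert 0.0 <= roc.auc <= 1.0

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.floats(min_value=0, max_value=1,
                                        allow_nan=False, width=32),
                              st.booleans()),
                    min_size=4, max_size=200))
    def test_auc_equals_concordant_pair_oracle(self, pairs):
        labels = [l for _, l in pairs]
        if all(labels) or not any(labels):
            return
        scored = scores_from([(float(s), l) for s, l in pairs])
        roc = ml.roc_curve(scored)
        assert roc.auc == pytest.approx(concordant_pair_auc(scored),
                                        abs=1e-9)


class TestYouden:
    def test_identity_at_reported_operating_point(self):
        # tpr = 1 and fpr = 0.021 give J = 0.979
        assert ml.youden_j(sensitivity=1.0, specificity=1 - 0.021) == \
            pytest.approx(0.979)

    def test_perfect_classifier(self):
        roc = ml.roc_curve(scores_from([(0.9, 1), (0.8, 1), (0.3, 0),
                                        (0.2, 0)]))
        y = ml.youden_optimal(roc)
        assert y.j_max == 1.0
        # the optimal threshold separates the classes
        assert 0.3 < y.optimal_threshold <= 0.8

    def test_useless_classifier(self):
        roc = ml.roc_curve(scores_from([(0.5, 1), (0.5, 0)]))
        y = ml.youden_optimal(roc)
        assert y.j_max == 0.0

    def test_tie_resolves_to_higher_threshold(self):
        # J = 0.5 at both t = 0.9 and t = 0.7; the more specific wins
        roc = ml.roc_curve(scores_from([(0.9, 1), (0.8, 0), (0.7, 1),
                                        (0.6, 0)]))
        y = ml.youden_optimal(roc)
        assert y.j_max == pytest.approx(0.5)
        assert y.optimal_threshold == pytest.approx(0.9)

    def test_j_equals_tpr_minus_fpr(self, fixture_matrix, fixture_gsp):
        roc = ml.roc_curve(ml.label_relations(fixture_matrix, fixture_gsp))
        y = ml.youden_optimal(roc)
        assert np.allclose(y.j_values, roc.tpr - roc.fpr)
        assert y.j_max == y.j_values.max()
        assert (-1 <= y.j_values).all() and (y.j_values <= 1).all()

    def test_invariant_under_monotone_transform(self):
        base = [(0.9, 1), (0.8, 0), (0.7, 1), (0.6, 0), (0.4, 1), (0.1, 0)]
        y1 = ml.youden_optimal(ml.roc_curve(scores_from(base)))
        y2 = ml.youden_optimal(ml.roc_curve(
            scores_from([(s ** 2, l) for s, l in base])))
        assert np.allclose(np.sort(y1.j_values), np.sort(y2.j_values))
        assert y1.j_max == pytest.approx(y2.j_max)
        assert y2.optimal_threshold == pytest.approx(
            y1.optimal_threshold ** 2)


def recover_planted_threshold(t, delta=0.05, n=400, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(t + delta, 1.0, size=n)
    neg = rng.uniform(0.0, t - delta, size=n)
    scored = scores_from([(float(s), 1) for s in pos]
                         + [(float(s), 0) for s in neg])
    return ml.youden_optimal(ml.roc_curve(scored))


class TestPlantedThresholdRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovery_within_delta(self, seed):
        rng = np.random.default_rng(seed)
        t = float(rng.uniform(0.3, 0.8))
        y = recover_planted_threshold(t, delta=0.05, seed=seed)
        assert y.j_max == 1.0
        # threshold grid = observed scores; the optimum is the smallest
        # planted positive, just above t + delta
        assert t - 0.05 < y.optimal_threshold <= t + 0.05 + 5e-3
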