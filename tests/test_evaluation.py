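import numpy as np
import pytest

from lsfregio.datasets import (ConditionDescriptor, ReactionRecord,
                               build_condition_vocabulary)
from lsfregio.errors import (ChargeTableError, EmptyPredictionError,
                             TrainingError, UndefinedMetricError)
from lsfregio.evaluation import (ChargeTable, MetricCounts, atom_accuracy,
                                 atom_morgan_fingerprints, auroc,
                                 eligible_sites, f_score, fukui_indices,
                                 fukui_predict, recall, rf_baseline,
                                 top1_accuracy)
from lsfregio.molgraph import parse_molecule, symmetry_orbits
from lsfregio.reaction_center import ReactiveSiteLabels


def pair_count_auroc(scores, labels):
    """O(n^2) oracle: fraction of (pos, neg) pairs ranked correctly,
    ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAtomMetrics:
    def test_reported_operating_point(self):
        """100 true positives against 125 incorrect sites lands at 0.62."""
        c = MetricCounts(tp=100, fp=75, fn=50, tn=0)
        assert round(f_score(c), 2) == 0.62

    def test_perfect_prediction(self):
        c = MetricCounts(tp=10, fp=0, fn=0, tn=90)
        assert f_score(c) == 1.0
        assert atom_accuracy(c) == 1.0
        assert recall(c) == 1.0

    def test_counts_from_predictions(self):
        c = MetricCounts.from_predictions(np.array([1, 1, 0, 0]),
                                          np.array([1, 0, 1, 0]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        assert c.total == 4

    def test_degenerate_f_score_warns_one(self):
        with pytest.warns(UserWarning):
            assert f_score(MetricCounts(tp=0, fp=0, fn=0, tn=5)) == 1.0

    def test_metric_formulas_against_loop_oracle(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + fp + fn == 0:
                continue
            c = MetricCounts(tp=tp, fp=fp, fn=fn, tn=tn)
            assert f_score(c) == pytest.approx(
                2 * tp / (2 * tp + fp + fn))
            assert atom_accuracy(c) == pytest.approx(
                (tp + tn) / (tp + fp + fn + tn))


class TestAuroc:
    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.uniform(size=200).round(2)   # force ties
        labels = rng.integers(0, 2, 200)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auroc(scores, labels) == pytest.approx(
            pair_count_auroc(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_perfect_separation(self):
        assert auroc(np.array([0.9, 0.8, 0.1]),
                     np.array([1, 1, 0])) == 1.0


class TestTop1:
    def test_argmax_in_true_set(self):
        probs = np.array([0.1, 0.9, 0.2])
        assert top1_accuracy([(probs, {1}, [0, 1, 2])]) == 1.0
        assert top1_accuracy([(probs, {0}, [0, 1, 2])]) == 0.0

    def test_ineligible_argmax_ignored(self):
        probs = np.array([0.99, 0.5, 0.2])
        # atom 0 not eligible (e.g. quaternary carbon)
        assert top1_accuracy([(probs, {1}, [1, 2])]) == 1.0

    def test_negative_records_excluded(self):
        probs = np.array([0.9, 0.1])
        assert top1_accuracy([(probs, {0}, [0, 1]),
                              (probs, set(), [0, 1])]) == 1.0

    def test_matches_loop_oracle_on_random_reactions(self, rng):
        reactions = []
        for _ in range(20):
            n = int(rng.integers(3, 15))
            probs = rng.uniform(size=n)
            eligible = sorted(rng.choice(n, size=rng.integers(1, n),
                                         replace=False).tolist())
            true = set(rng.choice(n, size=rng.integers(1, 3),
                                  replace=False).tolist())
            reactions.append((probs, true, eligible))
        hits = n_scored = 0
        for probs, true, eligible in reactions:
            best, best_p = None, -1.0
            for i in eligible:
                if probs[i] > best_p:
                    best, best_p = i, probs[i]
            n_scored += 1
            hits += best in true
        assert top1_accuracy(reactions) == pytest.approx(hits / n_scored)


def random_charge_table(rng, n=8):
    """Valid charge table: each state sums to its molecular charge."""
    def state(total):
        q = rng.normal(scale=0.2, size=n)
        return q - q.mean() + total / n
    return ChargeTable(q_minus=state(1.0), q_neutral=state(0.0),
                       q_plus=state(-1.0))


class TestFukui:
    def test_direct_substitution(self):
        t = ChargeTable(q_minus=np.array([0.6, 0.4]),
                        q_neutral=np.array([0.10, -0.10]),
                        q_plus=np.array([-0.20, -0.80]))
        idx = fukui_indices(t)
        assert idx.f_plus[0] == pytest.approx(0.30)
        assert idx.f_minus[0] == pytest.approx(0.50)
        assert idx.f_zero[0] == pytest.approx(0.40)

    def test_unchanged_atom_all_zero(self):
        t = ChargeTable(q_minus=np.array([0.0, 1.0]),
                        q_neutral=np.array([0.0, 0.0]),
                        q_plus=np.array([0.0, -1.0]))
        idx = fukui_indices(t)
        assert idx.f_plus[0] == idx.f_minus[0] == idx.f_zero[0] == 0.0

    def test_radical_index_identity_and_unit_sums(self, rng):
        for _ in range(25):
            idx = fukui_indices(random_charge_table(rng))
            np.testing.assert_allclose(
                idx.f_zero, 0.5 * (idx.f_plus + idx.f_minus), atol=1e-15)
            assert idx.f_plus.sum() == pytest.approx(1.0)
            assert idx.f_minus.sum() == pytest.approx(1.0)
            assert idx.f_zero.sum() == pytest.approx(1.0)

    def test_bad_charge_sums_rejected(self):
        with pytest.raises(ChargeTableError):
            ChargeTable(q_minus=np.array([0.0, 0.0]),
                        q_neutral=np.array([0.0, 0.0]),
                        q_plus=np.array([0.0, 0.0]))


class TestFukuiPredict:
    def _indices(self, f_plus, f_zero):
        f_plus = np.asarray(f_plus, dtype=float)
        f_zero = np.asarray(f_zero, dtype=float)
        from lsfregio.evaluation import FukuiIndices
        return FukuiIndices(f_plus=f_plus,
                            f_minus=2 * f_zero - f_plus, f_zero=f_zero)

    def test_dominant_carbon_selected(self):
        idx = self._indices([0.9, 0.1, 0.0], [0.1, 0.1, 0.8])
        sites, col = fukui_predict(idx, "electrophilic_radical", [0, 1, 2])
        assert sites == {0} and col == "f_plus"
        sites, col = fukui_predict(idx, "nucleophilic_radical", [0, 1, 2])
        assert sites == {2} and col == "f_zero"

    def test_ties_expand_k(self):
        idx = self._indices([0.5, 0.5, 0.1], [0.0, 0.0, 0.0])
        sites, _ = fukui_predict(idx, "electrophilic_radical", [0, 1, 2],
                                 k=1)
        assert sites == {0, 1}

    def test_unknown_class_best_fit(self):
        idx = self._indices([0.9, 0.0, 0.0], [0.0, 0.0, 0.9])
        sites, col = fukui_predict(idx, "unknown", [0, 1, 2],
                                   true_sites={0})
        assert sites == {0} and col == "best_fit:f_plus"
        sites, col = fukui_predict(idx, "unknown", [0, 1, 2],
                                   true_sites={2})
        assert sites == {2} and col == "best_fit:f_zero"

    def test_no_eligible_carbons(self):
        idx = self._indices([1.0], [1.0])
        with pytest.raises(EmptyPredictionError):
            fukui_predict(idx, "electrophilic_radical", [])

    def test_prediction_closed_under_symmetry(self):
        """Symmetric atoms with equal indices are selected together."""
        g = parse_molecule("c1ccncc1")
        orbits = symmetry_orbits(g)
        values = np.zeros(g.n_atoms)
        alpha = next(o for o in orbits if len(o) == 2
                     and any(g.elements[j] == "N"
                             for j, _ in g.neighbors(o[0])))
        values[alpha] = 0.7
        idx = self._indices(values, values)
        sites, _ = fukui_predict(idx, "electrophilic_radical",
                                 eligible_sites(g), k=1)
        assert sites == set(alpha)


def _labeled_record(rid, smiles, reactive, reagent):
    g = parse_molecule(smiles)
    labels = [1 if i in reactive else 0 for i in range(g.n_atoms)]
    return ReactionRecord(
        record_id=rid, sm=g,
        conditions=ConditionDescriptor(reagent=reagent, oxidant="tbhp"),
        labels=ReactiveSiteLabels(labels=labels))


class TestRandomForestBaseline:
    def test_symmetric_atoms_identical_fingerprints(self):
        g = parse_molecule("c1ccncc1")
        fp = atom_morgan_fingerprints(g)
        for orbit in symmetry_orbits(g):
            for i in orbit[1:]:
                assert np.array_equal(fp[orbit[0]], fp[i])

    def test_memorizes_tiny_separable_set(self):
        g = parse_molecule("c1ccncc1")
        alpha = {i for i in range(6) if g.elements[i] == "C"
                 and any(g.elements[j] == "N" for j, _ in g.neighbors(i))}
        records = [_labeled_record("a", "c1ccncc1", alpha, "r1"),
                   _labeled_record("b", "c1ccncc1", set(), "r2")]
        vocab = build_condition_vocabulary(records)
        result = rf_baseline(records, records, vocab, n_estimators=50,
                             seed=0)
        assert result.metrics["accuracy"] == 1.0
        assert result.metrics["f_score"] == 1.0

    def test_single_class_training_rejected(self):
        records = [_labeled_record("a", "c1ccccc1", set(), "r1")]
        vocab = build_condition_vocabulary(records)
        with pytest.raises(TrainingError):
            rf_baseline(records, records, vocab)
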