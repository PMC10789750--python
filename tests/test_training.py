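import math

import numpy as np
import pytest

from lsfregio.datasets import build_condition_vocabulary
from lsfregio.errors import ConfigError, TrainingError
from lsfregio.model import ModelConfig, init_params, predict_shifts
from lsfregio.synthetic import (SyntheticCorpusConfig, generate_molecules,
                                generate_nmr_corpus, generate_reactions)
from lsfregio.training import (ClassRatios, LossInputs, TrainConfig,
                               bce_loss, bce_weight, classify, finetune_lsf,
                               pretrain_nmr, validate_nmr)


class TestBceLoss:
    def test_single_atom_closed_form(self):
        loss = bce_loss(LossInputs(x=[0.5], y=[1.0], w=[1.0]))
        assert loss == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_prediction_vanishes(self):
        loss = bce_loss(LossInputs(x=[1.0, 0.0], y=[1.0, 0.0],
                                   w=[3.0, 7.0]), eps=1e-12)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_matches_scalar_loop_oracle(self, rng):
        """Vectorized loss equals a naive per-atom summation to 1e-10."""
        for _ in range(20):
            n = int(rng.integers(1, 60))
            x = rng.uniform(0.01, 0.99, n)
            y = rng.integers(0, 2, n).astype(float)
            w = rng.uniform(0, 3, n)
            expected = 0.0
            for xi, yi, wi in zip(x, y, w):
                expected -= wi * (yi * math.log(xi)
                                  + (1 - yi) * math.log(1 - xi))
            got = bce_loss(LossInputs(x=x, y=y, w=w))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_unit_weights_reduce_to_standard_bce(self, rng):
        x = rng.uniform(0.01, 0.99, 40)
        y = rng.integers(0, 2, 40).astype(float)
        standard = float(-np.sum(y * np.log(x) + (1 - y) * np.log(1 - x)))
        got = bce_loss(LossInputs(x=x, y=y, w=np.ones(40)))
        assert got == pytest.approx(standard, abs=1e-10)


def _symbolic_weight(variant, x, y, pred_p, true_p):
    """Symbolic (sympy) evaluation of the printed weight expressions with
    -log magnitudes, independent of the implementation."""
    import sympy as sp
    xs, ys, ps, ts = sp.symbols("x y p t")
    lp, l1p = -sp.log(ps), -sp.log(1 - ps)
    lt, l1t = -sp.log(ts), -sp.log(1 - ts)
    first = (xs * ys * lp + (1 - ys) * (1 - xs) * l1p
             + (1 - ys) * xs * lt + ys * (1 - xs) * l1t)
    second = (ys * xs * lt + (1 - ys) * (1 - xs) * l1t
              + (1 - ys) * xs * l1p + ys * xs * lp)
    expr = {1: first, 2: first + second, 3: 2 * first + second}[variant]
    return float(expr.subs({xs: x, ys: y, ps: pred_p, ts: true_p}))


class TestBceWeights:
    def test_balanced_ratios_symmetric_weights(self):
        """pred_p = true_p = 0.5: correct-positive and correct-negative
        weights coincide (all four log terms equal ln 2)."""
        r = ClassRatios(pred_p=0.5, true_p=0.5)
        w_pos = bce_weight(1, np.array([1.0]), np.array([1.0]), r)
        w_neg = bce_weight(1, np.array([0.0]), np.array([0.0]), r)
        assert w_pos == pytest.approx(w_neg)
        assert w_pos[0] == pytest.approx(math.log(2))

    def test_variant3_minus_variant2_is_first_bracket(self, rng):
        for _ in range(10):
            r = ClassRatios(pred_p=float(rng.uniform(0.05, 0.95)),
                            true_p=float(rng.uniform(0.05, 0.95)))
            x = rng.integers(0, 2, 8).astype(float)
            y = rng.integers(0, 2, 8).astype(float)
            w1 = bce_weight(1, x, y, r)
            w2 = bce_weight(2, x, y, r)
            w3 = bce_weight(3, x, y, r)
            np.testing.assert_allclose(w3 - w2, w1, atol=1e-12)

    @pytest.mark.parametrize("variant", [1, 2, 3])
    @pytest.mark.parametrize("x", [0.0, 1.0])
    @pytest.mark.parametrize("y", [0.0, 1.0])
    def test_truth_table_matches_symbolic_formula(self, variant, x, y):
        """Exhaustive (x, y) truth table against sympy evaluation."""
        pred_p, true_p = 0.3, 0.11
        got = bce_weight(variant, np.array([x]), np.array([y]),
                         ClassRatios(pred_p=pred_p, true_p=true_p))
        want = _symbolic_weight(variant, x, y, pred_p, true_p)
        assert got[0] == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("pred_p", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("true_p", [0.0, 0.5, 1.0])
    def test_finite_at_ratio_extremes(self, pred_p, true_p):
        r = ClassRatios(pred_p=pred_p, true_p=true_p)
        for variant in (1, 2, 3):
            x = np.array([0.0, 1.0, 0.0, 1.0])
            y = np.array([0.0, 0.0, 1.0, 1.0])
            assert np.all(np.isfinite(bce_weight(variant, x, y, r)))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            bce_weight(4, np.array([1.0]), np.array([1.0]),
                       ClassRatios(pred_p=0.5, true_p=0.5))


class TestClassify:
    def test_threshold(self):
        np.testing.assert_array_equal(
            classify(np.array([0.4, 0.6]), tau=0.5), [0.0, 1.0])


@pytest.fixture(scope="module")
def tiny_nmr():
    return generate_nmr_corpus(SyntheticCorpusConfig(
        n_molecules=25, size_range=(8, 16), seed=5))


@pytest.fixture(scope="module")
def tiny_reactions():
    cfg = SyntheticCorpusConfig(n_molecules=25, n_reactions=40,
                                size_range=(8, 16), seed=5)
    mols = generate_molecules(cfg)
    return generate_reactions(mols, cfg)


TINY = dict(hidden=12, rounds=2, batch_size=8, lr=3e-3)


class TestPretrainNmr:
    def test_constant_shifts_learned_to_near_zero_mae(self):
        mols = generate_molecules(SyntheticCorpusConfig(
            n_molecules=12, size_range=(8, 12), seed=2))
        from lsfregio.datasets import NMRRecord
        records = [NMRRecord(graph=g,
                             shifts={i: 100.0 for i in range(g.n_atoms)
                                     if g.elements[i] == "C"})
                   for g in mols]
        params = pretrain_nmr(records, TrainConfig(epochs=10, seed=0,
                                                   **TINY))
        assert validate_nmr(params, records) < 2.0

    def test_seeded_rerun_identical_trajectory(self, tiny_nmr):
        cfg = TrainConfig(epochs=2, seed=4, **TINY)
        a = pretrain_nmr(tiny_nmr, cfg)
        b = pretrain_nmr(tiny_nmr, cfg)
        assert a.history[0]["train_loss"] == b.history[0]["train_loss"]
        for k, t in a.tensors.items():
            assert np.array_equal(t.data, b.tensors[k].data)

    def test_beats_mean_shift_null_predictor(self, tiny_nmr):
        params = pretrain_nmr(tiny_nmr, TrainConfig(epochs=12, seed=0,
                                                    **TINY))
        all_ppm = np.concatenate([list(r.shifts.values())
                                  for r in tiny_nmr])
        null_mae = float(np.mean(np.abs(all_ppm - all_ppm.mean())))
        assert validate_nmr(params, tiny_nmr) < null_mae
        maes = [h["val_mae_ppm"] for h in params.history]
        assert maes[-1] < maes[0]

    def test_empty_input_rejected(self):
        with pytest.raises(TrainingError):
            pretrain_nmr([], TrainConfig())


class TestFinetuneLsf:
    def test_transfer_initializes_trunk_from_checkpoint(self,
                                                        tiny_nmr,
                                                        tiny_reactions):
        pre = pretrain_nmr(tiny_nmr, TrainConfig(epochs=1, seed=0, **TINY))
        vocab = build_condition_vocabulary(tiny_reactions)
        cfg = TrainConfig(epochs=0, seed=1, transfer="transfer", **TINY)
        # epochs=0: returned params are the starting point
        params = finetune_lsf(pre, tiny_reactions, vocab, cfg)
        for key in params.trunk_keys():
            assert np.array_equal(params.tensors[key].data,
                                  pre.tensors[key].data)

    def test_scratch_ignores_init(self, tiny_nmr, tiny_reactions):
        pre = pretrain_nmr(tiny_nmr, TrainConfig(epochs=1, seed=0, **TINY))
        vocab = build_condition_vocabulary(tiny_reactions)
        cfg = TrainConfig(epochs=0, seed=1, transfer="scratch", **TINY)
        params = finetune_lsf(pre, tiny_reactions, vocab, cfg)
        fresh = init_params(cfg.model_config(cond_dim=vocab.length))
        assert np.array_equal(params.tensors["W_in"].data,
                              fresh.tensors["W_in"].data)

    def test_transfer_without_init_rejected(self, tiny_reactions):
        vocab = build_condition_vocabulary(tiny_reactions)
        with pytest.raises(TrainingError):
            finetune_lsf(None, tiny_reactions, vocab,
                         TrainConfig(epochs=1, transfer="transfer", **TINY))

    def test_missing_labels_rejected(self, tiny_reactions):
        vocab = build_condition_vocabulary(tiny_reactions)
        broken = [tiny_reactions[0]]
        broken[0] = type(broken[0])(
            record_id="x", sm=broken[0].sm,
            conditions=broken[0].conditions, products=[], labels=None)
        with pytest.raises(TrainingError):
            finetune_lsf(None, broken, vocab,
                         TrainConfig(epochs=1, transfer="scratch", **TINY))

    def test_seeded_rerun_reproducible(self, tiny_reactions):
        vocab = build_condition_vocabulary(tiny_reactions)
        cfg = TrainConfig(epochs=2, seed=6, transfer="scratch", **TINY)
        a = finetune_lsf(None, tiny_reactions, vocab, cfg)
        b = finetune_lsf(None, tiny_reactions, vocab, cfg)
        for k, t in a.tensors.items():
            assert np.array_equal(t.data, b.tensors[k].data)

    def test_invalid_config_values(self):
        with pytest.raises(ConfigError):
            TrainConfig(loss_variant="w9")
        with pytest.raises(ConfigError):
            TrainConfig(transfer="psychic")
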