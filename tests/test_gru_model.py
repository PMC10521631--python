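"""Residual recurrent predictor: architecture accounting, gradient
correctness, additive decomposition, masking, determinism and training."""

import copy

import numpy as np
import pytest

from ccspred import chem, gru_model
from ccspred import synthetic_data as synth
from ccspred.baseline_model import SqrtFitParams, predict_init
from ccspred.gru_model import (
    CcsModel,
    ModelConfig,
    PredictionError,
    TrainConfig,
    build_model,
    extract_embeddings,
    hand_param_count,
    predict,
    train,
)
from ccspred.io_formats import Dataset, IonRecord

from conftest import split_dataset


def tiny_model(toy_baseline, **kw) -> CcsModel:
    cfg = ModelConfig(
        embedding_dim=kw.pop("embedding_dim", 6),
        gru_units=kw.pop("gru_units", (5, 4)),
        dense_units=kw.pop("dense_units", (7, 3)),
        dropout=kw.pop("dropout", 0.0),
        seed=kw.pop("seed", 3),
        **kw,
    )
    return build_model(baseline=toy_baseline, config=cfg)


class TestArchitecture:
    def test_default_param_count_near_550k(self, toy_baseline):
        model = build_model(baseline=toy_baseline, config=ModelConfig())
        assert abs(model.param_count - 550_000) / 550_000 < 0.05

    def test_param_count_matches_hand_accounting(self, toy_baseline):
        for cfg in (ModelConfig(), ModelConfig(embedding_dim=32, gru_units=(32, 32))):
            model = build_model(baseline=toy_baseline, config=cfg)
            assert model.param_count == hand_param_count(len(model.vocab), cfg)

    def test_oversized_vocab_rejected(self, toy_baseline):
        with pytest.raises(ValueError):
            chem.TokenVocab(("<PAD>",) + tuple(f"t{i}" for i in range(70)))

    def test_zeroed_residual_head_reproduces_baseline(self, toy_baseline):
        model = tiny_model(toy_baseline)
        model.zero_residual()
        ions = Dataset(
            records=[
                IonRecord(sequence=chem.tokenize("PEPTIDEK"), charge=2, mz=500.0, ccs=400.0),
                IonRecord(sequence=chem.tokenize("ACDKR"), charge=3, mz=300.0, ccs=380.0),
            ]
        )
        ccs_final, residual = predict(model, ions)
        assert np.allclose(residual, 0.0)
        expected = [predict_init(500.0, 2, toy_baseline), predict_init(300.0, 3, toy_baseline)]
        assert np.allclose(ccs_final, expected)


class TestGradients:
    def test_backward_matches_finite_differences(self, toy_baseline):
        """Analytic gradients of every layer agree with central differences."""
        model = tiny_model(toy_baseline)
        seqs = [chem.tokenize(s) for s in ("PEPTIDEK", "ACDKR", "S(ph)AMK")]
        charges = np.array([2, 3, 1])

        def loss():
            return float(np.sum(np.sin(model.forward_residual(seqs, charges))))

        res = model.forward_residual(seqs, charges)
        model.zero_grad()
        model.backward(np.cos(res))
        rng = np.random.default_rng(0)
        eps = 1e-6
        for layer in model._layers:
            for key, param in layer.params.items():
                flat = param.ravel()
                grad = layer.grads[key].ravel()
                for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                    old = flat[i]
                    flat[i] = old + eps
                    up = loss()
                    flat[i] = old - eps
                    down = loss()
                    flat[i] = old
                    numeric = (up - down) / (2 * eps)
                    denom = max(1e-6, abs(numeric) + abs(grad[i]))
                    assert abs(numeric - grad[i]) / denom < 1e-4, (key, i)


class TestPredict:
    def test_additive_decomposition_exact(self, trained_reduced):
        model, _, params, _, val_ds, _ = trained_reduced
        ccs_final, residual = predict(model, val_ds)
        base = np.array([predict_init(r.mz, r.charge, params) for r in val_ds.records])
        assert np.allclose(ccs_final - residual, base)

    def test_batch_equals_per_ion(self, toy_baseline):
        model = tiny_model(toy_baseline)
        recs = [
            IonRecord(sequence=chem.tokenize(s), charge=z, mz=m, ccs=400.0)
            for s, z, m in [("PEPTIDEK", 2, 500.0), ("AK", 1, 150.0), ("ACDEFGHIKLMNPQR", 4, 400.0)]
        ]
        batch, _ = predict(model, Dataset(records=recs))
        singles = [predict(model, Dataset(records=[r]))[0][0] for r in recs]
        assert np.allclose(batch, singles, atol=1e-9)

    def test_padding_invariance(self, toy_baseline):
        """Masked recurrence: the residual must not depend on padding length."""
        model = tiny_model(toy_baseline)
        short = chem.tokenize("PEK")
        long = chem.tokenize("ACDEFGHIKLMNPQRSTVWY")
        alone = model.forward_residual([short], np.array([2]))[0]
        padded = model.forward_residual([short, long], np.array([2, 2]))[0]
        assert alone == pytest.approx(padded, abs=1e-10)

    def test_charge_above_max_rejected_with_rows(self, toy_baseline):
        model = tiny_model(toy_baseline)
        recs = [IonRecord(sequence=chem.tokenize("AAK"), charge=5, mz=200.0, ccs=400.0)]
        with pytest.raises(PredictionError, match="charge > 4"):
            predict(model, Dataset(records=recs))


class TestTraining:
    def test_empty_training_set_rejected(self, toy_baseline):
        model = tiny_model(toy_baseline)
        with pytest.raises(ValueError):
            train(model, Dataset(), Dataset(), TrainConfig(max_epochs=1))

    def test_fixed_seed_reproduces_history(self, toy_baseline):
        truth = synth.SyntheticTruth(seed=2)
        ds, _ = synth.generate(truth, 200)
        tr, va = split_dataset(ds, 160, seed=0)
        histories = []
        for _ in range(2):
            model = tiny_model(toy_baseline, gru_units=(8, 8), embedding_dim=8, dropout=0.2)
            _, history = train(model, tr, va, TrainConfig(seed=5, max_epochs=3, batch_size=32))
            histories.append(history)
        assert histories[0] == histories[1]

    def test_baseline_frozen_through_training(self, trained_reduced, synthetic_5k):
        model, _, params, _, _, _ = trained_reduced
        # refit on the same data: identical values => training never touched them
        from ccspred import baseline_model, preprocess

        refit = baseline_model.fit_sqrt(preprocess.deduplicate(synthetic_5k[1]), max_charge=4)
        for c in refit.charges:
            assert model.baseline.w[c] == refit.w[c]
            assert model.baseline.b[c] == refit.b[c]

    def test_learns_token_effect_residuals(self, trained_reduced):
        """Validation MAE must improve on the baseline when residuals carry
        learnable sequence signal."""
        _, history, _, base_val_mae, _, _ = trained_reduced
        best = min(h["val_mae"] for h in history)
        assert best <= 0.5 * base_val_mae

    def test_plateau_schedule_in_history(self, trained_reduced):
        _, history, _, _, _, _ = trained_reduced
        lrs = [h["lr"] for h in history]
        assert lrs[0] == pytest.approx(1e-3)
        if len(set(lrs)) > 1:  # a plateau occurred within the epoch budget
            assert min(lrs) == pytest.approx(1e-4)
            drop = lrs.index(min(lrs))
            best_before = min(h["val_mae"] for h in history[: drop])
            plateau = [h["val_mae"] for h in history[drop - 3 : drop]]
            assert all(v >= best_before for v in plateau)

    def test_returns_best_validation_weights(self, trained_reduced):
        model, history, _, _, val_ds, _ = trained_reduced
        ccs_final, _ = predict(model, val_ds)
        obs = np.array([r.ccs for r in val_ds.records])
        final_mae = float(np.mean(np.abs(ccs_final - obs)))
        best = min(h["val_mae"] for h in history)
        assert final_mae == pytest.approx(best, rel=1e-6)


class TestEmbeddings:
    def test_vector_count_and_dim(self, toy_baseline):
        model = tiny_model(toy_baseline)
        emb = extract_embeddings(model)
        assert len(emb) == len(model.vocab)
        assert all(v.shape == (6,) for v in emb.values())

    def test_same_effect_tokens_more_similar_than_opposite(self, trained_reduced):
        """Tokens with identical generator effects (the three phospho tokens)
        should embed closer to each other than to an opposite-effect token."""
        model, _, _, _, _, truth = trained_reduced
        emb = extract_embeddings(model)

        def cos(a, b):
            return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))

        same = cos(emb["S-ph"], emb["T-ph"])
        opposite = np.mean([cos(emb["S-ph"], emb["W"]), cos(emb["T-ph"], emb["F"])])
        assert same > opposite


class TestSaveLoad:
    def test_roundtrip_preserves_predictions(self, toy_baseline, tmp_path):
        model = tiny_model(toy_baseline)
        recs = [IonRecord(sequence=chem.tokenize("PEPTIDEK"), charge=2, mz=500.0, ccs=400.0)]
        before, _ = predict(model, Dataset(records=recs))
        prefix = str(tmp_path / "model")
        model.save(prefix)
        loaded = CcsModel.load(prefix)
        after, _ = predict(loaded, Dataset(records=recs))
        assert np.allclose(before, after)
        assert loaded.param_count == model.param_count
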