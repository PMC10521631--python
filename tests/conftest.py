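import numpy as np
import pytest

from ccspred import baseline_model, gru_model, preprocess
from ccspred import synthetic_data as synth
from ccspred.io_formats import Dataset


@pytest.fixture(scope="session")
def toy_baseline() -> baseline_model.SqrtFitParams:
    """Hand-set baseline parameters for charges 1-4."""
    return baseline_model.SqrtFitParams(
        w={1: 14.0, 2: 17.0, 3: 21.0, 4: 25.0},
        b={1: 80.0, 2: 40.0, 3: 15.0, 4: 0.0},
        n={c: 2 for c in range(1, 5)},
        mae={c: 0.0 for c in range(1, 5)},
    )


@pytest.fixture(scope="session")
def synthetic_5k():
    """5,000 synthetic ions with token-effect residuals and σ=5 noise."""
    truth = synth.SyntheticTruth(seed=11)
    ds, components = synth.generate(truth, 5000)
    return truth, ds, components


def split_dataset(ds: Dataset, n_train: int, seed: int = 1):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(ds.records))
    train = Dataset(records=[ds.records[i] for i in idx[:n_train]], source_id=ds.source_id)
    val = Dataset(records=[ds.records[i] for i in idx[n_train:]], source_id=ds.source_id)
    return train, val


@pytest.fixture(scope="session")
def trained_reduced(synthetic_5k):
    """Reduced residual model trained once on the 5k synthetic dataset.

    Returns (model, history, baseline params, baseline-only validation MAE,
    validation dataset, generator truth). Shared across tests that probe
    training behaviour so the suite trains only once.
    """
    truth, ds, _ = synthetic_5k
    dedup = preprocess.deduplicate(ds)
    params = baseline_model.fit_sqrt(dedup, max_charge=4)
    train_ds, val_ds = split_dataset(dedup, 4000)

    base_val_mae = float(
        np.mean(
            [
                abs(baseline_model.predict_init(r.mz, r.charge, params) - r.ccs)
                for r in val_ds.records
            ]
        )
    )
    cfg = gru_model.ModelConfig(
        embedding_dim=32, gru_units=(32, 32), dense_units=(128, 64), seed=7
    )
    model = gru_model.build_model(baseline=params, config=cfg)
    tcfg = gru_model.TrainConfig(seed=7, max_epochs=20, batch_size=128)
    model, history = gru_model.train(model, train_ds, val_ds, tcfg)
    return model, history, params, base_val_mae, val_ds, truth
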