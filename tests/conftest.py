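import numpy as np
import pytest

from pathvnn.model import ModelConfig, _Batcher, build_model, predict_indices, split_triplets, train
from pathvnn.synthetic import simulate_preset

# training settings for the desk-scale synthetic runs: the small planted
# model converges with a larger learning rate and far fewer epochs than the
# full-scale reference configuration
FAST_TRAIN = dict(learning_rate=1e-3, epochs=25, batch_size=512)


@pytest.fixture(scope="session")
def tiny_setup():
    return simulate_preset("tiny", seed=0)


@pytest.fixture(scope="session")
def default_setup():
    return simulate_preset("default", seed=1)


def train_default_run(seed: int, epochs: int = FAST_TRAIN["epochs"],
                      shuffle_labels: bool = False):
    """Train one model on the default planted preset; returns everything the
    learning-sanity and interpretability checks need."""
    layout, cohort, feats, trip, truth = simulate_preset("default", seed=seed)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1000)
        trip = trip.assign(auc=rng.permutation(trip["auc"].to_numpy()))
    cfg = ModelConfig(seed=seed, epochs=epochs,
                      learning_rate=FAST_TRAIN["learning_rate"],
                      batch_size=FAST_TRAIN["batch_size"])
    model = build_model(layout, cfg, feats.width)
    model, history = train(model, cohort, feats, trip, cfg)
    _, test_idx, _ = split_triplets(len(trip), cfg.split_fractions,
                                    np.random.default_rng(cfg.seed))
    batcher = _Batcher(cohort, feats, trip)
    preds = predict_indices(model, batcher, test_idx)
    truths = trip["auc"].to_numpy()[test_idx]
    return {
        "layout": layout, "cohort": cohort, "feats": feats,
        "triplets": trip, "truth": truth, "model": model,
        "history": history, "test_preds": preds, "test_truths": truths,
    }


@pytest.fixture(scope="session")
def trained_runs():
    """Three seeded training runs on the default planted preset."""
    return {seed: train_default_run(seed) for seed in (1, 2, 3)}
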