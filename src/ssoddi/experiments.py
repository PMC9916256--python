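"""Reference experiments on the synthetic low-rank interaction data.

These are the package's standard end-to-end study conditions: generate
the default synthetic dataset, draw a balanced positive/unlabeled sample,
hold out 20% of it, tune the MLSTM-AE hyperparameters with sparrow search
on the training portion, retrain, and score the held-out pairs.
Companion routines run the permuted-label null (the same pipeline with
training labels shuffled) and a noise-robustness sweep.
"""

from __future__ import annotations

import numpy as np

from . import mlstm_ae
from .data_synth import SynthSpec, generate_synthetic_dti
from .eval_metrics import aupr, auc_roc, tune_hyperparameters
from .sso import SSOConfig

__all__ = ["tuned_holdout_experiment", "noise_sweep_auc"]


def _balanced_split(y: np.ndarray, rng: np.random.Generator, test_fraction=0.2):
    pos = np.where(y[:, 0] == 1)[0]
    neg = np.where(y[:, 0] == 0)[0]
    neg = rng.choice(neg, size=len(pos), replace=False)
    idx = np.concatenate([pos, neg])
    rng.shuffle(idx)
    n_test = int(round(test_fraction * len(idx)))
    return idx[n_test:], idx[:n_test]


def tuned_holdout_experiment(
    seed: int = 7,
    noise_sd: float = 0.1,
    permute_labels: bool = False,
    np_size: int = 10,
    t_max: int = 20,
    tune_epochs: int = 10,
    final_epochs: int = 60,
    spec: SynthSpec | None = None,
) -> dict:
    """SSO-tuned MLSTM-AE on default synthetic data; held-out AUC/AUPR.

    ``permute_labels=True`` runs the same pipeline with the training
    labels randomly permuted — the negative control whose held-out AUC
    should hover near chance.
    """
    spec = spec or SynthSpec(seed=seed, noise_sd=noise_sd)
    _, X, y, _ = generate_synthetic_dti(spec)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _balanced_split(y, rng)

    y_train = y[train_idx].copy()
    if permute_labels:
        y_train = y_train[rng.permutation(len(y_train))]

    batch = mlstm_ae.SequenceBatch(X[train_idx], y_train)
    tune_seed = int(rng.integers(2**31))
    best_hyper, best_err, trace = tune_hyperparameters(
        batch, seed=tune_seed, np_size=np_size, t_max=t_max, epochs=tune_epochs,
    )
    hyper = dict(best_hyper)
    hyper["epochs"] = final_epochs
    params, _ = mlstm_ae.train(batch, hyper, seed=tune_seed)
    scores = mlstm_ae.predict_scores(params, X[test_idx])[:, 0]
    truth = y[test_idx, 0]
    return {
        "auc": auc_roc(scores, truth),
        "aupr": aupr(scores, truth),
        "best_hyper": best_hyper,
        "tune_error_pct": float(best_err),
        "sso_trace": trace,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
    }


def noise_sweep_auc(
    noise_levels=(0.1, 0.5, 2.0),
    seeds=(7, 8, 9),
    epochs: int = 40,
) -> dict[float, float]:
    """Median held-out AUC of the default model across noise levels.

    Uses the default hyperparameters (no tuning) so the sweep isolates
    the effect of sequence noise on learnability.
    """
    medians = {}
    for noise in noise_levels:
        aucs = []
        for seed in seeds:
            spec = SynthSpec(seed=seed, noise_sd=noise)
            _, X, y, _ = generate_synthetic_dti(spec)
            rng = np.random.default_rng(seed)
            train_idx, test_idx = _balanced_split(y, rng)
            params, _ = mlstm_ae.train(
                mlstm_ae.SequenceBatch(X[train_idx], y[train_idx]),
                {"epochs": epochs}, seed=seed,
            )
            scores = mlstm_ae.predict_scores(params, X[test_idx])[:, 0]
            aucs.append(auc_roc(scores, y[test_idx, 0]))
        medians[noise] = float(np.median(aucs))
    return medians
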