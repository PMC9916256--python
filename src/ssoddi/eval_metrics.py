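"""Positive-unlabeled evaluation: AUC/AUPR, seeded CV, top-k% labeling.

Interaction prediction on bipartite matrices is a positive-unlabeled (PU)
problem: known interactions are positives, everything else is unlabeled.
Evaluation therefore (a) scores held-out positives against negatives
sampled from the unlabeled pairs, reporting ROC-AUC and AUPR per CV seed,
and (b) ranks all unlabeled pairs and counts how many inside the top k%
score above a labeling threshold — the top-k% labeling curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import mlstm_ae
from .data_synth import DTIDataset
from .sso import SSOConfig, optimize

__all__ = [
    "auc_roc",
    "aupr",
    "topk_labeling",
    "cv_evaluate",
    "HyperBox",
    "tune_hyperparameters",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute a ranking metric")


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def topk_labeling(unlabeled_scores, k_percent: float, theta: float = 0.5) -> tuple[int, int]:
    """Count labeled pairs inside the top k% of ranked unlabeled scores.

    Returns ``(n_considered, n_labeled)``: the ``ceil(k/100 * n)``
    top-scoring pairs, and how many of them score at or above ``theta``.
    Ties at the cut are broken by stable input order.
    """
    scores = np.asarray(unlabeled_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must be in (0, 100]")
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    n_considered = ceil(k_percent / 100.0 * scores.size)
    top = scores[np.argsort(-scores, kind="stable")[:n_considered]]
    return n_considered, int((top >= theta).sum())


@dataclass
class HyperBox:
    """Bounded hyperparameter box searched by the sparrow optimizer.

    Dimensions: log10 learning rate, hidden size, batch size, gamma.
    Integer hyperparameters are decoded by rounding; the learning rate
    lives on a log10 scale.
    """

    log10_lr: tuple[float, float] = (-2.5, -1.0)
    hidden: tuple[float, float] = (8, 48)
    batch_size: tuple[float, float] = (16, 96)
    gamma: tuple[float, float] = (0.0, 2.0)

    def bounds(self) -> list[tuple[float, float]]:
        return [self.log10_lr, self.hidden, self.batch_size, self.gamma]

    @staticmethod
    def decode(position: np.ndarray) -> dict:
        return {
            "learning_rate": float(10.0 ** position[0]),
            "hidden": int(round(position[1])),
            "batch_size": int(round(position[2])),
            "gamma": float(position[3]),
        }


def tune_hyperparameters(
    batch: mlstm_ae.SequenceBatch,
    seed: int,
    np_size: int = 10,
    t_max: int = 20,
    box: HyperBox | None = None,
    epochs: int = 15,
    sso_config: SSOConfig | None = None,
) -> tuple[dict, float, np.ndarray]:
    """Tune MLSTM-AE hyperparameters by sparrow search on validation error.

    The fitness is the exact-match classifier error rate (percent) of a
    model trained with the candidate hyperparameters, measured on the
    training run's own validation split at a 0.5 score threshold. Returns
    ``(best_hyper, best_error_pct, trace)``.
    """
    from .sso import fitness_error_rate

    box = box or HyperBox()
    rng = np.random.default_rng(seed)
    train_seed = int(rng.integers(2**31))
    sso_seed = int(rng.integers(2**31))
    # fixed internal validation split, shared by all candidates
    n = batch.n
    perm = np.random.default_rng(train_seed).permutation(n)
    n_val = max(1, int(round(0.2 * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    fit_batch = mlstm_ae.SequenceBatch(batch.x[tr_idx], batch.y[tr_idx])

    def objective(position: np.ndarray) -> float:
        hyper = HyperBox.decode(position)
        hyper["epochs"] = epochs
        params, _ = mlstm_ae.train(fit_batch, hyper, seed=train_seed)
        p = mlstm_ae.predict_scores(params, batch.x[val_idx])
        return fitness_error_rate((p >= 0.5).astype(int), batch.y[val_idx].astype(int))

    cfg = sso_config or SSOConfig(seed=sso_seed)
    best_pos, best_err, trace = optimize(
        objective, box.bounds(), cfg, NP=np_size, t_max=t_max
    )
    return HyperBox.decode(best_pos), best_err, trace


def _balanced_pu_sample(y_pos: np.ndarray, rng: np.random.Generator):
    """Split positives 5-fold and pair each fold with equal-size negatives."""
    pos = np.where(y_pos == 1)[0]
    neg = np.where(y_pos == 0)[0]
    pos = rng.permutation(pos)
    folds = np.array_split(pos, 5)
    neg_perm = rng.permutation(neg)
    out, start = [], 0
    for fold_pos in folds:
        fold_neg = neg_perm[start:start + len(fold_pos)]
        start += len(fold_pos)
        out.append((fold_pos, fold_neg))
    return out


def cv_evaluate(
    sequences: np.ndarray,
    labels: np.ndarray,
    cv_seeds: list[int],
    hyper: dict | None = None,
    dataset_name: str = "synthetic",
    pair_ids: list | None = None,
) -> pd.DataFrame:
    """Seeded cross-validated AUC/AUPR of the MLSTM-AE, as percentages.

    For each CV seed: positives (label bit 0) are split into 5 folds, each
    fold paired with an equal-size negative sample drawn from the
    unlabeled pairs; the model trains on the other folds and is scored on
    the held-out fold. The seed controls fold assignment, negative
    sampling and weight initialization, so rows are deterministic. When
    ``pair_ids`` are given, samples are canonicalized to sorted-id order
    first, making the rows invariant to input pair ordering. One row per
    seed: (dataset, cv_seed, auc, aupr), metrics in percent rounded to 2
    decimals.
    """
    if not cv_seeds:
        raise ValueError("cv_seeds must be non-empty")
    sequences = np.asarray(sequences, dtype=float)
    labels = np.asarray(labels)
    if pair_ids is not None:
        if len(pair_ids) != len(sequences):
            raise ValueError("pair_ids length must match the number of samples")
        order = np.argsort(np.array([str(p) for p in pair_ids]), kind="stable")
        sequences = sequences[order]
        labels = labels[order]
    y_pos = labels[:, 0]
    if y_pos.sum() == 0:
        raise ValueError("dataset has no positive pairs")

    rows = []
    for cv_seed in cv_seeds:
        rng = np.random.default_rng(cv_seed)
        folds = _balanced_pu_sample(y_pos, rng)
        all_scores, all_truth = [], []
        for k, (test_pos, test_neg) in enumerate(folds):
            if len(test_pos) == 0:
                continue
            train_pos = np.concatenate([folds[j][0] for j in range(5) if j != k])
            train_neg = np.concatenate([folds[j][1] for j in range(5) if j != k])
            tr = np.concatenate([train_pos, train_neg])
            te = np.concatenate([test_pos, test_neg])
            params, _ = mlstm_ae.train(
                mlstm_ae.SequenceBatch(sequences[tr], labels[tr]),
                hyper, seed=int(rng.integers(2**31)),
            )
            scores = mlstm_ae.predict_scores(params, sequences[te])[:, 0]
            all_scores.append(scores)
            all_truth.append(y_pos[te])
        scores = np.concatenate(all_scores)
        truth = np.concatenate(all_truth)
        rows.append({
            "dataset": dataset_name,
            "cv_seed": cv_seed,
            "auc": round(auc_roc(scores, truth) * 100.0, 2),
            "aupr": round(aupr(scores, truth) * 100.0, 2),
        })
    return pd.DataFrame(rows)
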