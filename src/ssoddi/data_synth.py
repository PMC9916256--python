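"""Interaction-matrix I/O and a seeded low-rank synthetic data generator.

Real drug-target gold standards (enzyme, GPCR, ion channel, nuclear
receptor) ship as adjacency TSVs with target rows and drug columns.  This
module reads and writes that layout plus an edge-list dialect, and provides
a generator that emulates such data: a bipartite 0/1 interaction matrix
with planted low-rank structure, per-pair fixed-length real-valued
sequences, and multilabel targets, all reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DTIDataset:
    """A bipartite drug-target interaction dataset.

    ``interactions`` is a 0/1 matrix of shape ``(len(targets), len(drugs))``
    — target rows, drug columns, matching the distributed gold-standard
    adjacency layout.
    """

    drugs: list[str]
    targets: list[str]
    interactions: np.ndarray

    def __post_init__(self) -> None:
        self.interactions = np.asarray(self.interactions)
        if self.interactions.shape != (len(self.targets), len(self.drugs)):
            raise ValueError(
                f"interaction matrix shape {self.interactions.shape} does not "
                f"match {len(self.targets)} targets x {len(self.drugs)} drugs"
            )
        if not np.isin(self.interactions, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        self.interactions = self.interactions.astype(np.int8)

    @property
    def n_interactions(self) -> int:
        return int(self.interactions.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DTIDataset):
            return NotImplemented
        return (
            self.drugs == other.drugs
            and self.targets == other.targets
            and np.array_equal(self.interactions, other.interactions)
        )


@dataclass
class SynthSpec:
    """Parameters of the synthetic low-rank interaction generator.

    Defaults are sized for desk-scale experiments: 60 drugs x 40 targets
    at 5% density gives 120 planted interactions, enough for 5-fold CV
    with balanced negative sampling while keeping full hyperparameter
    sweeps to minutes on one CPU.
    """

    n_drugs: int = 60
    n_targets: int = 40
    rank: int = 3
    density: float = 0.05
    noise_sd: float = 0.1
    T: int = 4
    d: int = 8
    C: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.density * self.n_drugs * self.n_targets < 1:
            raise ValueError("density too low: no interaction would be planted")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.T < 2 or self.T % 2:
            raise ValueError("T must be an even integer >= 2")
        if self.C < 1:
            raise ValueError("C must be >= 1")


def read_interaction_matrix(path: str | Path, dialect: str = "adjacency") -> DTIDataset:
    """Read a DTI dataset from an adjacency or edge-list TSV.

    Adjacency dialect: header row of drug ids, first column of target ids,
    0/1 cells.  Edge-list dialect: two columns ``drug_id<TAB>target_id``
    (with header), one row per interaction; the matrix is materialized with
    ids in first-appearance order.
    """
    path = Path(path)
    if dialect == "adjacency":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        drugs = [str(c) for c in df.columns]
        targets = [str(i) for i in df.index]
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in adjacency matrix: {exc}") from exc
        if np.isnan(mat).any():
            r, c = np.argwhere(np.isnan(mat))[0]
            raise ValueError(f"{path}: missing/ragged cell at row {r + 2}, column {c + 2}")
        if not np.isin(mat, (0.0, 1.0)).all():
            r, c = np.argwhere(~np.isin(mat, (0.0, 1.0)))[0]
            raise ValueError(
                f"{path}: non-binary cell value {mat[r, c]!r} at row {r + 2}, column {c + 2}"
            )
        return DTIDataset(drugs, targets, mat.astype(np.int8))
    if dialect == "edge_list":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns) != ["drug_id", "target_id"]:
            raise ValueError(
                f"{path}: edge list must have header 'drug_id\\ttarget_id', got {list(df.columns)}"
            )
        if df.isna().any().any():
            raise ValueError(f"{path}: ragged row in edge list")
        drugs = list(dict.fromkeys(df["drug_id"]))
        targets = list(dict.fromkeys(df["target_id"]))
        mat = np.zeros((len(targets), len(drugs)), dtype=np.int8)
        t_idx = {t: i for i, t in enumerate(targets)}
        d_idx = {d: j for j, d in enumerate(drugs)}
        for d, t in zip(df["drug_id"], df["target_id"]):
            mat[t_idx[t], d_idx[d]] = 1
        return DTIDataset(drugs, targets, mat)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'adjacency' or 'edge_list'")


def write_interaction_matrix(dataset: DTIDataset, path: str | Path, dialect: str = "adjacency") -> None:
    """Write ``dataset`` as a TSV; inverse of :func:`read_interaction_matrix`."""
    path = Path(path)
    if dialect == "adjacency":
        df = pd.DataFrame(dataset.interactions, index=dataset.targets, columns=dataset.drugs)
        df.to_csv(path, sep="\t")
    elif dialect == "edge_list":
        rows = [
            (dataset.drugs[j], dataset.targets[i])
            for j in range(len(dataset.drugs))
            for i in range(len(dataset.targets))
            if dataset.interactions[i, j]
        ]
        pd.DataFrame(rows, columns=["drug_id", "target_id"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'adjacency' or 'edge_list'")


def pair_to_sequence(drug_features: np.ndarray, target_features: np.ndarray, T: int) -> np.ndarray:
    """Tile a (drug, target) feature pair into a ``T x d`` sequence.

    The first ``T/2`` time steps carry the drug vector, the last ``T/2``
    the target vector.  This is the explicit bridge from bipartite pair
    data to the sequence model's input.
    """
    if T < 2 or T % 2:
        raise ValueError("T must be an even integer >= 2")
    drug_features = np.asarray(drug_features, dtype=float)
    target_features = np.asarray(target_features, dtype=float)
    if drug_features.shape != target_features.shape or drug_features.ndim != 1:
        raise ValueError("drug and target feature vectors must be 1-D with equal length")
    half = T // 2
    return np.vstack([np.tile(drug_features, (half, 1)), np.tile(target_features, (half, 1))])


def featurize_dataset(
    dataset: DTIDataset, T: int = 4, d: int = 8, rank: int = 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive per-pair sequences and labels from a real interaction matrix.

    Drug and target feature vectors are the leading ``rank`` singular
    factors of the 0/1 interaction matrix (scaled by sqrt of the singular
    values), pushed through a shared seeded random projection to width
    ``d`` — the same low-rank featurization the synthetic generator
    plants.  Every (target, drug) pair is emitted: sequence via
    :func:`pair_to_sequence`, label row ``[interacts, no-interaction]``.

    Returns ``(sequences N x T x d, labels N x 2, pair_index N x 2)``.
    """
    rng = np.random.default_rng(seed)
    M = dataset.interactions.astype(float)  # targets x drugs
    Ut, s, Vt = np.linalg.svd(M, full_matrices=False)
    r = min(rank, len(s))
    scale = np.sqrt(s[:r])
    target_lat = Ut[:, :r] * scale
    drug_lat = Vt[:r, :].T * scale
    proj = rng.standard_normal((r, d)) / math.sqrt(r)
    drug_feat = drug_lat @ proj
    target_feat = target_lat @ proj

    n_t, n_d = M.shape
    pair_index = np.array([(i, j) for i in range(n_t) for j in range(n_d)], dtype=int)
    X = np.empty((len(pair_index), T, d))
    y = np.zeros((len(pair_index), 2), dtype=np.int8)
    for k, (i, j) in enumerate(pair_index):
        X[k] = pair_to_sequence(drug_feat[j], target_feat[i], T)
        y[k, 0] = dataset.interactions[i, j]
        y[k, 1] = 1 - y[k, 0]
    return X, y, pair_index


def generate_synthetic_dti(
    spec: SynthSpec,
) -> tuple[DTIDataset, np.ndarray, np.ndarray, np.ndarray]:
    """Generate a seeded low-rank DTI dataset with per-pair sequences.

    Latent factors ``U`` (drugs) and ``V`` (targets) are standard-normal
    with ``rank`` columns; the pair affinity is the latent dot product and
    exactly ``ceil(density * n_drugs * n_targets)`` top-affinity pairs
    become interactions.  Each pair is emitted as one sample: its sequence
    is the drug and target latent rows projected to width ``d`` (a shared
    seeded random projection), tiled over the two halves of the sequence
    and perturbed with N(0, noise_sd^2) noise.  Labels are multilabel
    rows of width ``C``: bit 0 marks interaction, bit 1 (when ``C >= 2``)
    is the explicit no-interaction complement so every row has at least
    one active label; any further bits encode latent interaction "types"
    (the sign of the leading latent coordinate product) on positives.

    Returns ``(dataset, sequences, labels, pair_index)`` where
    ``sequences`` is ``N x T x d``, ``labels`` is ``N x C`` and
    ``pair_index`` is ``N x 2`` rows of (target_row, drug_col), with
    ``N = n_drugs * n_targets``.
    """
    rng = np.random.default_rng(spec.seed)
    U = rng.standard_normal((spec.n_drugs, spec.rank))
    V = rng.standard_normal((spec.n_targets, spec.rank))
    proj = rng.standard_normal((spec.rank, spec.d)) / math.sqrt(spec.rank)

    affinity = V @ U.T  # targets x drugs
    n_pos = math.ceil(spec.density * spec.n_drugs * spec.n_targets)
    flat = affinity.ravel()
    order = np.argsort(-flat, kind="stable")
    inter = np.zeros(flat.shape, dtype=np.int8)
    inter[order[:n_pos]] = 1
    inter = inter.reshape(affinity.shape)

    drugs = [f"D{j:04d}" for j in range(spec.n_drugs)]
    targets = [f"T{i:04d}" for i in range(spec.n_targets)]
    dataset = DTIDataset(drugs, targets, inter)

    drug_feat = U @ proj
    target_feat = V @ proj

    pair_index = np.array(
        [(i, j) for i in range(spec.n_targets) for j in range(spec.n_drugs)], dtype=int
    )
    N = len(pair_index)
    X = np.empty((N, spec.T, spec.d))
    y = np.zeros((N, spec.C), dtype=np.int8)
    for k, (i, j) in enumerate(pair_index):
        X[k] = pair_to_sequence(drug_feat[j], target_feat[i], spec.T)
        positive = bool(inter[i, j])
        y[k, 0] = 1 if positive else 0
        if spec.C >= 2:
            y[k, 1] = 0 if positive else 1
        if spec.C >= 3 and positive:
            y[k, 2] = 1 if U[j, 0] * V[i, 0] > 0 else 0
    if spec.noise_sd > 0:
        X += rng.normal(0.0, spec.noise_sd, size=X.shape)
    return dataset, X, y, pair_index
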