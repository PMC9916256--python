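"""Sparrow search optimization (SSO).

A population metaheuristic over a bounded box in R^d, minimizing a scalar
objective. Each iteration splits the population by fitness rank into three
behavioural roles:

* discoverers — the best ``ceil(PD*NP)`` sparrows lead the search: with
  probability tied to a warning value R2 drawn per sparrow, a safe
  discoverer contracts multiplicatively, ``X <- X * exp(-i / (alpha*T))``
  with ``alpha ~ U(0,1]``; an alarmed one (R2 >= ST) takes a random step
  ``X <- X + O*G`` with a standard-normal O and G the all-ones row;
* joiners — the remaining sparrows follow: a poorly ranked joiner
  (rank i > NP/2) jumps to ``O * exp((Xw - X)/i^2)`` elementwise, the rest
  move toward the best position ``Xb + |X - Xb| . B`` with B a row of
  +-1 draws;
* guarders — ``ceil(SD*NP)`` sparrows picked uniformly each iteration
  perform anti-predation moves: a non-best guarder jumps toward the global
  best, ``Xbest + beta*|X - Xbest|``; a guarder already at the best
  fitness steps away from the worst, ``X + K*(X - Xworst)/((f_i - f_w) + eps)``.

Positions are clipped to the box after every move and an elitist archive
tracks the best position ever evaluated, so the reported best fitness is
non-increasing. Every random draw descends from the config seed.

The module also provides the classifier-error fitness used for
hyperparameter tuning: percentage of samples whose predicted multilabel
row differs from the truth (exact-match criterion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SSOConfig",
    "SparrowPopulation",
    "init_population",
    "discoverer_move",
    "joiner_move",
    "guarder_move",
    "update_discoverers",
    "update_joiners",
    "update_guarders",
    "fitness_error_rate",
    "optimize",
]


@dataclass
class SSOConfig:
    """Tuning knobs of the sparrow search optimizer.

    ``st`` is the safety value in (0.5, 1]; ``pd_frac``/``sd_frac`` are
    the discoverer and guarder fractions; ``beta_integer``/``k_integer``
    switch the guarder draws from the continuous defaults
    (beta ~ N(0,1) truncated to [-1,1], K ~ U[-1,1]) to integer draws in
    {-1, 0, 1}, which are degenerate but offered for strict reading of
    the update rules.
    """

    st: float = 0.8
    pd_frac: float = 0.2
    sd_frac: float = 0.2
    epsilon: float = 1e-12
    seed: int = 0
    beta_integer: bool = False
    k_integer: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.st <= 1.0:
            raise ValueError("st must be in (0.5, 1]")
        if not 0 < self.pd_frac < 1 or not 0 < self.sd_frac < 1:
            raise ValueError("pd_frac and sd_frac must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class SparrowPopulation:
    """Positions, fitness values and bounds of one sparrow population."""

    X: np.ndarray          # NP x d positions
    f: np.ndarray          # NP fitness values (np.inf until evaluated)
    lo: np.ndarray         # d lower bounds
    hi: np.ndarray         # d upper bounds
    t: int = 0             # current iteration (1-based during optimize)
    t_max: int = 1         # iteration budget

    @property
    def np_size(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def clip(self) -> None:
        np.clip(self.X, self.lo, self.hi, out=self.X)

    def best_index(self) -> int:
        return int(np.argmin(self.f))

    def worst_index(self) -> int:
        return int(np.argmax(self.f))


def _as_bounds(bounds, d: int) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(bounds, dtype=float)
    if b.shape == (2,):
        b = np.tile(b, (d, 1))
    if b.shape != (d, 2):
        raise ValueError(f"bounds must be (lo, hi) or a {d} x 2 array, got {b.shape}")
    lo, hi = b[:, 0].copy(), b[:, 1].copy()
    if not (lo < hi).all():
        raise ValueError("every dimension needs lo < hi")
    return lo, hi


def init_population(NP: int, d: int, bounds, seed: int, t_max: int = 1) -> SparrowPopulation:
    """Uniformly initialize NP sparrows inside the box; reproducible by seed."""
    if NP < 4:
        raise ValueError("NP must be >= 4 to populate all three roles")
    if d < 1:
        raise ValueError("d must be >= 1")
    lo, hi = _as_bounds(bounds, d)
    rng = np.random.default_rng(seed)
    X = rng.uniform(lo, hi, size=(NP, d))
    return SparrowPopulation(X=X, f=np.full(NP, np.inf), lo=lo, hi=hi, t_max=t_max)


def _ranks(pop: SparrowPopulation) -> np.ndarray:
    """1-based ranks by ascending fitness (best sparrow has rank 1)."""
    order = np.argsort(pop.f, kind="stable")
    ranks = np.empty(pop.np_size, dtype=int)
    ranks[order] = np.arange(1, pop.np_size + 1)
    return ranks


def n_discoverers(pop_size: int, config: SSOConfig) -> int:
    return math.ceil(config.pd_frac * pop_size)


def n_guarders(pop_size: int, config: SSOConfig) -> int:
    return math.ceil(config.sd_frac * pop_size)


def discoverer_move(x: np.ndarray, rank: int, t_max: int, r2: float, st: float,
                    alpha: float, O: float) -> np.ndarray:
    """One discoverer's position update, all random draws passed in.

    Safe branch (r2 < st): multiplicative contraction by
    ``exp(-rank / (alpha * t_max))``. Alarmed branch (r2 >= st): add the
    normal draw O to every dimension (O times the all-ones row G).
    """
    x = np.asarray(x, dtype=float)
    if r2 < st:
        return x * math.exp(-rank / (alpha * t_max))
    return x + O


def joiner_move(x: np.ndarray, rank: int, n: int, x_best: np.ndarray,
                x_worst: np.ndarray, O: float, B: np.ndarray) -> np.ndarray:
    """One joiner's position update, all random draws passed in.

    Rank > n/2 (the hungry half): ``O * exp((Xw - x) / rank^2)``
    elementwise. Otherwise follow the best: ``Xb + |x - Xb| . B`` with B
    a row of +-1 entries.
    """
    x = np.asarray(x, dtype=float)
    if rank > n / 2:
        return O * np.exp((np.asarray(x_worst, dtype=float) - x) / (rank * rank))
    return np.asarray(x_best, dtype=float) + np.abs(x - x_best) * B


def guarder_move(x: np.ndarray, f_i: float, f_best: float, f_worst: float,
                 x_best: np.ndarray, x_worst: np.ndarray, beta: float, K: float,
                 epsilon: float) -> np.ndarray:
    """One guarder's anti-predation update, all random draws passed in.

    f_i > f_best: jump toward the global best, ``Xbest + beta*|x - Xbest|``.
    f_i == f_best: step away from the worst,
    ``x + K*(x - Xworst)/((f_i - f_worst) + epsilon)``.
    """
    x = np.asarray(x, dtype=float)
    if f_i > f_best:
        return np.asarray(x_best, dtype=float) + beta * np.abs(x - x_best)
    if f_i == f_best:
        return x + K * (x - np.asarray(x_worst, dtype=float)) / ((f_i - f_worst) + epsilon)
    return x.copy()


def update_discoverers(pop: SparrowPopulation, config: SSOConfig,
                       rng: np.random.Generator) -> None:
    """Move the best-ranked ceil(PD*NP) sparrows (in place, clipped)."""
    ranks = _ranks(pop)
    nd = n_discoverers(pop.np_size, config)
    for idx in np.where(ranks <= nd)[0]:
        r2 = rng.uniform(0.0, 1.0)
        alpha = 1.0 - rng.uniform(0.0, 1.0)  # U(0, 1]
        O = rng.standard_normal()
        pop.X[idx] = discoverer_move(
            pop.X[idx], int(ranks[idx]), pop.t_max, r2, config.st, alpha, O
        )
    pop.clip()


def update_joiners(pop: SparrowPopulation, config: SSOConfig,
                   rng: np.random.Generator) -> None:
    """Move the non-discoverer sparrows (in place, clipped)."""
    ranks = _ranks(pop)
    nd = n_discoverers(pop.np_size, config)
    Xb = pop.X[pop.best_index()].copy()
    Xw = pop.X[pop.worst_index()].copy()
    for idx in np.where(ranks > nd)[0]:
        O = rng.standard_normal()
        B = rng.choice((-1.0, 1.0), size=pop.dim)
        pop.X[idx] = joiner_move(pop.X[idx], int(ranks[idx]), pop.np_size, Xb, Xw, O, B)
    pop.clip()


def update_guarders(pop: SparrowPopulation, config: SSOConfig,
                    rng: np.random.Generator, guarder_indices: np.ndarray,
                    x_best: np.ndarray, f_best: float) -> None:
    """Anti-predation moves for the randomly chosen guarders (in place).

    ``x_best``/``f_best`` are the global (archived) best position and
    fitness. beta ~ N(0,1) truncated to [-1,1] and K ~ U[-1,1] by
    default; integer draws in {-1,0,1} via the config flags.
    """
    f_w = pop.f[pop.worst_index()]
    Xw = pop.X[pop.worst_index()].copy()
    for idx in guarder_indices:
        if config.beta_integer:
            beta = float(rng.integers(-1, 2))
        else:
            beta = float(np.clip(rng.standard_normal(), -1.0, 1.0))
        if config.k_integer:
            K = float(rng.integers(-1, 2))
        else:
            K = rng.uniform(-1.0, 1.0)
        pop.X[idx] = guarder_move(
            pop.X[idx], float(pop.f[idx]), f_best, float(f_w), x_best, Xw,
            beta, K, config.epsilon,
        )
    pop.clip()


def fitness_error_rate(predicted_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Classifier error rate in percent under the exact-match criterion.

    A sample counts as misclassified if any of its label bits differs.
    """
    predicted_labels = np.asarray(predicted_labels)
    true_labels = np.asarray(true_labels)
    if predicted_labels.shape != true_labels.shape:
        raise ValueError(
            f"shape mismatch: {predicted_labels.shape} vs {true_labels.shape}"
        )
    if predicted_labels.ndim != 2 or predicted_labels.shape[0] == 0:
        raise ValueError("label matrices must be non-empty N x C arrays")
    mis = (predicted_labels != true_labels).any(axis=1)
    return float(mis.sum() / len(mis) * 100.0)


def optimize(objective, bounds, config: SSOConfig, NP: int = 20, t_max: int = 100,
             callback=None):
    """Minimize ``objective`` over the box with sparrow search.

    Returns ``(best_position, best_fitness, trace)`` where ``trace`` is
    the length-``t_max`` array of the archived best fitness after each
    iteration. NaN objective values are treated as +inf with a warning.
    An elitist archive keeps the best position ever evaluated, so the
    trace is monotonically non-increasing. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    b = np.asarray(bounds, dtype=float)
    d = b.shape[0] if b.ndim == 2 else 1
    pop = init_population(NP, d, bounds, seed=int(rng.integers(2**31)), t_max=t_max)

    def safe_eval(x: np.ndarray) -> float:
        val = float(objective(x))
        if math.isnan(val):
            warnings.warn("objective returned NaN; treated as +inf", stacklevel=2)
            return math.inf
        return val

    for k in range(NP):
        pop.f[k] = safe_eval(pop.X[k])

    best_i = pop.best_index()
    x_best = pop.X[best_i].copy()
    f_best = float(pop.f[best_i])

    trace = np.empty(t_max)
    for t in range(1, t_max + 1):
        pop.t = t
        update_discoverers(pop, config, rng)
        update_joiners(pop, config, rng)
        for k in range(NP):
            pop.f[k] = safe_eval(pop.X[k])
        guarders = rng.choice(NP, size=n_guarders(NP, config), replace=False)
        update_guarders(pop, config, rng, guarders, x_best, f_best)
        for k in guarders:
            pop.f[k] = safe_eval(pop.X[k])
        cand = pop.best_index()
        if pop.f[cand] < f_best:
            f_best = float(pop.f[cand])
            x_best = pop.X[cand].copy()
        trace[t - 1] = f_best
        if callback is not None:
            callback(t, x_best, f_best)
    return x_best, f_best, trace
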