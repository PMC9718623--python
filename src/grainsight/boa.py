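"""Improved butterfly optimization for wrapper feature selection.

The butterfly optimization algorithm (BOA) moves a population of candidate
solutions through [0,1]^D.  Each butterfly emits a fragrance
``f = c * I^a`` (sensory modality ``c``, stimulus intensity ``I``, power
exponent ``a``); with probability ``switch_p`` it takes a global step
toward the best-known position, otherwise a local step along the
difference of two random peers.  Here the stimulus intensity is the
inverse of the (minimized) fitness, so better butterflies take bolder
steps.

The "improved" variant hybridizes BOA with the cross-entropy (CE) method:
a Bernoulli distribution over feature subsets is refit each iteration to
the elite fraction of the population (the KL-minimizing per-dimension
bit mean), exponentially smoothed, and fresh subsets sampled from it
replace the worst butterflies — a global search pressure alongside BOA's
swarm moves.  Two integration modes are provided: ``inject`` (default,
CE samples replace the worst butterflies each iteration) and
``replace-global`` (CE sampling substitutes for BOA's global move).

Feature subsets are scored by a wrapper fitness: stratified k-fold
cross-validated error of a 5-nearest-neighbor classifier on the selected
columns, plus a sparsity penalty ``lam * n_selected / D``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "BOAConfig",
    "CEState",
    "Butterfly",
    "SelectionResult",
    "fragrance",
    "global_move",
    "local_move",
    "binarize",
    "fitness",
    "ce_update",
    "run_improved_boa",
    "minimize_continuous",
]

_EPS = 1e-6


@dataclass(frozen=True)
class BOAConfig:
    pop_size: int = 30
    n_iters: int = 200
    sensory_c: float = 0.01
    power_a: float = 0.1
    switch_p: float = 0.8
    bin_thresh: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if not 0 < self.power_a <= 1:
            raise ValueError("power_a must be in (0, 1]")
        if not 0 <= self.switch_p <= 1:
            raise ValueError("switch_p must be in [0, 1]")


@dataclass
class CEState:
    """Bernoulli distribution over feature subsets maintained by CE."""

    a_k: np.ndarray  # per-dimension inclusion probability
    rho: float = 0.1  # elite fraction
    alpha_s: float = 0.7  # smoothing parameter
    gamma: float = np.inf  # current elite fitness threshold
    n_ce: int | None = None  # CE samples per iteration (None -> pop_size)

    @classmethod
    def uniform(cls, dim: int, **kwargs) -> "CEState":
        return cls(a_k=np.full(dim, 0.5), **kwargs)


@dataclass
class Butterfly:
    position: np.ndarray  # in [0,1]^D
    fitness: float = np.inf

    @property
    def fragrance_intensity(self) -> float:
        return 1.0 / (self.fitness + _EPS)


@dataclass
class SelectionResult:
    mask: np.ndarray
    selected_ids: list[str]
    best_fitness_trace: list[float]

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def fragrance(cfg: BOAConfig, stimulus: float) -> float:
    """Perceived fragrance f = c * I^a for stimulus intensity I >= 0."""
    if stimulus < 0:
        raise ValueError("stimulus must be nonnegative")
    return cfg.sensory_c * stimulus**cfg.power_a


def global_move(position: np.ndarray, best: np.ndarray, rn: float, frag: float) -> np.ndarray:
    """Step toward the best-known position: P + (rn^2 * b_p - P) * f."""
    return np.clip(position + (rn**2 * best - position) * frag, 0.0, 1.0)


def local_move(
    position: np.ndarray, peer_k: np.ndarray, peer_l: np.ndarray, rn: float, frag: float
) -> np.ndarray:
    """Step along a random peer difference: P + (rn^2 * P_k - P_l) * f."""
    return np.clip(position + (rn**2 * peer_k - peer_l) * frag, 0.0, 1.0)


def binarize(position: np.ndarray, bin_thresh: float = 0.5) -> np.ndarray:
    """Threshold a position into a subset mask; an empty mask is repaired
    by switching on the single largest-position bit (first index on ties)."""
    mask = (position > bin_thresh).astype(np.int8)
    if mask.sum() == 0:
        mask[int(np.argmax(position))] = 1
    return mask


def _wrapper_folds(labels: np.ndarray, n_folds: int = 3, seed: int = 0, n_repeats: int = 2):
    """Fixed folds for the wrapper: ``n_repeats`` independent stratified
    k-fold partitions.  Averaging the error over two partitions roughly
    halves the variance a subset search could otherwise exploit by
    overfitting one fixed partition."""
    folds = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1000 * r)
        folds.extend(skf.split(np.zeros(len(labels)), labels))
    return folds


def fitness(
    mask: np.ndarray,
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    lam: float = 0.01,
    folds=None,
) -> float:
    """Wrapper fitness: 5-NN stratified-CV error + lam * subset fraction."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask must select at least one feature")
    X = (features.to_numpy() if isinstance(features, pd.DataFrame) else features)[:, mask]
    y = np.asarray(labels)
    folds = folds if folds is not None else _wrapper_folds(y)
    errors = []
    for train_idx, test_idx in folds:
        knn = KNeighborsClassifier(n_neighbors=5)
        knn.fit(X[train_idx], y[train_idx])
        errors.append(np.mean(knn.predict(X[test_idx]) != y[test_idx]))
    return float(np.mean(errors) + lam * mask.sum() / mask.size)


def ce_update(elite_masks: list[np.ndarray], state: CEState) -> CEState:
    """Refit the CE Bernoulli distribution to the elite subset masks.

    a+ is the per-dimension elite bit mean (the KL-minimizing Bernoulli
    MLE); smoothing gives a_{k+1} = alpha_s * a+ + (1 - alpha_s) * a_k,
    clipped to [0.01, 0.99] so sampling never degenerates.  An empty
    elite set leaves the state unchanged.
    """
    if not elite_masks:
        logger.warning("empty elite set; CE state unchanged")
        return state
    a_plus = np.mean([np.asarray(m, dtype=float) for m in elite_masks], axis=0)
    a_next = state.alpha_s * a_plus + (1.0 - state.alpha_s) * state.a_k
    return replace(state, a_k=np.clip(a_next, 0.01, 0.99))


class _CachedFitness:
    """Memoizes the wrapper fitness by mask bytes; subsets recur often."""

    def __init__(self, features, labels, lam, folds):
        self._X = features.to_numpy() if isinstance(features, pd.DataFrame) else features
        self._y = np.asarray(labels)
        self._lam = lam
        self._folds = folds
        self._cache: dict[bytes, float] = {}

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        if key not in self._cache:
            self._cache[key] = fitness(mask, self._X, self._y, self._lam, self._folds)
        return self._cache[key]


def run_improved_boa(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    boa_cfg: BOAConfig | None = None,
    ce_state: CEState | None = None,
    lam: float = 0.01,
    use_ce: bool = True,
    ce_mode: str = "inject",
) -> SelectionResult:
    """BOA + CE wrapper feature selection over the columns of ``features``.

    Per iteration: (i) every butterfly moves (global toward the best
    position with probability ``switch_p``, else local); (ii) positions
    are binarized and scored; (iii) the CE distribution is refit to the
    elite fraction; (iv) in ``inject`` mode, fresh CE subset samples
    replace the worst butterflies; (v) best-ever bookkeeping.  With
    ``use_ce=False`` the loop is canonical BOA.  Fully deterministic for
    a fixed seed/config/data.
    """
    if ce_mode not in ("inject", "replace-global"):
        raise ValueError(f"unknown ce_mode {ce_mode!r}")
    cfg = boa_cfg or BOAConfig()
    column_ids = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"f_{j}" for j in range(np.asarray(features).shape[1])]
    )
    dim = len(column_ids)
    labels = np.asarray(labels)
    folds = _wrapper_folds(labels, seed=cfg.seed)
    score = _CachedFitness(features, labels, lam, folds)
    rng = np.random.default_rng(cfg.seed)
    state = ce_state or CEState.uniform(dim)
    if state.n_ce is None:
        state = replace(state, n_ce=cfg.pop_size)

    swarm = [Butterfly(position=rng.random(dim)) for _ in range(cfg.pop_size)]
    for b in swarm:
        b.fitness = score(binarize(b.position, cfg.bin_thresh))
    best = min(swarm, key=lambda b: b.fitness)
    best_mask = binarize(best.position, cfg.bin_thresh)
    best_fit = best.fitness
    trace = [best_fit]

    for _ in range(cfg.n_iters):
        # (i) swarm moves
        for j, b in enumerate(swarm):
            frag = fragrance(cfg, b.fragrance_intensity)
            rn = rng.random()
            if rng.random() < cfg.switch_p:
                if use_ce and ce_mode == "replace-global":
                    b.position = (rng.random(dim) < state.a_k).astype(float)
                else:
                    b.position = global_move(b.position, best_mask.astype(float), rn, frag)
            else:
                k, l = rng.choice(np.delete(np.arange(cfg.pop_size), j), 2, replace=False)
                b.position = local_move(
                    b.position, swarm[k].position, swarm[l].position, rn, frag
                )
        # (ii) evaluate
        masks = [binarize(b.position, cfg.bin_thresh) for b in swarm]
        for b, m in zip(swarm, masks):
            b.fitness = score(m)
        # (iii) CE refit from the elite fraction
        if use_ce:
            fits = np.array([b.fitness for b in swarm])
            gamma = float(np.quantile(fits, state.rho))
            elites = [m for m, f in zip(masks, fits) if f <= gamma]
            state = replace(ce_update(elites, state), gamma=gamma)
            # (iv) inject fresh CE samples over the worst butterflies
            if ce_mode == "inject":
                order = np.argsort(fits)[::-1]  # worst first
                for idx in order[: state.n_ce]:
                    sample = (rng.random(dim) < state.a_k).astype(np.int8)
                    if sample.sum() == 0:
                        sample[int(np.argmax(state.a_k))] = 1
                    swarm[idx].position = sample.astype(float)
                    swarm[idx].fitness = score(sample)
        # (v) best-ever bookkeeping
        contender = min(swarm, key=lambda b: b.fitness)
        if contender.fitness < best_fit:
            best_fit = contender.fitness
            best_mask = binarize(contender.position, cfg.bin_thresh)
        trace.append(best_fit)

    selected = [cid for cid, bit in zip(column_ids, best_mask) if bit]
    return SelectionResult(mask=best_mask, selected_ids=selected, best_fitness_trace=trace)


def minimize_continuous(
    func, dim: int, cfg: BOAConfig | None = None
) -> tuple[np.ndarray, float, list[float]]:
    """Canonical BOA on a continuous objective over [0,1]^dim (no CE).

    Returns (best position, best fitness, best-ever trace).  Used both as
    a convergence check of the swarm dynamics and as a generic continuous
    optimizer.
    """
    cfg = cfg or BOAConfig()
    rng = np.random.default_rng(cfg.seed)
    swarm = [Butterfly(position=rng.random(dim)) for _ in range(cfg.pop_size)]
    for b in swarm:
        b.fitness = float(func(b.position))
    best = min(swarm, key=lambda b: b.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    trace = [best_fit]
    for _ in range(cfg.n_iters):
        for j, b in enumerate(swarm):
            frag = fragrance(cfg, b.fragrance_intensity)
            rn = rng.random()
            if rng.random() < cfg.switch_p:
                b.position = global_move(b.position, best_pos, rn, frag)
            else:
                k, l = rng.choice(np.delete(np.arange(cfg.pop_size), j), 2, replace=False)
                b.position = local_move(
                    b.position, swarm[k].position, swarm[l].position, rn, frag
                )
            b.fitness = float(func(b.position))
            if b.fitness < best_fit:
                best_fit = b.fitness
                best_pos = b.position.copy()
        trace.append(best_fit)
    return best_pos, best_fit, trace
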