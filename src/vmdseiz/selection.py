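"""Binary grey-wolf optimization (BGWO) over EEG channel subsets.

A pack of wolves carries candidate channel masks. Each iteration the three
fittest wolves (alpha, beta, delta) guide every wolf through the canonical
grey-wolf continuous updates; the averaged leader-guided candidate is pushed
through a steep sigmoid transfer and thresholded against a uniform random
draw per dimension to produce the next binary mask. Fitness is the
stratified cross-validated accuracy of a KNN classifier restricted to the
masked channels, minus a small cardinality penalty. The best mask ever seen
is tracked elitistically and finally coerced to exactly ``target_channels``
channels by greedy add/drop on the same fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix
from .signal_io import ParameterError


@dataclass
class BGWOConfig:
    """Wrapper-selection settings.

    ``knn_k``/``fitness_folds`` control the KNN fitness; ``cardinality_weight``
    is the penalty per unit of |mask|/d discouraging needlessly large subsets;
    ``target_channels`` fixes the final subset size (5 in the seizure
    pipeline).
    """

    pack_size: int = 10
    n_iter: int = 30
    knn_k: int = 5
    fitness_folds: int = 5
    cardinality_weight: float = 0.01
    target_channels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pack_size < 3:
            raise ParameterError("pack_size must be >= 3 (alpha, beta, delta)")
        if self.target_channels < 1:
            raise ParameterError("target_channels must be >= 1")


@dataclass
class SelectionResult:
    """Final channel mask plus the optimization trace."""

    mask: np.ndarray
    history: np.ndarray
    leader_fitness: float
    evaluations: int

    @property
    def selected_channels(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.mask)]


def sigmoid_transfer(x: np.ndarray | float) -> np.ndarray | float:
    """Steep logistic S(x) = 1 / (1 + exp(-10 (x - 0.5))) mapping a
    leader-averaged coordinate into a bit probability."""
    return 1.0 / (1.0 + np.exp(-10.0 * (np.asarray(x, dtype=float) - 0.5)))


def binarize(
    i1: np.ndarray, i2: np.ndarray, i3: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mask bit d is 1 iff S((i1+i2+i3)/3)_d exceeds a fresh Uniform[0,1)
    draw r3_d."""
    i1, i2, i3 = (np.asarray(v, dtype=float) for v in (i1, i2, i3))
    if not (i1.shape == i2.shape == i3.shape):
        raise ParameterError("leader candidate vectors differ in length")
    prob = sigmoid_transfer((i1 + i2 + i3) / 3.0)
    r3 = rng.uniform(0.0, 1.0, size=i1.shape)
    return (prob > r3).astype(int)


def knn_fitness(
    features: FeatureMatrix, mask: np.ndarray, cfg: BGWOConfig
) -> float:
    """Stratified CV accuracy of KNN on the masked channels, penalized by
    subset size; the empty mask scores 0 by convention."""
    mask = np.asarray(mask).astype(int)
    if mask.size != features.n_channels:
        raise ParameterError(
            f"mask length {mask.size} != channel count {features.n_channels}"
        )
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 0.0
    x = features.select_channels(mask)
    model = make_pipeline(
        StandardScaler(), KNeighborsClassifier(n_neighbors=cfg.knn_k)
    )
    cv = StratifiedKFold(
        n_splits=cfg.fitness_folds, shuffle=True, random_state=cfg.seed
    )
    acc = cross_val_score(model, x, features.labels, cv=cv, scoring="accuracy")
    return float(acc.mean() - cfg.cardinality_weight * n_sel / mask.size)


def _coerce_cardinality(
    mask: np.ndarray,
    target: int,
    fitness: "callable",
) -> np.ndarray:
    """Greedy add/drop to exactly ``target`` ones, guided by fitness."""
    mask = mask.copy()
    while mask.sum() > target:
        on = np.flatnonzero(mask)
        best_drop, best_fit = on[0], -np.inf
        for ch in on:
            trial = mask.copy()
            trial[ch] = 0
            f = fitness(trial)
            if f > best_fit:
                best_fit, best_drop = f, ch
        mask[best_drop] = 0
    while mask.sum() < target:
        off = np.flatnonzero(mask == 0)
        best_add, best_fit = off[0], -np.inf
        for ch in off:
            trial = mask.copy()
            trial[ch] = 1
            f = fitness(trial)
            if f > best_fit:
                best_fit, best_add = f, ch
        mask[best_add] = 1
    return mask


def bgwo_select(features: FeatureMatrix, cfg: BGWOConfig) -> SelectionResult:
    """Run BGWO channel selection and return the final mask with its trace.

    The returned mask has exactly ``cfg.target_channels`` ones; the recorded
    ``history`` is the elitist best-so-far fitness per iteration and is
    non-decreasing. Fully deterministic under ``cfg.seed``.
    """
    labels = features.labels
    if np.unique(labels).size < 2:
        raise ParameterError("need at least two classes for wrapper selection")
    d = features.n_channels
    if d < cfg.target_channels:
        raise ParameterError(
            f"channel count {d} < target_channels {cfg.target_channels}"
        )

    cache: dict[bytes, float] = {}
    n_eval = 0

    def fit_of(mask: np.ndarray) -> float:
        nonlocal n_eval
        key = mask.astype(np.int8).tobytes()
        if key not in cache:
            cache[key] = knn_fitness(features, mask, cfg)
            n_eval += 1
        return cache[key]

    if d == cfg.target_channels:
        mask = np.ones(d, dtype=int)
        f = fit_of(mask)
        return SelectionResult(
            mask=mask, history=np.asarray([f]), leader_fitness=f, evaluations=n_eval
        )

    rng = np.random.default_rng(cfg.seed)
    pos = rng.integers(0, 2, size=(cfg.pack_size, d)).astype(float)
    best_mask = None
    best_fit = -np.inf
    history = []

    for it in range(cfg.n_iter):
        fits = np.array([fit_of(pos[w].astype(int)) for w in range(cfg.pack_size)])
        order = np.argsort(fits)[::-1]
        alpha, beta, delta = pos[order[0]], pos[order[1]], pos[order[2]]
        if fits[order[0]] > best_fit:
            best_fit = float(fits[order[0]])
            best_mask = pos[order[0]].astype(int).copy()
        history.append(best_fit)

        a = 2.0 - 2.0 * it / max(cfg.n_iter - 1, 1)  # 2 -> 0 linearly
        new_pos = np.empty_like(pos)
        for w in range(cfg.pack_size):
            cands = []
            for leader in (alpha, beta, delta):
                r1 = rng.uniform(size=d)
                r2 = rng.uniform(size=d)
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                D = np.abs(C * leader - pos[w])
                cands.append(leader - A * D)
            new_bin = binarize(cands[0], cands[1], cands[2], rng)
            new_pos[w] = new_bin
        pos = np.clip(new_pos, 0.0, 1.0)

    fits = np.array([fit_of(pos[w].astype(int)) for w in range(cfg.pack_size)])
    top = int(np.argmax(fits))
    if fits[top] > best_fit:
        best_fit = float(fits[top])
        best_mask = pos[top].astype(int).copy()

    final = _coerce_cardinality(best_mask, cfg.target_channels, fit_of)
    leader_fitness = fit_of(final)
    return SelectionResult(
        mask=final,
        history=np.asarray(history),
        leader_fitness=leader_fitness,
        evaluations=n_eval,
    )
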