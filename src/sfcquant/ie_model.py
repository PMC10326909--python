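"""Guided regularized random-forest regression of log10 response factors.

The model regresses log10 RF (or log10 ionization efficiency) on molecular
and eluent descriptors with a regularized random forest (RRF).  RRF differs
from a plain random forest in one place: the variance-reduction gain of a
candidate split on a feature that has not yet been used anywhere in the
(sequentially grown) ensemble is multiplied by a penalty

    lambda_j = (1 - coef_imp) * coef_reg + coef_imp * imp_j,

where ``coef_reg`` in (0, 1] is the base penalty for entering a new feature,
``coef_imp`` in [0, 1] weights guidance by ``imp_j``, the gain importance of
feature j in a preliminary unregularized forest normalized to max 1 (guided
RRF).  Features already in the used set compete unpenalized, so the ensemble
concentrates on a sparse feature subset.  With ``coef_reg = 1`` and
``coef_imp = 0`` every lambda_j is 1 and the model reduces to an ordinary
random forest.

Cross-validation is rank-stratified: chemicals are sorted by the target and
fold labels are permuted within consecutive blocks, so every fold spans the
whole response-factor distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RRFHyperparams",
    "IEModel",
    "make_folds_rank_stratified",
    "train_rrf",
    "tune_hyperparameters",
    "cross_validated_predictions",
]


@dataclass(frozen=True)
class RRFHyperparams:
    """mtry: features sampled per split; coef_reg: base penalty in (0, 1];
    coef_imp: importance-guidance weight in [0, 1]; n_trees; min_node:
    nodes at or below this size become leaves."""

    mtry: int
    coef_reg: float = 1.0
    coef_imp: float = 0.5
    n_trees: int = 500
    min_node: int = 5

    def __post_init__(self) -> None:
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if not 0 < self.coef_reg <= 1:
            raise ValueError("coef_reg must be in (0, 1]")
        if not 0 <= self.coef_imp <= 1:
            raise ValueError("coef_imp must be in [0, 1]")
        if self.n_trees < 1 or self.min_node < 1:
            raise ValueError("n_trees and min_node must be >= 1")


class _Tree:
    """Array-backed regression tree (feature < 0 marks a leaf)."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def finalize(self) -> None:
        self.feature = np.asarray(self.feature, dtype=np.int64)  # type: ignore[assignment]
        self.threshold = np.asarray(self.threshold, dtype=float)  # type: ignore[assignment]
        self.left = np.asarray(self.left, dtype=np.int64)  # type: ignore[assignment]
        self.right = np.asarray(self.right, dtype=np.int64)  # type: ignore[assignment]
        self.value = np.asarray(self.value, dtype=float)  # type: ignore[assignment]

    def predict(self, X: np.ndarray) -> np.ndarray:
        cur = np.zeros(X.shape[0], dtype=np.int64)
        feat = self.feature
        while True:
            f = feat[cur]
            mask = f >= 0
            if not mask.any():
                break
            idx = np.nonzero(mask)[0]
            nd = cur[idx]
            xv = X[idx, feat[nd]]
            go_left = xv <= self.threshold[nd]
            cur[idx] = np.where(go_left, self.left[nd], self.right[nd])
        return self.value[cur]

    def used_features(self) -> np.ndarray:
        f = np.asarray(self.feature)
        return np.unique(f[f >= 0])


def _best_split(
    X: np.ndarray, y: np.ndarray, feats: np.ndarray, lam: np.ndarray
) -> tuple[int, float, float] | None:
    """Best penalized variance-reduction split over candidate ``feats``.

    Returns (feature, threshold, unpenalized_gain) or None.  ``lam`` holds
    the penalty multiplier per candidate column.
    """
    n = y.size
    Xc = X[:, feats]
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order]
    csum = np.cumsum(ys, axis=0)
    total = csum[-1, :]
    nl = np.arange(1, n, dtype=float)[:, None]
    sl = csum[:-1, :]
    gain = sl**2 / nl + (total - sl) ** 2 / (n - nl) - (total**2) / n
    gain[xs[1:] <= xs[:-1]] = -np.inf  # no split between equal x
    pgain = gain * lam[None, :]
    pgain[~np.isfinite(gain)] = -np.inf
    best = np.max(pgain)
    if not np.isfinite(best) or best <= 1e-12:
        return None
    # bootstrap duplicates make exact gain ties common (several features can
    # induce the same partition); break near-ties by the smallest threshold,
    # an intrinsic key that does not depend on descriptor column order
    rows, cols = np.nonzero(pgain >= best - 1e-9 * abs(best))
    thrs = 0.5 * (xs[rows, cols] + xs[rows + 1, cols])
    pick = int(np.argmin(thrs))
    row, col = int(rows[pick]), int(cols[pick])
    return int(feats[col]), float(thrs[pick]), float(gain[row, col])


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    hyper: RRFHyperparams,
    rng: np.random.Generator,
    used_mask: np.ndarray,
    lam_new: np.ndarray,
    gain_importance: np.ndarray,
) -> _Tree:
    n, p = X.shape
    mtry = min(hyper.mtry, p)
    tree = _Tree()
    root = tree.add_node()
    stack: list[tuple[int, np.ndarray]] = [(root, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        yn = y[idx]
        tree.value[node] = float(yn.mean())
        if idx.size <= hyper.min_node or np.ptp(yn) == 0.0:
            continue
        if mtry < p:
            feats = rng.choice(p, size=mtry, replace=False)
        else:
            feats = np.arange(p)
        lam = np.where(used_mask[feats], 1.0, lam_new[feats])
        split = _best_split(X[idx], yn, feats, lam)
        if split is None:
            continue
        f, thr, gain = split
        go_left = X[idx, f] <= thr
        if not go_left.any() or go_left.all():  # pragma: no cover - guarded by _best_split
            continue
        used_mask[f] = True
        gain_importance[f] += gain
        left = tree.add_node()
        right = tree.add_node()
        tree.feature[node] = f
        tree.threshold[node] = thr
        tree.left[node] = left
        tree.right[node] = right
        stack.append((left, idx[go_left]))
        stack.append((right, idx[~go_left]))
    tree.finalize()
    return tree


@dataclass
class IEModel:
    """A fitted RRF ensemble.

    ``importances`` are out-of-bag permutation importances (mean MSE
    increase); ``used_features`` is the set of descriptor indices selected
    anywhere in the forest.  Predictions are means over trees.
    """

    trees: list[_Tree]
    oob_indices: list[np.ndarray]
    hyper: RRFHyperparams
    used_features: set[int]
    importances: np.ndarray
    gain_importances: np.ndarray
    training_meta: dict = field(default_factory=dict)
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += tree.predict(X)
        return out / len(self.trees)

    def top_features(self, k: int = 10) -> np.ndarray:
        return np.argsort(self.importances)[::-1][:k]


def _permutation_importances(
    trees: list[_Tree],
    oob_indices: list[np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    p = X.shape[1]
    imp = np.zeros(p)
    for tree, oob in zip(trees, oob_indices):
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        for f in tree.used_features():
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            imp[f] += float(np.mean((tree.predict(Xp) - yo) ** 2)) - base
    return imp / len(trees)


def train_rrf(
    X: np.ndarray,
    y: np.ndarray,
    hyper: RRFHyperparams,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    bootstrap: bool = True,
) -> IEModel:
    """Fit the guided regularized random forest.

    When ``coef_imp > 0`` a preliminary unregularized forest is fitted first
    and its gain importances (normalized to max 1) guide the penalty.
    ``bootstrap=False`` trains every tree on the full sample (no out-of-bag
    points, so permutation importances are zero).  Raises ``ValueError`` when
    ``mtry`` exceeds the number of descriptors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("X and y must align")
    if hyper.mtry > p:
        raise ValueError(f"mtry={hyper.mtry} exceeds the {p} available descriptors")
    ss = np.random.SeedSequence([int(seed) % (2**31), 0x5FC])
    rng_pre, rng_main, rng_imp = (np.random.default_rng(s) for s in ss.spawn(3))

    if hyper.coef_imp > 0:
        pre_hyper = RRFHyperparams(
            mtry=hyper.mtry, coef_reg=1.0, coef_imp=0.0,
            n_trees=hyper.n_trees, min_node=hyper.min_node,
        )
        pre = _fit_forest(X, y, pre_hyper, rng_pre, lam_new=np.ones(p), bootstrap=bootstrap)
        imp = pre["gain_importances"]
        imp_norm = imp / imp.max() if imp.max() > 0 else np.zeros(p)
    else:
        imp_norm = np.zeros(p)
    lam_new = (1.0 - hyper.coef_imp) * hyper.coef_reg + hyper.coef_imp * imp_norm

    fit = _fit_forest(X, y, hyper, rng_main, lam_new=lam_new, bootstrap=bootstrap)
    importances = _permutation_importances(fit["trees"], fit["oob"], X, y, rng_imp)
    return IEModel(
        trees=fit["trees"],
        oob_indices=fit["oob"],
        hyper=hyper,
        used_features=set(np.flatnonzero(fit["used_mask"]).tolist()),
        importances=importances,
        gain_importances=fit["gain_importances"],
        training_meta={"seed": int(seed), "n": n, "p": p},
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def _fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    hyper: RRFHyperparams,
    rng: np.random.Generator,
    lam_new: np.ndarray,
    bootstrap: bool = True,
) -> dict:
    n, p = X.shape
    used_mask = np.zeros(p, dtype=bool)
    gain_importance = np.zeros(p)
    trees: list[_Tree] = []
    oob: list[np.ndarray] = []
    all_idx = np.arange(n)
    for _ in range(hyper.n_trees):
        boot = rng.integers(0, n, size=n) if bootstrap else all_idx
        oob.append(np.setdiff1d(all_idx, boot, assume_unique=False))
        trees.append(
            _grow_tree(X[boot], y[boot], hyper, rng, used_mask, lam_new, gain_importance)
        )
    return {"trees": trees, "oob": oob, "used_mask": used_mask, "gain_importances": gain_importance}


def make_folds_rank_stratified(
    values: np.ndarray, k: int = 10, seed: int = 0
) -> np.ndarray:
    """Rank-stratified fold assignment (0-based labels in ``0..k-1``).

    Chemicals are sorted by value; within each consecutive block of ``k``
    ranks the fold labels are a seeded permutation of ``0..k-1`` (partial
    final block gets a random label subset), so every fold spans the whole
    distribution and fold sizes differ by at most one.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < k:
        raise ValueError(f"need at least k={k} chemicals, got {n}")
    rng = np.random.default_rng(int(seed) % (2**31))
    order = np.argsort(values, kind="stable")
    folds = np.empty(n, dtype=np.int64)
    for start in range(0, n, k):
        block = order[start : start + k]
        folds[block] = rng.permutation(k)[: block.size]
    return folds


def cross_validated_predictions(
    X: np.ndarray,
    y: np.ndarray,
    hyper: RRFHyperparams,
    folds: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predictions: each chemical is predicted by the model not
    trained on its fold; every chemical receives exactly one prediction."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = np.asarray(folds)
    preds = np.full(y.shape, np.nan)
    for f in np.unique(folds):
        test = folds == f
        model = train_rrf(X[~test], y[~test], hyper, seed=int(seed) + 1000 * int(f) + 1)
        preds[test] = model.predict(X[test])
    assert not np.isnan(preds).any()
    return preds


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    grid: Iterable[RRFHyperparams],
    seed: int = 0,
    n_folds: int = 2,
    n_repeats: int = 2,
) -> RRFHyperparams:
    """Grid search by repeated rank-stratified cross-validation.

    Scores each grid point by mean validation RMSE over ``n_folds``-fold CV
    repeated ``n_repeats`` times (default two-by-two) and returns the argmin;
    ties break toward the earlier grid point.  Deterministic given ``seed``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fold_sets = [
        make_folds_rank_stratified(y, k=n_folds, seed=int(seed) + 17 * rep)
        for rep in range(n_repeats)
    ]
    best: tuple[float, int] | None = None
    for gi, hyper in enumerate(grid):
        h = hyper
        if h.mtry > X.shape[1]:
            h = RRFHyperparams(X.shape[1], h.coef_reg, h.coef_imp, h.n_trees, h.min_node)
        errs = []
        # same folds and same training seeds for every grid point (paired CV)
        for rep, folds in enumerate(fold_sets):
            preds = cross_validated_predictions(X, y, h, folds, seed=int(seed) + 101 * rep)
            errs.append(float(np.sqrt(np.mean((preds - y) ** 2))))
        score = float(np.mean(errs))
        if best is None or score < best[0]:
            best = (score, gi)
    return grid[best[1]]
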