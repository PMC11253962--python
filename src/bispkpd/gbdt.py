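"""Gradient-boosted regression trees, written from first principles.

Boosting for the squared loss: start from f_0(x) = 0, and at stage m fit a
regression tree T(x; Xi_m) to the current residuals r_i = y_i - f_{m-1}(x_i)
(for squared loss the residual equals the negative loss gradient), then set

    f_m(x) = f_{m-1}(x) + nu * T(x; Xi_m)

with shrinkage nu in (0, 1].  With nu = 1 this is the literal forward
stagewise recursion; the default nu = 0.1 trades stages for generalization.

Trees are grown greedily by variance reduction with midpoint split
candidates between consecutive sorted unique feature values; ties are
broken toward the lowest feature index, then the lowest threshold, so
fitting is deterministic given the input order.

The module also ships a small spectral feature extractor turning a sampled
EEG-like signal into per-epoch band powers, spectral edge frequency and
spectral entropy — the kind of feature matrix a BIS regressor consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .exceptions import ValidationError

__all__ = [
    "RegressionTree",
    "BoostedEnsemble",
    "FeatureMatrix",
    "fit_tree",
    "fit_boosted",
    "predict",
    "eeg_features",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class _Node:
    """Internal split node (feature, threshold, children) or leaf (value)."""

    value: float
    feature: int | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "feature" not in d:
            return cls(value=d["value"])
        return cls(
            value=0.0,
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass(frozen=True)
class RegressionTree:
    """A fitted binary regression tree; every leaf predicts the mean of the
    training targets routed to it."""

    root: _Node
    max_depth: int
    min_samples_leaf: int
    n_features: int

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.n_features)
        out = np.empty(X.shape[0])
        self._fill(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _fill(self, node: _Node, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.value
            return
        go_left = X[idx, node.feature] <= node.threshold
        self._fill(node.left, X, idx[go_left], out)
        self._fill(node.right, X, idx[~go_left], out)

    def depth(self) -> int:
        def walk(node: _Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(walk(node.left), walk(node.right))

        return walk(self.root)

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "n_features": self.n_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            root=_Node.from_dict(d["root"]),
            max_depth=int(d["max_depth"]),
            min_samples_leaf=int(d["min_samples_leaf"]),
            n_features=int(d["n_features"]),
        )


@dataclass(frozen=True)
class BoostedEnsemble:
    """Additive model f(x) = f0 + nu * sum of tree outputs.

    ``train_mse`` records the training MSE after each stage; for nu <= 1 it
    is non-increasing.
    """

    trees: tuple[RegressionTree, ...]
    shrinkage: float
    f0: float
    n_features: int
    train_mse: tuple[float, ...] = ()

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.n_features)
        out = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            out += self.shrinkage * tree.predict(X)
        return out

    def staged_predict(self, X) -> Iterator[np.ndarray]:
        """Predictions after each boosting stage (m = 1..M)."""
        X = _as_matrix(X, self.n_features)
        out = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            out = out + self.shrinkage * tree.predict(X)
            yield out

    def to_dict(self) -> dict:
        return {
            "shrinkage": self.shrinkage,
            "f0": self.f0,
            "n_features": self.n_features,
            "train_mse": list(self.train_mse),
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedEnsemble":
        return cls(
            trees=tuple(RegressionTree.from_dict(t) for t in d["trees"]),
            shrinkage=float(d["shrinkage"]),
            f0=float(d["f0"]),
            n_features=int(d["n_features"]),
            train_mse=tuple(d.get("train_mse", ())),
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Named per-epoch features with an optional aligned target vector."""

    features: pd.DataFrame
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValidationError("feature matrix contains missing values")
        if self.target is not None:
            object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
            if len(self.target) != len(self.features):
                raise ValidationError("features and target differ in row count")

    @property
    def values(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)


def _as_matrix(X, n_features: int | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D matrix")
    if n_features is not None and X.shape[1] != n_features:
        raise ValidationError(
            f"feature-count mismatch: model expects {n_features}, got {X.shape[1]}"
        )
    return X


def _best_split(
    X: np.ndarray, y: np.ndarray, min_samples_leaf: int
) -> tuple[int, float, float] | None:
    """Greedy variance-reduction split.

    Returns (feature, threshold, children_sse) for the split minimizing the
    summed squared error of the two children, or None if no admissible
    candidate exists.  Zero-gain splits are allowed on impure nodes — an
    interaction (e.g. XOR) has no first-level gain yet needs the split.
    Candidates are midpoints between consecutive distinct sorted values; the
    first-best candidate is kept, so exact ties resolve to the lowest
    feature index, then lowest threshold.
    """
    n, d = X.shape
    best: tuple[float, int, float] | None = None
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cut = np.nonzero(np.diff(xs) > 0)[0]  # split after sorted position i
        if cut.size == 0:
            continue
        csum = np.cumsum(ys)
        csq = np.cumsum(ys * ys)
        nl = cut + 1
        nr = n - nl
        ok = (nl >= min_samples_leaf) & (nr >= min_samples_leaf)
        if not np.any(ok):
            continue
        cut, nl, nr = cut[ok], nl[ok], nr[ok]
        sl, sql = csum[cut], csq[cut]
        sse = (sql - sl * sl / nl) + ((csq[-1] - sql) - (csum[-1] - sl) ** 2 / nr)
        i = int(np.argmin(sse))  # argmin keeps the first (lowest threshold) tie
        if best is None or sse[i] < best[0] - _TIE_EPS:
            best = (float(sse[i]), j, 0.5 * (xs[cut[i]] + xs[cut[i] + 1]))
    if best is None:
        return None
    return best[1], best[2], best[0]


def _grow(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int, min_leaf: int) -> _Node:
    if depth >= max_depth or y.size < 2 * min_leaf or np.ptp(y) == 0.0:
        return _Node(value=float(y.mean()))
    split = _best_split(X, y, min_leaf)
    if split is None:
        return _Node(value=float(y.mean()))
    j, thr, _ = split
    mask = X[:, j] <= thr
    return _Node(
        value=float(y.mean()),
        feature=j,
        threshold=thr,
        left=_grow(X[mask], y[mask], depth + 1, max_depth, min_leaf),
        right=_grow(X[~mask], y[~mask], depth + 1, max_depth, min_leaf),
    )


def fit_tree(
    features,
    residuals,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
) -> RegressionTree:
    """Fit one regression tree to residuals by greedy variance reduction."""
    X = _as_matrix(features)
    y = np.asarray(residuals, dtype=float).ravel()
    if X.shape[0] == 0 or y.size == 0:
        raise ValidationError("cannot fit a tree on empty input")
    if X.shape[0] != y.size:
        raise ValidationError("features and residuals differ in length")
    if max_depth < 0 or min_samples_leaf < 1:
        raise ValidationError("max_depth must be >= 0 and min_samples_leaf >= 1")
    root = _grow(X, y, 0, max_depth, min_samples_leaf)
    return RegressionTree(
        root=root, max_depth=max_depth, min_samples_leaf=min_samples_leaf,
        n_features=X.shape[1],
    )


def fit_boosted(
    features,
    targets,
    n_stages: int = 100,
    shrinkage: float = 0.1,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
) -> BoostedEnsemble:
    """Fit an M-stage boosted ensemble to ``targets``.

    The model starts from f0 = 0; each stage fits a tree to the residuals of
    the model so far and adds it with the shrinkage factor.  The staged
    training MSE is recorded on the ensemble.
    """
    if n_stages < 1:
        raise ValidationError("n_stages must be >= 1")
    if not 0 < shrinkage:
        raise ValidationError("shrinkage must be > 0")
    X = _as_matrix(features)
    y = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValidationError("features and targets differ in length")

    f0 = 0.0
    current = np.full(y.size, f0)
    trees: list[RegressionTree] = []
    staged_mse: list[float] = []
    for _ in range(n_stages):
        tree = fit_tree(X, y - current, max_depth=max_depth, min_samples_leaf=min_samples_leaf)
        trees.append(tree)
        current = current + shrinkage * tree.predict(X)
        staged_mse.append(float(np.mean((y - current) ** 2)))
    return BoostedEnsemble(
        trees=tuple(trees),
        shrinkage=shrinkage,
        f0=f0,
        n_features=X.shape[1],
        train_mse=tuple(staged_mse),
    )


def predict(ensemble: BoostedEnsemble, features) -> np.ndarray:
    """Functional alias for :meth:`BoostedEnsemble.predict`."""
    return ensemble.predict(features)


# --- spectral features ------------------------------------------------------

#: EEG frequency bands (Hz): half-open intervals [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


def eeg_features(signal, fs: float, epoch_seconds: float = 2.0) -> FeatureMatrix:
    """Per-epoch spectral features of a sampled signal.

    The signal is cut into non-overlapping epochs of ``epoch_seconds``; for
    each epoch a periodogram P(f) is computed and reduced to: band powers
    (integral of P over each band in :data:`BANDS`), total power, spectral
    edge frequency SEF95 (lowest f below which 95% of total power lies) and
    normalized spectral entropy H = -sum(p log p)/log(N) with p = P/sum(P).
    A silent (all-zero) epoch has zero powers and, by convention, zero
    entropy and zero SEF95.
    """
    if fs <= 0:
        raise ValidationError("sampling rate must be > 0")
    x = np.asarray(signal, dtype=float).ravel()
    n_per = int(round(epoch_seconds * fs))
    if n_per < 2:
        raise ValidationError("epoch too short for a spectrum")
    if x.size < n_per:
        raise ValidationError(
            f"signal ({x.size} samples) shorter than one epoch ({n_per} samples)"
        )
    n_epochs = x.size // n_per
    rows = []
    for e in range(n_epochs):
        seg = x[e * n_per : (e + 1) * n_per]
        f, p = periodogram(seg, fs=fs)
        df = f[1] - f[0]
        total = float(np.sum(p) * df)
        row = {}
        for name, (lo, hi) in BANDS.items():
            band = (f >= lo) & (f < hi)
            row[name] = float(np.sum(p[band]) * df)
        row["total_power"] = total
        if total > 0:
            cum = np.cumsum(p) * df
            row["sef95"] = float(f[np.searchsorted(cum, 0.95 * total)])
            pn = p[p > 0] / np.sum(p)
            row["spectral_entropy"] = float(-np.sum(pn * np.log(pn)) / np.log(p.size))
        else:
            row["sef95"] = 0.0
            row["spectral_entropy"] = 0.0
        rows.append(row)
    return FeatureMatrix(features=pd.DataFrame(rows))
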