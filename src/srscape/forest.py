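"""Bagged regression-tree ensemble for isoscape prediction.

The ensemble is an explicit bagging layer over sklearn decision trees:
each tree is grown on a bootstrap resample (n draws of n, with
replacement) and the per-tree in-bag counts are retained, which the
infinitesimal-jackknife standard errors in :mod:`srscape.uncertainty`
require.  Out-of-bag (OOB) predictions average only the trees for which a
sample was never drawn, giving honest error estimates without a holdout.

Categorical predictors are one-hot encoded before splitting; a category
code never seen in training marks a cell as strict extrapolation (see
:mod:`srscape.mask`) and its prediction is withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import RepeatedKFold
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .grid import PredictorStack, Raster


class IsoscapeForest(RegressorMixin, BaseEstimator):
    """Bagged regression trees with retained in-bag bookkeeping.

    Parameters
    ----------
    n_trees : int
        Ensemble size B.
    mtry : int
        Number of (encoded) predictors sampled at each split.
    min_node_size : int
        Minimal terminal-node size of each tree; the tuning target the
        original random-forest toolchains call "node size".
    categorical : sequence of str, optional
        Names of categorical columns when ``X`` is a DataFrame.
    random_state : int, optional
        Seed; fixed seed gives bit-identical in-bag counts and predictions.

    Attributes
    ----------
    trees_ : list of DecisionTreeRegressor
    inbag_counts_ : ndarray of shape (B, n_train)
        N[b, i] = times sample i was drawn for tree b; each row sums to n.
    oob_prediction_ : ndarray of shape (n_train,)
        NaN for samples that were in-bag for every tree.
    oob_r2_, oob_rmse_ : float
    training_ranges_ : dict
        Per original predictor: (min, max) for continuous, a frozenset of
        seen codes for categorical.  Used for strict-extrapolation masking.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int = 2,
        min_node_size: int = 2,
        categorical=None,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.categorical = categorical
        self.random_state = random_state

    # -- encoding ---------------------------------------------------------

    def _encode_fit(self, X: pd.DataFrame) -> np.ndarray:
        self.categories_ = {}
        for col in self._categorical:
            codes = np.unique(X[col].to_numpy())
            self.categories_[col] = codes[~pd.isna(codes)]
        return self._encode(X)

    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        """One-hot categorical columns against the training categories.

        Unseen codes encode to all-zero dummies; they are flagged
        separately by :meth:`unseen_category_mask`.
        """
        blocks = []
        names = []
        for col in self.predictor_names_:
            v = X[col].to_numpy(dtype=float)
            if col in self._categorical:
                for code in self.categories_[col]:
                    blocks.append((v == code).astype(float))
                    names.append(f"{col}={code:g}")
            else:
                blocks.append(v)
                names.append(col)
        self.encoded_names_ = names
        return np.column_stack(blocks)

    def unseen_category_mask(self, X: pd.DataFrame) -> np.ndarray:
        """True for rows holding a categorical code not seen in training."""
        mask = np.zeros(len(X), dtype=bool)
        for col in self._categorical:
            mask |= ~np.isin(X[col].to_numpy(dtype=float), self.categories_[col])
        return mask

    @property
    def _categorical(self) -> list[str]:
        return list(self.categorical or [])

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != y.size:
            raise ValueError("X and y lengths differ")
        if np.isnan(X.to_numpy(dtype=float)).any():
            raise ValueError("X contains missing values; infill first")
        self.predictor_names_ = list(X.columns)
        self.kinds_ = {
            c: ("categorical" if c in self._categorical else "continuous")
            for c in self.predictor_names_
        }
        Xe = self._encode_fit(X)
        n, p = Xe.shape
        if not (1 <= self.mtry <= p):
            raise ValueError(f"mtry={self.mtry} outside [1, {p}]")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

        self.training_ranges_ = {}
        for col in self.predictor_names_:
            if col in self._categorical:
                self.training_ranges_[col] = frozenset(
                    float(c) for c in self.categories_[col]
                )
            else:
                v = X[col].to_numpy(dtype=float)
                self.training_ranges_[col] = (float(v.min()), float(v.max()))

        rng = np.random.default_rng(self.random_state)
        B = self.n_trees
        self.trees_ = []
        self.inbag_counts_ = np.zeros((B, n), dtype=np.int32)
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n, dtype=int)
        for b in range(B):
            idx = rng.integers(0, n, n)
            self.inbag_counts_[b] = np.bincount(idx, minlength=n)
            tree = DecisionTreeRegressor(
                max_features=self.mtry,
                min_samples_leaf=self.min_node_size,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xe[idx], y[idx])
            self.trees_.append(tree)
            oob = self.inbag_counts_[b] == 0
            if oob.any():
                oob_sum[oob] += tree.predict(Xe[oob])
                oob_cnt[oob] += 1

        with np.errstate(invalid="ignore"):
            self.oob_prediction_ = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
        seen = oob_cnt > 0
        self.n_oob_excluded_ = int(n - seen.sum())
        resid = y[seen] - self.oob_prediction_[seen]
        sse = float(resid @ resid)
        sst = float(((y[seen] - y[seen].mean()) ** 2).sum())
        self.oob_rmse_ = float(np.sqrt(sse / seen.sum()))
        self.oob_r2_ = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
        self.y_train_ = y
        self.y_range_ = (float(y.min()), float(y.max()))
        self.n_features_in_ = len(self.predictor_names_)
        return self

    # -- prediction -------------------------------------------------------

    def _as_encoded(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = pd.DataFrame(X)
        missing = [c for c in self.predictor_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        return self._encode(X)

    def predict(self, X) -> np.ndarray:
        """Ensemble mean prediction (average of per-tree predictions)."""
        return self.predict_trees(X).mean(axis=0)

    def predict_trees(self, X) -> np.ndarray:
        """Per-tree predictions, shape (B, n_points)."""
        Xe = self._as_encoded(X)
        return np.vstack([t.predict(Xe) for t in self.trees_])

    def predict_se(self, X, bias_correction: bool = True) -> np.ndarray:
        """Infinitesimal-jackknife standard error of the bagged prediction."""
        from .uncertainty import ij_variance

        tree_preds = self.predict_trees(X)
        var, _ = ij_variance(self.inbag_counts_, tree_preds, bias_correction=bias_correction)
        return np.sqrt(var)

    def predict_surface(self, stack: PredictorStack) -> Raster:
        """Predict the isoscape mean for every fully-valued, in-domain cell.

        Cells with any missing predictor or an unseen categorical code are
        NaN (the latter are strict extrapolation by definition).
        """
        frame = stack.to_frame()
        ok = ~frame[self.predictor_names_].isna().any(axis=1).to_numpy()
        sub = frame.loc[ok, self.predictor_names_]
        unseen = self.unseen_category_mask(sub)
        out = np.full(frame.shape[0], np.nan)
        idx = np.flatnonzero(ok)[~unseen]
        if idx.size:
            out[idx] = self.predict(sub[~unseen])
        return Raster(out.reshape(stack.spec.shape), stack.spec)


@dataclass
class CVReport:
    """Repeated k-fold cross-validation metrics."""

    fold_r2: list[float]
    fold_rmse: list[float]
    k_folds: int
    repeats: int

    @property
    def r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def rmse(self) -> float:
        return float(np.mean(self.fold_rmse))


def cross_validate(
    X,
    y,
    k_folds: int = 5,
    repeats: int = 10,
    seed: int | None = None,
    **forest_params,
) -> CVReport:
    """Repeated k-fold CV of an :class:`IsoscapeForest`.

    Folds are random partitions (no spatial blocking); each repeat
    reshuffles with a seed derived from ``seed``.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < k_folds:
        raise ValueError(f"n={n} < k_folds={k_folds}")
    splitter = RepeatedKFold(n_splits=k_folds, n_repeats=repeats, random_state=seed)
    fold_r2, fold_rmse = [], []
    base = np.random.SeedSequence(seed)
    for child, (train, test) in zip(base.spawn(k_folds * repeats), splitter.split(X)):
        model = IsoscapeForest(
            random_state=int(child.generate_state(1)[0] % (2**31 - 1)), **forest_params
        )
        model.fit(X.iloc[train], y[train])
        pred = model.predict(X.iloc[test])
        resid = y[test] - pred
        sse = float(resid @ resid)
        sst = float(((y[test] - y[test].mean()) ** 2).sum())
        fold_rmse.append(float(np.sqrt(sse / test.size)))
        fold_r2.append(1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0))
    return CVReport(fold_r2, fold_rmse, k_folds, repeats)


@dataclass
class TuneResult:
    best_mtry: int
    best_min_node_size: int
    oob_rmse: dict = field(default_factory=dict)


def tune(
    X,
    y,
    mtry_grid=(1, 2, 3, 4),
    node_size_grid=(1, 2, 5, 10),
    n_trees: int = 300,
    categorical=None,
    seed: int | None = None,
) -> TuneResult:
    """Grid-search ``(mtry, min_node_size)`` by OOB RMSE.

    Returns the grid point with minimal OOB RMSE; ties broken toward the
    smaller ``mtry``, then the smaller node size.
    """
    if not mtry_grid or not node_size_grid:
        raise ValueError("empty tuning grid")
    X = pd.DataFrame(X)
    results = {}
    best = None
    for mtry in sorted(mtry_grid):
        for node in sorted(node_size_grid):
            model = IsoscapeForest(
                n_trees=n_trees,
                mtry=mtry,
                min_node_size=node,
                categorical=categorical,
                random_state=seed,
            )
            model.fit(X, y)
            results[(mtry, node)] = model.oob_rmse_
            key = (model.oob_rmse_, mtry, node)
            if best is None or key < best:
                best = key
    return TuneResult(best_mtry=best[1], best_min_node_size=best[2], oob_rmse=results)
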