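"""Strict-extrapolation masking and environmental similarity (MOP).

Random-forest isoscapes are unreliable outside the environmental
conditions they were trained on.  Two complementary diagnostics are
provided:

* a *strict* mask removing every cell where at least one predictor falls
  outside its training range (continuous) or holds an unseen code
  (categorical);
* a mobility-oriented parity (MOP) similarity surface: the mean
  Mahalanobis distance from each cell's predictor vector to the nearest
  fraction (default 10 %) of the training cloud.  Larger values mean the
  cell is less like anything the model saw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .grid import PredictorStack, Raster


def strict_mask(stack: PredictorStack, training_ranges: dict) -> Raster:
    """Boolean grid (1.0 = excluded) of strict extrapolation cells.

    A cell is masked iff any predictor is missing, outside its training
    [min, max] (continuous), or an unseen category code (categorical).
    ``training_ranges`` is ``IsoscapeForest.training_ranges_``: name ->
    (min, max) tuple or frozenset of codes.
    """
    masked = np.zeros(stack.spec.shape, dtype=bool)
    for name, rng in training_ranges.items():
        layer = stack.layers[name]
        missing = np.isnan(layer)
        if isinstance(rng, (frozenset, set)):
            codes = np.array(sorted(rng), dtype=float)
            out = ~np.isin(layer, codes)
        else:
            lo, hi = rng
            out = (layer < lo) | (layer > hi)
        masked |= missing | (out & ~missing)
    return Raster(masked.astype(np.float64), stack.spec)


def _one_hot_design(frame: pd.DataFrame, kinds: dict, categories: dict | None = None):
    """Encode a design for Mahalanobis work: categoricals one-hot.

    When ``categories`` is given (training categories per column) the same
    dummy columns are produced for any input; unseen codes encode to zero.
    """
    blocks, cats = [], {}
    for col, kind in kinds.items():
        v = frame[col].to_numpy(dtype=float)
        if kind == "categorical":
            codes = (
                np.asarray(sorted(categories[col]), dtype=float)
                if categories
                else np.unique(v[~np.isnan(v)])
            )
            cats[col] = codes
            for code in codes:
                blocks.append((v == code).astype(float))
        else:
            blocks.append(v)
    return np.column_stack(blocks), cats


def _regularized_precision(X: np.ndarray, condition_limit: float = 1e8):
    """Inverse covariance of the training cloud, shrunk if ill-conditioned.

    Uses a Ledoit-Wolf-style diagonal shrinkage toward the average
    variance when the raw covariance's condition number exceeds
    ``condition_limit`` (one-hot columns are often collinear).
    """
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > condition_limit:
        from sklearn.covariance import ledoit_wolf

        cov, _ = ledoit_wolf(X)
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "training covariance singular even after shrinkage; "
                "drop constant or duplicated predictors"
            )
    return np.linalg.inv(cov)


def mop_similarity(
    stack: PredictorStack,
    training: pd.DataFrame,
    kinds: dict,
    fraction: float = 0.10,
    exclude: Raster | None = None,
    chunk_cells: int = 2048,
) -> Raster:
    """MOP environmental-similarity surface.

    Per cell: Mahalanobis distances (training-cloud covariance) from the
    cell's predictor vector to every training row; the reported value is
    the mean of the smallest ``ceil(fraction * n_train)`` distances.
    Cells under ``exclude`` (e.g. the strict mask) or with missing
    predictors are NaN.
    """
    n = len(training)
    if n < 10:
        raise ValueError("need at least 10 training rows for MOP")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    Xt, cats = _one_hot_design(training[list(kinds)], kinds)
    VI = _regularized_precision(Xt)
    k = int(np.ceil(fraction * n))

    frame = stack.to_frame()
    ok = ~frame[list(kinds)].isna().any(axis=1).to_numpy()
    if exclude is not None:
        ok &= ~(exclude.values.ravel() > 0)
    idx = np.flatnonzero(ok)
    Xc, _ = _one_hot_design(frame.loc[ok, list(kinds)], kinds, categories=cats)
    out = np.full(frame.shape[0], np.nan)
    for start in range(0, idx.size, chunk_cells):
        sl = slice(start, start + chunk_cells)
        d = cdist(Xc[sl], Xt, metric="mahalanobis", VI=VI)
        part = np.partition(d, k - 1, axis=1)[:, :k]
        out[idx[sl]] = part.mean(axis=1)
    return Raster(out.reshape(stack.spec.shape), stack.spec)
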