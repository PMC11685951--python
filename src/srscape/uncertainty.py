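"""Per-cell prediction standard errors via the infinitesimal jackknife.

For a bagged predictor with B trees, per-tree predictions t_b(x) and
in-bag counts N[b, i], the raw IJ variance estimate is

    V_raw(x) = sum_i Cov_b[N[b, i], t_b(x)]^2

with the empirical covariance over trees normalised by 1/B.  Monte-Carlo
noise from finite B inflates V_raw; the bias-corrected estimate subtracts

    (n / B^2) * sum_b (t_b(x) - tbar(x))^2

and is truncated at zero (the correction can overshoot for small B).
"""

from __future__ import annotations

import numpy as np

from .grid import PredictorStack, Raster


def ij_variance(
    inbag_counts: np.ndarray,
    tree_preds: np.ndarray,
    bias_correction: bool = True,
) -> tuple[np.ndarray, int]:
    """Infinitesimal-jackknife variance of bagged predictions.

    Parameters
    ----------
    inbag_counts : ndarray of shape (B, n_train)
    tree_preds : ndarray of shape (B, m) or (B,)
        Per-tree predictions at m query points.

    Returns
    -------
    variance : ndarray of shape (m,)
        Non-negative; truncated at zero where the bias correction
        overshoots.
    n_truncated : int
        Number of query points whose corrected variance was truncated.
    """
    N = np.asarray(inbag_counts, dtype=float)
    T = np.atleast_2d(np.asarray(tree_preds, dtype=float))
    if T.shape[0] != N.shape[0]:
        T = T.T
    B, n = N.shape
    if B < 2:
        raise ValueError("need at least 2 trees for a covariance over trees")
    if T.shape[0] != B:
        raise ValueError("tree_preds and inbag_counts disagree on B")

    Nc = N - N.mean(axis=0, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    cov = Nc.T @ Tc / B  # (n, m): Cov_b[N[:, i], t_b] per query point
    raw = np.einsum("im,im->m", cov, cov)
    if bias_correction:
        correction = (n / B**2) * np.einsum("bm,bm->m", Tc, Tc)
        corrected = raw - correction
    else:
        corrected = raw
    truncated = corrected < 0
    return np.where(truncated, 0.0, corrected), int(truncated.sum())


def se_surface(model, stack: PredictorStack, bias_correction: bool = True, chunk_cells: int = 4096) -> Raster:
    """IJ standard-error surface for every cell the model predicts.

    Cells with missing predictors or unseen categorical codes are NaN,
    mirroring :meth:`IsoscapeForest.predict_surface`.  Work is chunked so
    the (B, m) per-tree prediction block stays small.
    """
    frame = stack.to_frame()
    ok = ~frame[model.predictor_names_].isna().any(axis=1).to_numpy()
    sub = frame.loc[ok, model.predictor_names_]
    unseen = model.unseen_category_mask(sub)
    idx = np.flatnonzero(ok)[~unseen]
    out = np.full(frame.shape[0], np.nan)
    sub = sub[~unseen]
    for start in range(0, idx.size, chunk_cells):
        sl = slice(start, start + chunk_cells)
        tree_preds = model.predict_trees(sub.iloc[sl])
        var, _ = ij_variance(model.inbag_counts_, tree_preds, bias_correction=bias_correction)
        out[idx[sl]] = np.sqrt(var)
    return Raster(out.reshape(stack.spec.shape), stack.spec)
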