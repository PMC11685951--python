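"""Model diagnostics: residuals, spatial correlogram, importance, partial
dependence.

The correlogram tests whether model residuals are spatially
autocorrelated, which would signal proximity effects the predictors do
not explain.  Pair distances are binned into equal-count distance classes
and a Moran-style correlation is computed per class; significance comes
from a permutation null (residuals shuffled over locations), so no
distributional assumptions are made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import haversine_km


@dataclass
class ResidualSummary:
    residuals: np.ndarray
    fraction_within: float
    band: float = 0.002
    n_excluded: int = 0


def residual_summary(model, y, band: float = 0.002) -> ResidualSummary:
    """OOB residuals (y - OOB prediction) and the share within +/- band.

    Samples that were in-bag for every tree have no OOB prediction and are
    excluded with a warning.
    """
    y = np.asarray(y, dtype=float)
    pred = model.oob_prediction_
    seen = ~np.isnan(pred)
    n_excl = int((~seen).sum())
    if n_excl:
        warnings.warn(f"{n_excl} sample(s) with zero OOB trees excluded", stacklevel=2)
    resid = y[seen] - pred[seen]
    frac = float(np.mean(np.abs(resid) <= band)) if resid.size else float("nan")
    return ResidualSummary(resid, frac, band, n_excl)


@dataclass
class Correlogram:
    bin_edges_km: np.ndarray          # (n_bins + 1,)
    correlation: np.ndarray           # per-bin, NaN when undefined
    pair_counts: np.ndarray
    envelope_low: np.ndarray          # 2.5 % permutation percentile
    envelope_high: np.ndarray         # 97.5 % permutation percentile
    low_count_flag: np.ndarray        # bins with < 30 pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_km": self.bin_edges_km[:-1],
                "bin_high_km": self.bin_edges_km[1:],
                "correlation": self.correlation,
                "pairs": self.pair_counts,
                "envelope_low": self.envelope_low,
                "envelope_high": self.envelope_high,
                "low_count": self.low_count_flag,
            }
        )


def _bin_correlations(z: np.ndarray, i_idx, j_idx, bin_id, n_bins, var) -> np.ndarray:
    """Moran-style per-bin correlation: mean over pairs of z_i * z_j / var."""
    prod = z[i_idx] * z[j_idx]
    sums = np.bincount(bin_id, weights=prod, minlength=n_bins)
    counts = np.bincount(bin_id, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts / var
    return out


def correlogram(
    residuals,
    lon,
    lat,
    n_bins: int = 10,
    n_perm: int = 199,
    seed: int | None = None,
) -> Correlogram:
    """Binned spatial correlogram of residuals with a permutation envelope.

    Distances are great-circle km; bins hold equal pair counts.  The
    envelope is the 2.5/97.5 percentile band of the per-bin statistic
    under ``n_perm`` random permutations of residuals over locations.
    All-identical residuals give zero variance and NaN correlations.
    """
    z = np.asarray(residuals, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 points")
    i_idx, j_idx = np.triu_indices(n, k=1)
    d = haversine_km(lat[i_idx], lon[i_idx], lat[j_idx], lon[j_idx])

    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = 0.0, edges[-1] * (1 + 1e-12)
    edges = np.unique(edges)
    n_bins = len(edges) - 1
    bin_id = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(bin_id, minlength=n_bins)

    zc = z - z.mean()
    var = float(zc @ zc) / n
    # all-identical residuals: variance is zero up to rounding of the mean
    degenerate = var <= np.finfo(float).eps * max(1.0, float(np.max(np.abs(z))) ** 2)
    if degenerate:
        nan = np.full(n_bins, np.nan)
        return Correlogram(edges, nan, counts, nan, nan, counts < 30)

    obs = _bin_correlations(zc, i_idx, j_idx, bin_id, n_bins, var)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, n_bins))
    for p in range(n_perm):
        zp = rng.permutation(zc)
        perm_stats[p] = _bin_correlations(zp, i_idx, j_idx, bin_id, n_bins, var)
    low, high = np.percentile(perm_stats, [2.5, 97.5], axis=0)
    return Correlogram(edges, np.clip(obs, -1, 1), counts, low, high, counts < 30)


def importance(
    model,
    X,
    y,
    n_repeats: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """OOB permutation importance, ranked.

    For each original predictor (all of a categorical's codes move
    together) the column is permuted ``n_repeats`` times and the mean
    increase in OOB MSE over the unpermuted baseline is reported.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    oob_trees = model.inbag_counts_ == 0  # (B, n)
    seen = oob_trees.any(axis=0)

    def oob_mse(frame) -> float:
        tree_preds = model.predict_trees(frame)  # (B, n)
        sums = np.where(oob_trees, tree_preds, 0.0).sum(axis=0)
        cnts = oob_trees.sum(axis=0)
        pred = sums[seen] / cnts[seen]
        return float(np.mean((y[seen] - pred) ** 2))

    baseline = oob_mse(X)
    rng = np.random.default_rng(seed)
    rows = []
    for col in model.predictor_names_:
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            deltas.append(oob_mse(Xp) - baseline)
        rows.append((col, float(np.mean(deltas)), float(np.std(deltas))))
    out = pd.DataFrame(rows, columns=["predictor", "mse_increase", "sd"])
    return out.sort_values("mse_increase", ascending=False).reset_index(drop=True)


def partial_dependence(model, X, predictor: str, values) -> pd.DataFrame:
    """Partial-dependence curve: PD(v) = mean prediction with the
    predictor forced to v over all training rows.

    Values outside the training range are computed but flagged.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    values = np.asarray(values, dtype=float)
    rng = model.training_ranges_[predictor]
    if isinstance(rng, (frozenset, set)):
        flagged = ~np.isin(values, np.array(sorted(rng), dtype=float))
    else:
        flagged = (values < rng[0]) | (values > rng[1])
    pd_vals = []
    for v in values:
        Xv = X.copy()
        Xv[predictor] = v
        pd_vals.append(float(model.predict(Xv).mean()))
    return pd.DataFrame(
        {"value": values, "partial_dependence": pd_vals, "outside_training_range": flagged}
    )
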