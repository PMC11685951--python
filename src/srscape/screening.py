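"""Collinearity diagnostics for the predictor set.

Screening is advisory: it reports pairwise Pearson correlations and
variance-inflation factors (VIF) for the continuous predictors so a
modeller can prune a redundant set, but it never drops columns itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DesignMatrix


@dataclass
class ScreenReport:
    """Pearson matrix, per-column VIF and |r|-flagged pairs."""

    pearson: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    r_threshold: float = 0.8

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.pearson.to_csv(directory / "pearson.csv")
        self.vif.rename("vif").to_csv(directory / "vif.csv")
        lines = [f"|r| threshold: {self.r_threshold}"]
        for a, b, r in self.flagged_pairs:
            lines.append(f"flagged: {a} ~ {b}  r={r:+.4f}")
        if not self.flagged_pairs:
            lines.append("no pairs flagged")
        (directory / "summary.txt").write_text("\n".join(lines) + "\n")


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF_j = 1 / (1 - R^2_j), column j regressed (with intercept) on the
    rest; +inf when the fit is exact (rank deficiency)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return float("inf")  # constant column: undefined, reported as inf
    r2 = 1.0 - float(resid @ resid) / sst
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def screen(design: DesignMatrix, r_threshold: float = 0.8) -> ScreenReport:
    """Correlation/VIF screen over the continuous predictor columns.

    Categorical columns are excluded.  With a single continuous column the
    Pearson matrix is [[1]] and the VIF table is empty (undefined).
    """
    cols = design.continuous_columns
    if not cols:
        raise ValueError("no continuous columns to screen")
    frame = design.frame[cols]
    pearson = frame.corr(method="pearson")
    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(pearson.loc[a, b])
            if abs(r) > r_threshold:
                flagged.append((a, b, r))
    if len(cols) < 2:
        vif = pd.Series(dtype=float)
    else:
        X = frame.to_numpy(dtype=float)
        vif = pd.Series({c: _vif_one(X, j) for j, c in enumerate(cols)})
    return ScreenReport(pearson, vif, flagged, r_threshold)
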