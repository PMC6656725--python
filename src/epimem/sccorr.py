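"""Single-cell fluorescence correlation: Kendall tau-b and comparison of two
independent correlations via the Fisher Z transformation.

Flow-cytometry intensities are digitized and tie-heavy, so the
tie-corrected tau-b is used throughout. Two groups' taus are compared with
z_i = atanh(tau_i) and Fieller's variance 0.437/(n_i - 4) for the Fisher-z
of a Kendall coefficient (the Pearson-style 1/(n - 3) is available for
sensitivity analyses); the difference is referred to a standard normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CellMatrix",
    "CorrelationComparison",
    "load_cell_matrix",
    "kendall_tau",
    "compare_correlations",
    "loess_trend",
]


@dataclass
class CellMatrix:
    cell_ids: list
    marker_ids: list
    intensities: np.ndarray  # cells x markers
    transform: str = "raw"  # raw | arcsinh

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.cell_ids), len(self.marker_ids)):
            raise ValueError("intensity shape does not match ids")
        if np.isnan(self.intensities).any():
            raise ValueError("intensities contain missing values after load")

    def marker(self, marker_id: str) -> np.ndarray:
        return self.intensities[:, self.marker_ids.index(marker_id)]


@dataclass(frozen=True)
class CorrelationComparison:
    tau_1: float
    tau_2: float
    n_1: int
    n_2: int
    z: float
    p: float


def load_cell_matrix(
    path: str | Path, group: str | None = None, arcsinh_cofactor: float | None = None
) -> CellMatrix:
    """Load a cell x marker TSV (cell_id, optional group column, markers).

    Rows with missing values are dropped with a log message. When
    ``group`` is given the table is filtered to that group first.
    """
    df = pd.read_csv(path, sep="\t")
    if group is not None:
        if "group" not in df.columns:
            raise ValueError("TSV has no 'group' column")
        df = df[df["group"] == group]
    meta_cols = [c for c in ("cell_id", "group") if c in df.columns]
    markers = [c for c in df.columns if c not in meta_cols]
    before = len(df)
    df = df.dropna(subset=markers)
    if len(df) < before:
        logger.info("dropped %d cells with missing intensities", before - len(df))
    intensities = df[markers].to_numpy(dtype=float)
    transform = "raw"
    if arcsinh_cofactor is not None:
        intensities = np.arcsinh(intensities / arcsinh_cofactor)
        transform = "arcsinh"
    cell_ids = list(df["cell_id"]) if "cell_id" in df.columns else list(range(len(df)))
    return CellMatrix(cell_ids, markers, intensities, transform)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected rank correlation).

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with C/D the concordant and
    discordant pair counts, n0 = n(n-1)/2 and n1/n2 the tie terms of x/y.
    Undefined (error) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need n >= 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined for an all-tied vector")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


def compare_correlations(
    tau_1: float,
    n_1: int,
    tau_2: float,
    n_2: int,
    variance: str = "fieller",
) -> CorrelationComparison:
    """Fisher-Z comparison of two independent Kendall correlations.

    z_i = atanh(tau_i); SE_i^2 = 0.437/(n_i - 4) (Fieller) or 1/(n_i - 3)
    (Pearson-style); z = (z_1 - z_2)/sqrt(SE_1^2 + SE_2^2) with a
    two-sided normal p. Antisymmetric under swapping groups.
    """
    for tau in (tau_1, tau_2):
        if abs(tau) >= 1:
            raise ValueError("|tau| must be < 1 (atanh diverges at 1)")
    if n_1 < 10 or n_2 < 10:
        raise ValueError("need n >= 10 per group")
    if variance == "fieller":
        v1, v2 = 0.437 / (n_1 - 4), 0.437 / (n_2 - 4)
    elif variance == "pearson":
        v1, v2 = 1.0 / (n_1 - 3), 1.0 / (n_2 - 3)
    else:
        raise ValueError("variance must be 'fieller' or 'pearson'")
    z = (math.atanh(tau_1) - math.atanh(tau_2)) / math.sqrt(v1 + v2)
    # floor keeps p in (0, 1] when the normal tail underflows at large |z|
    p = min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324))
    return CorrelationComparison(tau_1, tau_2, n_1, n_2, z, p)


def loess_trend(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Local linear (LOESS degree-1) trend with a pointwise SE band.

    At each grid point the span-nearest fraction of the data is fit by
    weighted least squares with tricube weights; the standard error is the
    usual WLS linear-smoother form with a residual-variance estimate from
    the local fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 20:
        raise ValueError("need paired vectors with n >= 20")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    k = max(2, int(math.ceil(span * len(x))))
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = np.empty(n_grid)
    se = np.empty(n_grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        mask = w > 0
        X = np.column_stack([np.ones(mask.sum()), x[mask] - x0])
        W = w[mask]
        A = X.T @ (W[:, None] * X)
        bvec = X.T @ (W * y[mask])
        coef, *_ = np.linalg.lstsq(A, bvec, rcond=None)
        fitted[i] = coef[0]
        # linear-smoother weights l(x0) = e1' (X'WX)^-1 X'W
        try:
            Ainv = np.linalg.pinv(A)
            l = (Ainv @ (X.T * W))[0]
            resid = y[mask] - X @ coef
            dof = max(1.0, W.sum() - 2.0)
            sigma2 = float((W * resid**2).sum() / dof)
            se[i] = math.sqrt(sigma2 * float((l**2).sum()))
        except np.linalg.LinAlgError:
            se[i] = np.nan
    return pd.DataFrame({"x": grid, "fit": fitted, "se": se})
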