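"""Canonical correlation between bioavailability and clinical severity scores.

The analysis asks whether a single breath-derived quantity (ln AUC, a proxy
of systemic bioavailability) carries the same information as a block of
clinical severity scores (MELD, FIB4, APRI).  CCA finds unit-variance linear
combinations of the two blocks with maximal correlation; canonical loadings
(correlations of each original variable with its canonical variate) say which
variables carry the association.  Significance of the first dimension uses
Bartlett's chi-square approximation to Wilks' lambda (Rao's F available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidInputError

__all__ = ["CCAResult", "canonical_correlation", "cca_scores"]


@dataclass(frozen=True)
class CCAResult:
    canonical_correlations: np.ndarray  # descending, in [0, 1]
    x_loadings: pd.DataFrame            # variables x dimensions
    y_loadings: pd.DataFrame
    x_weights: np.ndarray               # standardized-scale projection weights
    y_weights: np.ndarray
    wilks_lambda: float
    bartlett_chi2: float
    df: int
    p_value: float                      # first-dimension sequential test
    n_complete: int
    x_columns: tuple[str, ...]
    y_columns: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    p_value_rao: float

    @property
    def first_correlation(self) -> float:
        return float(self.canonical_correlations[0])


def _as_matrix(block, default_prefix: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(float), [str(c) for c in block.columns]
    arr = np.asarray(block, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{default_prefix}{i}" for i in range(arr.shape[1])]


def canonical_correlation(x_block, y_block) -> CCAResult:
    """CCA of two blocks measured on the same samples (complete cases only).

    Rows with any missing value in either block are dropped and counted via
    ``n_complete``.  Columns are standardized; the correlations are the
    singular values of Qx' Qy from QR decompositions of the centred blocks
    (numerically equivalent to the eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx).  Sign convention: each dimension is flipped so
    the y variable with the largest |loading| loads positively.
    """
    X, xcols = _as_matrix(x_block, "x")
    Y, ycols = _as_matrix(y_block, "y")
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("blocks must have the same number of rows")
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    X, Y = X[ok], Y[ok]
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q + 1:
        raise InvalidInputError(
            f"need n > p + q + 1 complete cases, have n={n}, p={p}, q={q}")

    def standardize(M, cols):
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        for j, s in enumerate(sd):
            if s <= 0 or not np.isfinite(s):
                raise DegenerateDataError(f"column '{cols[j]}' is constant")
        return (M - mu) / sd, mu, sd

    Xs, xmu, xsd = standardize(X, xcols)
    Ys, ymu, ysd = standardize(Y, ycols)

    Qx, Rx = np.linalg.qr(Xs)
    Qy, Ry = np.linalg.qr(Ys)
    for R, cols in ((Rx, xcols), (Ry, ycols)):
        small = np.abs(np.diag(R)) < 1e-10 * math.sqrt(n)
        if small.any():
            raise DegenerateDataError(
                f"column '{cols[int(np.flatnonzero(small)[0])]}' is collinear")

    U, svals, Vt = np.linalg.svd(Qx.T @ Qy)
    m = min(p, q)
    r = np.clip(svals[:m], 0.0, 1.0)

    # weights on the standardized scale, scaled so variates have unit variance
    Wx = np.linalg.solve(Rx, U[:, :m]) * math.sqrt(n - 1)
    Wy = np.linalg.solve(Ry, Vt.T[:, :m]) * math.sqrt(n - 1)
    scores_x = Xs @ Wx
    scores_y = Ys @ Wy

    # sign convention: dominant y loading positive; flip both blocks together
    y_load = _corr_columns(Ys, scores_y)
    for d in range(m):
        jmax = int(np.argmax(np.abs(y_load[:, d])))
        if y_load[jmax, d] < 0:
            Wx[:, d] *= -1
            Wy[:, d] *= -1
            scores_x[:, d] *= -1
            scores_y[:, d] *= -1
    x_load = _corr_columns(Xs, scores_x)
    y_load = _corr_columns(Ys, scores_y)

    lam = float(np.prod(1.0 - r ** 2))
    chi2 = -(n - 1 - (p + q + 1) / 2.0) * math.log(max(lam, 1e-300))
    df = p * q
    p_val = float(sps.chi2.sf(chi2, df))

    # Rao's F approximation for the same first-dimension test
    s = math.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
    w = n - 1 - (p + q + 1) / 2.0
    df2 = w * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f_stat = (1.0 - lam_s) / lam_s * df2 / df
    p_rao = float(sps.f.sf(f_stat, df, df2)) if df2 > 0 else float("nan")

    dims = [f"dim{i+1}" for i in range(m)]
    return CCAResult(
        canonical_correlations=r,
        x_loadings=pd.DataFrame(x_load, index=xcols, columns=dims),
        y_loadings=pd.DataFrame(y_load, index=ycols, columns=dims),
        x_weights=Wx, y_weights=Wy,
        wilks_lambda=lam, bartlett_chi2=float(chi2), df=df, p_value=p_val,
        n_complete=int(n), x_columns=tuple(xcols), y_columns=tuple(ycols),
        x_mean=xmu, x_sd=xsd, y_mean=ymu, y_sd=ysd,
        p_value_rao=p_rao,
    )


def _corr_columns(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """corr(block[:, j], scores[:, d]) for all j, d."""
    n = block.shape[0]
    bz = (block - block.mean(axis=0)) / block.std(axis=0, ddof=0)
    sz = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
    return bz.T @ sz / n


def cca_scores(result: CCAResult, x_block, y_block) -> pd.DataFrame:
    """First canonical variate pair for each (complete) sample.

    Projections use the fitted standardization and weights, so on the
    training data corr(score_x, score_y) equals the first canonical
    correlation.
    """
    X, _ = _as_matrix(x_block, "x")
    Y, _ = _as_matrix(y_block, "y")
    if X.shape[1] != len(result.x_columns) or Y.shape[1] != len(result.y_columns):
        raise InvalidInputError("block dimensions do not match the fitted result")
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    Xs = (X[ok] - result.x_mean) / result.x_sd
    Ys = (Y[ok] - result.y_mean) / result.y_sd
    return pd.DataFrame({
        "score_x": Xs @ result.x_weights[:, 0],
        "score_y": Ys @ result.y_weights[:, 0],
    })
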