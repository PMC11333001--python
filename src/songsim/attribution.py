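"""Multiple regression on distance matrices (MRM) for feature attribution.

Which acoustic measures explain an embedding's pairwise distances?  Each
z-scored summary measure (or group of measures) yields a predictor
distance matrix; the vectorised lower triangle of the response matrix is
regressed on the predictors' lower triangles by ordinary least squares
(all vectors z-scored, so coefficients are standardised), and inference
uses the permutation scheme in which rows and columns of the response
matrix are permuted jointly while the predictors stay fixed.

Three groupings mirror the three analyses the package supports: all 26
individual measures; 6 grouped features (Euclidean over each feature's 5
summary statistics, plus syllable length); and 3 grouped statistics
(mean / start / end pooled across features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import SUMMARY_FEATURES
from .dtw import DissimilarityMatrix

__all__ = ["MRMResult", "build_predictor_matrices", "mrm"]


@dataclass
class MRMResult:
    coefficients: pd.Series  # standardised coefficient per predictor
    r_squared: float
    p_values: pd.Series  # permutation p per coefficient
    model_p: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")
        self.r_squared = min(self.r_squared, 1.0)
        if np.any(self.p_values <= 0) or np.any(self.p_values > 1):
            raise ValueError("p-values must lie in (0, 1]")


def build_predictor_matrices(
    stats: pd.DataFrame, grouping: str = "per_measure"
) -> dict[str, np.ndarray]:
    """Predictor distance matrices from per-syllable summary statistics.

    ``stats`` is indexed by syllable id with the 26 summary-measure
    columns.  Measures are z-scored first; zero-variance measures are
    excluded with a warning.  Groupings: ``per_measure`` gives one
    absolute-difference matrix per measure (26); ``per_feature`` gives the
    Euclidean distance over each feature's five statistics plus syllable
    length (6); ``per_statistic`` pools each of mean/start/end across the
    five features (3).
    """
    if len(stats) < 3:
        raise ValueError("need at least 3 syllables")
    z = stats.copy().astype(np.float64)
    dropped = []
    for col in list(z.columns):
        sd = z[col].std(ddof=0)
        if sd < 1e-12:
            dropped.append(col)
            z = z.drop(columns=col)
        else:
            z[col] = (z[col] - z[col].mean()) / sd
    if dropped:
        warnings.warn(f"zero-variance measures excluded: {dropped}")

    def euclid(cols: list[str]) -> np.ndarray:
        x = z[cols].to_numpy()
        return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1))

    out: dict[str, np.ndarray] = {}
    if grouping == "per_measure":
        for col in z.columns:
            x = z[col].to_numpy()
            out[col] = np.abs(x[:, None] - x[None, :])
    elif grouping == "per_feature":
        for feat in SUMMARY_FEATURES:
            cols = [c for c in z.columns if c.startswith(feat + "_")]
            if cols:
                out[feat] = euclid(cols)
        if "syllable_length" in z.columns:
            out["syllable_length"] = euclid(["syllable_length"])
    elif grouping == "per_statistic":
        for stat in ("mean", "start", "end"):
            cols = [f"{f}_{stat}" for f in SUMMARY_FEATURES
                    if f"{f}_{stat}" in z.columns]
            if cols:
                out[stat] = euclid(cols)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return out


def _lower(v: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(v.shape[0], k=-1)
    return v[i, j]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 1e-15 else 1.0)


def mrm(
    response: DissimilarityMatrix | np.ndarray,
    predictors: dict[str, np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
) -> MRMResult:
    """MRM: OLS of the response distances on predictor distances.

    Lower triangles (diagonal excluded) are vectorised and z-scored, so
    reported coefficients are standardised.  The null distribution
    permutes the rows and columns of the response matrix jointly
    ``n_perm`` times; two-sided coefficient p-values and the model-level
    R^2 p-value use the plus-one correction, so the smallest attainable p
    is ``1 / (n_perm + 1)``.
    """
    r_mat = response.values if isinstance(response, DissimilarityMatrix) else response
    r_mat = np.asarray(r_mat, dtype=np.float64)
    n = r_mat.shape[0]
    if r_mat.shape != (n, n):
        raise ValueError("response must be square")
    for name, p in predictors.items():
        if np.asarray(p).shape != (n, n):
            raise ValueError(f"predictor {name!r} shape mismatch")
    names = list(predictors)
    x_cols = [_zscore(_lower(np.asarray(predictors[k], dtype=np.float64)))
              for k in names]
    x = np.column_stack([np.ones(x_cols[0].size), *x_cols])
    xtx = x.T @ x
    cond = np.linalg.cond(xtx)
    if cond > 1e10:
        warnings.warn(f"collinear predictors (condition number {cond:.2e}); "
                      "using pseudo-inverse")
    pinv = np.linalg.pinv(x)

    def fit(y: np.ndarray) -> tuple[np.ndarray, float]:
        beta = pinv @ y
        resid = y - x @ beta
        sst = float((y**2).sum())  # y is z-scored: mean 0
        r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
        return beta[1:], max(0.0, min(1.0, r2))

    y_obs = _zscore(_lower(r_mat))
    beta_obs, r2_obs = fit(y_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    exceed_r2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = _zscore(_lower(r_mat[np.ix_(perm, perm)]))
        beta_p, r2_p = fit(y_perm)
        exceed += np.abs(beta_p) >= np.abs(beta_obs)
        exceed_r2 += r2_p >= r2_obs
    p_coef = (1.0 + exceed) / (n_perm + 1.0)
    p_model = (1.0 + exceed_r2) / (n_perm + 1.0)
    return MRMResult(
        coefficients=pd.Series(beta_obs, index=names),
        r_squared=r2_obs,
        p_values=pd.Series(p_coef, index=names),
        model_p=float(p_model),
        n_permutations=n_perm,
    )
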