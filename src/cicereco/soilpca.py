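"""Soil-chemistry transforms and principal component analysis.

Eighteen macro/micronutrient and chemical variables are measured per soil
sample.  Before ordination, thirteen of them are natural-log transformed
(Zn, Fe, Ca, Mn, Na, Mg, nitrogen, total carbon, inorganic carbon, total
sulfur, lime-CaCO3, electrical conductivity, potassium), pH is
exponentiated, and the remainder (Cu, organic carbon, P2O5, organic
matter) are left untransformed.  The PCA runs on the correlation matrix by
default (center + unit scale after transforms), with mean imputation of
missing values and component loadings reported against a configurable
display threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SOIL_VARIABLES",
    "LOG_VARIABLES",
    "EXP_VARIABLES",
    "PCAResult",
    "transform_soil",
    "pca",
]

SOIL_VARIABLES = [
    "Cu", "Zn", "Fe", "Ca", "Mn", "Na", "K", "Mg", "N",
    "organic_C", "inorganic_C", "total_C", "S", "lime_CaCO3",
    "pH", "EC", "P2O5", "organic_matter",
]
LOG_VARIABLES = frozenset(
    ["Zn", "Fe", "Ca", "Mn", "Na", "Mg", "N", "total_C", "inorganic_C",
     "S", "lime_CaCO3", "EC", "K"]
)
EXP_VARIABLES = frozenset(["pH"])
ID_COLUMNS = ("sample_id", "site")


def transform_soil(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the per-variable transforms; unknown variables raise.

    Zero or negative values under a log transform become missing, with a
    warning.
    """
    out = table.copy()
    for col in table.columns:
        if col in ID_COLUMNS:
            continue
        if col not in SOIL_VARIABLES:
            raise KeyError(f"unknown soil variable {col!r}")
        x = pd.to_numeric(out[col], errors="coerce").astype(float)
        if col in LOG_VARIABLES:
            bad = x <= 0
            if bad.any():
                warnings.warn(f"{col}: {int(bad.sum())} non-positive value(s) set missing under log")
                x = x.where(~bad)
            out[col] = np.log(x)
        elif col in EXP_VARIABLES:
            out[col] = np.exp(x)
        else:
            out[col] = x
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame             # samples x components
    loadings: pd.DataFrame           # variables x components (eigvec * sqrt(eigval))
    eigenvectors: pd.DataFrame
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    n_imputed: int
    column_means: np.ndarray
    column_scales: np.ndarray

    def high_loadings(self, threshold: float = 1.0, components: int = 2) -> pd.DataFrame:
        """Variables with |loading| above the display threshold on the
        leading components (presets 1.0 and 1.5 both in circulation)."""
        sub = self.loadings.iloc[:, :components]
        return sub[(sub.abs() > threshold).any(axis=1)]


def pca(table: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of a (transformed) sample-by-variable table.

    Centers always; ``scale=True`` gives the correlation-matrix PCA.
    Missing values are mean-imputed (count reported).  Computed via SVD, so
    more variables than samples is allowed (with a warning).
    """
    num = table.drop(columns=[c for c in ID_COLUMNS if c in table.columns])
    X = num.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 samples and 2 variables")
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means, X)
    if p > n:
        warnings.warn("more variables than samples; PCA still computed via SVD")
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant variable(s); cannot unit-scale")
    else:
        sd = np.ones(p)
    Xs = Xc / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    eigvals = S**2 / (n - 1)
    ratio = eigvals / eigvals.sum()
    k = S.shape[0]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * S, index=num.index, columns=comp_names)
    eigvecs = pd.DataFrame(Vt.T, index=num.columns, columns=comp_names)
    loadings = eigvecs * np.sqrt(eigvals)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvectors=eigvecs,
        explained_variance_ratio=ratio,
        eigenvalues=eigvals,
        n_imputed=n_imputed,
        column_means=mu,
        column_scales=sd,
    )
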