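"""Global methylation structure and genotype-based fine structure.

Principal-coordinate analysis (classical multidimensional scaling) of the
inter-individual Euclidean distance matrix of M-values summarises global
methylation patterns; genotype PCA (allele-frequency standardised SVD)
captures genetic structure, with components beyond those collinear with
continental ancestry serving as fine-scale (sub-continental) structure
covariates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MethylationMatrix

__all__ = ["PCoAResult", "pcoa", "genotype_pca", "associate_pc", "residualize"]


def _orient(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude loading of each column is
    made positive."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


@dataclass
class PCoAResult:
    """Principal coordinates (column-centered, scaled by sqrt(eigenvalue))."""

    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # k, nonincreasing, nonnegative

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be nonincreasing")


def pcoa(values, k: int = 10) -> PCoAResult:
    """Classical scaling of the Euclidean distance matrix.

    ``values`` is a samples x features matrix (DataFrame or array) of
    M-values.  Gower double-centering of -D**2/2 followed by
    eigendecomposition; coordinate j is the eigenvector scaled by the square
    root of its eigenvalue.  Numerically negative eigenvalues are clipped at
    zero with a warning.
    """
    if isinstance(values, MethylationMatrix):
        values = values.to_m().values
    X = np.asarray(values, dtype=float)
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(len(X))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > max(evals.max(), 1.0) * 1e-10).sum())
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    if np.any(evals[:k] < 0):
        warnings.warn("negative eigenvalues clipped at 0", stacklevel=2)
    evals = np.clip(evals[:k], 0.0, None)
    coords = _orient(evecs[:, :k] * np.sqrt(evals))
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCoAResult(pd.DataFrame(coords, index=index, columns=cols), evals)


def genotype_pca(geno: GenotypeMatrix, k: int = 10):
    """Allele-frequency standardised genotype PCA.

    Missing dosages are mean-imputed; each SNP is centered at 2*p_hat and
    scaled by sqrt(2*p_hat*(1-p_hat)); monomorphic SNPs are dropped.
    Returns ``(scores DataFrame, eigenvalues, dropped SNP list)``.
    """
    X = geno.dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    p_hat = col_mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    dropped = list(geno.snps[~poly])
    X = (X[:, poly] - 2 * p_hat[poly]) / np.sqrt(2 * p_hat[poly] * (1 - p_hat[poly]))
    X -= X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(s))
    scores = _orient(u[:, :k] * s[:k])
    evals = (s[:k] ** 2) / max(len(X) - 1, 1)
    cols = [f"gPC{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, index=geno.samples, columns=cols), evals, dropped


def associate_pc(pc: pd.Series, predictor, covariates: pd.DataFrame | None = None):
    """Omnibus nested-ANOVA p for a factor or compositional predictor on one
    principal coordinate, adjusted for covariates.

    ``predictor`` may be a categorical Series (k-1 indicators) or a
    DataFrame of K ancestry proportions (K-1 columns enter, last column the
    reference).  Returns the nested-ANOVA result; rank-deficient designs
    return a result with ``stable=False`` and no p-value.
    """
    from .ewas import RankError, build_design, fit_ols, nested_anova

    y = np.asarray(pc, dtype=float)
    index = pc.index
    X_red = build_design(index, covariates)
    if isinstance(predictor, pd.DataFrame):
        block = predictor.iloc[:, :-1].copy()
        block.columns = [f"anc_{c}" for c in block.columns]
    else:
        block = pd.get_dummies(pd.Series(predictor, index=index), prefix="grp", drop_first=True).astype(float)
    X_full = pd.concat([X_red, block.loc[index]], axis=1)
    try:
        full, red = fit_ols(y, X_full), fit_ols(y, X_red)
    except RankError:
        return PCAssociation(np.nan, 0, 0, np.nan, stable=False)
    a = nested_anova(full, red)
    return PCAssociation(a.F, a.df1, a.df2, a.p, stable=True)


@dataclass
class PCAssociation:
    F: float
    df1: int
    df2: int
    p: float
    stable: bool = True


def residualize(values, block: pd.DataFrame) -> pd.DataFrame:
    """Column-wise OLS residuals of ``values`` on the covariate block
    (an intercept is always included); residuals are orthogonal to the
    block."""
    if isinstance(values, MethylationMatrix):
        values = values.to_m().values
    Y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones(len(Y)), np.asarray(block, dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate block is rank deficient")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(resid, index=values.index, columns=values.columns)
    return pd.DataFrame(resid)
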