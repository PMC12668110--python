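"""Variant QC, covariate residualisation and rank-based inverse normal
transformation (INT)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2, rankdata

from .genotypes import GenotypeMatrix
from .simulate import PhenotypeVector


@dataclass(frozen=True)
class QCThresholds:
    """Variant inclusion thresholds: MAF >= 0.1%, missingness <= 5%,
    Hardy-Weinberg p >= 1e-10, imputation INFO >= 0.8."""

    maf_min: float = 0.001
    missing_max: float = 0.05
    hwe_p_min: float = 1e-10
    info_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min", "info_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square p-value per variant from rounded hard calls.

    Dosages are rounded to {0,1,2}; missing values are ignored.  HWE is
    undefined on fractional dosages, so the test operates on the implied
    genotype classes.  Monomorphic variants get p = 1.
    """
    d = np.asarray(dosages, float)
    m = d.shape[1]
    pvals = np.ones(m)
    calls = np.rint(d)
    valid = ~np.isnan(calls)
    for j in range(m):
        c = calls[valid[:, j], j]
        n = len(c)
        if n == 0:
            continue
        n_aa = np.sum(c == 0)
        n_ab = np.sum(c == 1)
        n_bb = np.sum(c == 2)
        p = (n_ab + 2 * n_bb) / (2 * n)
        if p in (0.0, 1.0):
            continue
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.array([n_aa, n_ab, n_bb])
        stat = np.sum((obs - exp) ** 2 / exp)
        pvals[j] = chi2.sf(stat, df=1)
    return pvals


def qc_filter_variants(
    G: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> np.ndarray:
    """Boolean mask of variants passing all four QC filters.

    A variant passes iff MAF >= maf_min, missing rate <= missing_max,
    HWE p >= hwe_p_min and INFO >= info_min (all boundaries inclusive).
    """
    hwe_p = hwe_pvalues(G.dosages)
    return (
        (G.maf >= thresholds.maf_min)
        & (G.missing_rate <= thresholds.missing_max)
        & (hwe_p >= thresholds.hwe_p_min)
        & (G.info >= thresholds.info_min)
    )


def build_covariate_design(
    covariates: pd.DataFrame, categorical: tuple[str, ...] = ("batch", "centre")
) -> np.ndarray:
    """Expand a covariate table into a full-rank design matrix with intercept.

    Categorical columns are one-hot encoded with the first level dropped as
    reference.  Collinear columns are pruned with a warning; a design that is
    rank-deficient even after pruning raises.
    """
    if covariates.isna().any().any():
        raise ValueError("covariate table contains missing values")
    cats = [c for c in categorical if c in covariates.columns]
    X = pd.get_dummies(covariates, columns=cats, drop_first=True, dtype=float)
    X = X.astype(float)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])

    # prune collinear columns greedily, keeping earlier ones
    keep = [0]
    for j in range(1, mat.shape[1]):
        trial = mat[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear covariate column index {j - 1}", stacklevel=2
            )
    pruned = mat[:, keep]
    if np.linalg.matrix_rank(pruned) < pruned.shape[1]:
        raise ValueError("covariate design rank-deficient after pruning")
    return pruned


def regress_out_covariates(
    y: PhenotypeVector | np.ndarray, covariates: pd.DataFrame | np.ndarray
) -> PhenotypeVector:
    """Least-squares residuals of the phenotype on the covariate design.

    Residuals are orthogonal to every covariate column (to numerical
    precision).  Accepts either a raw array of covariate columns (an
    intercept is added) or a pre-built design DataFrame.
    """
    vec = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    if isinstance(covariates, pd.DataFrame):
        X = build_covariate_design(covariates)
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != len(vec):
            raise ValueError("covariate rows must match phenotype length")
        X = np.column_stack([np.ones(len(vec)), C]) if C.size else np.ones((len(vec), 1))
    coef, *_ = np.linalg.lstsq(X, vec, rcond=None)
    resid = vec - X @ coef
    if isinstance(y, PhenotypeVector):
        return y.advance(resid, "residual")
    return PhenotypeVector(resid, "residual")


def inverse_normal_transform(
    values: PhenotypeVector | np.ndarray, offset: float = 0.5
) -> PhenotypeVector:
    """Rank-based inverse normal transformation.

    A value with (average, for ties) rank r among n maps to
    Phi^-1((r - offset)/n).  Invariant under strictly monotone transforms of
    the input.  All-equal input is rejected (ranks degenerate).
    """
    vec = values.values if isinstance(values, PhenotypeVector) else np.asarray(values, float)
    if len(vec) < 2:
        raise ValueError("INT requires at least two observations")
    if np.all(vec == vec[0]):
        raise ValueError("INT undefined for constant input")
    r = rankdata(vec, method="average")
    out = ndtri((r - offset) / len(vec))
    if isinstance(values, PhenotypeVector):
        return values.advance(out, "int")
    return PhenotypeVector(out, "int")
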