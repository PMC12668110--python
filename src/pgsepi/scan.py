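"""Genome-wide SNP x PGS interaction scan and stepwise isolation of
independent hits with dominance control.

For every variant the model

    phenotype = alpha + beta*SNP + gamma*PGS + delta*SNP x PGS + eps

is fitted by OLS, with the leave-one-chromosome-out (LOCO), mean-corrected
score of the variant's chromosome standing in for the PGS so that LD between
the variant and score members cannot manufacture interactions (phantom
epistasis).  Genome-wide significant interactions are then distilled into an
independent set by a forward stepwise procedure that carries a
squared-dosage term per SNP, so dominance/recessiveness at a single locus is
never misread as an interaction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .regression import batched_product_ols, ols_fit
from .simulate import PhenotypeVector

GENOME_WIDE_P = 5e-8


def prepare_dependent(
    y: PhenotypeVector | np.ndarray,
    pgs_full: np.ndarray,
    interact_covariates: np.ndarray | None = None,
) -> PhenotypeVector:
    """Regress the (non-LOCO, mean-corrected) full score and its interactions
    with selected covariate columns out of the INT phenotype.

    Removing the full score soaks up as much additive signal as possible;
    the score x covariate interactions guard against interactions with
    aggregate structure (centre, ancestry).  Collinear interaction columns
    are dropped with a warning.
    """
    vec = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    cols = [np.ones(len(vec)), np.asarray(pgs_full, float)]
    if interact_covariates is not None:
        C = np.asarray(interact_covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        for j in range(C.shape[1]):
            cols.append(pgs_full * C[:, j])
    X = np.column_stack(cols)
    # drop collinear columns greedily
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear PGS-interaction column {j}", stacklevel=2)
    Xk = X[:, keep]
    coef, *_ = np.linalg.lstsq(Xk, vec, rcond=None)
    resid = vec - Xk @ coef
    if isinstance(y, PhenotypeVector):
        return y.advance(resid, "pgs_adjusted")
    return PhenotypeVector(resid, "pgs_adjusted")


def snp_pgs_scan(
    G: GenotypeMatrix,
    loco_scores: dict[int, np.ndarray],
    y: PhenotypeVector | np.ndarray,
) -> pd.DataFrame:
    """Per-variant 4-parameter interaction GWAS.

    ``loco_scores`` maps chromosome -> mean-corrected LOCO score; each
    variant is tested against the score of its own chromosome.  Returns one
    row per variant with coefficients, SEs, the two-sided interaction
    p-value and a degeneracy flag.  Deterministic and chromosome-parallel by
    construction.
    """
    vec = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    D = G.imputed()
    frames = []
    for k in np.unique(G.chrom):
        if int(k) not in loco_scores:
            raise KeyError(f"no LOCO score provided for chromosome {k}")
        idx = np.where(G.chrom == k)[0]
        fit = batched_product_ols(vec, loco_scores[int(k)], D[:, idx])
        frames.append(
            pd.DataFrame(
                {
                    "variant_idx": idx,
                    "variant_id": G.variant_id[idx],
                    "chrom": G.chrom[idx],
                    "pos": G.pos[idx],
                    "alpha": fit["coef"][:, 0],
                    "beta": fit["coef"][:, 1],
                    "gamma": fit["coef"][:, 2],
                    "delta": fit["coef"][:, 3],
                    "se_beta": fit["se"][:, 1],
                    "se_gamma": fit["se"][:, 2],
                    "se_delta": fit["se"][:, 3],
                    "p_delta": fit["p"][:, 3],
                    "degenerate": fit["degenerate"],
                    "n": fit["n"],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def stepwise_independent_hits(
    scan: pd.DataFrame,
    G: GenotypeMatrix,
    loco_scores: dict[int, np.ndarray],
    y: PhenotypeVector | np.ndarray,
    threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Forward stepwise selection of independent interaction hits.

    Candidates (scan rows with interaction p <= threshold) are visited in
    order of increasing p (ties by chromosome, then position).  For each, the
    joint model gains the SNP's dosage, its square (dominance control) and
    its product with the SNP's LOCO score; the candidate is retained iff its
    interaction term stays below the threshold, otherwise its three columns
    are removed.  Candidates whose columns make the design rank-deficient
    are dropped.  Returns the retained hits with final joint-model
    statistics.
    """
    vec = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    D = G.imputed()
    cand = scan[(scan["p_delta"] <= threshold) & (~scan["degenerate"])]
    cand = cand.sort_values(["p_delta", "chrom", "pos"], kind="stable")
    n = len(vec)
    X = np.ones((n, 1))
    retained: list[dict] = []

    def _blocks(row):
        g = D[:, int(row.variant_idx)]
        P = loco_scores[int(row.chrom)]
        return np.column_stack([g, g * g, g * P])

    for row in cand.itertuples(index=False):
        B = _blocks(row)
        trial = np.hstack([X, B])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            continue  # perfectly collinear with current model
        try:
            fit = ols_fit(trial, vec)
        except np.linalg.LinAlgError:
            continue
        p_int = fit.p[-1]
        if p_int <= threshold:
            X = trial
            retained.append(
                {
                    "variant_idx": int(row.variant_idx),
                    "variant_id": row.variant_id,
                    "chrom": int(row.chrom),
                    "pos": int(row.pos),
                    "p_scan": float(row.p_delta),
                }
            )

    if not retained:
        return pd.DataFrame(
            columns=[
                "variant_idx", "variant_id", "chrom", "pos", "p_scan",
                "delta", "se_delta", "p_delta", "survived_stepwise",
                "dominance_controlled",
            ]
        )
    final = ols_fit(X, vec)
    rows = []
    for i, h in enumerate(retained):
        j = 1 + 3 * i + 2  # interaction column of hit i in the joint design
        rows.append(
            {
                **h,
                "delta": final.coef[j],
                "se_delta": final.se[j],
                "p_delta": final.p[j],
                "survived_stepwise": True,
                "dominance_controlled": True,
            }
        )
    return pd.DataFrame(rows)
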