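"""Pairwise SNP x SNP interaction GWAS seeded by SNP x PGS hits.

Each focal hit is tested against every other variant in the genome on the
residual+INT phenotype (the PGS is deliberately *not* regressed out here).
Partners within 1 Mb of the focal SNP are flagged cis and excluded from the
reported tiers, since LD with an unobserved additive variant (phantom
epistasis) is a local phenomenon.  Surviving pairs are frequency-filtered:
the main tier needs both MAFs >= 1%; a secondary tier needs interaction
frequency (mean dosage product / 2) >= 0.1%.  Interacting networks are
refitted jointly with main, squared (dominance) and all pairwise product
terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .regression import batched_product_ols, ols_fit
from .scan import GENOME_WIDE_P

CIS_WINDOW = 1_000_000


def interaction_frequency(g1: np.ndarray, g2: np.ndarray) -> float:
    """Mean product of the two dosage vectors divided by two.

    The pair analogue of a single variant's allele frequency: the rate at
    which the two minor alleles co-occur within individuals.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    if np.isnan(g1).any():
        g1 = np.where(np.isnan(g1), np.nanmean(g1), g1)
    if np.isnan(g2).any():
        g2 = np.where(np.isnan(g2), np.nanmean(g2), g2)
    return float(np.mean(g1 * g2) / 2.0)


def pairwise_gwas(
    G: GenotypeMatrix,
    focal_idx: int,
    y: np.ndarray,
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Test the focal SNP against every variant for a pairwise interaction.

    Fits ``y ~ 1 + g_focal + g_partner + g_focal*g_partner`` per partner.
    The dependent variable is the covariate-residualised, INT phenotype
    without PGS adjustment.  Partners on the focal chromosome within
    ``cis_window`` (the focal SNP itself included) are cis-flagged.
    """
    vec = np.asarray(y.values if hasattr(y, "values") else y, float)
    D = G.imputed()
    gf = D[:, focal_idx]
    fit = batched_product_ols(vec, gf, D)
    prod_mean = (D * gf[:, None]).mean(0)
    cis = (G.chrom == G.chrom[focal_idx]) & (
        np.abs(G.pos.astype(np.int64) - int(G.pos[focal_idx])) <= cis_window
    )
    return pd.DataFrame(
        {
            "focal_idx": focal_idx,
            "focal_id": G.variant_id[focal_idx],
            "partner_idx": np.arange(G.n_variants),
            "partner_id": G.variant_id,
            "chrom": G.chrom,
            "pos": G.pos,
            "coef": fit["coef"][:, 3],
            "se": fit["se"][:, 3],
            "p": fit["p"][:, 3],
            "maf_focal": G.maf[focal_idx],
            "maf_partner": G.maf,
            "interaction_frequency": prod_mean / 2.0,
            "cis_flag": cis,
            "degenerate": fit["degenerate"],
        }
    )


def tier_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Assign each pair to the main / secondary / discarded tier.

    main: both MAFs >= 1%; secondary: interaction frequency >= 0.1%;
    otherwise discarded.  Cis-flagged pairs are always discarded.  Pure
    function of the stored frequencies (idempotent).
    """
    out = pairs.copy()
    main = (out["maf_focal"] >= 0.01) & (out["maf_partner"] >= 0.01)
    secondary = out["interaction_frequency"] >= 0.001
    tier = np.where(main, "main", np.where(secondary, "secondary", "discarded"))
    tier = np.where(out["cis_flag"], "discarded", tier)
    out["tier"] = tier
    return out


def stepwise_pair_hits(
    pairs: pd.DataFrame,
    G: GenotypeMatrix,
    y: np.ndarray,
    threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Isolate independent significant partners of one focal SNP.

    Mirrors the SNP x PGS stepwise procedure: candidates sorted by
    increasing p; the joint model starts with the focal SNP's dosage and its
    square and gains (g_partner, g_partner^2, g_focal*g_partner) per
    candidate, which is retained iff its interaction stays below the
    threshold.  Cis-flagged and degenerate rows are never candidates.
    """
    vec = np.asarray(y.values if hasattr(y, "values") else y, float)
    D = G.imputed()
    cand = pairs[
        (pairs["p"] <= threshold) & (~pairs["cis_flag"]) & (~pairs["degenerate"])
    ].sort_values(["p", "chrom", "pos"], kind="stable")
    if cand.empty:
        return cand.assign(survived_stepwise=pd.Series(dtype=bool))
    focal_idx = int(cand["focal_idx"].iloc[0])
    gf = D[:, focal_idx]
    X = np.column_stack([np.ones(len(vec)), gf, gf * gf])
    retained_rows = []
    for row in cand.itertuples(index=False):
        gp = D[:, int(row.partner_idx)]
        trial = np.hstack([X, np.column_stack([gp, gp * gp, gf * gp])])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            continue
        fit = ols_fit(trial, vec)
        if fit.p[-1] <= threshold:
            X = trial
            retained_rows.append(row._asdict())
    if not retained_rows:
        return pd.DataFrame(columns=list(pairs.columns) + ["survived_stepwise"])
    final = ols_fit(X, vec)
    out = pd.DataFrame(retained_rows)
    for i in range(len(out)):
        j = 3 + 3 * i + 2
        out.loc[i, "coef"] = final.coef[j]
        out.loc[i, "se"] = final.se[j]
        out.loc[i, "p"] = final.p[j]
    out["survived_stepwise"] = True
    return out


def joint_network_fit(
    G: GenotypeMatrix,
    snp_idx: np.ndarray,
    y: np.ndarray,
    strong_p: float = GENOME_WIDE_P,
    suggestive_p: float = 1e-4,
) -> dict:
    """Joint refit of an interacting SNP network.

    A single OLS with all main effects, squared dosages (diagonal:
    dominance) and pairwise products (off-diagonal) for 2-10 member SNPs.
    Effect alleles are flipped beforehand so every marginal main effect is
    non-negative.  Returns symmetric coefficient and p matrices plus an
    edge list classified as strong (p <= 5e-8) or suggestive (p <= 1e-4).
    """
    snp_idx = np.asarray(snp_idx, int)
    k = len(snp_idx)
    if not 2 <= k <= 10:
        raise ValueError("network fit supports 2 to 10 SNPs")
    vec = np.asarray(y.values if hasattr(y, "values") else y, float)
    D = G.imputed()[:, snp_idx].copy()
    flipped = np.zeros(k, dtype=bool)
    for j in range(k):
        g = D[:, j]
        gc = g - g.mean()
        if float(gc @ (vec - vec.mean())) < 0:
            D[:, j] = 2.0 - g
            flipped[j] = True

    cols = [np.ones(len(vec))]
    labels: list[tuple] = [("intercept",)]
    for j in range(k):
        cols.append(D[:, j])
        labels.append(("main", j))
    for j in range(k):
        cols.append(D[:, j] ** 2)
        labels.append(("diag", j))
    for a in range(k):
        for b in range(a + 1, k):
            cols.append(D[:, a] * D[:, b])
            labels.append(("pair", a, b))
    fit = ols_fit(np.column_stack(cols), vec)

    coef_mat = np.zeros((k, k))
    p_mat = np.ones((k, k))
    main = np.zeros(k)
    main_p = np.ones(k)
    edges = []
    for lab, c, p in zip(labels, fit.coef, fit.p):
        if lab[0] == "main":
            main[lab[1]] = c
            main_p[lab[1]] = p
        elif lab[0] == "diag":
            coef_mat[lab[1], lab[1]] = c
            p_mat[lab[1], lab[1]] = p
        elif lab[0] == "pair":
            a, b = lab[1], lab[2]
            coef_mat[a, b] = coef_mat[b, a] = c
            p_mat[a, b] = p_mat[b, a] = p
            if p <= strong_p:
                edges.append((int(snp_idx[a]), int(snp_idx[b]), float(c), float(p), "strong"))
            elif p <= suggestive_p:
                edges.append((int(snp_idx[a]), int(snp_idx[b]), float(c), float(p), "suggestive"))
    return {
        "snp_idx": snp_idx,
        "flipped": flipped,
        "main_effects": main,
        "main_p": main_p,
        "coef_matrix": coef_mat,
        "p_matrix": p_mat,
        "edges": pd.DataFrame(
            edges, columns=["node_a", "node_b", "coef", "p", "edge_class"]
        ),
        "fit": fit,
    }
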