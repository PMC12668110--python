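"""End-to-end pipeline: QC -> covariates -> INT -> GWAS -> loose C+T PGS with
joint-effect adjustment -> LOCO -> mean correction -> SNP x PGS scan ->
stepwise hits -> optional pairwise refinement.

Each stage writes a TSV into the output directory and appends to a
structured JSON log recording seeds, thresholds and input checksums, so a
rerun with identical inputs and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .genotypes import GenotypeMatrix
from .pgs import (
    PGSModel,
    adjust_joint_effects,
    build_loco_scores,
    clump_and_threshold,
    marginal_gwas,
    mean_correct,
    select_p_threshold,
)
from .preprocess import QCThresholds, inverse_normal_transform, qc_filter_variants, regress_out_covariates
from .scan import prepare_dependent, snp_pgs_scan, stepwise_independent_hits
from .pairwise import pairwise_gwas, stepwise_pair_hits, tier_pairs
from .simulate import PhenotypeVector


@dataclass
class PipelineResult:
    qc_mask: np.ndarray
    gwas: object
    pgs_model: PGSModel
    loco_corrected: dict[int, np.ndarray]
    pgs_corrected: np.ndarray
    scan: pd.DataFrame
    hits: pd.DataFrame
    pairs: pd.DataFrame | None
    y_int: PhenotypeVector
    y_dep: PhenotypeVector
    log: dict = field(default_factory=dict)


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline_arrays(
    G: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    config: pio.PipelineConfig | None = None,
) -> PipelineResult:
    """Run the analysis on in-memory arrays (the library-level entry point).

    Stages: variant QC; covariate residualisation; INT; marginal GWAS;
    loose C+T (clump r2 0.90, held-out-selected p threshold) with iterative
    joint-effect adjustment; LOCO scores; mean correction of the full and
    every LOCO score; PGS adjustment of the dependent variable; SNP x PGS
    scan; stepwise independent hits; optional pairwise refinement of each
    hit.
    """
    cfg = config or pio.PipelineConfig()
    log: dict = {"seed": cfg.seed, "thresholds": {
        "significance_p": cfg.significance_p,
        "clump_r2_loose": cfg.clump_r2_loose,
        "maf_min": cfg.maf_min,
    }}

    qc = qc_filter_variants(
        G,
        QCThresholds(cfg.maf_min, cfg.missing_max, cfg.hwe_p_min, cfg.info_min),
    )
    Gq = G.subset_variants(np.where(qc)[0])
    log["n_variants_qc"] = int(qc.sum())

    y0 = PhenotypeVector(np.asarray(phenotype, float), "raw")
    if covariates is not None:
        y_res = regress_out_covariates(y0, covariates)
    else:
        y_res = y0.advance(y0.values - y0.values.mean(), "residual")
    y_int = inverse_normal_transform(y_res)

    res = marginal_gwas(Gq, y_int.values)
    p_thr = select_p_threshold(
        Gq, y_int.values, r2_threshold=cfg.clump_r2_loose, seed=cfg.seed
    )
    log["pgs_p_threshold"] = p_thr
    sel = clump_and_threshold(Gq, res, cfg.clump_r2_loose, p_thr, cfg.window)
    if sel.size == 0:
        sel = np.array([int(np.argmin(res.p))])  # degenerate: keep top variant
        log["pgs_fallback_top_variant"] = True
    model = adjust_joint_effects(
        Gq, sel, res.beta[sel], y_int.values,
        clump_r2=cfg.clump_r2_loose, p_threshold=p_thr,
    )
    model = build_loco_scores(model, Gq)

    pgs_corr, _ = mean_correct(model.score_full, y_int.values)
    loco_corr: dict[int, np.ndarray] = {}
    for k, score in model.loco.items():
        if np.std(score) == 0:
            loco_corr[k] = np.zeros_like(score)
        else:
            loco_corr[k], _ = mean_correct(score, y_int.values)

    y_dep = prepare_dependent(y_int, pgs_corr)
    scan = snp_pgs_scan(Gq, loco_corr, y_dep)
    hits = stepwise_independent_hits(scan, Gq, loco_corr, y_dep, cfg.significance_p)

    pairs = None
    if cfg.run_pairwise and len(hits):
        frames = []
        for h in hits.itertuples(index=False):
            pw = pairwise_gwas(Gq, int(h.variant_idx), y_int.values, cfg.window)
            kept = stepwise_pair_hits(pw, Gq, y_int.values, cfg.significance_p)
            if len(kept):
                frames.append(tier_pairs(kept))
        pairs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return PipelineResult(
        qc_mask=qc, gwas=res, pgs_model=model, loco_corrected=loco_corr,
        pgs_corrected=pgs_corr, scan=scan, hits=hits, pairs=pairs,
        y_int=y_int, y_dep=y_dep, log=log,
    )


def run_pipeline(config: pio.PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs, run the stages, write TSVs and a
    JSON log into ``config.output_dir``.  Any stage failure halts with the
    stage name; earlier outputs are preserved on disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        G = pio.read_genotypes(config.genotypes)
        pheno = pio.read_phenotype_tsv(config.phenotype)
        y = pheno.iloc[:, 1].to_numpy(float)
        cov = None
        if config.covariates:
            cov_df = pd.read_csv(config.covariates, sep="\t")
            cov = cov_df.drop(columns=cov_df.columns[0])
        stage = "analysis"
        result = run_pipeline_arrays(G, y, cov, config)
        stage = "write_outputs"
        result.log["inputs"] = {
            "genotypes": _checksum(config.genotypes),
            "phenotype": _checksum(config.phenotype),
        }
        pio.write_table(result.scan, out / "interaction_scan.tsv")
        pio.write_table(result.hits, out / "independent_hits.tsv")
        weights = pd.DataFrame(
            {
                "variant_id": np.asarray(result.pgs_model.variant_idx, int),
                "weight": result.pgs_model.weights,
            }
        )
        pio.write_table(weights, out / "pgs_weights.tsv")
        if result.pairs is not None:
            pio.write_table(result.pairs, out / "pairwise_hits.tsv")
        with open(out / "run_log.json", "w") as fh:
            json.dump(result.log, fh, indent=2, sort_keys=True)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc
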