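"""Partitioning a polygenic score by transcription-factor binding.

Starting from the independent hits of a standard C+T score, each hit
("driver") is extended to its LD tags (r2 >= 0.75 within 1 Mb).  Under the
assumption of exactly one causal variant per region, per-tag approximate
Bayes factors give a posterior over the causal variant, which is reweighted
by a multiplicative annotation prior: coding consequence, enhancer/promoter
histone marks (H3K4me1/H3K4me3) and, per transcription factor, a motif
disruption score expressed as an odds ratio against an enhancer background.
The enrichment parameter alpha of each annotation is estimated by maximum
likelihood.  The resulting TF-specific score TFS enters the six-term
interaction model

    phenotype = a + b*SNP + g*PGS + d*SNP x PGS + zeta*TFS + eta*SNP x TFS

so that a TF signal is only reported when it is distinct from the
whole-score interaction.  Signals explained by a single pairwise partner
inside the score are removed by rebuilding the TFS without that partner and
its tags and re-testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.isotonic import IsotonicRegression

from .genotypes import GenotypeMatrix
from .regression import ols_fit

TF_SIGNIFICANCE_P = 1e-5  # Bonferroni 0.01/1000 for ~<=1000 TF scores per trait

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class Region:
    """A driver hit with its LD tags and per-tag causal evidence."""

    driver_idx: int
    tag_idx: np.ndarray
    bf: np.ndarray                      # normalized, sums to 1
    beta_driver: float = 0.0
    annotations: dict = field(default_factory=dict)   # name -> 0/1 array per tag
    motif_or: dict = field(default_factory=dict)      # motif id -> OR array per tag

    def __post_init__(self) -> None:
        self.tag_idx = np.asarray(self.tag_idx, int)
        self.bf = np.asarray(self.bf, float)
        if self.driver_idx not in self.tag_idx:
            raise ValueError("driver must be among its own tags")
        if len(self.bf) != len(self.tag_idx):
            raise ValueError("one Bayes factor per tag required")
        if abs(self.bf.sum() - 1.0) > 1e-8:
            raise ValueError("Bayes factors must be normalized within the region")


@dataclass
class AlphaEstimate:
    """Maximum-likelihood enrichment of one annotation (or motif)."""

    name: str
    alpha: float
    loglik: float
    dataset_id: str | None = None
    flag: str = ""


@dataclass
class MotifModel:
    """A position count matrix and its log-odds form.

    Log odds use a pseudocount of 1 per cell against a uniform base
    composition.
    """

    motif_id: str
    tf_name: str
    counts: np.ndarray   # (L, 4) in A C G T order
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 matrix (A C G T)")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every motif position needs a positive count sum")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        c = self.counts + self.pseudocount
        freq = c / c.sum(axis=1, keepdims=True)
        return np.log(freq / 0.25)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class TFScore:
    """Per-individual partitioned score with LOCO versions."""

    tf_id: str
    values: np.ndarray
    loco: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# regions and Bayes factors

def define_regions(
    G: GenotypeMatrix,
    hit_idx: np.ndarray,
    r2: float = 0.75,
    window: int = 1_000_000,
) -> list[Region]:
    """Tag each driver hit with same-chromosome variants at r2 >= 0.75
    within +-1 Mb; the driver is always a member of its own region."""
    D = G.imputed()
    Dc = D - D.mean(0)
    norms = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
    regions = []
    for h in np.asarray(hit_idx, int):
        near = np.where(
            (G.chrom == G.chrom[h])
            & (np.abs(G.pos.astype(np.int64) - int(G.pos[h])) <= window)
        )[0]
        tags = [h]
        for j in near:
            if j == h or norms[j] == 0 or norms[h] == 0:
                continue
            r = float(Dc[:, j] @ Dc[:, h]) / (norms[j] * norms[h])
            if r * r >= r2:
                tags.append(int(j))
        tags = np.sort(np.asarray(tags, int))
        regions.append(
            Region(
                driver_idx=int(h),
                tag_idx=tags,
                bf=np.full(len(tags), 1.0 / len(tags)),
            )
        )
    return regions


def approximate_bayes_factors(
    beta: np.ndarray, se: np.ndarray, prior_variance: float = 0.04
) -> np.ndarray:
    """Wakefield approximate Bayes factors, normalized to sum to one.

    log ABF = 0.5 log(V/(V+W)) + 0.5 z^2 W/(V+W) with V = se^2 and prior
    effect variance W (default 0.04); computed in log space and rescaled so
    that only relative evidence within the region matters.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    log_abf = 0.5 * np.log(V / (V + prior_variance)) + 0.5 * z2 * prior_variance / (
        V + prior_variance
    )
    return np.exp(log_abf - logsumexp(log_abf))


# ---------------------------------------------------------------------------
# annotation enrichment

_LOG_ALPHA_BOUNDS = (np.log(0.01), np.log(100.0))


def _region_loglik(log_alpha: float, bfs: list[np.ndarray], anns: list[np.ndarray]) -> float:
    alpha = np.exp(log_alpha)
    total = 0.0
    for bf, a in zip(bfs, anns):
        prior = 1.0 + a * (alpha - 1.0)
        prior = np.maximum(prior, 0.0)
        s = prior.sum()
        if s <= 0:
            return -np.inf
        total += np.log(float((prior / s) @ bf))
    return total


def fit_annotation_alpha(
    regions: list[Region], annotation: str, values: list[np.ndarray] | None = None
) -> AlphaEstimate:
    """Maximum-likelihood enrichment parameter for one annotation.

    The prior that tag t is the causal variant of its region is proportional
    to 1 + a_t (alpha - 1); the region log-likelihood is
    log sum_t pi_t(alpha) BF_t and alpha is optimised on the log scale in
    [0.01, 100].  Annotations that are constant within every region leave
    alpha unidentifiable (flagged, alpha = 1).  The returned likelihood is
    never below the alpha = 1 null.
    """
    if len(regions) < 1:
        raise ValueError("at least one region required")
    if values is None:
        values = [np.asarray(r.annotations[annotation], float) for r in regions]
    else:
        values = [np.asarray(v, float) for v in values]
    bfs = [r.bf for r in regions]
    if all(np.all(v == v[0]) for v in values):
        return AlphaEstimate(
            annotation, 1.0, _region_loglik(0.0, bfs, values), flag="unidentifiable"
        )
    res = minimize_scalar(
        lambda la: -_region_loglik(la, bfs, values),
        bounds=_LOG_ALPHA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    la = float(res.x)
    ll = _region_loglik(la, bfs, values)
    ll_null = _region_loglik(0.0, bfs, values)
    if ll_null >= ll:
        la, ll = 0.0, ll_null
    flag = ""
    if min(la - _LOG_ALPHA_BOUNDS[0], _LOG_ALPHA_BOUNDS[1] - la) < 1e-3:
        flag = "boundary"
    return AlphaEstimate(annotation, float(np.exp(la)), float(ll), flag=flag)


def select_best_dataset(
    regions: list[Region],
    datasets: dict[str, list[np.ndarray]],
    mark: str,
) -> tuple[str, AlphaEstimate]:
    """Fit the enrichment model per candidate peak dataset and return the
    dataset maximising the likelihood (the best-fitting tissue/cell type)."""
    if not datasets:
        raise ValueError("no candidate datasets supplied")
    best: tuple[str, AlphaEstimate] | None = None
    for ds_id in sorted(datasets):
        est = fit_annotation_alpha(regions, mark, values=datasets[ds_id])
        est.dataset_id = ds_id
        if best is None or est.loglik > best[1].loglik:
            best = (ds_id, est)
    return best


# ---------------------------------------------------------------------------
# motif scanning and odds calibration

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(ch, -1) for ch in seq.upper()], dtype=int)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _best_score_one(seq: str, centre: int, motif: MotifModel) -> float:
    """Best log-odds over placements whose footprint covers ``centre``."""
    lo = motif.log_odds
    L = motif.length
    col_min = lo.min(axis=1)  # non-ACGT bases score as the worst base
    idx = _encode(seq)
    best = -np.inf
    for start in range(max(0, centre - L + 1), min(len(seq) - L, centre) + 1):
        s = 0.0
        for k in range(L):
            b = idx[start + k]
            s += lo[k, b] if b >= 0 else col_min[k]
        best = max(best, s)
    return best


def motif_best_score(
    window_seq: str,
    motif: MotifModel,
    snp_offset: int | None = None,
    alleles: tuple[str, str] | None = None,
) -> float:
    """Best motif match overlapping the SNP in a sequence window.

    Scans every placement whose footprint covers the (central by default)
    SNP position, on both strands, for both alleles when supplied, and
    returns the maximum log-odds score.  A window shorter than the motif
    yields -inf (the odds ratio is then forced to 1).
    """
    if snp_offset is None:
        snp_offset = len(window_seq) // 2
    if motif.length > len(window_seq):
        return -np.inf
    variants = []
    if alleles is None:
        variants.append(window_seq)
    else:
        for al in alleles:
            variants.append(window_seq[:snp_offset] + al + window_seq[snp_offset + 1 :])
    best = -np.inf
    for seq in variants:
        best = max(best, _best_score_one(seq, snp_offset, motif))
        rc = reverse_complement(seq)
        best = max(best, _best_score_one(rc, len(seq) - 1 - snp_offset, motif))
    return best


@dataclass
class MotifOddsCalibrator:
    """Empirical odds of a motif score under an enhancer vs. a
    non-regulatory SNP background.

    For a score s, the raw odds ratio is the ratio of add-one-smoothed
    empirical survival probabilities P(score >= s | enhancer) /
    P(score >= s | non-regulatory); the curve is made monotone
    non-decreasing by isotonic regression over the pooled score grid and
    floored at 1.
    """

    grid: np.ndarray
    odds_at_grid: np.ndarray

    @classmethod
    def fit(
        cls, enhancer_scores: np.ndarray, nonregulatory_scores: np.ndarray
    ) -> "MotifOddsCalibrator":
        e = np.sort(np.asarray(enhancer_scores, float))
        b = np.sort(np.asarray(nonregulatory_scores, float))
        if len(e) < 1 or len(b) < 1:
            raise ValueError("both backgrounds must be non-empty")
        if e.std() == 0 and b.std() == 0:
            grid = np.unique(np.concatenate([e[:1], b[:1]]))
            return cls(grid, np.ones_like(grid))
        grid = np.unique(np.concatenate([e, b]))
        surv_e = (len(e) - np.searchsorted(e, grid, side="left") + 1.0) / (len(e) + 1.0)
        surv_b = (len(b) - np.searchsorted(b, grid, side="left") + 1.0) / (len(b) + 1.0)
        raw = surv_e / surv_b
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        mono = iso.fit_transform(grid, raw)
        return cls(grid, np.maximum(mono, 1.0))

    def odds(self, score):
        """Odds ratio at the given score(s); -inf sentinels (window shorter
        than the motif) and scores below the grid floor at 1."""
        scalar = np.isscalar(score)
        s = np.atleast_1d(np.asarray(score, float))
        out = np.ones_like(s)
        finite = np.isfinite(s) & (s >= self.grid[0])
        pos = np.clip(
            np.searchsorted(self.grid, s[finite], side="right") - 1,
            0,
            len(self.grid) - 1,
        )
        out[finite] = self.odds_at_grid[pos]
        # scores above the grid keep the top-of-grid odds (monotone tail)
        return float(out[0]) if scalar else out


def calibrate_motif_odds(
    enhancer_scores: np.ndarray, nonregulatory_scores: np.ndarray
) -> MotifOddsCalibrator:
    """Fit the enhancer-vs-nonregulatory odds curve for one motif."""
    return MotifOddsCalibrator.fit(enhancer_scores, nonregulatory_scores)


# ---------------------------------------------------------------------------
# weights and score assembly

def compute_weights(
    a_coding: np.ndarray,
    a_h1: np.ndarray,
    a_h3: np.ndarray,
    motif_or: np.ndarray | None,
    alpha_motif: float = 1.0,
    alpha_coding: float = 1.0,
    alpha_h1: float = 1.0,
    alpha_h3: float = 1.0,
) -> np.ndarray:
    """Per-tag prior weight combining motif, coding and histone evidence:

        w = [1 + (OR-1)(alpha_m-1) + a_c (alpha_c-1)]
            x [1 + a_h1 (alpha_h1-1)] x [1 + a_h3 (alpha_h3-1)]

    TF and coding act additively within the first factor (biologically
    distinct routes to causality); histone factors multiply.  Each factor is
    floored at 0 since weights model prior probabilities.  A missing motif
    OR is treated as OR = 1.
    """
    a_c = np.asarray(a_coding, float)
    a1 = np.asarray(a_h1, float)
    a3 = np.asarray(a_h3, float)
    orr = np.ones_like(a_c) if motif_or is None else np.asarray(motif_or, float)
    f0 = 1.0 + (orr - 1.0) * (alpha_motif - 1.0) + a_c * (alpha_coding - 1.0)
    f1 = 1.0 + a1 * (alpha_h1 - 1.0)
    f3 = 1.0 + a3 * (alpha_h3 - 1.0)
    return np.maximum(f0, 0.0) * np.maximum(f1, 0.0) * np.maximum(f3, 0.0)


def assemble_tf_pgs(
    G: GenotypeMatrix,
    regions: list[Region],
    weights: list[np.ndarray],
    tf_id: str = "TF",
    exclude_idx: set[int] | None = None,
) -> TFScore:
    """Sum the weighted posterior score over regions:

        TFS_i = sum_d sum_t BF_{d,t} w_{d,t} beta_d g_{i,t}

    with leave-one-chromosome-out versions per chromosome.  ``exclude_idx``
    removes individual tags (used by the pairwise-driver check).
    """
    D = G.imputed()
    n = G.n_individuals
    chroms = np.unique(G.chrom)
    full = np.zeros(n)
    per_chrom = {int(k): np.zeros(n) for k in chroms}
    for reg, w in zip(regions, weights):
        keep = np.ones(len(reg.tag_idx), bool)
        if exclude_idx:
            keep = np.array([t not in exclude_idx for t in reg.tag_idx])
        if not keep.any():
            continue
        contrib = D[:, reg.tag_idx[keep]] @ (
            reg.bf[keep] * np.asarray(w)[keep] * reg.beta_driver
        )
        full += contrib
        per_chrom[int(G.chrom[reg.driver_idx])] += contrib
    loco = {int(k): full - per_chrom[int(k)] for k in chroms}
    return TFScore(tf_id=tf_id, values=full, loco=loco)


# ---------------------------------------------------------------------------
# interaction testing

@dataclass
class TFInteractionResult:
    eta: float
    se_eta: float
    p_eta: float
    zeta: float
    delta: float
    significant: bool
    flag: str = ""
    fit: object = None


def tf_interaction_test(
    g_focal: np.ndarray,
    pgs_loco: np.ndarray,
    tfs_loco: np.ndarray,
    y: np.ndarray,
    threshold: float = TF_SIGNIFICANCE_P,
) -> TFInteractionResult:
    """Six-term interaction model with both the whole score and the TF score.

    Regressors: intercept, SNP, PGS, SNP x PGS, TFS, SNP x TFS; the quantity
    of interest is the SNP x TFS coefficient eta.  A TF score collinear with
    the PGS (r2 > 0.999) is skipped, as no TF-specific signal is separable.
    """
    g = np.asarray(g_focal, float)
    P = np.asarray(pgs_loco, float)
    T = np.asarray(tfs_loco, float)
    vec = np.asarray(y.values if hasattr(y, "values") else y, float)
    if P.std() > 0 and T.std() > 0:
        r2 = float(np.corrcoef(P, T)[0, 1]) ** 2
        if r2 > 0.999:
            return TFInteractionResult(
                np.nan, np.nan, 1.0, np.nan, np.nan, False, flag="collinear_with_pgs"
            )
    elif T.std() == 0:
        return TFInteractionResult(
            np.nan, np.nan, 1.0, np.nan, np.nan, False, flag="degenerate_tfs"
        )
    X = np.column_stack([np.ones_like(g), g, P, g * P, T, g * T])
    try:
        fit = ols_fit(X, vec)
    except np.linalg.LinAlgError:
        return TFInteractionResult(
            np.nan, np.nan, 1.0, np.nan, np.nan, False, flag="rank_deficient"
        )
    return TFInteractionResult(
        eta=float(fit.coef[5]),
        se_eta=float(fit.se[5]),
        p_eta=float(fit.p[5]),
        zeta=float(fit.coef[4]),
        delta=float(fit.coef[3]),
        significant=bool(fit.p[5] <= threshold),
        fit=fit,
    )


def pairwise_driver_check(
    G: GenotypeMatrix,
    regions: list[Region],
    weights: list[np.ndarray],
    g_focal: np.ndarray,
    pgs_loco: np.ndarray,
    y: np.ndarray,
    pairwise_partner_idx: np.ndarray,
    focal_chrom: int,
    tag_r2: float = 0.80,
    window: int = 1_000_000,
    threshold: float = TF_SIGNIFICANCE_P,
    tf_id: str = "TF",
) -> tuple[TFInteractionResult, TFScore | None]:
    """Re-test a TF interaction after removing pairwise-driven tags.

    Significant pairwise partners of the focal SNP and their own tags
    (r2 >= 0.80 within 1 Mb) are excluded from the TF score, which is then
    rebuilt and the six-term test rerun.  A signal that vanishes is
    pairwise-driven, not TF-wide; an empty score after removal is reported
    as pairwise-driven outright.
    """
    partners = np.asarray(pairwise_partner_idx, int)
    if partners.size == 0:
        tfs = assemble_tf_pgs(G, regions, weights, tf_id=tf_id)
        res = tf_interaction_test(
            g_focal, pgs_loco, tfs.loco[int(focal_chrom)], y, threshold
        )
        return res, tfs
    exclude: set[int] = set(partners.tolist())
    D = G.imputed()
    Dc = D - D.mean(0)
    norms = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
    all_tags = np.unique(np.concatenate([r.tag_idx for r in regions]))
    for pidx in partners:
        for t in all_tags:
            if t in exclude or G.chrom[t] != G.chrom[pidx]:
                continue
            if abs(int(G.pos[t]) - int(G.pos[pidx])) > window:
                continue
            if norms[t] == 0 or norms[pidx] == 0:
                continue
            r = float(Dc[:, t] @ Dc[:, pidx]) / (norms[t] * norms[pidx])
            if r * r >= tag_r2:
                exclude.add(int(t))
    tfs = assemble_tf_pgs(G, regions, weights, tf_id=tf_id, exclude_idx=exclude)
    if np.std(tfs.values) == 0:
        return (
            TFInteractionResult(
                np.nan, np.nan, 1.0, np.nan, np.nan, False, flag="pairwise_driven"
            ),
            None,
        )
    res = tf_interaction_test(
        g_focal, pgs_loco, tfs.loco[int(focal_chrom)], y, threshold
    )
    if not res.significant and not res.flag:
        res.flag = "pairwise_driven"
    return res, tfs
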