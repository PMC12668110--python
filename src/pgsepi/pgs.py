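"""Polygenic score construction.

Two clumping-and-thresholding (C+T) flavours are supported: a *loose* score
(clump r2 = 0.90) whose marginal weights are subsequently corrected for
double counting by an iterative joint-effect adjustment, and a *standard*
score (clump r2 = 0.10) used for score partitioning.  Both get 22
leave-one-chromosome-out (LOCO) versions so a focal SNP is never tested
against a score containing variants it is in LD with, and a data-driven mean
correction that linearises the score-phenotype map to absorb global
(non-specific) epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import t as t_dist

from .genotypes import GenotypeMatrix


@dataclass
class GWASResult:
    """Per-variant marginal association statistics."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        self.p = np.asarray(self.p, float)


@dataclass
class MeanCorrectionMap:
    """Piecewise-linear map from raw score to bin-mean phenotype.

    Knots are (per-bin score median, per-bin phenotype mean) after sorting
    individuals by score; beyond the terminal knots the terminal segment's
    slope is continued (flat clipping would manufacture interactions in the
    tails).
    """

    x_knots: np.ndarray
    y_knots: np.ndarray
    bin_sizes: np.ndarray

    def apply(self, pgs: np.ndarray) -> np.ndarray:
        x, yk = self.x_knots, self.y_knots
        out = np.interp(pgs, x, yk)
        if len(x) >= 2:
            lo_slope = (yk[1] - yk[0]) / (x[1] - x[0])
            hi_slope = (yk[-1] - yk[-2]) / (x[-1] - x[-2])
            below = pgs < x[0]
            above = pgs > x[-1]
            out[below] = yk[0] + lo_slope * (pgs[below] - x[0])
            out[above] = yk[-1] + hi_slope * (pgs[above] - x[-1])
        return out


@dataclass
class PGSModel:
    """A set of score variants with (possibly adjusted) weights.

    ``loco[k]`` is the per-individual score over all variants *not* on
    chromosome k; ``score_full`` sums every variant, so
    ``score_full = loco[k] + partial_k`` exactly for every k.
    """

    variant_idx: np.ndarray
    weights: np.ndarray
    clump_r2: float
    p_threshold: float
    loco: dict[int, np.ndarray] = field(default_factory=dict)
    score_full: np.ndarray | None = None


def marginal_gwas(G: GenotypeMatrix, y: np.ndarray) -> GWASResult:
    """Simple per-variant regression of the phenotype on each dosage.

    Vectorised over variants; two-sided p from the t reference with n-2 dof.
    Zero-variance variants are flagged with beta 0, se inf, p 1.
    """
    D = G.imputed()
    y = np.asarray(y, float)
    n = len(y)
    gm = D.mean(0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", D, D) - n * gm**2
    sxy = D.T @ yc
    ok = sxx > 1e-12
    beta = np.zeros(G.n_variants)
    se = np.full(G.n_variants, np.inf)
    p = np.ones(G.n_variants)
    beta[ok] = sxy[ok] / sxx[ok]
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta[ok] ** 2 * sxx[ok], 0.0)
    sigma2 = rss / (n - 2)
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tv = beta[ok] / se[ok]
    p[ok] = 2.0 * t_dist.sf(np.abs(tv), n - 2)
    # guard exact fits where p underflows to 0: keep in (0, 1]
    p[ok] = np.maximum(p[ok], np.finfo(float).tiny)
    return GWASResult(beta, se, p)


def _centered(G: GenotypeMatrix) -> np.ndarray:
    D = G.imputed()
    return D - D.mean(0)


def clump_and_threshold(
    G: GenotypeMatrix,
    result: GWASResult,
    r2_threshold: float = 0.90,
    p_threshold: float = 5e-8,
    window: int = 1_000_000,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Greedy LD clumping: retain sub-threshold variants whose genotype r2
    with every already-retained variant within +-1 Mb is <= ``r2_threshold``.

    Variants are visited in order of increasing p (ties broken by chromosome
    then position for determinism).  Retention of a variant depends only on
    more-significant variants, so the retained set at a stricter threshold
    is exactly the sub-threshold subset of the retained set at a looser one.
    Returns retained variant indices sorted by genomic coordinate.
    """
    cand = np.where(result.p <= p_threshold)[0]
    if cand.size == 0:
        return np.array([], dtype=int)
    order = cand[np.lexsort((G.pos[cand], G.chrom[cand], result.p[cand]))]
    if _precomputed is None:
        Dc = _centered(G)
        norms = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
    else:
        Dc, norms = _precomputed
    pos = G.pos.astype(np.int64)
    by_chrom: dict[int, list[int]] = {}
    for j in order:
        near = [
            k
            for k in by_chrom.get(int(G.chrom[j]), [])
            if abs(pos[k] - pos[j]) <= window and norms[k] > 0
        ]
        if near and norms[j] > 0:
            dots = Dc[:, near].T @ Dc[:, j]
            r2 = (dots / (norms[near] * norms[j])) ** 2
            if np.any(r2 > r2_threshold):
                continue
        by_chrom.setdefault(int(G.chrom[j]), []).append(int(j))
    retained = sorted(j for lst in by_chrom.values() for j in lst)
    return np.array(retained, dtype=int)


DEFAULT_P_GRID = (5e-8, 1e-6, 1e-5, 1e-4, 1e-3)


def select_p_threshold(
    G: GenotypeMatrix,
    y: np.ndarray,
    candidates: tuple[float, ...] = DEFAULT_P_GRID,
    r2_threshold: float = 0.90,
    heldout_fraction: float = 0.1,
    seed: int = 0,
) -> float:
    """Pick the C+T p-value threshold by held-out predictive performance.

    The sample is split (default 90/10, seeded); for each candidate
    threshold a score is built from training-sample marginal effects after
    clumping, and the threshold maximising the squared correlation between
    the held-out phenotype and the score is returned.  If no variant passes
    any candidate, the loosest candidate is returned.
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("candidate threshold grid is empty")
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    n = len(y)
    ho = rng.choice(n, size=max(1, int(round(heldout_fraction * n))), replace=False)
    tr = np.setdiff1d(np.arange(n), ho)
    Gtr = GenotypeMatrix(
        G.dosages[tr], G.chrom, G.pos, G.variant_id, G.maf, G.info, G.missing_rate
    )
    res = marginal_gwas(Gtr, y[tr])
    D = G.imputed()
    # one clumping pass at the loosest candidate; stricter candidates are
    # its sub-threshold subsets (greedy retention is prefix-stable in p)
    Dtr = Gtr.imputed()
    Dtr = Dtr - Dtr.mean(0)
    norms = np.sqrt(np.einsum("ij,ij->j", Dtr, Dtr))
    loosest = clump_and_threshold(
        Gtr, res, r2_threshold, max(candidates), _precomputed=(Dtr, norms)
    )
    best_t, best_r2 = candidates[0], -np.inf
    for thr in sorted(candidates):
        sel = loosest[res.p[loosest] <= thr]
        if sel.size == 0:
            continue
        score = D[ho][:, sel] @ res.beta[sel]
        if score.std() == 0 or y[ho].std() == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(score, y[ho])[0, 1]) ** 2
        if r2 > best_r2:
            best_t, best_r2 = thr, r2
    if best_r2 == -np.inf:
        best_t = max(candidates)
    return best_t


def adjust_joint_effects(
    G: GenotypeMatrix,
    variant_idx: np.ndarray,
    marginal_weights: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    clump_r2: float = 0.90,
    p_threshold: float = 5e-8,
) -> PGSModel:
    """Correct marginal C+T weights for double counting of correlated
    neighbours by cyclic coordinate descent towards the joint OLS fit.

    Each sweep refits every variant against the residual of the current
    score excluding that variant; iteration stops when the largest absolute
    weight update falls below ``tol``.  For a full-rank (centered) design
    this converges to the multiple-regression solution, which guarantees
    that a residual GWAS of ``y - score`` on the score's variants is
    genome-wide non-significant by construction.  Loose clumping admits
    neighbour pairs at r2 up to 0.9, where cyclic descent can contract
    slowly; if the sweep cap is reached the adjustment is completed at the
    same limit point by solving the normal equations directly, so the
    construction guarantee always holds.
    """
    variant_idx = np.asarray(variant_idx, dtype=int)
    w = np.asarray(marginal_weights, float).copy()
    y = np.asarray(y, float)
    Dc = _centered(G)[:, variant_idx]
    yc = y - y.mean()
    # precompute the Gram matrix so each coordinate update is O(m): the
    # update (g_j . r)/(g_j . g_j) equals (Xty_j - gram_j . w)/gram_jj
    gram = Dc.T @ Dc
    xty = Dc.T @ yc
    norms2 = np.diag(gram).copy()
    converged = False
    for _ in range(max_sweeps):
        max_step = 0.0
        for j in range(len(w)):
            if norms2[j] <= 1e-12:
                continue
            step = (xty[j] - gram[j] @ w) / norms2[j]
            if step != 0.0:
                w[j] += step
            max_step = max(max_step, abs(step))
        if max_step < tol:
            converged = True
            break
    if not converged:
        # same limit point, computed directly (min-norm under collinearity)
        w, *_ = np.linalg.lstsq(gram, xty, rcond=None)
    return PGSModel(
        variant_idx=variant_idx,
        weights=w,
        clump_r2=clump_r2,
        p_threshold=p_threshold,
    )


def build_loco_scores(model: PGSModel, G: GenotypeMatrix) -> PGSModel:
    """Populate per-chromosome leave-one-chromosome-out scores.

    ``loco[k]`` excludes every score variant on chromosome k; the full score
    decomposes exactly as loco[k] + chromosome-k partial for every k.
    """
    D = G.imputed()
    chroms = np.unique(G.chrom)
    full = D[:, model.variant_idx] @ model.weights
    model.score_full = full
    model.loco = {}
    v_chrom = G.chrom[model.variant_idx]
    for k in chroms:
        on_k = v_chrom == k
        if not on_k.any():
            model.loco[int(k)] = full.copy()
        else:
            partial = D[:, model.variant_idx[on_k]] @ model.weights[on_k]
            model.loco[int(k)] = full - partial
    return model


def _mean_correction_bins(
    n: int, interior: int = 1000, tail_bins: int = 20, tail_size: int = 50
) -> np.ndarray:
    """Bin sizes for the mean correction: ``tail_bins`` small bins of
    ``tail_size`` at each end, interior bins of ``interior`` (the last
    interior bin absorbs any remainder).  For samples too small for the full
    scheme, all three knobs are scaled proportionally."""
    full_n = 2 * tail_bins * tail_size + 2 * interior
    if n < full_n:
        f = n / full_n
        tail_size = max(1, int(round(tail_size * f)))
        tail_bins = max(2, int(round(tail_bins * min(1.0, 2 * f))))
        interior = max(4 * tail_size, int(round(interior * f)))
        while 2 * tail_bins * tail_size + interior > n and tail_bins > 2:
            tail_bins -= 1
        if 2 * tail_bins * tail_size + interior > n:
            raise ValueError(f"sample of {n} too small for mean correction")
    mid = n - 2 * tail_bins * tail_size
    n_interior = max(1, mid // interior)
    sizes = [tail_size] * tail_bins + [interior] * n_interior + [tail_size] * tail_bins
    sizes[tail_bins + n_interior - 1] += mid - n_interior * interior
    if len(sizes) < 4:
        raise ValueError("fewer than 4 mean-correction bins constructible")
    return np.asarray(sizes)


def mean_correct(
    pgs: np.ndarray,
    y: np.ndarray,
    interior: int = 1000,
    tail_bins: int = 20,
    tail_size: int = 50,
) -> tuple[np.ndarray, MeanCorrectionMap]:
    """Replace each individual's score by the interpolated bin-mean phenotype.

    Individuals are sorted by score and split into 20 bins of 50 at each
    tail with interior bins of 1000 (scaled down proportionally for small
    samples); knots are the per-bin score median and phenotype mean; each
    score is replaced by piecewise-linear interpolation at its value.  This
    linearises any smooth monotone score-phenotype map, removing global
    non-linearity as a source of spurious interactions.
    """
    pgs = np.asarray(pgs, float)
    y = np.asarray(y, float)
    n = len(pgs)
    sizes = _mean_correction_bins(n, interior, tail_bins, tail_size)
    order = np.argsort(pgs, kind="stable")
    edges = np.concatenate([[0], np.cumsum(sizes)])
    xs, ys = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        idx = order[a:b]
        xs.append(np.median(pgs[idx]))
        ys.append(y[idx].mean())
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    # collapse tied x-knots (possible with heavily tied scores)
    ux, inv = np.unique(xs, return_inverse=True)
    if len(ux) < len(xs):
        uy = np.array([ys[inv == i].mean() for i in range(len(ux))])
        xs, ys = ux, uy
    if len(xs) < 2:
        raise ValueError("mean correction requires at least 2 distinct knots")
    cmap = MeanCorrectionMap(xs, ys, sizes)
    return cmap.apply(pgs), cmap
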