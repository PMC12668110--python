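"""Quantitative-trait simulation: null architecture grid and planted gene-gene
interactions driven by focal SNPs.

Two frameworks are provided.  The *null* framework enumerates a 72-scenario
grid of additive architectures (polygenicity x causal positioning x
frequency-coupled effect sizes x global non-linearity x heritability) used to
measure false-positive rates of interaction tests.  The *interaction*
framework plants epistatic effects between 22 focal "left-hand side" (LHS)
SNPs and subsets of a 1000-SNP additive architecture, producing eight traits
that vary in interaction magnitude and frequency adjustment of effect sizes,
used to measure power and coefficient recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

N_CAUSAL_LEVELS = (100, 1000, 10000)
POSITIONING_LEVELS = ("random", "clustered")
FREQ_ADJUST_LEVELS = ("none", "ldak")
TRANSFORM_LEVELS = ("none", "sigmoid_before_noise", "sigmoid_after_noise")
HERITABILITY_LEVELS = (0.30, 0.60)

INTERACTION_MAGNITUDES = (0.01, 0.10, 0.50, 1.00)
RHS_SET_SIZES = (1, 20, 100, 1000)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the null simulation grid."""

    n_causal: int
    positioning: str
    freq_adjust: str
    transform: str
    heritability: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal not in N_CAUSAL_LEVELS:
            raise ValueError(f"n_causal must be one of {N_CAUSAL_LEVELS}")
        if self.positioning not in POSITIONING_LEVELS:
            raise ValueError(f"positioning must be one of {POSITIONING_LEVELS}")
        if self.freq_adjust not in FREQ_ADJUST_LEVELS:
            raise ValueError(f"freq_adjust must be one of {FREQ_ADJUST_LEVELS}")
        if self.transform not in TRANSFORM_LEVELS:
            raise ValueError(f"transform must be one of {TRANSFORM_LEVELS}")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")


@dataclass
class PhenotypeVector:
    """Per-individual trait values with their processing stage.

    ``stage`` moves only forward through raw -> residual -> int ->
    pgs_adjusted.  For simulated traits, ``true_components`` records the
    additive genetic part, the interaction part, the noise part and the
    realized additive heritability.
    """

    values: np.ndarray
    stage: str = "raw"
    true_components: dict = field(default_factory=dict)

    _STAGES = ("raw", "residual", "int", "pgs_adjusted")

    def advance(self, values: np.ndarray, stage: str) -> "PhenotypeVector":
        if self._STAGES.index(stage) <= self._STAGES.index(self.stage):
            raise ValueError(f"stage may only move forward, {self.stage} -> {stage}")
        return PhenotypeVector(np.asarray(values, float), stage, self.true_components)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class InteractionDesign:
    """22 focal LHS SNPs, their RHS target sets, signs and shared magnitude grid.

    Categories: 8 LHS with a direct effect (drawn from the causal set), 8
    without, and 6 "biased" LHS without a direct effect whose targets are
    predominantly (4:1) positive-effect causal SNPs.
    """

    lhs_snps: np.ndarray          # variant indices, length 22
    category: np.ndarray          # {"direct","no_direct","biased"}
    rhs_sets: list                # list of index arrays
    sign: np.ndarray              # +1/-1 per LHS
    causal_idx: np.ndarray        # the 1000 causal variant indices
    causal_effects: np.ndarray    # unadjusted N(0,1) effects of the causal set
    freq_adjust_levels: tuple = FREQ_ADJUST_LEVELS
    magnitudes: tuple = INTERACTION_MAGNITUDES

    def __post_init__(self) -> None:
        if len(self.lhs_snps) != 22:
            raise ValueError("design must contain exactly 22 LHS SNPs")
        counts = {c: int(np.sum(self.category == c)) for c in
                  ("direct", "no_direct", "biased")}
        if (counts["direct"], counts["no_direct"], counts["biased"]) != (8, 8, 6):
            raise ValueError(f"category counts must be 8/8/6, got {counts}")
        causal = set(self.causal_idx.tolist())
        for rhs in self.rhs_sets:
            if not set(np.asarray(rhs).tolist()) <= causal:
                raise ValueError("every RHS set must be a subset of the causal set")


def enumerate_null_grid(base_seed: int = 0) -> list[SimulationConfig]:
    """All 72 null-architecture configurations, deterministically ordered.

    The grid is the full cross-product 3 (polygenicity) x 2 (positioning) x
    2 (frequency adjustment) x 3 (transform) x 2 (heritability).  Each config
    receives a distinct seed derived from ``base_seed``.
    """
    configs = []
    for i, (nc, pos, fa, tr, h2) in enumerate(
        itertools.product(
            N_CAUSAL_LEVELS,
            POSITIONING_LEVELS,
            FREQ_ADJUST_LEVELS,
            TRANSFORM_LEVELS,
            HERITABILITY_LEVELS,
        )
    ):
        configs.append(
            SimulationConfig(nc, pos, fa, tr, h2, seed=base_seed * 100 + i)
        )
    return configs


def _scaled_sigmoid(x: np.ndarray, steepness: float = 1.0) -> np.ndarray:
    """Logistic transform centred on the sample mean, rescaled to preserve the
    input's mean and variance.

    The logistic is applied on the standardized scale with the given
    steepness; the output is then affinely mapped back so that its first two
    sample moments match the input's, which keeps heritability bookkeeping
    interpretable while leaving the non-linear shape intact.
    """
    mu, sd = x.mean(), x.std()
    u = 1.0 / (1.0 + np.exp(-steepness * (x - mu) / sd))
    su = u.std()
    if su == 0:
        return x.copy()
    return (u - u.mean()) * (sd / su) + mu


def _ldak_adjust(effects: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Scale effect sizes by [2p(1-p)]^-0.25 (frequency-coupled architecture)."""
    p = np.clip(maf, 1e-6, 0.5)
    return effects * (2.0 * p * (1.0 - p)) ** -0.25


def _place_causal(
    G: GenotypeMatrix, n_causal: int, positioning: str, rng: np.random.Generator
) -> np.ndarray:
    m = G.n_variants
    if n_causal > m:
        raise ValueError(f"n_causal={n_causal} exceeds variant count {m}")
    if positioning == "random":
        return rng.choice(m, size=n_causal, replace=False)

    # clustered: half into 1 Mb regions at an average density of five per
    # region (Poisson(5) truncated at 1), the rest at random
    half = n_causal // 2
    chosen: set[int] = set()
    chroms = np.unique(G.chrom)
    spans = {
        c: (G.pos[G.chrom == c].min(), G.pos[G.chrom == c].max()) for c in chroms
    }
    for c in chroms:
        if spans[c][1] - spans[c][0] < 1_000_000:
            raise ValueError(
                "clustered positioning requires chromosome spans of at least 1 Mb"
            )
    attempts = 0
    while len(chosen) < half and attempts < 10_000:
        attempts += 1
        c = rng.choice(chroms)
        lo_p, hi_p = spans[c]
        anchor = rng.integers(lo_p, hi_p)
        in_region = np.where(
            (G.chrom == c) & (G.pos >= anchor) & (G.pos < anchor + 1_000_000)
        )[0]
        in_region = np.array([i for i in in_region if i not in chosen])
        if in_region.size == 0:
            continue
        k = 0
        while k < 1:  # Poisson(5) truncated at >= 1
            k = rng.poisson(5)
        k = min(k, in_region.size, half - len(chosen))
        chosen.update(rng.choice(in_region, size=k, replace=False).tolist())
    rest_pool = np.setdiff1d(np.arange(m), np.fromiter(chosen, int, len(chosen)))
    rest = rng.choice(rest_pool, size=n_causal - len(chosen), replace=False)
    return np.sort(np.concatenate([np.fromiter(chosen, int, len(chosen)), rest]))


def _add_noise_to_h2(
    genetic: np.ndarray, h2: float, rng: np.random.Generator
) -> np.ndarray:
    """Return a noise vector scaled so the realized additive heritability
    Var(genetic)/Var(genetic + noise) equals ``h2`` exactly in-sample."""
    eps = rng.standard_normal(len(genetic))
    eps = eps - eps.mean()
    # remove the chance in-sample correlation with the genetic component so
    # the realized variance ratio is exact
    gc = genetic - genetic.mean()
    denom = float(gc @ gc)
    if denom > 0:
        eps = eps - (float(gc @ eps) / denom) * gc
    target_sd = genetic.std() * np.sqrt((1.0 - h2) / h2)
    return eps * (target_sd / eps.std())


def simulate_null_phenotype(
    config: SimulationConfig, G: GenotypeMatrix
) -> PhenotypeVector:
    """Simulate an additive (interaction-free) trait under one grid config.

    Causal SNPs are placed per ``config.positioning``; effects are standard
    Normal, optionally frequency-adjusted; the summed genetic component is
    standardized; a scaled sigmoid is applied before or after noise per
    ``config.transform``; noise is scaled so the realized additive
    heritability (before any post-noise transform) equals
    ``config.heritability`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    causal = _place_causal(G, config.n_causal, config.positioning, rng)
    beta = rng.standard_normal(config.n_causal)
    if config.freq_adjust == "ldak":
        beta = _ldak_adjust(beta, G.maf[causal])
    g = G.imputed()[:, causal] @ beta
    g = (g - g.mean()) / g.std()

    if config.transform == "sigmoid_before_noise":
        g = _scaled_sigmoid(g)
        g = (g - g.mean()) / g.std()
    eps = _add_noise_to_h2(g, config.heritability, rng)
    y = g + eps
    if config.transform == "sigmoid_after_noise":
        y = _scaled_sigmoid(y)

    h2_real = g.var() / (g + eps).var()
    return PhenotypeVector(
        values=y,
        stage="raw",
        true_components={
            "additive": g,
            "interaction": np.zeros_like(g),
            "noise": eps,
            "h2": h2_real,
            "causal_idx": causal,
            "effects": beta,
        },
    )


def build_interaction_design(
    G: GenotypeMatrix,
    causal_idx: np.ndarray,
    causal_effects: np.ndarray,
    seed: int = 0,
    maf_min: float = 0.05,
) -> InteractionDesign:
    """Select 22 focal LHS SNPs and their RHS target sets.

    8 LHS come from the causal set ("direct"), 8 from non-causal variants
    ("no_direct") and 6 from non-causal variants whose targets are drawn at a
    four-to-one proportion from positive-effect causal SNPs ("biased").  All
    LHS require MAF >= ``maf_min``.  RHS-set sizes cycle round-robin over
    {1, 20, 100, 1000} within each category; biased LHS cycle over
    {1, 20, 100} only, since the full causal set cannot satisfy the 4:1
    positive proportion.  Each LHS interacts with all its targets with one
    sign, drawn with equal probability.
    """
    causal_idx = np.asarray(causal_idx)
    causal_effects = np.asarray(causal_effects, float)
    if len(causal_idx) != 1000:
        raise ValueError("the causal set must contain exactly 1000 variants")
    rng = np.random.default_rng(seed)
    eligible = G.maf >= maf_min
    causal_pool = causal_idx[eligible[causal_idx]]
    noncausal_pool = np.setdiff1d(np.where(eligible)[0], causal_idx)
    if len(causal_pool) < 8 or len(noncausal_pool) < 14:
        raise ValueError("fewer than 22 eligible LHS candidates")

    direct = rng.choice(causal_pool, size=8, replace=False)
    others = rng.choice(noncausal_pool, size=14, replace=False)
    no_direct, biased = others[:8], others[8:]

    lhs = np.concatenate([direct, no_direct, biased])
    category = np.array(["direct"] * 8 + ["no_direct"] * 8 + ["biased"] * 6)
    sign = rng.choice([-1.0, 1.0], size=22)

    pos_mask = causal_effects > 0
    pos_causal, neg_causal = causal_idx[pos_mask], causal_idx[~pos_mask]

    rhs_sets: list[np.ndarray] = []
    size_cycle = {"direct": itertools.cycle(RHS_SET_SIZES),
                  "no_direct": itertools.cycle(RHS_SET_SIZES),
                  "biased": itertools.cycle((1, 20, 100))}
    for cat in category:
        s = next(size_cycle[cat])
        if cat == "biased":
            n_pos = int(round(0.8 * s))
            rhs = np.concatenate([
                rng.choice(pos_causal, size=n_pos, replace=False),
                rng.choice(neg_causal, size=s - n_pos, replace=False),
            ])
        elif s == 1000:
            rhs = causal_idx.copy()
        else:
            rhs = rng.choice(causal_idx, size=s, replace=False)
        rhs_sets.append(np.sort(rhs))

    return InteractionDesign(
        lhs_snps=lhs,
        category=category,
        rhs_sets=rhs_sets,
        sign=sign,
        causal_idx=causal_idx,
        causal_effects=causal_effects,
    )


def simulate_interaction_phenotypes(
    design: InteractionDesign,
    G: GenotypeMatrix,
    heritability: float = 0.30,
    seed: int = 0,
) -> list[PhenotypeVector]:
    """Generate the eight interaction traits sharing one causal architecture.

    Traits vary over frequency adjustment of effect sizes {none, ldak} and
    interaction magnitude c in {0.01, 0.1, 0.5, 1.0}.  The phenotype is

        y = sum_j beta_j g_j
          + sum_l sum_{j in RHS_l} sign_l * c * beta_j * g_l * g_j
          + noise,

    with beta on the scale where the additive component has unit variance, so
    a positive sign scales up (in absolute value) the effect of every RHS
    target.  Noise is scaled so the additive heritability equals
    ``heritability``.  Order: freq_adjust outer, magnitude inner.
    """
    rng = np.random.default_rng(seed)
    D = G.imputed()
    out: list[PhenotypeVector] = []
    for fa in design.freq_adjust_levels:
        beta = design.causal_effects.copy()
        if fa == "ldak":
            beta = _ldak_adjust(beta, G.maf[design.causal_idx])
        additive_raw = D[:, design.causal_idx] @ beta
        scale = additive_raw.std()
        beta_scaled = beta / scale
        additive = (additive_raw - additive_raw.mean()) / scale
        # positions of each RHS set within the causal array
        order = np.argsort(design.causal_idx)
        sorted_causal = design.causal_idx[order]
        for c in design.magnitudes:
            inter = np.zeros(G.n_individuals)
            for lhs, rhs, sgn in zip(design.lhs_snps, design.rhs_sets, design.sign):
                pos_in_causal = order[np.searchsorted(sorted_causal, rhs)]
                coefs = sgn * c * beta_scaled[pos_in_causal]
                inter += D[:, lhs] * (D[:, rhs] @ coefs)
            eps = _add_noise_to_h2(additive, heritability, rng)
            y = additive + inter + eps
            out.append(
                PhenotypeVector(
                    values=y,
                    stage="raw",
                    true_components={
                        "additive": additive,
                        "interaction": inter,
                        "noise": eps,
                        "h2": additive.var() / (additive + eps).var(),
                        "freq_adjust": fa,
                        "magnitude": c,
                        "effects_scaled": beta_scaled,
                        "causal_idx": design.causal_idx,
                    },
                )
            )
    return out


def predicted_attenuated_delta(
    G: GenotypeMatrix,
    lhs: int,
    rhs_idx: np.ndarray,
    rhs_coefs: np.ndarray,
    pgs_values: np.ndarray,
    adjust_for: np.ndarray | None = None,
) -> float:
    """Expected fitted interaction coefficient when the focal SNP truly
    interacts only with a subset of the score's variants.

    The true interaction term u = g_lhs * sum_{j in S} c_j g_j is projected
    onto the fitted design [1, g, PGS, g x PGS]; the returned value is the
    g x PGS coefficient of that projection, i.e. the attenuation induced by
    testing against the whole score.  When S spans the whole score with the
    score's own weights, this is the unattenuated coefficient.

    ``adjust_for`` optionally lists extra columns (e.g. the full
    non-LOCO score) that the analysis regresses out of the dependent
    variable before scanning; the same projection is then applied to u, so
    the prediction matches what the scan actually estimates.
    """
    rhs_idx = np.asarray(rhs_idx)
    if rhs_idx.size == 0:
        raise ValueError("RHS subset must be non-empty")
    D = G.imputed()
    g = D[:, lhs]
    u = g * (D[:, rhs_idx] @ np.asarray(rhs_coefs, float))
    if adjust_for is not None:
        A = np.asarray(adjust_for, float)
        if A.ndim == 1:
            A = A[:, None]
        A = np.column_stack([np.ones(len(u)), A])
        coef_a, *_ = np.linalg.lstsq(A, u, rcond=None)
        u = u - A @ coef_a
    X = np.column_stack([np.ones_like(g), g, pgs_values, g * pgs_values])
    coef, *_ = np.linalg.lstsq(X, u, rcond=None)
    return float(coef[3])
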