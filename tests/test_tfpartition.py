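"""Region tagging, Bayes factors, enrichment estimation, motif scoring,
odds calibration, score assembly and the six-term interaction test."""

import numpy as np
import pytest

from pgsepi import (
    MotifModel,
    Region,
    approximate_bayes_factors,
    assemble_tf_pgs,
    calibrate_motif_odds,
    compute_weights,
    define_regions,
    fit_annotation_alpha,
    generate_genotypes,
    motif_best_score,
    pairwise_driver_check,
    select_best_dataset,
    tf_interaction_test,
)
from pgsepi.tfpartition import reverse_complement


class TestRegions:
    def test_isolated_hit_is_singleton(self):
        G = generate_genotypes(800, 50, 5, block_rho=0.0, seed=1)
        regions = define_regions(G, [7])
        assert len(regions[0].tag_idx) == 1 and regions[0].driver_idx == 7

    def test_tags_match_brute_force_r2(self, ld_panel):
        G = ld_panel
        D = G.imputed()
        hit = 100
        regions = define_regions(G, [hit], r2=0.75)
        expected = [hit]
        for j in range(G.n_variants):
            if j == hit or abs(int(G.pos[j]) - int(G.pos[hit])) > 1_000_000:
                continue
            r = np.corrcoef(D[:, j], D[:, hit])[0, 1]
            if r * r >= 0.75:
                expected.append(j)
        assert sorted(regions[0].tag_idx.tolist()) == sorted(expected)

    def test_driver_always_included(self, ld_panel):
        regions = define_regions(ld_panel, [3, 50, 200])
        for r in regions:
            assert r.driver_idx in r.tag_idx


class TestBayesFactors:
    def test_singleton_region_normalizes_to_one(self):
        bf = approximate_bayes_factors(np.array([0.1]), np.array([0.02]))
        assert bf[0] == pytest.approx(1.0)

    def test_identical_tags_split_evenly(self):
        bf = approximate_bayes_factors(np.array([0.1, 0.1]), np.array([0.02, 0.02]))
        np.testing.assert_allclose(bf, [0.5, 0.5])

    def test_matches_closed_form(self):
        """Hand evaluation of the Wakefield ABF for z = (6, 4, 1), se=0.02,
        W=0.04."""
        se = np.full(3, 0.02)
        z = np.array([6.0, 4.0, 1.0])
        beta = z * se
        bf = approximate_bayes_factors(beta, se, prior_variance=0.04)
        V = se**2
        raw = np.sqrt(V / (V + 0.04)) * np.exp(0.5 * z**2 * 0.04 / (V + 0.04))
        np.testing.assert_allclose(bf, raw / raw.sum(), rtol=1e-10)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            approximate_bayes_factors(np.array([0.1]), np.array([0.0]))


def _simulate_regions(alpha, n_regions, rng, annot_rate=0.3, se=0.02, W=0.04):
    """Generate regions from the stated prior model: one causal tag per
    region with probability proportional to 1 + a(alpha - 1); the causal
    tag's z is drawn from the marginal implied by the effect prior W."""
    regions = []
    for _ in range(n_regions):
        k = int(rng.integers(3, 9))
        a = (rng.random(k) < annot_rate).astype(float)
        prior = 1.0 + a * (alpha - 1.0)
        causal = rng.choice(k, p=prior / prior.sum())
        z = rng.normal(0.0, 1.0, k)
        z[causal] = rng.normal(0.0, np.sqrt(1.0 + W / se**2))
        beta = z * se
        bf = approximate_bayes_factors(beta, np.full(k, se), W)
        regions.append(
            Region(driver_idx=0, tag_idx=np.arange(k), bf=bf, annotations={"a": a})
        )
    return regions


class TestAlphaEstimation:
    def test_null_annotation_gives_alpha_near_one(self):
        # 800 regions: the null sampling SD of log alpha-hat is ~0.1, so
        # the 0.2 bound is a ~2-sigma check
        rng = np.random.default_rng(10)
        regions = _simulate_regions(1.0, 800, rng)
        est = fit_annotation_alpha(regions, "a")
        assert abs(np.log(est.alpha)) < 0.2

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(11)
        regions = _simulate_regions(5.0, 500, rng)
        est = fit_annotation_alpha(regions, "a")
        assert 3.5 <= est.alpha <= 7.0

    def test_likelihood_never_below_null(self):
        rng = np.random.default_rng(12)
        regions = _simulate_regions(2.0, 50, rng)
        est = fit_annotation_alpha(regions, "a")
        from pgsepi.tfpartition import _region_loglik

        ll_null = _region_loglik(0.0, [r.bf for r in regions],
                                 [r.annotations["a"] for r in regions])
        assert est.loglik >= ll_null - 1e-9

    def test_constant_annotation_unidentifiable(self):
        rng = np.random.default_rng(13)
        regions = _simulate_regions(1.0, 20, rng, annot_rate=2.0)  # all annotated
        est = fit_annotation_alpha(regions, "a")
        assert est.alpha == 1.0 and est.flag == "unidentifiable"

    def test_single_region_max_bf_annotation_hits_boundary(self):
        bf = np.array([0.9, 0.05, 0.05])
        a = np.array([1.0, 0.0, 0.0])
        region = Region(driver_idx=0, tag_idx=np.arange(3), bf=bf, annotations={"a": a})
        est = fit_annotation_alpha([region], "a")
        assert est.flag == "boundary"
        assert est.alpha == pytest.approx(100.0, rel=1e-2)


class TestDatasetSelection:
    def test_singleton_returned(self):
        rng = np.random.default_rng(14)
        regions = _simulate_regions(3.0, 100, rng)
        values = [r.annotations["a"] for r in regions]
        ds, est = select_best_dataset(regions, {"only": values}, "h1")
        assert ds == "only"

    def test_true_generating_dataset_preferred(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            regions = _simulate_regions(5.0, 150, rng)
            true_vals = [r.annotations["a"] for r in regions]
            noise_vals = [
                (rng.random(len(r.tag_idx)) < 0.3).astype(float) for r in regions
            ]
            ds, _ = select_best_dataset(
                regions, {"true": true_vals, "noise": noise_vals}, "h1"
            )
            wins += ds == "true"
        assert wins >= 18  # >= 90% of seeded replicates

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_dataset([], {}, "h1")


def _brute_force_best(window, motif, snp_offset, alleles):
    """Exhaustive enumeration over alleles, strands and placements."""
    lo = motif.log_odds
    L = motif.length
    col_min = lo.min(axis=1)
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    best = -np.inf
    for al in alleles:
        seq = window[:snp_offset] + al + window[snp_offset + 1:]
        for s, centre in ((seq, snp_offset), (reverse_complement(seq), len(seq) - 1 - snp_offset)):
            for start in range(0, len(s) - L + 1):
                if not (start <= centre <= start + L - 1):
                    continue
                score = 0.0
                for k in range(L):
                    b = lookup.get(s[start + k].upper(), -1)
                    score += lo[k, b] if b >= 0 else col_min[k]
                best = max(best, score)
    return best


@pytest.fixture(scope="module")
def toy_motif():
    counts = np.array(
        [[12, 1, 1, 1], [1, 12, 1, 1], [1, 1, 12, 1], [1, 1, 1, 12],
         [12, 1, 1, 1], [1, 12, 1, 1], [12, 1, 1, 1], [1, 1, 1, 12],
         [1, 1, 12, 1], [12, 1, 1, 1], [1, 12, 1, 1], [1, 1, 12, 1]]
    )  # 12-bp consensus ACGTACATGACG
    return MotifModel("TOY", "TOY_TF", counts)


class TestMotifScoring:
    def test_consensus_at_centre_reaches_max(self, toy_motif):
        consensus = "ACGTACATGACG"
        win = "T" * 24 + consensus + "T" * 24
        s = motif_best_score(win, toy_motif, snp_offset=30)
        assert s == pytest.approx(toy_motif.max_score())

    def test_strand_symmetry(self, toy_motif, rng):
        bases = np.array(list("ACGT"))
        win = "".join(rng.choice(bases, 60))
        s_fwd = motif_best_score(win, toy_motif, snp_offset=30)
        s_rev = motif_best_score(reverse_complement(win), toy_motif, snp_offset=29)
        assert s_fwd == pytest.approx(s_rev)

    def test_matches_brute_force_enumeration(self, toy_motif, rng):
        bases = np.array(list("ACGT"))
        for _ in range(10):
            win = "".join(rng.choice(bases, 60))
            alleles = tuple(rng.choice(bases, 2, replace=False))
            got = motif_best_score(win, toy_motif, snp_offset=30, alleles=alleles)
            want = _brute_force_best(win, toy_motif, 30, alleles)
            assert got == pytest.approx(want)

    def test_padding_invariance(self, toy_motif, rng):
        """Scores depend only on placements overlapping the SNP, so flanking
        sequence beyond the motif's reach cannot change the result."""
        bases = np.array(list("ACGT"))
        win = "".join(rng.choice(bases, 60))
        s60 = motif_best_score(win, toy_motif, snp_offset=30)
        padded = "A" * 20 + win + "C" * 20
        s100 = motif_best_score(padded, toy_motif, snp_offset=50)
        assert s60 == pytest.approx(s100)

    def test_window_shorter_than_motif(self, toy_motif):
        assert motif_best_score("ACGT", toy_motif, snp_offset=2) == -np.inf


class TestOddsCalibration:
    def test_identical_backgrounds_give_unit_odds(self, rng):
        x = rng.normal(0, 1, 1000)
        cal = calibrate_motif_odds(x, x)
        for s in (-2.0, 0.0, 2.0):
            assert cal.odds(s) == pytest.approx(1.0, abs=0.05)

    def test_floor_below_minimum(self, rng):
        cal = calibrate_motif_odds(rng.normal(5, 1, 600), rng.normal(0, 1, 600))
        assert cal.odds(-100.0) == 1.0
        assert cal.odds(-np.inf) == 1.0

    def test_monotone_and_at_least_one(self, rng):
        cal = calibrate_motif_odds(rng.normal(1, 2, 800), rng.normal(0, 1, 800))
        assert np.all(np.diff(cal.odds_at_grid) >= -1e-12)
        assert np.all(cal.odds_at_grid >= 1.0)

    def test_planted_motif_enrichment(self, toy_motif, rng):
        """Enhancer windows carry the consensus 20% of the time; the odds at
        the consensus score exceed 3."""
        bases = np.array(list("ACGT"))
        consensus = "ACGTACATGACG"

        def window(with_motif):
            s = "".join(rng.choice(bases, 60))
            if with_motif:
                s = s[:24] + consensus + s[36:]
            return s

        enh = [motif_best_score(window(rng.random() < 0.2), toy_motif, 30)
               for _ in range(600)]
        non = [motif_best_score(window(False), toy_motif, 30) for _ in range(600)]
        cal = calibrate_motif_odds(np.array(enh), np.array(non))
        assert cal.odds(toy_motif.max_score()) > 3.0

    def test_degenerate_backgrounds(self):
        cal = calibrate_motif_odds(np.zeros(10), np.zeros(10))
        assert cal.odds(0.0) == 1.0


class TestWeights:
    def test_all_alphas_one_gives_unit_weights(self):
        w = compute_weights(
            np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0]),
            np.array([2.0, 5.0]),
        )
        np.testing.assert_allclose(w, 1.0)

    def test_single_factor_arithmetic(self):
        w = compute_weights(
            np.array([1.0]), np.array([0.0]), np.array([0.0]), None,
            alpha_coding=3.0,
        )
        assert w[0] == pytest.approx(3.0)

    def test_joint_formula_example(self):
        # (1 + (2-1)(4-1) + 0) * (1 + 1*(2-1)) * 1 = 8
        w = compute_weights(
            np.array([0.0]), np.array([1.0]), np.array([0.0]), np.array([2.0]),
            alpha_motif=4.0, alpha_h1=2.0,
        )
        assert w[0] == pytest.approx(8.0)

    def test_negative_factor_floored(self):
        w = compute_weights(
            np.array([1.0]), np.array([0.0]), np.array([0.0]), None,
            alpha_coding=0.0,  # factor would be 0; never negative
        )
        assert w[0] == 0.0
        w2 = compute_weights(
            np.array([0.0]), np.array([0.0]), np.array([0.0]), np.array([10.0]),
            alpha_motif=0.5,
        )
        assert w2[0] == 0.0  # 1 + 9*(-0.5) = -3.5 -> floored


class TestScoreAssembly:
    def _regions_and_weights(self, G, rng, n_regions=5):
        drivers = rng.choice(G.n_variants, n_regions, replace=False)
        regions = define_regions(G, drivers)
        weights = []
        for r in regions:
            k = len(r.tag_idx)
            r.bf = rng.dirichlet(np.ones(k))
            r.beta_driver = float(rng.normal())
            weights.append(rng.uniform(0.5, 2.0, k))
        return regions, weights

    def test_matches_double_summation_oracle(self, rng):
        G = generate_genotypes(400, 200, 4, seed=30)
        regions, weights = self._regions_and_weights(G, rng)
        tfs = assemble_tf_pgs(G, regions, weights)
        D = G.imputed()
        expected = np.zeros(400)
        for r, w in zip(regions, weights):
            for t, bf, wt in zip(r.tag_idx, r.bf, w):
                expected += bf * wt * r.beta_driver * D[:, t]
        np.testing.assert_allclose(tfs.values, expected, atol=1e-12)

    def test_loco_additivity(self, rng):
        G = generate_genotypes(300, 200, 4, seed=31)
        regions, weights = self._regions_and_weights(G, rng)
        tfs = assemble_tf_pgs(G, regions, weights)
        D = G.imputed()
        for k, loco in tfs.loco.items():
            partial = np.zeros(300)
            for r, w in zip(regions, weights):
                if int(G.chrom[r.driver_idx]) == k:
                    for t, bf, wt in zip(r.tag_idx, r.bf, w):
                        partial += bf * wt * r.beta_driver * D[:, t]
            np.testing.assert_allclose(loco + partial, tfs.values, atol=1e-12)

    def test_single_tag_weight_two(self):
        G = generate_genotypes(100, 20, 2, seed=32)
        r = Region(driver_idx=5, tag_idx=np.array([5]), bf=np.array([1.0]),
                   beta_driver=0.7)
        tfs = assemble_tf_pgs(G, [r], [np.array([2.0])])
        np.testing.assert_allclose(tfs.values, 2.0 * 0.7 * G.imputed()[:, 5])


class TestEq2Testing:
    def test_planted_eta_recovered(self):
        G = generate_genotypes(12000, 60, 3, seed=33)
        rng = np.random.default_rng(34)
        g = G.imputed()[:, int(np.where(G.maf >= 0.25)[0][0])]
        pgs = rng.standard_normal(12000)
        tfs_raw = rng.standard_normal(12000)
        # orthogonalise the TF score against the whole score
        tfs = tfs_raw - pgs * (pgs @ tfs_raw) / (pgs @ pgs)
        y = 0.3 * pgs + 0.2 * g * tfs + rng.standard_normal(12000)
        res = tf_interaction_test(g, pgs, tfs, y)
        assert abs(res.eta - 0.2) <= 2 * res.se_eta
        assert res.significant

    def test_tfs_equal_to_pgs_skipped(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        pgs = rng.standard_normal(500)
        res = tf_interaction_test(g, pgs, pgs.copy(), rng.standard_normal(500))
        assert res.flag == "collinear_with_pgs" and not res.significant

    def test_matches_six_term_ols_oracle(self, rng):
        import statsmodels.api as sm

        g = rng.binomial(2, 0.3, 100).astype(float)
        pgs = rng.standard_normal(100)
        tfs = rng.standard_normal(100)
        y = rng.standard_normal(100)
        res = tf_interaction_test(g, pgs, tfs, y)
        X = sm.add_constant(np.column_stack([g, pgs, g * pgs, tfs, g * tfs]))
        fit = sm.OLS(y, X).fit()
        assert abs(res.eta - fit.params[5]) < 1e-9
        assert abs(res.se_eta - fit.bse[5]) < 1e-9
        assert abs(res.p_eta - fit.pvalues[5]) < 1e-9

    def test_nesting_reduces_to_four_term_model(self, rng):
        """A phenotype generated exactly by the four-term whole-score model
        yields zeta = eta = 0 and the same delta in the six-term fit."""
        g = rng.binomial(2, 0.3, 300).astype(float)
        pgs = rng.standard_normal(300)
        tfs = rng.standard_normal(300)
        y = 0.5 + 0.3 * g + 0.7 * pgs + 0.2 * g * pgs  # noise-free, nested
        res = tf_interaction_test(g, pgs, tfs, y)
        assert abs(res.delta - 0.2) < 1e-10
        assert abs(res.zeta) < 1e-10
        assert abs(res.eta) < 1e-10


class TestPairwiseDriverCheck:
    def _setup(self, seed, spread):
        G = generate_genotypes(8000, 120, 4, block_rho=0.0, seed=seed)
        rng = np.random.default_rng(seed + 1)
        focal = int(np.where((G.chrom == 1) & (G.maf >= 0.25))[0][0])
        driver_pool = np.where((G.chrom >= 2) & (G.maf >= 0.1))[0]
        n_regions = 30 if spread else 1
        drivers = driver_pool[:: max(1, len(driver_pool) // n_regions)][:n_regions]
        regions = define_regions(G, drivers)
        weights = [np.ones(len(r.tag_idx)) for r in regions]
        for r in regions:
            r.beta_driver = 0.1
        return G, rng, focal, regions, weights

    def test_signal_from_single_partner_flagged_pairwise_driven(self):
        G, rng, focal, regions, weights = self._setup(60, spread=False)
        D = G.imputed()
        partner = regions[0].driver_idx
        g, gp = D[:, focal], D[:, partner]
        y = 0.25 * g * gp + rng.standard_normal(8000)
        pgs = rng.standard_normal(8000)
        res, _ = pairwise_driver_check(
            G, regions, weights, g, pgs, y,
            pairwise_partner_idx=np.array([partner]),
            focal_chrom=int(G.chrom[focal]),
        )
        assert not res.significant
        assert res.flag == "pairwise_driven"

    def test_spread_signal_survives_partner_removal(self):
        G, rng, focal, regions, weights = self._setup(61, spread=True)
        D = G.imputed()
        tfs0 = assemble_tf_pgs(G, regions, weights)
        g = D[:, focal]
        pgs = rng.standard_normal(8000)
        t = tfs0.loco[int(G.chrom[focal])]
        t = (t - t.mean()) / t.std()
        y = 0.15 * g * t + rng.standard_normal(8000)
        outside_partner = int(np.where((G.chrom == 1) & (G.maf >= 0.1))[0][-1])
        res, _ = pairwise_driver_check(
            G, regions, weights, g, pgs, y,
            pairwise_partner_idx=np.array([outside_partner]),
            focal_chrom=int(G.chrom[focal]),
        )
        assert res.significant

    def test_no_partners_is_identity(self):
        G, rng, focal, regions, weights = self._setup(62, spread=True)
        D = G.imputed()
        g = D[:, focal]
        pgs = rng.standard_normal(8000)
        y = rng.standard_normal(8000)
        tfs = assemble_tf_pgs(G, regions, weights)
        direct = tf_interaction_test(g, pgs, tfs.loco[int(G.chrom[focal])], y)
        res, _ = pairwise_driver_check(
            G, regions, weights, g, pgs, y,
            pairwise_partner_idx=np.array([], int),
            focal_chrom=int(G.chrom[focal]),
        )
        assert res.eta == pytest.approx(direct.eta)
        assert res.p_eta == pytest.approx(direct.p_eta)
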