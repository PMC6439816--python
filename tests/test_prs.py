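"""Scoring, clumping, PCA covariates, GEE inference and FDR control."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from twinprs.io import GenotypeData
from twinprs.prs import (
    GenotypePCA,
    PrsScorer,
    exclude_diagnosed,
    fdr_adjust,
    gee_associate,
    harmonize_alleles,
    ld_clump,
    score_prs,
)
from twinprs.simulate import (
    attach_genetic_phenotype,
    draw_causal_effects,
    simulate_genotypes,
    simulate_twin_pairs,
)
from twinprs.types import ClumpSpec, PolygenicSpec

from conftest import make_ae_spec


def _geno(dosages, positions=None, alleles=None, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(m)],
        "chrom": "1", "pos": positions,
        "allele1": [a for a, _ in alleles],
        "allele2": [b for _, b in alleles],
    })
    return GenotypeData(ids=ids or [f"i{k}" for k in range(n)],
                        variants=variants, dosages=dosages)


def _sumstats(ids, betas, ps, ea="A", oa="G", pos=None):
    m = len(ids)
    return pd.DataFrame({
        "id": ids, "chrom": ["1"] * m,
        "pos": pos if pos is not None else 1000 * (np.arange(m) + 1),
        "effect_allele": [ea] * m if isinstance(ea, str) else ea,
        "other_allele": [oa] * m if isinstance(oa, str) else oa,
        "beta": betas, "se": [0.01] * m, "p": ps, "n": [10_000] * m,
    })


class TestHarmonize:
    def test_swap_flips_sign_and_ambiguous_dropped(self, rng):
        geno = _geno(rng.integers(0, 3, size=(20, 5)),
                     alleles=[("A", "G"), ("G", "A"), ("A", "T"),
                              ("C", "G"), ("C", "T")])
        ss = _sumstats(["rs1", "rs2", "rs3", "rs4", "rs5", "rs9"],
                       [0.1] * 6, [0.5] * 6,
                       ea=["A", "A", "A", "C", "C", "A"],
                       oa=["G", "G", "T", "G", "T", "G"],
                       pos=[1000, 2000, 3000, 4000, 5000, 9000])
        out = harmonize_alleles(ss, geno)
        # rs3 (A/T) and rs4 (C/G) ambiguous, rs9 absent -> 3 rows
        assert list(out["id"]) == ["rs1", "rs2", "rs5"]
        assert out.loc[out["id"] == "rs2", "beta"].iloc[0] == pytest.approx(-0.1)
        assert out.loc[out["id"] == "rs1", "beta"].iloc[0] == pytest.approx(0.1)

    def test_zero_overlap_error(self, rng):
        geno = _geno(rng.integers(0, 3, size=(5, 2)))
        ss = _sumstats(["rsX"], [0.1], [0.5])
        with pytest.raises(ValueError, match="overlap"):
            harmonize_alleles(ss, geno)


class TestClump:
    def _correlated_geno(self, rng, n=400):
        a = rng.integers(0, 3, size=n).astype(float)
        b = a.copy()
        flip = rng.random(n) < 0.25   # r2(a,b) well above 0.1
        b[flip] = rng.integers(0, 3, size=flip.sum())
        c = rng.integers(0, 3, size=n).astype(float)  # ~independent
        return _geno(np.column_stack([a, b, c]),
                     positions=[1000, 2000, 3000])

    def test_greedy_walkthrough(self, rng):
        geno = self._correlated_geno(rng)
        ss = _sumstats(["rs1", "rs2", "rs3"], [0.1, 0.1, 0.1],
                       [1e-8, 1e-4, 1e-3], pos=[1000, 2000, 3000])
        w = harmonize_alleles(ss, geno)
        out = ld_clump(w, geno, ClumpSpec(r2=0.1, window_kb=250))
        assert list(out["id"]) == ["rs1", "rs3"]

    def test_independent_all_retained(self, rng):
        geno = _geno(rng.integers(0, 3, size=(500, 4)))
        ss = _sumstats([f"rs{j}" for j in range(1, 5)], [0.1] * 4,
                       [0.1, 0.2, 0.3, 0.4])
        w = harmonize_alleles(ss, geno)
        out = ld_clump(w, geno, ClumpSpec(r2=0.1, window_kb=250))
        assert len(out) == 4

    def test_equal_p_tie_breaks_by_position(self, rng):
        a = rng.integers(0, 3, size=300).astype(float)
        geno = _geno(np.column_stack([a, a]), positions=[1000, 2000])
        ss = _sumstats(["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01],
                       pos=[1000, 2000])
        w = harmonize_alleles(ss, geno)
        out = ld_clump(w, geno, ClumpSpec(r2=0.1, window_kb=250))
        assert list(out["id"]) == ["rs1"]  # lower position wins

    def test_row_order_invariance(self, rng):
        geno = self._correlated_geno(rng)
        ss = _sumstats(["rs1", "rs2", "rs3"], [0.1, 0.1, 0.1],
                       [1e-8, 1e-4, 1e-3], pos=[1000, 2000, 3000])
        w = harmonize_alleles(ss, geno)
        out1 = ld_clump(w, geno, ClumpSpec(r2=0.1, window_kb=250))
        out2 = ld_clump(w.iloc[::-1].reset_index(drop=True), geno,
                        ClumpSpec(r2=0.1, window_kb=250))
        assert sorted(out1["id"]) == sorted(out2["id"])


class TestScore:
    def test_toy_weighted_sum(self):
        geno = _geno([[2.0, 1.0]])
        w = pd.DataFrame({"geno_idx": [0, 1], "beta": [0.1, -0.2],
                          "p": [0.1, 0.1], "id": ["rs1", "rs2"]})
        prof = score_prs(geno, w, thresholds=[0.5])
        assert prof.raw[0.5].iloc[0] == pytest.approx(0.0)

    def test_z_transform_uses_sample_sd(self):
        geno = _geno([[0.0], [1.0], [2.0]])
        w = pd.DataFrame({"geno_idx": [0], "beta": [1.0], "p": [0.1],
                          "id": ["rs1"]})
        prof = score_prs(geno, w, thresholds=[0.5])
        np.testing.assert_allclose(prof.zscores[0.5], [-1.0, 0.0, 1.0])

    def test_missing_dosage_mean_imputed(self):
        # target allele freq 0.25 from the observed calls
        geno = _geno([[np.nan], [1.0], [0.0], [0.0], [1.0]])
        w = pd.DataFrame({"geno_idx": [0], "beta": [2.0], "p": [0.1],
                          "id": ["rs1"]})
        prof = score_prs(geno, w, thresholds=[0.5])
        assert prof.raw[0.5].iloc[0] == pytest.approx(2.0 * 0.5)

    def test_empty_threshold_flagged_zeros(self, caplog):
        geno = _geno([[1.0], [2.0]])
        w = pd.DataFrame({"geno_idx": [0], "beta": [1.0], "p": [0.9],
                          "id": ["rs1"]})
        with caplog.at_level("WARNING", logger="twinprs"):
            prof = score_prs(geno, w, thresholds=[1e-8, 1.0])
        assert (prof.raw[1e-8] == 0).all()
        assert prof.n_variants[1e-8] == 0
        assert "selects no variants" in caplog.text

    def test_n_variants_monotone_in_threshold(self, poly_cohort):
        prof = PrsScorer(thresholds=[1e-4, 0.05, 0.5, 1.0]).fit_transform(
            poly_cohort["geno"], poly_cohort["sumstats"])
        ns = [prof.n_variants[t] for t in sorted(prof.n_variants)]
        assert ns == sorted(ns)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=2, max_size=6))
    def test_score_linearity(self, betas):
        rng = np.random.default_rng(0)
        m = len(betas)
        geno = _geno(rng.integers(0, 3, size=(10, m)))
        base = pd.DataFrame({"geno_idx": range(m), "p": [0.1] * m,
                             "id": [f"rs{j + 1}" for j in range(m)]})
        w1 = base.assign(beta=betas)
        w2 = base.assign(beta=[0.3] * m)
        w12 = base.assign(beta=[b + 0.3 for b in betas])
        s = lambda w: score_prs(geno, w, thresholds=[0.5]).raw[0.5]
        np.testing.assert_allclose(s(w1) + s(w2), s(w12), atol=1e-12)


class TestPCA:
    def test_orthonormal_and_signed(self, poly_cohort):
        pca = GenotypePCA(n_components=4)
        scores = pca.fit_transform(poly_cohort["geno"])
        g = scores.to_numpy()
        gram = g.T @ g / (len(g) - 1)
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        for k in range(4):
            load = pca.loadings_[k]
            assert load[np.argmax(np.abs(load))] > 0

    def test_pc1_separates_subpopulations(self):
        pspec = PolygenicSpec(m_variants=300, n_causal=0, fst=0.2,
                              ld_rho=0.0, seed=15)
        table = simulate_twin_pairs(make_ae_spec(n_per_group=150, seed=15))
        geno, meta = simulate_genotypes(pspec, table)
        scores = GenotypePCA(n_components=2).fit_transform(geno)
        pop = meta["subpop"].reindex(scores.index).to_numpy()
        r = np.corrcoef(scores["PC1"], pop)[0, 1]
        assert abs(r) > 0.9

    def test_too_few_variants_error(self, rng):
        geno = _geno(rng.integers(0, 3, size=(30, 5)))
        with pytest.raises(ValueError):
            GenotypePCA(n_components=10).fit(geno)


class TestGee:
    def test_singleton_clusters_equal_hc0(self, rng):
        n = 150
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 0.3 * x + 0.2 * z + rng.normal(size=n)
        res = gee_associate(y, x, covariates=z,
                            clusters=np.arange(n), family="linear")
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x, z]))).fit(
            cov_type="HC0")
        assert res.beta == pytest.approx(ols.params[1], rel=1e-8)
        assert res.se == pytest.approx(ols.bse[1], rel=1e-6)

    def test_logistic_or_equals_cross_product(self):
        # cells: exposed a=10 cases / b=90 controls; unexposed c=20 / d=80
        y = np.concatenate([np.ones(10), np.zeros(90),
                            np.ones(20), np.zeros(80)])
        x = np.concatenate([np.ones(100), np.zeros(100)])
        res = gee_associate(y, x, family="logistic")
        assert res.or_ == pytest.approx((10 * 80) / (90 * 20), rel=1e-6)

    def test_cluster_duplication_leaves_inference_unchanged(self, rng):
        n = 120
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        clusters = np.arange(n)
        base = gee_associate(y, x, clusters=clusters, family="linear")
        dup = gee_associate(np.repeat(y, 2), np.repeat(x, 2),
                            clusters=np.repeat(clusters, 2), family="linear")
        assert dup.beta == pytest.approx(base.beta, rel=1e-8)
        assert dup.se == pytest.approx(base.se, rel=1e-6)

    def test_too_few_cases_error(self, rng):
        with pytest.raises(ValueError, match="10x"):
            gee_associate(rng.normal(size=15), rng.normal(size=15),
                          covariates=rng.normal(size=(15, 3)))

    def test_type_one_error_rate(self, rng):
        # null score, paired outcomes correlated within cluster
        n_pairs, reps, alpha = 100, 200, 0.05
        rejections = 0
        for _ in range(reps):
            shared = np.repeat(rng.normal(size=n_pairs), 2)
            y = 0.7 * shared + rng.normal(size=2 * n_pairs)
            x = rng.normal(size=2 * n_pairs)
            res = gee_associate(y, x,
                                clusters=np.repeat(np.arange(n_pairs), 2),
                                family="linear")
            rejections += res.p < alpha
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_and_delta_r2_at_construction(self):
        # independent variants and an (almost) noiseless discovery GWAS, so
        # the clumped-and-thresholded score closely tracks the true score
        # and its incremental R^2 approaches the generating h2 of 0.05
        pspec = PolygenicSpec(m_variants=400, n_causal=40, h2_score=0.05,
                              n_discovery=5_000_000, ld_rho=0.0, seed=33)
        table = simulate_twin_pairs(make_ae_spec(n_per_group=600, seed=33))
        geno, meta = simulate_genotypes(pspec, table)
        eff = draw_causal_effects(pspec)
        from twinprs.simulate import simulate_discovery_sumstats
        ss = simulate_discovery_sumstats(pspec, geno.variants, meta["maf"],
                                         eff)
        out = attach_genetic_phenotype(geno, eff, pspec)
        prof = PrsScorer(thresholds=[0.5]).fit_transform(geno, ss)
        pairs = [i.rsplit("_", 1)[0] for i in geno.ids]
        res = gee_associate(out["score_outcome"], prof.z(0.5),
                            clusters=pairs, family="linear")
        assert res.p < 1e-3
        assert res.r2 == pytest.approx(0.05, abs=0.02)

    def test_stratification_confounding_removed_by_pcs(self):
        pspec = PolygenicSpec(m_variants=300, n_causal=0, fst=0.15,
                              confound_shift=0.8, h2_score=0.0,
                              ld_rho=0.0, seed=27)
        table = simulate_twin_pairs(make_ae_spec(n_per_group=200, seed=27))
        geno, meta = simulate_genotypes(pspec, table)
        eff = draw_causal_effects(pspec)  # all zero
        out = attach_genetic_phenotype(geno, eff, pspec,
                                       subpop=meta["subpop"])
        # weights partially aligned with the subpopulation frequency
        # contrast (random sign flips keep the score an imperfect ancestry
        # proxy rather than a collinear copy of PC1); no causal pathway
        pop = meta["subpop"].reindex(geno.ids).to_numpy()
        contrast = (geno.dosages[pop == 1].mean(axis=0)
                    - geno.dosages[pop == 0].mean(axis=0))
        flip = np.where(np.random.default_rng(0).random(
            pspec.m_variants) < 0.45, -1.0, 1.0)
        w = pd.DataFrame({"geno_idx": np.arange(pspec.m_variants),
                          "beta": contrast * flip,
                          "p": np.full(pspec.m_variants, 0.01),
                          "id": geno.variants["id"]})
        prof = score_prs(geno, w, thresholds=[0.5])
        pairs = [i.rsplit("_", 1)[0] for i in geno.ids]
        naive = gee_associate(out["score_outcome"], prof.z(0.5),
                              clusters=pairs, family="linear")
        pcs = GenotypePCA(n_components=5).fit_transform(geno)
        adj = gee_associate(out["score_outcome"], prof.z(0.5),
                            covariates=pcs, clusters=pairs, family="linear")
        assert naive.p < 1e-10         # ancestry confounding bites
        assert abs(adj.beta) < abs(naive.beta) / 5
        assert adj.p > 0.01            # and the PCs remove it


class TestExclusion:
    def test_counts(self):
        df = pd.DataFrame({"dx": [1] * 7 + [0] * 93,
                           "y": np.arange(100)})
        out = exclude_diagnosed(df, "dx")
        assert len(out) == 93

    def test_identity_when_none_diagnosed(self):
        df = pd.DataFrame({"dx": [0] * 10, "y": range(10)})
        pd.testing.assert_frame_equal(exclude_diagnosed(df, "dx"), df)

    def test_attenuates_case_driven_effect(self, rng):
        n = 2000
        x = rng.normal(size=n)
        dx = (x > 1.5).astype(float)
        y = 2.0 * dx + rng.normal(size=n)  # effect only through cases
        df = pd.DataFrame({"x": x, "dx": dx, "y": y})
        full = gee_associate(df["y"], df["x"], family="linear")
        sub = exclude_diagnosed(df, "dx")
        excl = gee_associate(sub["y"], sub["x"], family="linear")
        assert abs(excl.beta) < abs(full.beta) / 2


class TestFdr:
    def test_hand_stepped_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.5],
                                   atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2] * 5), [0.2] * 5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_in_rank_and_capped(self, ps):
        adj = fdr_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
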