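"""Polygenic model fitting, mmscore vs GLS oracle, phased GWAS and
conditional analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlkit import gwas as gw
from pqtlkit import kinship as kin
from pqtlkit import synthetic as syn


def gls_wald_oracle(y, g, Omega_inv):
    """Explicit GLS refit with the marker as fixed effect, Omega fixed."""
    X = np.column_stack([np.ones(len(y)), g])
    A = X.T @ Omega_inv @ X
    beta = np.linalg.solve(A, X.T @ Omega_inv @ y)
    var = np.linalg.inv(A)[1, 1]
    return beta[1] ** 2 / var


@pytest.fixture(scope="module")
def fitted_small(small_cohort):
    ped, K, geno = small_cohort
    mk = geno.markers["id"].iloc[10]
    panel = syn.simulate_traits(
        [syn.TraitModel("t", h2=0.5, cis_snp=(mk, 0.3))], K, seed=21, genotypes=geno
    )
    y = panel.ddcq.loc["t"]
    Kg = kin.genomic_kinship(geno)
    fit = gw.fit_polygenic(y, K=Kg.values)
    return y, geno, Kg, fit


class TestPolygenicFit:
    def test_identity_kinship_collapses_to_ols(self, rng):
        n = 100
        ids = [f"s{i}" for i in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids)
        K = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        fit = gw.fit_polygenic(y, K=K)
        assert fit.h2 == 0.0
        assert fit.boundary
        assert fit.beta["intercept"] == pytest.approx(y.mean(), rel=1e-9)

    def test_optimum_beats_fine_grid(self, fitted_small):
        y, geno, Kg, fit = fitted_small
        eig = fit.eig
        yv = y.loc[eig.ids].to_numpy()
        Xt = eig.U.T @ np.ones((len(yv), 1))
        yt = eig.U.T @ yv
        grid_ll = [
            gw._profile(h, eig.lam, Xt, yt, reml=False)[0]
            for h in np.linspace(1e-6, 1 - 1e-6, 101)
        ]
        assert fit.loglik >= max(grid_ll) - 1e-7

    def test_h2_recovery(self, family_cohort):
        _, K = family_cohort
        eig = gw.eigen_kinship(kin.KinshipMatrix(K, 0))
        errs = []
        for h2 in (0.2, 0.5, 0.8):
            models = [syn.TraitModel(f"r{r}", h2=h2) for r in range(5)]
            panel = syn.simulate_traits(models, K, seed=int(100 * h2))
            for m in models:
                fit = gw.fit_polygenic(panel.ddcq.loc[m.name], eig=eig)
                errs.append(abs(fit.h2 - h2))
        assert np.mean(errs) < 0.07

    def test_kinship_rescale_invariance(self, fitted_small):
        y, geno, Kg, fit = fitted_small
        scaled = kin.KinshipMatrix(Kg.values * 4.0, Kg.n_markers)
        fit2 = gw.fit_polygenic(y, K=scaled.values)
        assert fit2.h2 == pytest.approx(fit.h2, abs=1e-6)
        assert fit2.sigma2_g == pytest.approx(fit.sigma2_g / 4.0, rel=1e-4)

    def test_small_sample_rejected(self, rng):
        ids = [f"s{i}" for i in range(10)]
        y = pd.Series(rng.normal(size=10), index=ids)
        K = pd.DataFrame(np.eye(10), index=ids, columns=ids)
        with pytest.raises(ValueError):
            gw.fit_polygenic(y, K=K)


class TestHeritabilityLRT:
    def test_boundary_gives_half(self, rng):
        n = 120
        ids = [f"s{i}" for i in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids)
        K = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        fit = gw.fit_polygenic(y, K=K)
        assert gw.heritability_pvalue(fit) == 0.5

    def test_power_at_high_h2(self, family_cohort):
        _, K = family_cohort
        eig = gw.eigen_kinship(kin.KinshipMatrix(K, 0))
        models = [syn.TraitModel(f"p{r}", h2=0.6) for r in range(10)]
        panel = syn.simulate_traits(models, K, seed=31)
        rejected = sum(
            gw.heritability_pvalue(gw.fit_polygenic(panel.ddcq.loc[m.name], eig=eig))
            < 0.05 / 77
            for m in models
        )
        assert rejected >= 9


class TestMMScore:
    def test_matches_gls_wald_oracle(self, fitted_small):
        y, geno, Kg, fit = fitted_small
        eig = fit.eig
        Oi = eig.U @ np.diag(1.0 / (fit.sigma2 * fit._w)) @ eig.U.T
        yv = y.loc[fit.ids].to_numpy()
        rel_errs = []
        for mk in geno.markers["id"].iloc[:60]:
            g = geno.dosages.loc[fit.ids, mk].to_numpy()
            if g.var() == 0:
                continue
            oracle = gls_wald_oracle(yv, g, Oi)
            got = gw.mmscore(fit, geno.dosages[mk], mk)
            if oracle > 1e-8:
                rel_errs.append(abs(got.chi2 - oracle) / oracle)
        assert max(rel_errs) < 1e-6

    def test_orthogonal_marker_null(self, fitted_small):
        y, geno, Kg, fit = fitted_small
        # construct g exactly orthogonal to the residual in the Omega^-1 metric
        wi = 1.0 / fit._w
        r = fit._yt_resid
        gt = np.ones_like(r)
        gt -= r * (r @ (wi * gt)) / (r @ (wi * r))
        g = pd.Series(fit.eig.U @ gt, index=fit.ids)
        g = g - g.min()  # keep dosage-like positivity; affine shift is absorbed
        res = gw.mmscore(fit, g, "orth")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_variance_marker_skipped(self, fitted_small):
        y, geno, Kg, fit = fitted_small
        g = pd.Series(1.0, index=fit.ids)
        res = gw.mmscore(fit, g, "flat")
        assert res.skipped_reason == "zero_variance"

    @pytest.mark.parametrize(
        "p,n,expected_pct",
        [(4.4e-58, 653 + 317, 26.6), (6.8e-37, 641 + 311, 16.9)],
    )
    def test_variance_explained_identity(self, p, n, expected_pct):
        # chi2-inversion of a printed combined p-value over the combined N
        assert 100 * gw.variance_explained_from_p(p, n) == pytest.approx(
            expected_pct, abs=0.05
        )


class TestInflation:
    def test_constant_chi2_gives_unit_lambda(self):
        assert gw.inflation_lambda(np.full(100, 0.4549)) == 1.0

    def test_null_scan_calibrated(self, medium_genotyped_cohort, grm_medium):
        ped, K_exp, geno = medium_genotyped_cohort
        panel = syn.simulate_traits([syn.TraitModel("null", h2=0.4)], K_exp, seed=41)
        fit = gw.fit_polygenic(panel.ddcq.loc["null"], K=grm_medium.values)
        scan = gw.score_scan(fit, geno.dosages)
        ok = scan[scan["skipped"] == ""]
        assert gw.inflation_lambda(ok["chi2"]) == pytest.approx(1.0, abs=0.05)
        assert (ok["p"] < 1e-3).mean() == pytest.approx(1e-3, abs=5e-4)


class TestVarianceExplainedRaw:
    def test_exact_linear_trait(self, small_cohort):
        _, _, geno = small_cohort
        g = geno.dosages[geno.markers["id"].iloc[3]]
        y = 0.7 * g
        assert gw.variance_explained_raw(y, g) == pytest.approx(1.0, rel=1e-9)

    def test_null_expectation(self, rng):
        n = 500
        fracs = [
            gw.variance_explained_raw(
                pd.Series(rng.normal(size=n)), pd.Series(rng.binomial(2, 0.3, n))
            )
            for _ in range(50)
        ]
        assert np.mean(fracs) == pytest.approx(1 / (n - 1), rel=0.5)

    def test_too_few_cases(self, rng):
        with pytest.raises(ValueError):
            gw.variance_explained_raw(
                pd.Series(rng.normal(size=5)), pd.Series(rng.binomial(2, 0.3, 5))
            )


@pytest.fixture(scope="module")
def planted_gwas():
    # population-cohort relatedness: a minority of nuclear families among
    # mostly unrelated participants
    spec = syn.PedigreeSpec(n_families=60, offspring_per_family=4, n_singletons=540)
    ped = syn.simulate_pedigree(spec, seed=50)
    K = syn.expected_kinship(ped)
    geno = syn.simulate_genotypes(ped, 800, seed=51)
    mk = geno.markers["id"].iloc[100]
    p = geno.dosages[mk].mean() / 2
    beta = float(np.sqrt(0.25 / (2 * p * (1 - p))))
    panel = syn.simulate_traits(
        [syn.TraitModel("t", h2=0.4, cis_snp=(mk, beta))], K, seed=52, genotypes=geno
    )
    # pedigree-expected kinship stands in for a dense-marker GRM (the scan
    # panel here is far too sparse to estimate kinship without attenuation)
    Kped = kin.KinshipMatrix(K, n_markers=0, estimator="pedigree")
    cohorts = ped["cohort"]
    results = gw.run_gwas(panel.ddcq, geno, cohorts, Kped, gw.GwasRunConfig())
    return mk, panel, geno, Kped, results["t"]


class TestRunGwas:
    def test_planted_signal_found_and_replicated(self, planted_gwas):
        mk, panel, geno, Kg, res = planted_gwas
        assert mk in res.hits["discovery"]
        assert mk in res.hits["replication"]
        assert mk in res.hits["combined"]
        assert res.top_marker == mk

    def test_planted_var_expl_recovered(self, planted_gwas):
        mk, panel, geno, Kg, res = planted_gwas
        comb = res.phase("combined").set_index("marker")
        planted = panel.components["t"]["frac_cis_snp"]
        assert comb.loc[mk, "var_expl"] == pytest.approx(planted, abs=0.05)

    def test_lambda_near_one(self, planted_gwas):
        _, _, _, _, res = planted_gwas
        assert 0.9 < res.lambdas["discovery"] < 1.1
        assert 0.9 < res.lambdas["combined"] < 1.1

    def test_thresholds_follow_design(self, planted_gwas):
        _, _, geno, _, res = planted_gwas
        m = geno.dosages.shape[1]
        assert res.thresholds["discovery"] == pytest.approx(0.05 / m)
        assert res.thresholds["replication"] == pytest.approx(
            0.05 / len(res.hits["discovery"])
        )

    def test_empty_cohort_rejected(self, family_cohort):
        ped, K = family_cohort
        geno = syn.simulate_genotypes(ped, 150, seed=53)
        panel = syn.simulate_traits([syn.TraitModel("t", h2=0.3)], K, seed=54)
        Kg = kin.genomic_kinship(geno, min_markers=100)
        bad = pd.Series("discovery", index=ped.index)
        with pytest.raises(ValueError, match="non-empty"):
            gw.run_gwas(panel.ddcq, geno, bad, Kg)


class TestConditional:
    def test_conditioning_on_self_kills_signal(self, planted_gwas):
        mk, panel, geno, Kg, res = planted_gwas
        cond = gw.conditional_scan(panel.ddcq.loc["t"], geno, Kg, mk)
        row = cond.set_index("marker").loc[mk]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-8) or row["skipped"] != ""

    def test_perfect_proxy_killed(self, planted_gwas):
        mk, panel, geno, Kg, res = planted_gwas
        D = geno.dosages.copy()
        proxy_id = "proxy"
        D[proxy_id] = D[mk]
        markers = pd.concat(
            [geno.markers, pd.DataFrame([{
                "id": proxy_id, "chrom": int(geno.markers.set_index("id").loc[mk, "chrom"]),
                "pos": int(geno.markers["pos"].max() + 1), "ref": "A", "alt": "G",
                "af": float(D[mk].mean() / 2),
            }])],
            ignore_index=True,
        )
        geno2 = syn.GenotypeDosages(markers=markers, dosages=D, hard_call=True)
        cond = gw.conditional_scan(panel.ddcq.loc["t"], geno2, Kg, mk)
        row = cond.set_index("marker").loc[proxy_id]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-8) or row["skipped"] != ""

    def test_independent_second_signal_survives(self, family_cohort):
        ped, K = family_cohort
        geno = syn.simulate_genotypes(ped, 400, seed=61)
        ids = geno.markers["id"]
        mk1, mk2 = ids.iloc[50], ids.iloc[55]  # same chromosome, unlinked
        def beta_for(mk, frac):
            p = geno.dosages[mk].mean() / 2
            return float(np.sqrt(frac / (2 * p * (1 - p))))
        # two independent causal markers on one chromosome
        rngy = np.random.default_rng(62)
        g1 = geno.dosages[mk1].to_numpy()
        g2 = geno.dosages[mk2].to_numpy()
        y = (
            beta_for(mk1, 0.2) * g1
            + beta_for(mk2, 0.15) * g2
            + rngy.normal(0, np.sqrt(0.65), len(ped))
        )
        ys = pd.Series(y, index=ped.index, name="t")
        Kg = kin.genomic_kinship(geno, min_markers=100)
        cond = gw.conditional_scan(ys, geno, Kg, mk1)
        row = cond.set_index("marker").loc[mk2]
        assert bool(row["significant"])

    def test_constant_top_marker_rejected(self, planted_gwas):
        mk, panel, geno, Kg, res = planted_gwas
        D = geno.dosages.copy()
        D["const"] = 1.0
        markers = pd.concat(
            [geno.markers, pd.DataFrame([{
                "id": "const", "chrom": 1, "pos": int(geno.markers["pos"].max() + 2),
                "ref": "A", "alt": "G", "af": 0.5,
            }])],
            ignore_index=True,
        )
        geno2 = syn.GenotypeDosages(markers=markers, dosages=D, hard_call=True)
        with pytest.raises(ValueError, match="constant"):
            gw.conditional_scan(panel.ddcq.loc["t"], geno2, Kg, "const")
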