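"""PCA, mixture-model EM, and gene/chromosome membership summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import three_lineage_config

from cohet.core import GeneMap, PipelineError
from cohet.ancestry import (
    chromosome_ancestry,
    fit_mixture,
    gene_ancestry,
    neglogp_profile,
    run_pca,
    select_by_membership,
    standardize_genotypes,
)
from cohet.pipeline import analyze_panel
from cohet.synthetic_data import simulate


class TestStandardize:
    def test_closed_form_at_half_frequency(self, tiny_sim):
        """At p = 0.5 the standardized codes are -sqrt(2), 0, +sqrt(2)."""
        import cohet.core as core

        ds = tiny_sim.dataset
        # build a fake SNP with genotypes 0/1/2 balanced -> p = 0.5
        g = np.tile([0, 1, 2], 20).reshape(-1, 1)
        snp = pd.DataFrame(
            {"snp_id": ["s"], "chromosome": "1", "position": [1]}
        )
        animals = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(60)], "breed_id": "X"}
        )
        dataset = core.GenotypeDataset(
            genotypes=g,
            snp_table=snp,
            animal_table=animals,
            breed_table=pd.DataFrame({"breed_id": ["X"], "lineage": ["BTI"]}),
        )
        std = standardize_genotypes(dataset)
        vals = np.unique(np.round(std.matrix, 6))
        root2 = np.sqrt(2.0)
        assert np.allclose(vals, [-root2 / 1, 0, root2], atol=1e-6)

    def test_columns_centered(self, tiny_analysis):
        std = standardize_genotypes(tiny_analysis.dataset)
        assert np.abs(std.matrix.mean(axis=0)).max() < 1e-10

    def test_monomorphic_dropped_and_logged(self, tiny_sim, caplog):
        ds = tiny_sim.dataset
        g = ds.genotypes.copy()
        g[:, 0] = 0
        ds2 = type(ds)(g, ds.snp_table, ds.animal_table, ds.breed_table)
        with caplog.at_level("WARNING"):
            std = standardize_genotypes(ds2)
        assert ds.snp_table["snp_id"][0] not in std.snp_ids
        assert "monomorphic" in caplog.text


class TestPca:
    def test_pc1_tracks_true_ancestry(self):
        for seed in range(3):
            sim = simulate(three_lineage_config(seed=100 + seed))
            res = analyze_panel(sim)
            cor = np.corrcoef(
                res.pca.scores[:, 0],
                res.dataset.animal_table["true_ancestry"],
            )[0, 1]
            assert abs(cor) >= 0.99

    def test_pc1_oriented_indicine_negative(self, tiny_analysis):
        bi = tiny_analysis.dataset.lineage_mask("BI")
        bt = tiny_analysis.dataset.lineage_mask("BT")
        assert tiny_analysis.pca.scores[bi, 0].mean() < 0
        assert tiny_analysis.pca.scores[bt, 0].mean() > 0

    def test_var_explained_contract(self, tiny_analysis):
        v = tiny_analysis.pca.var_explained
        assert (v >= 0).all() and v.sum() <= 1.0 + 1e-12
        assert (np.diff(v) <= 1e-12).all()

    def test_scores_orthogonal(self, tiny_analysis):
        s = tiny_analysis.pca.scores
        cov = s.T @ s
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.diag(cov).max()

    def test_loadings_unit_norm(self, tiny_analysis):
        norms = np.linalg.norm(tiny_analysis.pca.loadings, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_duplicate_animals_get_identical_scores(self, tiny_analysis):
        std = standardize_genotypes(tiny_analysis.dataset)
        x = np.vstack([std.matrix, std.matrix[:1]])
        std2 = type(std)(matrix=x, snp_ids=std.snp_ids, freq=std.freq)
        pca = run_pca(std2, k=3)
        assert np.allclose(pca.scores[0], pca.scores[-1], atol=1e-8)

    def test_k_out_of_range_rejected(self, tiny_analysis):
        std = standardize_genotypes(tiny_analysis.dataset)
        with pytest.raises(PipelineError):
            run_pca(std, k=std.matrix.shape[0])


class TestMixtureEm:
    def sample(self, seed, n=20_000, pi=0.31, mu=(-1.0, 1.0), sd=0.2):
        rng = np.random.default_rng(seed)
        z = rng.random(n) < pi
        return np.where(z, rng.normal(mu[0], sd, n), rng.normal(mu[1], sd, n))

    def test_parameter_recovery(self):
        x = self.sample(1)
        fit = fit_mixture(x)
        assert fit.pi1 == pytest.approx(0.31, abs=0.02)
        assert fit.mu1 == pytest.approx(-1.0, abs=0.02)
        assert fit.mu2 == pytest.approx(1.0, abs=0.02)

    def test_matches_independent_em_implementation(self):
        """Cross-check against scikit-learn's GaussianMixture on the same
        draws (independent EM route)."""
        from sklearn.mixture import GaussianMixture

        x = self.sample(2, n=5000)
        ours = fit_mixture(x)
        gm = GaussianMixture(n_components=2, tol=1e-8, max_iter=1000,
                             random_state=0).fit(x.reshape(-1, 1))
        means = np.sort(gm.means_.ravel())
        weights = gm.weights_[np.argsort(gm.means_.ravel())]
        assert ours.mu1 == pytest.approx(means[0], abs=0.01)
        assert ours.mu2 == pytest.approx(means[1], abs=0.01)
        assert ours.pi1 == pytest.approx(weights[0], abs=0.01)

    def test_posteriors_sum_to_one(self):
        fit = fit_mixture(self.sample(3, n=2000))
        assert np.abs(fit.m1 + fit.m2 - 1.0).max() < 1e-12

    def test_posterior_half_at_midpoint_of_symmetric_mixture(self):
        """With equal weights and variances, the posterior at the midpoint
        of the two means is exactly 1/2 by symmetry."""
        from cohet.ancestry import MixtureAncestry

        mix = MixtureAncestry(
            pi1=0.5, mu1=-1.0, var1=0.04, pi2=0.5, mu2=1.0, var2=0.04,
            m1=np.array([]), m2=np.array([]), loglik_trace=np.array([0.0]),
        )
        assert mix.posterior(0.0) == pytest.approx(0.5, abs=1e-12)
        # and an EM fit of a symmetric sample lands close to that ideal
        fit = fit_mixture(self.sample(4, n=10_000, pi=0.5))
        mid = 0.5 * (fit.mu1 + fit.mu2)
        assert fit.posterior(mid) == pytest.approx(0.5, abs=0.05)

    def test_loglik_trace_non_decreasing(self):
        fit = fit_mixture(self.sample(5, n=2000))
        assert (np.diff(fit.loglik_trace) >= -1e-8).all()

    def test_degenerate_input_rejected(self):
        with pytest.raises(PipelineError):
            fit_mixture(np.ones(100))

    def test_permutation_invariance(self):
        x = self.sample(6, n=2000)
        rng = np.random.default_rng(0)
        fit_a = fit_mixture(x)
        fit_b = fit_mixture(rng.permutation(x))
        assert fit_a.mu1 == pytest.approx(fit_b.mu1, abs=1e-6)
        assert fit_a.pi1 == pytest.approx(fit_b.pi1, abs=1e-6)

    def test_sign_flip_relabels_components(self):
        x = self.sample(7, n=2000, pi=0.31)
        fit_a = fit_mixture(x)
        fit_b = fit_mixture(-x)
        assert fit_a.mu1 == pytest.approx(-fit_b.mu2, abs=1e-4)
        assert fit_a.pi1 == pytest.approx(fit_b.pi2, abs=1e-4)


def toy_gene_map():
    genes = pd.DataFrame(
        {"gene_id": ["gA", "gB"], "chromosome": ["1", "2"],
         "start": [1, 1], "end": [10, 10]}
    )
    assignments = pd.DataFrame(
        {"gene_id": ["gA", "gA", "gB"], "snp_id": ["s1", "s2", "s3"]}
    )
    return GeneMap(genes=genes, assignments=assignments)


class TestGeneAncestry:
    def make_mixture(self, m1, snp_ids):
        from cohet.ancestry import MixtureAncestry

        m1 = np.asarray(m1, dtype=float)
        return MixtureAncestry(
            pi1=0.5, mu1=-1, var1=0.1, pi2=0.5, mu2=1, var2=0.1,
            m1=m1, m2=1 - m1, loglik_trace=np.array([0.0]),
            snp_ids=np.asarray(snp_ids),
        )

    def test_gene_posterior_is_mean_of_snp_posteriors(self):
        mix = self.make_mixture([0.9, 0.7, 1.0], ["s1", "s2", "s3"])
        ga = gene_ancestry(mix, toy_gene_map())
        assert ga.set_index("gene_id").loc["gA", "pr_indicine"] == pytest.approx(0.8)
        assert ga.set_index("gene_id").loc["gB", "pr_indicine"] == pytest.approx(1.0)

    def test_memberships_complementary(self, tiny_analysis):
        ga = tiny_analysis.gene_ancestry
        assert np.allclose(ga["pr_indicine"] + ga["pr_taurine"], 1.0)

    def test_gene_without_posterior_snp_excluded(self, caplog):
        mix = self.make_mixture([0.9, 0.7], ["s1", "s2"])  # s3 missing
        with caplog.at_level("WARNING"):
            ga = gene_ancestry(mix, toy_gene_map())
        assert list(ga["gene_id"]) == ["gA"]

    def test_membership_selection(self):
        ga = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "pr_indicine": [0.96, 0.94, 0.50],
            }
        )
        ga["pr_taurine"] = 1 - ga["pr_indicine"]
        ind, tau = select_by_membership(ga, cutoff=0.95)
        assert ind == ["g1"] and tau == []
        ind_all, _ = select_by_membership(ga, cutoff=1.0)
        assert ind_all == []
        assert not set(ind) & set(tau)

    def test_membership_cutoff_range_enforced(self):
        ga = pd.DataFrame({"gene_id": ["g"], "pr_indicine": [1.0], "pr_taurine": [0.0]})
        with pytest.raises(PipelineError):
            select_by_membership(ga, cutoff=0.4)


class TestProfiles:
    def make_ga(self, pr_taurine):
        ga = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(pr_taurine))],
                "chromosome": "1",
                "pr_taurine": pr_taurine,
            }
        )
        ga["pr_indicine"] = 1 - ga["pr_taurine"]
        return ga

    def test_neglogp_values_and_flags(self):
        prof = neglogp_profile(self.make_ga([1e-5, 0.5, 1.0]), base=10, flag_threshold=4)
        vals = prof["neglogp_indicine"].to_numpy()
        assert vals[0] == pytest.approx(5.0)
        assert vals[1] == pytest.approx(np.log10(2), abs=1e-6)
        assert vals[2] == 0.0
        assert list(prof["flag_indicine"]) == [True, False, False]

    def test_chromosome_means(self):
        ga = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "chromosome": ["1", "1", "2"],
                "pr_indicine": [0.2, 0.4, 0.9],
            }
        )
        ga["pr_taurine"] = 1 - ga["pr_indicine"]
        chrom = chromosome_ancestry(ga).set_index("chromosome")
        assert chrom.loc["1", "pr_indicine"] == pytest.approx(0.3)
        assert chrom.loc["2", "pr_indicine"] == pytest.approx(0.9)
        # gene-count-weighted chromosome mean equals the genome-wide mean
        w = (chrom["pr_indicine"] * chrom["n_genes"]).sum() / chrom["n_genes"].sum()
        assert w == pytest.approx(ga["pr_indicine"].mean())


def test_fixed_difference_genes_get_concordant_membership(tiny_sim, tiny_analysis):
    """Genes engineered to be informative for one subspecies must receive a
    near-0/1 membership on the matching side."""
    ga = tiny_analysis.gene_ancestry.set_index("gene_id")
    tau = [g for g in tiny_sim.gene_sets["tauset"] if g in ga.index]
    ind = [g for g in tiny_sim.gene_sets["indset"] if g in ga.index]
    concordant = (ga.loc[tau, "pr_taurine"] > 0.5).sum() + (
        ga.loc[ind, "pr_indicine"] > 0.5
    ).sum()
    assert concordant >= 0.95 * (len(tau) + len(ind))
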