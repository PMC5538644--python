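"""HET statistics, HWE chi-square screening, and breed clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from conftest import three_lineage_config

from cohet.core import GeneMap, GenotypeDataset, PipelineError
from cohet.heterozygosity import (
    cluster_breeds,
    compute_het,
    genes_deviating_hwe,
    hwe_chi_square,
    hwe_test,
)
from cohet.synthetic_data import (
    BreedSpec,
    SimulationConfig,
    SubspeciesFreqs,
    simulate,
    simulate_genotypes,
)


def single_breed_dataset(genotypes, breed="B1", lineage="BT"):
    g = np.asarray(genotypes)
    snp = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(g.shape[1])],
            "chromosome": "1",
            "position": np.arange(1, g.shape[1] + 1),
        }
    )
    animals = pd.DataFrame(
        {"animal_id": [f"a{i}" for i in range(g.shape[0])], "breed_id": breed}
    )
    return GenotypeDataset(
        genotypes=g,
        snp_table=snp,
        animal_table=animals,
        breed_table=pd.DataFrame({"breed_id": [breed], "lineage": [lineage]}),
    )


class TestHet:
    def test_snp_het_is_share_of_heterozygotes(self):
        ds = single_breed_dataset(np.array([[0], [1], [1], [2]]))
        het = compute_het(ds)
        assert het.snp_het.loc["s0", "B1"] == pytest.approx(50.0)

    def test_gene_het_is_mean_of_snp_het(self):
        g = np.array(
            [
                [1, 1, 1],
                [1, 1, 1],
                [0, 1, 2],
                [0, 0, 0],
                [0, 0, 0],
            ]
        )  # SNP HETs: 40, 60, 40 -> not the target; craft explicitly below
        ds = single_breed_dataset(g)
        gm = GeneMap(
            genes=pd.DataFrame(
                {"gene_id": ["gA"], "chromosome": ["1"], "start": [1], "end": [3]}
            ),
            assignments=pd.DataFrame(
                {"gene_id": ["gA"] * 3, "snp_id": ["s0", "s1", "s2"]}
            ),
        )
        het = compute_het(ds, gm)
        expected = het.snp_het["B1"].mean()
        assert het.gene_het.loc["gA", "B1"] == pytest.approx(expected)

    def test_all_homozygous_breed_is_zero(self):
        ds = single_breed_dataset(np.array([[0, 2], [2, 0], [0, 0]]))
        het = compute_het(ds)
        assert (het.snp_het["B1"] == 0).all()

    def test_missing_excluded_from_denominator(self):
        ds = single_breed_dataset(np.array([[1], [1], [-1], [0]]))
        het = compute_het(ds)
        assert het.snp_het.loc["s0", "B1"] == pytest.approx(100 * 2 / 3)

    def test_admixed_lineage_exceeds_pure_in_gene_het(self, tiny_analysis):
        means = tiny_analysis.het.gene_het.mean()
        assert means["XB1"] > means["BI1"]
        assert means["XB1"] > means["BT1"]


class TestHweChiSquare:
    @pytest.mark.parametrize(
        "counts,stat,p",
        [
            ((25, 50, 25), 0.0, 1.0),          # perfect HWE
            ((50, 0, 50), 100.0, None),        # complete heterozygote deficit
            ((30, 40, 30), 4.0, 0.0455),       # mild deficit
        ],
    )
    def test_closed_form_statistics(self, counts, stat, p):
        s, pv = hwe_chi_square(*[np.array([c]) for c in counts])
        assert s[0] == pytest.approx(stat, abs=1e-10)
        if p is not None:
            assert pv[0] == pytest.approx(p, abs=2e-4)
        assert pv[0] == pytest.approx(float(chi2_dist.sf(stat, 1)), rel=1e-10)

    def test_monomorphic_gives_p_one(self):
        s, pv = hwe_chi_square(np.array([50]), np.array([0]), np.array([0]))
        assert s[0] == 0.0 and pv[0] == 1.0

    def test_empty_sample_gives_nan(self):
        s, pv = hwe_chi_square(np.array([0]), np.array([0]), np.array([0]))
        assert np.isnan(s[0]) and np.isnan(pv[0])

    def test_type_one_error_calibrated_on_pure_breed(self):
        """On a pure breed (true HWE), the 1% chi-square screen rejects at
        close to the nominal rate."""
        cfg = SimulationConfig(
            n_snp=5000, n_genes=100, fst=0.2,
            breeds=[BreedSpec("BI1", "BI", 1.0, 500)], seed=12,
        )
        res = simulate(cfg)
        hw = hwe_test(res.dataset)
        poly = res.dataset.allele_freq() > 0
        rate = (hw.pvalue["BI1"].to_numpy()[poly] < 0.01).mean()
        assert 0.005 <= rate <= 0.02

    def test_wahlund_effect_in_heterogeneous_composite(self):
        """A composite breed whose animals vary in ancestry shows a strong
        heterozygote deficit at fixed-difference SNP."""
        cfg = SimulationConfig(
            n_snp=600, n_genes=100, fst=0.3,
            breeds=[BreedSpec("XB", "BTI", 0.5, 500)],
            ancestry_sd=0.15, seed=13,
        )
        freqs = SubspeciesFreqs(np.full(600, 1 - 1e-6), np.full(600, 1e-6))
        ds = simulate_genotypes(cfg, freqs)
        hw = hwe_test(ds)
        rate = (hw.pvalue["XB"].to_numpy() < 0.01).mean()
        assert rate >= 0.10  # >= 10x the nominal 1%

    def test_counts_sum_to_non_missing(self, tiny_analysis):
        hw = tiny_analysis.hwe
        total = sum(hw.counts[k] for k in ("n_0", "n_1", "n_2"))
        for breed in total.columns:
            n_breed = tiny_analysis.dataset.breed_mask(breed).sum()
            assert (total[breed] <= n_breed).all()


class TestHweGeneLists:
    def make_hwe(self, pvals):
        from cohet.heterozygosity import HweResult

        pv = pd.DataFrame(pvals)
        pv.index = [f"s{i}" for i in range(len(pv))]
        pv.index.name = "snp_id"
        zeros = pv.copy() * 0
        return HweResult(chi2=zeros, pvalue=pv, counts={})

    def gene_map(self):
        return GeneMap(
            genes=pd.DataFrame(
                {"gene_id": ["gA"], "chromosome": ["1"], "start": [1], "end": [9]}
            ),
            assignments=pd.DataFrame(
                {"gene_id": ["gA"] * 3, "snp_id": ["s0", "s1", "s2"]}
            ),
        )

    def test_gene_without_significant_snp_never_flagged(self):
        hw = self.make_hwe({"B1": [0.5, 0.5, 0.5], "B2": [0.5, 0.5, 0.5]})
        per_breed, union = genes_deviating_hwe(hw, self.gene_map(), alpha=0.01)
        assert union == [] and all(v == [] for v in per_breed.values())

    def test_single_significant_snp_flags_gene_in_that_breed(self):
        hw = self.make_hwe({"B1": [0.5, 0.005, 0.5], "B2": [0.5, 0.5, 0.5]})
        per_breed, union = genes_deviating_hwe(hw, self.gene_map(), alpha=0.01)
        assert per_breed["B1"] == ["gA"]
        assert per_breed["B2"] == []
        assert union == ["gA"]

    def test_alpha_zero_flags_nothing(self):
        hw = self.make_hwe({"B1": [0.0, 0.0, 0.0]})
        _, union = genes_deviating_hwe(hw, self.gene_map(), alpha=0.0)
        assert union == []

    def test_fraction_rule(self):
        hw = self.make_hwe({"B1": [0.005, 0.5, 0.5]})
        _, union = genes_deviating_hwe(hw, self.gene_map(), alpha=0.01, min_frac=0.5)
        assert union == []


class TestClustering:
    def test_identical_breeds_merge_at_zero_height(self):
        gh = pd.DataFrame({"B1": [10.0, 20.0], "B2": [10.0, 20.0], "B3": [50.0, 70.0]})
        cl = cluster_breeds(gh)
        assert cl.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_gene_row_permutation_invariance(self, tiny_analysis):
        gh = tiny_analysis.het.gene_het
        cl_a = cluster_breeds(gh)
        cl_b = cluster_breeds(gh.sample(frac=1, random_state=1))
        assert np.allclose(cl_a.linkage_matrix, cl_b.linkage_matrix)

    def test_three_lineages_recovered(self):
        """Cutting the breed dendrogram at three clusters separates the two
        pure lineages and the composites."""
        from sklearn.metrics import adjusted_rand_score

        cfg = three_lineage_config(
            seed=21,
            breeds=[
                BreedSpec("BI1", "BI", 1.0, 80),
                BreedSpec("BI2", "BI", 1.0, 80),
                BreedSpec("BT1", "BT", 0.0, 80),
                BreedSpec("BT2", "BT", 0.0, 80),
                BreedSpec("XB1", "BTI", 0.5, 80),
                BreedSpec("XB2", "BTI", 0.375, 80),
            ],
        )
        sim = simulate(cfg)
        from cohet.pipeline import analyze_panel

        res = analyze_panel(sim)
        cl = cluster_breeds(res.het.gene_het)
        cut = cl.cut(3)
        lineages = sim.dataset.breed_table.set_index("breed_id")["lineage"]
        ari = adjusted_rand_score(
            [lineages[b] for b in cl.breed_ids], [cut[b] for b in cl.breed_ids]
        )
        assert ari == 1.0

    def test_single_breed_rejected(self):
        with pytest.raises(PipelineError):
            cluster_breeds(pd.DataFrame({"B1": [1.0, 2.0]}))

    def test_newick_contains_all_breeds(self, tiny_analysis):
        cl = cluster_breeds(tiny_analysis.het.gene_het)
        nwk = cl.to_newick()
        assert nwk.endswith(";")
        for breed in cl.breed_ids:
            assert breed in nwk


def test_allele_coding_flip_leaves_het_unchanged(tiny_sim):
    """HET is a function of heterozygote status only, so recoding g -> 2-g
    at any subset of SNP leaves the whole HET hierarchy unchanged."""
    ds = tiny_sim.dataset
    rng = np.random.default_rng(0)
    flip = rng.random(ds.n_snp) < 0.5
    g = ds.genotypes.copy()
    miss = g == -1
    g[:, flip] = 2 - g[:, flip]
    g[miss] = -1
    ds2 = type(ds)(g, ds.snp_table, ds.animal_table, ds.breed_table)
    a = compute_het(ds, tiny_sim.gene_map)
    b = compute_het(ds2, tiny_sim.gene_map)
    pd.testing.assert_frame_equal(a.gene_het, b.gene_het)
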