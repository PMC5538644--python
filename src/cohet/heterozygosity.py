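"""Per-breed heterozygosity, Hardy-Weinberg screening, breed clustering.

Percentage heterozygosity (HET) of a SNP in a breed is the share of
non-missing animals carrying a heterozygous genotype, times 100.  Gene HET
averages a gene's SNP; lineage HET averages the breeds of a lineage with
equal weight; chromosome HET averages a chromosome's genes.  HWE deviation
is screened per (SNP, breed) with the allelic-frequency chi-square test
(1 df, no continuity correction) at a nominal threshold, and a gene is
flagged for a breed as soon as one of its SNP deviates.  Breed profiles of
gene HET are clustered by UPGMA on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .core import MISSING, GeneMap, GenotypeDataset, PipelineError

logger = logging.getLogger("cohet.het")


@dataclass
class HetTable:
    """HET percentages at SNP, gene, lineage and chromosome level."""

    snp_het: pd.DataFrame  # index snp_id, columns breed_id
    gene_het: pd.DataFrame  # index gene_id, columns breed_id
    lineage_het: pd.DataFrame  # index gene_id, columns lineage
    chrom_het: pd.DataFrame  # index chromosome, columns lineage


def compute_het(dataset: GenotypeDataset, gene_map: GeneMap | None = None) -> HetTable:
    """Compute the HET hierarchy; all averaging steps are unweighted."""
    g = dataset.genotypes
    breeds = dataset.breed_ids
    het_cols = {}
    for breed in breeds:
        mask = dataset.breed_mask(breed)
        sub = g[mask]
        n_obs = (sub != MISSING).sum(axis=0)
        n_het = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            het = np.where(n_obs > 0, 100.0 * n_het / np.maximum(n_obs, 1), np.nan)
        if (n_obs == 0).any():
            logger.warning(
                "breed %s has %d all-missing SNP cells", breed, int((n_obs == 0).sum())
            )
        het_cols[breed] = het
    snp_het = pd.DataFrame(het_cols, index=dataset.snp_table["snp_id"].to_numpy())
    snp_het.index.name = "snp_id"

    if gene_map is None:
        empty = pd.DataFrame()
        return HetTable(snp_het, empty, empty, empty)

    merged = gene_map.assignments.merge(
        snp_het.reset_index(), on="snp_id", how="inner"
    )
    gene_het = merged.groupby("gene_id")[breeds].mean()
    gene_het.index.name = "gene_id"

    lineage_of = dataset.breed_table.set_index("breed_id")["lineage"]
    lineage_het = gene_het.T.groupby(lineage_of).mean().T
    lineage_het = lineage_het[sorted(lineage_het.columns)]

    chrom_of = gene_map.genes.set_index("gene_id")["chromosome"]
    chrom_het = lineage_het.groupby(chrom_of).mean()
    chrom_het.index.name = "chromosome"
    return HetTable(snp_het, gene_het, lineage_het, chrom_het)


@dataclass
class HweResult:
    """Chi-square HWE screen per (SNP, breed)."""

    chi2: pd.DataFrame  # index snp_id, columns breed_id
    pvalue: pd.DataFrame
    counts: dict[str, pd.DataFrame]  # genotype-class counts n_0/n_1/n_2

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: snp_id, breed_id, n_0, n_1, n_2, chi2, p."""
        rows = []
        for breed in self.chi2.columns:
            frame = pd.DataFrame(
                {
                    "snp_id": self.chi2.index,
                    "breed_id": breed,
                    "n_hom_major": self.counts["n_0"][breed].to_numpy(),
                    "n_het": self.counts["n_1"][breed].to_numpy(),
                    "n_hom_minor": self.counts["n_2"][breed].to_numpy(),
                    "chi2": self.chi2[breed].to_numpy(),
                    "p_value": self.pvalue[breed].to_numpy(),
                }
            )
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def hwe_chi_square(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square (1 df) for genotype counts against HWE expectations.

    ``p_hat = (2 n2 + n1) / 2n``; expected counts ``n q^2, 2 n p q, n p^2``
    with q = 1 - p_hat.  Monomorphic samples (p_hat 0 or 1) return
    (0, 1); empty samples return NaN.
    """
    n0 = np.asarray(n0, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n2 + n1) / (2.0 * n)
        q = 1.0 - p
        e0 = n * q * q
        e1 = 2.0 * n * p * q
        e2 = n * p * p
        stat = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            stat = stat + term
        pval = chi2.sf(stat, df=1)
    mono = (p <= 0.0) | (p >= 1.0)
    stat = np.where(mono, 0.0, stat)
    pval = np.where(mono, 1.0, pval)
    empty = n == 0
    stat = np.where(empty, np.nan, stat)
    pval = np.where(empty, np.nan, pval)
    return stat, pval


def hwe_test(dataset: GenotypeDataset) -> HweResult:
    """Run the chi-square HWE screen for every SNP within every breed."""
    g = dataset.genotypes
    breeds = dataset.breed_ids
    idx = dataset.snp_table["snp_id"].to_numpy()
    stats, pvals = {}, {}
    counts = {key: {} for key in ("n_0", "n_1", "n_2")}
    for breed in breeds:
        sub = g[dataset.breed_mask(breed)]
        n0 = (sub == 0).sum(axis=0)
        n1 = (sub == 1).sum(axis=0)
        n2 = (sub == 2).sum(axis=0)
        stat, pval = hwe_chi_square(n0, n1, n2)
        stats[breed] = stat
        pvals[breed] = pval
        counts["n_0"][breed] = n0
        counts["n_1"][breed] = n1
        counts["n_2"][breed] = n2
    make = lambda cols: pd.DataFrame(cols, index=pd.Index(idx, name="snp_id"))
    return HweResult(
        chi2=make(stats),
        pvalue=make(pvals),
        counts={k: make(v) for k, v in counts.items()},
    )


def genes_deviating_hwe(
    hwe: HweResult,
    gene_map: GeneMap,
    alpha: float = 0.01,
    min_frac: float | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-breed lists of genes deviating from HWE, plus their union.

    By default a gene is flagged for a breed if any of its SNP has
    ``p < alpha`` there; ``min_frac`` switches to requiring at least that
    fraction of the gene's SNP to deviate.
    """
    per_breed: dict[str, list[str]] = {}
    union: set[str] = set()
    sig = hwe.pvalue < alpha
    merged = gene_map.assignments.merge(
        sig.reset_index(), on="snp_id", how="inner"
    )
    for breed in hwe.pvalue.columns:
        by_gene = merged.groupby("gene_id")[breed]
        flagged = by_gene.mean() >= min_frac if min_frac else by_gene.any()
        genes = sorted(flagged[flagged].index)
        per_breed[breed] = genes
        union.update(genes)
    return per_breed, sorted(union)


@dataclass
class BreedClustering:
    """UPGMA dendrogram over breed gene-HET profiles."""

    breed_ids: list[str]
    linkage_matrix: np.ndarray
    cophenetic: pd.DataFrame

    def leaves(self) -> list[str]:
        return [self.breed_ids[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        flat = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.breed_ids, (int(c) for c in flat)))

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        node = to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.breed_ids[node.id]
            left = walk(node.left)
            right = walk(node.right)
            bl = lambda child: (node.dist - child.dist) / 2.0
            return (
                f"({left}:{bl(node.left):.6f},{right}:{bl(node.right):.6f})"
            )

        return walk(node) + ";"


def cluster_breeds(gene_het: pd.DataFrame) -> BreedClustering:
    """Agglomerative (average-linkage/UPGMA, Euclidean) clustering of the
    breed columns of the gene x breed HET matrix.  Genes with any missing
    value are dropped first; breeds are ordered by id for determinism."""
    if gene_het.shape[1] < 2:
        raise PipelineError("breed clustering needs at least two breeds")
    clean = gene_het.dropna(axis=0)
    if len(clean) < len(gene_het):
        logger.warning(
            "dropped %d genes with missing HET before clustering",
            len(gene_het) - len(clean),
        )
    breeds = sorted(gene_het.columns)
    profiles = clean[breeds].T.to_numpy()
    z = linkage(profiles, method="average", metric="euclidean")
    coph = squareform(cophenet(z, pdist(profiles))[1])
    return BreedClustering(
        breed_ids=breeds,
        linkage_matrix=z,
        cophenetic=pd.DataFrame(coph, index=breeds, columns=breeds),
    )
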