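"""SNP and gene filters applied ahead of all analyses.

Three rules: drop sex-chromosome SNP, assign SNP to every gene whose span
padded by a 1-kb window contains the SNP position (boundaries inclusive),
and keep only genes carrying at least the median per-gene SNP count (the
threshold can also be fixed to an integer).  All filters are idempotent.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneMap, GenotypeDataset, PipelineError

logger = logging.getLogger("cohet.preprocess")


def filter_autosomal(
    dataset: GenotypeDataset, autosomes: Sequence[str]
) -> GenotypeDataset:
    """Keep only SNP mapped to the listed autosomes; animals unchanged."""
    wanted = {str(c) for c in autosomes}
    mask = dataset.snp_table["chromosome"].astype(str).isin(wanted).to_numpy()
    if not mask.any():
        raise PipelineError("no SNP left after autosome filter")
    dropped = int((~mask).sum())
    if dropped:
        logger.info("autosome filter dropped %d SNP", dropped)
    return dataset.subset_snps(mask)


def map_snp_to_genes(
    dataset: GenotypeDataset,
    annotation: pd.DataFrame,
    window_bp: int = 1000,
) -> GeneMap:
    """Assign each SNP to every gene whose padded span contains it.

    A SNP at exactly ``start - window_bp`` or ``end + window_bp`` is
    assigned (inclusive boundaries); a SNP inside two overlapping padded
    spans is assigned to both genes.  SNP matching no gene simply receive
    no assignment and are thereby excluded from gene-level analyses.
    """
    if annotation.empty:
        raise PipelineError("gene annotation is empty")
    pairs: list[tuple[str, str]] = []
    snp = dataset.snp_table
    for chrom, genes_c in annotation.groupby("chromosome", sort=False):
        sub = snp[snp["chromosome"].astype(str) == str(chrom)]
        if sub.empty:
            continue
        order = np.argsort(sub["position"].to_numpy(), kind="mergesort")
        pos = sub["position"].to_numpy()[order]
        ids = sub["snp_id"].to_numpy()[order]
        lo = np.searchsorted(pos, genes_c["start"].to_numpy() - window_bp, side="left")
        hi = np.searchsorted(pos, genes_c["end"].to_numpy() + window_bp, side="right")
        for gene_id, a, b in zip(genes_c["gene_id"], lo, hi):
            pairs.extend((gene_id, s) for s in ids[a:b])
    assignments = pd.DataFrame(pairs, columns=["gene_id", "snp_id"])
    gene_map = GeneMap(genes=annotation.reset_index(drop=True), assignments=assignments)
    logger.info(
        "assigned %d SNP-gene pairs over %d genes",
        len(assignments),
        len(annotation),
    )
    return gene_map


def filter_genes_by_snp_count(
    gene_map: GeneMap, min_snp: int | str = "median"
) -> GeneMap:
    """Drop genes with fewer SNP than the threshold.

    ``min_snp="median"`` uses the median per-gene SNP count over genes with
    at least one SNP; with an even number of genes the lower of the two
    central values is taken, keeping the threshold an attainable integer.
    """
    counts = gene_map.snp_counts()
    nonzero = counts[counts > 0]
    if nonzero.empty:
        raise PipelineError("no gene has any assigned SNP")
    if min_snp == "median":
        values = np.sort(nonzero.to_numpy())
        threshold = int(values[(len(values) - 1) // 2])
    else:
        threshold = int(min_snp)
    keep = counts[counts >= threshold].index
    logger.info(
        "gene SNP-count filter (threshold %d) kept %d/%d genes",
        threshold,
        len(keep),
        len(counts),
    )
    return gene_map.subset_genes(keep)


def preprocess(
    dataset: GenotypeDataset,
    annotation: pd.DataFrame,
    autosomes: Sequence[str] | None = None,
    window_bp: int = 1000,
    min_snp: int | str = "median",
) -> tuple[GenotypeDataset, GeneMap]:
    """Run the full filter chain; the returned dataset is restricted to SNP
    assigned to at least one retained gene (the set all later stages use)."""
    if autosomes is not None:
        dataset = filter_autosomal(dataset, autosomes)
    gene_map = map_snp_to_genes(dataset, annotation, window_bp=window_bp)
    gene_map = filter_genes_by_snp_count(gene_map, min_snp=min_snp)
    kept_snps = gene_map.assigned_snp_ids()
    if not kept_snps:
        raise PipelineError("no SNP assigned to retained genes")
    return dataset.subset_snps(np.array(kept_snps)), gene_map
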