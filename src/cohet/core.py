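"""Core data model shared across the pipeline.

The pipeline operates on a single in-memory representation of a genotyped
panel: an animals x SNP matrix of minor-allele counts plus three side tables
(SNP map, animal/breed assignment, breed/lineage assignment).  Gene-level
analyses additionally carry a :class:`GeneMap` linking SNP to the genes whose
1-kb-padded span contains them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cohet")

#: Sentinel for a missing genotype.  All statistics exclude missing entries.
MISSING: int = -1

#: Recognised breed lineages: pure Bos indicus, pure Bos taurus, and
#: taurine-indicine composites/crossbreds.
LINEAGES: tuple[str, ...] = ("BI", "BT", "BTI")


class CohetError(Exception):
    """Base class for package errors."""


class ConfigError(CohetError, ValueError):
    """Invalid configuration (simulation or stage parameters)."""


class FormatError(CohetError, ValueError):
    """Malformed input file; message names the file and, where known, line."""


class PipelineError(CohetError, RuntimeError):
    """A stage precondition failed (e.g. a filter left no SNP)."""


@dataclass
class GenotypeDataset:
    """Animals x SNP genotype matrix with its map, animal and breed tables.

    genotypes
        ``(n_animals, n_snp)`` integer array of minor-allele counts in
        ``{0, 1, 2}`` with :data:`MISSING` for no-calls.
    snp_table
        One row per SNP, aligned with matrix columns: ``snp_id``,
        ``chromosome``, ``position`` (1-based), ``allele_minor``,
        ``allele_major``.
    animal_table
        One row per animal, aligned with matrix rows: ``animal_id``,
        ``breed_id`` (extra metadata columns are preserved).
    breed_table
        One row per breed: ``breed_id``, ``lineage`` in :data:`LINEAGES`.
    """

    genotypes: np.ndarray
    snp_table: pd.DataFrame
    animal_table: pd.DataFrame
    breed_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n_animals, n_snp = self.genotypes.shape
        if len(self.snp_table) != n_snp:
            raise FormatError(
                f"snp_table has {len(self.snp_table)} rows for {n_snp} matrix columns"
            )
        if len(self.animal_table) != n_animals:
            raise FormatError(
                f"animal_table has {len(self.animal_table)} rows for "
                f"{n_animals} matrix rows"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise FormatError(f"genotype codes outside {{0,1,2,{MISSING}}}: {bad}")
        if (self.snp_table["position"] <= 0).any():
            raise FormatError("SNP positions must be positive (1-based)")
        known = set(self.breed_table["breed_id"])
        used = set(self.animal_table["breed_id"])
        orphan = used - known
        if orphan:
            raise FormatError(f"animals reference unknown breeds: {sorted(orphan)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snp_table["snp_id"])

    @property
    def breed_ids(self) -> list[str]:
        return sorted(self.breed_table["breed_id"])

    def lineage_of(self, breed_id: str) -> str:
        table = self.breed_table.set_index("breed_id")["lineage"]
        return table[breed_id]

    def breed_mask(self, breed_id: str) -> np.ndarray:
        return (self.animal_table["breed_id"] == breed_id).to_numpy()

    def lineage_mask(self, lineage: str) -> np.ndarray:
        breeds = set(
            self.breed_table.loc[self.breed_table["lineage"] == lineage, "breed_id"]
        )
        return self.animal_table["breed_id"].isin(breeds).to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing genotypes."""
        g = self.genotypes
        obs = g != MISSING
        counts = np.where(obs, g, 0).sum(axis=0)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, counts / (2 * n), np.nan)

    # -- subsetting --------------------------------------------------------
    def subset_snps(self, keep: np.ndarray | Sequence[str]) -> "GenotypeDataset":
        """Return a dataset restricted to the given SNP (bool mask, integer
        positions, or SNP ids; original column order is preserved)."""
        keep_arr = np.asarray(keep)
        if keep_arr.dtype == bool:
            idx = np.flatnonzero(keep_arr)
        elif np.issubdtype(keep_arr.dtype, np.integer):
            idx = keep_arr
        else:
            pos = pd.Series(
                np.arange(self.n_snp), index=self.snp_table["snp_id"].to_numpy()
            )
            idx = np.sort(pos[pd.Index(keep_arr)].to_numpy())
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            snp_table=self.snp_table.iloc[idx].reset_index(drop=True),
        )


@dataclass
class GeneMap:
    """Gene spans plus a many-to-many SNP-to-gene assignment.

    genes
        One row per gene: ``gene_id``, ``chromosome``, ``start``, ``end``
        (1-based inclusive coordinates, the MAP-position convention).
    assignments
        One row per (gene, SNP) pair: ``gene_id``, ``snp_id``.  A SNP inside
        two overlapping padded spans appears once per gene.
    """

    genes: pd.DataFrame
    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.genes["gene_id"].duplicated()
        if dup.any():
            raise FormatError(
                f"duplicate gene ids: {sorted(self.genes.loc[dup, 'gene_id'])}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes["gene_id"])

    def snp_counts(self) -> pd.Series:
        """Number of assigned SNP per gene (genes with zero SNP included)."""
        counts = self.assignments.groupby("gene_id").size()
        return counts.reindex(sorted(self.genes["gene_id"]), fill_value=0)

    def snps_for(self, gene_id: str) -> list[str]:
        sub = self.assignments.loc[self.assignments["gene_id"] == gene_id, "snp_id"]
        return sub.tolist()

    def subset_genes(self, gene_ids: Iterable[str]) -> "GeneMap":
        keep = set(gene_ids)
        return GeneMap(
            genes=self.genes[self.genes["gene_id"].isin(keep)].reset_index(drop=True),
            assignments=self.assignments[
                self.assignments["gene_id"].isin(keep)
            ].reset_index(drop=True),
        )

    def assigned_snp_ids(self) -> list[str]:
        """SNP assigned to at least one gene, deduplicated, in sorted order."""
        return sorted(self.assignments["snp_id"].unique())


def check_lineages(values: Iterable[str]) -> None:
    bad = sorted(set(values) - set(LINEAGES))
    if bad:
        raise FormatError(f"unknown lineage codes {bad}; expected one of {LINEAGES}")
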