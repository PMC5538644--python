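"""Synthetic admixed-genotype panels for exercising the pipeline.

The generator emulates the statistical structure of a multi-breed cattle
panel descended from two diverged subspecies (indicine and taurine):

* two ancestral allele-frequency vectors diverged at a tunable F_ST under
  the Balding-Nichols model;
* pure breeds (ancestry proportion 0 or 1) and admixed/composite breeds
  (0 < alpha < 1) whose animals draw each allele copy from the indicine
  pool with probability alpha — i.e. unlinked SNP, no LD;
* SNP organised into gene blocks of at least six SNP, with decoy SNP more
  than 1 kb away from every gene;
* optional "skewed" gene sets whose SNP are made strongly ancestry
  informative toward a designated component, for testing the gene-set
  permutation machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, ConfigError, GeneMap, GenotypeDataset, LINEAGES

logger = logging.getLogger("cohet.synthetic")

#: Keep simulated allele frequencies off the exact 0/1 boundary.
_FREQ_EPS = 1e-6

#: Base-pair spacing between consecutive SNP inside a gene block.
_INTRA_GENE_SPACING = 200
#: Gap between a gene span and the next feature; > 2x the 1-kb window so
#: padded spans never overlap and decoys are unambiguous.
_INTER_FEATURE_GAP = 4000


@dataclass(frozen=True)
class BreedSpec:
    """One simulated breed: id, lineage, indicine ancestry, herd size."""

    breed_id: str
    lineage: str
    ancestry: float  # proportion of indicine allele copies, alpha
    n_animals: int


@dataclass(frozen=True)
class SkewedSet:
    """A gene set engineered to be ancestry-informative for one component."""

    name: str
    n_genes: int
    component: Literal["indicine", "taurine"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic panel.

    ``fst`` is the Balding-Nichols divergence between the two subspecies;
    ``ancestral_maf_range`` bounds the ancestral minor-allele frequency
    (the ancestral frequency is the drawn MAF or its mirror, equally
    likely); ``snp_per_gene`` SNP are laid inside every gene span and the
    remainder become intergenic decoys.
    """

    n_snp: int
    n_genes: int
    breeds: Sequence[BreedSpec]
    n_chromosomes: int = 1
    fst: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    snp_per_gene: int = 6
    skewed_sets: Sequence[SkewedSet] = field(default_factory=tuple)
    #: standard deviation of animal-level indicine ancestry within BTI
    #: breeds (Beta-distributed around the breed mean).  0 means every
    #: animal draws each allele copy independently at the breed mean, which
    #: keeps admixed breeds in Hardy-Weinberg equilibrium; a positive value
    #: makes herd-mates heterogeneous in ancestry and produces the Wahlund
    #: heterozygote deficit real composite breeds show.
    ancestry_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ConfigError(f"fst must be in (0, 1), got {self.fst}")
        if self.snp_per_gene < 6:
            raise ConfigError("genes must carry at least six SNP")
        if self.n_snp < self.snp_per_gene * self.n_genes:
            raise ConfigError(
                f"n_snp={self.n_snp} cannot host {self.n_genes} genes of "
                f"{self.snp_per_gene} SNP each"
            )
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("ancestral_maf_range must lie within (0, 0.5]")
        if self.n_chromosomes < 1 or self.n_chromosomes > self.n_genes:
            raise ConfigError("need 1 <= n_chromosomes <= n_genes")
        if not self.breeds:
            raise ConfigError("at least one breed is required")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.ancestry_sd < 0:
            raise ConfigError("ancestry_sd must be non-negative")
        seen = set()
        for b in self.breeds:
            if b.breed_id in seen:
                raise ConfigError(f"duplicate breed_id {b.breed_id!r}")
            seen.add(b.breed_id)
            if b.lineage not in LINEAGES:
                raise ConfigError(f"unknown lineage {b.lineage!r} for {b.breed_id}")
            if b.lineage == "BI" and b.ancestry != 1.0:
                raise ConfigError(f"BI breed {b.breed_id} must have ancestry 1")
            if b.lineage == "BT" and b.ancestry != 0.0:
                raise ConfigError(f"BT breed {b.breed_id} must have ancestry 0")
            if b.lineage == "BTI" and not 0 < b.ancestry < 1:
                raise ConfigError(
                    f"BTI breed {b.breed_id} needs ancestry strictly inside (0, 1)"
                )
            if b.n_animals < 1:
                raise ConfigError(f"breed {b.breed_id} needs at least one animal")
        if sum(s.n_genes for s in self.skewed_sets) > self.n_genes:
            raise ConfigError("skewed sets oversubscribe the gene pool")
        names = [s.name for s in self.skewed_sets]
        if len(names) != len(set(names)):
            raise ConfigError("skewed set names must be unique")

    # deterministic, independent streams for each generation step
    def _rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream,))
        return np.random.default_rng(ss)

    @property
    def mean_indicine_ancestry(self) -> float:
        """Animal-weighted mean indicine ancestry of the whole panel."""
        total = sum(b.n_animals for b in self.breeds)
        return sum(b.n_animals * b.ancestry for b in self.breeds) / total

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        breeds = [
            BreedSpec(
                breed_id=str(b["breed_id"]),
                lineage=str(b["lineage"]),
                ancestry=float(b["ancestry"]),
                n_animals=int(b["n_animals"]),
            )
            for b in raw.pop("breeds")
        ]
        sets = [
            SkewedSet(
                name=str(s["name"]),
                n_genes=int(s["n_genes"]),
                component=s["component"],
            )
            for s in raw.pop("skewed_sets", [])
        ]
        if "ancestral_maf_range" in raw:
            raw["ancestral_maf_range"] = tuple(raw["ancestral_maf_range"])
        return cls(breeds=breeds, skewed_sets=sets, **raw)


class SubspeciesFreqs(NamedTuple):
    """Per-SNP allele-A frequency in each subspecies pool."""

    p_indicine: np.ndarray
    p_taurine: np.ndarray


def simulate_allele_freqs(config: SimulationConfig) -> SubspeciesFreqs:
    """Draw diverged subspecies allele frequencies (Balding-Nichols).

    An ancestral frequency ``p`` is drawn uniformly from the configured MAF
    range or its mirror ``1 - p`` (each with probability 1/2); each
    subspecies frequency is then Beta-distributed with mean ``p`` and
    variance ``p (1 - p) fst``, i.e. ``Beta(p (1-F)/F, (1-p) (1-F)/F)``.
    """
    rng = config._rng(0)
    lo, hi = config.ancestral_maf_range
    maf = rng.uniform(lo, hi, size=config.n_snp)
    mirror = rng.random(config.n_snp) < 0.5
    p_anc = np.where(mirror, 1.0 - maf, maf)
    f = config.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    p_ind = rng.beta(a, b)
    p_tau = rng.beta(a, b)
    clip = lambda p: np.clip(p, _FREQ_EPS, 1.0 - _FREQ_EPS)
    return SubspeciesFreqs(clip(p_ind), clip(p_tau))


def assign_gene_blocks(config: SimulationConfig) -> tuple[GeneMap, pd.DataFrame]:
    """Lay SNP on chromosomes in gene blocks plus intergenic decoys.

    Genes are split as evenly as possible across chromosomes; each gene span
    covers a contiguous block of ``snp_per_gene`` SNP.  Leftover SNP are
    placed after the genes of each chromosome with > 1 kb clearance so the
    1-kb window rule never captures them.  Returns the resulting
    :class:`GeneMap` and the SNP table (``snp_id, chromosome, position``)
    in matrix column order.
    """
    n_gene_snp = config.snp_per_gene * config.n_genes
    n_decoys = config.n_snp - n_gene_snp

    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1
    decoys_per_chrom = np.full(config.n_chromosomes, n_decoys // config.n_chromosomes)
    decoys_per_chrom[: n_decoys % config.n_chromosomes] += 1

    snp_rows: list[tuple[str, str, int]] = []
    gene_rows: list[tuple[str, str, int, int]] = []
    assign_rows: list[tuple[str, str]] = []
    snp_i = 0
    gene_i = 0
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        pos = 1000
        for _ in range(genes_per_chrom[c]):
            gene_id = f"g{gene_i:05d}"
            gene_i += 1
            first = pos
            for _ in range(config.snp_per_gene):
                snp_id = f"snp{snp_i:06d}"
                snp_i += 1
                snp_rows.append((snp_id, chrom, pos))
                assign_rows.append((gene_id, snp_id))
                last = pos
                pos += _INTRA_GENE_SPACING
            gene_rows.append((gene_id, chrom, first, last))
            pos = last + _INTER_FEATURE_GAP
        for _ in range(decoys_per_chrom[c]):
            snp_id = f"snp{snp_i:06d}"
            snp_i += 1
            snp_rows.append((snp_id, chrom, pos))
            pos += _INTER_FEATURE_GAP

    snp_table = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position"])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "start", "end"])
    assignments = pd.DataFrame(assign_rows, columns=["gene_id", "snp_id"])
    return GeneMap(genes=genes, assignments=assignments), snp_table


def designate_skewed_sets(
    config: SimulationConfig,
    gene_map: GeneMap,
    freqs: SubspeciesFreqs,
) -> tuple[dict[str, list[str]], SubspeciesFreqs]:
    """Pick disjoint gene sets and make their SNP ancestry-informative.

    For each requested set, genes are drawn without replacement and the
    subspecies frequencies of their SNP are overwritten so that
    ``|p_indicine - p_taurine|`` is large and the allele common in the
    designated component's pure lineage is the *panel-wide minor* allele
    (taking the breed mix into account).  That places the SNP firmly in the
    matching mode of the PC1-loading mixture downstream.
    """
    if not config.skewed_sets:
        return {}, freqs

    rng = config._rng(2)
    p_ind = freqs.p_indicine.copy()
    p_tau = freqs.p_taurine.copy()
    # frequency arrays follow snp-table (layout) order
    _, snp_table = assign_gene_blocks(config)
    snp_pos = {s: i for i, s in enumerate(snp_table["snp_id"])}

    alpha_bar = config.mean_indicine_ancestry
    available = sorted(gene_map.genes["gene_id"])
    sets: dict[str, list[str]] = {}
    for spec in config.skewed_sets:
        if spec.n_genes > len(available):
            raise ConfigError(f"skewed set {spec.name!r} oversubscribes remaining genes")
        chosen = sorted(rng.choice(available, size=spec.n_genes, replace=False))
        available = [g for g in available if g not in set(chosen)]
        sets[spec.name] = chosen

        # high frequency in the designated pure lineage, low in the other;
        # cap the high side so the informative allele stays globally minor
        if spec.component == "taurine":
            weight_hi = 1.0 - alpha_bar
        else:
            weight_hi = alpha_bar
        p_lo = 0.05
        cap = (0.45 - (1.0 - weight_hi) * p_lo) / max(weight_hi, 1e-9)
        p_hi_target = float(np.clip(cap, 0.35, 0.90))

        snp_idx = np.array(
            [
                snp_pos[s]
                for g in chosen
                for s in gene_map.assignments.loc[
                    gene_map.assignments["gene_id"] == g, "snp_id"
                ]
            ]
        )
        hi = rng.uniform(p_hi_target - 0.05, p_hi_target, size=snp_idx.size)
        lo = rng.uniform(0.02, 0.08, size=snp_idx.size)
        if spec.component == "taurine":
            p_tau[snp_idx] = hi
            p_ind[snp_idx] = lo
        else:
            p_ind[snp_idx] = hi
            p_tau[snp_idx] = lo
    return sets, SubspeciesFreqs(p_ind, p_tau)


def simulate_genotypes(
    config: SimulationConfig,
    freqs: SubspeciesFreqs,
    snp_table: pd.DataFrame | None = None,
) -> GenotypeDataset:
    """Sample genotypes for every breed; recode to minor-allele counts.

    Each allele copy of an animal from a breed with indicine ancestry
    ``alpha`` descends from the indicine pool with probability ``alpha`` and
    is then Bernoulli with that pool's allele-A frequency.  Genotypes are
    recoded to counts of the panel-wide minor allele (ties toward allele A,
    the first-listed allele).  The realised indicine ancestry fraction of
    each animal is recorded in ``animal_table["true_ancestry"]``.
    """
    if snp_table is None:
        _, snp_table = assign_gene_blocks(config)
    n_snp = config.n_snp
    if len(snp_table) != n_snp or len(freqs.p_indicine) != n_snp:
        raise ConfigError("snp_table/freqs size does not match config.n_snp")

    rng = config._rng(1)
    blocks: list[np.ndarray] = []
    animal_rows: list[tuple[str, str, float]] = []
    for breed in config.breeds:
        n = breed.n_animals
        alpha = np.full(n, breed.ancestry)
        if breed.lineage == "BTI" and config.ancestry_sd > 0:
            mean = breed.ancestry
            var = min(config.ancestry_sd**2, 0.9 * mean * (1.0 - mean))
            conc = mean * (1.0 - mean) / var - 1.0
            alpha = rng.beta(mean * conc, (1.0 - mean) * conc, size=n)
        anc = rng.random((n, n_snp, 2)) < alpha[:, None, None]
        p = np.where(anc, freqs.p_indicine[None, :, None], freqs.p_taurine[None, :, None])
        g_a = (rng.random((n, n_snp, 2)) < p).sum(axis=2).astype(np.int8)
        blocks.append(g_a)
        realised = anc.mean(axis=(1, 2))
        for j in range(n):
            animal_rows.append(
                (f"{breed.breed_id}_{j:04d}", breed.breed_id, float(realised[j]))
            )

    g_a = np.vstack(blocks)
    freq_a = g_a.mean(axis=0) / 2.0
    a_is_minor = freq_a <= 0.5  # tie -> allele A, the first-listed allele
    genotypes = np.where(a_is_minor[None, :], g_a, 2 - g_a).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes = np.where(miss, MISSING, genotypes).astype(np.int8)

    snp_table = snp_table.copy()
    snp_table["allele_minor"] = np.where(a_is_minor, "A", "B")
    snp_table["allele_major"] = np.where(a_is_minor, "B", "A")

    animal_table = pd.DataFrame(
        animal_rows, columns=["animal_id", "breed_id", "true_ancestry"]
    )
    breed_table = pd.DataFrame(
        [(b.breed_id, b.lineage, b.ancestry) for b in config.breeds],
        columns=["breed_id", "lineage", "ancestry"],
    )
    return GenotypeDataset(
        genotypes=genotypes,
        snp_table=snp_table,
        animal_table=animal_table,
        breed_table=breed_table,
    )


@dataclass
class SimulationResult:
    """A complete synthetic panel plus its generating truth."""

    config: SimulationConfig
    dataset: GenotypeDataset
    gene_map: GeneMap
    gene_sets: dict[str, list[str]]
    #: subspecies frequencies re-expressed on the minor-allele scale used by
    #: the genotype coding (so pure-breed allele-frequency estimates should
    #: recover them directly)
    freqs_minor: SubspeciesFreqs
    #: raw allele-A frequencies as simulated
    freqs: SubspeciesFreqs


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: frequencies, layout, skewed sets, genotypes."""
    freqs = simulate_allele_freqs(config)
    gene_map, snp_table = assign_gene_blocks(config)
    gene_sets, freqs = designate_skewed_sets(config, gene_map, freqs)
    dataset = simulate_genotypes(config, freqs, snp_table)
    a_is_minor = (dataset.snp_table["allele_minor"] == "A").to_numpy()
    freqs_minor = SubspeciesFreqs(
        np.where(a_is_minor, freqs.p_indicine, 1.0 - freqs.p_indicine),
        np.where(a_is_minor, freqs.p_taurine, 1.0 - freqs.p_taurine),
    )
    logger.info(
        "simulated %d animals x %d SNP (%d genes, %d skewed sets)",
        dataset.n_animals,
        dataset.n_snp,
        config.n_genes,
        len(gene_sets),
    )
    return SimulationResult(
        config=config,
        dataset=dataset,
        gene_map=gene_map,
        gene_sets=gene_sets,
        freqs_minor=freqs_minor,
        freqs=freqs,
    )
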