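"""End-to-end orchestration of the six pipeline stages.

``run_pipeline`` executes simulate (or ingest) -> preprocess -> ancestry ->
heterozygosity -> geneset -> network inside a run directory.  Every stage
reads its inputs from the files earlier stages wrote and writes TSV/JSON
outputs plus a ``<stage>.ok`` marker, so individual stages can be re-run
and a ``resume`` run skips completed stages.  A manifest records package
version, seed, parameters and output checksums; identical config and seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GeneMap, GenotypeDataset, PipelineError
from . import ancestry as anc
from . import geneset as gs
from . import genotype_io as gio
from . import heterozygosity as het
from . import network as net
from . import preprocess as pre
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger("cohet.pipeline")

STAGES = ("simulate", "preprocess", "ancestry", "het", "geneset", "network")


def default_config() -> dict:
    """Paper-default stage parameters around a six-breed synthetic panel."""
    return {
        "simulate": {
            "n_snp": 9000,
            "n_genes": 1200,
            "n_chromosomes": 5,
            "fst": 0.2,
            "snp_per_gene": 6,
            "ancestry_sd": 0.15,
            "seed": 0,
            "breeds": [
                {"breed_id": "BI1", "lineage": "BI", "ancestry": 1.0, "n_animals": 150},
                {"breed_id": "BI2", "lineage": "BI", "ancestry": 1.0, "n_animals": 150},
                {"breed_id": "BT1", "lineage": "BT", "ancestry": 0.0, "n_animals": 150},
                {"breed_id": "BT2", "lineage": "BT", "ancestry": 0.0, "n_animals": 150},
                {"breed_id": "XB1", "lineage": "BTI", "ancestry": 0.5, "n_animals": 150},
                {"breed_id": "XB2", "lineage": "BTI", "ancestry": 0.25, "n_animals": 150},
            ],
            "skewed_sets": [
                {"name": "milk", "n_genes": 125, "component": "taurine"},
                {"name": "fertility", "n_genes": 86, "component": "indicine"},
            ],
        },
        "preprocess": {"window_bp": 1000, "min_snp": "median", "autosomes": None},
        "ancestry": {"k": 10, "cutoff": 0.95, "log_base": 10, "flag_threshold": 4},
        "het": {"alpha": 0.01},
        "geneset": {"n_perm": 10_000, "threshold": 0.5},
        "network": {"threshold": 0.95},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = default_config()
    for stage, block in user.items():
        if stage == "input":
            config["input"] = block
        elif stage in config and isinstance(block, Mapping):
            config[stage].update(block)
        else:
            config[stage] = block
    return config


# ---------------------------------------------------------------------------
# shared loaders
# ---------------------------------------------------------------------------

def _load_dataset(run_dir: Path, config: dict) -> GenotypeDataset:
    if "input" in config:
        inp = config["input"]
        prefix = Path(inp["plink_prefix"])
        dialect = inp.get("dialect", "ped")
        suffix = {"ped": (".ped", ".map"), "tped": (".tped", ".tfam")}[dialect]
        for ext in suffix:
            if not prefix.with_suffix(ext).exists():
                raise PipelineError(f"input file missing: {prefix.with_suffix(ext)}")
        return gio.read_plink(prefix, dialect, breed_table=inp.get("breed_table"))
    return gio.read_plink(run_dir / "simulate" / "panel", "tped",
                          breed_table=run_dir / "simulate" / "breeds.tsv")


def _load_annotation(run_dir: Path, config: dict) -> pd.DataFrame:
    if "input" in config:
        bed = Path(config["input"]["annotation_bed"])
        if not bed.exists():
            raise PipelineError(f"input file missing: {bed}")
        return gio.read_bed_annotation(bed)
    return gio.read_bed_annotation(run_dir / "simulate" / "genes.bed")


def _load_gene_map(run_dir: Path) -> GeneMap:
    genes = pd.read_csv(run_dir / "preprocess" / "genes.tsv", sep="\t",
                        dtype={"gene_id": str, "chromosome": str})
    assignments = pd.read_csv(run_dir / "preprocess" / "gene_map.tsv", sep="\t",
                              dtype=str)
    return GeneMap(genes=genes, assignments=assignments)


def _load_filtered_dataset(run_dir: Path, config: dict) -> tuple[GenotypeDataset, GeneMap]:
    dataset = _load_dataset(run_dir, config)
    gene_map = _load_gene_map(run_dir)
    kept = pd.read_csv(run_dir / "preprocess" / "snps_kept.tsv", sep="\t", dtype=str)
    return dataset.subset_snps(kept["snp_id"].to_numpy()), gene_map


def _gene_sets(run_dir: Path, config: dict) -> dict[str, list[str]]:
    sets_dir = run_dir / "simulate" / "sets"
    out: dict[str, list[str]] = {}
    if sets_dir.is_dir():
        for path in sorted(sets_dir.glob("*.tsv")):
            out[path.stem] = gio.read_gene_list(path)
    for name, path in (config.get("geneset", {}).get("gene_lists") or {}).items():
        out[name] = gio.read_gene_list(path)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(run_dir: Path, config: dict) -> None:
    if "input" in config:
        # ingestion mode: just verify inputs exist so errors surface early
        _load_dataset(run_dir, config)
        _load_annotation(run_dir, config)
        return
    out = run_dir / "simulate"
    sim_config = SimulationConfig.from_dict(config["simulate"])
    result = simulate(sim_config)
    gio.write_plink(result.dataset, out / "panel", dialect="tped")
    gio.write_breed_table(result.dataset, out / "breeds.tsv")
    gio.write_bed_annotation(result.gene_map.genes, out / "genes.bed")
    gio.write_tsv(
        result.dataset.animal_table[["animal_id", "breed_id", "true_ancestry"]],
        out / "truth_animals.tsv",
    )
    truth = result.dataset.snp_table[["snp_id"]].copy()
    truth["p_indicine"] = result.freqs_minor.p_indicine
    truth["p_taurine"] = result.freqs_minor.p_taurine
    gio.write_tsv(truth, out / "truth_freqs.tsv")
    for name, genes in result.gene_sets.items():
        gio.write_gene_list(genes, out / "sets" / f"{name}.tsv")


def stage_preprocess(run_dir: Path, config: dict) -> None:
    out = run_dir / "preprocess"
    dataset = _load_dataset(run_dir, config)
    annotation = _load_annotation(run_dir, config)
    params = config["preprocess"]
    filtered, gene_map = pre.preprocess(
        dataset,
        annotation,
        autosomes=params.get("autosomes"),
        window_bp=params.get("window_bp", 1000),
        min_snp=params.get("min_snp", "median"),
    )
    gio.write_tsv(gene_map.genes, out / "genes.tsv")
    gio.write_tsv(gene_map.assignments.sort_values(["gene_id", "snp_id"]),
                  out / "gene_map.tsv")
    gio.write_tsv(pd.DataFrame({"snp_id": filtered.snp_table["snp_id"]}),
                  out / "snps_kept.tsv")


def stage_ancestry(run_dir: Path, config: dict) -> None:
    out = run_dir / "ancestry"
    out.mkdir(parents=True, exist_ok=True)
    dataset, gene_map = _load_filtered_dataset(run_dir, config)
    params = config["ancestry"]
    std = anc.standardize_genotypes(dataset)
    bi_mask = dataset.lineage_mask("BI")
    k = min(params.get("k", 10), dataset.n_animals - 1, len(std.snp_ids))
    pca = anc.run_pca(std, k=k, bi_mask=bi_mask if bi_mask.any() else None)
    mixture = anc.fit_mixture(pca.loadings[:, 0], snp_ids=pca.snp_ids)
    gene_anc = anc.gene_ancestry(mixture, gene_map)

    scores = pd.DataFrame(
        pca.scores, columns=[f"pc{i + 1}" for i in range(pca.scores.shape[1])]
    )
    scores.insert(0, "animal_id", dataset.animal_table["animal_id"].to_numpy())
    gio.write_tsv(scores, out / "pca_scores.tsv")
    loadings = pd.DataFrame({"snp_id": pca.snp_ids, "pc1_loading": pca.loadings[:, 0]})
    gio.write_tsv(loadings, out / "loadings.tsv")
    gio.write_tsv(
        pd.DataFrame(
            {
                "component": [f"pc{i + 1}" for i in range(len(pca.var_explained))],
                "var_explained": pca.var_explained,
            }
        ),
        out / "var_explained.tsv",
    )
    with (out / "mixture.json").open("w") as fh:
        json.dump(mixture.params(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    gio.write_tsv(gene_anc, out / "gene_ancestry.tsv")
    gio.write_tsv(anc.chromosome_ancestry(gene_anc), out / "chromosome_ancestry.tsv")
    gio.write_tsv(
        anc.neglogp_profile(
            gene_anc,
            base=params.get("log_base", 10),
            flag_threshold=params.get("flag_threshold", 4),
        ),
        out / "neglogp.tsv",
    )
    ind, tau = anc.select_by_membership(gene_anc, cutoff=params.get("cutoff", 0.95))
    gio.write_gene_list(ind, out / "genes_indicine.tsv")
    gio.write_gene_list(tau, out / "genes_taurine.tsv")


def stage_het(run_dir: Path, config: dict) -> None:
    out = run_dir / "het"
    dataset, gene_map = _load_filtered_dataset(run_dir, config)
    alpha = config["het"].get("alpha", 0.01)
    table = het.compute_het(dataset, gene_map)
    gio.write_tsv(table.gene_het.reset_index(), out / "gene_het.tsv")
    gio.write_tsv(table.lineage_het.reset_index(), out / "lineage_het.tsv")
    gio.write_tsv(table.chrom_het.reset_index(), out / "chrom_het.tsv")
    hwe = het.hwe_test(dataset)
    gio.write_tsv(hwe.to_frame(), out / "hwe.tsv")
    per_breed, union = het.genes_deviating_hwe(hwe, gene_map, alpha=alpha)
    for breed, genes in per_breed.items():
        gio.write_gene_list(genes, out / "hwe_genes" / f"{breed}.tsv")
    gio.write_gene_list(union, out / "hwe_union.tsv")
    if len(table.gene_het.columns) >= 2:
        clustering = het.cluster_breeds(table.gene_het)
        (out / "breed_dendrogram.nwk").write_text(clustering.to_newick() + "\n")
    gene_anc = pd.read_csv(run_dir / "ancestry" / "gene_ancestry.tsv", sep="\t",
                           dtype={"gene_id": str, "chromosome": str})
    gio.write_tsv(
        gio.gene_summary_table(gene_map, table.lineage_het, gene_anc),
        out / "gene_summary.tsv",
    )


def stage_geneset(run_dir: Path, config: dict, seed: int) -> None:
    out = run_dir / "geneset"
    out.mkdir(parents=True, exist_ok=True)
    params = config["geneset"]
    gene_anc = pd.read_csv(run_dir / "ancestry" / "gene_ancestry.tsv", sep="\t",
                           dtype={"gene_id": str, "chromosome": str})
    sets = _gene_sets(run_dir, config)
    background = set(gene_anc["gene_id"])
    results = []
    for i, name in enumerate(sorted(sets)):
        members = [g for g in sets[name] if g in background]
        if not members:
            logger.warning("gene set %s has no genes in background; skipped", name)
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100 + i,)))
        results.append(
            gs.ancestry_permutation_test(
                gene_anc,
                members,
                n_perm=params.get("n_perm", 10_000),
                threshold=params.get("threshold", 0.5),
                seed=rng,
                set_name=name,
            )
        )
    gs.write_geneset_results(results, out / "permutation.json")

    hwe_union = gio.read_gene_list(run_dir / "het" / "hwe_union.tsv")
    ind = gio.read_gene_list(run_dir / "ancestry" / "genes_indicine.tsv")
    tau = gio.read_gene_list(run_dir / "ancestry" / "genes_taurine.tsv")
    fertility = sets.get("fertility", [])
    network_genes = gs.select_network_genes(hwe_union, [ind, tau], fertility)
    gio.write_gene_list(network_genes, out / "network_genes.tsv")

    attr_paths = params.get("attribute_tables") or {}
    tables = {name: gio.read_gene_list(path) for name, path in attr_paths.items()}
    tables["FE"] = fertility
    flags = gs.annotate_attributes(network_genes, tables)
    gio.write_tsv(flags.reset_index(), out / "attributes.tsv")

    term_path = params.get("term_map")
    if term_path:
        terms = pd.read_csv(term_path, sep="\t", dtype=str)
        term_map = terms.groupby("term")["gene_id"].apply(list).to_dict()
        overrep = gs.overrepresentation_test(
            hwe_union, term_map, sorted(background),
            p_cutoff=params.get("p_cutoff"),
        )
        gio.write_tsv(overrep, out / "overrepresentation.tsv")


def stage_network(run_dir: Path, config: dict) -> None:
    out = run_dir / "network"
    out.mkdir(parents=True, exist_ok=True)
    threshold = config["network"].get("threshold", 0.95)
    gene_het = pd.read_csv(run_dir / "het" / "gene_het.tsv", sep="\t",
                           dtype={"gene_id": str}).set_index("gene_id")
    network_genes = gio.read_gene_list(run_dir / "geneset" / "network_genes.tsv")
    gene_anc = pd.read_csv(run_dir / "ancestry" / "gene_ancestry.tsv", sep="\t",
                           dtype={"gene_id": str, "chromosome": str})
    flags = pd.read_csv(run_dir / "geneset" / "attributes.tsv", sep="\t",
                        dtype={"gene_id": str}).set_index("gene_id")

    present = [g for g in network_genes if g in gene_het.index]
    corr = net.correlation_matrix(gene_het, present)
    sig = net.pcit(corr)
    attrs = gene_anc.set_index("gene_id")[["pr_indicine", "pr_taurine"]].join(
        flags, how="left"
    )
    graph = net.build_network(corr, sig, threshold=threshold, node_attrs=attrs)
    net.write_edge_list(graph, out / "edges.tsv")
    net.write_graphml(graph, out / "network.graphml")
    diag = net.degree_diagnostics(graph)
    gio.write_tsv(diag.degrees.rename("degree").reset_index(), out / "degree.tsv")
    payload = {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "threshold": threshold,
        "hubs": diag.hubs,
        "scale_free": None if diag.fit is None else vars(diag.fit),
    }
    with (out / "scale_free.json").open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    fe = [g for g in (flags.index[flags.get("FE", pd.Series(dtype=bool)) == True]
                      if "FE" in flags.columns else [])]
    trio_payload: dict = {"trio": None}
    if len(set(fe) & set(graph.graph.nodes)) >= 3:
        trio = net.trio_span_search(graph, fe)
        trio_payload = {
            "trio": list(trio.trio),
            "coverage": trio.coverage,
            "n_covered": len(trio.covered),
            "method": trio.method,
        }
    else:
        logger.warning("fewer than 3 fertility genes in network; trio search skipped")
    with (out / "trio.json").open("w") as fh:
        json.dump(trio_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# in-memory composition (used by scripts and heavier tests)
# ---------------------------------------------------------------------------

from dataclasses import dataclass


@dataclass
class PanelAnalysis:
    """Results of the preprocess -> ancestry -> heterozygosity chain."""

    dataset: GenotypeDataset
    gene_map: GeneMap
    pca: "anc.PCAResult"
    mixture: "anc.MixtureAncestry"
    gene_ancestry: pd.DataFrame
    het: "het.HetTable"
    hwe: "het.HweResult"


def analyze_panel(
    sim,
    autosomes=None,
    window_bp: int = 1000,
    min_snp="median",
    k: int = 10,
) -> PanelAnalysis:
    """Run the core analysis chain on a :class:`SimulationResult` (or any
    object with ``dataset`` and ``gene_map`` attributes) without touching
    disk."""
    dataset, gene_map = pre.preprocess(
        sim.dataset,
        sim.gene_map.genes,
        autosomes=autosomes,
        window_bp=window_bp,
        min_snp=min_snp,
    )
    std = anc.standardize_genotypes(dataset)
    bi = dataset.lineage_mask("BI")
    k = min(k, dataset.n_animals - 1, len(std.snp_ids))
    pca = anc.run_pca(std, k=k, bi_mask=bi if bi.any() else None)
    mixture = anc.fit_mixture(pca.loadings[:, 0], snp_ids=pca.snp_ids)
    gene_anc = anc.gene_ancestry(mixture, gene_map)
    het_table = het.compute_het(dataset, gene_map)
    hwe = het.hwe_test(dataset)
    return PanelAnalysis(
        dataset=dataset,
        gene_map=gene_map,
        pca=pca,
        mixture=mixture,
        gene_ancestry=gene_anc,
        het=het_table,
        hwe=hwe,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    resume: bool = False,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Run the pipeline stages into ``out_dir``; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    config = copy.deepcopy(config)
    if seed is not None and "simulate" in config:
        config["simulate"]["seed"] = int(seed)
    run_seed = int(config.get("simulate", {}).get("seed", 0))
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    runners = {
        "simulate": lambda: stage_simulate(run_dir, config),
        "preprocess": lambda: stage_preprocess(run_dir, config),
        "ancestry": lambda: stage_ancestry(run_dir, config),
        "het": lambda: stage_het(run_dir, config),
        "geneset": lambda: stage_geneset(run_dir, config, run_seed),
        "network": lambda: stage_network(run_dir, config),
    }
    for stage in stages:
        marker = run_dir / f"{stage}.ok"
        if resume and marker.exists():
            logger.info("stage %s already complete; skipped", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            runners[stage]()
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
        marker.write_text("ok\n")

    manifest = {
        "package": "cohet",
        "version": __version__,
        "seed": run_seed,
        "config": config,
        "outputs": {
            str(p.relative_to(run_dir)): _sha256(p)
            for p in sorted(run_dir.rglob("*"))
            if p.is_file() and p.name != "manifest.json" and p.suffix != ".log"
        },
    }
    with (run_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return run_dir
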