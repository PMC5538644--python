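"""Gene-set statistics: ancestry-skew permutation test, over-representation,
functional-attribute annotation, and network gene selection.

The permutation test asks whether the number of genes in a set whose
taurine membership reaches a threshold could arise by drawing a same-sized
set at random (without replacement) from the background; its result is the
percentile of the observed count within the permutation distribution, with
ties excluded (strict-less convention).  Over-representation of a term's
genes in a target list uses the exact one-sided hypergeometric upper tail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import PipelineError

logger = logging.getLogger("cohet.geneset")


@dataclass
class GeneSetResult:
    """Permutation-test summary for one gene set."""

    set_name: str
    set_size: int
    n_background: int
    observed: int
    n_permutations: int
    threshold: float
    percentile: float
    permutation_counts: np.ndarray = field(repr=False)

    def summary(self) -> dict:
        return {
            "set_name": self.set_name,
            "set_size": self.set_size,
            "n_background": self.n_background,
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "threshold": self.threshold,
            "percentile": self.percentile,
        }


def ancestry_permutation_test(
    gene_ancestry: pd.DataFrame,
    gene_set: Sequence[str],
    n_perm: int = 10_000,
    threshold: float = 0.5,
    seed: int | np.random.Generator = 0,
    set_name: str = "gene_set",
) -> GeneSetResult:
    """Permutation percentile of a gene set's taurine-membership count.

    Each trial draws ``len(gene_set)`` genes without replacement from the
    background (all genes in ``gene_ancestry``) and counts how many have
    ``pr_taurine >= threshold``.  The percentile is
    ``100 * #{trials with count < observed} / n_perm`` — trials tying the
    observation do not count toward it.
    """
    if n_perm < 1:
        raise PipelineError("n_perm must be >= 1")
    background = gene_ancestry["gene_id"].to_numpy()
    hits = (gene_ancestry["pr_taurine"].to_numpy() >= threshold).astype(np.int64)
    index = pd.Index(background)
    members = pd.Index(pd.unique(pd.Series(list(gene_set))))
    if len(members) > len(background):
        raise PipelineError("gene set larger than background")
    missing = members.difference(index)
    if len(missing):
        raise PipelineError(f"gene set not contained in background: {list(missing)[:5]}")
    observed = int(hits[index.get_indexer(members)].sum())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    size = len(members)
    n_bg = len(background)
    # a without-replacement sample of `size` genes is the index of the
    # `size` smallest of n_bg iid uniform keys; chunked for memory
    chunk = max(1, int(4_000_000 // max(n_bg, 1)))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        keys = rng.random((stop - start, n_bg))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        counts[start:stop] = hits[idx].sum(axis=1)
    percentile = 100.0 * float((counts < observed).sum()) / n_perm
    return GeneSetResult(
        set_name=set_name,
        set_size=size,
        n_background=n_bg,
        observed=observed,
        n_permutations=n_perm,
        threshold=threshold,
        percentile=percentile,
        permutation_counts=counts,
    )


def overrepresentation_test(
    target_genes: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    background: Sequence[str],
    p_cutoff: float | None = None,
) -> pd.DataFrame:
    """Exact hypergeometric over-representation of each term in the target.

    For a background of ``N`` genes, a term covering ``K`` of them and a
    target of ``n`` genes overlapping the term in ``k``, the p-value is the
    upper tail ``P(X >= k)`` of Hypergeometric(N, K, n).  Terms are
    returned sorted by p (then term id); ``p_cutoff`` filters the report.
    """
    bg = pd.Index(pd.unique(pd.Series(list(background))))
    if len(bg) == 0:
        raise PipelineError("empty background")
    target = pd.Index(pd.unique(pd.Series(list(target_genes)))).intersection(bg)
    rows = []
    for term in sorted(term_map):
        term_genes = pd.Index(pd.unique(pd.Series(list(term_map[term])))).intersection(bg)
        k = len(target.intersection(term_genes))
        p = float(hypergeom.sf(k - 1, len(bg), len(term_genes), len(target)))
        rows.append((term, len(term_genes), len(target), k, p))
    result = pd.DataFrame(
        rows, columns=["term", "n_term", "n_target", "n_overlap", "p_value"]
    ).sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    if p_cutoff is not None:
        result = result[result["p_value"] <= p_cutoff].reset_index(drop=True)
    return result


def select_network_genes(
    hwe_union: Iterable[str],
    ancestry_lists: Iterable[Iterable[str]],
    fertility_list: Iterable[str] = (),
) -> list[str]:
    """Deduplicated, sorted union of the three candidate sources: genes out
    of HWE in any breed, genes of extreme indicine/taurine membership, and
    the a-priori fertility list."""
    union: set[str] = set(hwe_union)
    for lst in ancestry_lists:
        union.update(lst)
    union.update(fertility_list)
    return sorted(union)


def annotate_attributes(
    genes: Sequence[str],
    attribute_tables: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Boolean per-gene flags from user-supplied attribute gene lists.

    ``attribute_tables`` maps an attribute name (TF, TS, SE, KI, FE, ...)
    to the gene ids carrying it; genes absent from a table get False.
    """
    flags = pd.DataFrame(index=pd.Index(sorted(set(genes)), name="gene_id"))
    for name in sorted(attribute_tables):
        members = set(attribute_tables[name])
        flags[name] = flags.index.isin(members)
    return flags


def query_attributes(flags: pd.DataFrame, expr: str) -> list[str]:
    """Genes satisfying a boolean attribute expression, e.g.
    ``"TF and FE and (TS or SE or KI)"``."""
    return sorted(flags.query(expr).index)


def write_geneset_results(results: Iterable[GeneSetResult], path) -> None:
    """JSON summary of permutation results, deterministic key order."""
    payload = {r.set_name: r.summary() for r in results}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
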