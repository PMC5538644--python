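"""Co-heterozygosity network inference with PCIT.

Genes are connected when the Pearson correlation of their HET profiles
across breeds is both PCIT-significant and above a magnitude threshold.
PCIT examines every unordered gene trio (x, y, z): the three first-order
partial correlations are computed, a trio tolerance ``eps`` is the mean of
the signed ratios partial/raw (skipping ratios whose raw correlation is
zero), and edge (x, y) is discarded by the trio when
``|r_xy| <= |eps r_xz|`` and ``|r_xy| <= |eps r_yz|`` (non-strict).  An
edge is significant iff no trio discards it.  Diagnostics cover the
log-log degree-distribution fit (scale-free check), hub reporting, and the
search for the fertility-gene trio whose closed neighbourhood covers the
most network nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress

from .core import PipelineError

logger = logging.getLogger("cohet.network")

_CLIP = 1.0 - 1e-12


def correlation_matrix(
    gene_het: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between gene HET profiles across breeds.

    Rows of ``gene_het`` are genes, columns breeds (>= 3 required).
    Zero-variance or incomplete profiles are excluded with a warning.
    Off-diagonal values are clipped to +/-(1 - 1e-12) so downstream partial
    correlations stay finite; the diagonal is exactly 1.
    """
    if gene_het.shape[1] < 3:
        raise PipelineError("correlation needs HET profiles across >= 3 breeds")
    sub = gene_het if genes is None else gene_het.loc[list(genes)]
    ok = sub.notna().all(axis=1) & (sub.std(axis=1, ddof=0) > 0)
    if (~ok).any():
        logger.warning(
            "excluding %d genes with flat or incomplete HET profiles", int((~ok).sum())
        )
    sub = sub[ok]
    if len(sub) < 2:
        raise PipelineError("fewer than two usable gene profiles")
    r = np.corrcoef(sub.to_numpy())
    r = np.clip(r, -_CLIP, _CLIP)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=sub.index, columns=sub.index)


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation of x and y given z."""
    r_xy, r_xz, r_yz = (np.asarray(v, dtype=np.float64) for v in (r_xy, r_xz, r_yz))
    if (np.abs(r_xz) >= 1).any() or (np.abs(r_yz) >= 1).any():
        raise PipelineError("partial correlation undefined at |r| = 1; pre-clip inputs")
    out = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return float(out) if out.ndim == 0 else out


def _pcit_kernel(r: np.ndarray, keep: np.ndarray) -> None:
    n = r.shape[0]
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            rxy = r[x, y]
            for z in range(y + 1, n):
                rxz = r[x, z]
                ryz = r[y, z]
                pxy = (rxy - rxz * ryz) / math.sqrt((1.0 - rxz * rxz) * (1.0 - ryz * ryz))
                pxz = (rxz - rxy * ryz) / math.sqrt((1.0 - rxy * rxy) * (1.0 - ryz * ryz))
                pyz = (ryz - rxy * rxz) / math.sqrt((1.0 - rxy * rxy) * (1.0 - rxz * rxz))
                s = 0.0
                cnt = 0
                if rxy != 0.0:
                    s += pxy / rxy
                    cnt += 1
                if rxz != 0.0:
                    s += pxz / rxz
                    cnt += 1
                if ryz != 0.0:
                    s += pyz / ryz
                    cnt += 1
                if cnt == 0:
                    continue
                eps = s / cnt
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    keep[x, y] = False
                    keep[y, x] = False
                if abs(rxz) <= abs(eps * rxy) and abs(rxz) <= abs(eps * ryz):
                    keep[x, z] = False
                    keep[z, x] = False
                if abs(ryz) <= abs(eps * rxy) and abs(ryz) <= abs(eps * rxz):
                    keep[y, z] = False
                    keep[z, y] = False


try:  # compile the trio loop when numba is available; fall back to Python
    from numba import njit

    _pcit_kernel_fast = njit(cache=False)(_pcit_kernel)
except Exception:  # pragma: no cover - numba present in supported envs
    _pcit_kernel_fast = _pcit_kernel


def pcit(correlations: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Boolean edge-significance matrix from the PCIT trio rule.

    Every unordered trio is evaluated exactly once in canonical index
    order, so the result is deterministic.  Ratios with a zero raw
    correlation in the denominator are skipped and the trio tolerance is
    the mean of the remaining signed ratios; a trio with all three raw
    correlations zero discards nothing.
    """
    frame = isinstance(correlations, pd.DataFrame)
    r = correlations.to_numpy(dtype=np.float64) if frame else np.asarray(
        correlations, dtype=np.float64
    )
    n = r.shape[0]
    if r.shape != (n, n) or not np.allclose(r, r.T, atol=1e-10):
        raise PipelineError("correlation matrix must be square and symmetric")
    if n < 3:
        raise PipelineError("PCIT needs at least three genes")
    off = ~np.eye(n, dtype=bool)
    if (np.abs(r[off]) >= 1.0).any():
        raise PipelineError("off-diagonal |r| >= 1; clip correlations first")
    keep = np.ones((n, n), dtype=np.bool_)
    _pcit_kernel_fast(r, keep)
    np.fill_diagonal(keep, False)
    if frame:
        return pd.DataFrame(keep, index=correlations.index, columns=correlations.columns)
    return keep


@dataclass
class CoHetNetwork:
    """Thresholded PCIT-significant co-heterozygosity graph."""

    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (min(a, b), max(a, b), d["weight"], True)
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            sorted(rows), columns=["gene_a", "gene_b", "r", "significant"]
        )


def build_network(
    correlations: pd.DataFrame,
    significance: pd.DataFrame,
    threshold: float = 0.95,
    node_attrs: pd.DataFrame | None = None,
) -> CoHetNetwork:
    """Retain edges that are PCIT-significant and have ``|r| >= threshold``;
    nodes left without any edge are dropped from the sub-network."""
    if correlations.shape != significance.shape:
        raise PipelineError("correlation and significance matrices must conform")
    genes = list(correlations.index)
    r = correlations.to_numpy()
    sig = significance.to_numpy().astype(bool)
    mask = sig & (np.abs(r) >= threshold)
    graph = nx.Graph()
    xs, ys = np.nonzero(np.triu(mask, k=1))
    for i, j in zip(xs, ys):
        graph.add_edge(genes[i], genes[j], weight=float(r[i, j]))
    if node_attrs is not None:
        for gene in graph.nodes:
            if gene in node_attrs.index:
                graph.nodes[gene].update(
                    {k: _graphml_safe(v) for k, v in node_attrs.loc[gene].items()}
                )
    logger.info(
        "network at |r| >= %.2f: %d nodes, %d edges",
        threshold,
        graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return CoHetNetwork(graph=graph, threshold=threshold)


def _graphml_safe(value):
    if isinstance(value, (np.bool_, bool)):
        return bool(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    return value


@dataclass
class ScaleFreeFit:
    """Log-log regression of degree frequency on degree."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n_points: int


def scale_free_fit(degrees: Sequence[int]) -> ScaleFreeFit | None:
    """Regress log10(frequency of degree k) on log10(k) over observed
    k >= 1.  Returns None (with a warning) when fewer than two distinct
    degrees are observed."""
    degs = np.asarray([d for d in degrees if d >= 1])
    ks, freq = np.unique(degs, return_counts=True)
    if len(ks) < 2:
        logger.warning("scale-free fit refused: fewer than two distinct degrees")
        return None
    fit = linregress(np.log10(ks), np.log10(freq))
    return ScaleFreeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_points=len(ks),
    )


@dataclass
class DegreeDiagnostics:
    degrees: pd.Series
    fit: ScaleFreeFit | None
    hubs: list[str]


def degree_diagnostics(network: CoHetNetwork) -> DegreeDiagnostics:
    """Per-node degree table, scale-free fit, and max-degree hub genes."""
    degs = pd.Series(dict(network.graph.degree()), dtype=int).sort_index()
    degs.index.name = "gene_id"
    if degs.empty:
        return DegreeDiagnostics(degrees=degs, fit=None, hubs=[])
    top = degs.max()
    hubs = sorted(degs[degs == top].index)
    return DegreeDiagnostics(degrees=degs, fit=scale_free_fit(degs.to_numpy()), hubs=hubs)


@dataclass
class TrioSpanResult:
    trio: tuple[str, str, str]
    coverage: float
    covered: list[str]
    method: str


def _neighborhood_matrix(graph: nx.Graph, seeds: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    nodes = sorted(graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    mat = np.zeros((len(seeds), len(nodes)), dtype=bool)
    for i, s in enumerate(seeds):
        mat[i, pos[s]] = True
        for nb in graph.neighbors(s):
            mat[i, pos[nb]] = True
    return mat, nodes


def trio_span_search(
    network: CoHetNetwork,
    fe_genes: Iterable[str],
    method: str = "auto",
    exhaustive_limit: int = 100_000,
) -> TrioSpanResult:
    """Find the fertility-gene trio whose closed neighbourhood covers the
    largest fraction of network nodes.

    Coverage of a trio is ``|trio union its direct neighbours| / |nodes|``.
    All trios are enumerated when their number is at most
    ``exhaustive_limit``; otherwise a multi-start greedy search is used
    (grow a trio from every fertility seed by best marginal coverage).
    Ties break toward the lexicographically smallest trio.
    """
    graph = network.graph
    fe = sorted(set(fe_genes) & set(graph.nodes))
    if len(fe) < 3:
        raise PipelineError("trio search needs >= 3 fertility genes in the network")
    nbh, nodes = _neighborhood_matrix(graph, fe)
    n_nodes = len(nodes)

    def finish(best_idx: tuple[int, int, int], used: str) -> TrioSpanResult:
        cover = nbh[list(best_idx)].any(axis=0)
        trio = tuple(fe[i] for i in best_idx)
        return TrioSpanResult(
            trio=trio,
            coverage=float(cover.sum()) / n_nodes,
            covered=[nodes[i] for i in np.flatnonzero(cover)],
            method=used,
        )

    n_trios = math.comb(len(fe), 3)
    if method == "exhaustive" or (method == "auto" and n_trios <= exhaustive_limit):
        best, best_cov = None, -1
        for idx in combinations(range(len(fe)), 3):
            cov = int(nbh[list(idx)].any(axis=0).sum())
            if cov > best_cov:  # first (lexicographically smallest) wins ties
                best, best_cov = idx, cov
        return finish(best, "exhaustive")
    if method not in ("auto", "greedy"):
        raise PipelineError(f"unknown trio search method {method!r}")

    best, best_cov = None, -1
    for start in range(len(fe)):
        chosen = [start]
        cover = nbh[start].copy()
        for _ in range(2):
            gains = (nbh | cover[None, :]).sum(axis=1)
            gains[chosen] = -1
            pick = int(np.argmax(gains))  # argmax takes the first = smallest index
            chosen.append(pick)
            cover |= nbh[pick]
        idx = tuple(sorted(chosen))
        cov = int(cover.sum())
        if cov > best_cov or (cov == best_cov and idx < best):
            best, best_cov = idx, cov
    return finish(best, "greedy")


def write_edge_list(network: CoHetNetwork, path) -> None:
    from .genotype_io import write_tsv

    write_tsv(network.edge_table(), path)


def write_graphml(network: CoHetNetwork, path) -> None:
    """GraphML export with nodes and edges in deterministic order."""
    g = nx.Graph()
    g.add_nodes_from(sorted(network.graph.nodes(data=True)))
    for a, b, d in sorted(
        network.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
    ):
        g.add_edge(*sorted((a, b)), **d)
    nx.write_graphml(g, path)
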