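"""Independent oracles used to validate the package's implementations.

Everything here is written naively and separately from the library code:
these functions are the normative reference in equivalence tests and must
not import from the modules they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def weir_cockerham_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Two-population Weir-Cockerham theta over biallelic genotype matrices
    (animals x SNP minor-allele counts), ratio-of-sums across loci."""
    n1, n2 = g1.shape[0], g2.shape[0]
    p1, p2 = g1.mean(0) / 2.0, g2.mean(0) / 2.0
    h1, h2 = (g1 == 1).mean(0), (g2 == 1).mean(0)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    keep = (pbar > 0) & (pbar < 1)
    return float(a[keep].sum() / (a + b + c)[keep].sum())


def pcit_bruteforce(r: np.ndarray) -> np.ndarray:
    """Naive triple-loop PCIT: for every trio, tolerance = mean of signed
    partial/raw ratios (zero-denominator ratios skipped), edge discarded on
    non-strict double comparison; edge significant iff never discarded."""
    n = r.shape[0]
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    for x, y, z in itertools.combinations(range(n), 3):
        pairs = ((x, y, z), (x, z, y), (y, z, x))

        def partial(a: int, b: int, c: int) -> float:
            return (r[a, b] - r[a, c] * r[b, c]) / math.sqrt(
                (1.0 - r[a, c] * r[a, c]) * (1.0 - r[b, c] * r[b, c])
            )

        s = 0.0
        cnt = 0
        for a, b, c in pairs:
            if r[a, b] != 0.0:
                s += partial(a, b, c) / r[a, b]
                cnt += 1
        if cnt == 0:
            continue
        eps = s / cnt
        for a, b, c in pairs:
            if abs(r[a, b]) <= abs(eps * r[a, c]) and abs(r[a, b]) <= abs(eps * r[b, c]):
                keep[a, b] = keep[b, a] = False
    return keep


def random_correlation(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random dense correlation matrix (PSD by construction), clipped the
    way the network module expects."""
    data = rng.normal(size=(n + 5, n))
    r = np.corrcoef(data.T)
    r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)
    np.fill_diagonal(r, 1.0)
    return r


def best_trio_exhaustive(graph, candidates: list[str]) -> tuple[float, tuple]:
    """Exhaustive best closed-neighbourhood coverage over candidate trios."""
    nodes = set(graph.nodes)
    best_cov, best = -1.0, None
    for trio in itertools.combinations(sorted(candidates), 3):
        covered = set(trio)
        for g in trio:
            covered.update(graph.neighbors(g))
        cov = len(covered & nodes) / len(nodes)
        if cov > best_cov:
            best_cov, best = cov, trio
    return best_cov, best


def exhaustive_percentile(hits: np.ndarray, set_idx: list[int]) -> float:
    """Exact permutation percentile by enumerating every same-size subset of
    the background (strict-less tie convention)."""
    observed = int(hits[set_idx].sum())
    below = 0
    total = 0
    for combo in itertools.combinations(range(len(hits)), len(set_idx)):
        total += 1
        if int(hits[list(combo)].sum()) < observed:
            below += 1
    return 100.0 * below / total
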