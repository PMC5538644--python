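"""Ancestry dissection: PCA of standardized genotypes and mixture modelling.

The first principal component of a standardized multi-breed genotype matrix
captures the indicine-taurine axis.  Its per-SNP loadings form a bimodal
distribution that is modelled as a two-component univariate Normal mixture
fitted by EM; the posterior membership of each SNP in the lower-mean
(indicine) and higher-mean (taurine) component is averaged over a gene's
SNP to give the gene's indicine/taurine content, then summarised per
chromosome and thresholded into high-membership gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import MISSING, GeneMap, GenotypeDataset, PipelineError

logger = logging.getLogger("cohet.ancestry")

_NEGLOG_EPS = 1e-300
_VAR_FLOOR = 1e-12


@dataclass
class StandardizedGenotypes:
    """Unit-variance genotype matrix with the surviving SNP ids."""

    matrix: np.ndarray  # animals x snp, float64
    snp_ids: np.ndarray
    freq: np.ndarray  # per-SNP minor-allele frequency used for scaling


def standardize_genotypes(dataset: GenotypeDataset) -> StandardizedGenotypes:
    """Center and scale genotypes to ``(g - 2 p) / sqrt(2 p (1 - p))``.

    The allele frequency ``p`` is estimated over non-missing genotypes;
    missing entries contribute 0 after centering.  Monomorphic SNP carry no
    information and are dropped with a logged count.
    """
    if dataset.n_animals < 2:
        raise PipelineError("standardization needs at least two animals")
    g = dataset.genotypes.astype(np.float64)
    obs = dataset.genotypes != MISSING
    p = dataset.allele_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono == dataset.n_snp:
        raise PipelineError("all SNP are monomorphic")
    if n_mono:
        logger.warning("dropping %d monomorphic SNP before PCA", n_mono)
    g = g[:, poly]
    obs = obs[:, poly]
    p = p[poly]
    x = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[~obs] = 0.0
    return StandardizedGenotypes(
        matrix=x,
        snp_ids=dataset.snp_table.loc[poly, "snp_id"].to_numpy(),
        freq=p,
    )


@dataclass
class PCAResult:
    """Scores (animals x k), unit-norm loadings (SNP x k), variance shares."""

    scores: np.ndarray
    loadings: np.ndarray
    var_explained: np.ndarray
    snp_ids: np.ndarray


def run_pca(
    std: StandardizedGenotypes, k: int = 10, bi_mask: np.ndarray | None = None
) -> PCAResult:
    """Exact PCA via the animal-side covariance (animals << SNP).

    Loadings are recovered by back-projection and unit-normalized;
    ``var_explained`` is each component's share of the total variance of
    the standardized matrix.  When ``bi_mask`` flags the pure indicine
    animals, PC1 is oriented so their mean score is negative (indicine on
    the left of the axis).
    """
    x = std.matrix
    n, m = x.shape
    if not 1 <= k <= min(n - 1, m):
        raise PipelineError(f"k={k} out of range for {n} animals x {m} SNP")
    cov = x @ x.T
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:k]
    eigval = np.maximum(eigval[order], 0.0)
    u = eigvec[:, order]
    s = np.sqrt(eigval)
    scores = u * s
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = np.where(s > 0, (x.T @ u) / s, 0.0)
    var_explained = eigval / np.trace(cov)

    if bi_mask is not None and bi_mask.any():
        if scores[bi_mask, 0].mean() > 0:
            scores[:, 0] *= -1.0
            loadings[:, 0] *= -1.0
    return PCAResult(
        scores=scores,
        loadings=loadings,
        var_explained=var_explained,
        snp_ids=std.snp_ids,
    )


@dataclass
class MixtureAncestry:
    """Fitted two-component Normal mixture over PC1 SNP loadings.

    Component 1 (smaller mean) is the indicine mode, component 2 the
    taurine mode; ``m1``/``m2`` are per-SNP posterior memberships.
    """

    pi1: float
    mu1: float
    var1: float
    pi2: float
    mu2: float
    var2: float
    m1: np.ndarray
    m2: np.ndarray
    loglik_trace: np.ndarray
    snp_ids: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = False

    def posterior(self, x) -> np.ndarray:
        """Indicine-component posterior m1 evaluated at arbitrary points."""
        x = np.asarray(x, dtype=np.float64)
        l1 = np.log(self.pi1) + _norm_logpdf(x, self.mu1, self.var1)
        l2 = np.log(self.pi2) + _norm_logpdf(x, self.mu2, self.var2)
        return np.exp(l1 - np.logaddexp(l1, l2))

    def params(self) -> dict[str, float]:
        return {
            "pi_indicine": self.pi1,
            "mu_indicine": self.mu1,
            "var_indicine": self.var1,
            "pi_taurine": self.pi2,
            "mu_taurine": self.mu2,
            "var_taurine": self.var2,
            "loglik": float(self.loglik_trace[-1]),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def _norm_logpdf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def fit_mixture(
    loadings_pc1: np.ndarray,
    snp_ids: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> MixtureAncestry:
    """Maximum-likelihood EM fit of a two-component univariate Normal mixture.

    Initialization is deterministic: the data are split at their median and
    each half seeds one component's mean and variance, with equal mixing
    weights.  EM stops when the relative log-likelihood change drops below
    ``tol`` or after ``max_iter`` iterations.  Variances are floored at
    1e-12 to prevent component collapse.  The component with the smaller
    mean is labelled indicine.
    """
    x = np.asarray(loadings_pc1, dtype=np.float64)
    if x.size < 2 or np.unique(x).size < 2:
        raise PipelineError("mixture fit needs at least two distinct values")

    med = np.median(x)
    left = x[x <= med]
    right = x[x > med]
    if right.size == 0:  # heavy ties at the median
        left = x[x < med]
        right = x[x >= med]
    mu = np.array([left.mean(), right.mean()])
    var = np.array([max(left.var(), _VAR_FLOOR), max(right.var(), _VAR_FLOOR)])
    pi = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [
                np.log(pi[0]) + _norm_logpdf(x, mu[0], var[0]),
                np.log(pi[1]) + _norm_logpdf(x, mu[1], var[1]),
            ]
        )
        norm = logsumexp(logp, axis=0)
        loglik = float(norm.sum())
        resp = np.exp(logp - norm)
        trace.append(loglik)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(loglik - prev) <= tol * abs(prev):
                converged = True
                break
        w = resp.sum(axis=1)
        pi = w / x.size
        mu = (resp @ x) / w
        var = np.maximum((resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / w, _VAR_FLOOR)

    # label the lower-mean component as indicine
    lo, hi = (0, 1) if mu[0] <= mu[1] else (1, 0)
    return MixtureAncestry(
        pi1=float(pi[lo]),
        mu1=float(mu[lo]),
        var1=float(var[lo]),
        pi2=float(pi[hi]),
        mu2=float(mu[hi]),
        var2=float(var[hi]),
        m1=resp[lo],
        m2=resp[hi],
        loglik_trace=np.asarray(trace),
        snp_ids=None if snp_ids is None else np.asarray(snp_ids),
        n_iter=it,
        converged=converged,
    )


def gene_ancestry(mixture: MixtureAncestry, gene_map: GeneMap) -> pd.DataFrame:
    """Collapse SNP posteriors to per-gene indicine/taurine membership.

    The gene posterior is the unweighted mean of its SNP ``m1``; genes with
    no posterior-bearing SNP (e.g. all monomorphic) are excluded with a
    warning.  Returns gene_id, chromosome, n_snp, pr_indicine, pr_taurine.
    """
    if mixture.snp_ids is None:
        raise PipelineError("mixture carries no SNP ids; fit with snp_ids=")
    post = pd.DataFrame({"snp_id": mixture.snp_ids, "m1": mixture.m1})
    merged = gene_map.assignments.merge(post, on="snp_id", how="inner")
    agg = merged.groupby("gene_id")["m1"].agg(["mean", "size"])
    missing = set(gene_map.genes["gene_id"]) - set(agg.index)
    if missing:
        logger.warning("%d genes lack posterior-bearing SNP; excluded", len(missing))
    table = (
        agg.rename(columns={"mean": "pr_indicine", "size": "n_snp"})
        .reset_index()
        .merge(gene_map.genes[["gene_id", "chromosome"]], on="gene_id", how="left")
    )
    table["pr_taurine"] = 1.0 - table["pr_indicine"]
    return (
        table[["gene_id", "chromosome", "n_snp", "pr_indicine", "pr_taurine"]]
        .sort_values("gene_id")
        .reset_index(drop=True)
    )


def select_by_membership(
    gene_ancestry: pd.DataFrame, cutoff: float = 0.95
) -> tuple[list[str], list[str]]:
    """High-membership gene lists: (indicine >= cutoff, taurine >= cutoff)."""
    if not 0.5 < cutoff <= 1.0:
        raise PipelineError(f"membership cutoff must be in (0.5, 1], got {cutoff}")
    ind = gene_ancestry.loc[gene_ancestry["pr_indicine"] >= cutoff, "gene_id"]
    tau = gene_ancestry.loc[gene_ancestry["pr_taurine"] >= cutoff, "gene_id"]
    return sorted(ind), sorted(tau)


def neglogp_profile(
    gene_ancestry: pd.DataFrame, base: float = 10.0, flag_threshold: float = 4.0
) -> pd.DataFrame:
    """Genome-profile statistic: -log of the opposing component's posterior.

    A gene's standing on the indicine profile is ``-log(pr_taurine)`` (high
    indicine content means a vanishing taurine posterior) and vice versa;
    genes exceeding ``flag_threshold`` are flagged as significant
    contributors.  Posteriors are clamped at 1e-300 before the log.
    """
    out = gene_ancestry[["gene_id", "chromosome"]].copy()
    scale = np.log(base)
    for profile, opposing in (("indicine", "pr_taurine"), ("taurine", "pr_indicine")):
        p = np.clip(gene_ancestry[opposing].to_numpy(), _NEGLOG_EPS, None)
        val = -np.log(p) / scale
        out[f"neglogp_{profile}"] = val
        out[f"flag_{profile}"] = val > flag_threshold
    return out


def chromosome_ancestry(gene_ancestry: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome mean gene membership (unweighted over genes)."""
    agg = (
        gene_ancestry.groupby("chromosome")
        .agg(n_genes=("gene_id", "size"), pr_indicine=("pr_indicine", "mean"))
        .reset_index()
    )
    agg["pr_taurine"] = 1.0 - agg["pr_indicine"]
    return agg.sort_values("chromosome").reset_index(drop=True)
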