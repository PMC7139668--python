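"""Two-group differential expression on count matrices, with SE intersection.

The differential test is a deliberately simple negative-binomial exact-style
test: counts are scaled to a common library size, a single common
dispersion is estimated across genes by the method of moments, per-group
scaled sums are formed, and the p-value is the exact conditional tail of
one group's sum given the total, with each group sum modeled as NB with
size ``n_g / dispersion``.  In the dispersion -> 0 limit this reduces to
the conditional binomial (Poisson two-sample) exact test.  Full
edgeR-style machinery (TMM normalization, tagwise empirical-Bayes
dispersion, GLMs) is intentionally not replicated.

Fold-change/FDR filtering follows the standard thresholds: a gene is "up"
iff ``log2fc >= log2(fc_min)`` and ``fdr < fdr_max``, "down"
symmetrically, else "ns".  Also included: log-CPM normalization, the
SE-flagged-gene intersection count, a preranked running-sum enrichment
score, and a deterministic hierarchical row ordering for expression
heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

log = logging.getLogger(__name__)

GROUPS = ("control", "knockdown")

#: dispersion below this is treated as Poisson in the exact conditional test
_POISSON_EPS = 1.0e-8


class CountMatrix:
    """A gene x sample integer count table with two-group labels."""

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, str]) -> None:
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(groups.values()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        missing = [s for s in counts.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.counts = counts
        self.groups = pd.Series({s: groups[s] for s in counts.columns})

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path: str | Path, groups: Mapping[str, str]) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, groups)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def log_cpm(cm: CountMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    ``log2((count + prior) / (libsize + 2 * prior) * 1e6)`` per cell.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    libs = cm.library_sizes()
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {list(zero.index)}")
    return np.log2((cm.counts + prior).div(libs + 2 * prior, axis=1) * 1.0e6)


def estimate_common_dispersion(cm: CountMatrix) -> float:
    """Common NB dispersion by the method of moments across all genes.

    Counts are scaled to the mean library size; per gene and group,
    ``phi = (var - mean) / mean^2``; the common value is the median over
    informative genes, floored at 0.
    """
    libs = cm.library_sizes()
    scaled = cm.counts * (libs.mean() / libs)
    phis: list[np.ndarray] = []
    for group in GROUPS:
        sub = scaled[cm.samples_in(group)]
        if sub.shape[1] < 2:
            continue
        mean = sub.mean(axis=1).to_numpy()
        var = sub.var(axis=1, ddof=1).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mean) / mean**2
        phis.append(phi[np.isfinite(phi) & (mean > 0)])
    if not phis:
        raise ValueError("dispersion estimation needs >=2 samples in a group")
    pooled = np.concatenate(phis)
    if pooled.size == 0:
        return 0.0
    return float(max(0.0, np.median(pooled)))


def exact_conditional_test(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    dispersion: float,
) -> float:
    """Two-sided exact conditional p for group sums under a common NB model.

    Conditions on the total ``sum_a + sum_b``; the p-value sums the
    probabilities of all splits no more likely than the observed one.
    ``dispersion`` <= ~1e-8 uses the Poisson limit (conditional binomial).
    """
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if dispersion <= _POISSON_EPS:
        logp = sps.binom.logpmf(s, total, n_a / (n_a + n_b))
    else:
        mean = total / (n_a + n_b)  # per-sample mean under the null
        r_a, r_b = n_a / dispersion, n_b / dispersion
        p_a = r_a / (r_a + n_a * mean)
        p_b = r_b / (r_b + n_b * mean)
        logp = sps.nbinom.logpmf(s, r_a, p_a) + sps.nbinom.logpmf(s[::-1], r_b, p_b)
    # normalize in probability space (the conditional pmf)
    logp = logp - logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[sum_a]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


@dataclass(frozen=True)
class DETestConfig:
    prior: float = 0.5
    dispersion: float | None = None  # None -> method-of-moments estimate


def de_test(cm: CountMatrix, config: DETestConfig | None = None) -> pd.DataFrame:
    """Per-gene differential expression of knockdown vs control.

    Returns a frame indexed by gene with columns ``log2fc`` (mean log-CPM
    difference, knockdown minus control), ``p`` (exact-style conditional NB
    test on library-scaled group sums) and ``fdr`` (BH).  Genes with zero
    counts everywhere get ``p = 1``, ``log2fc = 0`` and ``allzero = True``.
    """
    config = config or DETestConfig()
    for group in GROUPS:
        if len(cm.samples_in(group)) < 2:
            raise ValueError(f"need >=2 samples in group {group!r}")
    ctrl = cm.samples_in("control")
    kd = cm.samples_in("knockdown")
    lcpm = log_cpm(cm, prior=config.prior)
    log2fc = (lcpm[kd].mean(axis=1) - lcpm[ctrl].mean(axis=1)).to_numpy()

    phi = (config.dispersion if config.dispersion is not None
           else estimate_common_dispersion(cm))
    log.info("common dispersion: %.4g", phi)
    libs = cm.library_sizes()
    scaled = cm.counts * (libs.mean() / libs)
    sums_a = scaled[ctrl].sum(axis=1).round().astype(int).to_numpy()
    sums_b = scaled[kd].sum(axis=1).round().astype(int).to_numpy()
    allzero = (cm.counts.sum(axis=1) == 0).to_numpy()

    pvals = np.ones(len(cm.genes))
    for i in range(len(cm.genes)):
        if allzero[i]:
            continue
        pvals[i] = exact_conditional_test(
            int(sums_a[i]), int(sums_b[i]), len(ctrl), len(kd), phi
        )
    log2fc = np.where(allzero, 0.0, log2fc)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": bh_fdr(pvals),
            "allzero": allzero,
        },
        index=pd.Index(cm.genes, name="gene"),
    )


def de_filter(
    results: pd.DataFrame,
    fc_min: float = 1.5,
    fdr_max: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Classify genes as up/down/ns by fold-change and FDR thresholds.

    Adds a ``status`` column to ``results`` in place and returns
    ``(down_genes, up_genes)``.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1 (a fold change)")
    lfc_min = np.log2(fc_min)
    up = (results["log2fc"] >= lfc_min) & (results["fdr"] < fdr_max)
    down = (results["log2fc"] <= -lfc_min) & (results["fdr"] < fdr_max)
    status = np.where(up, "up", np.where(down, "down", "ns"))
    results["status"] = status
    return list(results.index[down]), list(results.index[up])


def se_gene_de_count(
    results: pd.DataFrame,
    se_flag: Mapping[str, bool] | pd.Series,
) -> tuple[int, int]:
    """(number of SE-flagged genes, how many of them are differentially expressed).

    ``results`` must carry the ``status`` column from :func:`de_filter`.
    """
    if "status" not in results.columns:
        raise ValueError("run de_filter first (missing 'status' column)")
    flags = pd.Series(se_flag)
    missing = [g for g in results.index if g not in flags.index]
    if missing:
        raise ValueError(f"genes without SE flag: {missing[:5]}")
    flagged = results.index[flags.loc[results.index].astype(bool)]
    n_se = len(flagged)
    n_se_de = int((results.loc[flagged, "status"] != "ns").sum())
    return n_se, n_se_de


@dataclass(frozen=True)
class EnrichmentScore:
    gene_set: str
    es: float
    leading_edge: list[str]


def preranked_es(
    ranked: pd.Series,
    gene_set: Sequence[str],
    weight: float = 1.0,
    set_id: str = "set",
) -> EnrichmentScore:
    """Classic weighted Kolmogorov-Smirnov preranked enrichment score.

    ``ranked`` maps gene -> ranking score; genes are ranked by descending
    score.  Hits advance the running sum by ``|score|^weight`` (normalized);
    misses retreat by ``1/(N - Nh)``.  The enrichment score is the signed
    maximum deviation and the leading edge contains the set genes at or
    before (after, for negative ES) the extremum.
    """
    genes = list(ranked.sort_values(ascending=False, kind="mergesort").index)
    in_set = set(gene_set)
    if not in_set:
        raise ValueError("gene set is empty")
    if not in_set <= set(genes):
        raise ValueError("gene set must be a subset of the ranked universe")
    n, nh = len(genes), len(in_set)
    if nh >= n:
        raise ValueError("gene set must be a proper subset of the universe")
    scores = ranked.loc[genes].to_numpy(dtype=float)
    hit = np.array([g in in_set for g in genes])
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted steps
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit) / (n - nh)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g in genes[: i_ext + 1] if g in in_set]
    else:
        leading = [g for g in genes[i_ext:] if g in in_set]
    return EnrichmentScore(gene_set=set_id, es=es, leading_edge=leading)


def cluster_gene_order(matrix: pd.DataFrame) -> list[str]:
    """Deterministic hierarchical row order for expression heatmaps.

    Rows are z-scaled, clustered with Euclidean distance and complete
    linkage; ties resolve to input order via scipy's deterministic leaf
    ordering.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    order = leaves_list(linkage(z, method="complete", metric="euclidean"))
    return [matrix.index[i] for i in order]
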