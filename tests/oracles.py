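"""Brute-force reference implementations used as independent oracles.

Each function re-derives a pipeline quantity by exhaustive/per-base
computation, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def brute_overlap_classes(peaks_a, peaks_b, min_overlap):
    """All-pairs O(n^2) shared/only classification of set A against B."""
    shared = set()
    for p in peaks_a:
        for q in peaks_b:
            if p.chrom != q.chrom:
                continue
            if min(p.end, q.end) - max(p.start, q.start) >= min_overlap:
                shared.add(p.name)
                break
    return shared


def brute_loop_counts(peaks, loops):
    """All-pairs loop counting: a loop counts once per peak touching an anchor."""
    counts = {p.name: 0 for p in peaks}
    for lp in loops:
        for p in peaks:
            hit = False
            for anchor in (lp.anchor1, lp.anchor2):
                if (p.chrom == anchor.chrom
                        and min(p.end, anchor.end) - max(p.start, anchor.start) > 0):
                    hit = True
            if hit:
                counts[p.name] += 1
    return counts


def brute_bin_counts(fragments, chrom, edges):
    """Per-base membership counting summed into bins."""
    out = np.zeros(len(edges) - 1, dtype=int)
    for f in fragments:
        if f.chrom != chrom:
            continue
        for i in range(len(edges) - 1):
            if f.start < edges[i + 1] and f.end > edges[i]:
                out[i] += 1
    return out


def brute_range_count(fragments, chrom, start, end):
    return sum(
        1 for f in fragments
        if f.chrom == chrom and f.start < end and f.end > start
    )


def brute_nearest_tss(peaks, tss):
    """Exhaustive nearest-TSS scan with the coordinate/lexicographic tie rule."""
    out = {}
    for p in peaks:
        s = p.summit_or_midpoint()
        cands = [
            (abs(s - iv.start), iv.start, gene)
            for iv, gene in tss
            if iv.chrom == p.chrom
        ]
        out[p.name] = min(cands)[2] if cands else "NA"
    return out


def permutation_mw_p(x, y, n_resamples, seed):
    """Monte-Carlo two-sided permutation p for the Mann-Whitney U statistic."""
    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size

    def u_stat(a, b):
        # U of a: number of (i, j) pairs with a_i > b_j (+0.5 for ties)
        diff = a[:, None] - b[None, :]
        return (diff > 0).sum() + 0.5 * (diff == 0).sum()

    u_obs = u_stat(x, y)
    mu = n1 * y.size / 2
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        u = u_stat(perm[:n1], perm[n1:])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / n_resamples


def running_sum_es(ordered_genes, scores, gene_set, weight):
    """Direct running-sum recomputation of the preranked enrichment score."""
    n = len(ordered_genes)
    nh = len(gene_set)
    w = [abs(s) ** weight if g in gene_set else 0.0
         for g, s in zip(ordered_genes, scores)]
    denom = sum(w) or float(nh)
    if sum(w) == 0:
        w = [1.0 if g in gene_set else 0.0 for g in ordered_genes]
    running, best = 0.0, 0.0
    for g, wi in zip(ordered_genes, w):
        if g in gene_set:
            running += wi / denom
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best
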