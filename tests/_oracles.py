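"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (full enumeration, direct formulas,
explicit counting) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_copying_posteriors(
    ref: np.ndarray, obs: np.ndarray, stay: np.ndarray, eps: float
) -> np.ndarray:
    """Exact hidden-path posteriors by summing over all H**M paths.

    ref : (H, M) 0/1 reference alleles
    obs : (M,) observed target alleles, -1 where untyped
    stay : (M-1,) per-step no-switch probabilities
    Returns the (M, H) marginal posterior of the copied haplotype.
    """
    H, M = ref.shape
    post = np.zeros((M, H))
    total = 0.0
    for path in itertools.product(range(H), repeat=M):
        p = 1.0 / H
        for j in range(M):
            if j > 0:
                st = stay[j - 1]
                p *= st + (1 - st) / H if path[j] == path[j - 1] else (1 - st) / H
            if obs[j] >= 0:
                p *= (1 - eps) if ref[path[j], j] == obs[j] else eps
        for j in range(M):
            post[j, path[j]] += p
        total += p
    return post / total


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson's Fst estimator as a ratio of averages over sites.

    p1, p2 : per-site alt-allele frequencies in the two populations
    n1, n2 : haplotype sample sizes
    """
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def pearson_direct(x, y) -> float:
    """Pearson r straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))


def maf_decile_counts(maf: np.ndarray, floor: float) -> np.ndarray:
    """Direct count of panel SNPs per MAF decile of [floor, 0.5]."""
    edges = np.linspace(floor, 0.5, 11)
    counts = np.zeros(10, dtype=int)
    for m in maf:
        b = min(int((m - floor) / (edges[1] - edges[0])), 9)
        counts[b] += 1
    return counts
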