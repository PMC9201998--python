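"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (explicit loops,
exact arithmetic where feasible) and shares no code with the package.
"""

from fractions import Fraction
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by full enumeration


def hwe_exact_oracle(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact HWE p-value by enumerating every heterozygote
    configuration with the observed allele counts, using exact rationals."""
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    probs = {}
    total = Fraction(0)
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 0 or hom_c < 0:
            continue
        # multinomial count of genotype assignments x 2^h allele arrangements
        ways = Fraction(
            comb(n, hom_r) * comb(n - hom_r, h) * 2**h
        )
        probs[h] = ways
        total += ways
    probs = {h: w / total for h, w in probs.items()}
    obs = probs[n_het]
    return float(sum(w for w in probs.values() if w <= obs))


# ---------------------------------------------------------------------------
# four-taxon statistics, per-site loops


def pattern_sums_oracle(p1, p2, p3, pO):
    abba = baba = bbaa = 0.0
    for a, b, c, d in zip(p1, p2, p3, pO):
        abba += (1 - a) * b * c * (1 - d) + a * (1 - b) * (1 - c) * d
        baba += a * (1 - b) * c * (1 - d) + (1 - a) * b * (1 - c) * d
        bbaa += a * b * (1 - c) * (1 - d) + (1 - a) * (1 - b) * c * d
    return abba, baba, bbaa


def patterson_d_oracle(p1, p2, p3, pO):
    num = den = 0.0
    for a, b, c, d in zip(p1, p2, p3, pO):
        num += (b - a) * (c - d)
        den += (b + a - 2 * a * b) * (c + d - 2 * c * d)
    return num / den


def jackknife_oracle(p1, p2, p3, pO, n_blocks):
    """Delete-one block jackknife Z by explicitly recomputing D per deletion."""
    n = len(p1)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    d_full = patterson_d_oracle(p1, p2, p3, pO)
    loo = []
    for b in range(n_blocks):
        keep = [i for i in range(n) if not (edges[b] <= i < edges[b + 1])]
        loo.append(
            patterson_d_oracle(
                [p1[i] for i in keep], [p2[i] for i in keep],
                [p3[i] for i in keep], [pO[i] for i in keep],
            )
        )
    loo = np.array(loo)
    var = (n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()
    return d_full / np.sqrt(var)


def fdm_window_oracle(p1, p2, p3, pO):
    """f_dM for one window: dynamic-denominator ratio, per-site loop."""
    num = den_pos = den_neg = 0.0
    for a, b, c, d in zip(p1, p2, p3, pO):
        num += (b - a) * (c - d)
        pd = max(b, c)
        den_pos += (pd - a) * (pd - d)
        pn = max(a, c)
        den_neg += (b - pn) * (pn - d)
    den = abs(den_pos) if num >= 0 else abs(den_neg)
    if den == 0:
        return 0.0
    return max(-1.0, min(1.0, num / den))


# ---------------------------------------------------------------------------
# haplotype statistics


def ehh_oracle(haps, rows, core, x) -> float:
    """Fraction of haplotype pairs from ``rows`` identical at every site
    between core and x inclusive."""
    lo, hi = min(core, x), max(core, x)
    ident = 0
    pairs = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            pairs += 1
            if all(haps[rows[i], s] == haps[rows[j], s] for s in range(lo, hi + 1)):
                ident += 1
    return ident / pairs


def ehh12_oracle(haps, core, x) -> float:
    """Pooled-top-2 extended haplotype homozygosity over all haplotypes."""
    lo, hi = min(core, x), max(core, x)
    keys = {}
    for h in range(haps.shape[0]):
        k = tuple(haps[h, lo:hi + 1])
        keys[k] = keys.get(k, 0) + 1
    counts = sorted(keys.values(), reverse=True)
    if len(counts) >= 2:
        counts[0] += counts[1]
        counts[1] = 0
    K = haps.shape[0]
    return sum(c * (c - 1) for c in counts) / (K * (K - 1))


def mean_shared_length_oracle(haps, rows, core) -> float:
    """Mean over pairs of the length (in sites) of the maximal identical run
    containing the core site."""
    n_sites = haps.shape[1]
    lengths = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if haps[a, core] != haps[b, core]:
                lengths.append(0)
                continue
            lo = core
            while lo - 1 >= 0 and haps[a, lo - 1] == haps[b, lo - 1]:
                lo -= 1
            hi = core
            while hi + 1 < n_sites and haps[a, hi + 1] == haps[b, hi + 1]:
                hi += 1
            lengths.append(hi - lo + 1)
    return float(np.mean(lengths))


# ---------------------------------------------------------------------------
# DCMS and multiple testing


def dcms_oracle(p, x):
    """Literal double loop over the composite formula."""
    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    n_snp, n_stat = p.shape
    r = np.empty((n_stat, n_stat))
    for i in range(n_stat):
        for t in range(n_stat):
            xi, xt = x[:, i], x[:, t]
            r[i, t] = (
                ((xi - xi.mean()) * (xt - xt.mean())).sum()
                / np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xt - xt.mean()) ** 2).sum())
            )
    out = np.zeros(n_snp)
    for l in range(n_snp):
        for t in range(n_stat):
            w = 1.0 / sum(abs(r[i, t]) for i in range(n_stat))
            out[l] += w * np.log((1 - p[l, t]) / p[l, t])
    return out


def bh_oracle(p):
    """Step-up formula applied literally to the sorted vector."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = running
    q = np.empty(n)
    q[order] = q_sorted
    return q


def rank_pvalue_oracle(values):
    """Right-tail count-based p with half correction and tie averaging."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    out = np.empty(n)
    for i in range(n):
        greater = int((v > v[i]).sum())
        ties = int((v == v[i]).sum())
        # average descending rank over tied values
        r = greater + (ties + 1) / 2.0
        out[i] = (r - 0.5) / n
    return out


def hudson_fst_oracle(p1, p2, n1, n2):
    """Ratio-of-averages Hudson Fst from sample frequencies."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
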