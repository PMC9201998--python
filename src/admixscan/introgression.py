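"""Four-taxon introgression statistics on population allele frequencies.

Given derived/alt-allele frequencies for a quartet (P1, P2, P3, OUT) related
by the rooted tree (((P1, P2), P3), OUT), this module computes the ABBA/BABA
site-pattern sums, Patterson's D with a block-jackknife Z-score, the f4-ratio
admixture-fraction estimate (random split of P3 allele copies into two
halves), and a sliding-window f_dM local-ancestry scan with genome-wide
standardisation and tail calling.

Under the null of no gene flow, ABBA and BABA discordant patterns arise from
incomplete lineage sorting at equal rates, so D is centred on zero; an excess
of one pattern shifts D and, locally, gives f_dM windows of consistent sign —
positive when P3 shares excess derived variation with P2, negative with P1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, allele_freqs

logger = logging.getLogger(__name__)


@dataclass
class TrioFrequencies:
    """Per-site derived-allele frequencies for a (P1, P2, P3, OUT) quartet.

    Sites where any population has no genotyped sample are excluded at
    construction. ``p3_counts`` (derived copies, total copies per site) are
    kept when available so the f4-ratio can resample P3 allele copies.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    pO: np.ndarray
    chrom: np.ndarray | None = None
    pos_bp: np.ndarray | None = None
    p3_derived_copies: np.ndarray | None = None
    p3_total_copies: np.ndarray | None = None
    labels: tuple = ("P1", "P2", "P3", "OUT")

    def __post_init__(self) -> None:
        for a in ("p1", "p2", "p3", "pO"):
            v = np.asarray(getattr(self, a), dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{a} frequencies outside [0, 1]")
            setattr(self, a, v)
        n = len(self.p1)
        if not all(len(getattr(self, a)) == n for a in ("p2", "p3", "pO")):
            raise ValueError("frequency vectors differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.p1)

    def swap_p1_p2(self) -> "TrioFrequencies":
        return TrioFrequencies(
            self.p2, self.p1, self.p3, self.pO, self.chrom, self.pos_bp,
            self.p3_derived_copies, self.p3_total_copies,
            (self.labels[1], self.labels[0], self.labels[2], self.labels[3]),
        )


def trio_frequencies(
    ds: GenotypeDataset, p1: str, p2: str, p3: str, out: str, polarize: bool = False
) -> TrioFrequencies:
    """Build trio frequencies from a dataset, excluding sites where any of the
    four populations is entirely missing.

    With ``polarize=True`` the outgroup's major allele is taken as ancestral
    and frequencies are flipped accordingly; by default the alt allele is used
    as "derived" directly, which leaves D and f_dM unchanged because the
    outgroup enters the formulas symmetrically.
    """
    freqs = allele_freqs(ds, [p1, p2, p3, out])
    ok = np.ones(ds.n_snps, dtype=bool)
    for pop in (p1, p2, p3, out):
        ok &= freqs[f"n_{pop}"].to_numpy() > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d sites with an unobserved population", n_excluded)
    f1, f2, f3, fO = (freqs[p].to_numpy()[ok] for p in (p1, p2, p3, out))
    rows = ds.sample_indices(p3)
    d3 = ds.dosages[rows][:, ok]
    called = d3 != -1
    derived = np.where(called, d3, 0).sum(axis=0).astype(float)
    total = 2.0 * called.sum(axis=0)
    if polarize:
        flip = fO > 0.5
        f1, f2, f3, fO = (np.where(flip, 1 - f, f) for f in (f1, f2, f3, fO))
        derived = np.where(flip, total - derived, derived)
    return TrioFrequencies(
        f1, f2, f3, fO,
        chrom=ds.markers["chrom"].to_numpy()[ok],
        pos_bp=ds.markers["pos_bp"].to_numpy()[ok],
        p3_derived_copies=derived,
        p3_total_copies=total,
        labels=(p1, p2, p3, out),
    )


# ---------------------------------------------------------------------------
# pattern sums and D


@dataclass
class PatternSums:
    nABBA: float
    nBABA: float
    nBBAA: float


def pattern_sums(tf: TrioFrequencies) -> PatternSums:
    """Frequency-weighted counts of the three informative site patterns.

    Each sum adds, per site, the probability of drawing the pattern with the
    derived allele (B) in the named positions plus its ancestral/derived
    mirror image.
    """
    if tf.n_sites < 1:
        raise ValueError("no usable sites")
    p1, p2, p3, pO = tf.p1, tf.p2, tf.p3, tf.pO
    q1, q2, q3, qO = 1 - p1, 1 - p2, 1 - p3, 1 - pO
    return PatternSums(
        nABBA=float(np.sum(q1 * p2 * p3 * qO + p1 * q2 * q3 * pO)),
        nBABA=float(np.sum(p1 * q2 * p3 * qO + q1 * p2 * q3 * pO)),
        nBBAA=float(np.sum(p1 * p2 * q3 * qO + q1 * q2 * p3 * pO)),
    )


def _d_terms(p1, p2, p3, pO):
    num = (p2 - p1) * (p3 - pO)
    den = (p2 + p1 - 2 * p2 * p1) * (p3 + pO - 2 * p3 * pO)
    return num, den


def patterson_d(tf: TrioFrequencies) -> float:
    """Patterson's D = sum (p2-p1)(p3-pO) / sum (p2+p1-2 p2 p1)(p3+pO-2 p3 pO)."""
    num, den = _d_terms(tf.p1, tf.p2, tf.p3, tf.pO)
    if den.sum() <= 0:
        raise ZeroDivisionError("Patterson's D undefined: zero denominator")
    return float(num.sum() / den.sum())


@dataclass
class TrioStats:
    labels: tuple
    D: float
    Z_D: float
    f4_ratio: float
    n_sites: int
    n_blocks: int
    patterns: PatternSums = field(default=None)


def jackknife_z(tf: TrioFrequencies, n_blocks: int = 20) -> float:
    """Z-score of D from a delete-one block jackknife over contiguous
    equal-SNP-count blocks (sites are assumed genome-ordered)."""
    if n_blocks < 5:
        raise ValueError("need at least 5 jackknife blocks")
    if tf.n_sites < n_blocks:
        raise ValueError("fewer sites than jackknife blocks")
    num, den = _d_terms(tf.p1, tf.p2, tf.p3, tf.pO)
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den <= 0:
        raise ZeroDivisionError("Patterson's D undefined: zero denominator")
    d_full = tot_num / tot_den
    edges = np.linspace(0, tf.n_sites, n_blocks + 1).astype(int)
    d_loo = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        d_loo[b] = (tot_num - num[sl].sum()) / (tot_den - den[sl].sum())
    var = (n_blocks - 1) / n_blocks * np.sum((d_loo - d_loo.mean()) ** 2)
    if var == 0:
        warnings.warn("jackknife variance is zero; Z reported as +/-inf")
        return float(np.sign(d_full) * np.inf) if d_full != 0 else 0.0
    return float(d_full / np.sqrt(var))


def f4_ratio(tf: TrioFrequencies, seed=0) -> float:
    """Admixture-fraction estimate from a random split of P3's allele copies.

    At each site the derived copies among P3's sampled alleles are divided
    hypergeometrically into two halves a and b, and the ratio
    sum (p3a - pO)(p2 - p1) / sum (p3a - pO)(p3b - p1) is returned. When P2
    is an admixed population and P3 its donor source, the expectation of this
    ratio is the fraction of P2's ancestry derived from the P3 lineage.
    """
    if tf.p3_total_copies is None:
        raise ValueError("f4_ratio needs P3 allele-copy counts (use trio_frequencies)")
    m = tf.p3_total_copies.astype(int)
    k = tf.p3_derived_copies.astype(int)
    if np.any(m < 2):
        raise ValueError("every site needs >=2 P3 allele copies")
    rng = np.random.default_rng(seed)
    half_a = m // 2
    ka = rng.hypergeometric(k, m - k, half_a)
    pa = ka / half_a
    pb = (k - ka) / (m - half_a)
    num = np.sum((pa - tf.pO) * (tf.p2 - tf.p1))
    den = np.sum((pa - tf.pO) * (pb - tf.p1))
    if den == 0:
        raise ZeroDivisionError("f4-ratio undefined: zero denominator")
    return float(num / den)


def trio_stats(tf: TrioFrequencies, n_blocks: int = 20, seed=0) -> TrioStats:
    """D, jackknife Z, f4-ratio and pattern sums for one quartet."""
    return TrioStats(
        labels=tf.labels,
        D=patterson_d(tf),
        Z_D=jackknife_z(tf, n_blocks),
        f4_ratio=f4_ratio(tf, seed) if tf.p3_total_copies is not None else float("nan"),
        n_sites=tf.n_sites,
        n_blocks=n_blocks,
        patterns=pattern_sums(tf),
    )


# ---------------------------------------------------------------------------
# windowed f_dM


def _fdm_site_terms(p1, p2, p3, pO):
    """Per-site numerator and dynamic-denominator terms of f_dM.

    The numerator is the per-site D numerator (p2-p1)(p3-pO). The denominator
    uses the expected value under complete introgression: where the numerator
    sum is positive, the donor proxy P_D is the larger of {p2, p3} per site
    and the denominator term is (pD-p1)(pD-pO); where negative, P_D is the
    larger of {p1, p3} and the term is (p2-pD)(pD-pO).
    """
    num = (p2 - p1) * (p3 - pO)
    pd_pos = np.maximum(p2, p3)
    den_pos = (pd_pos - p1) * (pd_pos - pO)
    pd_neg = np.maximum(p1, p3)
    den_neg = (p2 - pd_neg) * (pd_neg - pO)
    return num, den_pos, den_neg


def fdm_values(p1, p2, p3, pO) -> float:
    """f_dM of one set of sites (a single window)."""
    num, den_pos, den_neg = _fdm_site_terms(p1, p2, p3, pO)
    s = num.sum()
    d = abs(den_pos.sum()) if s >= 0 else abs(den_neg.sum())
    return float(np.clip(s / d, -1.0, 1.0)) if d != 0 else 0.0


@dataclass
class WindowScore:
    chrom: str
    start_bp: int
    end_bp: int
    snp_start: int  # index of first SNP in the trio's site list
    fdm: float
    z_fdm: float = float("nan")
    ancestry_sign: str = "zero"  # P2_side(+) | P1_side(-) | zero


def fdm_scan(tf: TrioFrequencies, window_size: int = 10, step: int = 2) -> list[WindowScore]:
    """Sliding-window f_dM along each chromosome.

    Windows hold exactly ``window_size`` consecutive sites and advance by
    ``step``; the trailing partial window is dropped and windows never span
    chromosome boundaries. Spans are [first SNP bp, last SNP bp] inclusive.
    """
    if tf.chrom is None or tf.pos_bp is None:
        raise ValueError("fdm_scan needs per-site chrom/pos")
    scores: list[WindowScore] = []
    chroms = np.asarray(tf.chrom)
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        if len(idx) < window_size:
            warnings.warn(f"chromosome {c!r} has fewer than {window_size} sites; no windows")
            continue
        num, den_pos, den_neg = _fdm_site_terms(
            tf.p1[idx], tf.p2[idx], tf.p3[idx], tf.pO[idx]
        )
        pos = tf.pos_bp[idx]
        for s in range(0, len(idx) - window_size + 1, step):
            sl = slice(s, s + window_size)
            nsum = num[sl].sum()
            d = abs(den_pos[sl].sum()) if nsum >= 0 else abs(den_neg[sl].sum())
            f = float(np.clip(nsum / d, -1.0, 1.0)) if d != 0 else 0.0
            scores.append(
                WindowScore(
                    chrom=str(c),
                    start_bp=int(pos[s]),
                    end_bp=int(pos[s + window_size - 1]),
                    snp_start=int(idx[s]),
                    fdm=f,
                    ancestry_sign="P2_side" if f > 0 else ("P1_side" if f < 0 else "zero"),
                )
            )
    return scores


def z_and_tails(scores: list[WindowScore], tail_pct: float = 5.0):
    """Standardise f_dM genome-wide and call the two tails.

    Sets ``z_fdm`` on every window in place and returns
    ``(high_windows, low_windows)`` with the top and bottom ``tail_pct``
    percent (ceil of the count) of Z(f_dM).
    """
    if len(scores) < 20:
        raise ValueError("need at least 20 windows to standardise")
    f = np.array([w.fdm for w in scores])
    sd = f.std()
    if sd == 0 or np.all(f == f[0]):
        raise ValueError("f_dM standard deviation is zero")
    z = (f - f.mean()) / sd
    for w, zv in zip(scores, z):
        w.z_fdm = float(zv)
    k = int(np.ceil(tail_pct / 100.0 * len(scores)))
    order = np.argsort(z, kind="stable")
    low = [scores[i] for i in order[:k]]
    high = [scores[i] for i in order[-k:]]
    return high, low


def ancestry_fractions(scores: list[WindowScore]):
    """Window-count fractions of the genome with f_dM > 0 and < 0.

    Returns ``(frac_positive, frac_negative, frac_zero)``; exact zeros are
    reported separately rather than forced to a side.
    """
    if not scores:
        raise ValueError("no windows")
    f = np.array([w.fdm for w in scores])
    n = len(f)
    return (
        float((f > 0).sum() / n),
        float((f < 0).sum() / n),
        float((f == 0).sum() / n),
    )


def windows_to_frame(scores: list[WindowScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in scores],
            "start_bp": [w.start_bp for w in scores],
            "end_bp": [w.end_bp for w in scores],
            "fdm": [w.fdm for w in scores],
            "z_fdm": [w.z_fdm for w in scores],
            "ancestry_sign": [w.ancestry_sign for w in scores],
        }
    )
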