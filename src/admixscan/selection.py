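"""Within-population haplotype scans and their composite.

Implements the extended-haplotype-homozygosity family — EHH decay curves,
iHS (integrated haplotype score, ancestral vs derived core alleles), iHH12
(top-two extended haplotype classes pooled, soft-sweep sensitive) and nSL
(haplotype-sharing lengths counted in segregating sites, map-free) — and the
DCMS composite: rank p-values of each statistic are log-odds-transformed and
summed with weights that down-weight correlated statistics. Raw DCMS values
are calibrated against a robustly fitted normal distribution, converted to
upper-tail p-values, FDR-adjusted (Benjamini-Hochberg), and significant SNPs
are grown into regions bounded by the first flanking SNPs with q > 0.10.

All scans require a phased panel with no missing genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .genotype_io import HaplotypePanel

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000
MAX_EXTEND_BP = 1_000_000  # map-based statistics stop 1 Mb from the core
MAX_EXTEND_SITES = 100  # nSL stops 100 sites from the core
MAF_CUTOFF = 0.05
FREQ_BIN_WIDTH = 0.05
MIN_BIN_COUNT = 20


# ---------------------------------------------------------------------------
# EHH decay


@dataclass
class EhhDecay:
    """One-sided-concatenated EHH curve around a core site.

    ``d`` holds signed distances (cM for map-based statistics, site counts
    for nSL) with the core at 0; ``ehh`` the matching homozygosity values.
    """

    core_index: int
    allele_class: str  # "ancestral" | "derived" | "pooled-top2"
    d: np.ndarray
    ehh: np.ndarray
    truncation_left: str
    truncation_right: str

    def integrate(self) -> float:
        """Trapezoidal area under the curve over |distance|."""
        left = self.d <= 0
        right = self.d >= 0
        a = np.trapezoid(self.ehh[left][::-1], -self.d[left][::-1])
        b = np.trapezoid(self.ehh[right], self.d[right])
        return float(a + b)


def _extend(
    cols: list[list[int]],
    rows: list[int],
    core: int,
    lo: int,
    hi: int,
    step: int,
    pos: np.ndarray,
    dist: np.ndarray,
    cutoff: float,
    max_gap_bp: float,
    pooled: bool,
    max_extend_bp: float | None,
    max_extend_sites: int | None,
) -> tuple[list[float], list[float], str]:
    """Walk outward from the core, tracking extended-haplotype classes.

    Only classes of size >= 2 are tracked (a haplotype that becomes unique
    can never rejoin a class); ``cols`` is the panel transposed to plain
    Python lists for fast scalar access. Returns distances from core, EHH
    values, and the truncation reason.
    """
    k = len(rows)
    pair_norm = k * (k - 1)
    if pooled:
        c0 = cols[core]
        g1 = [r for r in rows if c0[r]]
        g0 = [r for r in rows if not c0[r]]
        groups = [g for g in (g0, g1) if len(g) >= 2]
    else:
        groups = [list(rows)]
    n_single = k - sum(len(g) for g in groups)
    ds: list[float] = []
    es: list[float] = []
    j = core
    prev = pos[core]
    reason = "chromosome_end"
    while True:
        j += step
        if j < lo or j >= hi:
            break
        if max_gap_bp is not None and abs(pos[j] - prev) > max_gap_bp:
            reason = "gap"
            break
        if max_extend_bp is not None and abs(pos[j] - pos[core]) > max_extend_bp:
            reason = "max_extension"
            break
        if max_extend_sites is not None and abs(j - core) > max_extend_sites:
            reason = "max_extension"
            break
        prev = pos[j]
        col = cols[j]
        nxt = []
        for g in groups:
            ones = [r for r in g if col[r]]
            n1 = len(ones)
            if n1 == len(g):
                nxt.append(g)
            elif n1 == 0:
                nxt.append(g)
            else:
                if n1 >= 2:
                    nxt.append(ones)
                else:
                    n_single += n1
                n0 = len(g) - n1
                if n0 >= 2:
                    nxt.append([r for r in g if not col[r]])
                else:
                    n_single += n0
        groups = nxt
        if pooled:
            sz = sorted((len(g) for g in groups), reverse=True) + [1] * n_single
            if len(sz) >= 2:
                sz[0] += sz[1]
                sz[1] = 0
            e = sum(c * (c - 1) for c in sz) / pair_norm
        else:
            e = sum(len(g) * (len(g) - 1) for g in groups) / pair_norm
        ds.append(abs(dist[j] - dist[core]))
        es.append(e)
        if e < cutoff or e == 0.0:
            reason = "threshold"
            break
    return ds, es, reason


def ehh_decay(
    panel: HaplotypePanel,
    core: int,
    allele_class: str = "derived",
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: float | None = MAX_GAP_BP,
    unit: str = "cm",
    max_extend_bp: float | None = None,
    max_extend_sites: int | None = None,
) -> EhhDecay | None:
    """EHH decay curve around ``core`` for one allele class (or pooled).

    EHH(x) is the probability that two random haplotypes from the class are
    identical at every site from the core to x. Returns None when the class
    has fewer than two haplotypes.
    """
    sl = [s for c, s in panel.chrom_slices().items()
          if s.start <= core < s.stop][0]
    pos = panel.markers["pos_bp"].to_numpy()
    if unit == "cm":
        dist = panel.markers["cm"].to_numpy()
    elif unit == "sites":
        dist = np.arange(panel.n_snps, dtype=float)
    else:
        raise ValueError(f"unknown distance unit {unit!r}")

    pooled = allele_class == "pooled-top2"
    if pooled:
        rows = list(range(panel.n_haps))
    else:
        want = 0 if allele_class == "ancestral" else 1
        rows = np.flatnonzero(panel.haps[:, core] == want).tolist()
    if len(rows) < 2:
        return None
    cols = panel.__dict__.get("_cols")
    if cols is None:
        cols = panel.haps.T.tolist()
        panel.__dict__["_cols"] = cols
    dl, el, tl = _extend(cols, rows, core, sl.start, sl.stop, -1, pos, dist,
                         cutoff, max_gap_bp, pooled, max_extend_bp, max_extend_sites)
    dr, er, tr = _extend(cols, rows, core, sl.start, sl.stop, +1, pos, dist,
                         cutoff, max_gap_bp, pooled, max_extend_bp, max_extend_sites)
    d = np.concatenate([-np.array(dl[::-1]), [0.0], np.array(dr)])
    e = np.concatenate([np.array(el[::-1]), [1.0], np.array(er)])
    return EhhDecay(core, allele_class, d, e, tl, tr)


# ---------------------------------------------------------------------------
# per-SNP statistics


def _freq_bins(freqs: np.ndarray, width: float = FREQ_BIN_WIDTH,
               min_count: int = MIN_BIN_COUNT) -> np.ndarray:
    """Frequency-bin group labels, merging under-occupied bins with their
    right neighbour (leftward at the top end)."""
    nbins = int(round(1.0 / width))
    raw = np.minimum((freqs / width).astype(int), nbins - 1)
    occupied = sorted(set(raw.tolist()))
    group_of: dict[int, int] = {}
    g = 0
    count = 0
    for i, b in enumerate(occupied):
        group_of[b] = g
        count += int((raw == b).sum())
        if count >= min_count and i < len(occupied) - 1:
            g += 1
            count = 0
    if count and count < min_count and g > 0:
        # fold a small trailing group into the previous one
        for b, gg in group_of.items():
            if gg == g:
                group_of[b] = g - 1
    return np.array([group_of[b] for b in raw])


def _standardize(values: np.ndarray, groups: np.ndarray | None) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    ok = ~np.isnan(values)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    for g in np.unique(groups[ok]):
        sel = ok & (groups == g)
        sd = values[sel].std()
        if sd > 0:
            out[sel] = (values[sel] - values[sel].mean()) / sd
    return out


def _integral_pair(panel, core, cutoff, max_gap_bp, unit):
    """(iHH_ancestral, iHH_derived) for one core; NaN components when a class
    is too small or its integral is zero."""
    out = []
    for cls in ("ancestral", "derived"):
        dec = ehh_decay(panel, core, cls, cutoff, max_gap_bp, unit,
                        max_extend_bp=MAX_EXTEND_BP)
        out.append(np.nan if dec is None else dec.integrate())
    return out


def ihs(panel: HaplotypePanel, maf_cutoff: float = MAF_CUTOFF,
        cutoff: float = EHH_CUTOFF, max_gap_bp: float = MAX_GAP_BP) -> pd.DataFrame:
    """Integrated haplotype score per SNP.

    iHS_raw = ln(iHH_ancestral / iHH_derived), standardised to zero mean and
    unit variance within derived-allele-frequency bins.
    """
    freqs = panel.freqs()
    n = panel.n_snps
    raw = np.full(n, np.nan)
    ihh_a = np.full(n, np.nan)
    ihh_d = np.full(n, np.nan)
    for j in range(n):
        if not maf_cutoff <= freqs[j] <= 1 - maf_cutoff:
            continue
        a, d = _integral_pair(panel, j, cutoff, max_gap_bp, "cm")
        ihh_a[j], ihh_d[j] = a, d
        if a and d and not (np.isnan(a) or np.isnan(d)) and a > 0 and d > 0:
            raw[j] = np.log(a / d)
    ok = ~np.isnan(raw)
    std = np.full(n, np.nan)
    if ok.any():
        groups = _freq_bins(freqs)
        std[ok] = _standardize(raw[ok], groups[ok])
    return pd.DataFrame(
        {"freq_derived": freqs, "ihh_a": ihh_a, "ihh_d": ihh_d,
         "ihs_raw": raw, "ihs_std": std}
    )


def ihh12(panel: HaplotypePanel, maf_cutoff: float = MAF_CUTOFF,
          cutoff: float = EHH_CUTOFF, max_gap_bp: float = MAX_GAP_BP) -> pd.DataFrame:
    """Integrated pooled haplotype homozygosity per SNP, standardised
    genome-wide."""
    freqs = panel.freqs()
    n = panel.n_snps
    raw = np.full(n, np.nan)
    for j in range(n):
        if not maf_cutoff <= freqs[j] <= 1 - maf_cutoff:
            continue
        dec = ehh_decay(panel, j, "pooled-top2", cutoff, max_gap_bp, "cm",
                        max_extend_bp=MAX_EXTEND_BP)
        if dec is not None:
            raw[j] = dec.integrate()
    return pd.DataFrame(
        {"freq_derived": freqs, "ihh12": raw, "ihh12_std": _standardize(raw, None)}
    )


def nsl(panel: HaplotypePanel, maf_cutoff: float = MAF_CUTOFF,
        max_snp_span: int | None = MAX_EXTEND_SITES) -> pd.DataFrame:
    """Number-of-segregating-sites analogue of iHS.

    The mean pairwise haplotype-sharing length around a core, in sites,
    equals the sum of the EHH curve sampled at every site, so the statistic
    reuses the EHH machinery with unit site spacing, no map, no decay cutoff
    and no gap limit.
    """
    freqs = panel.freqs()
    n = panel.n_snps
    raw = np.full(n, np.nan)
    sl_a = np.full(n, np.nan)
    sl_d = np.full(n, np.nan)
    for j in range(n):
        if not maf_cutoff <= freqs[j] <= 1 - maf_cutoff:
            continue
        vals = []
        for cls in ("ancestral", "derived"):
            dec = ehh_decay(panel, j, cls, cutoff=0.0, max_gap_bp=None, unit="sites",
                            max_extend_sites=max_snp_span)
            # mean pairwise shared length = sum of EHH over sites (core = 1)
            vals.append(np.nan if dec is None else float(dec.ehh.sum()))
        a, d = vals
        sl_a[j], sl_d[j] = a, d
        if a and d and not (np.isnan(a) or np.isnan(d)):
            raw[j] = np.log(a / d)
    ok = ~np.isnan(raw)
    std = np.full(n, np.nan)
    if ok.any():
        groups = _freq_bins(freqs)
        std[ok] = _standardize(raw[ok], groups[ok])
    return pd.DataFrame(
        {"freq_derived": freqs, "sl_a": sl_a, "sl_d": sl_d,
         "nsl_raw": raw, "nsl_std": std}
    )


# ---------------------------------------------------------------------------
# DCMS composition


def rank_pvalues(values: np.ndarray) -> np.ndarray:
    """Right-tailed fractional-rank p-values: p_i = (r_i - 0.5) / n with r_i
    the descending rank (ties averaged); always strictly inside (0, 1)."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-NA values")
    p = np.full(len(v), np.nan)
    r = sps.rankdata(-v[ok], method="average")
    p[ok] = (r - 0.5) / ok.sum()
    return p


def dcms_weights(stat_matrix: np.ndarray, names=None) -> np.ndarray:
    """Weight per statistic: 1 / sum_i |r_it| over the Pearson correlation
    matrix of the raw statistics (complete-case rows)."""
    x = np.asarray(stat_matrix, dtype=float)
    names = names or [f"stat{i}" for i in range(x.shape[1])]
    sds = x.std(axis=0)
    for t, sd in enumerate(sds):
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"statistic {names[t]!r} is constant; correlation undefined")
    r = np.atleast_2d(np.corrcoef(x, rowvar=False))
    return 1.0 / np.abs(r).sum(axis=0)


def dcms(p_matrix: np.ndarray, stat_matrix: np.ndarray, names=None) -> np.ndarray:
    """De-correlated composite of multiple signals.

    DCMS_l = sum_t w_t * log[(1 - p_lt) / p_lt], with w_t = 1 / sum_i |r_it|;
    rows with any NA component return NaN.
    """
    p = np.atleast_2d(np.asarray(p_matrix, dtype=float))
    x = np.atleast_2d(np.asarray(stat_matrix, dtype=float))
    if p.shape != x.shape:
        raise ValueError("p-value and statistic matrices must share a shape")
    complete = ~np.isnan(x).any(axis=1) & ~np.isnan(p).any(axis=1)
    w = dcms_weights(x[complete], names)
    out = np.full(p.shape[0], np.nan)
    out[complete] = (np.log((1.0 - p[complete]) / p[complete]) * w).sum(axis=1)
    return out


def calibrate(dcms_values: np.ndarray, tuning: float = 1.345):
    """Fit a normal distribution to DCMS values by a robust (Huber) location
    fit with iteratively re-scaled MAD, and convert to upper-tail p-values.

    Returns ``(mu, sigma, p)``.
    """
    v = np.asarray(dcms_values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 10:
        raise ValueError("need at least 10 values to calibrate")
    model = sm.RLM(v[ok], np.ones((ok.sum(), 1)), M=sm.robust.norms.HuberT(t=tuning))
    fit = model.fit(scale_est=sm.robust.scale.HuberScale())
    mu = float(fit.params[0])
    sigma = float(fit.scale)
    if sigma == 0:
        raise ValueError("robust scale is zero; cannot calibrate")
    p = np.full(len(v), np.nan)
    p[ok] = sps.norm.sf(v[ok], loc=mu, scale=sigma)
    return mu, sigma, p


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    q = np.full(len(p), np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# region building


@dataclass
class SelectedRegion:
    chrom: str
    start_bp: int
    end_bp: int
    member_snps: list[int]  # indices of q < q_sig SNPs inside
    min_q: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def build_regions(
    records: pd.DataFrame, q_sig: float = 0.05, q_flank: float = 0.10
) -> list[SelectedRegion]:
    """Grow significant SNPs (q < ``q_sig``) into intervals bounded by the
    first flanking SNPs with q > ``q_flank``; overlapping intervals merge.

    ``records`` needs columns chrom, pos_bp, q (position-sorted within
    chromosome); regions never cross chromosome boundaries and truncate at
    the outermost SNP when no qualifying flank exists.
    """
    regions: list[SelectedRegion] = []
    for c, sub in records.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        q = sub["q"].to_numpy()
        gidx = sub.index.to_numpy()
        seeds = np.flatnonzero(~np.isnan(q) & (q < q_sig))
        intervals = []
        for s in seeds:
            left = s
            for i in range(s - 1, -1, -1):
                if not np.isnan(q[i]) and q[i] > q_flank:
                    left = i
                    break
            else:
                left = 0
            right = s
            for i in range(s + 1, len(q)):
                if not np.isnan(q[i]) and q[i] > q_flank:
                    right = i
                    break
            else:
                right = len(q) - 1
            intervals.append((int(pos[left]), int(pos[right]), s))
        intervals.sort()
        merged: list[list] = []
        for lo, hi, s in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].append(s)
            else:
                merged.append([lo, hi, [s]])
        for lo, hi, ss in merged:
            inside = np.flatnonzero((pos >= lo) & (pos <= hi) & ~np.isnan(q) & (q < q_sig))
            regions.append(
                SelectedRegion(
                    chrom=str(c),
                    start_bp=lo,
                    end_bp=hi,
                    member_snps=[int(gidx[i]) for i in inside],
                    min_q=float(np.nanmin(q[inside])),
                )
            )
    return regions


def regions_to_frame(regions: list[SelectedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "n_snps": [len(r.member_snps) for r in regions],
            "min_q": [r.min_q for r in regions],
            "length_bp": [r.length_bp for r in regions],
        }
    )


# ---------------------------------------------------------------------------
# full scan driver


def scan_population(
    panel: HaplotypePanel,
    maf_cutoff: float = MAF_CUTOFF,
    cutoff: float = EHH_CUTOFF,
    max_gap_bp: float = MAX_GAP_BP,
) -> pd.DataFrame:
    """All three haplotype statistics, DCMS, calibrated p and q per SNP."""
    t_ihs = ihs(panel, maf_cutoff, cutoff, max_gap_bp)
    t_12 = ihh12(panel, maf_cutoff, cutoff, max_gap_bp)
    t_nsl = nsl(panel, maf_cutoff)
    df = pd.DataFrame(
        {
            "chrom": panel.markers["chrom"].to_numpy(),
            "pos_bp": panel.markers["pos_bp"].to_numpy(),
            "freq_derived": t_ihs["freq_derived"],
            "ihs_raw": t_ihs["ihs_raw"],
            "ihs_std": t_ihs["ihs_std"],
            "ihh12": t_12["ihh12"],
            "ihh12_std": t_12["ihh12_std"],
            "nsl_raw": t_nsl["nsl_raw"],
            "nsl_std": t_nsl["nsl_std"],
        }
    )
    # |standardised| scores: selection is signalled by either tail of iHS/nSL
    stat = np.column_stack(
        [np.abs(df["ihs_std"]), df["ihh12_std"], np.abs(df["nsl_std"])]
    )
    complete = ~np.isnan(stat).any(axis=1)
    if complete.sum() >= 2:
        pcols = np.full_like(stat, np.nan)
        for t in range(stat.shape[1]):
            pcols[complete, t] = rank_pvalues(stat[complete, t])
        df["p_ihs"], df["p_ihh12"], df["p_nsl"] = pcols.T
        df["dcms"] = dcms(pcols, stat, names=["ihs", "ihh12", "nsl"])
        mu, sigma, p = calibrate(df["dcms"].to_numpy())
        df["p_dcms"] = p
        df["q"] = bh_qvalues(p)
        df.attrs["calibration"] = {"mu": mu, "sigma": sigma}
    else:
        warnings.warn("too few complete SNPs for DCMS; scan returns raw statistics only")
        df["p_ihs"] = df["p_ihh12"] = df["p_nsl"] = np.nan
        df["dcms"] = df["p_dcms"] = df["q"] = np.nan
    return df
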