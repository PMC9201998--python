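"""Forward simulation of differentiated source populations, an outgroup, and
admixed hybrids with exact local-ancestry bookkeeping.

Population allele frequencies follow the Balding-Nichols model around a
shared ancestral frequency. Source panels acquire linkage disequilibrium by a
few generations of random mating with Poisson crossovers; hybrid panels start
as a mixture of source haplotypes and recombine within the hybrid pool, with
every crossover recorded in an :class:`AncestryTruth` so each marker's true
source is known. Hard and soft sweeps are imitated by copying one (or a few)
donor haplotype segments into a chosen fraction of carriers, which creates
the long shared haplotypes that EHH-family statistics detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeDataset,
    HaplotypePanel,
    make_marker_table,
    write_popmap,
    write_vcf,
)

SOURCE1, SOURCE2 = "SOURCE1", "SOURCE2"


@dataclass
class SweepSpec:
    """A planted sweep: copy a donor haplotype segment around ``pos_bp`` into
    ``carrier_fraction`` of the target panel's haplotypes."""

    chrom: str
    pos_bp: int
    carrier_fraction: float = 0.9
    core_span_bp: int = 500_000
    target_pop: str = "HYB"
    n_donors: int = 1  # >1 gives a soft sweep

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults emulate a two-source composite-breed design: two strongly
    differentiated sources (Fst ~ 0.1, of the order seen between taurine and
    indicine cattle), a distant outgroup, and a hybrid formed ~10 generations
    ago with 30% SOURCE2 ancestry (a Brangus/Beefmaster-like proportion).
    """

    n_snps: int = 2000
    n_chrom: int = 2
    chrom_len_bp: int = 10_000_000
    fst_sources: float = 0.10
    fst_outgroup: float = 0.60
    n_per_pop: int = 25
    alpha: float = 0.30
    n_generations: int = 10
    recomb_rate: float = 1.0  # cM/Mb
    n_founders: int = 100
    source_gens: int = 4  # random-mating generations building source LD
    pool_size: int = 150  # breeding individuals; samples are drawn from this pool
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.fst_sources < 1.0 or not 0.0 < self.fst_outgroup < 1.0:
            raise ValueError("Fst parameters must be in (0, 1)")


@dataclass
class AncestrySegment:
    chrom: str
    start_bp: int  # inclusive
    end_bp: int  # inclusive
    source: str  # SOURCE1 | SOURCE2


@dataclass
class AncestryTruth:
    """Per-haplotype ancestry mosaics; segments tile each chromosome."""

    segments: dict[int, list[AncestrySegment]]  # haplotype index -> tiling
    chrom_len_bp: dict[str, int]

    def subset(self, hap_indices) -> "AncestryTruth":
        """Truth restricted to the given haplotypes, renumbered 0..n-1."""
        return AncestryTruth(
            {k: self.segments[int(h)] for k, h in enumerate(hap_indices)},
            dict(self.chrom_len_bp),
        )

    def realized_alpha(self) -> float:
        """Genome-wide realized SOURCE2 fraction (bp-weighted over haplotypes)."""
        tot = s2 = 0
        for segs in self.segments.values():
            for seg in segs:
                span = seg.end_bp - seg.start_bp + 1
                tot += span
                if seg.source == SOURCE2:
                    s2 += span
        return s2 / tot if tot else float("nan")

    def source_at(self, hap: int, chrom: str, pos_bp: int) -> str:
        for seg in self.segments[hap]:
            if seg.chrom == chrom and seg.start_bp <= pos_bp <= seg.end_bp:
                return seg.source
        raise KeyError(f"position {chrom}:{pos_bp} not covered for haplotype {hap}")

    def source2_fraction_in(self, chrom: str, start_bp: int, end_bp: int) -> float:
        """Mean SOURCE2 fraction of [start_bp, end_bp] across haplotypes."""
        tot = s2 = 0
        for segs in self.segments.values():
            for seg in segs:
                if seg.chrom != chrom:
                    continue
                lo = max(seg.start_bp, start_bp)
                hi = min(seg.end_bp, end_bp)
                if lo <= hi:
                    tot += hi - lo + 1
                    if seg.source == SOURCE2:
                        s2 += hi - lo + 1
        return s2 / tot if tot else float("nan")

    def to_bed_frame(self) -> pd.DataFrame:
        rows = []
        for hap, segs in self.segments.items():
            for seg in segs:
                rows.append((seg.chrom, seg.start_bp - 1, seg.end_bp, hap, seg.source))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "haplotype", "source"])


# ---------------------------------------------------------------------------
# allele frequencies


def draw_population_freqs(n_snps: int, fst: float, seed, n_pops: int = 1):
    """Balding-Nichols population frequencies around a uniform ancestral draw.

    Returns ``(ancestral, [pop_freqs...])``; ancestral p ~ Uniform(0.05, 0.95)
    and each population's frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_snps)
    scale = (1.0 - fst) / fst
    pops = [rng.beta(anc * scale, (1.0 - anc) * scale) for _ in range(n_pops)]
    return anc, pops


def freqs_from_ancestral(anc: np.ndarray, fst: float, rng) -> np.ndarray:
    """One Balding-Nichols population draw around given ancestral frequencies."""
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(anc * scale, (1.0 - anc) * scale)


def simulate_trio_frequencies(
    n_sites: int,
    seed,
    alpha: float | None = None,
    n_hap: int = 50,
    f_branch: float = 0.05,
    f_out: float = 0.5,
):
    """Sampled allele frequencies for a (((P1,P2),P3),OUT) quartet.

    Site-independent Balding-Nichols drift along the tree: P1 and P2 share an
    internal branch, P3 and OUT drift from the root. With ``alpha`` set, P2
    becomes an admixed population drawing that fraction of its ancestry from
    the P3 population itself (gene flow P3 -> P2), which is the configuration
    whose f4-ratio expectation equals ``alpha``. Returns a dict with
    population frequencies and P3 allele-copy counts, all length ``n_sites``.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_sites)
    q12 = freqs_from_ancestral(p, f_branch, rng)
    f1 = freqs_from_ancestral(q12, f_branch, rng)
    f2 = freqs_from_ancestral(q12, f_branch, rng)
    f3 = freqs_from_ancestral(p, f_branch, rng)
    fO = freqs_from_ancestral(p, f_out, rng)
    if alpha is not None:
        f2 = (1.0 - alpha) * f2 + alpha * f3
    # finite-sample allele frequencies (n_hap haploid copies per population)
    s1 = rng.binomial(n_hap, f1) / n_hap
    s2 = rng.binomial(n_hap, f2) / n_hap
    k3 = rng.binomial(n_hap, f3)
    s3 = k3 / n_hap
    sO = rng.binomial(n_hap, fO) / n_hap
    return {
        "p1": s1,
        "p2": s2,
        "p3": s3,
        "pO": sO,
        "p3_derived_copies": k3.astype(float),
        "p3_total_copies": np.full(n_sites, float(n_hap)),
    }


# ---------------------------------------------------------------------------
# recombination machinery


def _meiosis(rng, cm: np.ndarray) -> np.ndarray:
    """Return a 0/1 vector selecting the parental haplotype per site for one
    chromosome, with Poisson(map length in Morgans) crossovers, no interference."""
    length_m = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
    n_x = rng.poisson(length_m)
    which = np.full(len(cm), rng.integers(2), dtype=np.int8)
    if n_x:
        for x in rng.uniform(cm[0], cm[-1], size=n_x):
            which[np.searchsorted(cm, x):] ^= 1
    return which


def simulate_source_panel(
    freqs: np.ndarray,
    markers: pd.DataFrame,
    n_ind: int,
    n_founders: int = 50,
    n_generations: int = 4,
    seed=0,
) -> HaplotypePanel:
    """Founder haplotypes drawn site-independently from ``freqs``, then
    ``n_generations`` of random mating with crossovers to build LD."""
    if n_founders < 4:
        raise ValueError("need at least 4 founders")
    rng = np.random.default_rng(seed)
    n_snps = len(markers)
    haps = (rng.random((2 * n_founders, n_snps)) < freqs).astype(np.uint8)
    if n_generations == 0:
        return HaplotypePanel(markers, haps[: 2 * n_ind].copy())
    chrom_sl = HaplotypePanel(markers, haps).chrom_slices()
    pool = haps
    for g in range(n_generations):
        n_out = 2 * n_ind if g == n_generations - 1 else pool.shape[0]
        nxt = np.empty((n_out, n_snps), dtype=np.uint8)
        n_parents = pool.shape[0] // 2
        for h in range(n_out):
            p = rng.integers(n_parents)
            h1, h2 = pool[2 * p], pool[2 * p + 1]
            for sl in chrom_sl.values():
                which = _meiosis(rng, markers["cm"].to_numpy()[sl])
                nxt[h, sl] = np.where(which == 0, h1[sl], h2[sl])
        pool = nxt
    return HaplotypePanel(markers, pool)


def simulate_hybrid(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    alpha: float,
    n_generations: int,
    n_ind: int,
    seed=0,
    chrom_len_bp: dict[str, int] | None = None,
) -> tuple[HaplotypePanel, AncestryTruth]:
    """Admix two source panels: founding hybrid haplotypes come from SOURCE2
    (``panel_b``) with probability ``alpha``, then the pool recombines for
    ``n_generations``; every crossover updates the ancestry truth."""
    if not panel_a.markers[["chrom", "pos_bp"]].equals(panel_b.markers[["chrom", "pos_bp"]]):
        raise ValueError("source panels have mismatched marker maps")
    rng = np.random.default_rng(seed)
    markers = panel_a.markers
    cm_all = markers["cm"].to_numpy()
    pos_all = markers["pos_bp"].to_numpy()
    chrom_sl = panel_a.chrom_slices()
    if chrom_len_bp is None:
        chrom_len_bp = {c: int(pos_all[sl][-1]) for c, sl in chrom_sl.items()}

    n_haps = 2 * n_ind
    pool = np.empty((n_haps, panel_a.n_snps), dtype=np.uint8)
    # ancestry carried per chromosome as breakpoint lists:
    # list of (start_bp, source) with segments ending at the next start - 1
    anc: list[dict[str, list[tuple[int, str]]]] = []
    for h in range(n_haps):
        if rng.random() < alpha:
            src_panel, src_name = panel_b, SOURCE2
        else:
            src_panel, src_name = panel_a, SOURCE1
        pool[h] = src_panel.haps[rng.integers(src_panel.n_haps)]
        anc.append({c: [(1, src_name)] for c in chrom_sl})

    def splice(trA, trB, chrom, cuts_bp):
        """Alternate between two ancestry tracks at the given breakpoints.

        Tracks are ``[(start_bp, source), ...]`` with each entry running to
        the next start; the result takes trA before the first cut, trB until
        the second, and so on, with adjacent same-source entries merged.
        """
        end = chrom_len_bp[chrom] + 1
        bounds = [1] + list(cuts_bp) + [end]
        tracks = (trA, trB)
        out: list[tuple[int, str]] = []
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            if lo >= hi:
                continue
            tr = tracks[k % 2]
            for i, (s, src) in enumerate(tr):
                e = tr[i + 1][0] if i + 1 < len(tr) else end
                a, b = max(s, lo), min(e, hi)
                if a < b and not (out and out[-1][1] == src):
                    out.append((a, src))
        return out

    for _ in range(n_generations):
        nxt = np.empty_like(pool)
        nxt_anc: list[dict[str, list[tuple[int, str]]]] = []
        for h in range(n_haps):
            p = rng.integers(n_ind)
            hA, hB = 2 * p, 2 * p + 1
            tracks: dict[str, list[tuple[int, str]]] = {}
            for c, sl in chrom_sl.items():
                cm = cm_all[sl]
                pos = pos_all[sl]
                length_m = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
                n_x = rng.poisson(length_m)
                first = int(rng.integers(2))
                cuts_cm = rng.uniform(cm[0], cm[-1], size=n_x) if n_x else np.array([])
                # work at integer-bp resolution so genotypes and ancestry use
                # identical breakpoints; coincident cuts cancel pairwise
                raw = [int(x) + 1 for x in np.interp(cuts_cm, cm, pos)] if n_x else []
                cuts_bp = sorted(b for b in set(raw) if raw.count(b) % 2 == 1)
                which = np.full(len(cm), first, dtype=np.int8)
                for b in cuts_bp:
                    which[np.searchsorted(pos, b):] ^= 1
                nxt[h, sl] = np.where(which == 0, pool[hA, sl], pool[hB, sl])
                a, b_ = (anc[hA][c], anc[hB][c]) if first == 0 else (anc[hB][c], anc[hA][c])
                tracks[c] = splice(a, b_, c, cuts_bp)
            nxt_anc.append(tracks)
        pool, anc = nxt, nxt_anc

    segments: dict[int, list[AncestrySegment]] = {}
    for h in range(n_haps):
        segs = []
        for c in chrom_sl:
            track = anc[h][c]
            for k, (s, src) in enumerate(track):
                end = (track[k + 1][0] - 1) if k + 1 < len(track) else chrom_len_bp[c]
                segs.append(AncestrySegment(c, s, end, src))
        segments[h] = segs
    return HaplotypePanel(markers, pool), AncestryTruth(segments, dict(chrom_len_bp))


def plant_sweep(
    panel: HaplotypePanel,
    spec: SweepSpec,
    seed=0,
    truth: AncestryTruth | None = None,
) -> HaplotypePanel:
    """Copy donor haplotype segment(s) around ``spec.pos_bp`` into
    ``ceil(carrier_fraction * n_haps)`` haplotypes (donors included).

    When ``truth`` is given it is updated in place: the copied interval of
    each carrier takes on the donor's ancestry mosaic there.
    """
    rng = np.random.default_rng(seed)
    m = panel.markers
    on_chrom = (m["chrom"] == spec.chrom).to_numpy()
    if not on_chrom.any():
        raise ValueError(f"chromosome {spec.chrom!r} not in panel")
    pos = m["pos_bp"].to_numpy()
    half = spec.core_span_bp // 2
    cols = np.flatnonzero(on_chrom & (pos >= spec.pos_bp - half) & (pos <= spec.pos_bp + half))
    if len(cols) == 0:
        raise ValueError("sweep span contains no markers")
    n_carriers = int(np.ceil(spec.carrier_fraction * panel.n_haps))
    if spec.carrier_fraction >= 1.0:
        import warnings

        warnings.warn("carrier_fraction=1 leaves the core monomorphic; iHS will be undefined there")
    order = rng.permutation(panel.n_haps)
    donors = order[: spec.n_donors]
    carriers = order[:n_carriers]
    haps = panel.haps.copy()
    donor_of = donors[np.arange(len(carriers)) % spec.n_donors]
    for c, d in zip(carriers, donor_of):
        haps[c, cols] = panel.haps[d, cols]
    if truth is not None:
        lo, hi = spec.pos_bp - half, spec.pos_bp + half
        for c, d in zip(carriers, donor_of):
            if c == d:
                continue
            _overwrite_ancestry(truth, int(c), int(d), spec.chrom, lo, hi)
    return HaplotypePanel(panel.markers, haps, panel.sample_ids)


def _overwrite_ancestry(truth: AncestryTruth, carrier: int, donor: int,
                        chrom: str, lo: int, hi: int) -> None:
    """Give ``carrier`` the donor's ancestry mosaic over [lo, hi] on ``chrom``."""
    lo = max(lo, 1)
    hi = min(hi, truth.chrom_len_bp[chrom])
    keep: list[AncestrySegment] = []
    for s in truth.segments[carrier]:
        if s.chrom != chrom or s.end_bp < lo or s.start_bp > hi:
            keep.append(s)
            continue
        if s.start_bp < lo:
            keep.append(AncestrySegment(chrom, s.start_bp, lo - 1, s.source))
        if s.end_bp > hi:
            keep.append(AncestrySegment(chrom, hi + 1, s.end_bp, s.source))
    ins = [
        AncestrySegment(chrom, max(s.start_bp, lo), min(s.end_bp, hi), s.source)
        for s in truth.segments[donor]
        if s.chrom == chrom and s.end_bp >= lo and s.start_bp <= hi
    ]
    segs = sorted(keep + ins, key=lambda s: (s.chrom, s.start_bp))
    merged: list[AncestrySegment] = []
    for s in segs:
        last = merged[-1] if merged else None
        if (last and last.chrom == s.chrom and last.source == s.source
                and last.end_bp + 1 == s.start_bp):
            merged[-1] = AncestrySegment(s.chrom, last.start_bp, s.end_bp, s.source)
        else:
            merged.append(s)
    truth.segments[carrier] = merged


# ---------------------------------------------------------------------------
# whole-study generation and export


@dataclass
class SyntheticStudy:
    dataset: GenotypeDataset
    panels: dict[str, HaplotypePanel]
    truth: AncestryTruth
    config: SimConfig


def _uniform_markers(cfg: SimConfig, rng) -> pd.DataFrame:
    per = cfg.n_snps // cfg.n_chrom
    chroms, pos = [], []
    for c in range(1, cfg.n_chrom + 1):
        n = per + (cfg.n_snps % cfg.n_chrom if c == cfg.n_chrom else 0)
        p = np.sort(rng.choice(np.arange(1, cfg.chrom_len_bp), size=n, replace=False))
        chroms += [str(c)] * n
        pos.append(p)
    pos_arr = np.concatenate(pos)
    cm = pos_arr * 1e-6 * cfg.recomb_rate
    return make_marker_table(chroms, pos_arr, cm=cm)


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full four-population design of one synthetic study:
    SRC1, SRC2 (differentiated sources), OUT (distant outgroup) and HYB
    (recombinant mosaic of the sources with SOURCE2 fraction ``alpha``)."""
    rng = np.random.default_rng(cfg.seed)
    markers = _uniform_markers(cfg, rng)
    anc = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    # the two sources sit at fst_sources from each other: each drifts at F/2-ish;
    # Balding-Nichols draws at fst/2 around the common ancestral frequency give
    # pairwise Hudson Fst close to fst_sources
    f_half = cfg.fst_sources / (2.0 - cfg.fst_sources)
    freq1 = freqs_from_ancestral(anc, f_half, rng)
    freq2 = freqs_from_ancestral(anc, f_half, rng)
    freq_out = freqs_from_ancestral(anc, cfg.fst_outgroup, rng)

    seeds = rng.integers(0, 2**31 - 1, size=5)
    pool = max(cfg.pool_size, cfg.n_per_pop)
    # breed everything in a pool larger than the sample so that sampled
    # haplotypes are not recent clones of each other
    p1_pool = simulate_source_panel(freq1, markers, pool, cfg.n_founders, cfg.source_gens, seeds[0])
    p2_pool = simulate_source_panel(freq2, markers, pool, cfg.n_founders, cfg.source_gens, seeds[1])
    pout = simulate_source_panel(freq_out, markers, max(2, cfg.n_per_pop // 5), cfg.n_founders, 0, seeds[2])
    hyb_pool, truth_pool = simulate_hybrid(p1_pool, p2_pool, cfg.alpha, cfg.n_generations, pool, seeds[3])
    sample = np.arange(2 * cfg.n_per_pop)
    p1 = p1_pool.subset_haps(sample)
    p2 = p2_pool.subset_haps(sample)
    hyb = hyb_pool.subset_haps(sample)
    truth = truth_pool.subset(sample)
    for k, spec in enumerate(cfg.sweep_specs):
        target = {"SRC1": p1, "SRC2": p2, "HYB": hyb, "OUT": pout}[spec.target_pop]
        swept = plant_sweep(target, spec, seed=int(seeds[4]) + k,
                            truth=truth if spec.target_pop == "HYB" else None)
        if spec.target_pop == "HYB":
            hyb = swept
        elif spec.target_pop == "SRC1":
            p1 = swept
        elif spec.target_pop == "SRC2":
            p2 = swept
        else:
            pout = swept

    panels = {"SRC1": p1, "SRC2": p2, "HYB": hyb, "OUT": pout}
    dataset = panels_to_dataset(panels, markers)
    return SyntheticStudy(dataset, panels, truth, cfg)


def panels_to_dataset(panels: dict[str, HaplotypePanel], markers: pd.DataFrame) -> GenotypeDataset:
    role_map = {"SRC1": "SOURCE1", "SRC2": "SOURCE2", "HYB": "HYBRID", "OUT": "OUTGROUP"}
    sample_ids, pop_of_sample = [], {}
    hap_blocks = []
    for pop, panel in panels.items():
        n_ind = panel.n_haps // 2
        for i in range(n_ind):
            sid = f"{pop}_{i:03d}"
            sample_ids.append(sid)
            pop_of_sample[sid] = pop
        hap_blocks.append(panel.haps[: 2 * n_ind])
    haps = np.vstack(hap_blocks).astype(np.int8)
    dosages = haps[0::2] + haps[1::2]
    return GenotypeDataset(
        sample_ids=sample_ids,
        pop_of_sample=pop_of_sample,
        role_of_pop={p: role_map.get(p, "OTHER") for p in panels},
        markers=markers,
        dosages=dosages,
        phased=True,
        haplotypes=haps,
    )


def export(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write phased VCF, popmap TSV, truth BED and a JSON sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "synthetic.vcf"),
        "popmap": str(outdir / "popmap.tsv"),
        "truth_bed": str(outdir / "ancestry_truth.bed"),
        "sidecar": str(outdir / "simulation.json"),
    }
    ds = study.dataset
    write_vcf(ds, paths["vcf"])
    write_popmap(ds.pop_of_sample, ds.role_of_pop, paths["popmap"])
    study.truth.to_bed_frame().to_csv(paths["truth_bed"], sep="\t", index=False, header=False)
    side = {
        "realized_alpha": study.truth.realized_alpha(),
        "nominal_alpha": study.config.alpha,
        "sweeps": [vars(s) for s in study.config.sweep_specs],
        "seed": study.config.seed,
    }
    with open(paths["sidecar"], "w") as fh:
        json.dump(side, fh, indent=2)
    return paths
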