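"""Genotype containers, VCF and population-map I/O, QC filters, allele frequencies.

The central container is :class:`GenotypeDataset`: a samples x SNPs dosage
matrix (0/1/2, ``-1`` for missing) with a marker table and population labels.
Phased inputs additionally carry a haplotype matrix so that haplotype-based
selection statistics can be computed downstream without re-reading the VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

#: recognised population roles in a four-taxon analysis
ROLES = ("SOURCE1", "SOURCE2", "HYBRID", "OUTGROUP", "OTHER")

MARKER_COLUMNS = ["chrom", "pos_bp", "cm", "ref", "alt", "is_autosomal"]


def default_cm(pos_bp: np.ndarray) -> np.ndarray:
    """Genetic positions at a uniform 1 cM/Mb when no genetic map is supplied."""
    return np.asarray(pos_bp, dtype=float) * 1e-6


@dataclass
class MarkerRecord:
    """A single biallelic SNP."""

    chrom: str
    pos_bp: int
    cm: float
    ref: str
    alt: str
    is_autosomal: bool = True


def _autosomal(chrom: str) -> bool:
    c = chrom.lower().removeprefix("chr").removeprefix("bta")
    return c.isdigit()


def make_marker_table(
    chrom,
    pos_bp,
    cm=None,
    ref=None,
    alt=None,
) -> pd.DataFrame:
    """Assemble a marker table, deriving cM positions and autosome flags."""
    chrom = np.asarray(chrom, dtype=object)
    pos_bp = np.asarray(pos_bp, dtype=np.int64)
    n = len(pos_bp)
    if cm is None:
        cm = default_cm(pos_bp)
    if ref is None:
        ref = np.full(n, "A", dtype=object)
    if alt is None:
        alt = np.full(n, "C", dtype=object)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos_bp,
            "cm": np.asarray(cm, dtype=float),
            "ref": ref,
            "alt": alt,
            "is_autosomal": [_autosomal(str(c)) for c in chrom],
        }
    )
    for c in pd.unique(df["chrom"]):
        p = df.loc[df["chrom"] == c, "pos_bp"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"marker positions not strictly increasing on {c}")
    return df


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes: rows are haplotypes (two consecutive per sample).

    Chromosomes are stored contiguously in the marker table; every operation
    that walks along the genome respects chromosome boundaries.
    """

    markers: pd.DataFrame
    haps: np.ndarray  # uint8 [n_haplotypes, n_snps]
    sample_ids: list[str] | None = None

    @property
    def n_haps(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[1]

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice of each chromosome, in marker-table order (cached)."""
        cached = self.__dict__.get("_chrom_slices")
        if cached is not None:
            return cached
        out: dict[str, slice] = {}
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        self.__dict__["_chrom_slices"] = out
        return out

    def subset_haps(self, rows) -> "HaplotypePanel":
        return HaplotypePanel(self.markers, self.haps[np.asarray(rows)], None)

    def freqs(self) -> np.ndarray:
        return self.haps.mean(axis=0)

    def to_dosages(self) -> np.ndarray:
        h = self.haps
        if h.shape[0] % 2:
            raise ValueError("odd haplotype count cannot form diploids")
        return (h[0::2].astype(np.int8) + h[1::2].astype(np.int8))


@dataclass
class GenotypeDataset:
    """Samples x biallelic-SNP dosages plus marker map and population labels."""

    sample_ids: list[str]
    pop_of_sample: dict[str, str]
    role_of_pop: dict[str, str]
    markers: pd.DataFrame
    dosages: np.ndarray  # int8 [n_samples, n_snps]; -1 = missing
    phased: bool = False
    haplotypes: np.ndarray | None = None  # int8 [2*n_samples, n_snps] when phased

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError("dosage matrix shape does not match samples x markers")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        missing_pop = [s for s in self.sample_ids if s not in self.pop_of_sample]
        if missing_pop:
            raise ValueError(f"samples without a population: {missing_pop}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_of_sample[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.pop_of_sample[s] == pop]
        if not idx:
            raise KeyError(f"population {pop!r} has no samples")
        return np.asarray(idx)

    def pops_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.role_of_pop.items() if r == role]

    def subset(self, sample_rows=None, snp_cols=None) -> "GenotypeDataset":
        rows = np.arange(self.n_samples) if sample_rows is None else np.asarray(sample_rows)
        cols = np.arange(self.n_snps) if snp_cols is None else np.asarray(snp_cols)
        sids = [self.sample_ids[i] for i in rows]
        haps = None
        if self.haplotypes is not None:
            hrows = np.repeat(rows * 2, 2) + np.tile([0, 1], len(rows))
            haps = self.haplotypes[np.ix_(hrows, cols)]
        return GenotypeDataset(
            sample_ids=sids,
            pop_of_sample={s: self.pop_of_sample[s] for s in sids},
            role_of_pop=dict(self.role_of_pop),
            markers=self.markers.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[np.ix_(rows, cols)],
            phased=self.phased,
            haplotypes=haps,
        )

    def haplotype_panel(self, pop: str | None = None) -> HaplotypePanel:
        """Extract the phased panel (optionally for one population).

        Requires phased data with no missing genotypes in the selected samples.
        """
        if not self.phased or self.haplotypes is None:
            raise ValueError("dataset is not phased; no haplotypes available")
        rows = np.arange(self.n_samples) if pop is None else self.sample_indices(pop)
        hrows = np.repeat(rows * 2, 2) + np.tile([0, 1], len(rows))
        haps = self.haplotypes[hrows]
        if (haps == MISSING).any():
            raise ValueError("missing genotypes present; remove them before haplotype scans")
        return HaplotypePanel(
            markers=self.markers,
            haps=haps.astype(np.uint8),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


# ---------------------------------------------------------------------------
# population map


def read_popmap(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read sample->population (and optional population->role) from a 2-3 column TSV."""
    pop_of_sample: dict[str, str] = {}
    role_of_pop: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"popmap line needs >=2 columns: {line!r}")
            sample, pop = parts[0], parts[1]
            pop_of_sample[sample] = pop
            if len(parts) >= 3 and parts[2]:
                role = parts[2].upper()
                if role not in ROLES:
                    raise ValueError(f"unknown role {role!r} for population {pop!r}")
                role_of_pop[pop] = role
    for pop in set(pop_of_sample.values()):
        role_of_pop.setdefault(pop, "OTHER")
    return pop_of_sample, role_of_pop


def write_popmap(pop_of_sample: dict[str, str], role_of_pop: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_of_sample.items():
            fh.write(f"{sample}\t{pop}\t{role_of_pop.get(pop, 'OTHER')}\n")


# ---------------------------------------------------------------------------
# VCF I/O

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path, popmap) -> GenotypeDataset:
    """Load biallelic SNPs from a VCF; multi-allelic and non-SNP records are skipped.

    ``popmap`` is a popmap TSV path or a ``(pop_of_sample, role_of_pop)`` pair.
    The dataset is flagged phased iff every non-missing genotype uses the
    phased separator.
    """
    if isinstance(popmap, tuple):
        pop_of_sample, role_of_pop = popmap
    else:
        pop_of_sample, role_of_pop = read_popmap(popmap)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_of_sample]
    if absent:
        raise ValueError(f"samples missing from popmap: {absent}")

    chroms, pos, refs, alts = [], [], [], []
    dos_rows, hap_rows = [], []
    n_skipped = 0
    all_phased = True
    last = {}
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in _SNP_ALLELES or var.ALT[0] not in _SNP_ALLELES:
            n_skipped += 1
            continue
        if var.CHROM in last and var.POS <= last[var.CHROM]:
            raise ValueError(f"unsorted or duplicate position {var.CHROM}:{var.POS}")
        last[var.CHROM] = var.POS
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col_d = np.empty(len(samples), dtype=np.int8)
        col_h = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                col_d[i] = MISSING
                col_h[2 * i] = col_h[2 * i + 1] = MISSING
            else:
                col_d[i] = a0 + a1
                col_h[2 * i], col_h[2 * i + 1] = a0, a1
                if not g[2]:
                    all_phased = False
        chroms.append(var.CHROM)
        pos.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dos_rows.append(col_d)
        hap_rows.append(col_h)
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNP records", n_skipped)
    if not pos:
        raise ValueError("no biallelic SNP records in VCF")

    markers = make_marker_table(chroms, pos, ref=refs, alt=alts)
    dosages = np.stack(dos_rows, axis=1)
    haplotypes = np.stack(hap_rows, axis=1) if all_phased else None
    return GenotypeDataset(
        sample_ids=samples,
        pop_of_sample={s: pop_of_sample[s] for s in samples},
        role_of_pop=role_of_pop,
        markers=markers,
        dosages=dosages,
        phased=all_phased,
        haplotypes=haplotypes,
    )


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write the dataset as a minimal VCF v4.2 (GT only)."""
    sep = "|" if ds.phased and ds.haplotypes is not None else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(ds.markers["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.sample_ids) + "\n")
        m = ds.markers
        for j in range(ds.n_snps):
            fields = [
                str(m.at[j, "chrom"]),
                str(int(m.at[j, "pos_bp"])),
                f"snp{j}",
                str(m.at[j, "ref"]),
                str(m.at[j, "alt"]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            if ds.haplotypes is not None:
                col = ds.haplotypes[:, j]
                gts = [
                    "./."
                    if col[2 * i] == MISSING
                    else f"{col[2 * i]}{sep}{col[2 * i + 1]}"
                    for i in range(ds.n_samples)
                ]
            else:
                d2g = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
                gts = [d2g[int(d)] for d in ds.dosages[:, j]]
            fh.write("\t".join(fields + gts) + "\n")


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCConfig:
    """Marker and sample filters applied before any analysis.

    Thresholds follow common SNP-array practice: minor-allele frequency below
    ``maf_min`` and SNP call rate below ``snp_call_min`` drop the marker;
    an exact Hardy-Weinberg test p-value below ``hwe_p_min`` flags gross
    genotyping artefacts; samples below ``sample_call_min`` call rate are
    removed first.
    """

    maf_min: float = 0.01
    snp_call_min: float = 0.90
    hwe_p_min: float = 1e-7
    sample_call_min: float = 0.90
    autosomes_only: bool = True

    def validate(self) -> None:
        for name in ("maf_min", "snp_call_min", "hwe_p_min", "sample_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_snps_in: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed: dict = field(default_factory=dict)  # filter name -> count

    def to_frame(self) -> pd.DataFrame:
        rows = [("snps_in", self.n_snps_in), ("samples_in", self.n_samples_in)]
        rows += list(self.removed.items())
        rows += [("snps_out", self.n_snps_out), ("samples_out", self.n_samples_out)]
        return pd.DataFrame(rows, columns=["filter", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Sums the probabilities of all heterozygote configurations (with the
    observed allele counts fixed) that are no more probable than the observed
    one, following the standard exact-test construction used by VCFtools and
    PLINK.  Monomorphic sites return 1.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # heterozygote count shares parity with the rare-allele count
    het_vals = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalised probabilities via the symmetric recurrence
    # P(h+2)/P(h) = 4 * nA(h) * nB(h) / ((h+2)*(h+1)) with nA/nB the hom counts
    logp = np.zeros(len(het_vals))
    for k in range(1, len(het_vals)):
        h = het_vals[k - 1]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[k] = logp[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log((h + 2.0) * (h + 1.0))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.searchsorted(het_vals, n_het)
    if obs >= len(het_vals) or het_vals[obs] != n_het:
        raise ValueError("heterozygote count inconsistent with allele counts")
    # tolerance guards against float ties in the "no more probable" comparison
    return float(p[p <= p[obs] * (1.0 + 1e-12)].sum())


def _snp_stats(dosages: np.ndarray):
    called = dosages != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return called, n_called, freq


def apply_qc(ds: GenotypeDataset, cfg: QCConfig | None = None) -> tuple[GenotypeDataset, QCReport]:
    """Apply the QC filters in a fixed order and tally removals.

    Order: (1) non-autosomal SNPs; (2) samples by call rate; (3) SNPs by
    call rate, MAF and HWE computed on the retained samples.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    rep = QCReport(n_snps_in=ds.n_snps, n_samples_in=ds.n_samples)

    snp_keep = np.ones(ds.n_snps, dtype=bool)
    if cfg.autosomes_only:
        snp_keep &= ds.markers["is_autosomal"].to_numpy()
    rep.removed["non_autosomal"] = int((~snp_keep).sum())
    ds1 = ds.subset(snp_cols=np.flatnonzero(snp_keep))

    called = ds1.dosages != MISSING
    sample_rate = called.mean(axis=1) if ds1.n_snps else np.ones(ds1.n_samples)
    samp_keep = sample_rate >= cfg.sample_call_min
    rep.removed["sample_call_rate"] = int((~samp_keep).sum())
    ds2 = ds1.subset(sample_rows=np.flatnonzero(samp_keep))
    if ds2.n_samples == 0:
        raise ValueError("empty dataset after QC: all samples removed")

    called, n_called, freq = _snp_stats(ds2.dosages)
    call_rate = n_called / ds2.n_samples
    maf = np.minimum(freq, 1.0 - freq)
    fail_call = call_rate < cfg.snp_call_min
    fail_maf = ~fail_call & ((maf < cfg.maf_min) | np.isnan(freq))

    fail_hwe = np.zeros(ds2.n_snps, dtype=bool)
    check = np.flatnonzero(~fail_call & ~fail_maf)
    d = ds2.dosages
    for j in check:
        col = d[:, j]
        col = col[col != MISSING]
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = len(col) - n_het - n_hom_alt
        if hwe_exact_p(n_het, n_hom_ref, n_hom_alt) < cfg.hwe_p_min:
            fail_hwe[j] = True

    rep.removed["snp_call_rate"] = int(fail_call.sum())
    rep.removed["maf"] = int(fail_maf.sum())
    rep.removed["hwe"] = int(fail_hwe.sum())
    keep = ~(fail_call | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("empty dataset after QC: all SNPs removed")
    out = ds2.subset(snp_cols=np.flatnonzero(keep))
    rep.n_snps_out = out.n_snps
    rep.n_samples_out = out.n_samples
    return out, rep


# ---------------------------------------------------------------------------
# allele frequencies


def allele_freqs(ds: GenotypeDataset, pops=None) -> pd.DataFrame:
    """Per-population alt-allele frequencies.

    freq = (sum of non-missing dosages) / (2 x non-missing sample count);
    sites where a population has no genotyped sample are NaN there.
    Returns a DataFrame with one column per population plus ``n_<pop>``
    called-sample counts.
    """
    pops = list(pops) if pops is not None else ds.populations()
    out = {}
    for pop in pops:
        rows = ds.sample_indices(pop)
        sub = ds.dosages[rows]
        _, n_called, freq = _snp_stats(sub)
        out[pop] = freq
        out[f"n_{pop}"] = n_called
    return pd.DataFrame(out)
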