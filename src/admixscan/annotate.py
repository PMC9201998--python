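"""Interval-to-gene lookup against a GFF3 annotation.

Regions and gene records use 1-based inclusive coordinates (the GFF3
convention); a gene is reported for a region when the two intervals overlap
by at least one base pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


@dataclass
class GeneRecord:
    gene_id: str
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_genes_gff3(path, feature_types=("gene",)) -> list[GeneRecord]:
    """Extract gene features from a GFF3 file; unparseable lines are skipped
    with a logged count."""
    genes: list[GeneRecord] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                n_bad += 1
                continue
            chrom, _, ftype, start, end, _, _, _, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                n_bad += 1
                continue
            a = dict(_ATTR_RE.findall(attrs))
            gid = a.get("ID", a.get("gene_id", f"{chrom}:{start}-{end}"))
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    name=a.get("Name", a.get("gene_name", gid)),
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    biotype=a.get("biotype", a.get("gene_biotype", "")),
                )
            )
    if n_bad:
        logger.info("skipped %d unparseable GFF lines", n_bad)
    return genes


def genes_in_regions(
    regions, gff_path, biotype_filter: str | None = "protein_coding"
) -> pd.DataFrame:
    """Genes overlapping each region by >= 1 bp.

    ``regions`` is an iterable of objects or tuples with chrom/start_bp/end_bp
    (1-based inclusive). Returns one row per (region, gene) with the overlap
    size, plus a de-duplicated ``attrs['gene_list']``.
    """
    genes = read_genes_gff3(gff_path)
    if biotype_filter:
        # an annotation without biotype tags keeps all features
        tagged = [g for g in genes if g.biotype]
        if tagged:
            genes = [g for g in genes if g.biotype == biotype_filter]
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for r in regions:
        if isinstance(r, tuple):
            chrom, start, end = r
        else:
            chrom, start, end = r.chrom, r.start_bp, r.end_bp
        for g in by_chrom.get(str(chrom), []):
            lo, hi = max(start, g.start), min(end, g.end)
            if lo <= hi:
                rows.append(
                    (str(chrom), start, end, g.gene_id, g.name, hi - lo + 1)
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "gene_id", "gene_name", "overlap_bp"]
    )
    df.attrs["gene_list"] = sorted(set(df["gene_id"])) if len(df) else []
    return df
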