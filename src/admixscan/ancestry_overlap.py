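"""Overlay selection signals on the f_dM introgression scan.

Each significant SNP (q < 0.05 in the DCMS scan) is assigned a source-lineage
origin from the mean f_dM of all sliding windows whose span contains it:
negative means the P1 (e.g. taurine) side, positive the P2 (e.g. indicine)
side. With a 10-SNP window and step 2, up to five windows harbor any SNP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .introgression import WindowScore
from .selection import SelectedRegion


@dataclass
class SnpAncestryCall:
    snp_index: int
    chrom: str
    pos_bp: int
    mean_fdm: float
    n_windows: int
    origin: str  # "P1_side" | "P2_side" | "zero" | "unassigned"


def assign_snp_ancestry(
    sig_snps: pd.DataFrame, window_scores: list[WindowScore]
) -> list[SnpAncestryCall]:
    """Call the origin of each significant SNP from its harboring windows.

    ``sig_snps`` needs columns chrom, pos_bp (index used as SNP id). SNPs
    outside every window are reported unassigned; a mean f_dM of exactly
    zero is its own category rather than being forced to a side.
    """
    by_chrom: dict[str, list[WindowScore]] = {}
    for w in window_scores:
        by_chrom.setdefault(w.chrom, []).append(w)
    calls = []
    for idx, row in sig_snps.iterrows():
        pos = int(row["pos_bp"])
        hits = [
            w.fdm
            for w in by_chrom.get(str(row["chrom"]), [])
            if w.start_bp <= pos <= w.end_bp
        ]
        if not hits:
            mean = float("nan")
            origin = "unassigned"
        else:
            mean = float(np.mean(hits))
            origin = "P2_side" if mean > 0 else ("P1_side" if mean < 0 else "zero")
        calls.append(
            SnpAncestryCall(int(idx), str(row["chrom"]), pos, mean, len(hits), origin)
        )
    return calls


@dataclass
class OverlapSummary:
    n_significant: int
    n_negative: int
    n_positive: int
    n_zero: int
    n_unassigned: int
    frac_negative: float  # over assigned SNPs
    frac_positive: float

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def summarize(calls: list[SnpAncestryCall]) -> OverlapSummary:
    """Counts and percentages of negative- vs positive-f_dM significant SNPs."""
    if not calls:
        raise ValueError("no calls to summarize")
    n_neg = sum(c.origin == "P1_side" for c in calls)
    n_pos = sum(c.origin == "P2_side" for c in calls)
    n_zero = sum(c.origin == "zero" for c in calls)
    n_un = sum(c.origin == "unassigned" for c in calls)
    assigned = n_neg + n_pos + n_zero
    return OverlapSummary(
        n_significant=len(calls),
        n_negative=n_neg,
        n_positive=n_pos,
        n_zero=n_zero,
        n_unassigned=n_un,
        frac_negative=round(100.0 * n_neg / assigned, 2) if assigned else float("nan"),
        frac_positive=round(100.0 * n_pos / assigned, 2) if assigned else float("nan"),
    )


def calls_to_frame(calls: list[SnpAncestryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_index": [c.snp_index for c in calls],
            "chrom": [c.chrom for c in calls],
            "pos_bp": [c.pos_bp for c in calls],
            "mean_fdm": [c.mean_fdm for c in calls],
            "n_windows": [c.n_windows for c in calls],
            "origin": [c.origin for c in calls],
        }
    )


def chromosome_paint(
    calls: list[SnpAncestryCall], regions: list[SelectedRegion]
) -> pd.DataFrame:
    """Ideogram-style table: one row per selected region with the majority
    origin of its significant SNPs (ties reported as "mixed")."""
    rows = []
    for r in regions:
        inside = [
            c for c in calls
            if c.chrom == r.chrom and r.start_bp <= c.pos_bp <= r.end_bp
        ]
        n_neg = sum(c.origin == "P1_side" for c in inside)
        n_pos = sum(c.origin == "P2_side" for c in inside)
        if n_neg > n_pos:
            origin = "P1_side"
        elif n_pos > n_neg:
            origin = "P2_side"
        elif n_neg or n_pos:
            origin = "mixed"
        else:
            origin = "unassigned"
        rows.append((r.chrom, r.start_bp, r.end_bp, origin))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "origin"])
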