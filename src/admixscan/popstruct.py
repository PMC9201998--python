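"""Population-structure summaries: IBS distances, neighbor-joining, PCA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_population_level(self, pop_of_label: dict[str, str]) -> "DistanceMatrix":
        """Average sample distances within population pairs."""
        pops = list(dict.fromkeys(pop_of_label[s] for s in self.labels))
        idx = {p: [i for i, s in enumerate(self.labels) if pop_of_label[s] == p] for p in pops}
        n = len(pops)
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                block = self.d[np.ix_(idx[pops[a]], idx[pops[b]])]
                out[a, b] = out[b, a] = block.mean()
        return DistanceMatrix(pops, out)


def ibs_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Mean identity-by-state mismatch: d(i,j) = mean |dos_i - dos_j| / 2 over
    SNPs called in both samples."""
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = ds.dosages.astype(float)
    g[ds.dosages == MISSING] = np.nan
    n = ds.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g[i + 1:]) / 2.0
        shared = ~np.isnan(diff)
        if (shared.sum(axis=1) == 0).any():
            j = i + 1 + int(np.argmax(shared.sum(axis=1) == 0))
            raise ValueError(
                f"samples {ds.sample_ids[i]!r} and {ds.sample_ids[j]!r} share no called SNPs"
            )
        d[i, i + 1:] = d[i + 1:, i] = np.nanmean(diff, axis=1)
    return DistanceMatrix(list(ds.sample_ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix, outgroup: str | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Ties in the Q-matrix go to the lowest (i, j) index pair for determinism;
    negative branch lengths are clamped to zero with the deficit moved to the
    sister edge. With ``outgroup`` given, the tree is re-rooted on that leaf's
    pendant edge.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes = [f"__leaf__{i}" for i in range(n)]
    newick = {nodes[i]: dm.labels[i] for i in range(n)}

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(np.round(q, 12)))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        newick_new = f"({newick[nodes[i]]}:{li:.10g},{newick[nodes[j]]}:{lj:.10g})"
        dn = 0.5 * (d[:, i] + d[:, j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.vstack([d[keep][:, keep], dn[keep][None, :]])
        d = np.hstack([d, np.append(dn[keep], 0.0)[:, None]])
        name = f"__node__{len(nodes)}"
        newick[name] = newick_new
        nodes = [nodes[x] for x in keep] + [name]

    # final three taxa: unique unrooted resolution
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    tree = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    if outgroup is not None:
        tree = _root_on(tree, outgroup)
    return tree


def _root_on(newick: str, outgroup: str) -> str:
    """Re-root an unrooted newick tree on the outgroup's pendant edge."""
    import dendropy  # local import: rooting only

    t = dendropy.Tree.get(data=newick, schema="newick")
    og = t.find_node_with_taxon_label(outgroup)
    if og is None:
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    return t.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    coordinates: np.ndarray  # [n_samples, k]
    explained_variance_fraction: np.ndarray

    def to_frame(self, ds: GenotypeDataset) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "sample", ds.sample_ids)
        df.insert(1, "pop", [ds.pop_of_sample[s] for s in ds.sample_ids])
        return df


def pca(ds: GenotypeDataset, k: int = 10) -> PcaResult:
    """PCA on variance-standardised genotypes (PLINK-style).

    Each SNP column is centred by 2*p-hat and scaled by sqrt(2*p-hat*(1-p-hat));
    missing entries become 0 after centring. Coordinates are the projections
    onto the top-k eigenvectors of the sample covariance.
    """
    if k > min(ds.n_samples, ds.n_snps):
        raise ValueError("k exceeds min(n_samples, n_snps)")
    g = ds.dosages.astype(float)
    miss = ds.dosages == MISSING
    g[miss] = np.nan
    if np.isnan(g).all(axis=0).any():
        raise ValueError("SNP with 100% missing rate")
    p = np.nanmean(g, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0] = 1.0
    x = (g - 2.0 * p) / denom
    x[np.isnan(x)] = 0.0
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    return PcaResult(
        coordinates=u[:, :k] * s[:k],
        explained_variance_fraction=var[:k] / var.sum(),
    )
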