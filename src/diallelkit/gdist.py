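"""Identity-by-state genetic distances, UPGMA dendrograms, tanglegrams.

For biallelic calls coded 0/1/2 (copies of the alternate allele), the
per-locus identity by state between calls x and y is the shared-allele
fraction ``1 - |x - y| / 2`` (1 for identical calls, 0.5 for heterozygote
vs homozygote, 0 for opposite homozygotes).  The pairwise IBS is the mean
over loci where both calls are present, and the genetic distance is
``GD = 1 - IBS``.  A strict-match variant (IBS = 1 iff the calls are
identical) is available via ``mode="strict"``.

UPGMA (average linkage) agglomerates the distance matrix into a rooted
ultrametric dendrogram: each merge sits at half the average inter-cluster
distance, and ties are broken deterministically by the lexicographically
smallest pair of cluster labels.  Entanglement compares the leaf orders of
two dendrograms on the same leaves (0 = identical order, 1 = one order is
the reverse of the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ibs_distance",
    "trait_distance",
    "upgma",
    "cophenetic",
    "entanglement",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair support counts."""

    d: pd.DataFrame
    support: pd.DataFrame | None = None

    def __post_init__(self):
        a = self.d.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(a, a.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (a < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.d.index)


def ibs_distance(snps: pd.DataFrame, mode: str = "shared_allele") -> DistanceMatrix:
    """Pairwise GD = 1 - IBS from a markers x parents call matrix.

    Missing calls (NaN) are skipped per pair; a pair sharing no non-missing
    marker is an error.  ``support`` records the number of loci used per
    pair.
    """
    if mode not in ("shared_allele", "strict"):
        raise ValueError(f"unknown IBS mode {mode!r}")
    if snps.shape[0] < 1:
        raise ValueError("need at least one marker")
    cols = list(snps.columns)
    if len(set(cols)) != len(cols):
        raise ValueError("parent labels must be unique")
    x = snps.to_numpy(dtype=float)
    p = len(cols)
    gd = np.zeros((p, p))
    sup = np.zeros((p, p), dtype=int)
    for i in range(p):
        sup[i, i] = np.sum(~np.isnan(x[:, i]))
        for j in range(i + 1, p):
            ok = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            n = int(ok.sum())
            if n == 0:
                raise ValueError(
                    f"parents {cols[i]!r} and {cols[j]!r} share no "
                    "non-missing marker")
            a, b = x[ok, i], x[ok, j]
            if mode == "shared_allele":
                ibs = float(np.mean(1.0 - np.abs(a - b) / 2.0))
            else:
                ibs = float(np.mean(a == b))
            gd[i, j] = gd[j, i] = 1.0 - ibs
            sup[i, j] = sup[j, i] = n
    mk = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return DistanceMatrix(d=mk(gd), support=mk(sup))


def trait_distance(trait_means: pd.DataFrame, scaling: str = "zscore") -> DistanceMatrix:
    """Euclidean distance between genotypes on column-standardized traits.

    Rows are genotypes, columns traits.  Each trait is z-scored (sample
    standard deviation, ddof=1) so traits on different scales contribute
    comparably; zero-variance traits are dropped with a warning.
    """
    import warnings

    if scaling != "zscore":
        raise ValueError(f"unknown scaling {scaling!r}")
    t = trait_means.astype(float)
    sd = t.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance traits: {dead}")
        t = t.drop(columns=dead)
        sd = sd.drop(dead)
    if t.shape[1] == 0:
        raise ValueError("no traits left after dropping zero-variance columns")
    z = (t - t.mean()) / sd
    a = z.to_numpy()
    diff = a[:, None, :] - a[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return DistanceMatrix(d=pd.DataFrame(d, index=t.index, columns=t.index))


@dataclass
class Dendrogram:
    """A rooted ultrametric tree node (leaf when ``children`` is empty).

    ``height`` is the merge height (0 for leaves); the branch length to a
    child is the height difference.  ``label`` is the leaf label, and every
    internal node carries the lexicographically smallest leaf label of its
    subtree for deterministic ordering.
    """

    height: float = 0.0
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def min_label(self) -> str:
        if self.is_leaf:
            return self.label
        return min(c.min_label for c in self.children)

    def leaves(self) -> list[str]:
        """Leaf labels in left-to-right display order."""
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, digits: int = 6) -> str:
        def fmt(node: "Dendrogram", parent_h: float) -> str:
            bl = round(parent_h - node.height, digits)
            bls = f"{bl:g}"
            if node.is_leaf:
                return f"{node.label}:{bls}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bls}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(dist: DistanceMatrix | pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Merge height is half the average distance between the merged clusters;
    after a merge, distances to the new cluster are size-weighted averages.
    Ties are broken by the lexicographically smallest (label_a, label_b)
    pair, and each merge places the cluster with the smaller minimum label
    on the left, so the output (and its Newick string) is deterministic.
    """
    d = dist.d if isinstance(dist, DistanceMatrix) else dist
    a = d.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T):
        raise ValueError("distance matrix must be symmetric")
    labels = [str(x) for x in d.index]
    nodes = [Dendrogram(height=0.0, label=lab) for lab in labels]
    sizes = [1] * len(nodes)
    active = list(range(len(nodes)))

    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                key_pair = tuple(sorted((nodes[i].min_label, nodes[j].min_label)))
                cand = (a[i, j], key_pair, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, _, i, j = best
        left, right = ((i, j) if nodes[i].min_label <= nodes[j].min_label
                       else (j, i))
        parent = Dendrogram(height=dij / 2.0, children=(nodes[left], nodes[right]))
        # weighted-average distances to the merged cluster
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            a[i, k] = a[k, i] = (ni * a[i, k] + nj * a[j, k]) / (ni + nj)
        nodes[i] = parent
        sizes[i] = ni + nj
        active.remove(j)
    return nodes[active[0]]


def cophenetic(tree: Dendrogram) -> pd.DataFrame:
    """Cophenetic distances: twice the merge height of each pair's ancestor."""
    labels = tree.leaves()
    n = len(labels)
    out = pd.DataFrame(np.zeros((n, n)), index=labels, columns=labels)

    def walk(node: Dendrogram):
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for u in groups[gi]:
                    for v in groups[gj]:
                        out.loc[u, v] = out.loc[v, u] = 2.0 * node.height
        return [u for g in groups for u in g]

    walk(tree)
    return out


def _rank_map(order: list[str]) -> dict[str, int]:
    return {lab: i + 1 for i, lab in enumerate(order)}


def entanglement(t1: Dendrogram, t2: Dendrogram, L: float = 1.5,
                 optimize: bool = False) -> float:
    """Entanglement between two dendrograms on the same leaf set.

    Leaves are ranked by display order in each tree; entanglement is the
    L-norm sum of rank differences divided by its worst case (one order
    fully reversed), giving a value in [0, 1] with 0 for identical orders.
    With ``optimize=True`` the rotations (child-order flips) of the second
    tree are searched exhaustively for the minimal value (practical for
    small leaf sets; the first tree's order is held fixed).
    """
    leaves1, leaves2 = t1.leaves(), t2.leaves()
    if sorted(leaves1) != sorted(leaves2):
        raise ValueError("dendrograms have different leaf sets")
    n = len(leaves1)
    if n < 2:
        return 0.0
    worst = float(sum(abs((i + 1) - (n - i)) ** L for i in range(n)))

    def score(order2: list[str]) -> float:
        r2 = _rank_map(order2)
        total = sum(abs((i + 1) - r2[lab]) ** L for i, lab in enumerate(leaves1))
        return total / worst

    if not optimize:
        return score(leaves2)

    internals: list[Dendrogram] = []

    def collect(node: Dendrogram):
        if not node.is_leaf:
            internals.append(node)
            for c in node.children:
                collect(c)

    collect(t2)
    m = len(internals)
    if m > 12:
        raise ValueError("exhaustive rotation search limited to small trees")
    best = 1.0
    for mask in range(1 << m):
        flip = {id(node) for b, node in enumerate(internals) if mask >> b & 1}

        def order(node: Dendrogram) -> list[str]:
            if node.is_leaf:
                return [node.label]
            kids = node.children[::-1] if id(node) in flip else node.children
            return [lab for c in kids for lab in order(c)]

        best = min(best, score(order(t2)))
        if best == 0.0:
            break
    return best
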