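"""Genotype-metabolome congruence statistics.

Spearman-based metabolomic distances between strains, complete-linkage
hierarchical clustering, scaled PCA, patristic distances from a newick tree,
and a permutation Mantel test (Pearson statistic on distance vectors,
one-sided greater, observed statistic included in the null count).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .features import FeatureMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "PcaResult",
    "PhyloTree",
    "MantelResult",
    "spearman_distance",
    "complete_linkage",
    "pca",
    "patristic",
    "mantel",
    "mantel_statistic",
]


@dataclass
class DistanceMatrix:
    """Symmetric strain-by-strain dissimilarities with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle entries, scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def spearman_distance(matrix: FeatureMatrix, level: str = "strain") -> DistanceMatrix:
    """1 - Spearman rank correlation between strain-mean abundance profiles.

    Ranks use midranks for ties (gap-filled zeros tie at the bottom). A
    constant profile has zero rank variance and raises, naming the strain.
    """
    if level != "strain":
        raise ValueError("only strain-level profiles are supported")
    profiles = matrix.strain_means(fill=0.0)  # features x strains
    if profiles.shape[1] < 2:
        raise ValueError("need at least two strains")
    ranks = np.column_stack(
        [rankdata(profiles[c].to_numpy()) for c in profiles.columns]
    )
    sd = ranks.std(axis=0)
    for j, strain in enumerate(profiles.columns):
        if sd[j] == 0:
            raise ValueError(
                f"strain {strain!r} has a constant abundance profile; "
                "rank correlation is undefined"
            )
    rho = np.corrcoef(ranks.T)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(list(profiles.columns), d)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence (scipy linkage encoding) plus leaf labels."""

    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge sequence as (member set A, member set B, height)."""
        n = len(self.labels)
        clusters: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, h, _) in enumerate(self.linkage):
            sa, sb = clusters[int(a)], clusters[int(b)]
            out.append((sa, sb, float(h)))
            clusters[n + k] = sa | sb
        return out

    def are_sisters(self, a: str, b: str) -> bool:
        """True when the first merge involving either leaf joins exactly {a, b}."""
        for sa, sb, _ in self.merges():
            touched = (a in sa or a in sb) or (b in sa or b in sb)
            if touched:
                return sa | sb == frozenset([a, b])
        return False

    def cophenetic(self) -> DistanceMatrix:
        d = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(list(self.labels), squareform(d))

    def nearest_neighbor(self, leaf: str) -> str:
        """Leaf with the smallest cophenetic distance to ``leaf``."""
        coph = self.cophenetic()
        i = coph.labels.index(leaf)
        row = coph.values[i].copy()
        row[i] = np.inf
        return coph.labels[int(np.argmin(row))]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}
        node_s = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            sa = f"{node_s[a]}:{h - node_h[a]:.10g}"
            sb = f"{node_s[b]}:{h - node_h[b]:.10g}"
            node_s[n + k] = f"({sa},{sb})"
            node_h[n + k] = h
        return node_s[n + len(self.linkage) - 1] + ";"


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Complete-linkage (max pairwise) agglomerative clustering.

    Merge heights are non-decreasing, which makes the dendrogram ultrametric.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least two labels")
    Z = hierarchy.linkage(d.condensed(), method="complete")
    return Dendrogram(Z, list(d.labels))


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: np.ndarray             # samples x components
    loadings: np.ndarray           # features x components (orthonormal)
    explained_fraction: np.ndarray  # per-component, non-increasing, sums <= 1
    sample_labels: list[str] = field(default_factory=list)
    feature_labels: list[str] = field(default_factory=list)


def pca(
    data: Union[pd.DataFrame, np.ndarray], scale: bool = True
) -> PcaResult:
    """PCA by SVD of the column-centered (and unit-variance scaled) data.

    Zero-variance features are dropped with a warning when scaling; the sign
    convention makes each component's largest-|loading| entry positive.
    Explained fractions are eigenvalue shares: lambda_k / sum(lambda).
    """
    if isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        sample_labels = [str(i) for i in data.index]
        feature_labels = [str(c) for c in data.columns]
    else:
        X = np.asarray(data, dtype=float)
        sample_labels = [str(i) for i in range(X.shape[0])]
        feature_labels = [str(j) for j in range(X.shape[1])]
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 features")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s) before scaling"
            )
            Xc = Xc[:, keep]
            feature_labels = [f for f, k in zip(feature_labels, keep) if k]
            sd = sd[keep]
        if Xc.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant features")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, Xc.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    eig = s**2
    frac = eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)
    scores = U * s
    loadings = Vt.T
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(scores, loadings, frac, sample_labels, feature_labels)


@dataclass
class PhyloTree:
    """Rooted/unrooted tree with branch lengths (substitutions/site)."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        if "(" in source:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=source, schema="newick", preserve_underscores=True
            )
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        return labels

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def patristic(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise sum of branch lengths along leaf-to-leaf paths.

    Computed from node depths: d(i, j) = depth(i) + depth(j) - 2 depth(MRCA).
    Any internal or terminal edge without a length raises (the seed root edge
    is exempt: it lies on no leaf-to-leaf path only when the root has a single
    child chain; a standard bifurcating root's edge is never traversed twice).
    """
    t = tree.tree
    root = t.seed_node
    depth: dict = {root: 0.0}
    order = []
    for node in t.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "(internal)"
            raise ValueError(f"missing branch length above node {label}")
        depth[node] = depth[node.parent_node] + float(node.edge.length)
        order.append(node)
    leaves = [lf for lf in t.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    # ancestor sets for MRCA lookup
    anc: dict = {}
    for lf in leaves:
        path = []
        node = lf
        while node is not None:
            path.append(node)
            node = node.parent_node
        anc[lf] = path
    n = len(leaves)
    d = np.zeros((n, n))
    anc_sets = {lf: set(id(x) for x in anc[lf]) for lf in leaves}
    for i in range(n):
        for j in range(i + 1, n):
            mrca = next(x for x in anc[leaves[i]] if id(x) in anc_sets[leaves[j]])
            d[i, j] = d[j, i] = depth[leaves[i]] + depth[leaves[j]] - 2 * depth[mrca]
    return DistanceMatrix(labels, d)


@dataclass
class MantelResult:
    """Permutation Mantel test outcome."""

    r: float
    p_value: float
    n_perm: int
    seed: Optional[int] = None

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValueError("r outside [-1, 1]")


def mantel_statistic(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation of the strictly-upper-triangle distance vectors."""
    v1, v2 = d1.condensed(), d2.condensed()
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in a distance vector")
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    exhaustive: bool = False,
) -> MantelResult:
    """One-sided (greater) permutation Mantel test.

    The null is built by jointly permuting rows and columns of ``d2`` and
    recomputing the statistic; p = (#{perm r >= observed} + 1) / (n_perm + 1),
    so the smallest achievable p at 999 permutations is 0.001. With
    ``exhaustive=True`` all n! label permutations are enumerated instead and
    p is the exact null fraction (identity included).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must carry identical ordered labels")
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    r_obs = mantel_statistic(d1, d2)
    v1 = d1.condensed()
    m2 = d2.values
    n = len(d1.labels)
    iu = np.triu_indices(n, k=1)
    v1n = (v1 - v1.mean()) / (v1.std() * np.sqrt(v1.size))

    def perm_r(p: np.ndarray) -> float:
        v2p = m2[np.ix_(p, p)][iu]
        s = v2p.std()
        if s == 0:
            return 0.0
        return float(v1n @ ((v2p - v2p.mean()) / (s * np.sqrt(v2p.size))))

    if exhaustive:
        rs = np.array(
            [perm_r(np.array(p)) for p in itertools.permutations(range(n))]
        )
        count = int(np.sum(rs >= r_obs - 1e-12))
        return MantelResult(r_obs, count / len(rs), len(rs), seed)

    if rng is None:
        rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if perm_r(p) >= r_obs - 1e-12:
            count += 1
    p_value = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p_value, n_perm, seed)
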