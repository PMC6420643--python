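"""Single-cell lineage trees by hierarchical clustering.

Single cells sampled at the end of an expansion carry binary barcodes over
the selected edit sites.  Cell-to-cell distance is one minus the Jaccard
index of the edit sets; average-linkage (UPGMA-style) agglomeration yields a
dendrogram whose splits are assessed by ordinary (Felsenstein) site
bootstrap: edit sites are resampled with replacement, the clustering is
repeated, and the support of an internal node is the fraction of replicates
containing the same leaf bipartition.  Cophenetic correlation between the
original and tree-implied distances measures how faithfully the dendrogram
represents the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must have zero diagonal")
        self.d = d

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Dendrogram:
    """Average-linkage tree: scipy linkage matrix + leaf labels + supports.

    ``supports`` maps each internal node's leaf set (a frozenset of labels,
    excluding the trivial all-leaves cluster and singletons) to a bootstrap
    support in [0, 1]; empty until :func:`bootstrap_support` fills it.
    """

    linkage: np.ndarray
    labels: list[str]
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    def clusters(self) -> list[frozenset[str]]:
        """Leaf sets of all non-trivial internal nodes, in merge order."""
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for step, (a, b, _h, _cnt) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + step] = merged
            if 1 < len(merged) < n:
                out.append(merged)
        return out

    def cophenetic(self) -> np.ndarray:
        return hierarchy.cophenet(self.linkage)


def _barcode_matrix(
    barcodes: "Mapping[str, Sequence[int]] | object",
) -> tuple[list[str], np.ndarray]:
    """Accept a mapping sample -> 0/1 vector or a pandas DataFrame
    (samples x sites)."""
    if hasattr(barcodes, "values") and hasattr(barcodes, "index"):
        labels = [str(s) for s in barcodes.index]
        mat = np.asarray(barcodes.values, dtype=bool)
    else:
        labels = sorted(barcodes)
        mat = np.asarray([barcodes[s] for s in labels], dtype=bool)
    return labels, mat


def jaccard_distance_matrix(
    barcodes, blacklist_columns: Iterable[int] = ()
) -> DistanceMatrix:
    """Pairwise Jaccard distances d = 1 - |A n B| / |A u B| between cells.

    A pair of cells with no edits at all is assigned distance 0 (maximally
    similar by convention).  ``blacklist_columns`` drops site columns before
    the distance computation.
    """
    labels, mat = _barcode_matrix(barcodes)
    if len(labels) < 2:
        raise ValueError("need >=2 cells")
    drop = set(blacklist_columns)
    if drop:
        keep = [j for j in range(mat.shape[1]) if j not in drop]
        mat = mat[:, keep]
    A = mat.astype(np.float64)
    inter = A @ A.T
    sizes = A.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(union > 0, 1.0 - inter / union, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sample_ids=labels, d=d)


def average_linkage_tree(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA-style agglomeration of the distance matrix."""
    Z = hierarchy.linkage(dm.condensed, method="average")
    return Dendrogram(linkage=Z, labels=list(dm.sample_ids))


def bootstrap_support(
    barcodes,
    n_boot: int = 1000,
    seed: int = 0,
    blacklist_columns: Iterable[int] = (),
) -> Dendrogram:
    """Site-bootstrap supports for the average-linkage tree.

    Resamples edit sites (columns) with replacement ``n_boot`` times,
    reclusters, and reports for each internal node of the original tree the
    fraction of replicates containing the same leaf bipartition.  With zero
    informative sites every support is 0.
    """
    labels, mat = _barcode_matrix(barcodes)
    if len(labels) < 3:
        raise ValueError("need >=3 cells for bootstrap supports")
    drop = set(blacklist_columns)
    if drop:
        keep = [j for j in range(mat.shape[1]) if j not in drop]
        mat = mat[:, keep]
    base = average_linkage_tree(
        jaccard_distance_matrix({s: mat[i] for i, s in enumerate(labels)})
    )
    targets = base.clusters()
    counts = {c: 0 for c in targets}
    rng = np.random.default_rng(seed)
    nsites = mat.shape[1]
    informative = np.any(mat, axis=0) & ~np.all(mat, axis=0)
    if nsites == 0 or not informative.any():
        base.supports = {c: 0.0 for c in targets}
        return base
    for _ in range(n_boot):
        cols = rng.integers(0, nsites, size=nsites)
        rep = average_linkage_tree(
            jaccard_distance_matrix(
                {s: mat[i, cols] for i, s in enumerate(labels)}
            )
        )
        rep_clusters = set(rep.clusters())
        for c in targets:
            if c in rep_clusters:
                counts[c] += 1
    base.supports = {c: counts[c] / n_boot for c in targets}
    return base


def cophenetic_correlation(dendrogram: Dendrogram, dm: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic distances."""
    if dendrogram.labels != dm.sample_ids:
        raise ValueError("leaf labels do not match the distance matrix")
    orig = dm.condensed
    coph = dendrogram.cophenetic()
    if np.ptp(orig) < 1e-12 * max(1.0, abs(orig).max()) or np.ptp(coph) < 1e-12 * max(
        1.0, abs(coph).max()
    ):
        raise ValueError("constant distances: cophenetic correlation undefined")
    r, _ = pearsonr(orig, coph)
    return float(r)


def to_newick(dendrogram: Dendrogram, support_percent: bool = True) -> str:
    """Newick string with bootstrap supports as internal node labels.

    Supports are written like bootstrapped P-values x 100 when
    ``support_percent`` (e.g. ``(A,B)95``); heights become branch lengths.
    """
    Z = dendrogram.linkage
    labels = dendrogram.labels
    n = len(labels)
    sets: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    height = {i: 0.0 for i in range(n)}

    def fmt_support(leafset: frozenset[str]) -> str:
        if leafset not in dendrogram.supports:
            return ""
        s = dendrogram.supports[leafset]
        return str(int(round(s * 100))) if support_percent else f"{s:.3f}"

    node: dict[int, str] = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        idx = n + step
        sets[idx] = sets[a] | sets[b]
        height[idx] = h
        la = h - height[a]
        lb = h - height[b]
        node[idx] = (
            f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})" + fmt_support(sets[idx])
        )
    return node[n + len(Z) - 1] + ";"
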