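"""Bulk-cell lineage tree reconstruction from edit co-occurrence graphs.

Each bulk node (an expanded well of cells) carries a barcode: the set of
called C→T edits.  Because edits accumulate irreversibly down the lineage, an
edit introduced in an ancestor is expressed by every descendant node, so the
substitution graph over edits encodes the tree.  Reconstruction proceeds as
in scar-based graph methods (LINNAEUS-style):

1. The first ancestor node is the sample with the maximal number of
   connections and is removed.
2. The remaining nodes are split into clades: connected components under the
   overlap (Jaccard >= ``min_overlap``) of their conditional barcodes — the
   edits not already explained by the removed ancestor chain.  Nodes in the
   same clade share a much higher fraction of novel barcodes than nodes in
   other clades.
3. Within a component, the ancestral ("top") edit is found probabilistically:
   for a candidate edit x, the detection rate p(x) is the fraction of nodes
   expressing edits connected to x that also express x; the chance that x
   would co-occur with edit y in at least one node is
   p(x-y) = 1 - (1 - p(x))**N_y with N_y nodes expressing y.  The number of
   realised connections of x is then Poisson-binomial distributed, and the
   candidate whose observed degree has the highest cumulative probability
   P(X <= degree) is the top edit.  The node expressing it with the smallest
   conditional barcode is the component's top (ancestor) node: it becomes
   the child of the node removed above it and is peeled off in turn, the
   procedure recursing until every node is designated.
4. Each peeled node contributes its novel edits as a chain in the edit-level
   tree; a node's placement is its last own edit (its anchor).

The module also exposes the edit-level primitives (edit network, clade
finding over expressing-set overlap, detection rate, Poisson-binomial CDF,
top-edit selection) as standalone operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

# Chance Jaccard overlap between the novel barcodes of two sister nodes is
# F/(2-F) <= 1/3 for editing rates F <= 0.5, while a true mother-child pair
# overlaps at 1/(2-F) >= 0.51; 0.4 separates the two regimes for the whole
# plausible rate range.
DEFAULT_MIN_OVERLAP = 0.4


# ---------------------------------------------------------------------------
# data containers


@dataclass
class EditNetwork:
    """Co-occurrence network over edits with expressing node-sets.

    Internally a boolean matrix ``M`` (edits x samples); ``edges`` holds the
    unordered edit pairs co-observed in at least one node.
    """

    edits: list[str]
    samples: list[str]
    M: np.ndarray  # bool, edits x samples
    depth_weight: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {e: i for i, e in enumerate(self.edits)}

    @property
    def expressing(self) -> dict[str, frozenset[str]]:
        return {
            e: frozenset(self.samples[j] for j in np.nonzero(self.M[i])[0])
            for i, e in enumerate(self.edits)
        }

    @property
    def edges(self) -> set[frozenset[str]]:
        inter = self.M.astype(np.int32) @ self.M.T.astype(np.int32)
        out: set[frozenset[str]] = set()
        for i in range(len(self.edits)):
            for j in range(i + 1, len(self.edits)):
                if inter[i, j] > 0:
                    out.add(frozenset((self.edits[i], self.edits[j])))
        return out

    def index_of(self, edit: str) -> int:
        return self._index[edit]


@dataclass
class EditTree:
    """Directed mother->child tree over edits with sample placements."""

    roots: list[str]
    parent: dict[str, str | None]
    placed_nodes: dict[str, str | None]  # sample -> anchor edit (None = above all clades)
    clades: list[frozenset[str]]
    root_sample: str | None = None
    sample_parent: dict[str, str | None] | None = None

    def chain(self, edit: str) -> list[str]:
        """Edits from the clade root down to ``edit`` (inclusive)."""
        out = []
        e: str | None = edit
        while e is not None:
            out.append(e)
            e = self.parent[e]
        return out[::-1]


@dataclass
class SampleTree:
    """Rooted tree over sample ids given by a parent map (root -> None)."""

    parent: dict[str, str | None]

    @property
    def root(self) -> str:
        roots = [s for s, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        return roots[0]

    def depth(self, sample: str) -> int:
        d = 0
        s = self.parent[sample]
        while s is not None:
            d += 1
            s = self.parent[s]
        return d

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {s: [] for s in self.parent}
        for s, p in self.parent.items():
            if p is not None:
                ch[p].append(s)
        for lst in ch.values():
            lst.sort()
        return ch


@dataclass(frozen=True)
class PlacementAccuracy:
    correct: int
    total: int

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else float("nan")


# ---------------------------------------------------------------------------
# network construction


def build_edit_network(
    barcodes: Mapping[str, Iterable[str]] | Sequence,
    depth_weight: Mapping[tuple[str, str], float] | None = None,
) -> EditNetwork:
    """Build the edit co-occurrence network from per-sample barcodes.

    ``barcodes`` maps sample id -> iterable of edit ids, or is a sequence of
    objects with ``sample_id``/``edits`` attributes (e.g.
    :class:`deamtrace.calling.CellBarcode`).
    """
    if not isinstance(barcodes, Mapping):
        barcodes = {b.sample_id: b.edits for b in barcodes}
    if not barcodes:
        raise ValueError("need >=1 barcode")
    samples = sorted(barcodes)
    edits = sorted({e for es in barcodes.values() for e in es})
    M = np.zeros((len(edits), len(samples)), dtype=bool)
    eidx = {e: i for i, e in enumerate(edits)}
    for j, s in enumerate(samples):
        for e in barcodes[s]:
            M[eidx[e], j] = True
    return EditNetwork(
        edits=edits,
        samples=samples,
        M=M,
        depth_weight=dict(depth_weight or {}),
    )


def _jaccard_adjacency(M: np.ndarray, min_overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Raw co-occurrence adjacency and overlap-thresholded adjacency."""
    Mf = M.astype(np.float32)
    inter = Mf @ Mf.T
    sizes = Mf.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    raw = inter > 0
    np.fill_diagonal(raw, False)
    thr = raw & (jac >= min_overlap)
    return raw, thr


def _component_labels(adj: np.ndarray) -> np.ndarray:
    n, labels = _cc(csr_matrix(adj), directed=False)
    return labels


def find_clades(
    network: EditNetwork,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    legacy_depth_weight: bool = False,
) -> list[frozenset[str]]:
    """Partition edits into clades.

    Default: keep an edge only when the Jaccard overlap of the two edits'
    expressing node-sets is >= ``min_overlap``; clades are the connected
    components of the retained graph.  ``legacy_depth_weight`` reproduces the
    earlier traversal that explores raw co-occurrence edges in order of
    decreasing sequencing-depth weight (components then equal plain
    connected components of the unthresholded graph).
    """
    if len(network.edits) == 0:
        return []
    raw, thr = _jaccard_adjacency(network.M, min_overlap)
    adj = raw if legacy_depth_weight else thr
    labels = _component_labels(adj)
    out: dict[int, set[str]] = {}
    for e, lab in zip(network.edits, labels):
        out.setdefault(int(lab), set()).add(e)
    return [frozenset(v) for _, v in sorted(out.items(), key=lambda kv: min(kv[1]))]


# ---------------------------------------------------------------------------
# probabilistic top-node selection


def detection_rate(x: str, network: EditNetwork) -> float:
    """p(x) = N_{x n C(x)} / N_{C(x)} over the co-occurrence graph.

    C(x) is the set of edits connected to x; the denominator counts nodes
    expressing any edit of C(x), the numerator those that also express x.
    """
    i = network.index_of(x)
    raw, _ = _jaccard_adjacency(network.M, 0.0)
    neigh = np.nonzero(raw[i])[0]
    if neigh.size == 0:
        raise ValueError(f"edit {x!r} has no connected edits")
    expressed_by_neigh = network.M[neigh].any(axis=0)
    n_c = int(expressed_by_neigh.sum())
    n_xc = int((expressed_by_neigh & network.M[i]).sum())
    return n_xc / n_c


def pairwise_edit_probability(p_x: float, n_y: int) -> float:
    """Chance of observing edits x and y together in at least one node:
    1 - (1 - p(x))**N_y."""
    if not (0.0 <= p_x <= 1.0):
        raise ValueError("p_x must lie in [0, 1]")
    if n_y < 0:
        raise ValueError("n_y must be >= 0")
    return 1.0 - (1.0 - p_x) ** n_y


def poisson_binomial_cdf(success_probs: Sequence[float], k: int) -> float:
    """P(X <= k) for X a sum of independent Bernoulli(p_i), by exact
    dynamic-programming convolution."""
    probs = np.asarray(success_probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    if not (0 <= k <= probs.size):
        raise ValueError(f"k={k} outside [0, {probs.size}]")
    # pmf over 0..k+? we only need mass at 0..k; keep k+1 states and an
    # absorbing overflow handled implicitly by dropping mass
    dp = np.zeros(k + 1)
    dp[0] = 1.0
    for p in probs:
        dp[1:] = dp[1:] * (1 - p) + dp[:-1] * p
        dp[0] *= 1 - p
    return float(dp.sum())


def _argbest(cand: Sequence[int], scores: Sequence[float], sizes, edit_ids) -> int:
    """Argmax of score with ties broken by larger expressing set, then by
    lexicographically smaller edit id.  Returns a component-local index."""
    best = None
    for ci, sc in zip(cand, scores):
        key = (sc, sizes[ci], [-ord(c) for c in edit_ids[ci]])
        if best is None or key > best[0]:
            best = (key, int(ci))
    return best[1]


def _select_top_index(
    raw_sub: np.ndarray,
    Msub: np.ndarray,
    sizes: np.ndarray,
    edit_ids: Sequence[str],
) -> int:
    """Component-local index of the top edit of one component.

    ``raw_sub`` is the co-occurrence adjacency restricted to the component,
    ``Msub`` the expressing matrix rows, ``sizes`` the expressing-set sizes,
    ``edit_ids`` the component's edit ids (for deterministic tie-breaking).

    Two exact shortcuts keep this fast on large components:

    * a candidate connected to every other member has CDF exactly 1 (its
      observed degree equals the number of potential connections), while a
      non-full candidate always has CDF < 1 (its detection rate is strictly
      positive, so exceeding the observed degree has positive probability);
    * P(X <= k) is non-decreasing in k and non-increasing in the detection
      rate p(x) (every success probability 1-(1-p)^N_y grows with p), so only
      candidates on the Pareto frontier of (k, -p) can attain the maximum;
      the exact DP is evaluated on the frontier only.
    """
    m = raw_sub.shape[0]
    if m == 1:
        return 0
    deg = raw_sub.sum(axis=1)
    full = np.nonzero(deg == m - 1)[0]
    if full.size:
        return _argbest(full, np.ones(full.size), sizes, edit_ids)

    # detection rate per candidate
    p = np.empty(m)
    for ci in range(m):
        neigh = np.nonzero(raw_sub[ci])[0]
        if neigh.size == 0:
            p[ci] = np.nan
            continue
        expressed_by_neigh = Msub[neigh].any(axis=0)
        n_c = int(expressed_by_neigh.sum())
        n_xc = int((expressed_by_neigh & Msub[ci]).sum())
        p[ci] = n_xc / n_c

    cand = [ci for ci in range(m) if np.isfinite(p[ci])]
    if not cand:  # no candidate has any connection; fall back to size/lex
        return _argbest(range(m), np.zeros(m), sizes, edit_ids)

    # Pareto frontier over unique (k, p): keep pairs not dominated by
    # another pair with k' >= k and p' <= p
    pairs: dict[tuple[int, float], list[int]] = {}
    for ci in cand:
        pairs.setdefault((int(deg[ci]), float(p[ci])), []).append(ci)
    frontier = []
    best_p = np.inf
    for (k, px), members in sorted(
        pairs.items(), key=lambda kp: (-kp[0][0], kp[0][1])
    ):
        if px < best_p:
            frontier.append(((k, px), members))
            best_p = px

    scored: list[tuple[float, int]] = []
    for (k, px), members in frontier:
        for ci in members:
            others = np.nonzero(np.arange(m) != ci)[0]
            probs = 1.0 - (1.0 - px) ** sizes[others]
            scored.append((poisson_binomial_cdf(probs, k), ci))
    smax = max(s for s, _ in scored)
    winners = [ci for s, ci in scored if s >= smax - 1e-15]
    return _argbest(winners, [smax] * len(winners), sizes, edit_ids)


def select_top_node(clade_edits: Iterable[str], network: EditNetwork) -> str:
    """Top (ancestral) edit of a clade by Poisson-binomial scoring."""
    clade = sorted(clade_edits)
    sub = np.array([network.index_of(e) for e in clade])
    raw, _ = _jaccard_adjacency(network.M, 0.0)
    raw_sub = raw[np.ix_(sub, sub)]
    Msub = network.M[sub]
    sizes = Msub.sum(axis=1)
    ci = _select_top_index(raw_sub, Msub, sizes, clade)
    return clade[ci]


# ---------------------------------------------------------------------------
# full reconstruction


def _first_ancestor(barcodes: Mapping[str, frozenset[str]]) -> str:
    """Sample with the maximal degree of connections.

    Two samples are connected when they share an edit or when one barcode is
    a subset of the other (an unedited or sparsely edited founder is an
    ancestor of everything).  Ties: smaller barcode, then lexicographic id.
    """
    samples = sorted(barcodes)
    edits_all = sorted({e for es in barcodes.values() for e in es})
    eidx = {e: i for i, e in enumerate(edits_all)}
    B = np.zeros((len(samples), max(len(edits_all), 1)), dtype=bool)
    for i, s in enumerate(samples):
        for e in barcodes[s]:
            B[i, eidx[e]] = True
    inter = B.astype(np.float32) @ B.T.astype(np.float32)
    sizes = B.sum(axis=1)
    overlap = inter > 0
    subset = (inter == sizes[:, None]) | (inter == sizes[None, :])
    adj = overlap | subset
    np.fill_diagonal(adj, False)
    deg = adj.sum(axis=1)
    order = sorted(
        range(len(samples)), key=lambda i: (-int(deg[i]), int(sizes[i]), samples[i])
    )
    return samples[order[0]]


def _node_component_labels(
    Bc: np.ndarray, min_overlap: float, legacy: bool
) -> np.ndarray:
    """Component labels for nodes under conditional-barcode overlap.

    ``Bc`` is a nodes x sites boolean matrix of conditional barcodes (edits
    not yet accounted for by the removed ancestor chain).  An edge joins two
    nodes whose conditional barcodes intersect and — unless ``legacy`` —
    whose Jaccard overlap is >= ``min_overlap``.
    """
    Bf = Bc.astype(np.float32)
    inter = Bf @ Bf.T
    sizes = Bf.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    adj = inter > 0
    np.fill_diagonal(adj, False)
    if not legacy:
        adj &= jac >= min_overlap
    return _component_labels(adj)


def _conditional_top_edit(C: np.ndarray, edit_ids: Sequence[str]) -> int:
    """Column index of the top edit given conditional expressing matrix C
    (nodes x edits, every column non-empty).

    Implements the Poisson-binomial top-edit rule of
    :func:`_select_top_index` with the same exact shortcuts, phrased on the
    conditional expressing sets of one node component.
    """
    m, E = C.shape
    expr = C.sum(axis=0)
    # an edit expressed by every node of the component co-occurs with every
    # other edit and has maximal expressing-set size: CDF = 1 and it wins
    # every tie-break
    common = np.nonzero(expr == m)[0]
    if common.size:
        return min(common, key=lambda j: edit_ids[j])
    # observed degree per candidate: edits co-expressed with x in >=1 node
    cooc_mask = np.zeros((E, E), dtype=bool)
    for j in range(E):
        cooc_mask[j] = C[C[:, j]].any(axis=0)
    deg = cooc_mask.sum(axis=1) - 1
    full = np.nonzero(deg == E - 1)[0]
    if full.size:
        best = max(full, key=lambda j: (expr[j], [-ord(c) for c in edit_ids[j]]))
        return int(best)
    # detection rates, Pareto frontier, exact DP (see _select_top_index)
    p = np.full(E, np.nan)
    for j in range(E):
        neigh = cooc_mask[j].copy()
        neigh[j] = False
        if not neigh.any():
            continue
        has_neigh = C[:, neigh].any(axis=1)
        n_c = int(has_neigh.sum())
        p[j] = int((has_neigh & C[:, j]).sum()) / n_c
    cand = [j for j in range(E) if np.isfinite(p[j])]
    if not cand:
        return int(max(range(E), key=lambda j: (expr[j], [-ord(c) for c in edit_ids[j]])))
    pairs: dict[tuple[int, float], list[int]] = {}
    for j in cand:
        pairs.setdefault((int(deg[j]), float(p[j])), []).append(j)
    frontier: list[tuple[tuple[int, float], list[int]]] = []
    best_p = np.inf
    for (k, px), members in sorted(pairs.items(), key=lambda kp: (-kp[0][0], kp[0][1])):
        if px < best_p:
            frontier.append(((k, px), members))
            best_p = px
    scored: list[tuple[float, int]] = []
    for (k, px), members in frontier:
        for j in members:
            others = np.nonzero(np.arange(E) != j)[0]
            probs = 1.0 - (1.0 - px) ** expr[others]
            scored.append((poisson_binomial_cdf(probs, k), j))
    smax = max(s for s, _ in scored)
    winners = [j for s, j in scored if s >= smax - 1e-15]
    best = max(winners, key=lambda j: (expr[j], [-ord(c) for c in edit_ids[j]]))
    return int(best)


def reconstruct_tree(
    barcodes: Mapping[str, Iterable[str]] | Sequence,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    legacy_depth_weight: bool = False,
) -> EditTree:
    """Reconstruct the lineage tree by iterative node peeling.

    After removing the first ancestor node (maximal degree), the remaining
    nodes are split into clades: connected components under the overlap of
    their *conditional* barcodes — the edits not already explained by the
    removed ancestor chain (nodes of the same clade share a much higher
    fraction of novel barcodes than nodes of other clades).  For each
    component the top edit is identified by the Poisson-binomial rule; the
    node expressing it with the smallest conditional barcode is the
    component's top (ancestor) node, becomes the child of the node that was
    removed above it, and is peeled off in turn.  The procedure repeats
    until every node is designated.

    The returned :class:`EditTree` also carries the edit-level tree: each
    peeled node contributes its novel edits as a chain, attached under the
    anchor edit of its parent node.  Deterministic for a given input
    regardless of the iteration order of ``barcodes``.
    """
    if not isinstance(barcodes, Mapping):
        barcodes = {b.sample_id: frozenset(b.edits) for b in barcodes}
    barcodes = {s: frozenset(es) for s, es in barcodes.items()}
    if len(barcodes) < 2:
        raise ValueError("need >=2 barcodes")

    root_sample = _first_ancestor(barcodes)
    samples = sorted(barcodes)
    edits_all = sorted({e for es in barcodes.values() for e in es})
    eidx = {e: i for i, e in enumerate(edits_all)}
    B = np.zeros((len(samples), len(edits_all)), dtype=bool)
    for i, s in enumerate(samples):
        for e in barcodes[s]:
            B[i, eidx[e]] = True
    row = {s: i for i, s in enumerate(samples)}

    sample_parent: dict[str, str | None] = {root_sample: None}
    edit_parent: dict[str, str | None] = {}
    placed: dict[str, str | None] = {}
    anchor: dict[str, str | None] = {}

    def add_chain(sample: str, novel_cols: np.ndarray, parent_anchor: str | None) -> None:
        """Chain the sample's novel edits under its parent's anchor edit."""
        prev = parent_anchor
        for j in sorted(novel_cols, key=lambda j: edits_all[j]):
            e = edits_all[j]
            if e in edit_parent:  # already introduced elsewhere (homoplasy)
                continue
            edit_parent[e] = prev
            prev = e
        anchor[sample] = prev
        placed[sample] = prev

    # the root sample's own edits start the chain above every clade
    root_cols = np.nonzero(B[row[root_sample]])[0]
    add_chain(root_sample, root_cols, None)
    placed[root_sample] = None  # the root node sits above all clades

    rest_rows = np.array([row[s] for s in samples if s != root_sample], dtype=int)
    if rest_rows.size:
        anc0 = B[row[root_sample]].copy()
        stack: list[tuple[np.ndarray, str, np.ndarray]] = []

        def push_components(rows: np.ndarray, par: str, anc: np.ndarray) -> None:
            if rows.size == 0:
                return
            Bc = B[rows] & ~anc
            labels = _node_component_labels(Bc, min_overlap, legacy_depth_weight)
            comps = [rows[labels == lab] for lab in np.unique(labels)]
            comps.sort(key=lambda c: samples[int(c.min())], reverse=True)
            for comp in comps:
                stack.append((comp, par, anc))

        push_components(rest_rows, root_sample, anc0)
        while stack:
            comp, par, anc = stack.pop()
            Bc = B[comp] & ~anc
            if comp.size == 1:
                ti = 0
            else:
                cols = np.nonzero(Bc.any(axis=0))[0]
                if cols.size == 0:
                    # no novel edits anywhere: attach deterministically
                    ti = int(np.argmin([samples[i] for i in comp]))
                else:
                    C = Bc[:, cols]
                    jstar = _conditional_top_edit(C, [edits_all[j] for j in cols])
                    expressers = np.nonzero(C[:, jstar])[0]
                    ti = min(
                        expressers,
                        key=lambda i: (int(Bc[i].sum()), samples[comp[i]]),
                    )
            top_row = int(comp[ti])
            top = samples[top_row]
            sample_parent[top] = par
            add_chain(top, np.nonzero(Bc[ti])[0], anchor.get(par))
            rest = np.delete(comp, ti)
            push_components(rest, top, anc | B[top_row])

    # clades = trees of the edit forest
    children: dict[str | None, list[str]] = {}
    for e, p in edit_parent.items():
        children.setdefault(p, []).append(e)
    roots = sorted(children.get(None, []))
    clades = []
    for r in roots:
        members = set()
        frontier = [r]
        while frontier:
            e = frontier.pop()
            members.add(e)
            frontier.extend(children.get(e, []))
        clades.append(frozenset(members))

    tree = EditTree(
        roots=roots,
        parent=edit_parent,
        placed_nodes=placed,
        clades=clades,
        root_sample=root_sample,
    )
    tree.sample_parent = sample_parent
    return tree


def derive_sample_tree(
    tree: EditTree, barcodes: Mapping[str, Iterable[str]] | Sequence
) -> SampleTree:
    """Sample-level tree implied by the reconstruction.

    The parent of each sample is the node that was peeled immediately above
    it during reconstruction; the first ancestor node is the root.
    """
    if not isinstance(barcodes, Mapping):
        barcodes = {b.sample_id: frozenset(b.edits) for b in barcodes}
    if tree.sample_parent is None:
        raise ValueError("edit tree carries no sample-level reconstruction")
    if set(tree.sample_parent) != set(barcodes):
        raise ValueError("barcodes do not match the reconstructed sample set")
    return SampleTree(parent=dict(tree.sample_parent))


def placement_accuracy(reconstructed: SampleTree, truth: SampleTree) -> PlacementAccuracy:
    """Fraction of nodes whose parent and depth both match the truth."""
    if set(reconstructed.parent) != set(truth.parent):
        raise ValueError("sample sets differ between reconstruction and truth")
    correct = 0
    for s in truth.parent:
        if (
            reconstructed.parent[s] == truth.parent[s]
            and reconstructed.depth(s) == truth.depth(s)
        ):
            correct += 1
    return PlacementAccuracy(correct=correct, total=len(truth.parent))
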