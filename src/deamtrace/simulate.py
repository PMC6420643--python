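"""Simulation of barcode accumulation on binary lineage trees.

The model system divides synchronously for G generations (one generation per
simulated day; generation g has 2^g cells).  Each of N target sites, once
selected as editable, converts C→T at a stepwise constant per-division rate
F (mutations/site/cell division); edits are irreversible and inherited, so a
node's edit set always contains its mother's.  Two perturbations emulate real
systems:

* dropout — each site is retained as editable with binomial probability
  1 - dropout_rate (default 30%), mimicking target loss by NHEJ deletions in
  nuclease-based systems;
* site editing bias — a fraction of sites (default 10%) saturates quickly;
  a biased site accepts an edit attempt whenever a uniform draw also falls
  at or below b = 1 - (site editing bias), implemented as an effective
  per-division rate F/b (capped at 1) with default b = 0.9.

Reconstruction quality is scored by triplet accuracy: the fraction of
mother-with-two-daughters units whose daughters the reconstruction places
under that mother (a 3-depth tree has 3 triplets; 1 correct = 33%).  The
percentage of correctly ordered ancestor/descendant pairs is available as an
alternative metric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bulk_tree import SampleTree, derive_sample_tree, reconstruct_tree

DEFAULT_DROPOUT = 0.3
DEFAULT_BIAS_FRACTION = 0.1
DEFAULT_B = 0.9


@dataclass(frozen=True)
class SimParams:
    """Simulation settings.

    ``max_cells`` optionally caps the number of cells followed per
    generation (a uniformly subsampled frontier), so deep trees stay
    tractable; None follows the complete binary tree.
    """

    G: int
    N: int
    F: float
    dropout_rate: float = DEFAULT_DROPOUT
    bias_fraction: float = DEFAULT_BIAS_FRACTION
    b: float = DEFAULT_B
    seed: int = 0
    max_cells: int | None = None

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0 < self.F <= 1):
            raise ValueError("F must lie in (0, 1]")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not (0 <= self.bias_fraction <= 1):
            raise ValueError("bias_fraction must lie in [0, 1]")
        if not (0 < self.b <= 1):
            raise ValueError("b must lie in (0, 1]")


@dataclass
class SimTree:
    """Ground-truth tree with per-node edit-birth generations.

    Node ids encode the lineage path: root "R", daughters append "0"/"1".
    ``edit_generation[n][j]`` is the generation at which site j was edited on
    the lineage of node n (0 = unedited); a node's cumulative edit set is
    simply the sites with a positive birth generation.
    """

    params: SimParams
    nodes: list[str]
    parent: dict[str, str | None]
    generation: dict[str, int]
    edit_generation: dict[str, np.ndarray]  # int16 over sites 0..N-1
    editable: np.ndarray
    biased: np.ndarray

    def site_label(self, j: int) -> str:
        return f"s{j:04d}"

    @property
    def edits(self) -> dict[str, np.ndarray]:
        """Per-node cumulative edit vectors (bool over sites)."""
        return {n: eg > 0 for n, eg in self.edit_generation.items()}

    def nodes_upto(self, generation: int | None = None) -> list[str]:
        if generation is None:
            generation = self.params.G
        return [n for n in self.nodes if self.generation[n] <= generation]

    def nodes_at(self, generation: int) -> list[str]:
        return [n for n in self.nodes if self.generation[n] == generation]

    def barcodes(
        self,
        generation: int | None = None,
        edit_window: int | None = None,
    ) -> dict[str, frozenset[str]]:
        """Per-node edit-set barcodes.

        ``generation`` truncates the tree (nodes up to that depth);
        ``edit_window`` truncates the edits (only conversions born at or
        before that generation), emulating an editor active for a limited
        number of generations on the full tree.
        """
        gw = self.params.G if edit_window is None else edit_window
        out = {}
        for n in self.nodes_upto(generation):
            eg = self.edit_generation[n]
            idx = np.nonzero((eg > 0) & (eg <= gw))[0]
            out[n] = frozenset(self.site_label(j) for j in idx)
        return out

    def sample_tree(self, generation: int | None = None) -> SampleTree:
        nodes = set(self.nodes_upto(generation))
        return SampleTree(parent={n: self.parent[n] for n in nodes})

    def subtree_nodes(self, root: str) -> list[str]:
        return [n for n in self.nodes if n.startswith(root)]


@dataclass(frozen=True)
class TripletScore:
    correct: int
    total: int

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else float("nan")


def apply_dropout(N: int, dropout_rate: float, seed_or_rng) -> np.ndarray:
    """Editable-site mask: each site kept with probability 1 - dropout_rate."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return rng.random(N) < (1.0 - dropout_rate)


def simulate_tree(params: SimParams) -> SimTree:
    """Grow the barcode-accumulation tree.

    The root starts unedited; at each division every still-unedited editable
    site flips independently with probability F (or F/b for biased sites).
    Fixing the seed makes the entire tree bit-reproducible.
    """
    rng = np.random.default_rng(params.seed)
    editable = apply_dropout(params.N, params.dropout_rate, rng)
    biased = rng.random(params.N) < params.bias_fraction
    rate = np.where(biased, min(params.F / params.b, 1.0), params.F)
    rate = np.where(editable, rate, 0.0)

    nodes = ["R"]
    parent: dict[str, str | None] = {"R": None}
    generation = {"R": 0}
    edit_gen = {"R": np.zeros(params.N, dtype=np.int16)}
    frontier = ["R"]
    for g in range(1, params.G + 1):
        children = [(mom, mom + c) for mom in frontier for c in ("0", "1")]
        if params.max_cells is not None and len(children) > params.max_cells:
            keep = rng.choice(len(children), size=params.max_cells, replace=False)
            children = [children[i] for i in sorted(keep)]
        new_frontier = []
        for mom, child in children:
            inherited = edit_gen[mom]
            new = (inherited == 0) & (rng.random(params.N) < rate)
            eg = inherited.copy()
            eg[new] = g
            edit_gen[child] = eg
            parent[child] = mom
            generation[child] = g
            nodes.append(child)
            new_frontier.append(child)
        frontier = new_frontier
    return SimTree(
        params=params,
        nodes=nodes,
        parent=parent,
        generation=generation,
        edit_generation=edit_gen,
        editable=editable,
        biased=biased,
    )


# ---------------------------------------------------------------------------
# scoring


def triplet_accuracy(truth: SampleTree, reconstructed: SampleTree) -> TripletScore:
    """Fraction of mother+two-daughter units placed correctly.

    A triplet is correct when the reconstruction assigns both daughters to
    that mother as their parent.
    """
    if set(truth.parent) != set(reconstructed.parent):
        raise ValueError("node sets differ between truth and reconstruction")
    children = truth.children()
    correct = total = 0
    for mom, kids in children.items():
        if len(kids) != 2:
            continue
        total += 1
        if all(reconstructed.parent[d] == mom for d in kids):
            correct += 1
    return TripletScore(correct=correct, total=total)


def pairwise_order_accuracy(truth: SampleTree, reconstructed: SampleTree) -> float:
    """Fraction of true ancestor/descendant pairs whose order the
    reconstruction preserves (the alternative accuracy metric)."""
    if set(truth.parent) != set(reconstructed.parent):
        raise ValueError("node sets differ between truth and reconstruction")

    def ancestors(st: SampleTree, n: str) -> set[str]:
        out = set()
        p = st.parent[n]
        while p is not None:
            out.add(p)
            p = st.parent[p]
        return out

    recon_anc = {n: ancestors(reconstructed, n) for n in truth.parent}
    correct = total = 0
    for n in truth.parent:
        for a in ancestors(truth, n):
            total += 1
            if a in recon_anc[n]:
                correct += 1
    return correct / total if total else float("nan")


def sister_clade_sharing(
    tree: SimTree,
    generation: int | None = None,
    edit_window: int | None = None,
) -> float:
    """Mean Jaccard overlap of aggregate edit sets between sister clades.

    Clades are rooted at ``generation`` (all rooting generations pooled when
    None) and extend to the bottom of the tree; ``edit_window`` restricts
    the aggregates to conversions born at or before that generation.
    """
    if generation is not None and not (1 <= generation <= tree.params.G):
        raise ValueError("generation outside the simulated range")
    gw = tree.params.G if edit_window is None else edit_window
    roots = (
        tree.nodes_at(generation)
        if generation is not None
        else [n for n in tree.nodes if n != "R"]
    )
    children: dict[str, list[str]] = {}
    for n in roots:
        children.setdefault(tree.parent[n], []).append(n)
    vals = []
    for mom, kids in sorted(children.items()):
        if len(kids) != 2:
            continue
        agg = []
        for k in sorted(kids):
            v = np.zeros(tree.params.N, dtype=bool)
            for n in tree.subtree_nodes(k):
                eg = tree.edit_generation[n]
                v |= (eg > 0) & (eg <= gw)
            agg.append(v)
        union = (agg[0] | agg[1]).sum()
        inter = (agg[0] & agg[1]).sum()
        vals.append(inter / union if union else 0.0)
    return float(np.mean(vals)) if vals else float("nan")


def consumed_fraction(tree: SimTree, generation: int) -> float:
    """Minimum over cells at ``generation`` of the fraction of editable
    sites already edited (how used-up the barcode space is).

    Because barcodes are inherited, this also equals the consumed fraction
    of the deepest cells when the editor is only active through
    ``generation``.
    """
    if generation < 0 or generation > tree.params.G:
        raise ValueError("generation outside the simulated range")
    n_editable = int(tree.editable.sum())
    if n_editable == 0:
        return 0.0
    fracs = [
        ((tree.edit_generation[n] > 0) & tree.editable).sum() / n_editable
        for n in tree.nodes_at(generation)
    ]
    return float(min(fracs)) if fracs else 0.0


# ---------------------------------------------------------------------------
# reconstruction plumbing and parameter sweeps

Reconstructor = Callable[[Mapping[str, frozenset[str]]], SampleTree]


def graph_reconstructor(min_overlap: float | None = None) -> Reconstructor:
    """Default reconstructor: the bulk-cell node-peeling graph method."""
    from .bulk_tree import DEFAULT_MIN_OVERLAP

    mo = DEFAULT_MIN_OVERLAP if min_overlap is None else min_overlap

    def rec(barcodes: Mapping[str, frozenset[str]]) -> SampleTree:
        tree = reconstruct_tree(barcodes, min_overlap=mo)
        return derive_sample_tree(tree, barcodes)

    return rec


def _score(truth: SampleTree, recon: SampleTree, metric: str) -> float:
    if metric == "triplet":
        return triplet_accuracy(truth, recon).accuracy
    if metric == "pairwise":
        return pairwise_order_accuracy(truth, recon)
    raise ValueError(f"unknown metric {metric!r}")


def accuracy_curve(
    params: SimParams,
    reconstructor: Reconstructor | None = None,
    metric: str = "triplet",
    protocol: str = "edit_window",
) -> pd.DataFrame:
    """Per-generation reconstruction accuracy for one simulated tree.

    ``protocol='edit_window'`` (default) emulates letting the editor run for
    g generations on the full depth-G experiment: for each g the complete
    tree is reconstructed from barcodes restricted to conversions born at or
    before g and scored against the fixed truth.  Accuracy rises while new
    generations keep being labelled and peaks as the editable sites are
    consumed.  ``protocol='tree_depth'`` instead stops the whole experiment
    at depth g (tree truncated, all edits kept).

    Also reports the minimum consumed fraction of editable sites at g and
    the mean sister-clade sharing under the same window.
    """
    if reconstructor is None:
        reconstructor = graph_reconstructor()
    tree = simulate_tree(params)
    rows = []
    if protocol == "edit_window":
        truth = tree.sample_tree()
    elif protocol != "tree_depth":
        raise ValueError(f"unknown protocol {protocol!r}")
    for g in range(1, params.G + 1):
        if protocol == "edit_window":
            barcodes = tree.barcodes(edit_window=g)
            acc = _score(truth, reconstructor(barcodes), metric)
            # redundancy of the freshly labelled generation: overlap between
            # the two sister cells' cumulative barcodes at generation g
            sharing = sister_clade_sharing(tree, g, edit_window=g)
        else:
            barcodes = tree.barcodes(g)
            acc = _score(tree.sample_tree(g), reconstructor(barcodes), metric)
            sharing = sister_clade_sharing(tree, g)
        rows.append(
            {
                "generation": g,
                "accuracy": acc,
                "consumed_fraction": consumed_fraction(tree, g),
                "sister_sharing": sharing,
            }
        )
    return pd.DataFrame(rows)


def _replicate_seed(base_seed: int, replicate: int) -> int:
    # stable sub-stream per replicate, kept within 31 bits
    return int(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(replicate,)).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_sweep(
    grid: Iterable[SimParams],
    replicates: int = 20,
    reconstructor: Reconstructor | None = None,
    metric: str = "triplet",
    protocol: str = "edit_window",
) -> pd.DataFrame:
    """Seeded accuracy surface over a grid of simulation settings.

    For every :class:`SimParams` in the grid and every replicate, simulates
    a tree to depth G and scores the reconstruction per generation.  The
    replicate seed is derived from ``params.seed``, so two grid entries that
    differ only in e.g. dropout form paired arms.
    """
    frames = []
    for params in grid:
        for rep in range(replicates):
            p = replace(params, seed=_replicate_seed(params.seed, rep))
            df = accuracy_curve(
                p, reconstructor=reconstructor, metric=metric, protocol=protocol
            )
            df.insert(0, "replicate", rep)
            df.insert(0, "bias_fraction", params.bias_fraction)
            df.insert(0, "dropout_rate", params.dropout_rate)
            df.insert(0, "F", params.F)
            df.insert(0, "N", params.N)
            df.insert(0, "G", params.G)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def mean_accuracy_by_generation(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (N, F, dropout_rate, bias_fraction, generation)."""
    return (
        sweep.groupby(["N", "F", "dropout_rate", "bias_fraction", "generation"])[
            "accuracy"
        ]
        .mean()
        .reset_index()
    )
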