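"""UMI-based molecule counting.

PCR amplification distorts per-molecule read counts; degenerate-base unique
molecular identifiers (UMIs) on one amplification primer let each original
molecule be counted once.  Reads sharing a UMI form a family; a family is kept
only when at least 70% of its reads agree on one sequence (the consensus).
Sequencing errors inside the UMI itself split one molecule across several
near-identical UMIs, so families whose UMIs lie within Hamming distance 2 of
each other are merged by connected components of the Hamming-distance graph,
retaining the highest-count UMI of each cluster.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

CONSENSUS_FRACTION = 0.70
MAX_HAMMING = 2


@dataclass
class UmiFamily:
    """Reads sharing one UMI; ``consensus`` is None below the 70% threshold."""

    umi: str
    member_sequences: tuple[str, ...]
    consensus: str | None

    @property
    def read_count(self) -> int:
        return len(self.member_sequences)


@dataclass
class UmiCluster:
    """A connected component of UMIs at pairwise-reachable Hamming distance <=2."""

    retained_umi: str
    merged_umis: frozenset[str]
    total_count: int


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def primer_match_fraction(read: str, primer: str) -> float:
    """Identity of the read prefix against the amplification primer."""
    if not primer:
        raise ValueError("empty primer")
    prefix = read[: len(primer)]
    if not prefix:
        return 0.0
    return sum(x == y for x, y in zip(prefix, primer)) / len(primer)


def filter_reads_by_primer(
    reads: Iterable[tuple[str, str]],
    primer: str,
    min_identity: float = 0.5,
) -> list[tuple[str, str]]:
    """Optional prefilter: keep reads whose primer-matching prefix identity
    is at least ``min_identity`` (default 0.5)."""
    return [
        (umi, seq)
        for umi, seq in reads
        if primer_match_fraction(seq, primer) >= min_identity
    ]


def group_by_umi(
    reads: Iterable[tuple[str, str]],
    consensus_fraction: float = CONSENSUS_FRACTION,
) -> list[UmiFamily]:
    """Group (umi, sequence) reads into families and call consensus.

    The consensus is the modal member sequence when its fraction of the
    family is >= ``consensus_fraction`` (ties on the mode are broken
    lexicographically); otherwise the family is flagged with a null
    consensus and excluded from molecule counting downstream.
    """
    by_umi: dict[str, list[str]] = defaultdict(list)
    length: int | None = None
    for umi, seq in reads:
        if length is None:
            length = len(umi)
        elif len(umi) != length:
            raise ValueError(
                f"mixed UMI lengths: expected {length}, got {len(umi)}"
            )
        by_umi[umi].append(seq)
    families = []
    for umi in sorted(by_umi):
        members = tuple(sorted(by_umi[umi]))
        counts = Counter(members)
        top_count = max(counts.values())
        modal = min(s for s, c in counts.items() if c == top_count)
        consensus = modal if top_count / len(members) >= consensus_fraction else None
        families.append(UmiFamily(umi=umi, member_sequences=members, consensus=consensus))
    return families


def _components(umis: list[str], max_hamming: int) -> list[list[int]]:
    """Connected components of the Hamming-distance graph (union-find)."""
    n = len(umis)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    arr = np.frombuffer("".join(umis).encode(), dtype="S1").reshape(n, -1)
    for i in range(n):
        dists = (arr[i + 1 :] != arr[i]).sum(axis=1)
        for off in np.nonzero(dists <= max_hamming)[0]:
            ri, rj = find(i), find(int(off) + i + 1)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    return list(groups.values())


def cluster_umis(
    families: Sequence[UmiFamily], max_hamming: int = MAX_HAMMING
) -> list[UmiCluster]:
    """Merge families whose UMIs are within ``max_hamming`` into clusters.

    Only families with a non-null consensus may be clustered.  Each cluster
    retains the UMI with the highest read count (ties lexicographic) and
    counts as one molecule.
    """
    for f in families:
        if f.consensus is None:
            raise ValueError("cluster_umis requires consensus-passing families")
    if not families:
        return []
    umis = [f.umi for f in families]
    count = {f.umi: f.read_count for f in families}
    clusters = []
    for comp in _components(umis, max_hamming):
        members = sorted(umis[i] for i in comp)
        retained = max(members, key=lambda u: (count[u], [-ord(c) for c in u]))
        clusters.append(
            UmiCluster(
                retained_umi=retained,
                merged_umis=frozenset(members),
                total_count=sum(count[u] for u in members),
            )
        )
    clusters.sort(key=lambda c: c.retained_umi)
    return clusters


def molecule_count(families: Sequence[UmiFamily], max_hamming: int = MAX_HAMMING) -> int:
    """Number of unique molecules after consensus filtering and clustering."""
    passing = [f for f in families if f.consensus is not None]
    return len(cluster_umis(passing, max_hamming=max_hamming))


def coefficient_of_variation(per_position_counts: Mapping[object, float]) -> float:
    """Population std / mean of per-position molecule counts.

    Used as the amplification-uniformity statistic: lower CV means more even
    coverage of target positions.
    """
    counts = np.asarray(list(per_position_counts.values()), dtype=float)
    if counts.size < 2:
        raise ValueError("need counts at >=2 positions")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("mean count is zero; CV undefined")
    return float(counts.std(ddof=0) / mean)
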