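"""File formats: samtools-mpileup text, Newick trees, TSV tables.

Site tables are 1-based inclusive on disk (samtools convention) and 0-based
half-open in memory.  C→T edits are counted strand-aware: a C→T conversion
on the forward strand appears as T reads at a C reference base, the same
chemistry on the reverse strand as A reads at a G reference base; both are
the same edit.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from skbio import TreeNode

from .bulk_tree import SampleTree
from .calling import SiteCounts


class PileupFormatError(ValueError):
    """Malformed pileup input; carries the offending line number."""


_INDEL_RE = re.compile(r"^[+-](\d+)")


def _decode_bases(bases: str, line_no: int) -> dict[str, int]:
    """Count called bases from an mpileup base string.

    Handles '.'/',' (reference match), ACGT/acgt (mismatch), '^X' read
    starts, '$' read ends, '+n/-n' indels, '*' deletions and '<'/'>'
    reference skips.
    """
    counts: dict[str, int] = {}
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases[i:])
            if not m:
                raise PileupFormatError(f"line {line_no}: bad indel in {bases!r}")
            length = int(m.group(1))
            i += len(m.group(0)) + length
            continue
        if c in ".,ACGTNacgtn*<>":
            key = c.upper() if c not in ".,<>*" else c
            if c == ",":
                key = "."
            counts[key] = counts.get(key, 0) + 1
            i += 1
            continue
        raise PileupFormatError(f"line {line_no}: unexpected character {c!r}")
    return counts


def read_pileup(
    path: str | Path | _io.TextIOBase,
    sample_id: str = "sample",
    dialect: str = "mpileup",
) -> list[SiteCounts]:
    """Parse per-site C→T counts.

    ``dialect='mpileup'``: 6-column samtools mpileup text (chrom, 1-based
    pos, ref, depth, read bases, quals); alt reads are T (+Tt) at a C
    reference or A (+Aa) at a G reference.  ``dialect='tsv'``: precomputed
    table with columns site_id, sample_id, depth, alt_count.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        need = {"site_id", "sample_id", "depth", "alt_count"}
        if not need <= set(df.columns):
            raise PileupFormatError(f"TSV dialect requires columns {sorted(need)}")
        return [
            SiteCounts.from_counts(
                str(r.site_id), str(r.sample_id), int(r.depth), int(r.alt_count)
            )
            for r in df.itertuples()
        ]
    if dialect != "mpileup":
        raise ValueError(f"unknown dialect {dialect!r}")

    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle, close = path, False
    out = []
    try:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 4:
                raise PileupFormatError(
                    f"line {line_no}: expected >=4 pileup columns"
                )
            chrom, pos, ref = fields[0], fields[1], fields[2].upper()
            try:
                depth = int(fields[3])
            except ValueError as exc:
                raise PileupFormatError(
                    f"line {line_no}: non-integer depth {fields[3]!r}"
                ) from exc
            site_id = f"{chrom}:{pos}"
            if depth == 0 or len(fields) < 6:
                out.append(SiteCounts.from_counts(site_id, sample_id, 0, 0))
                continue
            counts = _decode_bases(fields[4], line_no)
            if ref == "C":
                alt = counts.get("T", 0)
            elif ref == "G":
                alt = counts.get("A", 0)
            else:
                alt = 0
            out.append(SiteCounts.from_counts(site_id, sample_id, depth, alt))
    finally:
        if close:
            handle.close()
    return out


def write_pileup(records: Sequence[tuple[str, int, str, int, int]], path: str | Path) -> None:
    """Write a minimal 6-column pileup: (chrom, 1-based pos, ref, depth, alt).

    Reference-matching reads are written as '.', alt reads as the edited
    base (T at C, A at G), qualities as 'I'.
    """
    with open(path, "w") as fh:
        for chrom, pos, ref, depth, alt in records:
            altbase = "T" if ref.upper() == "C" else "A"
            bases = "." * (depth - alt) + altbase * alt
            quals = "I" * depth
            fh.write(f"{chrom}\t{pos}\t{ref}\t{depth}\t{bases}\t{quals}\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    p = Path(path)
    if not p.exists() or p.stat().st_size == 0:
        raise ValueError(f"empty or missing newick file: {p}")
    return TreeNode.read(str(p), format="newick")


def sample_tree_to_newick(tree: SampleTree) -> str:
    """Newick for a tree whose internal nodes are themselves samples.

    Every node keeps its label; internal samples appear as internal node
    labels, so the string round-trips through standard Newick parsers.
    """
    children = tree.children()

    def render(node: str) -> str:
        kids = children.get(node, [])
        if not kids:
            return node
        return "(" + ",".join(render(k) for k in kids) + ")" + node

    return render(tree.root) + ";"


def newick_to_sample_tree(text: str) -> SampleTree:
    """Inverse of :func:`sample_tree_to_newick` for label-distinct trees."""
    tn = TreeNode.read(_io.StringIO(text), format="newick")
    parent: dict[str, str | None] = {}

    def walk(node: TreeNode, par: str | None) -> None:
        name = node.name
        if name is None:
            raise ValueError("all nodes must be labelled")
        parent[name] = par
        for ch in node.children:
            walk(ch, name)

    walk(tn, None)
    return SampleTree(parent=parent)


# ---------------------------------------------------------------------------
# TSV tables


def write_barcodes_tsv(
    barcodes: Iterable, site_ordering: Sequence[str], path: str | Path
) -> None:
    """Barcode table: sample_id, cigar_string, and one 0/1 column per site."""
    from .calling import binary_vector

    rows = []
    for b in barcodes:
        row = {"sample_id": b.sample_id, "cigar_string": b.cigar_string}
        vec = binary_vector(b, site_ordering)
        row.update({s: int(v) for s, v in zip(site_ordering, vec)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_barcodes_tsv(path: str | Path) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Read the barcode table back to sample -> edit-set plus site ordering."""
    df = pd.read_csv(path, sep="\t")
    sites = [c for c in df.columns if c not in ("sample_id", "cigar_string")]
    out = {}
    for r in df.itertuples(index=False):
        d = r._asdict()
        out[str(d["sample_id"])] = frozenset(s for s in sites if int(d[s]) == 1)
    return out, sites


def read_timecourse_tsv(path: str | Path) -> "pd.DataFrame":
    """Time-course table with columns hours, wildtype_fraction[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    need = {"hours", "wildtype_fraction"}
    if not need <= set(df.columns):
        raise ValueError(f"time-course TSV requires columns {sorted(need)}")
    return df


def read_umi_reads(path: str | Path, dialect: str = "tsv") -> list[tuple[str, str]]:
    """(umi, sequence) pairs from a read table or FASTQ.

    ``dialect='tsv'``: columns read_id, umi, sequence.  ``dialect='fastq'``:
    the UMI is the part of the read name after the last underscore.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        need = {"read_id", "umi", "sequence"}
        if not need <= set(df.columns):
            raise ValueError(f"UMI TSV requires columns {sorted(need)}")
        return [(str(r.umi), str(r.sequence)) for r in df.itertuples()]
    if dialect == "fastq":
        from Bio import SeqIO

        return [
            (rec.id.rsplit("_", 1)[-1], str(rec.seq))
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    raise ValueError(f"unknown dialect {dialect!r}")
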