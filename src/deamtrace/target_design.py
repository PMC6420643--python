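"""Protospacer screening and spacer ranking for deaminase barcoding.

A cytidine-deaminase base editor (nickase Cas9 fused to a deaminase) converts
C:G pairs to T:A inside a narrow window of the protospacer — positions 4–8
counted from the PAM-distal end — next to an NGG PAM.  To barcode interspersed
repeat elements with a single sgRNA, one screens the repeat consensus (or a
set of amplicon sequences) for 20-nt spacers that (i) sit 5' of an NGG PAM and
(ii) carry at least one editable C in the 4–8 window, then picks the spacer
with the most perfect-match occurrences across the target regions.

Coordinates are 0-based half-open internally and refer to the forward strand
of the input sequence; window positions are 1-based with position 1 at the
PAM-distal end of the protospacer (the standard BE3 convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

SPACER_LEN = 20
PAM_LEN = 3
#: editable window, 1-based positions counted from the PAM-distal end
WINDOW = (4, 8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProtospacerHit:
    """One candidate protospacer with an editable C in the 4–8 window.

    ``start`` is the 0-based start of the 20-nt protospacer on the forward
    strand of ``sequence_id``; for ``strand == '-'`` the protospacer and PAM
    read 5'→3' on the reverse strand but the interval is reported in
    forward-strand coordinates.
    """

    sequence_id: str
    start: int
    strand: str
    spacer: str
    pam: str
    window_c_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError("spacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1] != "G" or self.pam[2] != "G":
            raise ValueError("PAM must match NGG")
        for p in self.window_c_positions:
            if not (WINDOW[0] <= p <= WINDOW[1]):
                raise ValueError(f"window position {p} outside {WINDOW}")
            if self.spacer[p - 1] != "C":
                raise ValueError(f"spacer position {p} is not a C")
        if not self.window_c_positions:
            raise ValueError("retained hits must have >=1 editable C")


@dataclass(frozen=True)
class SpacerRanking:
    spacer: str
    match_count: int
    rank: int


class FastaFormatError(ValueError):
    """Raised when input records are not parseable DNA FASTA."""


def _window_cs(spacer: str) -> tuple[int, ...]:
    lo, hi = WINDOW
    return tuple(p for p in range(lo, hi + 1) if spacer[p - 1] == "C")


def _scan_one_strand(
    sequence_id: str, seq: str, seqlen: int, strand: str
) -> Iterable[ProtospacerHit]:
    """Yield hits on one strand; ``seq`` is the 5'→3' strand sequence."""
    for i in range(0, len(seq) - SPACER_LEN - PAM_LEN + 1):
        spacer = seq[i : i + SPACER_LEN]
        pam = seq[i + SPACER_LEN : i + SPACER_LEN + PAM_LEN]
        if pam[1] != "G" or pam[2] != "G":
            continue
        if "N" in spacer or "N" in pam:
            continue
        cs = _window_cs(spacer)
        if not cs:
            continue
        if strand == "+":
            start = i
        else:
            # map the interval back to forward-strand coordinates
            start = seqlen - (i + SPACER_LEN)
        yield ProtospacerHit(sequence_id, start, strand, spacer, pam, cs)


def scan_protospacers(
    sequences: Iterable, both_strands: bool = True
) -> list[ProtospacerHit]:
    """Screen sequences for NGG-adjacent 20-nt spacers with an editable C.

    Parameters
    ----------
    sequences
        Iterable of Biopython ``SeqRecord`` objects or ``(id, sequence)``
        pairs.  Sequences may contain only A/C/G/T/N (case-insensitive); an N
        anywhere in a candidate spacer or PAM disqualifies that hit.
    both_strands
        Scan the reverse complement as well (default).

    Returns
    -------
    list of :class:`ProtospacerHit`, in scan order (forward strand first).
    """
    hits: list[ProtospacerHit] = []
    for rec in sequences:
        if hasattr(rec, "seq"):
            seq_id, seq = rec.id, str(rec.seq)
        else:
            seq_id, seq = rec
        seq = seq.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FastaFormatError(
                f"record {seq_id!r} contains non-DNA characters {bad}"
            )
        hits.extend(_scan_one_strand(seq_id, seq, len(seq), "+"))
        if both_strands:
            rc = str(Seq(seq).reverse_complement())
            hits.extend(_scan_one_strand(seq_id, rc, len(seq), "-"))
    return hits


def rank_spacers(
    hits: Sequence[ProtospacerHit], min_matches: int = 2
) -> list[SpacerRanking]:
    """Group identical spacers, count perfect-match hits and rank them.

    Spacers with fewer than ``min_matches`` hits are dropped (the design
    default of 2 keeps only spacers usable as multi-site barcodes).  Ranks are
    1..K by descending match count, ties broken lexicographically.
    """
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.spacer] = counts.get(h.spacer, 0) + 1
    kept = [(s, c) for s, c in counts.items() if c >= min_matches]
    kept.sort(key=lambda sc: (-sc[1], sc[0]))
    return [
        SpacerRanking(spacer=s, match_count=c, rank=i + 1)
        for i, (s, c) in enumerate(kept)
    ]


def pairwise_similarity(elements: Sequence[str]) -> float:
    """Mean pairwise identity fraction over all unordered string pairs.

    Strings are compared position-wise without alignment and must all have
    equal length; identity of a pair is (matching positions) / length.
    """
    if len(elements) < 2:
        raise ValueError("need at least two strings")
    lengths = {len(s) for s in elements}
    if len(lengths) != 1:
        raise ValueError("position-wise similarity requires equal lengths")
    (length,) = lengths
    if length == 0:
        raise ValueError("strings must be non-empty")
    total = 0.0
    npairs = 0
    for a, b in itertools.combinations(elements, 2):
        total += sum(x == y for x, y in zip(a, b)) / length
        npairs += 1
    return total / npairs


def hits_to_rows(hits: Sequence[ProtospacerHit]) -> list[dict]:
    """Rows for TSV export (window positions as a comma-joined list)."""
    return [
        {
            "sequence_id": h.sequence_id,
            "start": h.start,
            "strand": h.strand,
            "spacer": h.spacer,
            "pam": h.pam,
            "window_c_positions": ",".join(map(str, h.window_c_positions)),
        }
        for h in hits
    ]
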