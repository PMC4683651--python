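"""Sort CCS reads into forward x reverse barcode-pair bins.

A read is assigned to a pair when the forward barcode matches near its 5'
end and the reverse-complemented reverse barcode near its 3' end (each with
at least ``min_matches`` of 16 positional identities, default 12), in either
read orientation. Candidate placements come from two sources: exact hits of
any 12-nt barcode window within the terminal search span (the fast
prescreen), plus a direct scan of every terminal offset, which guarantees
that no qualifying placement is missed.

Reads qualifying for zero pairs land in the UNASSIGNED bin with reason
``no-hit``; reads qualifying for more than one pair are conservatively
UNASSIGNED with reason ``ambiguous`` rather than given to the best match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ._dna import revcomp
from .io import Barcode, ReadRecord

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class BarcodePair:
    forward_id: str
    reverse_id: str

    @property
    def key(self) -> str:
        return f"{self.forward_id}{self.reverse_id}"


@dataclass
class DemuxAssignment:
    """Outcome of demultiplexing one read."""

    read_id: str
    pair_key: str  # pair key or UNASSIGNED
    orientation: str  # "as-is" | "reverse-complement"
    fwd_matches: int
    rev_matches: int
    trimmed_sequence: str
    reason: Optional[str] = None  # for UNASSIGNED: "no-hit" | "ambiguous"

    @property
    def assigned(self) -> bool:
        return self.pair_key != UNASSIGNED


def enumerate_pairs(
    forwards: Sequence[Barcode],
    reverses: Sequence[Barcode],
    scheme: Optional[Sequence[tuple[Sequence[str], Sequence[str]]]] = None,
) -> list[BarcodePair]:
    """Enumerate forward x reverse barcode pairs.

    Default is the full cross product. ``scheme`` may give pairing blocks as
    (forward_ids, reverse_ids) tuples; the blocks are concatenated in order
    (duplicate keys across blocks are rejected).
    """
    fwd_ids = [b.id for b in forwards]
    rev_ids = [b.id for b in reverses]
    if len(set(fwd_ids)) != len(fwd_ids) or len(set(rev_ids)) != len(rev_ids):
        raise ValueError("barcode ids must be unique within each role")
    if scheme is None:
        return [BarcodePair(f, r) for f in fwd_ids for r in rev_ids]
    known_f, known_r = set(fwd_ids), set(rev_ids)
    pairs: list[BarcodePair] = []
    seen: set[str] = set()
    for block_f, block_r in scheme:
        for f in block_f:
            if f not in known_f:
                raise ValueError(f"pairing scheme references unknown forward barcode {f!r}")
            for r in block_r:
                if r not in known_r:
                    raise ValueError(
                        f"pairing scheme references unknown reverse barcode {r!r}"
                    )
                pair = BarcodePair(f, r)
                if pair.key in seen:
                    raise ValueError(f"duplicate pair {pair.key!r} in pairing scheme")
                seen.add(pair.key)
                pairs.append(pair)
    return pairs


def barcode_windows(barcode: Barcode, window_len: int = 12) -> list[str]:
    """All contiguous ``window_len``-mers of a barcode, 5' to 3'."""
    if window_len <= 0:
        raise ValueError("window length must be positive")
    if window_len > len(barcode.sequence):
        raise ValueError("window length exceeds barcode length")
    seq = barcode.sequence
    return [seq[i : i + window_len] for i in range(len(seq) - window_len + 1)]


def _identities(read_seq: str, barcode_seq: str, offset: int) -> int:
    """Positional identities of the barcode placed at ``offset``; positions
    running off the read end count as mismatches."""
    count = 0
    for k, b in enumerate(barcode_seq):
        pos = offset + k
        if pos < len(read_seq) and read_seq[pos] == b:
            count += 1
    return count


def match_barcode(
    read: ReadRecord | str,
    barcode: Barcode,
    search_span: int = 50,
    min_matches: int = 12,
    window_len: int = 12,
) -> Optional[tuple[int, int]]:
    """Locate a barcode near a read's 5' end.

    Returns (best identity count, smallest offset achieving it), or None
    when no placement reaches ``min_matches``. Candidate offsets are the
    union of window-prescreen hits and the direct terminal offset scan.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if len(seq) < len(barcode.sequence):
        return None
    prefix = seq[: search_span + len(barcode.sequence)]
    offsets: set[int] = set(range(0, max(1, search_span - len(barcode.sequence) + 1)))
    for w_idx, window in enumerate(barcode_windows(barcode, window_len)):
        hit = prefix.find(window)
        while hit != -1:
            implied = hit - w_idx
            if implied >= 0:
                offsets.add(implied)
            hit = prefix.find(window, hit + 1)
    best, best_offset = -1, -1
    for offset in sorted(offsets):
        ident = _identities(seq, barcode.sequence, offset)
        if ident > best:
            best, best_offset = ident, offset
    if best < min_matches:
        return None
    return best, best_offset


def demultiplex(
    reads: Sequence[ReadRecord],
    pairs: Sequence[BarcodePair],
    barcodes: Mapping[str, Barcode],
    search_span: int = 50,
    min_matches: int = 12,
) -> dict[str, list[DemuxAssignment]]:
    """Partition reads into barcode-pair bins plus an UNASSIGNED bin.

    Every read appears in exactly one bin. A read is assigned iff exactly
    one pair reaches ``min_matches`` at both ends in at least one
    orientation; multi-pair hits are UNASSIGNED(ambiguous).
    """
    if not pairs:
        raise ValueError("no barcode pairs to demultiplex against")
    bins: dict[str, list[DemuxAssignment]] = {p.key: [] for p in pairs}
    bins[UNASSIGNED] = []
    fwd_ids = {p.forward_id for p in pairs}
    rev_ids = {p.reverse_id for p in pairs}
    for read in reads:
        hits: list[tuple[str, str, tuple[int, int, int, int]]] = []
        for orientation, seq in (
            ("as-is", read.sequence),
            ("reverse-complement", revcomp(read.sequence)),
        ):
            rc = revcomp(seq)
            fhits = {
                fid: match_barcode(seq, barcodes[fid], search_span, min_matches)
                for fid in fwd_ids
            }
            rhits = {
                rid: match_barcode(rc, barcodes[rid], search_span, min_matches)
                for rid in rev_ids
            }
            for pair in pairs:
                hf, hr = fhits[pair.forward_id], rhits[pair.reverse_id]
                if hf is not None and hr is not None:
                    hits.append(
                        (pair.key, orientation, (hf[0], hf[1], hr[0], hr[1]))
                    )
        distinct_pairs = {h[0] for h in hits}
        if len(distinct_pairs) == 1:
            pair_key, orientation, (fm, fo, rm, ro) = hits[0]
            seq = read.sequence if orientation == "as-is" else revcomp(read.sequence)
            trimmed = seq[fo + 16 : len(seq) - ro - 16]
            bins[pair_key].append(
                DemuxAssignment(
                    read_id=read.id,
                    pair_key=pair_key,
                    orientation=orientation,
                    fwd_matches=fm,
                    rev_matches=rm,
                    trimmed_sequence=trimmed,
                )
            )
        else:
            reason = "no-hit" if not hits else "ambiguous"
            bins[UNASSIGNED].append(
                DemuxAssignment(
                    read_id=read.id,
                    pair_key=UNASSIGNED,
                    orientation="as-is",
                    fwd_matches=0,
                    rev_matches=0,
                    trimmed_sequence="",
                    reason=reason,
                )
            )
    return bins


def trim_assigned(assignment: DemuxAssignment) -> ReadRecord:
    """The barcode-trimmed insert of an assigned read, forward-oriented."""
    if not assignment.assigned:
        raise ValueError(f"read {assignment.read_id!r} is unassigned; nothing to trim")
    return ReadRecord(id=assignment.read_id, sequence=assignment.trimmed_sequence)
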