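"""End-to-end (semi-global) affine-gap alignment of CCS reads to an amplicon.

The aligner consumes the entire read; reference overhang at either end is
free. This is the "fitting" variant of global alignment: a trimmed insert is
expected to span the amplicon, but a few terminal bases of slack from
imperfect barcode trimming must not be forced into the alignment as noise.

Gap cost convention: a gap of length k costs ``gap_open + (k-1)*gap_extend``
(the first gap base pays the open penalty). The dynamic program is computed
row-wise with numpy; the horizontal (deletion) state is resolved with a
prefix-scan identity that is exact whenever ``gap_open <= gap_extend``,
which the scoring-scheme invariant guarantees.

Tie-breaking is deterministic: diagonal moves are preferred over deletions,
deletions over insertions, and the leftmost optimal end column is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._dna import encode, revcomp
from .io import ReadRecord, Reference

NEG = -(10**8)  # effective -infinity for int32 DP


class BandTooNarrowError(ValueError):
    """The optimal alignment leaves the requested band; widen the band."""


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters (defaults tuned for ~85-99% identity reads)."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignedRead:
    """An end-to-end alignment of one read against one reference.

    ``sequence`` is the read in reference-forward orientation (i.e. already
    reverse-complemented when ``strand`` is '-'); ``cigar`` uses the internal
    '='/'X'/'I'/'D' vocabulary and refers to that oriented sequence.
    ``start`` is the 0-based reference offset of the first aligned column.
    """

    read_id: str
    reference_name: str
    start: int
    cigar: tuple[tuple[str, int], ...]
    strand: str
    score: int
    sequence: str

    def __post_init__(self) -> None:
        read_len = sum(n for op, n in self.cigar if op in "=XIMS")
        if read_len != len(self.sequence):
            raise ValueError(
                f"CIGAR read-consuming ops sum to {read_len}, "
                f"sequence is {len(self.sequence)} nt"
            )
        for (a, _), (b, _) in zip(self.cigar, self.cigar[1:]):
            if a == b:
                raise ValueError("adjacent CIGAR ops of the same type")

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.start + sum(n for op, n in self.cigar if op in "=XMD")

    def merged_cigar(self, collapse: str = "") -> tuple[tuple[str, int], ...]:
        """CIGAR with '='/'X' collapsed into 'M' when ``collapse == 'M'``."""
        out: list[list] = []
        for op, n in self.cigar:
            if collapse == "M" and op in "=X":
                op = "M"
            if out and out[-1][0] == op:
                out[-1][1] += n
            else:
                out.append([op, n])
        return tuple((op, n) for op, n in out)

    def reference_columns(self):
        """Yield (ref_pos, read_pos_or_None, op) for every reference-consuming column.

        ``read_pos`` is None for deleted columns. Insertions are reported as
        (anchor_ref_pos, read_pos, 'I') once per inserted base, where the
        anchor is the reference position *before* which the base is inserted.
        """
        ref_pos, read_pos = self.start, 0
        for op, n in self.cigar:
            if op in "=XM":
                for _ in range(n):
                    yield ref_pos, read_pos, op
                    ref_pos += 1
                    read_pos += 1
            elif op == "D":
                for _ in range(n):
                    yield ref_pos, None, "D"
                    ref_pos += 1
            elif op in "IS":
                for _ in range(n):
                    yield ref_pos, read_pos, "I"
                    read_pos += 1


def _semiglobal_dp(
    read: str, ref: str, scheme: ScoringScheme
) -> tuple[int, int, tuple[tuple[str, int], ...], int]:
    """Core DP. Returns (score, ref_start, cigar, max_diag_excursion).

    The last element is max |j - i| along the optimal path, used for the
    band-width contract check.
    """
    n, m = len(read), len(ref)
    x = encode(read)
    y = encode(ref)
    o, e = scheme.gap_open, scheme.gap_extend
    ma, mi = scheme.match, scheme.mismatch

    H = np.empty((n + 1, m + 1), dtype=np.int32)
    E = np.empty((n + 1, m + 1), dtype=np.int32)  # vertical: gap in reference (I)
    F = np.empty((n + 1, m + 1), dtype=np.int32)  # horizontal: gap in read (D)
    H[0, :] = 0  # leading reference overhang is free
    E[0, :] = NEG
    F[0, :] = NEG

    jj = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        E[i, :] = np.maximum(H[i - 1, :] + o, E[i - 1, :] + e)
        sub = np.where(y == x[i - 1], ma, mi).astype(np.int32)
        # N in either sequence never counts as a match
        if x[i - 1] == 4:
            sub[:] = mi
        else:
            sub[y == 4] = mi
        htmp = E[i, :].copy()
        np.maximum(htmp[1:], H[i - 1, :-1] + sub, out=htmp[1:])
        # F[i,j] = e*(j-1) + max_{k<j}(htmp[k] + o - e*k); exact given o <= e
        g = np.maximum.accumulate(htmp + o - e * jj)
        F[i, 0] = NEG
        F[i, 1:] = g[:-1] + e * (jj[1:] - 1)
        H[i, :] = np.maximum(htmp, F[i, :])

    j = int(np.argmax(H[n, :]))  # leftmost optimal end column
    score = int(H[n, j])

    # traceback: prefer diagonal > deletion > insertion
    ops: list[str] = []
    i = n
    state = "H"
    max_excursion = abs(j - n)
    while i > 0:
        max_excursion = max(max_excursion, abs(j - i))
        if state == "H":
            if j > 0:
                s = ma if (x[i - 1] == y[j - 1] and x[i - 1] != 4) else mi
                if H[i, j] == H[i - 1, j - 1] + s:
                    ops.append("=" if s == ma else "X")
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("D")
            if F[i, j] == F[i, j - 1] + e:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # E
            ops.append("I")
            if E[i, j] == E[i - 1, j] + e:
                i -= 1
            else:
                i -= 1
                state = "H"
    max_excursion = max(max_excursion, abs(j))

    cigar: list[tuple[str, int]] = []
    for op in reversed(ops):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, j, tuple(cigar), max_excursion


def align_semiglobal(
    read: Union[str, ReadRecord],
    reference: Reference,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    band: Optional[int] = None,
    both_strands: bool = True,
) -> AlignedRead:
    """Align a read end-to-end against an amplicon reference.

    Both the read and its reverse complement are scored and the better
    placement returned (ties go to '+'). With ``band`` set, the optimal
    path must stay within ``band`` of the main diagonal or a
    :class:`BandTooNarrowError` is raised — the result is never a silent
    band-constrained suboptimum.
    """
    if isinstance(read, ReadRecord):
        read_id, seq = read.id, read.sequence
    else:
        read_id, seq = "read", read
    if not seq:
        raise ValueError("cannot align an empty read")
    if band is not None and band < abs(len(seq) - len(reference)):
        raise BandTooNarrowError(
            f"band {band} < length difference "
            f"{abs(len(seq) - len(reference))}; widen the band"
        )

    fwd = _semiglobal_dp(seq, reference.sequence, scheme)
    if both_strands:
        rc_seq = revcomp(seq)
        rev = _semiglobal_dp(rc_seq, reference.sequence, scheme)
    else:
        rev = None

    if rev is not None and rev[0] > fwd[0]:
        score, start, cigar, excursion = rev
        strand, oriented = "-", rc_seq
    else:
        score, start, cigar, excursion = fwd
        strand, oriented = "+", seq

    if band is not None and excursion > band:
        raise BandTooNarrowError(
            f"optimal alignment leaves the band (excursion {excursion} > "
            f"band {band}); widen the band"
        )
    return AlignedRead(
        read_id=read_id,
        reference_name=reference.name,
        start=start,
        cigar=cigar,
        strand=strand,
        score=score,
        sequence=oriented,
    )


def align_all(
    reads: Sequence[ReadRecord],
    reference: Reference,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    band: Optional[int] = None,
) -> list[AlignedRead]:
    """Align every read in a demultiplexed bin to its reference."""
    return [align_semiglobal(r, reference, scheme=scheme, band=band) for r in reads]


def render_text_pileup(
    alignments: Sequence[AlignedRead],
    reference: Reference,
    window: tuple[int, int],
) -> str:
    """Render alignments over a reference window as a text pileup.

    '.' and ',' mark matches on the + and - strand; mismatching bases are
    shown as the read base (uppercase on +, lowercase on -); '*' marks a
    deleted reference position; ' ' marks columns a read does not cover.
    The first row is the reference sequence over the window.
    """
    start, end = window
    if not (0 <= start < end <= len(reference)):
        raise ValueError(f"window {window} outside reference of length {len(reference)}")
    width = end - start
    lines = [reference.sequence[start:end]]
    for aln in alignments:
        if aln.reference_end <= start or aln.start >= end:
            continue
        row = [" "] * width
        minus = aln.strand == "-"
        for ref_pos, read_pos, op in aln.reference_columns():
            if not (start <= ref_pos < end) or op == "I":
                continue
            col = ref_pos - start
            if op == "D":
                row[col] = "*"
            else:
                base = aln.sequence[read_pos]
                if base == reference.sequence[ref_pos]:
                    row[col] = "," if minus else "."
                else:
                    row[col] = base.lower() if minus else base.upper()
        lines.append("".join(row))
    return "\n".join(lines)
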