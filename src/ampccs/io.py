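"""Readers and writers for the pipeline's on-disk formats.

Covers FASTA/FASTQ (via Biopython), a legacy bare-sequence reference dialect
(``ref.txt``: a file with no header line and only ACGTN characters), barcode
list files (two-column TSV or FASTA, auto-detected), SNP-panel and
parental-panel TSVs, and a minimal SAM writer for downstream inspection with
standard tools.

All coordinates are 0-based half-open internally; SAM output and panel TSVs
use the conventional 1-based positions.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import validate_dna

if TYPE_CHECKING:  # pragma: no cover
    from .align import AlignedRead

MISSING = "?"  # allele symbol for sites a read does not cover

DEFAULT_QUALITY_CHAR = "I"  # Phred+33 Q40 placeholder; qualities never enter computation


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reference:
    """An amplicon reference sequence.

    Sequences are uppercase ACGTN and at least 50 nt long: anything shorter
    cannot carry the dual 16-nt barcodes plus an insert.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference name must be non-empty")
        if len(self.sequence) < 50:
            raise ValueError(
                f"reference {self.name!r} is {len(self.sequence)} nt; minimum is 50"
            )
        validate_dna(self.sequence, allow_n=True, context=f"reference {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Barcode:
    """A 16-nt sample-identifying tag conjugated to a PCR primer."""

    id: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"barcode role must be forward/reverse, got {self.role!r}")
        if len(self.sequence) != 16:
            raise ValueError(
                f"barcode {self.id!r} is {len(self.sequence)} nt; barcodes are exactly 16 nt"
            )
        validate_dna(self.sequence, allow_n=False, context=f"barcode {self.id!r}")


@dataclass
class ReadRecord:
    """A consensus (CCS) read; ``passes`` is 0 when unknown."""

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    passes: int = 0

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.passes < 0:
            raise ValueError("pass count cannot be negative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpSite:
    """One polymorphic site of a SNP panel.

    ``position`` is 0-based on the reference; ``label`` is the human-readable
    site name used in reports (e.g. "19", "+58").
    """

    label: str
    position: int
    ref: str
    alts: tuple[str, ...] = ()


@dataclass(frozen=True)
class SnpPanel:
    """Ordered polymorphic sites within one amplicon."""

    sites: tuple[SnpSite, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("panel positions must be strictly increasing")
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("panel labels must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, i):
        return self.sites[i]


@dataclass(frozen=True)
class ParentalSite:
    """A SNP site with its recipient and donor parental alleles."""

    label: str
    position: int
    recipient: str
    donor: str

    def __post_init__(self) -> None:
        if self.recipient == self.donor:
            raise ValueError(
                f"site {self.label!r}: recipient and donor alleles must differ"
            )


@dataclass(frozen=True)
class ParentalPanel:
    """SNP panel annotated with the two parental alleles at every site."""

    sites: tuple[ParentalSite, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("panel positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, i):
        return self.sites[i]


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a 4-line-per-record FASTQ file into ReadRecords.

    Raises :class:`ParseError` naming the (0-based) record index on a
    truncated record or a sequence/quality length mismatch.
    """
    records: list[ReadRecord] = []
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0] if title else ""
                if len(seq) != len(qual):
                    raise ParseError(
                        f"record {len(records)} ({read_id!r}): sequence length "
                        f"{len(seq)} != quality length {len(qual)}"
                    )
                records.append(
                    ReadRecord(
                        id=read_id,
                        sequence=seq.upper(),
                        qualities=[ord(c) - 33 for c in qual],
                    )
                )
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"record {len(records)}: {exc}") from exc
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            if rec.qualities is not None:
                qual = "".join(chr(q + 33) for q in rec.qualities)
            else:
                qual = DEFAULT_QUALITY_CHAR * len(rec.sequence)
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[Reference]:
    """Read references from FASTA, or from a legacy bare-sequence file.

    A file whose first non-blank character is not ``>`` and whose content is
    a single ACGTN sequence is read as one reference named after the file
    stem (the historical ``ref.txt`` dialect).
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        return []
    if stripped[0] != ">":
        seq = "".join(text.split()).upper()
        return [Reference(name=path.stem, sequence=seq)]
    refs = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        refs.append(Reference(name=rec.id, sequence=str(rec.seq).upper()))
    return refs


def write_fasta(references: Iterable[Reference], path: str | Path) -> None:
    with open(path, "w") as out:
        for ref in references:
            out.write(f">{ref.name}\n")
            for i in range(0, len(ref.sequence), 80):
                out.write(ref.sequence[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# barcode lists
# ---------------------------------------------------------------------------


def read_barcode_file(path: str | Path, role: str) -> list[Barcode]:
    """Read a barcode list from two-column TSV (id, sequence) or FASTA.

    The dialect is auto-detected from the first non-blank character
    (``>`` means FASTA).
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    entries: list[tuple[str, str]] = []
    if stripped.startswith(">"):
        for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
            entries.append((rec.id, str(rec.seq).upper()))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 'id<TAB>sequence'"
                )
            entries.append((fields[0], fields[1].upper()))
    barcodes = [Barcode(id=bid, sequence=seq, role=role) for bid, seq in entries]
    seen: set[str] = set()
    for bc in barcodes:
        if bc.id in seen:
            raise ParseError(f"duplicate barcode id {bc.id!r} in {path.name}")
        seen.add(bc.id)
    return barcodes


def write_barcode_file(barcodes: Iterable[Barcode], path: str | Path) -> None:
    with open(path, "w") as out:
        for bc in barcodes:
            out.write(f"{bc.id}\t{bc.sequence}\n")


# ---------------------------------------------------------------------------
# SNP panels
# ---------------------------------------------------------------------------


def read_snp_panel(path: str | Path) -> SnpPanel:
    """Read a SNP panel TSV: columns label, position (1-based), ref, alts.

    ``alts`` is a comma-separated list and may be empty.
    """
    sites = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("label\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"panel line {lineno}: expected at least 3 columns")
        label, pos, ref = fields[0], int(fields[1]), fields[2].upper()
        alts = tuple(
            a.strip().upper() for a in fields[3].split(",") if a.strip()
        ) if len(fields) > 3 else ()
        sites.append(SnpSite(label=label, position=pos - 1, ref=ref, alts=alts))
    return SnpPanel(sites=tuple(sites))


def read_parental_panel(path: str | Path) -> ParentalPanel:
    """Read a parental panel TSV: label, position (1-based), recipient, donor."""
    sites = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("label\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"parental panel line {lineno}: expected 4 columns")
        sites.append(
            ParentalSite(
                label=fields[0],
                position=int(fields[1]) - 1,
                recipient=fields[2].upper(),
                donor=fields[3].upper(),
            )
        )
    return ParentalPanel(sites=tuple(sites))


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------


def sam_record(aln: "AlignedRead", reference: Reference) -> str:
    """Format one alignment as a mandatory-11-column SAM line."""
    if aln.reference_name != reference.name:
        raise ValueError(
            f"alignment of {aln.read_id!r} refers to {aln.reference_name!r}, "
            f"not {reference.name!r}"
        )
    flag = 16 if aln.strand == "-" else 0
    cigar = "".join(
        f"{length}{'M' if op in '=X' else op}" for op, length in aln.merged_cigar("M")
    )
    return "\t".join(
        [
            aln.read_id,
            str(flag),
            reference.name,
            str(aln.start + 1),  # SAM POS is 1-based
            "60",
            cigar,
            "*",
            "0",
            "0",
            aln.sequence,
            "*",
        ]
    )


def read_sam(path: str | Path) -> list["AlignedRead"]:
    """Read alignments from the minimal SAM dialect written by write_sam.

    Accepts M/=/X/I/D/S CIGAR ops; header lines are validated for the
    @HD/@SQ records but otherwise ignored.
    """
    from .align import AlignedRead  # deferred: io must not import align at module load

    alignments: list[AlignedRead] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(f"SAM line {lineno}: expected 11 columns")
            qname, flag, rname, pos, _mapq, cigar_str, *_rest = fields[:7]
            seq = fields[9]
            cigar: list[tuple[str, int]] = []
            num = ""
            for ch in cigar_str:
                if ch.isdigit():
                    num += ch
                elif ch in "M=XIDS":
                    cigar.append((ch, int(num)))
                    num = ""
                else:
                    raise ParseError(f"SAM line {lineno}: unsupported CIGAR op {ch!r}")
            alignments.append(
                AlignedRead(
                    read_id=qname,
                    reference_name=rname,
                    start=int(pos) - 1,
                    cigar=tuple(cigar),
                    strand="-" if int(flag) & 16 else "+",
                    score=0,
                    sequence=seq,
                )
            )
    return alignments


def write_sam(
    alignments: Sequence["AlignedRead"], reference: Reference, path: str | Path
) -> None:
    """Write alignments as minimal SAM (@HD/@SQ headers + 11 mandatory columns)."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        out.write(f"@SQ\tSN:{reference.name}\tLN:{len(reference)}\n")
        for aln in alignments:
            out.write(sam_record(aln, reference) + "\n")
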