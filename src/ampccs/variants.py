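"""Pileup construction, variant calling and the per-position error landscape.

Variant calling on demultiplexed amplicon bins is threshold-based: an
alternate allele is reported when its read fraction and absolute count both
clear floors (defaults 0.10 and 5), a site is homozygous-alt when the
alternate fraction reaches 0.90, and heterozygous when reference and
alternate both clear the reporting floors. The causative mutation of a
mutant sample — the change present in essentially every read — is any call
with fraction >= 0.80, classified into the mutation taxonomy used for
forward-mutation spectra: single base substitution, 1-bp indel, 2-5-bp
deletion, large (>=6 bp) deletion, or complex (clustered/mixed changes
within 10 nt).

The error landscape pools reads from many independent mutant samples and
measures, at every reference position, the frequency of base-substitution
miscalls; each sample's own causative site is excluded from its reads so
that real mutations do not masquerade as errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import AlignedRead
from .io import Reference

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
DEL = "DEL"


@dataclass
class PositionProfile:
    """Allele tallies at one reference position (0-based)."""

    position: int
    counts: dict[str, int]  # A/C/G/T/N/DEL -> count; sums to depth
    insertions: dict[str, int]  # inserted sequence anchored *after* this position
    depth: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.depth:
            raise ValueError(
                f"position {self.position}: counts sum "
                f"{sum(self.counts.values())} != depth {self.depth}"
            )


@dataclass
class VariantCall:
    position: int  # 0-based reference offset of the first affected base
    ref: str
    alt: str  # alt base(s); "" for a deletion; inserted seq for an insertion
    type: str  # substitution | insertion | deletion
    length: int
    alt_count: int
    depth: int
    alt_fraction: float
    zygosity: str  # heterozygous | homozygous-alt


@dataclass
class MutationReport:
    """Causative-mutation summary for one demultiplexed sample."""

    sample: str
    causative: Optional[VariantCall]
    mutation_class: str  # substitution | indel-1bp | deletion-2-5bp |
    #                      large-deletion | complex | none
    supporting_read_fraction: float
    all_causative: tuple[VariantCall, ...] = ()


@dataclass
class ErrorLandscape:
    """Per-position base-substitution error frequencies over an amplicon."""

    frequencies: np.ndarray  # float, len(reference)
    depths: np.ndarray  # substitution-eligible depth (aligned bases) per position
    excluded: dict[int, list[str]]  # position -> samples excluded there
    mean_frequency: float
    zero_error_positions: int
    high_error_positions: list[int]  # positions exceeding the threshold
    threshold: float


def pileup(
    alignments: Sequence[AlignedRead], reference: Reference
) -> list[PositionProfile]:
    """Column-wise allele tallies across a reference.

    Match/mismatch columns count the read base, deleted columns count DEL,
    and insertions are tallied at the reference position *before* which the
    bases were inserted (length-weighted as whole events, not per base).
    """
    m = len(reference)
    base_counts = np.zeros((m, 6), dtype=np.int64)  # A C G T N DEL
    ins_maps: list[dict[str, int]] = [dict() for _ in range(m)]
    for aln in alignments:
        if aln.reference_name != reference.name:
            raise ValueError(
                f"alignment of {aln.read_id!r} is against {aln.reference_name!r}"
            )
        ref_pos, read_pos = aln.start, 0
        for op, ln in aln.cigar:
            if op in "=XM":
                for k in range(ln):
                    base_counts[ref_pos + k, _BASE_INDEX[aln.sequence[read_pos + k]]] += 1
                ref_pos += ln
                read_pos += ln
            elif op == "D":
                base_counts[ref_pos : ref_pos + ln, 5] += 1
                ref_pos += ln
            else:  # I / S consume the read only; anchor insertions after prev column
                if op == "I" and 0 < ref_pos <= m:
                    anchor = ref_pos - 1
                    ins_seq = aln.sequence[read_pos : read_pos + ln]
                    ins_maps[anchor][ins_seq] = ins_maps[anchor].get(ins_seq, 0) + 1
                read_pos += ln
    profiles = []
    for pos in range(m):
        counts = {
            "A": int(base_counts[pos, 0]),
            "C": int(base_counts[pos, 1]),
            "G": int(base_counts[pos, 2]),
            "T": int(base_counts[pos, 3]),
            "N": int(base_counts[pos, 4]),
            DEL: int(base_counts[pos, 5]),
        }
        profiles.append(
            PositionProfile(
                position=pos,
                counts=counts,
                insertions=ins_maps[pos],
                depth=int(base_counts[pos].sum()),
            )
        )
    return profiles


def call_variants(
    profiles: Sequence[PositionProfile],
    reference: Reference,
    min_alt_fraction: float = 0.10,
    min_alt_count: int = 5,
    hom_fraction: float = 0.90,
) -> list[VariantCall]:
    """Threshold-based variant calls from pileup profiles.

    Runs of adjacent deletion-qualifying columns are merged into a single
    deletion call (supported by the minimum per-column deletion count).
    Zero-depth positions are skipped.
    """
    calls: list[VariantCall] = []
    ref_seq = reference.sequence

    def passes(count: int, depth: int) -> bool:
        return depth > 0 and count >= min_alt_count and count / depth >= min_alt_fraction

    # substitutions and insertions, position by position
    for prof in profiles:
        if prof.depth == 0:
            continue
        pos = prof.position
        ref_base = ref_seq[pos]
        for base in "ACGT":
            if base == ref_base:
                continue
            c = prof.counts[base]
            if passes(c, prof.depth):
                frac = c / prof.depth
                zyg = (
                    "homozygous-alt"
                    if frac >= hom_fraction
                    else "heterozygous"
                )
                calls.append(
                    VariantCall(
                        position=pos,
                        ref=ref_base,
                        alt=base,
                        type="substitution",
                        length=1,
                        alt_count=c,
                        depth=prof.depth,
                        alt_fraction=frac,
                        zygosity=zyg,
                    )
                )
        for ins_seq, c in sorted(prof.insertions.items()):
            if passes(c, prof.depth):
                frac = c / prof.depth
                calls.append(
                    VariantCall(
                        position=pos,
                        ref="",
                        alt=ins_seq,
                        type="insertion",
                        length=len(ins_seq),
                        alt_count=c,
                        depth=prof.depth,
                        alt_fraction=frac,
                        zygosity="homozygous-alt" if frac >= hom_fraction else "heterozygous",
                    )
                )

    # deletions: qualifying columns merged by adjacency
    del_cols = [
        p for p in profiles if p.depth > 0 and passes(p.counts[DEL], p.depth)
    ]
    run: list[PositionProfile] = []
    for prof in del_cols + [None]:  # type: ignore[list-item]
        if run and (prof is None or prof.position != run[-1].position + 1):
            start = run[0].position
            length = len(run)
            count = min(p.counts[DEL] for p in run)
            depth = max(p.depth for p in run)
            frac = count / depth
            calls.append(
                VariantCall(
                    position=start,
                    ref=ref_seq[start : start + length],
                    alt="",
                    type="deletion",
                    length=length,
                    alt_count=count,
                    depth=depth,
                    alt_fraction=frac,
                    zygosity="homozygous-alt" if frac >= hom_fraction else "heterozygous",
                )
            )
            run = []
        if prof is not None:
            run.append(prof)

    calls.sort(key=lambda c: (c.position, c.type, c.alt))
    return calls


def identify_causative(
    calls: Sequence[VariantCall],
    sample: str = "sample",
    min_fraction: float = 0.80,
) -> MutationReport:
    """The sample-defining mutation: any call with alt fraction >= 0.80.

    A single qualifying call is classified by its type and length; several
    qualifying calls within 10 nt of each other, or of mixed type, are a
    complex change. Several well-separated same-type calls are reported by
    the strongest one.
    """
    causative = [c for c in calls if c.alt_fraction >= min_fraction]
    if not causative:
        return MutationReport(sample, None, "none", 0.0)
    if len(causative) > 1:
        positions = sorted(c.position for c in causative)
        clustered = any(b - a <= 10 for a, b in zip(positions, positions[1:]))
        mixed = len({c.type for c in causative}) > 1
        if clustered or mixed:
            top = max(causative, key=lambda c: c.alt_fraction)
            return MutationReport(
                sample, top, "complex", top.alt_fraction, tuple(causative)
            )
    top = max(causative, key=lambda c: c.alt_fraction)
    if top.type == "substitution":
        klass = "substitution"
    elif top.length == 1:
        klass = "indel-1bp"
    elif top.type == "deletion" and 2 <= top.length <= 5:
        klass = "deletion-2-5bp"
    elif top.type == "deletion":
        klass = "large-deletion"
    else:
        klass = "complex"  # multi-nt insertion
    return MutationReport(sample, top, klass, top.alt_fraction, tuple(causative))


def error_landscape(
    samples: Sequence[tuple[Sequence[AlignedRead], MutationReport]],
    reference: Reference,
    threshold: float = 0.01,
) -> ErrorLandscape:
    """Pooled per-position base-substitution error frequencies.

    Each sample's reads are excluded at that sample's own causative
    position(s) (per-sample exclusion, not global masking), so causative
    mutations do not inflate the error estimate. Frequency at a position is
    (non-reference base calls) / (aligned bases), pooled over samples.
    """
    if not samples:
        raise ValueError("error landscape requires at least one sample")
    m = len(reference)
    mismatch = np.zeros(m, dtype=np.int64)
    depth = np.zeros(m, dtype=np.int64)
    excluded: dict[int, list[str]] = {}
    ref_codes = np.array([_BASE_INDEX[b] for b in reference.sequence])
    for alignments, report in samples:
        profs = pileup(alignments, reference)
        base = np.zeros((m, 5), dtype=np.int64)
        for p in profs:
            for b, idx in _BASE_INDEX.items():
                base[p.position, idx] = p.counts[b]
        aligned = base[:, :4].sum(axis=1)  # N never counts as a substitution call
        sub_mismatch = aligned - np.where(
            ref_codes < 4, base[np.arange(m), np.minimum(ref_codes, 3)], 0
        )
        mask = np.ones(m, dtype=bool)
        for call in report.all_causative or (
            (report.causative,) if report.causative else ()
        ):
            span = range(call.position, call.position + max(1, len(call.ref) or 1))
            for pos in span:
                if 0 <= pos < m:
                    mask[pos] = False
                    excluded.setdefault(pos, []).append(report.sample)
        mismatch[mask] += sub_mismatch[mask]
        depth[mask] += aligned[mask]
    freq = np.divide(
        mismatch, depth, out=np.zeros(m, dtype=float), where=depth > 0
    )
    covered = depth > 0
    mean_freq = float(freq[covered].mean()) if covered.any() else 0.0
    return ErrorLandscape(
        frequencies=freq,
        depths=depth,
        excluded=excluded,
        mean_frequency=mean_freq,
        zero_error_positions=int(((freq == 0) & covered).sum()),
        high_error_positions=[int(i) for i in np.flatnonzero(freq > threshold)],
        threshold=threshold,
    )


def compare_landscapes(
    a: ErrorLandscape, b: ErrorLandscape
) -> tuple[list[tuple[int, float, float]], float]:
    """Paired per-position frequencies of two landscapes and their Pearson r.

    Only positions covered in both landscapes enter the comparison; the
    correlation is the reproducibility check between independent libraries.
    """
    if len(a.frequencies) != len(b.frequencies):
        raise ValueError("landscapes cover references of different lengths")
    both = (a.depths > 0) & (b.depths > 0)
    if not both.any():
        raise ValueError("landscapes share no covered positions")
    table = [
        (int(i), float(a.frequencies[i]), float(b.frequencies[i]))
        for i in np.flatnonzero(both)
    ]
    fa, fb = a.frequencies[both], b.frequencies[both]
    if fa.std() == 0 or fb.std() == 0:
        corr = 1.0 if np.allclose(fa, fb) else 0.0
    else:
        corr = float(np.corrcoef(fa, fb)[0, 1])
    return table, corr
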