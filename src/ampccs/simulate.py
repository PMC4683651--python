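"""Synthetic CCS data generator: the sequencing instrument stand-in.

Simulates amplicon templates (reference plus planted edits), error-laden
single-pass subreads, and multi-pass two-strand consensus reads, with
barcodes attached for demultiplexing. The single-pass error model reflects
the raw-polymerase-read regime of circular single-molecule sequencing: a
per-base error probability of 10-15% dominated (>90%) by 1-nt indels, the
remainder uniform substitutions. Consensus building requires at least three
complete passes covering both strands (two of one strand, one of the
complement); fewer passes yield poor consensus quality and are rejected.

The generator also offers a residual-error mode that emits consensus-level
reads directly, with a small substitution-only noise rate, for scenarios
where the multi-pass machinery itself is not under study.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._dna import revcomp
from .align import ScoringScheme, _semiglobal_dp
from .io import Barcode, ReadRecord, Reference, write_fastq

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}

# Scoring used when aligning subreads to the consensus draft: single-pass
# errors are overwhelmingly 1-nt indels, so a 1-nt gap (cost 3) must be
# preferred over a mismatch (cost 5), otherwise draft indel errors get
# absorbed as mismatch runs and the column votes misregister.
CCS_VOTE_SCHEME = ScoringScheme(match=2, mismatch=-5, gap_open=-3, gap_extend=-3)


@dataclass(frozen=True)
class ErrorModel:
    """Single-pass error statistics of the simulated polymerase.

    ``homopolymer_indel_multiplier`` optionally inflates the per-base indel
    probability inside homopolymer runs of length >= 4 (off at 1.0);
    real instruments err preferentially next to long mononucleotide runs.
    """

    single_pass_rate: float = 0.12
    indel_fraction: float = 0.92
    insertion_vs_deletion: float = 0.5
    homopolymer_indel_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.single_pass_rate < 1.0):
            raise ValueError("single_pass_rate must be in [0, 1)")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ValueError("indel_fraction must be in [0, 1]")
        if not (0.0 <= self.insertion_vs_deletion <= 1.0):
            raise ValueError("insertion_vs_deletion must be in [0, 1]")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")


def homopolymer_mask(seq: str, min_run: int = 4) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs of >= min_run."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


@dataclass(frozen=True)
class CcsPolicy:
    """Minimum-pass requirements for building a consensus read."""

    min_passes: int = 3
    min_per_strand: bool = True  # >=2 passes of one strand and >=1 of the other

    def __post_init__(self) -> None:
        if self.min_passes < 2:
            raise ValueError("min_passes must be at least 2")


@dataclass(frozen=True)
class Edit:
    """One planted template edit.

    ``position`` is a 0-based reference offset; ``ref_len`` reference bases
    starting there are replaced by ``alt`` (substitution: ref_len 1 and a
    1-nt alt; insertion: ref_len 0, alt inserted *before* position;
    deletion: alt empty; complex: anything else).
    """

    position: int
    ref_len: int
    alt: str

    def __post_init__(self) -> None:
        if self.position < 0 or self.ref_len < 0:
            raise ValueError("edit position and ref_len must be non-negative")
        if self.ref_len == 0 and not self.alt:
            raise ValueError("empty edit")

    @property
    def kind(self) -> str:
        if self.ref_len == 1 and len(self.alt) == 1:
            return "substitution"
        if self.ref_len == 0:
            return "insertion"
        if not self.alt:
            return "deletion"
        return "complex"


@dataclass(frozen=True)
class TemplateSpec:
    """A template drawn from a reference plus edits, with a mixture weight."""

    reference: Reference
    edits: tuple[Edit, ...] = ()
    abundance: float = 1.0
    label: str = "template"

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


def apply_edits(reference: Reference, edits: Sequence[Edit]) -> str:
    """Apply sorted, non-overlapping edits to a reference sequence."""
    ordered = sorted(edits, key=lambda e: (e.position, e.ref_len))
    for a, b in zip(ordered, ordered[1:]):
        if a.position + a.ref_len > b.position:
            raise ValueError(
                f"overlapping edits at positions {a.position} and {b.position}"
            )
        if a.ref_len == 0 and b.ref_len == 0 and a.position == b.position:
            raise ValueError(f"two insertions anchored at position {a.position}")
    seq = reference.sequence
    if ordered and ordered[-1].position + ordered[-1].ref_len > len(seq):
        raise ValueError("edit extends past the reference end")
    out = []
    cursor = 0
    for e in ordered:
        out.append(seq[cursor : e.position])
        out.append(e.alt)
        cursor = e.position + e.ref_len
    out.append(seq[cursor:])
    return "".join(out)


def simulate_subread(
    template: str,
    model: ErrorModel,
    strand: str = "+",
    rng: Optional[np.random.Generator] = None,
    return_errors: bool = False,
):
    """One error-laden single pass over a template.

    Each template base is independently hit with probability
    ``single_pass_rate``; a hit is a 1-nt indel with probability
    ``indel_fraction`` (insertion of a random base before the position, or
    deletion of it, split by ``insertion_vs_deletion``), otherwise a
    substitution to a uniformly chosen other base. '-' strand output is the
    reverse complement of the error-laden copy.

    With ``return_errors`` the planted errors are returned alongside as
    (template_position, kind) tuples — the calibration oracle interface.
    """
    if not template:
        raise ValueError("cannot simulate a subread from an empty template")
    rng = np.random.default_rng() if rng is None else rng
    n = len(template)
    r_sub = model.single_pass_rate * (1.0 - model.indel_fraction)
    r_indel = np.full(n, model.single_pass_rate * model.indel_fraction)
    if model.homopolymer_indel_multiplier > 1.0:
        r_indel[homopolymer_mask(template)] *= model.homopolymer_indel_multiplier
        np.clip(r_indel, 0.0, 1.0 - r_sub, out=r_indel)
    hit_rate = r_sub + r_indel
    hits = np.flatnonzero(rng.random(n) < hit_rate)
    indel_prob = np.divide(
        r_indel[hits], hit_rate[hits], out=np.zeros(hits.size), where=hit_rate[hits] > 0
    )
    is_indel = rng.random(hits.size) < indel_prob
    is_insertion = rng.random(hits.size) < model.insertion_vs_deletion
    base_choice = rng.integers(0, 3, size=hits.size)
    insert_choice = rng.integers(0, 4, size=hits.size)

    pieces: list[str] = []
    errors: list[tuple[int, str]] = []
    cursor = 0
    for idx, pos in enumerate(hits):
        pieces.append(template[cursor:pos])
        if is_indel[idx]:
            if is_insertion[idx]:
                pieces.append(_BASES[insert_choice[idx]] + template[pos])
                errors.append((int(pos), "ins"))
            else:
                errors.append((int(pos), "del"))
        else:
            pieces.append(_OTHER[template[pos]][base_choice[idx]]
                          if template[pos] in _OTHER else template[pos])
            errors.append((int(pos), "sub"))
        cursor = pos + 1
    pieces.append(template[cursor:])
    seq = "".join(pieces)
    if strand == "-":
        seq = revcomp(seq)
    return (seq, errors) if return_errors else seq


def _vote_round(seqs: Sequence[str], draft: str, scheme: ScoringScheme) -> str:
    """Align every subread to the draft and resolve each column by majority.

    Ties keep the draft base; a strict gap majority drops the column; an
    insertion carried by a strict majority of subreads is emitted (most
    common inserted sequence, ties lexicographic).
    """
    n, m = len(seqs), len(draft)
    votes = np.full((n, m), 255, dtype=np.uint8)  # 0-4 base codes, 5 gap
    code = {b: i for i, b in enumerate("ACGTN")}
    insertions: dict[int, list[str]] = defaultdict(list)
    for row, seq in enumerate(seqs):
        _, start, cigar, _ = _semiglobal_dp(seq, draft, scheme)
        ref_pos, read_pos = start, 0
        for op, ln in cigar:
            if op in "=X":
                for k in range(ln):
                    votes[row, ref_pos + k] = code[seq[read_pos + k]]
                ref_pos += ln
                read_pos += ln
            elif op == "D":
                votes[row, ref_pos : ref_pos + ln] = 5
                ref_pos += ln
            else:  # I
                insertions[ref_pos].append(seq[read_pos : read_pos + ln])
                read_pos += ln

    out: list[str] = []
    bases = "ACGTN"
    for j in range(m + 1):
        shared = insertions.get(j)
        if shared and len(shared) > n / 2:
            counts = Counter(shared)
            top = max(counts.values())
            out.append(sorted(s for s, c in counts.items() if c == top)[0])
        if j == m:
            break
        col = votes[:, j]
        col = col[col != 255]
        if col.size == 0:
            out.append(draft[j])
            continue
        counts = np.bincount(col, minlength=6)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1 and winners[0] == 5:
            continue  # strict gap majority: column dropped
        if winners.size > 1 or winners[0] == code[draft[j]]:
            out.append(draft[j])  # ties keep the draft base
        else:
            out.append(bases[winners[0]])
    return "".join(out)


def build_ccs(
    subreads: Sequence[tuple[str, str]],
    policy: CcsPolicy = CcsPolicy(),
    read_id: str = "ccs",
    scheme: ScoringScheme = CCS_VOTE_SCHEME,
    rounds: int = 3,
) -> Optional[ReadRecord]:
    """Build a consensus read from strand-tagged subreads, or reject.

    Rejection (None) occurs when there are fewer than ``min_passes``
    subreads or the strand mix lacks two passes of one strand plus one of
    the complement. Otherwise all subreads are oriented to '+', the
    median-length subread serves as the initial draft, and the consensus
    is refined over ``rounds`` align-and-vote iterations (see
    :func:`_vote_round`): realigning against the polished draft fixes the
    indel mis-registration that a single vote against an error-laden draft
    leaves behind. Iteration stops early once the draft is stable.
    """
    if not subreads:
        raise ValueError("no subreads given")
    n = len(subreads)
    if n < policy.min_passes:
        return None
    plus = sum(1 for _, s in subreads if s == "+")
    minus = n - plus
    if policy.min_per_strand and (min(plus, minus) < 1 or max(plus, minus) < 2):
        return None

    seqs = [seq if s == "+" else revcomp(seq) for seq, s in subreads]
    order = sorted(range(n), key=lambda i: (len(seqs[i]), i))
    draft = seqs[order[len(order) // 2]]
    for _ in range(rounds):
        polished = _vote_round(seqs, draft, scheme)
        if polished == draft:
            break
        draft = polished
    return ReadRecord(id=read_id, sequence=draft, passes=n)


def mutate_substitutions(
    seq: str, rate: "float | np.ndarray", rng: np.random.Generator
) -> str:
    """Apply independent per-base substitutions (residual CCS noise).

    ``rate`` is a scalar or a per-position array of length ``len(seq)``.
    """
    if np.isscalar(rate) and rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    choice = rng.integers(0, 3, size=hits.size)
    chars = list(seq)
    for idx, pos in enumerate(hits):
        if chars[pos] in _OTHER:
            chars[pos] = _OTHER[chars[pos]][choice[idx]]
    return "".join(chars)


def simulate_ccs_reads(
    template: str,
    n_reads: int,
    substitution_rate: float,
    rng: np.random.Generator,
    id_prefix: str = "read",
    passes: int = 5,
) -> list[ReadRecord]:
    """Consensus-level reads with substitution-only residual noise."""
    return [
        ReadRecord(
            id=f"{id_prefix}_{i}",
            sequence=mutate_substitutions(template, substitution_rate, rng),
            passes=passes,
        )
        for i in range(n_reads)
    ]


def random_reference(
    length: int, rng: np.random.Generator, name: str = "synthetic_ref"
) -> Reference:
    """A uniformly random synthetic amplicon reference."""
    seq = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])
    return Reference(name=name, sequence=seq)


def random_barcodes(
    n_forward: int,
    n_reverse: int,
    rng: np.random.Generator,
    min_distance: int = 8,
) -> tuple[list[Barcode], list[Barcode]]:
    """Synthetic 16-nt barcode sets with enforced pairwise Hamming distance.

    The distance floor (between all barcodes and their reverse complements,
    across both roles) keeps the 12-of-16 assignment rule unambiguous.
    """
    accepted: list[str] = []

    def far_enough(cand: str) -> bool:
        for prev in accepted:
            for other in (prev, revcomp(prev)):
                if sum(a != b for a, b in zip(cand, other)) < min_distance:
                    return False
        return True

    attempts = 0
    while len(accepted) < n_forward + n_reverse:
        cand = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=16)])
        if far_enough(cand):
            accepted.append(cand)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not generate a distant-enough barcode set")
    forwards = [
        Barcode(id=f"F{i + 1}", sequence=accepted[i], role="forward")
        for i in range(n_forward)
    ]
    reverses = [
        Barcode(id=f"R{i + 1}", sequence=accepted[n_forward + i], role="reverse")
        for i in range(n_reverse)
    ]
    return forwards, reverses


@dataclass(frozen=True)
class SampleSpec:
    """One barcoded sample: a template mixture and a read budget."""

    name: str
    forward_id: str
    reverse_id: str
    templates: tuple[TemplateSpec, ...]
    n_reads: int

    @property
    def pair_key(self) -> str:
        return f"{self.forward_id}{self.reverse_id}"


def simulate_run(
    samples: Sequence[SampleSpec],
    barcodes: Mapping[str, Barcode],
    seed: int,
    mode: str = "ccs",
    residual_substitution_rate: float = 0.002,
    model: ErrorModel = ErrorModel(),
    policy: CcsPolicy = CcsPolicy(),
    pass_range: tuple[int, int] = (3, 8),
) -> tuple[list[ReadRecord], list[dict]]:
    """Simulate a barcoded sequencing run.

    Reads are drawn from each sample's templates proportionally to
    abundance, decorated with the sample's forward barcode at the 5' end
    and the reverse-complemented reverse barcode at the 3' end, and emitted
    in a random orientation. ``mode`` is either "ccs" (consensus-level reads
    with ``residual_substitution_rate`` noise) or "subread" (full multi-pass
    simulation through :func:`build_ccs`; pass counts uniform over
    ``pass_range``, strands alternating from a random start).

    Returns (reads, truth rows); each truth row records the read's sample,
    pair key, template label, orientation, and pass count — the oracle
    interface for every downstream test.
    """
    if mode not in ("ccs", "subread"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    truth: list[dict] = []
    for sample in samples:
        for key in (sample.forward_id, sample.reverse_id):
            if key not in barcodes:
                raise ValueError(f"unknown barcode id {key!r}")
        fwd = barcodes[sample.forward_id].sequence
        rev_rc = revcomp(barcodes[sample.reverse_id].sequence)
        weights = np.array([t.abundance for t in sample.templates], dtype=float)
        if weights.sum() <= 0:
            raise ValueError(f"sample {sample.name!r}: abundances sum to zero")
        weights /= weights.sum()
        tmpl_seqs = [apply_edits(t.reference, t.edits) for t in sample.templates]
        # exact largest-remainder allocation: abundances 73:17 over 90 reads
        # give exactly 73 and 17, not a multinomial draw
        ideal = weights * sample.n_reads
        counts = np.floor(ideal).astype(int)
        remainder = sample.n_reads - counts.sum()
        if remainder > 0:
            order = np.argsort(-(ideal - counts), kind="stable")
            counts[order[:remainder]] += 1
        assignment = np.repeat(np.arange(len(tmpl_seqs)), counts)
        rng.shuffle(assignment)
        for i in range(sample.n_reads):
            t_idx = int(assignment[i])
            template = tmpl_seqs[t_idx]
            if mode == "ccs":
                insert = mutate_substitutions(
                    template, residual_substitution_rate, rng
                )
                passes = int(rng.integers(pass_range[0], pass_range[1] + 1))
            else:
                ccs = None
                while ccs is None:
                    n_passes = int(rng.integers(pass_range[0], pass_range[1] + 1))
                    first = "+" if rng.random() < 0.5 else "-"
                    strands = [
                        first if k % 2 == 0 else ("-" if first == "+" else "+")
                        for k in range(n_passes)
                    ]
                    subreads = [
                        (simulate_subread(template, model, s, rng), s)
                        for s in strands
                    ]
                    ccs = build_ccs(subreads, policy)
                insert = ccs.sequence
                passes = ccs.passes
            full = fwd + insert + rev_rc
            orientation = "as-is" if rng.random() < 0.5 else "reverse-complement"
            if orientation == "reverse-complement":
                full = revcomp(full)
            read_id = f"{sample.name}_{i}"
            reads.append(ReadRecord(id=read_id, sequence=full, passes=passes))
            truth.append(
                {
                    "read_id": read_id,
                    "sample": sample.name,
                    "pair_key": sample.pair_key,
                    "template": sample.templates[t_idx].label,
                    "orientation": orientation,
                    "passes": passes,
                }
            )
    return reads, truth


def write_truth_tsv(truth: Iterable[dict], path: str | Path) -> None:
    truth = list(truth)
    columns = ["read_id", "sample", "pair_key", "template", "orientation", "passes"]
    with open(path, "w") as out:
        out.write("\t".join(columns) + "\n")
        for row in truth:
            out.write("\t".join(str(row[c]) for c in columns) + "\n")


def write_run(
    reads: Sequence[ReadRecord],
    truth: Sequence[dict],
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write a simulated run as ``<prefix>.fastq`` + ``<prefix>.truth.tsv``."""
    prefix = Path(prefix)
    fastq = prefix.with_suffix(".fastq")
    truth_path = prefix.with_suffix(".truth.tsv")
    write_fastq(reads, fastq)
    write_truth_tsv(truth, truth_path)
    return fastq, truth_path
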