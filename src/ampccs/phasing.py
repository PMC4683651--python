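"""Read-level SNP phasing over an amplicon-wide SNP panel.

Because every CCS read spans the whole amplicon, the haplotype of each
molecule is read off directly: the allele vector over the panel sites.
Reads are grouped by identical vectors, low-support groups are set aside as
noise, the space of possible haplotypes is the Cartesian product over the
heterozygous sites (2^k vectors for k het sites), and minority haplotypes
are tested for a single-crossover relationship to the two most abundant
(parental) haplotypes.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignedRead
from .io import MISSING, SnpPanel


@dataclass
class HaplotypeCall:
    """A group of reads sharing one allele vector."""

    vector: tuple[str, ...]
    read_ids: tuple[str, ...]
    count: int

    @property
    def name(self) -> str:
        return "-".join(self.vector)


@dataclass
class GroupingResult:
    groups: list[HaplotypeCall]  # passing filters, count desc then lexicographic
    noise: list[HaplotypeCall]  # below min_count or min_fraction
    n_dropped_missing: int
    n_input: int


@dataclass
class CrossoverResult:
    parent1: tuple[str, ...]
    parent2: tuple[str, ...]
    recombinant: HaplotypeCall
    switch_count: int
    # (left, right) 1-based panel-site indices flanking the exchange,
    # None unless switch_count == 1
    breakpoint: Optional[tuple[int, int]]
    unexplained_sites: tuple[int, ...]  # 0-based panel indices matching neither parent
    reciprocal_with: Optional[tuple[str, ...]] = None


def extract_haplotype(alignment: AlignedRead, panel: SnpPanel) -> tuple[str, ...]:
    """The read's allele vector over the panel.

    Sites covered by a match/mismatch column give the read base; deleted or
    uncovered sites give MISSING. Insertions adjacent to a site do not
    alter the site's call.
    """
    wanted = {site.position: i for i, site in enumerate(panel)}
    vector = [MISSING] * len(panel)
    for ref_pos, read_pos, op in alignment.reference_columns():
        if op == "I":
            continue
        idx = wanted.get(ref_pos)
        if idx is None:
            continue
        vector[idx] = MISSING if op == "D" else alignment.sequence[read_pos]
    return tuple(vector)


def group_haplotypes(
    vectors: Sequence[tuple[str, ...]],
    read_ids: Optional[Sequence[str]] = None,
    min_count: int = 3,
    min_fraction: float = 0.02,
    drop_missing: bool = True,
) -> GroupingResult:
    """Group identical allele vectors and filter low-support groups.

    Reads with a MISSING site are dropped first (when ``drop_missing``);
    groups failing the count or fraction floor are reported as noise, not
    discarded. Group order is count-descending, ties lexicographic.
    """
    if not vectors:
        raise ValueError("no allele vectors to group")
    if read_ids is None:
        read_ids = [f"read_{i}" for i in range(len(vectors))]
    if len(read_ids) != len(vectors):
        raise ValueError("read_ids and vectors differ in length")

    kept: dict[tuple[str, ...], list[str]] = defaultdict(list)
    n_dropped = 0
    for vec, rid in zip(vectors, read_ids):
        if drop_missing and MISSING in vec:
            n_dropped += 1
            continue
        kept[tuple(vec)].append(rid)
    if not kept:
        raise ValueError(
            f"all {len(vectors)} reads were dropped for missing panel sites"
        )
    n_grouped = sum(len(v) for v in kept.values())
    calls = [
        HaplotypeCall(vector=vec, read_ids=tuple(rids), count=len(rids))
        for vec, rids in kept.items()
    ]
    calls.sort(key=lambda c: (-c.count, c.vector))
    groups = [
        c for c in calls if c.count >= min_count and c.count / n_grouped >= min_fraction
    ]
    noise = [c for c in calls if c not in groups]
    return GroupingResult(
        groups=groups,
        noise=noise,
        n_dropped_missing=n_dropped,
        n_input=len(vectors),
    )


def enumerate_possible(
    alleles_per_site: Sequence[Sequence[str]],
) -> tuple[int, list[tuple[str, ...]]]:
    """All haplotypes compatible with per-site zygosity.

    Each entry lists the alleles present at that site (one for a homozygous
    site, two for a heterozygous one). The count is the product of the
    per-site allele counts — 2^k for k heterozygous biallelic sites.
    """
    for i, alleles in enumerate(alleles_per_site):
        if len(alleles) == 0:
            raise ValueError(f"site {i} has no alleles")
    vectors = [tuple(v) for v in itertools.product(*alleles_per_site)]
    return len(vectors), vectors


def infer_crossover(groups: Sequence[HaplotypeCall]) -> list[CrossoverResult]:
    """Relate minority haplotypes to the two parental (most abundant) ones.

    At each site where the parents differ (the informative, heterozygous
    sites), the minority allele is assigned to parent 1 or parent 2; a
    single switch along panel order marks a simple crossover, and its
    breakpoint is reported as the interval between the flanking informative
    sites (1-based panel indices) — the data cannot localize it further.
    Two minority haplotypes with mirrored assignments and the same
    breakpoint are flagged as a reciprocal pair.
    """
    if len(groups) < 2:
        raise ValueError("crossover inference requires at least two haplotype groups")
    ordered = sorted(groups, key=lambda g: (-g.count, g.vector))
    p1, p2 = ordered[0].vector, ordered[1].vector
    het_sites = [i for i in range(len(p1)) if p1[i] != p2[i]]
    results: list[CrossoverResult] = []
    for minority in ordered[2:]:
        vec = minority.vector
        assignment: list[Optional[int]] = []
        unexplained: list[int] = []
        for i in het_sites:
            if vec[i] == p1[i]:
                assignment.append(1)
            elif vec[i] == p2[i]:
                assignment.append(2)
            else:
                assignment.append(None)
                unexplained.append(i)
        informative = [
            (site, a) for site, a in zip(het_sites, assignment) if a is not None
        ]
        switches = sum(
            1
            for (_, a), (_, b) in zip(informative, informative[1:])
            if a != b
        )
        breakpoint = None
        if switches == 1 and not unexplained:
            for (s_left, a), (s_right, b) in zip(informative, informative[1:]):
                if a != b:
                    breakpoint = (s_left + 1, s_right + 1)
                    break
        results.append(
            CrossoverResult(
                parent1=p1,
                parent2=p2,
                recombinant=minority,
                switch_count=switches,
                breakpoint=breakpoint,
                unexplained_sites=tuple(unexplained),
            )
        )
    # reciprocal pairing: mirrored assignments, same breakpoint
    for i, r in enumerate(results):
        if r.breakpoint is None:
            continue
        for other in results[i + 1 :]:
            if other.breakpoint != r.breakpoint or other.reciprocal_with:
                continue
            mirrored = all(
                (r.recombinant.vector[s], other.recombinant.vector[s])
                in ((p1[s], p2[s]), (p2[s], p1[s]))
                for s in het_sites
            )
            if mirrored:
                r.reciprocal_with = other.recombinant.vector
                other.reciprocal_with = r.recombinant.vector
                break
    return results
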