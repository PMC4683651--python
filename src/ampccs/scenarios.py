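"""Benchmark scenarios: DLBCL amplicon allele tables and their simulations.

The DLBCL (diffuse large B-cell lymphoma) benchmark consists of published
per-site allele tallies for a MYD88 exon 5 amplicon (four SNP sites,
reference alleles t-g-a-t) and an EZH2 exon 16 amplicon (five SNP sites,
reference a-a-a-g-a) across eleven tumor and cell-line samples, plus the
haplotype groupings observed in the corresponding CCS reads. The reference
sequences used here are synthetic 2-kb stand-ins with the SNP sites planted
at fixed offsets: the real amplicon context does not affect site-level
tallies, phasing, or crossover structure, which is what these scenarios
exercise.

Site labels follow the exon-relative convention of the source tables
("19" = position 19 of the exon, "+58" = 58 nt downstream of the exon).
"""

from __future__ import annotations

import numpy as np

from ._dna import revcomp
from .io import Barcode, ReadRecord, Reference, SnpPanel, SnpSite
from .simulate import mutate_substitutions, random_barcodes, random_reference

# MYD88 exon 5 amplicon: per-sample allele tallies at the four SNP sites.
# Each cell maps observed base -> read count; the first base listed in
# MYD88_REF_ALLELES is the reference allele at that site.
MYD88_SITE_LABELS = ("19", "+58", "+1245", "+1524")
MYD88_REF_ALLELES = ("T", "G", "A", "T")
MYD88_TABLE: dict[str, tuple[dict[str, int], ...]] = {
    "DLBCL773": ({"T": 8, "C": 65}, {"G": 73}, {"A": 3, "G": 70}, {"T": 73}),
    "DLBCL778": ({"T": 17, "C": 73}, {"G": 90}, {"A": 90}, {"T": 90}),
    "DLBCL799": ({"T": 26, "C": 29}, {"G": 37, "T": 18}, {"A": 55}, {"T": 55}),
    "DLBCL816": ({"T": 88, "C": 19}, {"G": 107}, {"A": 53, "G": 54}, {"T": 107}),
    "DLBCL894": ({"T": 165, "C": 50}, {"G": 215}, {"A": 315}, {"T": 315}),
    "DLBCL832": ({"T": 75}, {"G": 75}, {"A": 75}, {"T": 75}),
    "Ly3": ({"C": 79}, {"G": 79}, {"G": 79}, {"T": 63, "A": 16}),
    "Ly10": ({"T": 16, "C": 28}, {"G": 44}, {"A": 16, "G": 28}, {"T": 44}),
    "SKI": ({"T": 310}, {"G": 310}, {"A": 151, "G": 159}, {"T": 310}),
    "Karpas422": ({"T": 11}, {"G": 11}, {"A": 11}, {"T": 11}),
    "Ly1": ({"T": 121}, {"G": 121}, {"A": 121}, {"T": 121}),
}

# EZH2 exon 16 amplicon, sample DLBCL799: four observed haplotypes over the
# five SNP sites (reference alleles a-a-a-g-a), with read counts. The two
# minority haplotypes are reciprocal single-crossover products of the two
# majority ones, exchanging between the 3rd and 5th polymorphic positions.
EZH2_REF_ALLELES = ("A", "A", "A", "G", "A")
EZH2_DLBCL799_HAPLOTYPES: dict[tuple[str, ...], int] = {
    ("G", "A", "G", "G", "G"): 41,
    ("A", "A", "A", "G", "A"): 57,
    ("A", "A", "A", "G", "G"): 11,
    ("G", "A", "G", "G", "A"): 12,
}

# MYD88 exon 5 haplotype groupings (reads per haplotype vector)
MYD88_DLBCL778_HAPLOTYPES: dict[tuple[str, ...], int] = {
    ("C", "G", "A", "T"): 73,
    ("T", "G", "A", "T"): 17,
}
MYD88_LY10_HAPLOTYPES: dict[tuple[str, ...], int] = {
    ("C", "G", "G", "T"): 28,
    ("T", "G", "A", "T"): 16,
}

_MYD88_POSITIONS = (218, 557, 1444, 1723)  # 0-based offsets in the synthetic amplicon
_EZH2_POSITIONS = (299, 699, 1099, 1499, 1899)


def _plant_sites(ref: Reference, positions, alleles) -> Reference:
    seq = list(ref.sequence)
    for pos, base in zip(positions, alleles):
        seq[pos] = base
    return Reference(name=ref.name, sequence="".join(seq))


def myd88_amplicon(seed: int = 20150) -> tuple[Reference, SnpPanel]:
    """Synthetic MYD88-exon-5-like 2-kb amplicon with its 4-site SNP panel."""
    rng = np.random.default_rng(seed)
    ref = _plant_sites(
        random_reference(2000, rng, name="MYD88_exon5_synthetic"),
        _MYD88_POSITIONS,
        MYD88_REF_ALLELES,
    )
    alt_map = {"19": ("C",), "+58": ("T",), "+1245": ("G",), "+1524": ("A",)}
    panel = SnpPanel(
        sites=tuple(
            SnpSite(label=lab, position=pos, ref=refb, alts=alt_map[lab])
            for lab, pos, refb in zip(
                MYD88_SITE_LABELS, _MYD88_POSITIONS, MYD88_REF_ALLELES
            )
        )
    )
    return ref, panel


def ezh2_amplicon(seed: int = 20151) -> tuple[Reference, SnpPanel]:
    """Synthetic EZH2-exon-16-like 2-kb amplicon with its 5-site SNP panel."""
    rng = np.random.default_rng(seed)
    ref = _plant_sites(
        random_reference(2000, rng, name="EZH2_exon16_synthetic"),
        _EZH2_POSITIONS,
        EZH2_REF_ALLELES,
    )
    panel = SnpPanel(
        sites=tuple(
            SnpSite(
                label=str(i + 1),
                position=pos,
                ref=refb,
                alts=("G",) if refb != "G" else ("A",),
            )
            for i, (pos, refb) in enumerate(zip(_EZH2_POSITIONS, EZH2_REF_ALLELES))
        )
    )
    return ref, panel


def haplotype_template(
    reference: Reference, panel: SnpPanel, vector: tuple[str, ...]
) -> str:
    """Template sequence carrying the given allele at each panel site."""
    seq = list(reference.sequence)
    for site, allele in zip(panel, vector):
        seq[site.position] = allele
    return "".join(seq)


def simulate_haplotype_reads(
    reference: Reference,
    panel: SnpPanel,
    haplotype_counts: dict[tuple[str, ...], int],
    residual_substitution_rate: float,
    seed: int,
    barcode_pair: tuple[Barcode, Barcode] | None = None,
    id_prefix: str = "read",
) -> list[ReadRecord]:
    """CCS-level reads from a haplotype mixture with planted exact counts.

    Unlike a proportional draw, the per-haplotype read counts are exact —
    these scenarios reproduce observed datasets whose composition is given,
    not sampled. Residual substitution noise is applied per base; reads are
    optionally barcoded (forward barcode 5', reverse-complemented reverse
    barcode 3') and emitted in random orientation.
    """
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    i = 0
    for vector, count in haplotype_counts.items():
        template = haplotype_template(reference, panel, vector)
        for _ in range(count):
            insert = mutate_substitutions(template, residual_substitution_rate, rng)
            if barcode_pair is not None:
                fwd, rev = barcode_pair
                full = fwd.sequence + insert + revcomp(rev.sequence)
            else:
                full = insert
            if rng.random() < 0.5:
                full = revcomp(full)
            reads.append(ReadRecord(id=f"{id_prefix}_{i}", sequence=full, passes=5))
            i += 1
    return reads


def reads_from_site_tallies(
    reference: Reference,
    panel: SnpPanel,
    tallies: tuple[dict[str, int], ...],
    id_prefix: str = "read",
) -> list[ReadRecord]:
    """Error-free reads whose per-site allele tallies match a table row.

    The table gives marginal counts per site, not haplotypes; alleles are
    assigned to reads site-independently in a fixed order, which preserves
    every marginal tally. Sites with fewer tallied reads than the row
    maximum are left at the reference base for the remainder (tally depths
    can differ between sites in real data).
    """
    depth = max(sum(cell.values()) for cell in tallies)
    seqs = [list(reference.sequence) for _ in range(depth)]
    for site, cell in zip(panel, tallies):
        row = 0
        for base, count in cell.items():
            for _ in range(count):
                seqs[row][site.position] = base
                row += 1
    return [
        ReadRecord(id=f"{id_prefix}_{i}", sequence="".join(s), passes=5)
        for i, s in enumerate(seqs)
    ]


def benchmark_barcodes(seed: int = 20152) -> tuple[list[Barcode], list[Barcode]]:
    """The synthetic F1-F24 / R1-R16 barcode set used by the scenarios."""
    rng = np.random.default_rng(seed)
    return random_barcodes(24, 16, rng)


def run_dlbcl778_phasing(seed: int):
    """Full-pipeline phasing of the simulated DLBCL778 MYD88 read set.

    Simulates the 73:17 C-g-a-t / t-g-a-t haplotype mixture at 0.2%
    residual per-base noise with F1/R1 barcodes, demultiplexes, trims,
    aligns, and groups haplotypes. Returns the GroupingResult.
    """
    from .align import align_semiglobal
    from .demux import demultiplex, enumerate_pairs, trim_assigned
    from .phasing import extract_haplotype, group_haplotypes

    ref, panel = myd88_amplicon()
    forwards, reverses = benchmark_barcodes()
    barcodes = {b.id: b for b in forwards + reverses}
    reads = simulate_haplotype_reads(
        ref,
        panel,
        MYD88_DLBCL778_HAPLOTYPES,
        residual_substitution_rate=0.002,
        seed=seed,
        barcode_pair=(barcodes["F1"], barcodes["R1"]),
        id_prefix="dlbcl778",
    )
    pairs = enumerate_pairs(forwards[:2], reverses[:2])
    bins = demultiplex(reads, pairs, barcodes)
    inserts = [trim_assigned(a) for a in bins["F1R1"]]
    alignments = [align_semiglobal(r, ref) for r in inserts]
    vectors = [extract_haplotype(a, panel) for a in alignments]
    return group_haplotypes(vectors, read_ids=[a.read_id for a in alignments])


def run_dlbcl799_phasing(seed: int):
    """Phasing + crossover inference on the simulated DLBCL799 EZH2 reads.

    Simulates the four printed haplotypes (41/57/11/12) at 0.5% residual
    noise, aligns, groups, and infers crossovers among minority haplotypes.
    Returns (GroupingResult, list of CrossoverResult).
    """
    from .align import align_semiglobal
    from .phasing import extract_haplotype, group_haplotypes, infer_crossover

    ref, panel = ezh2_amplicon()
    reads = simulate_haplotype_reads(
        ref,
        panel,
        EZH2_DLBCL799_HAPLOTYPES,
        residual_substitution_rate=0.005,
        seed=seed,
        id_prefix="dlbcl799",
    )
    alignments = [align_semiglobal(r, ref) for r in reads]
    vectors = [extract_haplotype(a, panel) for a in alignments]
    grouping = group_haplotypes(vectors, read_ids=[a.read_id for a in alignments])
    crossovers = infer_crossover(grouping.groups) if len(grouping.groups) >= 3 else []
    return grouping, crossovers
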