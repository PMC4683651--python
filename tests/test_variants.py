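"""Pileup, variant calling, causative classification, error landscape."""

import numpy as np
import pytest

from ampccs.align import AlignedRead, align_semiglobal
from ampccs.scenarios import (
    MYD88_REF_ALLELES,
    MYD88_TABLE,
    myd88_amplicon,
    reads_from_site_tallies,
)
from ampccs.simulate import mutate_substitutions, random_reference
from ampccs.variants import (
    DEL,
    call_variants,
    compare_landscapes,
    error_landscape,
    identify_causative,
    pileup,
)


def _perfect_alignment(seq, ref, read_id="r"):
    """An alignment asserted to span the whole reference with M columns."""
    assert len(seq) == len(ref)
    return AlignedRead(
        read_id=read_id,
        reference_name=ref.name,
        start=0,
        cigar=(("M", len(seq)),),
        strand="+",
        score=0,
        sequence=seq,
    )


class TestPileup:
    def test_perfect_reads_uniform_depth(self, small_ref):
        alns = [
            _perfect_alignment(small_ref.sequence, small_ref, f"r{i}")
            for i in range(10)
        ]
        profiles = pileup(alns, small_ref)
        assert all(p.depth == 10 for p in profiles)
        assert all(p.counts[small_ref.sequence[p.position]] == 10 for p in profiles)

    def test_two_nt_deletion_counts(self, small_ref):
        read = small_ref.sequence[:90] + small_ref.sequence[92:]
        aln = align_semiglobal(read, small_ref)
        profiles = pileup([aln], small_ref)
        del_cols = [p.position for p in profiles if p.counts[DEL] == 1]
        assert len(del_cols) == 2
        assert del_cols[1] == del_cols[0] + 1

    def test_depth_conservation_fuzz(self, rng):
        # depth always equals the sum of base + DEL tallies, whatever mix of
        # substitutions and indels the reads carry
        ref = random_reference(150, rng)
        from ampccs.simulate import ErrorModel, simulate_subread

        model = ErrorModel(single_pass_rate=0.05)
        reads = [simulate_subread(ref.sequence, model, "+", rng) for _ in range(15)]
        alns = [align_semiglobal(r, ref) for r in reads]
        profiles = pileup(alns, ref)
        for p in profiles:
            assert sum(p.counts.values()) == p.depth

    def test_insertion_anchored_not_counted_in_depth(self, small_ref):
        read = small_ref.sequence[:100] + "TTT" + small_ref.sequence[100:]
        aln = align_semiglobal(read, small_ref)
        profiles = pileup([aln], small_ref)
        anchored = [p for p in profiles if p.insertions]
        assert len(anchored) == 1
        assert list(anchored[0].insertions.values()) == [1]
        assert all(p.depth == 1 for p in profiles)


class TestCallVariants:
    def _profiles_for(self, reads, ref):
        return pileup([_perfect_alignment(r, ref, f"r{i}") for i, r in enumerate(reads)], ref)

    def test_fully_mutant_site_homozygous_alt(self, small_ref):
        # every read carries the alternate base: homozygous-alt
        seq = list(small_ref.sequence)
        pos = 50
        alt = "A" if seq[pos] != "A" else "G"
        seq[pos] = alt
        reads = ["".join(seq)] * 79
        calls = call_variants(self._profiles_for(reads, small_ref), small_ref)
        assert len(calls) == 1
        assert (calls[0].position, calls[0].alt, calls[0].zygosity) == (
            pos, alt, "homozygous-alt",
        )

    def test_minor_allele_heterozygous(self, small_ref):
        # 19 alt / 107 (fraction 0.178): reported, heterozygous
        pos, refbase = 50, small_ref.sequence[50]
        alt = "A" if refbase != "A" else "G"
        mutant = list(small_ref.sequence)
        mutant[pos] = alt
        reads = [small_ref.sequence] * 88 + ["".join(mutant)] * 19
        calls = call_variants(self._profiles_for(reads, small_ref), small_ref)
        assert len(calls) == 1
        assert calls[0].zygosity == "heterozygous"
        assert calls[0].alt_count == 19 and calls[0].depth == 107

    def test_below_threshold_not_called(self, small_ref):
        pos = 50
        alt = "A" if small_ref.sequence[pos] != "A" else "G"
        mutant = list(small_ref.sequence)
        mutant[pos] = alt
        reads = [small_ref.sequence] * 199 + ["".join(mutant)]
        assert call_variants(self._profiles_for(reads, small_ref), small_ref) == []

    def test_deletion_merged_across_columns(self, small_ref):
        read = small_ref.sequence[:80] + small_ref.sequence[83:]
        alns = [align_semiglobal(read, small_ref) for _ in range(10)]
        for i, a in enumerate(alns):
            a.read_id = f"r{i}"
        calls = call_variants(pileup(alns, small_ref), small_ref)
        dels = [c for c in calls if c.type == "deletion"]
        assert len(dels) == 1
        assert dels[0].length == 3
        assert dels[0].alt_count == 10

    def test_insertion_called(self, small_ref):
        read = small_ref.sequence[:100] + "TT" + small_ref.sequence[100:]
        alns = [align_semiglobal(read, small_ref) for _ in range(8)]
        calls = call_variants(pileup(alns, small_ref), small_ref)
        ins = [c for c in calls if c.type == "insertion"]
        assert len(ins) == 1
        assert ins[0].alt == "TT" and ins[0].alt_count == 8


class TestTableZygosity:
    @pytest.mark.parametrize("sample", sorted(MYD88_TABLE))
    def test_tally_reconstruction_reproduces_zygosity(self, sample):
        """Read sets rebuilt from each allele-tally row give back the
        het/hom status the printed counts imply under the calling thresholds."""
        ref, panel = myd88_amplicon()
        tallies = MYD88_TABLE[sample]
        reads = reads_from_site_tallies(ref, panel, tallies)
        alns = [_perfect_alignment(r.sequence, ref, r.id) for r in reads]
        calls = call_variants(pileup(alns, ref), ref)
        by_pos = {c.position: c for c in calls}
        for site, refbase, cell in zip(panel, MYD88_REF_ALLELES, tallies):
            depth = sum(cell.values())
            alt_items = [(b, c) for b, c in cell.items() if b != refbase]
            # closed-form expectation from the tallies and thresholds
            expected = None
            for base, count in alt_items:
                if count >= 5 and count / depth >= 0.10:
                    expected = (
                        "homozygous-alt" if count / depth >= 0.90 else "heterozygous"
                    )
            got = by_pos.get(site.position)
            if expected is None:
                assert got is None
            else:
                assert got is not None and got.zygosity == expected


class TestCausative:
    def _report(self, reads, ref, sample="s"):
        alns = [align_semiglobal(r, ref) for r in reads]
        calls = call_variants(pileup(alns, ref), ref)
        return identify_causative(calls, sample=sample)

    def test_two_bp_deletion_class(self, small_ref):
        read = small_ref.sequence[:120] + small_ref.sequence[122:]
        report = self._report([read] * 10, small_ref)
        assert report.mutation_class == "deletion-2-5bp"
        assert report.causative.length == 2

    def test_forty_bp_deletion_class(self, rng):
        ref = random_reference(400, rng)
        read = ref.sequence[:150] + ref.sequence[190:]
        report = self._report([read] * 10, ref)
        assert report.mutation_class == "large-deletion"
        assert report.causative.length == 40
        assert report.causative.position == 150

    def test_single_substitution_class(self, small_ref):
        seq = list(small_ref.sequence)
        seq[60] = "A" if seq[60] != "A" else "G"
        report = self._report(["".join(seq)] * 10, small_ref)
        assert report.mutation_class == "substitution"

    def test_one_bp_indel_class(self, small_ref):
        read = small_ref.sequence[:77] + small_ref.sequence[78:]
        report = self._report([read] * 10, small_ref)
        assert report.mutation_class == "indel-1bp"

    def test_clustered_changes_are_complex(self, small_ref):
        seq = list(small_ref.sequence)
        for pos in (60, 65):
            seq[pos] = "A" if seq[pos] != "A" else "G"
        report = self._report(["".join(seq)] * 10, small_ref)
        assert report.mutation_class == "complex"
        assert len(report.all_causative) == 2

    def test_no_causative(self, small_ref):
        report = self._report([small_ref.sequence] * 10, small_ref)
        assert report.mutation_class == "none"
        assert report.causative is None


class TestErrorLandscape:
    def test_all_perfect_reads_zero_everywhere(self, small_ref):
        alns = [_perfect_alignment(small_ref.sequence, small_ref, f"r{i}") for i in range(5)]
        report = identify_causative([], sample="s1")
        scape = error_landscape([(alns, report)], small_ref)
        assert scape.mean_frequency == 0.0
        assert scape.zero_error_positions == len(small_ref)

    def test_causative_site_excluded_per_sample(self, small_ref):
        # the mutant sample's reads must not contribute at its own causative
        # position, so the pooled frequency there stays zero
        pos = 50
        alt = "A" if small_ref.sequence[pos] != "A" else "G"
        mutant = list(small_ref.sequence)
        mutant[pos] = alt
        mut_alns = [
            _perfect_alignment("".join(mutant), small_ref, f"m{i}") for i in range(10)
        ]
        wt_alns = [
            _perfect_alignment(small_ref.sequence, small_ref, f"w{i}") for i in range(10)
        ]
        mut_calls = call_variants(pileup(mut_alns, small_ref), small_ref)
        mut_report = identify_causative(mut_calls, sample="mut")
        wt_report = identify_causative([], sample="wt")
        scape = error_landscape(
            [(mut_alns, mut_report), (wt_alns, wt_report)], small_ref
        )
        assert scape.frequencies[pos] == 0.0
        assert scape.depths[pos] == 10  # only the wild-type sample contributes
        assert "mut" in scape.excluded[pos]

    def test_estimator_unbiased_at_known_rate(self, rng):
        # per-position estimates within 3 binomial SE of the simulated
        # substitution rate at >= 99% of positions
        p = 0.005
        ref = random_reference(300, rng)
        depth = 2000
        alns = [
            _perfect_alignment(
                mutate_substitutions(ref.sequence, p, rng), ref, f"r{i}"
            )
            for i in range(depth)
        ]
        report = identify_causative([], sample="s")
        scape = error_landscape([(alns, report)], ref)
        se = np.sqrt(p * (1 - p) / depth)
        within = np.abs(scape.frequencies - p) <= 3 * se
        assert within.mean() >= 0.99
        assert abs(scape.mean_frequency - p) <= 3 * se / np.sqrt(len(ref)) * 3

    def test_no_samples_rejected(self, small_ref):
        with pytest.raises(ValueError):
            error_landscape([], small_ref)


class TestCompareLandscapes:
    def _scape(self, ref, rates, rng, n=300):
        alns = [
            _perfect_alignment(
                mutate_substitutions(ref.sequence, rates, rng), ref, f"r{i}"
            )
            for i in range(n)
        ]
        return error_landscape([(alns, identify_causative([], sample="s"))], ref)

    def test_identical_landscapes_correlate_perfectly(self, rng):
        ref = random_reference(100, rng)
        a = self._scape(ref, 0.01, rng, n=50)
        _, corr = compare_landscapes(a, a)
        assert corr == pytest.approx(1.0)

    def test_shared_positional_effects_correlate(self, rng):
        # two independent libraries drawn from the same position-specific
        # error profile: per-position frequencies positively correlated
        ref = random_reference(200, rng)
        rates = np.full(len(ref), 0.002)
        hot = rng.choice(len(ref), size=20, replace=False)
        rates[hot] = 0.05
        a = self._scape(ref, rates, rng)
        b = self._scape(ref, rates, rng)
        _, corr = compare_landscapes(a, b)
        assert corr > 0.5

    def test_length_mismatch_rejected(self, rng):
        ref_a = random_reference(100, rng)
        ref_b = random_reference(120, rng)
        a = self._scape(ref_a, 0.01, rng, n=10)
        b = self._scape(ref_b, 0.01, rng, n=10)
        with pytest.raises(ValueError):
            compare_landscapes(a, b)
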