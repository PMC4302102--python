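"""Context classification, calling semantics, dedup and summary statistics."""
import numpy as np
import pytest

from mebs.io_formats import (
    Genome,
    ORIGINAL_BOTTOM,
    ORIGINAL_TOP,
    FormatError,
    revcomp,
)
from mebs.methylation_caller import (
    CytosineCall,
    FragmentMethProfile,
    call_from_alignments,
    capture_specificity,
    classify_context,
    context_summary,
    conversion_efficiency,
    fragment_profiles,
    methylation_ratio,
)

from conftest import make_read


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", "CG"),
            ("ACTGA", 1, "+", "CHG"),
            ("ACTTA", 1, "+", "CHH"),
            ("AACG", 3, "-", "CG"),     # bottom C at top G; upstream C pairs it
            ("AGTT", 1, "-", "unknown"),  # non-CG with the window off the edge
            ("ACNGA", 1, "+", "unknown"),
            ("TTC", 2, "+", "unknown"),   # next base off the scaffold
            ("GGAT", 0, "-", "unknown"),
            ("CAGTA", 2, "-", "CHG"),     # bottom strand reads C,T,G -> CHG
        ],
    )
    def test_contexts(self, seq, pos, strand, expected):
        genome = Genome({"s1": seq})
        assert classify_context(genome, "s1", pos, strand) == expected

    def test_non_cytosine_position_rejected(self):
        genome = Genome({"s1": "AAAA"})
        with pytest.raises(ValueError):
            classify_context(genome, "s1", 0, "+")


class TestCalling:
    def setup_method(self):
        self.genome = Genome({"s1": "ACGT"})

    def test_retained_c_is_methylated(self):
        calls = call_from_alignments([make_read("ACGT")], self.genome)
        (call,) = calls
        assert (call.pos, call.strand, call.context) == (1, "+", "CG")
        assert (call.meth, call.unmeth) == (1, 0)

    def test_converted_c_is_unmethylated(self):
        (call,) = call_from_alignments([make_read("ATGT")], self.genome)
        assert (call.meth, call.unmeth) == (0, 1)

    def test_bottom_strand_read_informs_minus_cytosines(self):
        # the G at position 2 is a bottom-strand C; read G = methylated
        (call,) = call_from_alignments(
            [make_read("ACGT", conv=ORIGINAL_BOTTOM)], self.genome)
        assert (call.pos, call.strand) == (2, "-")
        assert call.meth == 1

    def test_mismatch_bases_ignored(self):
        calls = call_from_alignments([make_read("AAGT")], self.genome)
        assert calls == []  # A at a top C is a sequencing error, not evidence

    def test_overlapping_mates_counted_once_mate1_wins(self):
        r1 = make_read("ACGT", read_id="frag")
        r2 = make_read("ATGT", read_id="frag")
        (call,) = call_from_alignments([r1, r2], self.genome)
        assert (call.meth, call.unmeth) == (1, 0)

    def test_doubling_mate_overlap_changes_nothing(self):
        reads = [make_read("ACGT", read_id="f"), make_read("ACGT", read_id="f")]
        once = call_from_alignments(reads[:1], self.genome)
        twice = call_from_alignments(reads, self.genome)
        assert [(c.meth, c.unmeth) for c in once] == [
            (c.meth, c.unmeth) for c in twice]

    def test_non_unique_reads_skipped_and_counted(self):
        stats = {}
        calls = call_from_alignments(
            [make_read("ACGT", unique=False)], self.genome, stats)
        assert calls == [] and stats["skipped_non_unique"] == 1

    def test_untagged_read_rejected(self):
        with pytest.raises(FormatError, match="conversion"):
            call_from_alignments([make_read("ACGT", conv=None)], self.genome)

    def test_count_conservation_against_bruteforce(self, rng):
        """Total observations equal a per-position recount after dedup."""
        genome = Genome({"g": "ACGTCGATCGGCTACG" * 20})
        reads = []
        for i in range(100):
            start = int(rng.integers(0, 280))
            conv = ORIGINAL_TOP if rng.random() < 0.5 else ORIGINAL_BOTTOM
            frag = genome["g"][start : start + 40]
            reads.append(make_read(frag, start=start, scaffold="g",
                                   read_id=f"f{i // 2}", conv=conv))
        stats = {}
        calls = call_from_alignments(reads, genome, stats)
        total = sum(c.meth + c.unmeth for c in calls)
        assert total == stats["observations"]
        # brute-force: per fragment, count distinct informative positions
        expected = 0
        frags: dict = {}
        for r in reads:
            frags.setdefault(r.read_id, []).append(r)
        for mates in frags.values():
            seen = set()
            for r in mates:
                base = "C" if r.conversion_strand == ORIGINAL_TOP else "G"
                for off, ch in enumerate(r.seq):
                    if genome["g"][r.start + off] == base:
                        # error-free reads always show the reference base
                        seen.add(r.start + off)
            expected += len(seen)
        assert total == expected

    def test_strand_symmetry_under_reverse_complement(self):
        genome = Genome({"g": "AACGTTCGGATCCGA"})
        L = len(genome["g"])
        reads = [make_read(genome["g"][2:12], start=2, scaffold="g")]
        calls = call_from_alignments(reads, genome)
        rc_genome = Genome({"g": revcomp(genome["g"])})
        rc_reads = [make_read(revcomp(reads[0].seq), start=L - 12, scaffold="g",
                              conv=ORIGINAL_BOTTOM)]
        rc_calls = call_from_alignments(rc_reads, rc_genome)
        mapped = sorted(
            (L - 1 - c.pos, {"+": "-", "-": "+"}[c.strand], c.context, c.meth,
             c.unmeth)
            for c in rc_calls)
        original = sorted(
            (c.pos, c.strand, c.context, c.meth, c.unmeth) for c in calls)
        assert mapped == original


class TestRatiosAndSummaries:
    def test_methylation_ratio(self):
        assert methylation_ratio(CytosineCall("s", 0, "+", "CG", 7, 3)) == 70.0
        assert methylation_ratio(CytosineCall("s", 0, "+", "CG", 0, 5)) == 0.0
        assert methylation_ratio(CytosineCall("s", 0, "+", "CG", 12, 0)) == 100.0

    def test_zero_coverage_ratio_rejected(self):
        with pytest.raises(ValueError):
            methylation_ratio(CytosineCall("s", 0, "+", "CG", 0, 0))

    def test_context_summary_pooling(self):
        calls = [
            CytosineCall("s", 0, "+", "CG", 9, 1),
            CytosineCall("s", 5, "+", "CHH", 1, 99),
        ]
        s = context_summary(calls)
        assert s.percent("CG") == 90.0
        assert s.percent("CHH") == 1.0
        assert s.overall_percent == pytest.approx(100 * 10 / 110)
        assert s.uncovered == {"CHG"}
        assert s.percent("CHG") == 0.0

    def test_unknown_context_excluded_from_summary(self):
        calls = [CytosineCall("s", 0, "+", "unknown", 5, 0)]
        s = context_summary(calls)
        assert s.uncovered == {"CG", "CHG", "CHH"}

    def test_conversion_efficiency(self):
        calls = [CytosineCall("s", i, "+", "CHH", 0, 1) for i in range(990)]
        calls += [CytosineCall("s", 1000 + i, "+", "CHG", 1, 0) for i in range(10)]
        assert conversion_efficiency(calls) == 99.0

    def test_conversion_efficiency_needs_non_cg(self):
        with pytest.raises(ValueError):
            conversion_efficiency([CytosineCall("s", 0, "+", "CG", 1, 0)])


class TestFragments:
    def test_profile_counts(self):
        genome = Genome({"g": "CACACACACA"})  # five top-strand Cs
        read = make_read("CACATATATA", scaffold="g", read_id="f1")
        profiles, hist = fragment_profiles([read], genome)
        assert profiles[0].n_cytosines == 5 and profiles[0].n_methylated == 2
        assert hist == {2: 1}

    def test_fragment_without_cytosines(self):
        genome = Genome({"g": "ATATATAT"})
        read = make_read("ATATATAT", scaffold="g")
        profiles, hist = fragment_profiles([read], genome)
        assert profiles[0].n_cytosines == 0
        assert hist == {0: 1}

    def test_capture_specificity_small(self):
        profiles = [FragmentMethProfile(f"f{i}", n, m)
                    for i, (n, m) in enumerate([(5, 2), (3, 0), (4, 1), (2, 0)])]
        assert capture_specificity(profiles) == 50.0

    def test_capture_specificity_all_methylated(self):
        profiles = [FragmentMethProfile("f", 4, 1)]
        assert capture_specificity(profiles) == 0.0

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            FragmentMethProfile("f", 2, 3)
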