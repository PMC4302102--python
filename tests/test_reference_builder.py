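"""Consensus rule, liftover arithmetic and coverage metrics."""
import numpy as np
import pytest

from mebs.io_formats import FormatError, Genome, Region
from mebs.reference_builder import (
    DELETED,
    CoverageTrack,
    PileupColumn,
    average_coverage,
    breadth_and_depth,
    build_consensus,
    consensus_base,
    iter_mpileup,
    lift_regions,
    read_pileup_tsv,
    write_pileup_tsv,
)
from mebs.simulator import SimConfig, simulate_genome, simulate_relative

from conftest import make_read


def col(scaffold="s1", pos=0, **kw):
    return PileupColumn(scaffold=scaffold, pos=pos, **kw)


class TestConsensusBase:
    def test_low_coverage_gives_n(self):
        assert consensus_base(col(base_counts={"A": 2, "C": 1})) == "N"

    def test_majority_base_wins(self):
        assert consensus_base(col(base_counts={"A": 3, "G": 2})) == "A"

    def test_deletion_competes_in_the_same_vote(self):
        assert consensus_base(col(base_counts={"C": 1}, deletion_count=5)) == DELETED

    def test_only_n_calls_stay_n(self):
        assert consensus_base(col(base_counts={"N": 6})) == "N"

    def test_tie_requires_rng(self):
        with pytest.raises(ValueError):
            consensus_base(col(base_counts={"A": 2, "G": 2}))

    def test_tie_split_is_even(self):
        rng = np.random.default_rng(42)
        c = col(base_counts={"A": 2, "G": 2})
        draws = [consensus_base(c, rng=rng) for _ in range(10_000)]
        frac_a = draws.count("A") / len(draws)
        assert 0.48 <= frac_a <= 0.52
        assert set(draws) == {"A", "G"}


class TestBuildConsensus:
    def test_zero_coverage_becomes_all_n(self):
        src = Genome({"s1": "ACGT"})
        out = build_consensus([], src, seed=1)
        assert out.genome["s1"] == "NNNN"
        assert out.stats["s1"]["n_count"] == 4

    def test_majority_deletion_removes_base_and_shifts_liftover(self):
        src = Genome({"s1": "ACGT"})
        cols = [
            col(pos=0, base_counts={"A": 5}),
            col(pos=1, base_counts={"C": 1}, deletion_count=5),
            col(pos=2, base_counts={"G": 5}),
            col(pos=3, base_counts={"T": 5}),
        ]
        out = build_consensus(cols, src, seed=1)
        assert out.genome["s1"] == "AGT"
        assert out.liftover.map("s1", 2) == 1
        assert out.liftover.map("s1", 1) is None
        assert out.stats["s1"]["deletions"] == 1

    def test_majority_insertion_emitted_at_junction(self):
        src = Genome({"s1": "AC"})
        cols = [
            col(pos=0, base_counts={"A": 8}, insertion_counts={"GG": 6}),
            col(pos=1, base_counts={"C": 8}),
        ]
        out = build_consensus(cols, src, seed=1)
        assert out.genome["s1"] == "AGGC"
        assert out.stats["s1"]["insertions"] == 1
        # liftover still maps both source positions
        assert out.liftover.map("s1", 1) == 3

    def test_minority_insertion_suppressed(self):
        src = Genome({"s1": "AC"})
        cols = [
            col(pos=0, base_counts={"A": 8}, insertion_counts={"GG": 2}),
            col(pos=1, base_counts={"C": 8}),
        ]
        out = build_consensus(cols, src, seed=1)
        assert out.genome["s1"] == "AC"

    def test_unsorted_input_rejected(self):
        src = Genome({"s1": "ACGT"})
        cols = [col(pos=2, base_counts={"G": 5}), col(pos=1, base_counts={"C": 5})]
        with pytest.raises(FormatError, match="sorted"):
            build_consensus(cols, src, seed=1)

    def test_determinism_under_seed(self):
        src = Genome({"s1": "ACGTACGT"})
        cols = [col(pos=i, base_counts={"A": 2, "G": 2}) for i in range(8)]
        a = build_consensus(list(cols), src, seed=9).genome["s1"]
        b = build_consensus(list(cols), src, seed=9).genome["s1"]
        assert a == b

    def test_bruteforce_agreement_on_random_columns(self, rng):
        """Independent argmax/tie enumeration agrees column by column."""
        def brute(c, min_cov, r):
            cov = sum(c.base_counts.values()) + c.deletion_count
            if cov < min_cov:
                return "N"
            cands = {b: n for b, n in c.base_counts.items() if b in "ACGT" and n}
            if c.deletion_count:
                cands[DELETED] = c.deletion_count
            if not cands:
                return "N"
            top = max(cands.values())
            tied = sorted(b for b, n in cands.items() if n == top)
            return tied[0] if len(tied) == 1 else tied[int(r.integers(len(tied)))]

        for i in range(300):
            counts = {b: int(rng.integers(0, 5)) for b in "ACGT"}
            c = col(pos=i, base_counts=counts,
                    deletion_count=int(rng.integers(0, 3)))
            seed = int(rng.integers(1 << 30))
            assert consensus_base(c, rng=np.random.default_rng(seed)) == brute(
                c, 4, np.random.default_rng(seed))


class TestLiftRegions:
    def _lift(self, arr):
        from mebs.reference_builder import Liftover
        return Liftover({"s1": np.asarray(arr, dtype=np.int64)})

    def test_identity(self):
        lift = self._lift([0, 1, 2, 3])
        out, dropped = lift_regions([Region("s1", 1, 3)], lift)
        assert (out[0].start, out[0].end) == (1, 3) and not dropped

    def test_upstream_deletion_shifts_left(self):
        lift = self._lift([0, -1, 1, 2])
        out, _ = lift_regions([Region("s1", 2, 4)], lift)
        assert (out[0].start, out[0].end) == (1, 3)

    def test_fully_deleted_region_dropped(self):
        lift = self._lift([0, -1, -1, 1])
        out, dropped = lift_regions([Region("s1", 1, 3, name="gone")], lift)
        assert out == [] and dropped[0].name == "gone"

    def test_off_scaffold_region_rejected(self):
        lift = self._lift([0, 1])
        with pytest.raises(FormatError):
            lift_regions([Region("s1", 0, 5)], lift)

    def test_liftover_monotone_on_simulated_indels(self):
        cfg = SimConfig(seed=21, genome_length=20_000, n_scaffolds=1, n_cgis=2)
        genome, _ = simulate_genome(cfg)
        rel = simulate_relative(genome, cfg)
        out = build_consensus(rel.pileup_columns(), genome, seed=3)
        arr = out.liftover.maps["scaf1"]
        kept = arr[arr >= 0]
        assert (np.diff(kept) > 0).all()


class TestSelfConsensus:
    def test_error_free_depth_reconstructs_exactly(self):
        cfg = SimConfig(seed=8, genome_length=10_000, n_scaffolds=1, n_cgis=1,
                        snv_rate=0.0, indel_rate=0.0, relative_depth=5)
        genome, _ = simulate_genome(cfg)
        rel = simulate_relative(genome, cfg)
        out = build_consensus(rel.pileup_columns(), genome, seed=2)
        assert out.genome["scaf1"] == genome["scaf1"]
        assert out.stats["scaf1"] == {
            "n_count": 0, "substitutions": 0, "insertions": 0, "deletions": 0}


class TestCoverage:
    def test_average_coverage_arithmetic(self):
        assert average_coverage(1000, 100, 50_000) == 2.0
        assert average_coverage(123_511_268, 100, 2_700_000_000) == pytest.approx(
            4.6, abs=0.1)
        assert average_coverage(0, 100, 50_000) == 0.0

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            average_coverage(1, 100, 0)

    def test_breadth_and_depth_small(self):
        track = CoverageTrack({"s1": np.array([0, 0, 2, 4])})
        breadth, depth = breadth_and_depth(track)
        assert breadth == 50.0 and depth == 3.0

    def test_all_zero_track_degenerate(self):
        track = CoverageTrack({"s1": np.zeros(10, dtype=int)})
        assert breadth_and_depth(track) == (0.0, 0.0)

    def test_breadth_matches_bruteforce_on_planted_reads(self, rng):
        genome = Genome({"g": "A" * 10_000})
        reads = [make_read("A" * 100, start=int(rng.integers(0, 9_900)),
                           scaffold="g", read_id=f"r{i}") for i in range(500)]
        track = CoverageTrack.from_reads(reads, genome)
        depth = np.zeros(10_000, dtype=int)
        for r in reads:
            depth[r.start : r.start + 100] += 1
        assert (track.depths["g"] == depth).all()
        breadth, mean_depth = breadth_and_depth(track)
        covered = depth > 0
        assert breadth == pytest.approx(100.0 * covered.sum() / 10_000)
        assert mean_depth == pytest.approx(depth[covered].mean())


class TestPileupIO:
    def test_tsv_round_trip(self, tmp_path):
        cols = [
            col(pos=0, ref_base="A", base_counts={"A": 3, "G": 1},
                insertion_counts={"TT": 2}),
            col(pos=1, ref_base="C", deletion_count=4),
        ]
        p = tmp_path / "p.tsv"
        write_pileup_tsv(cols, p)
        back = list(read_pileup_tsv(p))
        assert back[0].base_counts == {"A": 3, "G": 1}
        assert back[0].insertion_counts == {"TT": 2}
        assert back[1].deletion_count == 4

    def test_mpileup_base_string_parsing(self, tmp_path):
        p = tmp_path / "m.pileup"
        p.write_text(
            "s1\t1\tA\t5\t..,Tg\tIIIII\n"
            "s1\t2\tC\t4\t.+2GG.^].*\tIIII\n"
        )
        cols = list(iter_mpileup(p))
        assert cols[0].pos == 0
        assert cols[0].base_counts == {"A": 3, "T": 1, "G": 1}
        assert cols[1].insertion_counts == {"GG": 1}
        assert cols[1].deletion_count == 1
        assert cols[1].base_counts == {"C": 3}
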