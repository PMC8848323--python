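"""Chromosome assignment, size classification and scaffold splitting."""

import numpy as np
import pandas as pd
import pytest

import synpaint as sp
from synpaint.composition import WindowTrack
from synpaint.karyotype import AssignmentError, BreakpointCandidate, SplitError


def mk_assembly(**lengths):
    return sp.Assembly([sp.SequenceRecord(id=k, seq="A" * v) for k, v in lengths.items()])


def hit(marker, scaffold):
    return sp.HitRecord(qseqid=marker, sseqid=scaffold, sstart=1, length=100, pident=99.0)


class TestClassify:
    def test_threshold_rules(self):
        classes = sp.classify_macro_micro(
            {"a": 60_000_000, "b": 30_000_000, "c": 5_000_000}
        )
        assert classes == {"a": "macro", "b": "micro", "c": "unplaced"}

    def test_macro_boundary_inclusive(self):
        assert sp.classify_macro_micro({"a": 50_000_000})["a"] == "macro"

    def test_micro_boundary_exclusive(self):
        assert sp.classify_macro_micro({"a": 8_000_000})["a"] == "unplaced"

    def test_empty(self):
        assert sp.classify_macro_micro({}) == {}

    def test_nonpositive_length_errors(self):
        with pytest.raises(ValueError):
            sp.classify_macro_micro({"a": 0})


class TestAssign:
    def setup_method(self):
        self.asm = mk_assembly(S=60_000_000, T=55_000_000, U=30_000_000)
        self.m2c = {f"m{i}": "chr1" for i in range(10)}
        self.m2c.update({f"k{i}": "chr2" for i in range(10)})
        self.m2c.update({f"u{i}": "chrU" for i in range(6)})

    def test_majority_rule(self):
        hits = [hit(f"m{i}", "S") for i in range(8)] + [hit(f"m{i}", "T") for i in range(8, 10)]
        hits += [hit(f"k{i}", "T") for i in range(9)]
        a = sp.assign_chromosomes(hits, self.m2c, self.asm)
        assert a.by_scaffold["S"].source_label == "chr1"
        assert a.by_scaffold["S"].evidence == {"chr1": 8}
        assert a.by_scaffold["T"].source_label == "chr2"

    def test_macro_labels_numbered_by_length(self):
        hits = [hit(f"m{i}", "T") for i in range(5)] + [hit(f"k{i}", "S") for i in range(5)]
        a = sp.assign_chromosomes(hits, self.m2c, self.asm)
        assert a.by_scaffold["S"].chrom_label == "macro1"  # S is longer
        assert a.by_scaffold["T"].chrom_label == "macro2"

    def test_no_evidence_errors(self):
        with pytest.raises(AssignmentError, match="no assignable evidence"):
            sp.assign_chromosomes([hit("zz", "S")], self.m2c, self.asm)

    def test_tie_flags_ambiguous(self):
        hits = [hit(f"m{i}", "S") for i in range(5)] + [hit(f"k{i}", "S") for i in range(5)]
        a = sp.assign_chromosomes(hits, self.m2c, self.asm)
        assert a.by_scaffold["S"].ambiguous
        assert a.by_scaffold["S"].chrom_label is None

    def test_below_min_votes_ambiguous(self):
        a = sp.assign_chromosomes([hit("m0", "S")], self.m2c, self.asm)
        assert a.by_scaffold["S"].ambiguous

    def test_conflicting_majorities_error(self):
        hits = [hit(f"m{i}", "S") for i in range(6)] + [hit(f"k{i}", "S") for i in range(4)]
        with pytest.raises(AssignmentError, match="majority"):
            sp.assign_chromosomes(hits, self.m2c, self.asm)

    def test_invariant_to_order_and_duplication(self):
        hits = [hit(f"m{i}", "S") for i in range(8)] + [hit(f"k{i}", "T") for i in range(8)]
        ref = sp.assign_chromosomes(hits, self.m2c, self.asm)
        rng = np.random.default_rng(0)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        doubled = shuffled + shuffled
        for variant in (shuffled, doubled):
            a = sp.assign_chromosomes(variant, self.m2c, self.asm)
            assert {s: x.chrom_label for s, x in a.by_scaffold.items()} == {
                s: x.chrom_label for s, x in ref.by_scaffold.items()
            }

    def test_unknown_markers_counted(self):
        hits = [hit(f"m{i}", "S") for i in range(4)] + [hit("mystery", "S")]
        a = sp.assign_chromosomes(hits, self.m2c, self.asm)
        assert a.n_unknown_markers == 1


class TestGapJunctions:
    def test_midpoints_of_long_n_runs(self):
        rec = sp.SequenceRecord(id="s", seq="A" * 100 + "N" * 60 + "A" * 100 + "N" * 10 + "A" * 30)
        assert sp.find_gap_junctions(rec) == [130]

    def test_threshold_configurable(self):
        rec = sp.SequenceRecord(id="s", seq="A" * 10 + "N" * 10 + "A" * 10)
        assert sp.find_gap_junctions(rec, min_gap=10) == [15]
        assert sp.find_gap_junctions(rec, min_gap=11) == []


def synthetic_track(scaffold, gc_left, gc_right, rep_left, rep_right, n_windows=20,
                    junction_win=10, noise=0.3, seed=0):
    """A handcrafted window track: two homogeneous regimes with small noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_windows):
        left = i < junction_win
        rows.append({
            "chrom": scaffold, "chrom_class": "micro", "index": i,
            "start": i * 1_000_000, "end": (i + 1) * 1_000_000, "effective_len": 1_000_000,
            "gc_pct": (gc_left if left else gc_right) + rng.normal(0, noise),
            "gene_frac": 0.25 + rng.normal(0, 0.02),
            "repeat_frac": (rep_left if left else rep_right) + rng.normal(0, noise / 50),
        })
    return WindowTrack(df=pd.DataFrame(rows))


class TestScoreBreakpoints:
    def test_true_junction_dominates_decoys(self):
        track = synthetic_track("scf", 36.0, 40.0, 0.47, 0.31)
        cands = [10_000_000] + [3_000_000, 5_500_000, 14_200_000, 16_700_000]
        scored = sp.score_breakpoints("scf", cands, track)
        best = max(scored, key=lambda c: c.shift_score)
        assert best.position == 10_000_000
        assert best.shift_score >= 2.0
        assert best.opposed

    def test_homogeneous_scaffold_mostly_refuses_to_split(self):
        # pure noise can cross any finite threshold occasionally; the
        # contract is that a compositionally uniform scaffold raises the
        # no-breakpoint error in the majority of replicates
        cands = [3_000_000, 6_000_000, 10_000_000, 14_000_000, 17_000_000]
        refused = 0
        for seed in range(20):
            track = synthetic_track("scf", 38.0, 38.0, 0.4, 0.4, seed=seed)
            scored = sp.score_breakpoints("scf", cands, track)
            try:
                sp.split_scaffold(mk_assembly(scf=20_000_000), "scf", scored)
            except SplitError:
                refused += 1
        assert refused > 10

    def test_candidate_outside_scaffold_errors(self):
        track = synthetic_track("scf", 36.0, 40.0, 0.47, 0.31)
        with pytest.raises(ValueError, match="outside"):
            sp.score_breakpoints("scf", [25_000_000], track)

    def test_short_flank_flagged(self):
        track = synthetic_track("scf", 36.0, 40.0, 0.47, 0.31)
        scored = sp.score_breakpoints("scf", [500_000], track)
        assert scored[0].flagged


class TestSplitScaffold:
    @staticmethod
    def candidate(pos, score, gd, dgc=4.0, drep=-0.15):
        return BreakpointCandidate(
            scaffold="scf", position=pos, source="supplied",
            delta_gc=dgc, delta_repeat=drep, local_gd=gd, shift_score=score,
        )

    def test_min_gd_rule_between_passers(self):
        asm = mk_assembly(scf=1_000_000)
        scored = [self.candidate(200_000, 3.0, 0.25), self.candidate(600_000, 2.5, 0.10)]
        _, report = sp.split_scaffold(asm, "scf", scored)
        assert report["chosen_position"] == 600_000

    def test_unopposed_shift_not_a_passer(self):
        asm = mk_assembly(scf=1_000_000)
        scored = [self.candidate(200_000, 5.0, 0.1, dgc=4.0, drep=0.15)]
        with pytest.raises(SplitError):
            sp.split_scaffold(asm, "scf", scored)

    def test_split_conserves_sequence(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        asm = sp.Assembly([sp.SequenceRecord(id="scf", seq=seq)])
        scored = [self.candidate(4_321, 3.0, 0.1)]
        curated, report = sp.split_scaffold(asm, "scf", scored)
        left, right = curated["scf_L"], curated["scf_R"]
        assert left.seq + right.seq == seq
        assert curated.total_length == asm.total_length
        assert report["chosen_position"] == 4_321

    def test_other_records_untouched(self):
        asm = mk_assembly(a=1000, scf=1_000_000, b=2000)
        curated, _ = sp.split_scaffold(asm, "scf", [self.candidate(500_000, 3.0, 0.1)])
        assert [r.id for r in curated.records] == ["a", "scf_L", "scf_R", "b"]

    def test_missing_scaffold_errors(self):
        with pytest.raises(KeyError):
            sp.split_scaffold(mk_assembly(a=1000), "scf", [self.candidate(10, 3.0, 0.1)])


class TestHiddenFusionFixture:
    def test_curation_reaches_expected_micro_count(self):
        sc = sp.hidden_fusion_scenario(seed=3, with_macros=False)
        asm = sc["assembly"]
        before = sp.classify_macro_micro(asm.lengths())
        assert sum(1 for v in before.values() if v == "micro") == 10
        track = sp.build_track(asm, sc["genes"], sc["repeats"], sc["class_map"])
        scored = sp.score_breakpoints(sc["fused_scaffold"], sc["candidates"], track)
        curated, report = sp.split_scaffold(asm, sc["fused_scaffold"], scored)
        after = sp.classify_macro_micro(curated.lengths())
        assert sum(1 for v in after.values() if v == "micro") == 11
        assert report["chosen_position"] == sc["true_junction"]
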