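"""Marker partitioning, best-hit selection, filtering and block chaining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synpaint as sp
from synpaint.painting import Marker, RetainedHit, marker_id, parse_marker_id


def mk_assembly(**seqs):
    return sp.Assembly([sp.SequenceRecord(id=k, seq=v) for k, v in seqs.items()])


def retained(chrom, index, scaffold, species="spA", aln=100, pident=99.0, tstart=None):
    m = Marker(chrom, index, index * 100, (index + 1) * 100)
    return RetainedHit(
        marker=m, species=species, target_scaffold=scaffold,
        target_start=index * 100 if tstart is None else tstart,
        aln_length=aln, pident=pident,
    )


class TestGenerateMarkers:
    def test_trailing_partial_tile_dropped(self):
        asm = mk_assembly(c="ACGT" * 262 + "AC")  # 1050 bp
        markers = sp.generate_markers(asm)
        assert len(markers) == 10
        assert markers[-1].end == 1000

    def test_n_tile_dropped_by_default(self):
        seq = "A" * 150 + "N" + "A" * 149  # N inside tile 1 of a 300-bp chromosome
        markers = sp.generate_markers(mk_assembly(c=seq))
        assert [m.index for m in markers] == [0, 2]
        assert markers[1].start == 200  # ordinals count dropped tiles

    def test_n_tile_kept_when_not_dropping(self):
        seq = "A" * 150 + "N" + "A" * 149
        markers = sp.generate_markers(mk_assembly(c=seq), drop_n=False)
        assert [m.index for m in markers] == [0, 1, 2]
        assert [m.contains_n for m in markers] == [False, True, False]

    def test_chromosome_shorter_than_marker(self):
        assert sp.generate_markers(mk_assembly(c="ACGT" * 10)) == []

    def test_marker_len_floor(self):
        with pytest.raises(ValueError):
            sp.generate_markers(mk_assembly(c="A" * 1000), marker_len=5)

    @pytest.mark.parametrize("chrom", ["chr1", "scf_4326_4427", "a_b_c"])
    def test_marker_id_round_trip(self, chrom):
        assert parse_marker_id(marker_id(chrom, 42)) == (chrom, 42)

    @pytest.mark.parametrize("bad", ["chr1", "chr1_", "_0042", "chr1_x42"])
    def test_bad_marker_ids_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_marker_id(bad)


class TestSelectBestHits:
    def setup_method(self):
        self.markers = sp.generate_markers(mk_assembly(c="A" * 1000))

    def test_longer_alignment_wins(self):
        mid = self.markers[0].id
        hits = [sp.HitRecord(mid, "s1", 1, 80, 99.9), sp.HitRecord(mid, "s2", 1, 95, 90.0)]
        (r,) = sp.select_best_hits(hits, self.markers, "spA")
        assert r.target_scaffold == "s2"
        assert r.aln_length == 95

    def test_one_row_per_marker_is_identity(self):
        hits = [sp.HitRecord(m.id, "s", m.start + 1, 100, 99.0) for m in self.markers]
        out = sp.select_best_hits(hits, self.markers, "spA")
        assert len(out) == len(hits)
        assert all(r.target_start == r.marker.start for r in out)

    def test_unknown_qseqid_dropped(self):
        hits = [sp.HitRecord("nope_0000001", "s", 1, 100, 99.0)]
        assert sp.select_best_hits(hits, self.markers, "spA") == []

    def test_sstart_converted_to_zero_based(self):
        (r,) = sp.select_best_hits(
            [sp.HitRecord(self.markers[0].id, "s", 101, 100, 99.0)], self.markers, "spA"
        )
        assert r.target_start == 100

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(0)
        hits = []
        for m in self.markers[:5]:
            for j in range(3):
                hits.append(sp.HitRecord(m.id, f"s{j}", 1 + j, 60 + j * 10, 95.0))
        ref = sp.select_best_hits(hits, self.markers, "spA")
        for _ in range(10):
            rng.shuffle(hits)
            assert sp.select_best_hits(hits, self.markers, "spA") == ref


class TestFilterHits:
    def test_alignment_length_boundary(self):
        hits = [retained("c", 0, "s", aln=49), retained("c", 1, "s", aln=50)]
        out = sp.filter_hits(hits)
        assert [h.aln_length for h in out] == [50]

    def test_empty(self):
        assert sp.filter_hits([]) == []

    def test_counts_by_construction(self):
        alns = [30, 45, 49, 49, 50, 51, 70, 100, 60, 55]  # 4 below 50
        hits = [retained("c", i, "s", aln=a) for i, a in enumerate(alns)]
        assert len(sp.filter_hits(hits)) == 6


def rle_chain_oracle(entries, min_run):
    """Brute-force run-length scan over (index, scaffold) pairs of one chromosome."""
    out = []
    run = []
    for idx, scaf in sorted(entries):
        if run and (idx != run[-1][0] + 1 or scaf != run[-1][1]):
            if len(run) >= min_run:
                out.append((run[0][0], run[-1][0], run[0][1]))
            run = []
        run.append((idx, scaf))
    if len(run) >= min_run:
        out.append((run[0][0], run[-1][0], run[0][1]))
    return out


class TestChainMarkers:
    def test_exact_threshold_run(self):
        hits = [retained("c", i, "sA") for i in range(10, 15)]
        (b,) = sp.chain_markers(hits)
        assert (b.first_index, b.last_index, b.marker_count) == (10, 14, 5)
        assert b.query_span == (1000, 1500)

    def test_below_threshold_discarded(self):
        assert sp.chain_markers([retained("c", i, "sA") for i in range(10, 14)]) == []

    def test_scaffold_change_breaks_run(self):
        hits = [retained("c", i, "sA") for i in range(5)]
        hits += [retained("c", i, "sB") for i in range(5, 12)]
        blocks = sp.chain_markers(hits)
        assert [(b.target_scaffold, b.marker_count) for b in blocks] == [("sA", 5), ("sB", 7)]

    def test_index_gap_breaks_run(self):
        hits = [retained("c", i, "sA") for i in [0, 1, 2, 3, 4, 6, 7, 8, 9, 10]]
        blocks = sp.chain_markers(hits)
        assert [(b.first_index, b.last_index) for b in blocks] == [(0, 4), (6, 10)]

    def test_duplicate_marker_errors(self):
        hits = [retained("c", 0, "sA"), retained("c", 0, "sB")]
        with pytest.raises(ValueError, match="duplicate"):
            sp.chain_markers(hits)

    def test_strict_mode_requires_monotone_target(self):
        tstarts = [0, 100, 200, 150, 250, 350]  # direction flips at index 3
        hits = [retained("c", i, "sA", tstart=t) for i, t in enumerate(tstarts)]
        assert len(sp.chain_markers(hits, min_run=3, strict_target=True)) == 2
        assert len(sp.chain_markers(hits, min_run=3, strict_target=False)) == 1

    @settings(max_examples=300, derandomize=True)
    @given(
        entries=st.lists(
            st.tuples(st.integers(0, 40), st.sampled_from(["sA", "sB", "sC"])),
            max_size=40, unique_by=lambda e: e[0],
        ),
        min_run=st.integers(1, 8),
    )
    def test_matches_run_length_oracle(self, entries, min_run):
        hits = [retained("c", i, s) for i, s in entries]
        got = [
            (b.first_index, b.last_index, b.target_scaffold)
            for b in sp.chain_markers(hits, min_run=min_run)
        ]
        assert got == rle_chain_oracle(entries, min_run)


class TestPaint:
    def test_zero_noise_identity_one_block_per_chrom(self, tiny_scenario):
        asm, markers = tiny_scenario["assembly"], tiny_scenario["markers"]
        _, truth = sp.apply_rearrangements(asm, [])
        hits = sp.emit_hits(markers, truth, sp.HitNoise(), seed=3)
        table = sp.paint(asm, {"spA": hits})
        for rec in asm.records:
            blocks = [b for b in table.blocks if b.query_chrom == rec.id]
            assert len(blocks) == 1
            marked = [m for m in markers if m.query_chrom == rec.id]
            assert blocks[0].query_span == (marked[0].start, marked[-1].end)

    def test_empty_species_listed_with_zero_blocks(self, tiny_scenario):
        table = sp.paint(tiny_scenario["assembly"], {"ghost": []})
        assert table.species == ["ghost"]
        assert table.blocks == []
        assert table.stats["ghost"]["raw_hits"] == 0

    def test_min_run_sweep_threshold(self):
        asm = mk_assembly(c="A" * 2000)
        markers = sp.generate_markers(asm)
        hits = [sp.HitRecord(markers[i].id, "s", markers[i].start + 1, 100, 99.0) for i in range(5)]
        for min_run in range(1, 11):
            table = sp.paint(asm, {"spA": hits}, sp.PaintingParams(min_run=min_run))
            assert bool(table.blocks) == (min_run <= 5)

    def test_retention_monotonicity(self, tiny_scenario):
        asm, markers = tiny_scenario["assembly"], tiny_scenario["markers"]
        _, truth = sp.apply_rearrangements(asm, [])
        hits = sp.emit_hits(
            markers, truth,
            sp.HitNoise(drop_rate=0.1, spurious_rate=0.05, aln_len_range=(30, 100)),
            seed=9,
        )
        table = sp.paint(asm, {"spA": hits})
        st_ = table.stats["spA"]
        assert st_["markers_in_blocks"] <= st_["filtered"] <= st_["retained"] <= st_["raw_hits"]
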