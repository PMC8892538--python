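"""Alignment-block reading and homologous-synteny-block chaining."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_block
from scaffotype3d import karyosim as ks
from scaffotype3d.synteny import (
    AlignmentBlock,
    AssemblyIndex,
    SyntenyError,
    chain_blocks,
    filter_scaffolds,
    read_blocks,
    read_hsbs,
    write_hsbs,
)


# ---------------------------------------------------------------------------
# Readers


class TestReadBlocks:
    def test_one_line_bedpair(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("chrA1\t0\t1000\ts7\t0\t1000\t+\n")
        blocks = read_blocks(p)
        assert blocks == [AlignmentBlock("chrA1", 0, 1000, "s7", 0, 1000, "+")]

    def test_empty_file_and_comments(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("# just a header\n\n")
        assert read_blocks(p) == []

    @pytest.mark.parametrize(
        "line, fragment",
        [
            ("chrA\t0\tnope\ts1\t0\t5\t+", ":1"),  # non-integer coordinate
            ("chrA\t0\t5\ts1\t0\t5", ":1"),  # missing strand column
            ("chrA\t10\t5\ts1\t0\t5\t+", "end 5"),  # end <= start
        ],
    )
    def test_malformed_line_names_location(self, tmp_path, line, fragment):
        p = tmp_path / "b.tsv"
        p.write_text(line + "\n")
        with pytest.raises(SyntenyError, match=fragment):
            read_blocks(p)

    def test_chain_minus_strand_flipped_to_forward(self, tmp_path):
        # one minus-strand aligned segment on a 10-kb query scaffold,
        # reverse-strand interval [0, 1000)
        p = tmp_path / "t.chain"
        p.write_text("chain 100 refA 20000 + 0 1000 q1 10000 - 0 1000 1\n1000\n")
        (block,) = read_blocks(p, "ucsc_chain")
        q_size, q_start, q_end = 10000, 0, 1000
        # independent coordinate flip: forward interval is [L - end, L - start)
        assert (block.tgt_start, block.tgt_end) == (q_size - q_end, q_size - q_start)
        assert (block.ref_start, block.ref_end) == (0, 1000)
        assert block.orientation == "-"

    def test_chain_decomposed_into_gap_free_segments(self, tmp_path):
        p = tmp_path / "t.chain"
        # two aligned segments of 500 and 300 bp, separated by dt=100, dq=50
        p.write_text(
            "chain 900 refA 20000 + 100 1000 q1 10000 + 200 1050 7\n"
            "500\t100\t50\n300\n"
        )
        blocks = read_blocks(p, "ucsc_chain")
        assert [(b.ref_start, b.ref_end, b.tgt_start, b.tgt_end) for b in blocks] == [
            (100, 600, 200, 700),
            (700, 1000, 750, 1050),
        ]


class TestFilterScaffolds:
    @pytest.mark.parametrize(
        "length, threshold, kept",
        [
            (49_999, 50_000, False),  # shorter than 50 kb: excluded
            (50_000, 50_000, True),  # boundary is inclusive-keep
            (10, 0, True),  # threshold 0 is the identity
        ],
    )
    def test_length_threshold(self, length, threshold, kept):
        blocks = [make_block(tgt="s1", tgt_end=min(length, 1000))]
        index = AssemblyIndex({"s1": length}, min_scaffold_len=threshold)
        assert (filter_scaffolds(blocks, index) == blocks) is kept

    def test_missing_scaffold_listed(self):
        blocks = [make_block(tgt="s1"), make_block(tgt="s2")]
        with pytest.raises(SyntenyError, match="s1, s2"):
            filter_scaffolds(blocks, AssemblyIndex({}))


# ---------------------------------------------------------------------------
# Chaining


def oracle_chain(blocks, resolution):
    """Independent re-derivation of the chaining semantics.

    Each pass partitions every (ref_chrom, scaffold, orientation) group at
    ref-sorted consecutive pairs violating the gap/diagonal predicate,
    applies the min-span filter, then trims reference overlaps keeping the
    longer span; passes repeat until nothing changes.  Blocks are plain
    tuples (key, ref_lo, ref_hi, tgt_lo, tgt_hi).
    """

    def extends(prev, nxt, orientation):
        if not 0 <= nxt[1] - prev[2] < resolution:
            return False
        if orientation == "+":
            gap = nxt[3] - prev[4]
        else:
            gap = prev[3] - nxt[4]
        return 0 <= gap < resolution

    def one_pass(items):
        groups = {}
        for it in items:
            groups.setdefault(it[0], []).append(it)
        merged = []
        for key, group in groups.items():
            group = sorted(group, key=lambda t: (t[1], t[2]))
            cuts = [
                i
                for i in range(1, len(group))
                if not extends(group[i - 1], group[i], key[2])
            ]
            for lo, hi in zip([0] + cuts, cuts + [len(group)]):
                chunk = group[lo:hi]
                ref_lo = min(t[1] for t in chunk)
                ref_hi = max(t[2] for t in chunk)
                tgt_lo = min(t[3] for t in chunk)
                tgt_hi = max(t[4] for t in chunk)
                if ref_hi - ref_lo >= resolution and tgt_hi - tgt_lo >= resolution:
                    merged.append((key, ref_lo, ref_hi, tgt_lo, tgt_hi))
        # overlap trim, longer ref span wins, smaller ref_start breaks ties
        merged.sort(key=lambda t: (-(t[2] - t[1]), t[1]))
        kept = []
        for key, rlo, rhi, tlo, thi in merged:
            for k2, r2lo, r2hi, *_ in kept:
                if k2[0] == key[0] and rlo < r2hi and r2lo < rhi:
                    if rlo < r2lo:
                        rhi = r2lo
                    else:
                        rlo = r2hi
                    if rhi <= rlo:
                        rlo = None
                        break
            if rlo is not None:
                kept.append((key, rlo, rhi, tlo, thi))
        return kept

    items = [
        ((b.ref_chrom, b.tgt_scaffold, b.orientation), b.ref_start, b.ref_end,
         b.tgt_start, b.tgt_end)
        for b in blocks
    ]
    for _ in range(20):
        nxt = one_pass(items)
        if sorted(nxt) == sorted(items):
            break
        items = nxt
    return set(items)


class TestChainBlocks:
    def test_gap_below_resolution_merges(self):
        blocks = [
            make_block(ref_start=0, ref_end=100_000, tgt_start=0, tgt_end=100_000),
            make_block(ref_start=150_000, ref_end=400_000, tgt_start=150_000, tgt_end=400_000),
        ]
        (hsb,) = chain_blocks(blocks, 300_000)
        assert (hsb.ref_start, hsb.ref_end) == (0, 400_000)
        assert hsb.n_source_blocks == 2

    def test_short_block_discarded(self):
        blocks = [make_block(ref_end=100_000, tgt_end=100_000)]
        assert chain_blocks(blocks, 300_000) == []

    def test_opposite_orientations_never_merge(self):
        blocks = [
            make_block(ref_start=0, ref_end=400_000, tgt_start=0, tgt_end=400_000, orientation="+"),
            make_block(ref_start=400_000, ref_end=800_000, tgt_start=400_000, tgt_end=800_000, orientation="-"),
        ]
        hsbs = chain_blocks(blocks, 300_000)
        assert len(hsbs) == 2
        assert {h.orientation for h in hsbs} == {"+", "-"}

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle_on_small_inputs(self, data):
        n = data.draw(st.integers(1, 8))
        resolution = data.draw(st.sampled_from([100, 200, 300]))
        blocks = []
        for k in range(n):
            start = data.draw(st.integers(0, 20)) * 50
            length = data.draw(st.integers(1, 8)) * 50
            tstart = data.draw(st.integers(0, 20)) * 50
            blocks.append(
                make_block(
                    ref_start=start,
                    ref_end=start + length,
                    tgt=data.draw(st.sampled_from(["s1", "s2"])),
                    tgt_start=tstart,
                    tgt_end=tstart + length,
                    orientation=data.draw(st.sampled_from("+-")),
                )
            )
        got = {
            ((h.ref_chrom, h.tgt_scaffold, h.orientation), h.ref_start, h.ref_end,
             h.tgt_start, h.tgt_end)
            for h in chain_blocks(blocks, resolution)
        }
        assert got == oracle_chain(blocks, resolution)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_chaining_is_idempotent(self, seed):
        import numpy as np

        r = np.random.default_rng(seed)
        blocks = []
        for _ in range(r.integers(1, 12)):
            start = int(r.integers(0, 40)) * 100_000
            length = int(r.integers(1, 8)) * 100_000
            blocks.append(
                make_block(
                    ref_start=start,
                    ref_end=start + length,
                    tgt_start=start,
                    tgt_end=start + length,
                    orientation=str(r.choice(["+", "-"])),
                )
            )
        once = chain_blocks(blocks, 300_000)
        twice = chain_blocks([h.as_alignment_block() for h in once], 300_000)
        assert [
            (h.ref_start, h.ref_end, h.tgt_start, h.tgt_end, h.orientation) for h in once
        ] == [(h.ref_start, h.ref_end, h.tgt_start, h.tgt_end, h.orientation) for h in twice]

    def test_unrearranged_genome_gives_one_hsb_per_chromosome(self):
        cfg = ks.SimConfig(n_chroms=4, seed=11, bin_size=500_000)
        ancestor, _ = ks.make_genome(cfg)
        _, truth = ks.apply_rearrangements(ancestor, [], bin_size=cfg.bin_size)
        hsbs = chain_blocks(truth.truth_blocks, 500_000)
        assert len(hsbs) == len(ancestor)
        for h in hsbs:
            assert h.ref_span >= ancestor[h.ref_chrom] - 2 * 500_000

    def test_coarser_resolution_covers_subset_on_truth_blocks(self):
        cfg = ks.SimConfig(n_chroms=4, seed=5, bin_size=500_000)
        ancestor, _ = ks.make_genome(cfg)
        events = ks.random_history(ancestor, 8, cfg.rng(), cfg.bin_size)
        _, truth = ks.apply_rearrangements(ancestor, events, bin_size=cfg.bin_size)
        fine = chain_blocks(truth.truth_blocks, 500_000)
        coarse = chain_blocks(truth.truth_blocks, 1_000_000)
        fine_cov = {
            (h.ref_chrom, pos)
            for h in fine
            for pos in range(h.ref_start, h.ref_end, 500_000)
        }
        coarse_cov = {
            (h.ref_chrom, pos)
            for h in coarse
            for pos in range(h.ref_start, h.ref_end, 500_000)
        }
        assert coarse_cov <= fine_cov


def test_hsb_tsv_round_trip(tmp_path):
    blocks = [
        make_block(ref_start=0, ref_end=400_000, tgt_start=0, tgt_end=400_000),
        make_block(ref_chrom="chrB", ref_start=0, ref_end=900_000, tgt="s2",
                   tgt_start=100_000, tgt_end=1_000_000, orientation="-"),
    ]
    hsbs = chain_blocks(blocks, 300_000)
    path = tmp_path / "hsbs.tsv"
    write_hsbs(hsbs, path)
    assert read_hsbs(path) == hsbs
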