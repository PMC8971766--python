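import pytest
from hypothesis import given, settings, strategies as st

from mutanome2vax import peptide_design as pep
from mutanome2vax.peptide_design import MutantContext


def brute_force_tile_starts(length, step, width=20):
    """Independent tiling oracle: leftmost tiles at the given step, then a
    right-aligned tile whenever the last residue is still uncovered."""
    if length <= width:
        return [1]
    starts = []
    s = 1
    while s + width - 1 <= length:
        starts.append(s)
        s += step
    if starts[-1] + width - 1 < length:
        starts.append(length - width + 1)
    return starts


@st.composite
def missense_contexts(draw):
    length = draw(st.integers(min_value=20, max_value=120))
    protein = "".join(draw(st.sampled_from(pep.AA_ALPHABET))
                      for _ in range(length))
    position = draw(st.integers(min_value=1, max_value=length))
    ref = protein[position - 1]
    alt = draw(st.sampled_from([a for a in pep.AA_ALPHABET if a != ref]))
    return MutantContext(gene="G1", protein=protein, position=position,
                         ref_aa=ref, alt_aa=alt)


class TestMissensePair:
    def test_short_protein_centered_variant(self):
        ctx = MutantContext(gene="G1", protein="ACDEFGHIKLMNPQRSTVWY",
                            position=6, ref_aa="G", alt_aa="W")
        mut, wt = pep.design_missense_pair(ctx, offset=6)
        assert mut.sequence == "ACDEFWHIKLMNPQRSTVWY"
        assert wt.sequence == "ACDEFGHIKLMNPQRSTVWY"
        assert mut.mut_index == 6

    def test_offset_15_interior(self):
        protein = "A" * 19 + "G" + "C" * 20  # variant at position 20
        ctx = MutantContext(gene="G1", protein=protein, position=20,
                            ref_aa="G", alt_aa="W")
        mut, wt = pep.design_missense_pair(ctx, offset=15)
        # window covers protein positions 6-25
        assert wt.sequence == protein[5:25]
        assert mut.mut_index == 15
        assert mut.sequence[14] == "W"

    def test_left_clamp_near_terminus(self):
        protein = "AC" + "G" + "D" * 27  # variant at position 3, 30 aa
        ctx = MutantContext(gene="G1", protein=protein, position=3,
                            ref_aa="G", alt_aa="W")
        mut, wt = pep.design_missense_pair(ctx, offset=6)
        # leftmost 20-window containing position 3 is 1..20
        assert wt.sequence == protein[:20]
        assert mut.mut_index == 3

    def test_identical_residues_rejected(self):
        with pytest.raises(ValueError):
            MutantContext(gene="G1", protein="ACDEFGHIKLMNPQRSTVWY",
                          position=3, ref_aa="D", alt_aa="D")

    @given(ctx=missense_contexts(), offset=st.sampled_from([6, 15]))
    @settings(max_examples=200, derandomize=True)
    def test_pair_differs_at_exactly_mut_index(self, ctx, offset):
        mut, wt = pep.design_missense_pair(ctx, offset)
        assert len(mut.sequence) == len(wt.sequence) <= 20
        diffs = [i for i, (a, b) in enumerate(zip(mut.sequence, wt.sequence), 1)
                 if a != b]
        assert diffs == [mut.mut_index]
        assert mut.sequence[mut.mut_index - 1] == ctx.alt_aa
        assert wt.sequence[wt.mut_index - 1] == ctx.ref_aa
        assert wt.sequence in ctx.protein  # WT peptide is a true substring


class TestFrameshiftTiles:
    def make_fs(self, native_before, tail_len):
        protein = "A" * native_before + "G" * 10
        pos = native_before + 1
        tail = "W" * tail_len
        return MutantContext(gene="G1", protein=protein, position=pos,
                             novel_tail=tail)

    @pytest.mark.parametrize("region_len, step, expected_starts", [
        (35, 10, [1, 11, 16]),
        (20, 10, [1]),
        (76, 10, [1, 11, 21, 31, 41, 51, 57]),
        (19, 10, [1]),
    ])
    def test_tile_starts_frozen_examples(self, region_len, step, expected_starts):
        assert pep.tile_starts(region_len, step) == expected_starts
        assert brute_force_tile_starts(region_len, step) == expected_starts

    @given(length=st.integers(min_value=1, max_value=300),
           step=st.integers(min_value=1, max_value=20))
    @settings(max_examples=200, derandomize=True)
    def test_tile_starts_match_oracle_and_cover(self, length, step):
        starts = pep.tile_starts(length, step)
        assert starts == brute_force_tile_starts(length, step)
        width = min(20, length)
        covered = set()
        for s in starts:
            covered |= set(range(s, s + width))
        assert covered >= set(range(1, length + 1))

    def test_novel_tail_fully_covered(self):
        ctx = self.make_fs(native_before=30, tail_len=57)
        tiles = pep.design_frameshift_tiles(ctx, upstream_flank=15, step=10)
        region = ctx.protein[15:30] + ctx.novel_tail  # the tiled region
        starts = pep.tile_starts(len(region), 10)
        covered = set()
        for t, s in zip(tiles, starts):
            assert t.sequence == region[s - 1: s - 1 + 20]
            covered |= set(range(s, s + len(t.sequence)))
        tail_interval = set(range(16, 16 + 57))  # 1-based tail residues
        assert covered >= tail_interval
        assert all(len(t.sequence) == 20 for t in tiles)

    def test_short_region_single_peptide(self):
        ctx = self.make_fs(native_before=3, tail_len=5)
        tiles = pep.design_frameshift_tiles(ctx, upstream_flank=15, step=10)
        assert len(tiles) == 1
        assert tiles[0].sequence == ctx.protein[:3] + ctx.novel_tail


class TestAssignPools:
    def peptides(self, gene, n):
        return [pep.LongPeptide(id=f"{gene}_{i}", sequence="ACDEFGHIKL",
                                gene=gene, is_mut=True) for i in range(n)]

    def test_auto_pools_per_gene(self):
        out = pep.assign_pools(self.peptides("G1", 2) + self.peptides("G2", 3),
                               "auto")
        pools = {p.gene: p.pool_id for p in out}
        assert len({p.pool_id for p in out}) == 2
        assert pools["G1"] != pools["G2"]

    def test_plan_mismatch_names_gene(self):
        with pytest.raises(ValueError, match="G1"):
            pep.assign_pools(self.peptides("G1", 3), {"G1": [2, 2]})

    def test_study_pool_census(self):
        # 12 genes with 2 peptides, 3 with 3, 1 with 4, 1 with 8
        peptides = []
        sizes = [2] * 12 + [3] * 3 + [4] + [8]
        for i, n in enumerate(sizes):
            peptides.extend(self.peptides(f"G{i}", n))
        out = pep.assign_pools(peptides, "auto")
        assert len(out) == 12 * 2 + 3 * 3 + 4 + 8 == 45
        pool_sizes = {}
        for p in out:
            pool_sizes[p.pool_id] = pool_sizes.get(p.pool_id, 0) + 1
        assert sorted(pool_sizes.values()) == sorted(sizes)
        assert len(pool_sizes) == 17
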