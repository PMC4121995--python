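"""Hairpin folding, window excision and novel-candidate calling."""

from __future__ import annotations

import numpy as np
import pytest

from srnapipe._energy import STACK, hairpin_energy
from srnapipe.annotate import GenomeHit
from srnapipe.novel import (
    FoldResult,
    call_novel,
    excise_windows,
    fold_mfe,
)
from srnapipe.preprocess import revcomp

from _oracles import fold_bruteforce, structure_energy

BASES = np.array(list("ACGU"))


def rand_rna(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestFoldMfe:
    def test_unpairable_sequence_is_all_dots(self):
        r = fold_mfe("A" * 15)
        assert r.structure == "." * 15
        assert r.mfe == 0.0

    def test_perfect_stem_with_tetraloop(self):
        r = fold_mfe("GGGGGGGGGG" + "AAAA" + "CCCCCCCCCC")
        e, npairs = fold_bruteforce(r.sequence)
        assert r.mfe == pytest.approx(e, abs=1e-9)
        assert r.n_pairs == npairs
        # closed form: 9 GC/GC stacks + minimal hairpin loop
        assert r.mfe == pytest.approx(9 * STACK[("GC", "GC")] + hairpin_energy(4))

    def test_mfe_never_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert fold_mfe(rand_rna(rng, int(rng.integers(10, 40)))).mfe <= 0.0

    def test_structure_well_formed(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = fold_mfe(rand_rna(rng, int(rng.integers(10, 60))))
            assert len(r.structure) == len(r.sequence)
            depth = 0
            for c in r.structure:
                assert c in "()."
                depth += {"(": 1, ")": -1, ".": 0}[c]
                assert depth >= 0
            assert depth == 0
            assert (r.mfe == 0.0) == (r.structure == "." * len(r.sequence))

    def test_dp_equals_enumeration_small(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            seq = rand_rna(rng, int(rng.integers(10, 19)))
            r = fold_mfe(seq)
            e, npairs = fold_bruteforce(seq)
            assert r.mfe == pytest.approx(e, abs=1e-9), seq
            assert r.n_pairs == npairs, seq
            # the reported structure evaluates to the reported energy
            pairs = [(i, j) for i, j in r.pair_table().items() if i < j]
            assert structure_energy(seq, pairs, 15) == pytest.approx(r.mfe, abs=1e-9)

    def test_revcomp_oracle_equivalence(self):
        rng = np.random.default_rng(3)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(15):
            seq = rand_rna(rng, int(rng.integers(10, 19)))
            rc = "".join(comp[b] for b in reversed(seq))
            r = fold_mfe(rc)
            e, npairs = fold_bruteforce(rc)
            assert r.mfe == pytest.approx(e, abs=1e-9)

    def test_stem_extension_monotone(self):
        # appending a closing complementary pair to a perfect stem never
        # raises the MFE
        prev = 0.0
        for k in range(4, 20):
            seq = "G" * k + "AAAA" + "C" * k
            mfe = fold_mfe(seq).mfe
            assert mfe <= prev + 1e-12
            prev = mfe

    def test_determinism(self):
        rng = np.random.default_rng(4)
        seq = rand_rna(rng, 80)
        r1, r2 = fold_mfe(seq), fold_mfe(seq)
        assert r1 == r2

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGUNACGUACGU")

    def test_length_limits(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGUA")
        with pytest.raises(ValueError):
            fold_mfe("A" * 301)

    def test_accepts_dna_input(self):
        assert fold_mfe("GGGGGGGGGGTTTTCCCCCCCCCC").sequence.count("T") == 0


class TestExciseWindows:
    def test_plus_strand_window(self):
        genome = {"chr1": "A" * 2000}
        tag = "A" * 22
        hits = {tag: [GenomeHit("chr1", 1000, 1022, "+")]}
        (w,) = excise_windows(hits, genome, flank=70)
        assert (w.start, w.end) == (930, 1092)
        assert w.sequence[w.tag_offset : w.tag_offset + 22] == tag

    def test_clipped_at_chromosome_start(self):
        genome = {"chr1": "A" * 2000}
        tag = "A" * 22
        hits = {tag: [GenomeHit("chr1", 10, 32, "+")]}
        (w,) = excise_windows(hits, genome, flank=70)
        assert w.start == 0
        assert w.tag_offset == 10

    def test_minus_strand_oriented_to_sense(self):
        rng = np.random.default_rng(5)
        g = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        genome = {"chr1": g}
        tag = revcomp(g[100:122])
        hits = {tag: [GenomeHit("chr1", 100, 122, "-")]}
        (w,) = excise_windows(hits, genome, flank=30)
        assert w.sequence[w.tag_offset : w.tag_offset + 22] == tag

    def test_window_contains_planted_precursor(self, small_dataset):
        refs = small_dataset["refs"]
        genome = refs.genome
        for nid, (chrom, start, end, strand) in refs.novel_loci.items():
            mature = refs.novel_matures[nid]
            prec = refs.novel_precursors[nid]
            gseq = genome[chrom][start:end]
            if strand == "+":
                pos = start + gseq.find(mature)
                hit = GenomeHit(chrom, pos, pos + len(mature), "+")
            else:
                pos = start + gseq.find(revcomp(mature))
                hit = GenomeHit(chrom, pos, pos + len(mature), "-")
            (w,) = excise_windows({mature: [hit]}, genome, flank=70)
            assert prec in w.sequence


def _hairpin_window(rng):
    """A window whose center is a strong planted hairpin, tag on the 5' arm."""
    from srnapipe.novel import PrecursorWindow

    arm = "".join(np.array(list("ACGT"))[rng.choice(4, 22, p=[0.2, 0.3, 0.3, 0.2])])
    hp = arm + "ATTTAATTTAAT" + revcomp(arm)
    flank_l = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
    flank_r = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
    seq = flank_l + hp + flank_r
    return PrecursorWindow(
        tag=arm,
        chrom="chr1",
        start=0,
        end=len(seq),
        strand="+",
        sequence=seq,
        tag_offset=30,
    )


class TestCallNovel:
    def test_mfe_boundary_strict(self):
        rng = np.random.default_rng(6)
        w = _hairpin_window(rng)

        def fake_fold(seq):
            real = fold_mfe(seq)
            return FoldResult(real.sequence, real.structure, -19.9, real.n_pairs)

        passing, rejected = call_novel(
            [w], {w.tag: 10.0}, {w.tag: 10.0}, fold_fn=fake_fold
        )
        assert passing == []
        assert rejected[0].mfe_pass is False

    def test_expression_floor(self):
        rng = np.random.default_rng(7)
        w = _hairpin_window(rng)
        passing, rejected = call_novel([w], {w.tag: 0.5}, {w.tag: 5.0})
        assert passing == []
        assert rejected[0].expression_pass is False
        assert rejected[0].fold is None  # folding skipped

    def test_good_hairpin_passes(self):
        rng = np.random.default_rng(8)
        w = _hairpin_window(rng)
        passing, rejected = call_novel([w], {w.tag: 10.0}, {w.tag: 10.0})
        assert len(passing) == 1
        cand = passing[0]
        assert cand.passed and cand.arm == "5p"
        assert cand.fold.mfe < -20.0

    def test_filters_are_the_only_gate(self):
        # with mfe_max=0 and tpm_min=0 every hairpin-shaped window passes
        from dataclasses import replace

        rng = np.random.default_rng(9)
        windows = [
            replace(_hairpin_window(rng), start=200 * i, end=200 * i + 116)
            for i in range(5)
        ]
        passing, rejected = call_novel(
            windows, {}, {}, mfe_max=0.0, tpm_min=0.0
        )
        assert len(passing) == len(windows)

    def test_overlapping_loci_collapsed_to_lowest_mfe(self):
        rng = np.random.default_rng(10)
        from dataclasses import replace

        w1 = _hairpin_window(rng)
        w2 = _hairpin_window(rng)
        w2 = replace(w2, start=w1.start + 10, end=w1.end + 10)
        passing, _ = call_novel(
            [w1, w2], {w1.tag: 9.0, w2.tag: 9.0}, {w1.tag: 9.0, w2.tag: 9.0}
        )
        assert len(passing) == 1
        e1 = fold_mfe(w1.sequence).mfe
        e2 = fold_mfe(w2.sequence).mfe
        assert passing[0].fold.mfe == min(e1, e2)

    def test_planted_hairpins_recovered(self, small_dataset):
        refs = small_dataset["refs"]
        from srnapipe.annotate import map_tags
        from srnapipe.preprocess import TagLibrary

        tags = {m: 1 for m in refs.novel_matures.values()}
        hits, _ = map_tags(TagLibrary("x", tags), refs.genome)
        windows = excise_windows(hits, refs.genome, flank=70)
        tpms = {m: 10.0 for m in tags}
        passing, _ = call_novel(windows, tpms, tpms)
        recovered = {c.window.tag for c in passing}
        assert recovered == set(refs.novel_matures.values())
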