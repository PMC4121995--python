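"""Genome mapping, priority-rule annotation and QC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from srnapipe.annotate import (
    Feature,
    GenomeHit,
    NcRNARecord,
    annotate_tags,
    chrom_distribution,
    map_tags,
    quantify_known_mirna,
    rrna_qc,
    AnnotatedTag,
)
from srnapipe.preprocess import TagLibrary, revcomp

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestMapTags:
    def test_forward_hit(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": rand_seq(rng, 500)}
        tag = genome["chr1"][100:122]
        lib = TagLibrary("x", {tag: 1})
        hits, frac = map_tags(lib, genome)
        assert GenomeHit("chr1", 100, 122, "+") in hits[tag]
        assert frac["unique"] == 1.0

    def test_reverse_hit(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": rand_seq(rng, 500)}
        tag = revcomp(genome["chr1"][50:72])
        hits, _ = map_tags(TagLibrary("x", {tag: 1}), genome)
        assert GenomeHit("chr1", 50, 72, "-") in hits[tag]

    def test_absent_tag_unmapped(self):
        genome = {"chr1": "ACGT" * 100}
        tag = "T" * 22  # poly-T never occurs in an ACGT repeat
        hits, frac = map_tags(TagLibrary("x", {tag: 1}), genome)
        assert hits[tag] == []
        assert frac["unique"] == 0.0

    def test_agrees_with_naive_scan(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": rand_seq(rng, 5000)}
        g = genome["chr1"]
        tags = [g[i : i + 20] for i in (0, 100, 4980)] + [
            revcomp(g[7:27]),
            rand_seq(rng, 20),
        ]
        lib = TagLibrary("x", {t: 1 for t in tags})
        hits, _ = map_tags(lib, genome)
        for tag in tags:
            expect = []
            rc = revcomp(tag)
            for i in range(len(g) - len(tag) + 1):
                if g[i : i + len(tag)] == tag:
                    expect.append(GenomeHit("chr1", i, i + len(tag), "+"))
            for i in range(len(g) - len(tag) + 1):
                if g[i : i + len(tag)] == rc:
                    expect.append(GenomeHit("chr1", i, i + len(tag), "-"))
            assert sorted(hits[tag], key=str) == sorted(expect, key=str)

    def test_genome_shorter_than_tag(self):
        hits, _ = map_tags(TagLibrary("x", {"A" * 22: 1}), {"chr1": "AAAA"})
        assert hits["A" * 22] == []

    def test_one_mismatch(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": rand_seq(rng, 300)}
        site = genome["chr1"][40:62]
        tag = site[:10] + ("A" if site[10] != "A" else "C") + site[11:]
        hits0, _ = map_tags(TagLibrary("x", {tag: 1}), genome, max_mismatch=0)
        hits1, _ = map_tags(TagLibrary("x", {tag: 1}), genome, max_mismatch=1)
        assert all(h.start != 40 for h in hits0[tag])
        assert any(h.start == 40 and h.strand == "+" for h in hits1[tag])

    def test_invalid_mismatch_budget(self):
        with pytest.raises(ValueError):
            map_tags(TagLibrary("x", {}), {"chr1": "ACGT"}, max_mismatch=3)


def _toy_refs():
    rng = np.random.default_rng(10)
    rrna = rand_seq(rng, 120)
    trna = rand_seq(rng, 90)
    prec = rand_seq(rng, 60)
    mature = prec[5:27]
    ncrna = [
        NcRNARecord("rrna1", "rRNA", "genbank", rrna),
        NcRNARecord("trna1", "tRNA", "rfam", trna),
    ]
    return rng, rrna, trna, prec, mature, ncrna


class TestPriorityRule:
    def test_rrna_beats_known_mirna(self):
        rng, rrna, trna, prec, mature, ncrna = _toy_refs()
        # a tag present in both an rRNA reference and a mature miRNA
        shared = rrna[10:32]
        matures = {"mir-x-5p": shared}
        lib = TagLibrary("x", {shared: 1})
        annotated, summary = annotate_tags(lib, ncrna, {}, matures, [], {})
        assert annotated[0].category == "rRNA"
        assert annotated[0].source == "genbank"

    def test_genbank_outranks_rfam(self):
        rng, rrna, trna, prec, mature, _ = _toy_refs()
        shared = rrna[0:22]
        ncrna = [
            NcRNARecord("a_rfam", "rRNA", "rfam", rrna),
            NcRNARecord("b_genbank", "tRNA", "genbank", "X" * 30 + shared),
        ]
        annotated, _ = annotate_tags(
            TagLibrary("x", {shared: 1}), ncrna, {}, {}, [], {}
        )
        # the GenBank tRNA match wins over the Rfam rRNA match
        assert annotated[0].category == "tRNA"
        assert annotated[0].source == "genbank"

    def test_mirna_beats_repeat(self):
        rng, rrna, trna, prec, mature, ncrna = _toy_refs()
        feats = [Feature("chr1", 0, 1000, "+", "repeat")]
        hits = {mature: [GenomeHit("chr1", 10, 32, "+")]}
        annotated, _ = annotate_tags(
            TagLibrary("x", {mature: 1}), [], {"p": prec}, {"m": mature}, feats, hits
        )
        assert annotated[0].category == "known_miRNA"

    def test_exon_antisense(self):
        tag = "ACGT" * 5 + "AC"
        feats = [Feature("chr1", 0, 1000, "-", "exon")]
        hits = {tag: [GenomeHit("chr1", 10, 32, "+")]}
        annotated, _ = annotate_tags(
            TagLibrary("x", {tag: 1}), [], {}, {}, feats, hits
        )
        assert annotated[0].category == "exon_antisense"

    def test_exon_sense_preferred_over_antisense(self):
        tag = "ACGT" * 5 + "AC"
        feats = [
            Feature("chr1", 0, 100, "-", "exon"),
            Feature("chr2", 0, 100, "+", "exon"),
        ]
        hits = {
            tag: [
                GenomeHit("chr1", 10, 32, "+"),
                GenomeHit("chr2", 10, 32, "+"),
            ]
        }
        annotated, _ = annotate_tags(TagLibrary("x", {tag: 1}), [], {}, {}, feats, hits)
        assert annotated[0].category == "exon_sense"

    def test_unknown_category_label_fails(self):
        bad = [NcRNARecord("x", "lncRNA", "genbank", "ACGT" * 10)]
        with pytest.raises(ValueError, match="lncRNA"):
            annotate_tags(TagLibrary("x", {}), bad, {}, {}, [], {})

    def test_matches_bruteforce_priority_oracle(self):
        rng, rrna, trna, prec, mature, ncrna = _toy_refs()
        repeat = Feature("chr1", 200, 260, "+", "repeat")
        exon = Feature("chr1", 300, 360, "+", "exon")
        intron = Feature("chr1", 400, 460, "-", "intron")
        feats = [repeat, exon, intron]
        tags = {
            rrna[4:26]: [GenomeHit("chr1", 210, 232, "+")],  # rRNA + repeat
            trna[0:22]: [],
            mature: [GenomeHit("chr1", 310, 332, "+")],  # miRNA + exon
            rand_seq(rng, 22): [GenomeHit("chr1", 205, 227, "+")],  # repeat
            rand_seq(rng, 22): [GenomeHit("chr1", 310, 332, "+")],  # exon sense
            rand_seq(rng, 22): [GenomeHit("chr1", 310, 332, "-")],  # exon anti
            rand_seq(rng, 22): [GenomeHit("chr1", 410, 432, "-")],  # intron sense
            rand_seq(rng, 22): [GenomeHit("chr1", 410, 432, "+")],  # intron anti
            rand_seq(rng, 22): [GenomeHit("chr1", 500, 522, "+")],  # nothing
            rand_seq(rng, 22): [],  # unmapped
        }
        lib = TagLibrary("x", {t: 1 for t in tags})
        annotated, summary = annotate_tags(
            lib, ncrna, {"p": prec}, {"m": mature}, feats, tags
        )

        def oracle(tag):
            for rec in ncrna:
                if rec.source == "genbank" and tag in rec.sequence:
                    return rec.cls
            for rec in ncrna:
                if rec.source == "rfam" and tag in rec.sequence:
                    return rec.cls
            if tag in mature or tag in prec:
                return "known_miRNA"
            hs = tags[tag]
            for kind, f in (("repeat", repeat), ("exon", exon), ("intron", intron)):
                for h in hs:
                    if h.chrom == f.chrom and h.start < f.end and f.start < h.end:
                        if kind == "repeat":
                            return "repeat"
                        return f"{kind}_{'sense' if h.strand == f.strand else 'antisense'}"
            return "unannotated"

        for at in annotated:
            assert at.category == oracle(at.sequence), at.sequence

        # partition invariant
        assert summary["unique"].sum() == lib.n_unique
        assert summary["total"].sum() == lib.total_clean

    def test_reannotation_is_idempotent(self):
        rng, rrna, trna, prec, mature, ncrna = _toy_refs()
        lib = TagLibrary("x", {mature: 3, rrna[0:22]: 2})
        a1, _ = annotate_tags(lib, ncrna, {"p": prec}, {"m": mature}, [], {})
        a2, _ = annotate_tags(lib, ncrna, {"p": prec}, {"m": mature}, [], {})
        assert [(x.sequence, x.category) for x in a1] == [
            (x.sequence, x.category) for x in a2
        ]


class TestRrnaQC:
    def _summary(self, rrna_total, grand_total):
        s = pd.DataFrame(
            0, index=["rRNA", "unannotated"], columns=["unique", "total"]
        )
        s.loc["rRNA", "total"] = rrna_total
        s.loc["unannotated", "total"] = grand_total - rrna_total
        return s

    def test_just_below_threshold_passes(self):
        assert rrna_qc(self._summary(399, 1000)).passed

    def test_at_threshold_fails(self):
        v = rrna_qc(self._summary(400, 1000))
        assert not v.passed and v.verdict == "FAIL"

    def test_zero_passes(self):
        assert rrna_qc(self._summary(0, 1000)).passed

    def test_empty_fails_loudly(self):
        with pytest.raises(ValueError):
            rrna_qc(self._summary(0, 0))


class TestQuantifyKnownMirna:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.arm5 = rand_seq(rng, 22)
        self.loop = rand_seq(rng, 12)
        self.arm3 = revcomp(self.arm5)
        self.prec = self.arm5 + self.loop + self.arm3
        self.matures = {"mir-1-5p": self.arm5}
        self.precursors = {"mir-1": self.prec}
        self.mature_of = {"mir-1-5p": "mir-1"}

    def test_exact_mature_counts(self):
        lib = TagLibrary("x", {self.arm5: 7})
        table, arms = quantify_known_mirna(
            lib, self.precursors, self.matures, self.mature_of
        )
        assert table.loc["mir-1-5p", "count"] == 7
        assert arms == {"5p": 1, "3p": 0}

    def test_loop_only_tag_not_counted(self):
        # 18 nt entirely in loop+3' arm, overlapping mature by 0
        tag = self.prec[24:42]
        lib = TagLibrary("x", {tag: 5})
        table, _ = quantify_known_mirna(
            lib, self.precursors, self.matures, self.mature_of
        )
        assert table.loc["mir-1-5p", "count"] == 0
        assert table.loc["mir-1-5p", "precursor_count"] == 5

    def test_overlap_rule(self):
        # tag overlapping the mature by exactly 16 nt counts
        tag = self.prec[6:28]
        lib = TagLibrary("x", {tag: 2})
        table, _ = quantify_known_mirna(
            lib, self.precursors, self.matures, self.mature_of
        )
        assert table.loc["mir-1-5p", "count"] == 2

    def test_mature_not_in_precursor_fails(self):
        with pytest.raises(ValueError, match="not found"):
            quantify_known_mirna(
                TagLibrary("x", {}),
                {"mir-1": "ACGT" * 20},
                {"mir-1-5p": "T" * 22},
                {"mir-1-5p": "mir-1"},
            )


class TestChromDistribution:
    def test_single_hit(self):
        at = AnnotatedTag("A" * 20, 1, [GenomeHit("chr1", 5, 25, "+")], "unannotated", "none")
        df = chrom_distribution([at])
        row = df[(df.chrom == "chr1") & (df.strand == "+")].iloc[0]
        assert row["unique"] == 1 and row["total"] == 1

    def test_multi_hit_counts_every_hit(self):
        at = AnnotatedTag(
            "A" * 20,
            3,
            [GenomeHit("chr1", 5, 25, "+"), GenomeHit("chr2", 9, 29, "-")],
            "unannotated",
            "none",
        )
        df = chrom_distribution([at]).set_index(["chrom", "strand"])
        assert df.loc[("chr1", "+"), "total"] == 3
        assert df.loc[("chr2", "-"), "total"] == 3

    def test_hand_tally(self):
        rng = np.random.default_rng(8)
        ats = []
        expect: dict[tuple[str, str], list[int]] = {}
        for i in range(20):
            nh = int(rng.integers(0, 3))
            hits = []
            for _ in range(nh):
                chrom = f"chr{int(rng.integers(1, 3))}"
                strand = "+-"[int(rng.integers(0, 2))]
                hits.append(GenomeHit(chrom, 0, 20, strand))
                cell = expect.setdefault((chrom, strand), [0, 0])
                cell[0] += 1
                cell[1] += i + 1
            ats.append(AnnotatedTag(f"tag{i}", i + 1, hits, "unannotated", "none"))
        df = chrom_distribution(ats).set_index(["chrom", "strand"])
        for (chrom, strand), (u, t) in expect.items():
            assert df.loc[(chrom, strand), "unique"] == u
            assert df.loc[(chrom, strand), "total"] == t
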