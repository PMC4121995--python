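"""Genome mapping and priority-rule annotation of collapsed tags.

Every tag receives exactly one category, resolved by a fixed precedence:
the rRNA-class ncRNAs (rRNA/scRNA/snRNA/snoRNA/tRNA, GenBank source before
Rfam) outrank known miRNAs, which outrank repeats, then exons, then
introns; anything else is unannotated.  Exon and intron assignments are
split sense/antisense by strand agreement between the genome hit and the
annotated feature.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import TagLibrary, revcomp

__all__ = [
    "GenomeHit",
    "Feature",
    "NcRNARecord",
    "AnnotatedTag",
    "map_tags",
    "annotate_tags",
    "rrna_qc",
    "quantify_known_mirna",
    "chrom_distribution",
]

#: ncRNA classes forming the top-priority group, in tie-break order.
NCRNA_CLASSES = ("rRNA", "scRNA", "snRNA", "snoRNA", "tRNA")

CATEGORIES = NCRNA_CLASSES + (
    "known_miRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
)


@dataclass(frozen=True)
class GenomeHit:
    chrom: str
    start: int  #: 0-based half-open
    end: int
    strand: str  #: '+' or '-'


@dataclass(frozen=True)
class Feature:
    """A repeat/exon/intron interval (0-based half-open internally)."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str  #: 'repeat', 'exon' or 'intron'


@dataclass(frozen=True)
class NcRNARecord:
    name: str
    cls: str  #: one of NCRNA_CLASSES
    source: str  #: 'genbank' or 'rfam'
    sequence: str  #: DNA alphabet


@dataclass
class AnnotatedTag:
    sequence: str
    count: int
    hits: list[GenomeHit]
    category: str
    source: str  #: 'genbank', 'rfam', 'mirbase', 'interval' or 'none'


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def _find_mismatch(chrom_seq: np.ndarray, tag: str, max_mismatch: int) -> list[int]:
    arr = np.frombuffer(tag.encode(), dtype=np.uint8)
    L = len(tag)
    n = chrom_seq.size - L + 1
    if n <= 0:
        return []
    mism = np.zeros(n, dtype=np.int32)
    for k in range(L):
        mism += chrom_seq[k : k + n] != arr[k]
    return np.nonzero(mism <= max_mismatch)[0].tolist()


def map_tags(
    lib: TagLibrary,
    genome: Mapping[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[GenomeHit]], dict[str, float]]:
    """Find all genomic occurrences of every tag on both strands.

    Minus-strand hits are located by searching the reverse complement of
    the tag; coordinates are always on the forward reference.  Returns the
    hit map and mapped fractions (unique- and count-weighted).
    """
    if not 0 <= max_mismatch <= 2:
        raise ValueError("max_mismatch must be within [0, 2]")
    chrom_arrays = (
        {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.items()}
        if max_mismatch > 0
        else {}
    )
    hits: dict[str, list[GenomeHit]] = {}
    n_mapped_unique = 0
    n_mapped_total = 0
    for tag in sorted(lib.tags):
        tag_hits: list[GenomeHit] = []
        rc = revcomp(tag)
        for chrom in sorted(genome):
            seq = genome[chrom]
            if max_mismatch == 0:
                fwd = _find_all(seq, tag)
                rev = _find_all(seq, rc)
            else:
                fwd = _find_mismatch(chrom_arrays[chrom], tag, max_mismatch)
                rev = _find_mismatch(chrom_arrays[chrom], rc, max_mismatch)
            for p in fwd:
                tag_hits.append(GenomeHit(chrom, p, p + len(tag), "+"))
            for p in rev:
                tag_hits.append(GenomeHit(chrom, p, p + len(tag), "-"))
        hits[tag] = tag_hits
        if tag_hits:
            n_mapped_unique += 1
            n_mapped_total += lib.tags[tag]
    fractions = {
        "unique": n_mapped_unique / lib.n_unique if lib.n_unique else 0.0,
        "total": n_mapped_total / lib.total_clean if lib.total_clean else 0.0,
    }
    return hits, fractions


def _overlaps(hit: GenomeHit, feat: Feature) -> bool:
    return (
        hit.chrom == feat.chrom and hit.start < feat.end and feat.start < hit.end
    )


def annotate_tags(
    lib: TagLibrary,
    ncrna: Sequence[NcRNARecord],
    precursors: Mapping[str, str],
    matures: Mapping[str, str],
    features: Sequence[Feature],
    hits: Mapping[str, list[GenomeHit]],
) -> tuple[list[AnnotatedTag], pd.DataFrame]:
    """Resolve every tag to one category by the priority rule.

    Returns the annotated tags and a category summary with per-category
    unique/total counts that partition the library exactly.
    """
    for rec in ncrna:
        if rec.cls not in NCRNA_CLASSES:
            raise ValueError(f"unknown ncRNA class {rec.cls!r} in {rec.name}")
        if rec.source not in ("genbank", "rfam"):
            raise ValueError(f"unknown ncRNA source {rec.source!r} in {rec.name}")

    cls_rank = {c: i for i, c in enumerate(NCRNA_CLASSES)}
    ncrna_sorted = sorted(
        ncrna, key=lambda r: (0 if r.source == "genbank" else 1, cls_rank[r.cls], r.name)
    )
    feats_by_kind: dict[str, list[Feature]] = defaultdict(list)
    for f in features:
        if f.kind not in ("repeat", "exon", "intron"):
            raise ValueError(f"unknown feature kind {f.kind!r}")
        feats_by_kind[f.kind].append(f)

    annotated: list[AnnotatedTag] = []
    for tag in sorted(lib.tags):
        count = lib.tags[tag]
        tag_hits = list(hits.get(tag, []))
        category, source = _resolve(
            tag, tag_hits, ncrna_sorted, precursors, matures, feats_by_kind
        )
        annotated.append(AnnotatedTag(tag, count, tag_hits, category, source))

    summary = pd.DataFrame(
        0, index=list(CATEGORIES), columns=["unique", "total"], dtype=int
    )
    for at in annotated:
        summary.loc[at.category, "unique"] += 1
        summary.loc[at.category, "total"] += at.count
    summary.index.name = "category"
    return annotated, summary


def _resolve(
    tag: str,
    tag_hits: list[GenomeHit],
    ncrna_sorted: Sequence[NcRNARecord],
    precursors: Mapping[str, str],
    matures: Mapping[str, str],
    feats_by_kind: Mapping[str, list[Feature]],
) -> tuple[str, str]:
    # 1. rRNA-class ncRNA, GenBank before Rfam (exact sense substring)
    for rec in ncrna_sorted:
        if tag in rec.sequence:
            return rec.cls, rec.source
    # 2. known miRNA (mature or precursor, exact sense substring)
    for seqs in (matures, precursors):
        for _mid in sorted(seqs):
            if tag in seqs[_mid]:
                return "known_miRNA", "mirbase"
    # 3-5. repeat > exon > intron via genome-hit interval overlap
    for hit in tag_hits:
        for f in feats_by_kind.get("repeat", ()):
            if _overlaps(hit, f):
                return "repeat", "interval"
    for kind in ("exon", "intron"):
        sense = False
        antisense = False
        for hit in tag_hits:
            for f in feats_by_kind.get(kind, ()):
                if _overlaps(hit, f):
                    if hit.strand == f.strand:
                        sense = True
                    else:
                        antisense = True
        if sense:
            return f"{kind}_sense", "interval"
        if antisense:
            return f"{kind}_antisense", "interval"
    return "unannotated", "none"


@dataclass(frozen=True)
class QCVerdict:
    ratio: float
    passed: bool

    @property
    def verdict(self) -> str:
        return "PASS" if self.passed else "FAIL"


def rrna_qc(summary: pd.DataFrame, total_clean: int | None = None) -> QCVerdict:
    """Sample quality mark: total-count rRNA ratio strictly below 40%."""
    if total_clean is None:
        total_clean = int(summary["total"].sum())
    if total_clean <= 0:
        raise ValueError("rrna_qc requires a non-empty summary")
    ratio = float(summary.loc["rRNA", "total"]) / total_clean
    return QCVerdict(ratio=ratio, passed=ratio < 0.40)


def quantify_known_mirna(
    lib: TagLibrary,
    precursors: Mapping[str, str],
    matures: Mapping[str, str],
    mature_of: Mapping[str, str],
    min_overlap: int = 16,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count tags per known mature miRNA.

    A tag counts toward a mature miRNA if it equals the mature sequence
    exactly, or lies within the precursor overlapping the mature region by
    at least *min_overlap* nt.  *mature_of* maps mature id -> precursor id.

    Returns a per-mature table (mature count, precursor count, detected)
    and arm tallies over detected ``-5p``/``-3p`` names.
    """
    mature_span: dict[str, tuple[str, int, int]] = {}
    for mid, mseq in matures.items():
        pid = mature_of[mid]
        pseq = precursors[pid]
        pos = pseq.find(mseq)
        if pos == -1:
            raise ValueError(f"mature {mid} not found in precursor {pid}")
        mature_span[mid] = (pid, pos, pos + len(mseq))

    mature_counts: dict[str, int] = dict.fromkeys(matures, 0)
    precursor_counts: dict[str, int] = dict.fromkeys(precursors, 0)
    for tag in sorted(lib.tags):
        count = lib.tags[tag]
        for mid in sorted(matures):
            pid, mstart, mend = mature_span[mid]
            if tag == matures[mid]:
                mature_counts[mid] += count
                continue
            pos = precursors[pid].find(tag)
            if pos != -1:
                ov = min(pos + len(tag), mend) - max(pos, mstart)
                if ov >= min_overlap:
                    mature_counts[mid] += count
        for pid in sorted(precursors):
            if tag in precursors[pid]:
                precursor_counts[pid] += count

    rows = []
    for mid in sorted(matures):
        pid = mature_of[mid]
        rows.append(
            {
                "mirna_id": mid,
                "precursor_id": pid,
                "count": mature_counts[mid],
                "precursor_count": precursor_counts[pid],
                "detected": mature_counts[mid] >= 1,
            }
        )
    table = pd.DataFrame(rows).set_index("mirna_id")
    arm_tallies = {
        "5p": sum(1 for mid in matures if mid.endswith("-5p") and mature_counts[mid] >= 1),
        "3p": sum(1 for mid in matures if mid.endswith("-3p") and mature_counts[mid] >= 1),
    }
    return table, arm_tallies


def chrom_distribution(annotated: Iterable[AnnotatedTag]) -> pd.DataFrame:
    """Per-(chromosome, strand) unique/total tag counts.

    Multi-hit tags contribute once per hit in this report (documented
    divergence from the one-category-per-tag summary).
    """
    cells: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for at in annotated:
        for hit in at.hits:
            cell = cells[(hit.chrom, hit.strand)]
            cell[0] += 1
            cell[1] += at.count
    rows = [
        {"chrom": c, "strand": s, "unique": u, "total": t}
        for (c, s), (u, t) in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "strand", "unique", "total"])
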