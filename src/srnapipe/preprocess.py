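"""Read cleaning, tag collapsing and library composition summaries.

Raw FASTQ reads are 3'-adapter-trimmed, quality- and length-filtered, then
collapsed into unique tags with counts.  All internal sequences use the DNA
alphabet (U is normalized to T); reports that present RNA convert at the
edge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

__all__ = [
    "FastqFormatError",
    "CleaningStats",
    "TagLibrary",
    "revcomp",
    "parse_fastq",
    "clean_reads",
    "collapse",
    "length_distribution",
    "base_composition",
    "library_overlap",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Raised on a malformed FASTQ record; the message names the record index."""


def parse_fastq(source: str | Path | TextIO) -> Iterator[tuple[str, str, str]]:
    """Yield ``(name, sequence, quality)`` from a FASTQ file or handle.

    Raises :class:`FastqFormatError` naming the (0-based) record index on a
    malformed record.
    """
    handle: TextIO
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        idx = 0
        while True:
            header = handle.readline()
            if not header:
                return
            if header.strip() == "" and not handle.readline():
                return
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise FastqFormatError(f"truncated FASTQ at record {idx}")
            header, seq, plus, qual = (
                header.rstrip("\n"),
                seq.rstrip("\n"),
                plus.rstrip("\n"),
                qual.rstrip("\n"),
            )
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"record {idx}: header does not start with '@'"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"record {idx}: separator line does not start with '+'"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {idx}: sequence and quality lengths differ"
                )
            yield header[1:].split()[0] if len(header) > 1 else "", seq, qual
            idx += 1
    finally:
        if close:
            handle.close()


@dataclass
class CleaningStats:
    """Exact partition of the input reads by fate."""

    n_input: int = 0
    n_kept: int = 0
    n_low_quality: int = 0
    n_adaptor_dimer: int = 0
    n_length: int = 0  #: insert shorter/longer than the retained range

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "kept": self.n_kept,
            "low_quality": self.n_low_quality,
            "adaptor_dimer": self.n_adaptor_dimer,
            "length": self.n_length,
        }

    def check_partition(self) -> bool:
        return (
            self.n_kept + self.n_low_quality + self.n_adaptor_dimer + self.n_length
            == self.n_input
        )


@dataclass
class TagLibrary:
    """Unique tags with counts for one library."""

    name: str
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def total_clean(self) -> int:
        return sum(self.tags.values())

    @property
    def n_unique(self) -> int:
        return len(self.tags)


def _trim_adapter(seq: str, adapter: str, min_overlap: int = 6) -> str | None:
    """Trim the 3' adapter by longest exact match; None when not found.

    A full internal occurrence wins (leftmost); otherwise the longest
    adapter prefix (>= *min_overlap*) matching the read's 3' end.
    """
    pos = seq.find(adapter)
    if pos != -1:
        return seq[:pos]
    max_k = min(len(adapter) - 1, len(seq))
    for k in range(max_k, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return None


def clean_reads(
    fastq: str | Path | TextIO | Iterable[tuple[str, str, str]],
    adapter: str,
    min_mean_q: float = 20.0,
    length_range: tuple[int, int] = (18, 30),
) -> tuple[list[str], CleaningStats]:
    """Quality-filter, adapter-trim and length-filter raw reads.

    Reads are processed in order: (1) mean Phred quality below *min_mean_q*
    -> ``low_quality``; (2) the 3' adapter is located by longest exact
    overlap (>= 6 nt) and trimmed — a zero-length insert is an
    ``adaptor_dimer``; reads without any adapter match keep their full
    sequence; (3) inserts outside *length_range* -> ``length``.

    Returns the kept inserts (DNA, uppercase) and a :class:`CleaningStats`
    that partitions the input exactly.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    lo, hi = length_range
    if lo < 15 or hi > 35 or lo > hi:
        raise ValueError(f"length range {length_range} outside supported [15, 35]")
    adapter = adapter.upper().replace("U", "T")

    if isinstance(fastq, (str, Path)) or hasattr(fastq, "readline"):
        records: Iterable[tuple[str, str, str]] = parse_fastq(fastq)  # type: ignore[arg-type]
    else:
        records = fastq

    stats = CleaningStats()
    kept: list[str] = []
    for _name, seq, qual in records:
        stats.n_input += 1
        if qual:
            mean_q = (sum(qual.encode("ascii")) / len(qual)) - 33.0
        else:
            mean_q = 0.0
        if mean_q < min_mean_q:
            stats.n_low_quality += 1
            continue
        seq = seq.upper().replace("U", "T")
        insert = _trim_adapter(seq, adapter)
        if insert is None:
            insert = seq
        if insert == "":
            stats.n_adaptor_dimer += 1
            continue
        if not lo <= len(insert) <= hi:
            stats.n_length += 1
            continue
        stats.n_kept += 1
        kept.append(insert)
    return kept, stats


def collapse(reads: Iterable[str], name: str = "library") -> TagLibrary:
    """Collapse cleaned reads into unique tags with counts."""
    counts = Counter(r.upper().replace("U", "T") for r in reads)
    return TagLibrary(name=name, tags=dict(counts))


def expand(lib: TagLibrary) -> list[str]:
    """Inverse of :func:`collapse` (read order is by sorted tag)."""
    out: list[str] = []
    for tag in sorted(lib.tags):
        out.extend([tag] * lib.tags[tag])
    return out


def length_distribution(lib: TagLibrary) -> pd.DataFrame:
    """Per-length unique and total tag counts, indexed by length."""
    rows: dict[int, list[int]] = {}
    for tag, count in lib.tags.items():
        cell = rows.setdefault(len(tag), [0, 0])
        cell[0] += 1
        cell[1] += count
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["unique", "total"]
    ).sort_index()
    df.index.name = "length"
    return df


def base_composition(lib: TagLibrary) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-base frequency by tag length, and per-position base frequency.

    Both tables are count-weighted and report the RNA alphabet (A/C/G/U);
    every row sums to 1.
    """
    if not lib.tags:
        raise ValueError("base_composition requires a non-empty library")
    bases = "ACGT"
    first: dict[int, dict[str, float]] = {}
    max_len = max(len(t) for t in lib.tags)
    pos_counts = [dict.fromkeys(bases, 0.0) for _ in range(max_len)]
    for tag, count in lib.tags.items():
        row = first.setdefault(len(tag), dict.fromkeys(bases, 0.0))
        row[tag[0]] += count
        for i, b in enumerate(tag):
            pos_counts[i][b] += count
    first_df = pd.DataFrame.from_dict(first, orient="index").sort_index()
    first_df = first_df.div(first_df.sum(axis=1), axis=0)
    pos_df = pd.DataFrame(pos_counts)
    pos_df = pos_df.div(pos_df.sum(axis=1), axis=0)
    pos_df.index.name = "position"
    first_df.index.name = "length"
    rename = {"T": "U"}
    return first_df.rename(columns=rename), pos_df.rename(columns=rename)


def library_overlap(a: TagLibrary, b: TagLibrary) -> dict[str, float]:
    """Shared/specific tag percentages between two libraries.

    Unique percentages are over the union of distinct sequences; total
    percentages are over the grand total of counts in both libraries.
    """
    if not a.tags or not b.tags:
        raise ValueError("library_overlap requires two non-empty libraries")
    sa, sb = set(a.tags), set(b.tags)
    shared = sa & sb
    union = sa | sb
    grand = a.total_clean + b.total_clean
    shared_counts = sum(a.tags[t] for t in shared) + sum(b.tags[t] for t in shared)
    a_only = sum(a.tags[t] for t in sa - sb)
    b_only = sum(b.tags[t] for t in sb - sa)
    return {
        "unique_common_pct": 100.0 * len(shared) / len(union),
        "total_common_pct": 100.0 * shared_counts / grand,
        f"unique_specific_pct_{a.name}": 100.0 * len(sa - sb) / len(union),
        f"unique_specific_pct_{b.name}": 100.0 * len(sb - sa) / len(union),
        f"total_specific_pct_{a.name}": 100.0 * a_only / grand,
        f"total_specific_pct_{b.name}": 100.0 * b_only / grand,
    }
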