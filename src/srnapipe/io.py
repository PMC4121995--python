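"""Plain-text readers/writers for the pipeline's reference formats.

FASTA and GFF3 are written/read with deterministic formatting so that a
fixed simulation seed yields byte-identical files.  ncRNA FASTA headers
carry ``class=`` and ``source=`` key-values; GFF3 intervals are 1-based
inclusive on disk and converted to 0-based half-open at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from .annotate import Feature, NcRNARecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_ncrna_fasta",
    "write_ncrna_fasta",
    "read_gff3",
    "write_gff3",
    "read_gene_terms",
    "write_gene_terms",
]

_WRAP = 70


def write_fasta(path: str | Path, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_ncrna_fasta(path: str | Path, records: Iterable[NcRNARecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name} class={rec.cls} source={rec.source}\n")
            for i in range(0, len(rec.sequence), _WRAP):
                fh.write(rec.sequence[i : i + _WRAP] + "\n")


def read_ncrna_fasta(path: str | Path) -> list[NcRNARecord]:
    records: list[NcRNARecord] = []
    name = cls = source = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            if cls is None or source is None:
                raise ValueError(f"ncRNA record {name} missing class=/source= header keys")
            records.append(NcRNARecord(name, cls, source, "".join(chunks)))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                name = fields[0]
                kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
                cls = kv.get("class")
                source = kv.get("source")
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return records


def write_gff3(path: str | Path, features: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            # 0-based half-open -> 1-based inclusive
            fh.write(
                f"{f.chrom}\tsrnapipe\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.kind}_{i + 1}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, kind, start, end, _score, strand = cols[:7]
            features.append(
                Feature(chrom, int(start) - 1, int(end), strand, kind)
            )
    return features


def write_gene_terms(path: str | Path, rows: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm_id\tterm_name\n")
        for gene, term_id, term_name in rows:
            fh.write(f"{gene}\t{term_id}\t{term_name}\n")


def read_gene_terms(path: str | Path) -> list[tuple[str, str, str]]:
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene"):
            raise ValueError("gene-term table must have a 'gene<TAB>term_id<TAB>term_name' header")
        for line in fh:
            if not line.strip():
                continue
            gene, term_id, term_name = line.rstrip("\n").split("\t")
            rows.append((gene, term_id, term_name))
    return rows
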