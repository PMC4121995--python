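"""Synthetic two-library small-RNA dataset with known ground truth.

Generates a random genome with planted known-miRNA precursors, novel
hairpins, ncRNA references and repeat/exon/intron intervals, then draws
two adapter-ligated FASTQ libraries (control and knockdown) as multinomial
samples over the planted sources.  Differentially expressed miRNAs are
planted at an exact expected-proportion ratio of ``2**log2fc`` between the
libraries; the imbalance is absorbed by the unannotated background
fraction so every other source keeps identical expected proportions.

All randomness is drawn from streams derived from the master seed (one
stream per library), so a fixed configuration reproduces byte-identical
outputs, and adding one library never perturbs the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .annotate import Feature, NcRNARecord
from .novel import fold_mfe
from .preprocess import revcomp
from . import io as sio

__all__ = [
    "SimulationConfig",
    "ReferenceBundle",
    "TruthManifest",
    "InfeasiblePackingError",
    "build_references",
    "simulate_libraries",
]

DEFAULT_FRACTIONS = {
    "miRNA": 0.35,
    "rRNA": 0.15,
    "tRNA": 0.05,
    "snRNA": 0.04,
    "snoRNA": 0.03,
    "scRNA": 0.03,
    "repeat": 0.05,
    "exon": 0.08,
    "intron": 0.07,
    "novel": 0.05,
    "random": 0.10,
}

_NCRNA_LENGTHS = {"rRNA": 300, "tRNA": 80, "snRNA": 120, "snoRNA": 100, "scRNA": 110}

# insert length distribution: 18..30 nt peaked at 22
_LENGTHS = np.arange(18, 31)
_LENGTH_W = np.array([1, 2, 5, 10, 20, 40, 20, 10, 5, 2, 1, 1, 1], dtype=float)
_LENGTH_P = _LENGTH_W / _LENGTH_W.sum()


class InfeasiblePackingError(ValueError):
    """Planted features do not fit in the configured genome."""


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 60_000
    n_known_mirna: int = 50
    n_novel_hairpin: int = 8
    n_de: int = 10
    planted_log2fc: float = 2.0
    library_depth: int = 100_000
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    dimer_rate: float = 0.01
    low_quality_rate: float = 0.02
    de_base_tpm: float = 100.0  #: planted DE level in the lower library

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        missing = set(DEFAULT_FRACTIONS) - set(self.fractions)
        if missing:
            raise ValueError(f"fractions missing categories: {sorted(missing)}")
        if self.library_depth <= 0:
            raise ValueError("library depth must be positive")
        if not 0 <= self.dimer_rate < 1:
            raise ValueError("dimer_rate must lie in [0, 1)")
        if not 0 <= self.low_quality_rate < 1:
            raise ValueError("low_quality_rate must lie in [0, 1)")
        if self.n_de > self.n_known_mirna:
            raise ValueError("n_de cannot exceed n_known_mirna")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    precursors: dict[str, str]  #: known precursors, DNA
    matures: dict[str, str]  #: known matures, DNA
    mature_of: dict[str, str]  #: mature id -> precursor id
    mirna_loci: dict[str, tuple[str, int, int, str]]  #: precursor id -> locus
    novel_precursors: dict[str, str]
    novel_matures: dict[str, str]
    novel_loci: dict[str, tuple[str, int, int, str]]
    novel_arms: dict[str, str]
    ncrna: list[NcRNARecord]
    features: list[Feature]
    utrs: dict[str, str]
    gene_terms: list[tuple[str, str, str]]
    #: genome offset past every planted feature; background reads are drawn
    #: from here on so the 'random' category stays genuinely unannotated
    background_start: int = 0
    paths: dict[str, Path] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "mirna_hairpin": outdir / "mirna_hairpin.fa",
            "mirna_mature": outdir / "mirna_mature.fa",
            "ncrna": outdir / "ncrna.fa",
            "features": outdir / "features.gff3",
            "utr3": outdir / "utr3.fa",
            "gene_terms": outdir / "gene_terms.tsv",
        }
        sio.write_fasta(paths["genome"], self.genome)
        sio.write_fasta(paths["mirna_hairpin"], self.precursors)
        sio.write_fasta(paths["mirna_mature"], self.matures)
        sio.write_ncrna_fasta(paths["ncrna"], self.ncrna)
        sio.write_gff3(paths["features"], self.features)
        sio.write_fasta(paths["utr3"], self.utrs)
        sio.write_gene_terms(paths["gene_terms"], self.gene_terms)
        self.paths = paths
        return paths


@dataclass
class TruthManifest:
    mirna: dict[str, dict[str, float]]  #: id -> true TPMs and log2fc
    de_ids: list[str]
    novel: list[dict]
    composition: dict[str, float]
    clean_fraction: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _random_seq(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length) if p is None
                                          else rng.choice(4, length, p=p)])


def _make_hairpin(
    rng: np.random.Generator,
    stem_len: int = 22,
    loop_len: int = 12,
    require_mfe: float | None = None,
    fold_fn: Callable = fold_mfe,
    max_tries: int = 50,
) -> tuple[str, str, str]:
    """Return (precursor, arm5, arm3) DNA sequences with a perfect stem."""
    gc_bias = np.array([0.2, 0.3, 0.3, 0.2])
    for _ in range(max_tries):
        arm5 = _random_seq(rng, stem_len, p=gc_bias)
        loop = _random_seq(rng, loop_len)
        arm3 = revcomp(arm5)
        hp = arm5 + loop + arm3
        if require_mfe is None or fold_fn(hp).mfe < require_mfe:
            return hp, arm5, arm3
    raise RuntimeError("could not draw a hairpin meeting the MFE requirement")


def build_references(config: SimulationConfig, outdir: str | Path | None = None) -> ReferenceBundle:
    """Build the reference bundle; deterministic for a fixed seed."""
    rng = np.random.default_rng([config.seed, 0])
    chrom = "chr1"
    genome = np.array(list("ACGT"))[rng.integers(0, 4, config.genome_length)]

    spacing = 30
    cursor = 200
    stem, loop = 22, 12
    hp_len = 2 * stem + loop

    precursors: dict[str, str] = {}
    matures: dict[str, str] = {}
    mature_of: dict[str, str] = {}
    mirna_loci: dict[str, tuple[str, int, int, str]] = {}
    novel_precursors: dict[str, str] = {}
    novel_matures: dict[str, str] = {}
    novel_loci: dict[str, tuple[str, int, int, str]] = {}
    novel_arms: dict[str, str] = {}
    ncrna: list[NcRNARecord] = []
    features: list[Feature] = []

    n_ncrna_per_class = 2
    n_feat_per_kind = 4
    feat_len = 150
    planted_len = (
        (config.n_known_mirna + config.n_novel_hairpin) * hp_len
        + n_ncrna_per_class * sum(_NCRNA_LENGTHS.values())
    )
    if config.genome_length < 10 * planted_len:
        raise InfeasiblePackingError(
            f"genome length {config.genome_length} < 10 x planted length {planted_len}"
        )

    def alloc(length: int, gap: int = spacing) -> int:
        nonlocal cursor
        start = cursor
        if start + length > config.genome_length - 200:
            raise InfeasiblePackingError(
                "planted features exceed genome capacity"
            )
        cursor = start + length + gap
        return start

    for i in range(config.n_known_mirna):
        hp, arm5, arm3 = _make_hairpin(rng, stem, loop)
        pid = f"sim-mir-{i + 1}"
        arm = "5p" if i % 2 == 0 else "3p"
        mid = f"sim-miR-{i + 1}-{arm}"
        start = alloc(hp_len)
        genome[start : start + hp_len] = list(hp)
        precursors[pid] = hp
        matures[mid] = arm5 if arm == "5p" else arm3
        mature_of[mid] = pid
        mirna_loci[pid] = (chrom, start, start + hp_len, "+")

    for j in range(config.n_novel_hairpin):
        hp, arm5, arm3 = _make_hairpin(rng, stem, loop, require_mfe=-20.0)
        nid = f"sim-novel-{j + 1}"
        arm = "5p" if j % 2 == 0 else "3p"
        strand = "+" if j % 2 == 0 else "-"
        # keep novel loci far enough apart that +/-70 nt candidate windows
        # from neighbouring hairpins never overlap
        start = alloc(hp_len, gap=180)
        genome[start : start + hp_len] = list(hp if strand == "+" else revcomp(hp))
        novel_precursors[nid] = hp
        novel_matures[nid] = arm5 if arm == "5p" else arm3
        novel_loci[nid] = (chrom, start, start + hp_len, strand)
        novel_arms[nid] = arm

    for cls in sorted(_NCRNA_LENGTHS):
        for r in range(n_ncrna_per_class):
            length = _NCRNA_LENGTHS[cls]
            seq = _random_seq(rng, length)
            start = alloc(length)
            genome[start : start + length] = list(seq)
            source = "genbank" if r % 2 == 0 else "rfam"
            ncrna.append(
                NcRNARecord(f"{cls.lower()}_{r + 1}", cls, source, seq)
            )

    for kind in ("repeat", "exon", "intron"):
        for r in range(n_feat_per_kind):
            start = alloc(feat_len)
            strand = "+" if r % 2 == 0 else "-"
            features.append(Feature(chrom, start, start + feat_len, strand, kind))

    genome_str = "".join(genome)
    for pid, (c, s, e, st) in mirna_loci.items():
        assert genome_str[s:e] == precursors[pid]

    # 3' UTRs: the first genes carry perfect sites for blocks of miRNAs so
    # the target-aggregation stage has genes hit by >3 DE miRNAs
    utrs: dict[str, str] = {}
    n_genes = 24
    mat_ids = sorted(matures)
    for g in range(n_genes):
        gid = f"GENE{g + 1:04d}"
        seq = _random_seq(rng, 60)
        if g < 6 and len(mat_ids) >= 5:
            for k in range(5):
                mid = mat_ids[(2 * g + k) % len(mat_ids)]
                seq += revcomp(matures[mid]) + _random_seq(rng, 8)
        else:
            seq += _random_seq(rng, 60)
        utrs[gid] = seq

    terms = [
        ("T0001", "signal transduction"),
        ("T0002", "cell cycle"),
        ("T0003", "RNA processing"),
        ("T0004", "metabolism"),
        ("T0005", "adhesion"),
        ("T0006", "transport"),
    ]
    gene_terms: list[tuple[str, str, str]] = []
    for g, gid in enumerate(sorted(utrs)):
        n_terms = 1 + int(rng.integers(0, 3))
        picks = rng.choice(len(terms), size=n_terms, replace=False)
        for t in sorted(picks):
            gene_terms.append((gid, terms[t][0], terms[t][1]))

    bundle = ReferenceBundle(
        genome={chrom: genome_str},
        precursors=precursors,
        matures=matures,
        mature_of=mature_of,
        mirna_loci=mirna_loci,
        novel_precursors=novel_precursors,
        novel_matures=novel_matures,
        novel_loci=novel_loci,
        novel_arms=novel_arms,
        ncrna=ncrna,
        features=features,
        utrs=utrs,
        gene_terms=gene_terms,
        background_start=cursor,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


@dataclass
class _Source:
    name: str
    category: str
    p_control: float
    p_knockdown: float
    kind: str  #: 'fixed', 'ref_window', 'genome_window', 'feature_window', 'dimer'
    payload: object = None


def build_source_table(
    config: SimulationConfig, refs: ReferenceBundle
) -> tuple[list[_Source], dict]:
    """Expected per-source read proportions for both libraries.

    DE miRNAs sit at ``de_base_tpm`` in their lower library and
    ``de_base_tpm * 2**|log2fc|`` in the higher one, so the planted
    expected-proportion ratio is exactly ``2**log2fc``; the knockdown
    'random' background absorbs the resulting imbalance.
    """
    f = config.fractions
    rng_truth = np.random.default_rng([config.seed, 1])
    mat_ids = sorted(refs.matures)
    de_idx = sorted(
        rng_truth.choice(len(mat_ids), size=config.n_de, replace=False).tolist()
    )
    signs = rng_truth.choice([1.0, -1.0], size=config.n_de)
    de_fc = {mat_ids[i]: float(s * config.planted_log2fc) for i, s in zip(de_idx, signs)}

    p_low = config.de_base_tpm / 1e6
    ratio = 2.0 ** abs(config.planted_log2fc)
    sources: list[_Source] = []
    sum_c = 0.0
    sum_k = 0.0
    mirna_truth: dict[str, dict[str, float]] = {}
    de_total_c = sum(
        p_low * (ratio if de_fc[m] < 0 else 1.0) for m in de_fc
    )
    n_null = len(mat_ids) - len(de_fc)
    p_null = (f["miRNA"] - de_total_c) / n_null if n_null else 0.0
    if p_null < 0:
        raise ValueError("miRNA fraction too small for the planted DE levels")
    for mid in mat_ids:
        if mid in de_fc:
            fc = de_fc[mid]
            pc = p_low * (ratio if fc < 0 else 1.0)
            pk = pc * 2.0**fc
        else:
            fc = 0.0
            pc = pk = p_null
        sources.append(_Source(mid, "miRNA", pc, pk, "fixed", refs.matures[mid]))
        sum_c += pc
        sum_k += pk
        mirna_truth[mid] = {
            "tpm_control": pc * 1e6,
            "tpm_knockdown": pk * 1e6,
            "log2fc": fc,
        }

    for nid in sorted(refs.novel_matures):
        p = f["novel"] / max(1, len(refs.novel_matures))
        sources.append(_Source(nid, "novel", p, p, "fixed", refs.novel_matures[nid]))
        sum_c += p
        sum_k += p

    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA"):
        recs = [r for r in refs.ncrna if r.cls == cls]
        if recs:
            sources.append(_Source(cls, cls, f[cls], f[cls], "ref_window", recs))
            sum_c += f[cls]
            sum_k += f[cls]

    for kind in ("repeat", "exon", "intron"):
        feats = [ft for ft in refs.features if ft.kind == kind]
        if feats:
            sources.append(
                _Source(kind, kind, f[kind], f[kind], "feature_window", feats)
            )
            sum_c += f[kind]
            sum_k += f[kind]

    rand_c = 1.0 - sum_c
    rand_k = 1.0 - sum_k
    if rand_k <= 0 or rand_c <= 0:
        raise ValueError(
            "random background fraction exhausted by planted DE imbalance"
        )
    sources.append(_Source("random", "random", rand_c, rand_k, "genome_window", None))

    truth_info = {
        "mirna": mirna_truth,
        "de_ids": sorted(de_fc),
    }
    return sources, truth_info


def _emit_insert(src: _Source, refs: ReferenceBundle, rng: np.random.Generator) -> str:
    if src.kind == "fixed":
        return src.payload  # type: ignore[return-value]
    length = int(rng.choice(_LENGTHS, p=_LENGTH_P))
    if src.kind == "ref_window":
        recs = src.payload  # type: ignore[assignment]
        rec = recs[int(rng.integers(0, len(recs)))]
        start = int(rng.integers(0, len(rec.sequence) - length + 1))
        return rec.sequence[start : start + length]
    if src.kind == "feature_window":
        feats = src.payload  # type: ignore[assignment]
        ft = feats[int(rng.integers(0, len(feats)))]
        start = int(rng.integers(ft.start, ft.end - length + 1))
        seq = refs.genome[ft.chrom][start : start + length]
        antisense = ft.kind in ("exon", "intron") and rng.random() < 0.10
        if (ft.strand == "-") != antisense:
            seq = revcomp(seq)
        return seq
    if src.kind == "genome_window":
        chrom = sorted(refs.genome)[0]
        gseq = refs.genome[chrom]
        start = int(rng.integers(refs.background_start, len(gseq) - length + 1))
        seq = gseq[start : start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        return seq
    raise AssertionError(src.kind)


def _write_library(
    path: Path,
    lib_name: str,
    sources: list[_Source],
    p_col: str,
    config: SimulationConfig,
    refs: ReferenceBundle,
    rng: np.random.Generator,
) -> None:
    d, l = config.dimer_rate, config.low_quality_rate
    real_scale = 1.0 - d - l
    probs = [d, l] + [real_scale * getattr(s, p_col) for s in sources]
    probs = np.asarray(probs)
    probs = probs / probs.sum()  # guard rounding; deviation is < 1e-12
    counts = rng.multinomial(config.library_depth, probs)

    idx = 0
    with open(path, "w") as fh:
        def emit(insert: str, lowq: bool) -> None:
            nonlocal idx
            seq = insert + config.adapter
            qual = ("#" if lowq else "I") * len(seq)
            fh.write(f"@{lib_name}_{idx}\n{seq}\n+\n{qual}\n")
            idx += 1

        for _ in range(counts[0]):  # adaptor-adaptor dimers
            emit("", False)
        lowq_src = _Source("lowq", "random", 0, 0, "genome_window", None)
        for _ in range(counts[1]):  # low-quality reads
            emit(_emit_insert(lowq_src, refs, rng), True)
        for s, c in zip(sources, counts[2:]):
            for _ in range(c):
                emit(_emit_insert(s, refs, rng), False)


def simulate_libraries(
    config: SimulationConfig,
    refs: ReferenceBundle,
    outdir: str | Path,
) -> tuple[Path, Path, TruthManifest]:
    """Write control and knockdown FASTQ libraries plus the truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sources, truth_info = build_source_table(config, refs)

    control_path = outdir / "control.fastq"
    knockdown_path = outdir / "knockdown.fastq"
    _write_library(
        control_path, "control", sources, "p_control", config, refs,
        np.random.default_rng([config.seed, 2]),
    )
    _write_library(
        knockdown_path, "knockdown", sources, "p_knockdown", config, refs,
        np.random.default_rng([config.seed, 3]),
    )

    clean_fraction = 1.0 - config.dimer_rate - config.low_quality_rate
    novel = [
        {
            "id": nid,
            "chrom": refs.novel_loci[nid][0],
            "start": refs.novel_loci[nid][1],
            "end": refs.novel_loci[nid][2],
            "strand": refs.novel_loci[nid][3],
            "mature": refs.novel_matures[nid],
            "arm": refs.novel_arms[nid],
        }
        for nid in sorted(refs.novel_loci)
    ]
    manifest = TruthManifest(
        mirna=truth_info["mirna"],
        de_ids=truth_info["de_ids"],
        novel=novel,
        composition=dict(config.fractions),
        clean_fraction=clean_fraction,
    )
    manifest.write(outdir / "truth.json")
    return control_path, knockdown_path, manifest
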