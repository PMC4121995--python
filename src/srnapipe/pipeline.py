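"""End-to-end orchestration and published-table replay.

``run_all`` executes preprocess -> annotate -> novel -> diffexpr ->
targets -> enrich on a pair of FASTQ libraries, persists every
intermediate as TSV/FASTA under the output directory, and returns a
machine-readable report.  ``replay_reference_table`` re-applies the DE
classification rule to a bundled table of published (log2 fold change,
adjusted p) values.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import diffexpr as de
from . import enrich as en
from . import io as sio
from . import novel as nov
from . import preprocess as pp
from . import targets as tg

__all__ = ["RunConfig", "StageError", "run_all", "replay_reference_table"]


@dataclass
class RunConfig:
    control_fastq: str
    knockdown_fastq: str
    genome_fasta: str
    ncrna_fasta: str
    mirna_hairpin_fasta: str
    mirna_mature_fasta: str
    features_gff3: str
    utr3_fasta: str
    gene_terms_tsv: str
    outdir: str = "srnapipe_out"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_mean_q: float = 20.0
    min_len: int = 18
    max_len: int = 30
    max_mismatch: int = 0
    mirna_min_overlap: int = 16
    flank: int = 70
    mfe_max: float = -20.0
    tpm_min: float = 1.0
    alpha_known: float = 0.01
    alpha_novel: float = 0.05
    min_fold: float = 2.0
    floor_tpm: float = 0.01
    evd_location_slope: float = 1.9
    evd_scale_slope: float = 0.28
    target_max_p: float = 0.05
    min_mirnas: int = 3
    correction: str = "bonferroni"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for name in (
            "control_fastq",
            "knockdown_fastq",
            "genome_fasta",
            "ncrna_fasta",
            "mirna_hairpin_fasta",
            "mirna_mature_fasta",
            "features_gff3",
            "utr3_fasta",
            "gene_terms_tsv",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not self.min_len <= self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.mfe_max > 0:
            raise ValueError("mfe_max must be <= 0")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _mature_of_map(matures: dict[str, str], precursors: dict[str, str]) -> dict[str, str]:
    """Pair each mature with the precursor containing it.

    Containment is authoritative; a shared name stem only breaks ties when
    several precursors contain the same mature sequence.
    """
    out: dict[str, str] = {}
    for mid, mseq in matures.items():
        stem = mid.removesuffix("-5p").removesuffix("-3p").lower().replace("mir", "mir")
        for pid in sorted(precursors, key=lambda p: (p.lower() != stem, p)):
            if mseq in precursors[pid]:
                out[mid] = pid
                break
        if mid not in out:
            raise ValueError(f"mature {mid} not found in any precursor")
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage in order; persists intermediates, returns the report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - aborts with stage name
                raise StageError(name, exc) from exc

        return wrap

    # --- preprocess ---------------------------------------------------
    @stage("preprocess")
    def _pre():
        libs = {}
        stats = {}
        for name, path in (
            ("control", config.control_fastq),
            ("knockdown", config.knockdown_fastq),
        ):
            reads, st = pp.clean_reads(
                path,
                adapter=config.adapter,
                min_mean_q=config.min_mean_q,
                length_range=(config.min_len, config.max_len),
            )
            if not st.check_partition():  # pragma: no cover - invariant
                raise RuntimeError("cleaning stats do not partition the input")
            libs[name] = pp.collapse(reads, name=name)
            stats[name] = st.as_dict()
        return libs, stats

    libs, clean_stats = _pre
    report["stages"]["preprocess"] = clean_stats
    control, knockdown = libs["control"], libs["knockdown"]
    for name, lib in libs.items():
        df = pd.DataFrame(
            sorted(lib.tags.items()), columns=["tag", "count"]
        )
        df.to_csv(outdir / f"tags_{name}.tsv", sep="\t", index=False)
        pp.length_distribution(lib).to_csv(outdir / f"lengths_{name}.tsv", sep="\t")
    report["stages"]["preprocess"]["overlap"] = pp.library_overlap(control, knockdown)

    # --- annotate -----------------------------------------------------
    @stage("annotate")
    def _ann():
        genome = sio.read_fasta(config.genome_fasta)
        ncrna = sio.read_ncrna_fasta(config.ncrna_fasta)
        precursors = sio.read_fasta(config.mirna_hairpin_fasta)
        matures = sio.read_fasta(config.mirna_mature_fasta)
        features = sio.read_gff3(config.features_gff3)
        merged = pp.TagLibrary(
            name="merged",
            tags={
                t: control.tags.get(t, 0) + knockdown.tags.get(t, 0)
                for t in set(control.tags) | set(knockdown.tags)
            },
        )
        hits, mapped_frac = ann.map_tags(merged, genome, config.max_mismatch)
        out = {}
        for name, lib in libs.items():
            annotated, summary = ann.annotate_tags(
                lib, ncrna, precursors, matures, features, hits
            )
            summary.to_csv(outdir / f"categories_{name}.tsv", sep="\t")
            qc = ann.rrna_qc(summary, lib.total_clean)
            out[name] = (annotated, summary, qc)
        return genome, ncrna, precursors, matures, features, hits, mapped_frac, out

    genome, ncrna, precursors, matures, features, hits, mapped_frac, ann_out = _ann
    report["stages"]["annotate"] = {
        "mapped_fraction": mapped_frac,
        "rrna_qc": {
            name: {"ratio": qc.ratio, "verdict": qc.verdict}
            for name, (_a, _s, qc) in ann_out.items()
        },
    }

    # --- known miRNA quantification + DE ------------------------------
    @stage("diffexpr")
    def _de():
        mature_of = _mature_of_map(matures, precursors)
        counts = {}
        for name, lib in libs.items():
            table, arms = ann.quantify_known_mirna(
                lib, precursors, matures, mature_of, config.mirna_min_overlap
            )
            counts[name] = table["count"]
        count_map = {
            mid: (int(counts["control"].get(mid, 0)), int(counts["knockdown"].get(mid, 0)))
            for mid in sorted(matures)
        }
        df = de.differential_expression(
            count_map,
            control.total_clean,
            knockdown.total_clean,
            alpha=config.alpha_known,
            min_fold=config.min_fold,
            floor=config.floor_tpm,
        )
        df.to_csv(outdir / "de_known.tsv", sep="\t", index=False)
        return count_map, df

    count_map, de_df = _de
    n_up = int((de_df["status"] == "up").sum())
    n_down = int((de_df["status"] == "down").sum())
    control_only, knockdown_only = de.sample_specific(count_map)
    report["stages"]["diffexpr"] = {
        "n_tested": int(len(de_df)),
        "n_up": n_up,
        "n_down": n_down,
        "control_specific": control_only,
        "knockdown_specific": knockdown_only,
    }

    # --- novel miRNA prediction ---------------------------------------
    @stage("novel")
    def _novel():
        unannot = {
            at.sequence: at.hits
            for at in ann_out["control"][0] + ann_out["knockdown"][0]
            if at.category == "unannotated" and at.hits
        }
        windows = nov.excise_windows(unannot, genome, flank=config.flank)
        tpm_c = {
            t: de.tpm(c, control.total_clean) for t, c in control.tags.items()
        }
        tpm_k = {
            t: de.tpm(c, knockdown.total_clean) for t, c in knockdown.tags.items()
        }
        passing, rejected = nov.call_novel(
            windows, tpm_c, tpm_k, mfe_max=config.mfe_max, tpm_min=config.tpm_min
        )
        rows = [
            {
                "tag": c.window.tag,
                "chrom": c.window.chrom,
                "start": c.window.start,
                "end": c.window.end,
                "strand": c.window.strand,
                "mfe": c.fold.mfe if c.fold else float("nan"),
                "structure": c.fold.structure if c.fold else "",
                "arm": c.arm or "",
                "tpm_control": c.tpm_control,
                "tpm_knockdown": c.tpm_knockdown,
            }
            for c in passing
        ]
        pd.DataFrame(
            rows,
            columns=[
                "tag", "chrom", "start", "end", "strand", "mfe",
                "structure", "arm", "tpm_control", "tpm_knockdown",
            ],
        ).to_csv(outdir / "novel_candidates.tsv", sep="\t", index=False)
        sio.write_fasta(
            outdir / "novel_precursors.fa",
            [(f"candidate_{i + 1}", c.window.sequence) for i, c in enumerate(passing)],
        )
        with open(outdir / "novel_rejections.tsv", "w") as fh:
            fh.write("tag\tmfe_pass\tarm_pass\texpression_pass\n")
            for c in rejected:
                fh.write(
                    f"{c.window.tag}\t{c.mfe_pass}\t{c.arm_pass}\t{c.expression_pass}\n"
                )
        return passing

    novel_passing = _novel
    report["stages"]["novel"] = {"n_candidates": len(novel_passing)}

    # --- target prediction --------------------------------------------
    @stage("targets")
    def _targets():
        utrs = sio.read_fasta(config.utr3_fasta)
        de_status = dict(zip(de_df["mirna_id"], de_df["status"]))
        de_matures = {
            mid: matures[mid]
            for mid in de_status
            if de_status[mid] in ("up", "down") and mid in matures
        }
        hits_ = tg.scan_targets(
            de_matures,
            utrs,
            params=tg.EvdParams(config.evd_location_slope, config.evd_scale_slope),
            max_p=config.target_max_p,
        )
        pd.DataFrame(
            [
                {
                    "mirna": h.mirna_id,
                    "gene": h.gene_id,
                    "position": h.position,
                    "energy": h.duplex_mfe,
                    "pvalue": h.pvalue,
                }
                for h in hits_
            ],
            columns=["mirna", "gene", "position", "energy", "pvalue"],
        ).to_csv(outdir / "target_hits.tsv", sep="\t", index=False)
        agg = tg.aggregate_targets(hits_, de_status, min_mirnas=config.min_mirnas)
        pd.DataFrame(
            agg, columns=["gene", "n_up_mirnas", "n_down_mirnas", "kept"]
        ).to_csv(outdir / "target_genes.tsv", sep="\t", index=False)
        return hits_, agg

    target_hits, target_agg = _targets
    kept_genes = [r["gene"] for r in target_agg if r["kept"]]
    report["stages"]["targets"] = {
        "n_hits": len(target_hits),
        "n_genes": len(target_agg),
        "n_kept_genes": len(kept_genes),
    }

    # --- enrichment ---------------------------------------------------
    @stage("enrich")
    def _enrich():
        rows = sio.read_gene_terms(config.gene_terms_tsv)
        universe = {g for g, _t, _n in rows}
        query = sorted(set(kept_genes) & universe) or sorted(
            {r["gene"] for r in target_agg} & universe
        )
        if not query:
            return []
        results = en.hypergeom_enrich(query, rows, correction=config.correction)
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "k": r.k,
                    "K": r.K,
                    "pvalue": r.pvalue,
                    "p_corrected": r.p_corrected,
                }
                for r in results
            ],
            columns=["term_id", "term_name", "k", "K", "pvalue", "p_corrected"],
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return results

    enrich_results = _enrich
    report["stages"]["enrich"] = {"n_terms": len(enrich_results)}

    report["summary"] = {
        "n_up_known": n_up,
        "n_down_known": n_down,
        "n_novel_candidates": len(novel_passing),
        "rrna_qc": report["stages"]["annotate"]["rrna_qc"],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _load_fixture(which: str) -> pd.DataFrame:
    name = {"known": "de_known.tsv", "novel": "de_novel.tsv"}[which]
    ref = importlib.resources.files("srnapipe.data") / name
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    expected = ["mirna_id", "log2fc", "direction", "adj_p"]
    if list(df.columns) != expected:
        raise ValueError(f"malformed fixture {name}: columns {list(df.columns)}")
    return df


def replay_reference_table(
    which: str = "known",
    alpha: float | None = None,
    min_fold: float = 2.0,
    fold_threshold: float | None = None,
) -> dict:
    """Re-apply the DE rule to a bundled table of published calls.

    *which* selects the known- or novel-miRNA table.  Returns per-row
    statuses and (n_up, n_down); when *fold_threshold* is given, also the
    up/down counts whose |log2fc| strictly exceeds it.
    """
    if alpha is None:
        alpha = 0.01 if which == "known" else 0.05
    df = _load_fixture(which)
    statuses, n_up, n_down = de.classify(
        df["log2fc"].tolist(), df["adj_p"].tolist(), alpha=alpha, min_fold=min_fold
    )
    out = {
        "n_up": n_up,
        "n_down": n_down,
        "statuses": dict(zip(df["mirna_id"], statuses)),
    }
    if fold_threshold is not None:
        out["n_up_above_threshold"] = int(
            sum(
                1
                for s, fc in zip(statuses, df["log2fc"])
                if s == "up" and fc > fold_threshold
            )
        )
        out["n_down_above_threshold"] = int(
            sum(
                1
                for s, fc in zip(statuses, df["log2fc"])
                if s == "down" and fc < -fold_threshold
            )
        )
    return out
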