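"""Pipeline orchestration: preprocess -> map -> quantify -> de, stage by stage.

Each stage reads the previous stage's declared files from the run
directory, so stages are independently re-runnable; ``run_pipeline`` runs
them all and writes a manifest with input checksums, effective parameters
and per-stage read accounting.  Reruns with identical config and inputs
reproduce identical DE tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from mircaste.align import ReferenceIndex, assign_to_mirbase, map_to_genome
from mircaste.config import PipelineConfig
from mircaste.diffexpr import ComparisonDesign, run_comparisons
from mircaste.expression import (
    ExpressionMatrix,
    build_matrix,
    choose_normalization_total,
    normalize_per_total,
    quality_frame,
    screen_libraries,
)
from mircaste.preprocess import preprocess_fastq, read_tags_fasta, write_tags_fasta
from mircaste.simulate import MiRNACatalog, read_fasta

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"library_id": str,
                                               "phenotype": str})
    required = {"library_id", "phenotype", "replicate", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["library_id"].duplicated().any():
        raise ValueError("duplicate library ids in sample sheet")
    return sheet


def resolve_run_dir(config: PipelineConfig) -> Path:
    name = config.run_name or time.strftime("run_%Y%m%d-%H%M%S")
    run_dir = Path(config.output_dir) / name
    run_dir.mkdir(parents=True, exist_ok=True)
    return run_dir


def _check_inputs(config: PipelineConfig) -> None:
    for label, p in [("genome_fasta", config.genome_fasta),
                     ("mirna_fasta", config.mirna_fasta),
                     ("sample_sheet", config.sample_sheet)]:
        if not p or not Path(p).is_file():
            raise FileNotFoundError(f"{label} not found: {p!r}")
    sheet = read_sample_sheet(config.sample_sheet)
    for _, row in sheet.iterrows():
        if not Path(row["path"]).is_file():
            raise FileNotFoundError(
                f"FASTQ for library {row['library_id']} not found: {row['path']}"
            )


# ---------------------------------------------------------------------------
# stages


def stage_preprocess(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Clean every library; write per-library tag FASTAs and a stats table."""
    sheet = read_sample_sheet(config.sample_sheet)
    tag_dir = run_dir / "tags"
    tag_dir.mkdir(exist_ok=True)
    rows = []
    for _, row in sheet.iterrows():
        tags, stats = preprocess_fastq(
            row["path"], adapter=config.adapter, min_overlap=config.min_overlap,
            hd_length=config.hd_length, l_min=config.l_min,
        )
        write_tags_fasta(tags, tag_dir / f"{row['library_id']}.tags.fasta")
        rows.append(
            {"library_id": row["library_id"],
             "input_reads": stats.input_reads,
             "discarded_ambiguous": stats.discarded_ambiguous,
             "discarded_no_adapter": stats.discarded_no_adapter,
             "discarded_short": stats.discarded_short,
             "accepted_reads": stats.accepted_reads}
        )
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "preprocess_stats.tsv", sep="\t", index=False)
    return table


def stage_map(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Map tags to the genome and assign genome-matching tags to miRNAs.

    Writes per-library hit tables (mapped tags only), per-library miRNA
    count tables, and the mapping-stats summary.
    """
    sheet = read_sample_sheet(config.sample_sheet)
    genome = read_fasta(config.genome_fasta)
    mature = {k: v.replace("U", "T") for k, v in read_fasta(config.mirna_fasta).items()}
    genome_index = ReferenceIndex(genome, seed_len=8)
    hit_dir = run_dir / "hits"
    count_dir = run_dir / "mirna_counts"
    hit_dir.mkdir(exist_ok=True)
    count_dir.mkdir(exist_ok=True)
    rows = []
    for lib in sheet["library_id"]:
        tags = read_tags_fasta(run_dir / "tags" / f"{lib}.tags.fasta")
        hits_by_tag, mstats = map_to_genome(tags, genome_index, k=config.k_genome)
        hit_rows = [
            {"tag": seq, "count": tags[seq], "reference": h.reference,
             "offset": h.offset, "strand": h.strand, "mismatches": h.mismatches}
            for seq, hits in hits_by_tag.items()
            for h in hits
        ]
        pd.DataFrame(
            hit_rows, columns=["tag", "count", "reference", "offset",
                               "strand", "mismatches"]
        ).to_csv(hit_dir / f"{lib}.hits.tsv", sep="\t", index=False)
        mapped_tags = Counter({seq: tags[seq] for seq in hits_by_tag})
        assignment = assign_to_mirbase(mapped_tags, mature, k_m=config.k_mirbase)
        pd.Series(assignment.per_mirna, name="count").rename_axis("miRNA").to_csv(
            count_dir / f"{lib}.mirna_counts.tsv", sep="\t"
        )
        incidence = assignment.incidence_fraction
        rows.append(
            {"library_id": lib,
             "total_redundant": mstats.total_redundant,
             "total_nonredundant": mstats.total_nonredundant,
             "mapped_redundant": mstats.mapped_redundant,
             "mapped_nonredundant": mstats.mapped_nonredundant,
             "redundant_pct": mstats.redundant_pct,
             "nonredundant_pct": mstats.nonredundant_pct,
             "mirna_incidence_pct":
                 None if incidence is None else 100.0 * incidence}
        )
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "mapping_stats.tsv", sep="\t", index=False)
    return table


def stage_quantify(config: PipelineConfig, run_dir: Path) -> ExpressionMatrix:
    """Build the miRNA x library matrix, normalize it, and screen libraries."""
    sheet = read_sample_sheet(config.sample_sheet)
    pstats = pd.read_csv(run_dir / "preprocess_stats.tsv", sep="\t",
                         dtype={"library_id": str})
    accepted = dict(zip(pstats["library_id"], pstats["accepted_reads"]))
    assignments = {}
    for lib in sheet["library_id"]:
        path = run_dir / "mirna_counts" / f"{lib}.mirna_counts.tsv"
        counts = pd.read_csv(path, sep="\t", index_col="miRNA")["count"]
        assignments[lib] = counts.to_dict()
    matrix = build_matrix(assignments, sheet, accepted)
    if config.normalization_total == "auto":
        n_norm = choose_normalization_total(list(accepted.values()))
    else:
        n_norm = config.normalization_total
    matrix = normalize_per_total(matrix, n_norm)
    qualities = screen_libraries(
        matrix, sheet, score_threshold=config.score_threshold,
        abundance_floor=config.abundance_floor, offset=config.offset,
        exclude=config.exclude_libraries,
    )
    matrix.raw.to_csv(run_dir / "matrix_raw.tsv", sep="\t", index_label="miRNA")
    matrix.normalized.to_csv(run_dir / "matrix_normalized.tsv", sep="\t",
                             index_label="miRNA")
    quality_frame(qualities).to_csv(run_dir / "library_quality.tsv", sep="\t",
                                    index=False)
    with open(run_dir / "normalization.json", "w") as fh:
        json.dump({"normalization_total": n_norm}, fh)
    return matrix


def stage_de(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Run all pairwise comparisons and write ranked DE tables."""
    sheet = read_sample_sheet(config.sample_sheet)
    norm = pd.read_csv(run_dir / "matrix_normalized.tsv", sep="\t",
                       index_col="miRNA")
    raw = pd.read_csv(run_dir / "matrix_raw.tsv", sep="\t", index_col="miRNA")
    pstats = pd.read_csv(run_dir / "preprocess_stats.tsv", sep="\t",
                         dtype={"library_id": str})
    totals = pd.Series(dict(zip(pstats["library_id"],
                                pstats["accepted_reads"]))).astype(float)
    matrix = ExpressionMatrix(raw=raw, accepted_totals=totals, normalized=norm)
    qual = pd.read_csv(run_dir / "library_quality.tsv", sep="\t",
                       dtype={"library_id": str})
    from mircaste.expression import LibraryQuality

    qualities = [
        LibraryQuality(r["library_id"],
                       None if pd.isna(r["score"]) else float(r["score"]),
                       bool(r["excluded"]))
        for _, r in qual.iterrows()
    ]
    design = ComparisonDesign.default()
    present = set(sheet["phenotype"])
    design.comparisons = [
        c for c in design.comparisons
        if c.phenotype_a in present and c.phenotype_b in present
    ]
    tables, summary = run_comparisons(
        matrix, sheet, design, qualities,
        ofc_threshold=config.ofc_threshold,
        abundance_floor=config.abundance_floor,
        offset=config.offset, ofc_variant=config.ofc_variant,
    )
    de_dir = run_dir / "de"
    de_dir.mkdir(exist_ok=True)
    for label, table in tables.items():
        table.to_csv(de_dir / f"{label}.tsv", sep="\t", index=False)
    summary.to_csv(run_dir / "de_summary.tsv", sep="\t", index=False)
    return summary


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunResult:
    run_dir: Path
    preprocess_stats: pd.DataFrame
    mapping_stats: pd.DataFrame
    matrix: ExpressionMatrix
    de_summary: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Run every stage under a fresh run directory and write the manifest."""
    _check_inputs(config)
    run_dir = resolve_run_dir(config)
    pstats = stage_preprocess(config, run_dir)
    mstats = stage_map(config, run_dir)
    matrix = stage_quantify(config, run_dir)
    de_summary = stage_de(config, run_dir)
    manifest = {
        "parameters": config.to_dict(),
        "inputs": {
            "genome_fasta": _sha256(config.genome_fasta),
            "mirna_fasta": _sha256(config.mirna_fasta),
            "sample_sheet": _sha256(config.sample_sheet),
        },
        "read_accounting": pstats.set_index("library_id").to_dict("index"),
        "mapping": mstats.set_index("library_id").to_dict("index"),
        "n_de_calls": int(len(de_summary)),
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(run_dir, pstats, mstats, matrix, de_summary)


def report(run_dir: str | Path) -> str:
    """Human-readable per-library statistics and DE summary for one run."""
    run_dir = Path(run_dir)
    if not run_dir.is_dir() or not any(run_dir.iterdir()):
        raise FileNotFoundError(f"no completed run at {run_dir}")
    lines = [f"mircaste run report: {run_dir.name}", ""]
    gaps = []
    p = run_dir / "preprocess_stats.tsv"
    if p.is_file():
        stats = pd.read_csv(p, sep="\t")
        lines.append(f"Libraries: {len(stats)}")
        lines.append("Per-library read accounting:")
        lines.append(stats.to_string(index=False))
    else:
        gaps.append("preprocessing statistics missing")
    m = run_dir / "mapping_stats.tsv"
    if m.is_file():
        stats = pd.read_csv(m, sep="\t")
        lines.append("")
        lines.append("Genome mapping (redundant = all reads, non-redundant = "
                     "unique tags):")
        cols = ["library_id", "redundant_pct", "nonredundant_pct",
                "mirna_incidence_pct"]
        lines.append(stats[cols].round(2).to_string(index=False))
    else:
        gaps.append("mapping statistics missing")
    q = run_dir / "library_quality.tsv"
    if q.is_file():
        qual = pd.read_csv(q, sep="\t")
        excluded = qual[qual["excluded"]]["library_id"].tolist()
        lines.append("")
        lines.append(f"Excluded libraries: {', '.join(excluded) or 'none'}")
    s = run_dir / "de_summary.tsv"
    if s.is_file():
        summary = pd.read_csv(s, sep="\t")
        comparisons = sorted((run_dir / "de").glob("*.tsv")) if (
            run_dir / "de").is_dir() else []
        lines.append(f"Comparisons run: {len(comparisons)}")
        lines.append(f"Differentially expressed miRNA calls: {len(summary)}")
        if len(summary):
            cols = ["miRNA", "comparison", "mean_a", "mean_b", "ofc",
                    "fold_change", "direction"]
            lines.append(summary[cols].round(3).to_string(index=False))
    else:
        gaps.append("DE summary missing")
    if gaps:
        lines.append("")
        lines.append("INCOMPLETE RUN: " + "; ".join(gaps))
    return "\n".join(lines) + "\n"
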