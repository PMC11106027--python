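"""End-to-end pipeline: scan -> ingest -> overlap -> classify -> conservation.

Ties the stages together behind a single configuration object, writes every
table produced, and records a machine-readable run manifest (config, seed,
output checksums) so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classify, conservation, overlap, scan, simulate, variants

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds of one analysis run.

    Either a single merged variant TSV or an exome/genome pair may be
    supplied; the pair is pooled and filtered at ``merged_min_ac``.
    """

    proteome_fasta: str
    variant_tsv: str | None = None
    exome_tsv: str | None = None
    genome_tsv: str | None = None
    mapping_tsv: str | None = None
    alignment_dir: str | None = None
    disease_tsv: str | None = None
    outdir: str = "polyxpop_out"
    exome_min_ac: int = 100
    genome_min_ac: int = 100
    merged_min_ac: int = 10
    min_repeat_len: int = 3
    focal_aa: str = "Q"
    conservation_min_len: int = 8
    baseline_n: int = 10000
    seed: int = 20240520


def _load_variants(config: PipelineConfig) -> variants.VariantSet:
    if config.variant_tsv:
        vs = variants.parse_variant_table(config.variant_tsv)
        return variants.filter_by_ac(vs, config.merged_min_ac)
    if config.exome_tsv and config.genome_tsv:
        exome = variants.parse_variant_table(config.exome_tsv)
        genome = variants.parse_variant_table(config.genome_tsv)
        return variants.merge_variant_sets(exome, genome, min_ac=config.merged_min_ac)
    raise ValueError("config must provide variant_tsv or an exome/genome pair")


def run_scan(config: PipelineConfig) -> Path:
    """Scan the proteome and write the homorepeat TSV."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = scan.read_proteome(config.proteome_fasta)
    repeats = scan.scan_proteome(proteome, min_len=config.min_repeat_len)
    out = outdir / "homorepeats.tsv"
    scan.write_homorepeat_table(repeats, out)
    logger.info("scanned %d proteins: %d homorepeats", len(proteome), len(repeats))
    return out


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage the configured inputs allow; return output paths.

    Always produced: homorepeat table, overlap summary with random-region
    baseline, per-amino-acid overlap, coverage/profile statistics, and the
    per-length-class variant-type table for the focal residue.  Tract
    conservation tables additionally require an alignment directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    proteome = scan.read_proteome(config.proteome_fasta)
    repeats = scan.scan_proteome(proteome, min_len=config.min_repeat_len)
    outputs["homorepeats"] = outdir / "homorepeats.tsv"
    scan.write_homorepeat_table(repeats, outputs["homorepeats"])

    vs = _load_variants(config)
    if config.mapping_tsv:
        mapping = variants.read_id_mapping(config.mapping_tsv)
        vs, report = variants.map_to_uniprot(vs, mapping, proteome)
        logger.info("id mapping: %d kept, %d unmapped, %d mismatches",
                    report.n_kept, report.n_unmapped, report.n_mismatch)
    vs = variants.refine_duplications(vs, proteome)

    observed = overlap.overlap_frequency(repeats, vs)
    baseline = overlap.class_baseline(
        repeats, proteome, vs, observed, n=config.baseline_n, seed=config.seed
    )
    summary = observed.per_class.merge(
        baseline.per_class[["length_class", "frequency", "fold_enrichment"]],
        on="length_class", how="left", suffixes=("", "_baseline"),
    ).rename(columns={"frequency_baseline": "baseline_frequency"})
    outputs["overlap_summary"] = outdir / "overlap_summary.tsv"
    summary.to_csv(outputs["overlap_summary"], sep="\t", index=False)

    outputs["per_aa_overlap"] = outdir / "per_aa_overlap.tsv"
    overlap.per_aa_overlap(repeats, vs).to_csv(outputs["per_aa_overlap"], sep="\t", index=False)

    coverage = overlap.proteome_variant_coverage(vs, proteome)
    profile = overlap.aa_frequency_profile(vs, proteome)
    outputs["aa_profile"] = outdir / "aa_profile.tsv"
    profile.to_csv(outputs["aa_profile"], sep="\t", index=False)

    pairs = classify.assign_variants_to_repeats(
        [r for r in repeats if r.aa == config.focal_aa], vs, aa=config.focal_aa
    )
    table = classify.tabulate(pairs)
    outputs["polyx_variant_table"] = outdir / "polyx_variant_table.tsv"
    classify.write_table(table, outputs["polyx_variant_table"])

    cons_records = []
    if config.alignment_dir:
        index = {p.protein_id: p for p in proteome}
        alignments = {}
        for path in sorted(Path(config.alignment_dir).glob("*.fasta")):
            pid = path.name.split(".")[0]
            if pid in index:
                alignments[pid] = conservation.read_alignment(path, pid, index[pid])
        cons_records = conservation.build_conservation_records(
            alignments, repeats, min_len=config.conservation_min_len
        )
        cons_records = conservation.attach_variant_status(cons_records, repeats, vs)
        cons_records = conservation.group_by_variation(cons_records)
        if config.disease_tsv:
            ann = pd.read_csv(config.disease_tsv, sep="\t")
            ids = set(zip(ann["protein_id"], ann["start"]))
            cons_records = conservation.annotate_disease(cons_records, ids)
        outputs["conservation"] = outdir / "conservation.tsv"
        conservation.write_conservation_table(cons_records, outputs["conservation"])
        comp = conservation.compare_variant_status(cons_records)
        outputs["conservation_by_length"] = outdir / "conservation_by_length.tsv"
        comp["per_length"].to_csv(outputs["conservation_by_length"], sep="\t", index=False)

    report_lines = [
        f"proteins: {len(proteome)}",
        f"homorepeats (min length {config.min_repeat_len}): {len(repeats)}",
        f"variants after filtering/mapping: {len(vs)} (AC >= {vs.ac_threshold})",
        f"residue coverage: {100 * coverage:.2f}%",
        f"overall overlap frequency: {100 * observed.overall_frequency:.2f}%",
    ]
    for _, row in summary.iterrows():
        report_lines.append(
            f"class {row['length_class']}: {100 * row['frequency']:.2f}% observed, "
            f"{100 * row['baseline_frequency']:.2f}% baseline, "
            f"fold {row['fold_enrichment']:.2f}"
        )
    if cons_records:
        comp = conservation.compare_variant_status(cons_records)
        report_lines.append(
            f"mean aligned-Q SD: {comp['mean_sd_with']:.2f} (with variants) vs "
            f"{comp['mean_sd_without']:.2f} (without)"
        )
    report_lines.extend(f"output: {p.name}" for p in outputs.values())
    outputs["report"] = outdir / "report.txt"
    outputs["report"].write_text("\n".join(report_lines) + "\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "outputs": {
            name: {"path": str(p), "sha256": simulate.file_checksum(p)}
            for name, p in outputs.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = manifest_path
    return outputs
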