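"""Simplified protein-level population variant records.

Variants are consumed at protein level, the way large population databases
summarise coding consequences: a protein id, the reference residue and
1-based position, a variant type (missense / deletion / insertion /
duplication / frameshift / stop), the affected span, and an allele count
(AC) used both as a prevalence weight and a filtering threshold.

A *duplication* is an insertion whose inserted residues copy the reference
sequence immediately preceding the insertion point — inside a homorepeat,
a repeat-unit gain produced by replication slippage.  Source data usually
encodes these as plain insertions; :func:`refine_duplication` reconstructs
the distinction from sequence context.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .scan import ProteinSequence

logger = logging.getLogger(__name__)

VARIANT_TYPES = ("missense", "deletion", "insertion", "duplication", "frameshift", "stop")

#: TSV schema of the simplified variant table ("." marks empty fields).
TABLE_COLUMNS = (
    "ensembl_protein_id",
    "ref_aa",
    "position",
    "vtype",
    "alt_aa",
    "inserted_seq",
    "span",
    "allele_count",
)


@dataclass(frozen=True)
class VariantRecord:
    """One simplified protein-level variant."""

    ensembl_protein_id: str
    ref_aa: str
    position: int
    vtype: str
    alt_aa: str | None = None
    inserted_seq: str | None = None
    span: int = 1
    allele_count: int = 1
    uniprot_acc: str | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.position < 1 or self.span < 1 or self.allele_count < 1:
            raise ValueError(
                f"invalid record at {self.ensembl_protein_id}:{self.position} "
                f"(span={self.span}, AC={self.allele_count})"
            )
        if self.vtype == "missense":
            if not self.alt_aa:
                raise ValueError("missense record requires alt_aa")
            if self.alt_aa == self.ref_aa:
                raise ValueError("synonymous record (alt_aa == ref_aa)")
        if self.vtype in ("insertion", "duplication") and not self.inserted_seq:
            raise ValueError(f"{self.vtype} record requires inserted_seq")

    @property
    def protein_id(self) -> str:
        """Mapped accession when available, source id otherwise."""
        return self.uniprot_acc or self.ensembl_protein_id

    @property
    def key(self) -> tuple:
        """Identity of a variant *site*: distinct alternates at one position
        are distinct sites."""
        return (
            self.ensembl_protein_id,
            self.position,
            self.vtype,
            self.alt_aa or self.inserted_seq or "",
            self.span,
        )

    @property
    def interval(self) -> tuple[int, int]:
        """1-based inclusive interval of affected reference residues.

        Insertions (and duplications) anchor at the single residue after
        which material is inserted; frameshift/stop anchor at the first
        affected residue.
        """
        if self.vtype in ("insertion", "duplication"):
            return (self.position, self.position)
        return (self.position, self.position + self.span - 1)


@dataclass
class VariantSet:
    """A collection of variant records with its provenance and AC threshold."""

    records: list[VariantRecord]
    source_label: str = "merged"
    ac_threshold: int = 1

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_protein(self) -> dict[str, list[VariantRecord]]:
        out: dict[str, list[VariantRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.protein_id, []).append(rec)
        return out


def _parse_field(value: str) -> str | None:
    value = value.strip()
    return None if value in (".", "") else value


def parse_variant_table(tsv_path: str | Path, max_bad_fraction: float = 0.01) -> VariantSet:
    """Parse the simplified variant TSV into a :class:`VariantSet`.

    Synonymous rows (``alt_aa == ref_aa``) are dropped with a counted
    warning.  Malformed rows are reported with their line number; if more
    than ``max_bad_fraction`` of rows are bad the parse aborts.
    """
    records: list[VariantRecord] = []
    n_bad = n_syn = n_rows = 0
    errors: list[str] = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{tsv_path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                rec = VariantRecord(
                    ensembl_protein_id=row["ensembl_protein_id"].strip(),
                    ref_aa=row["ref_aa"].strip(),
                    position=int(row["position"]),
                    vtype=row["vtype"].strip(),
                    alt_aa=_parse_field(row["alt_aa"]),
                    inserted_seq=_parse_field(row["inserted_seq"]),
                    span=int(row["span"]),
                    allele_count=int(row["allele_count"]),
                )
            except ValueError as exc:
                if "synonymous" in str(exc):
                    n_syn += 1
                else:
                    n_bad += 1
                    errors.append(f"line {lineno}: {exc}")
                continue
            records.append(rec)
    if n_syn:
        logger.warning("%s: dropped %d synonymous row(s)", tsv_path, n_syn)
    if n_bad:
        logger.warning("%s: %d malformed row(s): %s", tsv_path, n_bad, "; ".join(errors[:5]))
        if n_rows and n_bad / n_rows > max_bad_fraction:
            raise ValueError(
                f"{tsv_path}: {n_bad}/{n_rows} malformed rows exceeds "
                f"{max_bad_fraction:.0%} tolerance; first: {errors[0]}"
            )
    return VariantSet(records=records, source_label="merged", ac_threshold=1)


def write_variant_table(vs: VariantSet, path: str | Path) -> None:
    """Write a variant set back to the TSV schema (round-trips with
    :func:`parse_variant_table` up to column order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in vs.records:
            fh.write(
                f"{r.ensembl_protein_id}\t{r.ref_aa}\t{r.position}\t{r.vtype}\t"
                f"{r.alt_aa or '.'}\t{r.inserted_seq or '.'}\t{r.span}\t{r.allele_count}\n"
            )


#: VEP/SnpEff-style consequence terms handled by the VCF adapter.
CONSEQUENCE_MAP = {
    "missense_variant": "missense",
    "inframe_deletion": "deletion",
    "inframe_insertion": "insertion",
    "frameshift_variant": "frameshift",
    "stop_gained": "stop",
}


def parse_vep_vcf(vcf_path: str | Path, csq_tag: str = "CSQ") -> VariantSet:
    """Adapter for VCF input with per-allele consequence annotation.

    Each alternate allele of each site yields at most one record; the
    consequence term is mapped through :data:`CONSEQUENCE_MAP`, synonymous
    and unhandled terms are dropped and counted.  Requires the annotation
    header to declare at least Consequence, ENSP, Protein_position and
    Amino_acids fields, and the site to carry per-allele AC.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(vcf_path))
    raw = vcf.get_header_type(csq_tag)
    if raw is None:
        raise ValueError(f"{vcf_path}: missing {csq_tag!r} consequence annotation in header")
    fmt = raw.get("Description", "").rsplit("Format:", 1)
    if len(fmt) != 2:
        raise ValueError(f"{vcf_path}: {csq_tag} header lacks a 'Format:' field list")
    fields = [f.strip(' "') for f in fmt[1].strip(' "').split("|")]
    idx = {name: i for i, name in enumerate(fields)}
    for needed in ("Consequence", "ENSP", "Protein_position", "Amino_acids"):
        if needed not in idx:
            raise ValueError(f"{vcf_path}: {csq_tag} annotation lacks field {needed!r}")

    records: list[VariantRecord] = []
    n_dropped = 0
    for site in vcf:
        csq = site.INFO.get(csq_tag)
        if csq is None:
            continue
        acs = site.INFO.get("AC")
        if not isinstance(acs, tuple):
            acs = (acs,)
        for entry in str(csq).split(","):
            parts = entry.split("|")
            terms = parts[idx["Consequence"]].split("&")
            vtype = next((CONSEQUENCE_MAP[t] for t in terms if t in CONSEQUENCE_MAP), None)
            if vtype is None:
                n_dropped += 1
                continue
            allele_idx = 0
            if "ALLELE_NUM" in idx and parts[idx["ALLELE_NUM"]]:
                allele_idx = int(parts[idx["ALLELE_NUM"]]) - 1
            ac = int(acs[allele_idx]) if acs[allele_idx] is not None else 0
            if ac < 1:
                n_dropped += 1
                continue
            pos_field = parts[idx["Protein_position"]]
            if not pos_field:
                n_dropped += 1
                continue
            pos_parts = pos_field.split("-")
            position = int(pos_parts[0])
            span = int(pos_parts[-1]) - position + 1 if len(pos_parts) > 1 else 1
            aa_field = parts[idx["Amino_acids"]].split("/")
            ref_field = aa_field[0] or "-"
            ref_aa = ref_field[0]
            alt = aa_field[1] if len(aa_field) > 1 else None
            try:
                if vtype == "missense":
                    rec = VariantRecord(parts[idx["ENSP"]], ref_aa, position, "missense",
                                        alt_aa=alt, allele_count=ac)
                elif vtype == "insertion":
                    # VEP writes "Q/QQQ" (anchored) or "-/QQ" (pure insertion);
                    # strip the anchored reference prefix to get the insert.
                    inserted = alt or ""
                    if ref_field != "-" and inserted.startswith(ref_field):
                        inserted = inserted[len(ref_field):]
                    rec = VariantRecord(parts[idx["ENSP"]], ref_aa, position, "insertion",
                                        inserted_seq=inserted or alt,
                                        allele_count=ac)
                elif vtype == "deletion":
                    rec = VariantRecord(parts[idx["ENSP"]], ref_aa, position, "deletion",
                                        span=span, allele_count=ac)
                else:  # frameshift, stop: anchored at first affected residue
                    rec = VariantRecord(parts[idx["ENSP"]], ref_aa, position, vtype,
                                        allele_count=ac)
            except ValueError:
                n_dropped += 1
                continue
            records.append(rec)
    if n_dropped:
        logger.info("%s: dropped %d non-mappable consequence entries", vcf_path, n_dropped)
    return VariantSet(records=records, source_label="vcf", ac_threshold=1)


def filter_by_ac(vs: VariantSet, min_ac: int) -> VariantSet:
    """Keep records with ``allele_count >= min_ac`` and record the threshold."""
    if min_ac < 1:
        raise ValueError(f"min_ac must be >= 1, got {min_ac}")
    kept = [r for r in vs.records if r.allele_count >= min_ac]
    return VariantSet(records=kept, source_label=vs.source_label,
                      ac_threshold=max(vs.ac_threshold, min_ac))


def merge_variant_sets(
    exome: VariantSet,
    genome: VariantSet,
    min_ac: int = 10,
    mode: str = "pool",
) -> VariantSet:
    """Combine exome- and genome-derived sets into the merged AC-filtered set.

    ``mode="pool"`` (default) sums allele counts of records sharing the same
    site key before applying the threshold, treating the two sources as
    pooled evidence for the same allele.  ``mode="union"`` instead keeps the
    union of records that individually pass the threshold (summing AC for
    shared keys afterwards).
    """
    if mode not in ("pool", "union"):
        raise ValueError(f"unknown merge mode {mode!r}")
    if mode == "union":
        exome = filter_by_ac(exome, min_ac)
        genome = filter_by_ac(genome, min_ac)
    pooled: dict[tuple, VariantRecord] = {}
    for rec in list(exome.records) + list(genome.records):
        prev = pooled.get(rec.key)
        if prev is None:
            pooled[rec.key] = rec
        else:
            pooled[rec.key] = replace(prev, allele_count=prev.allele_count + rec.allele_count)
    merged = VariantSet(records=list(pooled.values()), source_label="merged", ac_threshold=1)
    return filter_by_ac(merged, min_ac) if mode == "pool" else replace_threshold(merged, min_ac)


def replace_threshold(vs: VariantSet, min_ac: int) -> VariantSet:
    vs.ac_threshold = max(vs.ac_threshold, min_ac)
    return vs


@dataclass
class MappingReport:
    """Bookkeeping for :func:`map_to_uniprot` drops."""

    n_unmapped: int = 0
    n_mismatch: int = 0
    n_kept: int = 0

    @property
    def mismatch_fraction(self) -> float:
        total = self.n_kept + self.n_mismatch
        return self.n_mismatch / total if total else 0.0


def read_id_mapping(tsv_path: str | Path) -> dict[str, str]:
    """Read a two-column (ensembl_protein_id, uniprot_acc) mapping TSV.

    Later rows for an already-mapped ensembl id are ignored (each source id
    maps to at most one retained accession)."""
    mapping: dict[str, str] = {}
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ens, uni = line.split("\t")[:2]
            if ens == "ensembl_protein_id":  # optional header
                continue
            mapping.setdefault(ens, uni)
    return mapping


def map_to_uniprot(
    vs: VariantSet,
    mapping: Mapping[str, str],
    proteome: Sequence[ProteinSequence],
) -> tuple[VariantSet, MappingReport]:
    """Attach reference-proteome accessions and validate reference residues.

    Records whose source id has no mapping are dropped; records whose
    ``ref_aa`` disagrees with the proteome residue at their position are
    dropped and counted separately (coordinate-mismatch report).  Pure
    insertions carry ``ref_aa = "-"`` and skip the residue check; their
    anchor must still lie inside the protein.
    """
    index = {p.protein_id: p for p in proteome}
    report = MappingReport()
    kept: list[VariantRecord] = []
    for rec in vs.records:
        acc = mapping.get(rec.ensembl_protein_id)
        if acc is None or acc not in index:
            report.n_unmapped += 1
            continue
        protein = index[acc]
        if rec.position > len(protein):
            report.n_mismatch += 1
            continue
        if rec.ref_aa != "-" and protein.residue(rec.position) != rec.ref_aa:
            report.n_mismatch += 1
            continue
        kept.append(replace(rec, uniprot_acc=acc))
        report.n_kept += 1
    if report.n_unmapped or report.n_mismatch:
        logger.info(
            "mapping: kept %d, dropped %d unmapped, %d coordinate mismatches (%.2f%%)",
            report.n_kept, report.n_unmapped, report.n_mismatch,
            100 * report.mismatch_fraction,
        )
    return VariantSet(kept, vs.source_label, vs.ac_threshold), report


def refine_duplication(v: VariantRecord, protein: ProteinSequence) -> VariantRecord:
    """Reclassify an insertion as a duplication from sequence context.

    An insertion becomes a duplication iff the inserted residues equal the
    reference substring of the same length ending at the anchor position —
    the protein-level signature of a replication-slippage repeat-unit gain.
    Windows extending before residue 1 leave the record unchanged.
    """
    if v.vtype != "insertion" or not v.inserted_seq:
        return v
    k = len(v.inserted_seq)
    lo = v.position - k + 1
    if lo < 1 or v.position > len(protein):
        return v
    preceding = protein.sequence[lo - 1 : v.position]
    if preceding == v.inserted_seq:
        return replace(v, vtype="duplication")
    return v


def refine_duplications(vs: VariantSet, proteome: Sequence[ProteinSequence]) -> VariantSet:
    """Apply :func:`refine_duplication` to every insertion in the set."""
    index = {p.protein_id: p for p in proteome}
    out = [
        refine_duplication(r, index[r.protein_id]) if r.protein_id in index else r
        for r in vs.records
    ]
    return VariantSet(out, vs.source_label, vs.ac_threshold)
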