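"""Cross-primate polyQ length conservation from ortholog alignments.

For each long human polyQ tract (>= 8 glutamines), the tract is mapped to
its column span in a multiple alignment of the human protein with primate
orthologs, glutamines aligning to the tract are counted per species, and
the standard deviation of those counts summarises how much the tract
length varies across primates.  Tracts are then grouped by that variation
and compared by human variant status and disease annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .overlap import overlaps
from .scan import Homorepeat, ProteinSequence
from .variants import VariantSet

logger = logging.getLogger(__name__)


@dataclass
class OrthologAlignment:
    """A human protein aligned with its (primate) orthologs.

    Rows are aligned sequences over residues plus the gap character ``-``;
    all rows have equal length.  The human row, ungapped, must equal the
    reference protein sequence.
    """

    human_protein_id: str
    species: list[str]  # non-human row labels, in file order
    rows: dict[str, str]  # label -> aligned sequence (human under its id)

    @property
    def human_row(self) -> str:
        return self.rows[self.human_protein_id]

    @property
    def n_columns(self) -> int:
        return len(self.human_row)


def read_alignment(
    aligned_fasta: str | Path,
    human_id: str,
    reference: ProteinSequence | None = None,
) -> OrthologAlignment:
    """Read one ortholog set from aligned FASTA.

    The row whose id (first ``|``-delimited accession token) matches
    ``human_id`` is the human reference row; remaining rows are orthologs
    labelled by their FASTA ids.  If ``reference`` is given, the ungapped
    human row is validated against it.
    """
    aln = AlignIO.read(str(aligned_fasta), "fasta")
    rows: dict[str, str] = {}
    labels: list[str] = []
    human_found = False
    for rec in aln:
        token = rec.id.split("|")
        label = token[1] if len(token) >= 3 and token[1] else rec.id
        rows[label] = str(rec.seq).upper()
        if label == human_id:
            human_found = True
        else:
            labels.append(label)
    if not human_found:
        raise ValueError(f"{aligned_fasta}: no row matches human id {human_id!r}")
    if not labels:
        raise ValueError(f"{aligned_fasta}: alignment has no ortholog rows")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{aligned_fasta}: ragged alignment rows (lengths {sorted(lengths)})")
    if reference is not None:
        ungapped = rows[human_id].replace("-", "")
        if ungapped != reference.sequence:
            raise ValueError(
                f"{aligned_fasta}: ungapped human row differs from reference "
                f"protein {human_id} ({len(ungapped)} vs {len(reference)} residues)"
            )
    return OrthologAlignment(human_protein_id=human_id, species=labels, rows=rows)


def map_region_to_columns(aln: OrthologAlignment, polyq: Homorepeat) -> tuple[int, int]:
    """Map a human tract to its inclusive alignment-column interval.

    The span runs from the column holding human residue ``polyq.start`` to
    the column holding residue ``polyq.end``.  Interior columns where the
    human row is gapped (ortholog insertions) are included — an ortholog's
    expanded tract counts fully as aligning with the human region.
    """
    if polyq.protein_id != aln.human_protein_id:
        raise ValueError(
            f"repeat on {polyq.protein_id} vs alignment of {aln.human_protein_id}"
        )
    col_start = col_end = None
    residue = 0
    for col, ch in enumerate(aln.human_row, start=1):
        if ch == "-":
            continue
        residue += 1
        if residue == polyq.start:
            col_start = col
        if residue == polyq.end:
            col_end = col
            break
    if col_start is None or col_end is None:
        raise ValueError(
            f"tract [{polyq.start},{polyq.end}] exceeds human row "
            f"({residue} residues) in alignment of {aln.human_protein_id}"
        )
    return (col_start, col_end)


def count_q(
    aln: OrthologAlignment,
    span: tuple[int, int],
    species: str,
    residue: str = "Q",
) -> int:
    """Number of ``residue`` characters one row places within a column span.

    Gaps and other residues do not count.
    """
    if species not in aln.rows:
        raise KeyError(f"unknown species/row {species!r}")
    lo, hi = span
    if not 1 <= lo <= hi <= aln.n_columns:
        raise ValueError(f"invalid column span [{lo},{hi}]")
    return aln.rows[species][lo - 1 : hi].count(residue)


def polyq_sd(counts: Sequence[int], ddof: int = 1) -> float:
    """Standard deviation of per-species aligned-glutamine counts.

    Sample standard deviation (divisor n-1) by default — conventional for
    the small species numbers involved; ``ddof=0`` switches to the
    population form.  Returns NaN for fewer than two counts.
    """
    if len(counts) < 2:
        return float("nan")
    return float(np.std(np.asarray(counts, dtype=float), ddof=ddof))


@dataclass
class ConservationRecord:
    """Per-tract conservation summary across primate orthologs."""

    protein_id: str
    start: int
    length: int
    q_counts: dict[str, int]  # per non-human species
    sd: float
    n_species: int
    has_variant: bool = False
    variant_count: int = 0
    variant_allele_sum: int = 0
    group: str | None = None  # large / medium / low (with-variant tracts only)
    disease_flag: bool = False

    @property
    def polyq_id(self) -> tuple[str, int]:
        return (self.protein_id, self.start)


def build_conservation_records(
    alignments: Mapping[str, OrthologAlignment],
    repeats: Sequence[Homorepeat],
    min_len: int = 8,
    include_human: bool = False,
) -> list[ConservationRecord]:
    """One record per polyQ tract of length >= ``min_len`` whose protein has
    an alignment.

    The SD is computed over the non-human species' aligned-glutamine counts
    by default (``include_human`` adds the human tract length itself).
    """
    records: list[ConservationRecord] = []
    for rep in repeats:
        if rep.aa != "Q" or rep.length < min_len:
            continue
        aln = alignments.get(rep.protein_id)
        if aln is None:
            continue
        span = map_region_to_columns(aln, rep)
        counts = {sp: count_q(aln, span, sp) for sp in aln.species}
        values = list(counts.values())
        if include_human:
            values.append(count_q(aln, span, aln.human_protein_id))
        records.append(
            ConservationRecord(
                protein_id=rep.protein_id,
                start=rep.start,
                length=rep.length,
                q_counts=counts,
                sd=polyq_sd(values),
                n_species=len(values),
            )
        )
    return records


def attach_variant_status(
    records: Sequence[ConservationRecord],
    repeats: Sequence[Homorepeat],
    vs: VariantSet,
) -> list[ConservationRecord]:
    """Fill has_variant / variant_count / variant_allele_sum per tract."""
    rep_by_id = {(r.protein_id, r.start): r for r in repeats}
    by_protein = vs.by_protein()
    out: list[ConservationRecord] = []
    for rec in records:
        rep = rep_by_id.get(rec.polyq_id)
        if rep is None:
            out.append(rec)
            continue
        hits = [v for v in by_protein.get(rep.protein_id, ()) if overlaps(rep, v)]
        rec = replace(
            rec,
            has_variant=bool(hits),
            variant_count=len(hits),
            variant_allele_sum=sum(v.allele_count for v in hits),
        )
        out.append(rec)
    return out


def group_by_variation(
    records: Sequence[ConservationRecord],
    k: int = 3,
) -> list[ConservationRecord]:
    """Label with-variant tracts as large / medium / low variation tertiles.

    Records with ``has_variant`` are ranked by descending SD (ties broken
    by protein accession then start — deterministic) and split into ``k``
    groups whose sizes differ by at most one; labels follow descending SD.
    Tracts without variants keep ``group=None``.
    """
    labels = ("large", "medium", "low") if k == 3 else tuple(f"g{i}" for i in range(k))
    with_var = [r for r in records if r.has_variant]
    rest = [r for r in records if not r.has_variant]
    if not with_var:
        return list(records)
    if len(with_var) < k:
        logger.warning(
            "only %d with-variant tract(s); assigning all to %r", len(with_var), labels[0]
        )
        groups = [with_var]
    else:
        ordered = sorted(with_var, key=lambda r: (-r.sd, r.protein_id, r.start))
        groups = [list(part) for part in np.array_split(ordered, k)]
    out = []
    for label, grp in zip(labels, groups):
        out.extend(replace(r, group=label) for r in grp)
    out.extend(rest)
    return out


def annotate_disease(
    records: Sequence[ConservationRecord],
    disease_ids: Iterable[tuple[str, int]],
) -> list[ConservationRecord]:
    """Set the disease flag for tracts listed in a (protein_id, start) set."""
    ids = set(disease_ids)
    return [replace(r, disease_flag=(r.polyq_id in ids)) for r in records]


def compare_variant_status(records: Sequence[ConservationRecord]) -> dict:
    """Mean SD for tracts with vs without human variants, plus per-exact-
    length stratified means.

    Returns a dict with ``mean_sd_with``, ``mean_sd_without`` and a
    ``per_length`` DataFrame (length, n/mean_sd per status); strata empty
    on one side are retained with NaN.
    """
    with_sd = [r.sd for r in records if r.has_variant and not np.isnan(r.sd)]
    without_sd = [r.sd for r in records if not r.has_variant and not np.isnan(r.sd)]
    rows = []
    for L in sorted({r.length for r in records}):
        w = [r.sd for r in records if r.length == L and r.has_variant]
        wo = [r.sd for r in records if r.length == L and not r.has_variant]
        rows.append(
            {
                "length": L,
                "n_with": len(w),
                "mean_sd_with": float(np.mean(w)) if w else float("nan"),
                "n_without": len(wo),
                "mean_sd_without": float(np.mean(wo)) if wo else float("nan"),
            }
        )
    return {
        "mean_sd_with": float(np.mean(with_sd)) if with_sd else float("nan"),
        "mean_sd_without": float(np.mean(without_sd)) if without_sd else float("nan"),
        "per_length": pd.DataFrame(rows),
    }


def compare_disease(
    records: Sequence[ConservationRecord],
    disease_ids: Iterable[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per variation group, mean SD and mean allele sum by disease status.

    If ``disease_ids`` is given the records are (re-)annotated first.
    Returns one row per (group, disease status) with the means and, per
    group, the disease/non-disease ratio of mean allele sums (NaN where a
    stratum is empty).
    """
    if disease_ids is not None:
        records = annotate_disease(records, disease_ids)
    rows = []
    groups = sorted({r.group for r in records if r.group is not None})
    for grp in groups:
        sub = [r for r in records if r.group == grp]
        dis = [r for r in sub if r.disease_flag]
        non = [r for r in sub if not r.disease_flag]
        mean_ac_dis = float(np.mean([r.variant_allele_sum for r in dis])) if dis else float("nan")
        mean_ac_non = float(np.mean([r.variant_allele_sum for r in non])) if non else float("nan")
        for label, part, mean_ac in (("disease", dis, mean_ac_dis),
                                     ("non_disease", non, mean_ac_non)):
            rows.append(
                {
                    "group": grp,
                    "status": label,
                    "n": len(part),
                    "mean_sd": float(np.mean([r.sd for r in part])) if part else float("nan"),
                    "mean_allele_sum": mean_ac,
                    "allele_sum_ratio": (mean_ac_dis / mean_ac_non
                                         if non and dis and mean_ac_non else float("nan")),
                }
            )
    return pd.DataFrame(rows)


def write_conservation_table(records: Sequence[ConservationRecord], path) -> None:
    species = sorted({sp for r in records for sp in r.q_counts})
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "start": r.start,
            "length": r.length,
            "n_species": r.n_species,
            "sd": r.sd,
            "has_variant": int(r.has_variant),
            "variant_count": r.variant_count,
            "variant_allele_sum": r.variant_allele_sum,
            "group": r.group or ".",
            "disease_flag": int(r.disease_flag),
        }
        for sp in species:
            row[f"q_{sp}"] = r.q_counts.get(sp, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
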