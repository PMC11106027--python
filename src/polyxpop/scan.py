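"""Proteome reading and maximal homorepeat detection.

A homorepeat (polyX) is a maximal run of a single amino acid within one
protein.  Runs are reported with 1-based inclusive coordinates, the
convention used by protein-level variant annotation.  Repeats of length
three and above are stratified into the length classes ``3``, ``4-5``,
``6-7`` and ``8+`` used throughout the package.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The twenty standard amino acids; other letters (X, U, B, Z, ...) are
#: tolerated in sequences but excluded from repeat output by default.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Length-class labels, ordered.  Classes partition the integers >= 3.
LENGTH_CLASSES = ("3", "4-5", "6-7", "8+")


@dataclass(frozen=True)
class ProteinSequence:
    """One protein of the (one-sequence-per-gene) reference proteome."""

    protein_id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"whitespace in sequence of {self.protein_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class Homorepeat:
    """A maximal pure run of one amino acid, 1-based inclusive interval."""

    protein_id: str
    aa: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_class(self) -> str:
        return length_class(self.length)


def length_class(length: int) -> str:
    """Map a repeat length (>= 3) to its class label.

    The boundary case is length 8: the longest class is ``8+`` (length >= 8),
    matching the minimum of eight glutamines used for the polyQ
    conservation analysis.
    """
    if length < 3:
        raise ValueError(f"length class undefined for length {length} < 3")
    if length == 3:
        return "3"
    if length <= 5:
        return "4-5"
    if length <= 7:
        return "6-7"
    return "8+"


def _accession_from_header(header: str) -> str:
    """Extract the accession from a FASTA id token.

    UniProt-style ``db|ACC|NAME`` ids yield the middle field; anything else
    is returned verbatim (first whitespace-delimited token).
    """
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def read_proteome(
    fasta_path: str | Path,
    gene_dedup_map: Mapping[str, str] | None = None,
) -> list[ProteinSequence]:
    """Read a proteome FASTA (plain or gzip) into :class:`ProteinSequence`.

    Parameters
    ----------
    fasta_path
        Path to a FASTA file; ``.gz`` suffixed files are decompressed.
    gene_dedup_map
        Optional mapping ``accession -> gene id``.  When given, exactly one
        protein is kept per gene: the lexicographically smallest accession
        (deterministic).  Accessions absent from the map are retained.

    Raises
    ------
    ValueError
        On duplicate protein ids or records with empty sequences.
    """
    fasta_path = Path(fasta_path)
    opener = gzip.open if fasta_path.suffix == ".gz" else open
    proteins: list[ProteinSequence] = []
    seen: set[str] = set()
    with opener(fasta_path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            acc = _accession_from_header(rec.description or rec.id)
            if acc in seen:
                raise ValueError(f"duplicate protein id {acc!r} in {fasta_path}")
            seen.add(acc)
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"record {acc!r} in {fasta_path} has an empty sequence")
            gene = gene_dedup_map.get(acc) if gene_dedup_map else None
            proteins.append(ProteinSequence(protein_id=acc, sequence=seq, gene_id=gene))
    if not proteins:
        logger.warning("no records parsed from %s", fasta_path)
    if gene_dedup_map:
        proteins = _dedup_by_gene(proteins)
    return proteins


def _dedup_by_gene(proteins: Sequence[ProteinSequence]) -> list[ProteinSequence]:
    by_gene: dict[str, ProteinSequence] = {}
    kept: list[ProteinSequence] = []
    for p in proteins:
        if p.gene_id is None:
            kept.append(p)
            continue
        best = by_gene.get(p.gene_id)
        if best is None or p.protein_id < best.protein_id:
            by_gene[p.gene_id] = p
    dropped = sum(p.gene_id is not None for p in proteins) - len(by_gene)
    if dropped:
        logger.info("gene dedup dropped %d redundant isoform(s)", dropped)
    kept.extend(sorted(by_gene.values(), key=lambda p: p.protein_id))
    return kept


def scan_homorepeats(
    protein: ProteinSequence,
    min_len: int = 3,
    aa_filter: str | None = None,
    include_nonstandard: bool = False,
) -> list[Homorepeat]:
    """Detect all maximal pure runs of length >= ``min_len`` in one protein.

    Runs are returned in ascending start order.  Maximality is guaranteed by
    construction: consecutive runs of the same residue are always separated
    by at least one different residue.

    Parameters
    ----------
    min_len
        Minimum run length (default 3, the shortest repeat analysed).
    aa_filter
        Restrict output to runs of this residue (e.g. ``"Q"`` for polyQ).
    include_nonstandard
        If true, runs of non-standard letters (X, U, B, Z...) are reported
        too; by default only the 20 standard amino acids form repeats.
    """
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    repeats: list[Homorepeat] = []
    pos = 1
    for aa, group in groupby(protein.sequence):
        run_len = sum(1 for _ in group)
        keep = (
            run_len >= min_len
            and (aa_filter is None or aa == aa_filter)
            and (include_nonstandard or aa in STANDARD_AA)
        )
        if keep:
            repeats.append(
                Homorepeat(protein_id=protein.protein_id, aa=aa, start=pos, end=pos + run_len - 1)
            )
        pos += run_len
    return repeats


def scan_proteome(
    proteome: Iterable[ProteinSequence],
    min_len: int = 3,
    aa_filter: str | None = None,
    include_nonstandard: bool = False,
) -> list[Homorepeat]:
    """Scan every protein of a proteome; concatenation of per-protein scans."""
    out: list[Homorepeat] = []
    for protein in proteome:
        out.extend(scan_homorepeats(protein, min_len, aa_filter, include_nonstandard))
    return out


def write_homorepeat_table(repeats: Iterable[Homorepeat], path: str | Path) -> None:
    """Write repeats as TSV (protein_id, aa, start, end, length; 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("protein_id\taa\tstart\tend\tlength\n")
        for r in repeats:
            fh.write(f"{r.protein_id}\t{r.aa}\t{r.start}\t{r.end}\t{r.length}\n")


def write_homorepeat_bed(repeats: Iterable[Homorepeat], path: str | Path) -> None:
    """BED-like export: 0-based half-open coordinates (protein as the 'chrom')."""
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.protein_id}\t{r.start - 1}\t{r.end}\t{r.aa}\n")
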