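"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators stand in for the multi-GB proteome / population-variant /
ortholog downloads: a proteome with injected homorepeats of controlled
lengths, protein-level variant tables under an iid per-position rate model
with a configurable type mix, and ortholog alignments whose per-species
glutamine counts are the human tract length plus integer jitter.  Every
generator is a pure function of its spec (seed included) and emits a
ground-truth table alongside its files.

A fourth generator, :func:`table1_fixture`, builds a deterministic toy
proteome and raw variant table whose end-to-end classification reproduces
the published per-length-class polyQ variant-type table row for row
(duplications are encoded as raw insertions so the context-based
refinement is exercised).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .scan import STANDARD_AA, Homorepeat, ProteinSequence, length_class
from .variants import VariantRecord, VariantSet, write_variant_table

#: Approximate residue composition of the human proteome, used as the
#: background model for synthetic protein sequences.
HUMAN_AA_FREQS = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}

#: The six primate ortholog species used for the conservation analysis.
PRIMATE_SPECIES = (
    "pan_troglodytes",
    "gorilla_gorilla",
    "pongo_abelii",
    "chlorocebus_sabaeus",
    "papio_anubis",
    "macaca_mulatta",
)

#: Default variant-type mix, loosely matching the relative prevalence of
#: protein-level consequence classes in population exome data (missense
#: dominant; indels and truncating types rarer).
DEFAULT_TYPE_DIST = {
    "missense": 0.60,
    "deletion": 0.10,
    "duplication": 0.08,
    "insertion": 0.04,
    "frameshift": 0.13,
    "stop": 0.05,
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic data generators.

    ``variant_rate`` defaults to 0.0145: the analysis observes population
    variants covering about 1.45% of reference-proteome positions, so the
    iid per-position rate is set to match that coverage.  ``q_jitter_sigma``
    defaults to 2.0 glutamines, a dispersion at which cross-primate tract
    lengths visibly spread without collapsing short tracts to zero.
    """

    seed: int = 20240520
    n_proteins: int = 150
    protein_length_log_mean: float = 6.0  # lognormal, ~400 aa median
    protein_length_log_sigma: float = 0.45
    protein_length_min: int = 60
    protein_length_max: int = 3000
    injections: tuple = (
        ("Q", (3, 4, 5, 6, 7, 8, 9, 10, 12, 15, 20), 80),
        ("A", (3, 4, 5, 6, 8), 40),
        ("E", (3, 4, 5, 8), 40),
        ("G", (3, 4, 6), 40),
    )
    variant_rate: float = 0.0145
    type_dist: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_DIST))
    ac_pareto_shape: float = 1.2
    ac_pareto_scale: float = 8.0
    ac_max: int = 2_000_000
    n_species: int = 6
    q_jitter_sigma: float = 2.0
    species_missing_prob: float = 0.0


def _rng(spec: SyntheticSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def _draw_background(rng: np.random.Generator, n: int, freqs=HUMAN_AA_FREQS) -> np.ndarray:
    letters = np.array(list(freqs))
    probs = np.array(list(freqs.values()))
    probs = probs / probs.sum()
    return rng.choice(letters, size=n, p=probs)


def gen_proteome(spec: SyntheticSpec) -> tuple[list[ProteinSequence], pd.DataFrame]:
    """Generate a synthetic proteome with injected homorepeats.

    Residues flanking an injected run are forced to differ from the run's
    residue, so truth lengths are exact; accidental background runs may
    occur elsewhere and are deliberately left in place.

    Returns the proteome and a truth table (protein_id, aa, start, end,
    length) of every injected repeat.
    """
    rng = _rng(spec, 1)
    lengths = np.exp(
        rng.normal(spec.protein_length_log_mean, spec.protein_length_log_sigma, spec.n_proteins)
    ).astype(int)
    lengths = np.clip(lengths, spec.protein_length_min, spec.protein_length_max)
    seqs = [_draw_background(rng, int(n)) for n in lengths]
    occupied: list[list[tuple[int, int]]] = [[] for _ in seqs]
    truth_rows = []

    for aa, length_choices, count in spec.injections:
        for _ in range(count):
            run_len = int(rng.choice(length_choices))
            placed = False
            for _try in range(1000):
                pi = int(rng.integers(0, len(seqs)))
                plen = len(seqs[pi])
                if plen < run_len + 2:
                    continue
                start0 = int(rng.integers(1, plen - run_len))  # 0-based, flanks inside
                # buffer of one residue so injected runs never merge
                if any(start0 - 1 <= e and start0 + run_len >= s for s, e in occupied[pi]):
                    continue
                seqs[pi][start0 : start0 + run_len] = aa
                for flank in (start0 - 1, start0 + run_len):
                    if seqs[pi][flank] == aa:
                        others = [c for c in STANDARD_AA if c != aa]
                        seqs[pi][flank] = others[int(rng.integers(0, len(others)))]
                occupied[pi].append((start0 - 1, start0 + run_len))
                truth_rows.append(
                    {
                        "protein_id": f"SYN{pi:05d}",
                        "aa": aa,
                        "start": start0 + 1,
                        "end": start0 + run_len,
                        "length": run_len,
                    }
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {aa}-run of length {run_len} after 1000 tries"
                )

    proteome = [
        ProteinSequence(protein_id=f"SYN{i:05d}", sequence="".join(s))
        for i, s in enumerate(seqs)
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "aa", "start", "end", "length"]
    ).sort_values(["protein_id", "start"]).reset_index(drop=True)
    return proteome, truth


def ensembl_id(protein_id: str) -> str:
    """Synthetic Ensembl-style id paired with a proteome accession."""
    return f"ENSP_{protein_id}"


def id_mapping_for(proteome: Sequence[ProteinSequence]) -> dict[str, str]:
    """Identity-style ensembl->accession mapping for a synthetic proteome."""
    return {ensembl_id(p.protein_id): p.protein_id for p in proteome}


def _draw_ac(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    ac = int(rng.pareto(spec.ac_pareto_shape) * spec.ac_pareto_scale) + 1
    return min(ac, spec.ac_max)


def gen_variants(
    spec: SyntheticSpec,
    proteome: Sequence[ProteinSequence],
) -> tuple[VariantSet, pd.DataFrame]:
    """Generate protein-level variants under the iid per-position rate model.

    Each position of each protein independently receives a variant with
    probability ``variant_rate``; its type is drawn from ``type_dist`` and
    its allele count from a heavy-tailed (Pareto) integer distribution that
    straddles the usual AC thresholds so filtering paths are exercised.
    Duplications are emitted as raw insertions whose inserted residues copy
    the immediately preceding reference residues, so the context-based
    refinement step is exercised downstream; the truth table records the
    intended type.
    """
    rng = _rng(spec, 2)
    types = list(spec.type_dist)
    probs = np.array([spec.type_dist[t] for t in types])
    probs = probs / probs.sum()
    records: list[VariantRecord] = []
    truth_rows = []
    for protein in proteome:
        n = len(protein)
        hits = np.flatnonzero(rng.random(n) < spec.variant_rate)
        for pos0 in hits:
            pos = int(pos0) + 1
            ref = protein.residue(pos)
            vtype = types[int(rng.choice(len(types), p=probs))]
            ac = _draw_ac(rng, spec)
            alt = inserted = None
            span = 1
            emitted = vtype
            if vtype == "missense":
                if ref not in STANDARD_AA:
                    continue
                choices = [c for c in STANDARD_AA if c != ref]
                alt = choices[int(rng.integers(0, len(choices)))]
            elif vtype == "deletion":
                span = int(min(rng.integers(1, 4), n - pos + 1))
            elif vtype == "duplication":
                j = int(min(rng.integers(1, 4), pos))
                inserted = protein.sequence[pos - j : pos]
                emitted = "insertion"
            elif vtype == "insertion":
                for _ in range(100):
                    k = int(rng.integers(1, 4))
                    cand = "".join(
                        STANDARD_AA[i] for i in rng.integers(0, 20, size=k)
                    )
                    if pos - k < 0 or protein.sequence[pos - k : pos] != cand:
                        inserted = cand
                        break
                else:
                    continue
            rec = VariantRecord(
                ensembl_protein_id=ensembl_id(protein.protein_id),
                ref_aa=ref,
                position=pos,
                vtype=emitted,
                alt_aa=alt,
                inserted_seq=inserted,
                span=span,
                allele_count=ac,
            )
            records.append(rec)
            truth_rows.append(
                {
                    "protein_id": protein.protein_id,
                    "position": pos,
                    "true_type": vtype,
                    "emitted_type": emitted,
                    "span": span,
                    "allele_count": ac,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "position", "true_type", "emitted_type", "span", "allele_count"],
    )
    return VariantSet(records=records, source_label="synthetic", ac_threshold=1), truth


def gen_ortholog_sets(
    spec: SyntheticSpec,
    proteome: Sequence[ProteinSequence],
    repeats: Sequence[Homorepeat],
    min_len: int = 8,
) -> tuple[dict, pd.DataFrame]:
    """Build ortholog alignments whose per-species glutamine counts are the
    human tract length plus integer jitter.

    For each polyQ tract of length >= ``min_len``, every species' aligned
    glutamine count is ``max(0, L + rint(N(0, q_jitter_sigma)))``.
    Alignments are constructed directly: species tract contractions appear
    as gap columns, expansions as insertion columns where the human row is
    gapped — so downstream column mapping is exercised.  Outside tract
    blocks all rows equal the human sequence.

    Returns ``{protein_id: OrthologAlignment}`` and a truth table of every
    per-species count.
    """
    from .conservation import OrthologAlignment

    rng = _rng(spec, 3)
    species = list(PRIMATE_SPECIES[: spec.n_species])
    by_protein: dict[str, list[Homorepeat]] = {}
    for rep in repeats:
        if rep.aa == "Q" and rep.length >= min_len:
            by_protein.setdefault(rep.protein_id, []).append(rep)

    alignments: dict[str, OrthologAlignment] = {}
    truth_rows = []
    index = {p.protein_id: p for p in proteome}
    for pid in sorted(by_protein):
        protein = index[pid]
        tracts = sorted(by_protein[pid], key=lambda r: r.start)
        present = [
            sp for sp in species
            if spec.species_missing_prob == 0 or rng.random() >= spec.species_missing_prob
        ]
        if not present:
            present = [species[0]]
        human_parts: list[str] = []
        orth_parts: dict[str, list[str]] = {sp: [] for sp in present}
        cursor = 1  # 1-based position in the human sequence
        for tract in tracts:
            between = protein.sequence[cursor - 1 : tract.start - 1]
            human_parts.append(between)
            for sp in present:
                orth_parts[sp].append(between)
            L = tract.length
            targets = {
                sp: max(0, L + int(np.rint(rng.normal(0.0, spec.q_jitter_sigma))))
                for sp in present
            }
            width = max([L] + list(targets.values()))
            # insertion columns sit before the tract's last residue so the
            # mapped column span covers every species' expanded glutamines
            human_parts.append("Q" * (L - 1) + "-" * (width - L) + "Q")
            for sp in present:
                t = targets[sp]
                orth_parts[sp].append("Q" * t + "-" * (width - t))
                truth_rows.append(
                    {
                        "protein_id": pid,
                        "start": tract.start,
                        "length": L,
                        "species": sp,
                        "q_count": t,
                    }
                )
            cursor = tract.end + 1
        tail = protein.sequence[cursor - 1 :]
        human_parts.append(tail)
        for sp in present:
            orth_parts[sp].append(tail)
        rows = {pid: "".join(human_parts)}
        for sp in present:
            rows[sp] = "".join(orth_parts[sp])
        alignments[pid] = OrthologAlignment(
            human_protein_id=pid, species=present, rows=rows
        )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "start", "length", "species", "q_count"]
    )
    return alignments, truth


def write_ortholog_fasta(alignments: dict, outdir: str | Path) -> list[Path]:
    """Write each ortholog alignment as aligned FASTA (one file per protein)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pid, aln in sorted(alignments.items()):
        path = outdir / f"{pid}.aln.fasta"
        with open(path, "w") as fh:
            fh.write(f">{pid}\n{aln.rows[pid]}\n")
            for sp in aln.species:
                fh.write(f">{sp}\n{aln.rows[sp]}\n")
        paths.append(path)
    return paths


def write_proteome_fasta(proteome: Sequence[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteome:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")


# --------------------------------------------------------------------------
# Published per-length-class polyQ variant-type table (the worked example).
# Each row: (length class, type label, number of distinct sites, summed
# allele count).  The length-3 class lists two separate "Gln > Lys" rows in
# the published table; key-level tabulation necessarily pools rows sharing
# (class, label), so comparisons use :func:`expected_polyq_table`.
# --------------------------------------------------------------------------
TABLE1_ROWS: tuple[tuple[str, str, int, int], ...] = (
    ("3", "Gln > Arg", 14, 105904),
    ("3", "Gln > His", 13, 176822),
    ("3", "Gln > Glu", 10, 341790),
    ("3", "Gln > Lys", 7, 119149),
    ("3", "Deletion", 5, 132770),
    ("3", "Frameshift", 3, 86716),
    ("3", "Gln > Pro", 2, 37006),
    ("3", "STOP", 2, 3115),
    ("3", "Duplication", 2, 262471),
    ("3", "Gln > Leu", 1, 637),
    ("3", "Gln > Lys", 1, 54),
    ("4-5", "Duplication", 10, 288488),
    ("4-5", "Deletion", 5, 31359),
    ("4-5", "Gln > Arg", 4, 285752),
    ("4-5", "Gln > Pro", 4, 12622),
    ("4-5", "Gln > His", 3, 544),
    ("4-5", "Gln > Lys", 2, 76022),
    ("4-5", "Gln > Glu", 2, 17314),
    ("4-5", "Frameshift", 1, 88),
    ("6-7", "Duplication", 19, 76849),
    ("6-7", "Deletion", 9, 166023),
    ("6-7", "Frameshift", 2, 17524),
    ("6-7", "Gln > Pro", 1, 66),
    ("6-7", "Gln > His", 1, 241),
    ("6-7", "Gln > Glu", 1, 1128),
    ("6-7", "Gln > Arg", 1, 754),
    ("8+", "Deletion", 90, 1547410),
    ("8+", "Duplication", 81, 452267),
    ("8+", "Frameshift", 51, 579171),
    ("8+", "Gln > Pro", 15, 30739),
    ("8+", "Gln > His", 12, 17591),
    ("8+", "Insertion", 11, 6543),
    ("8+", "Gln > Arg", 2, 1717),
    ("8+", "Gln > Glu", 2, 482),
)

_AA1 = {v: k for k, v in {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}.items()}

#: polyQ tract lengths of the fixture proteome, one protein per tract.
_FIXTURE_TRACTS: dict[str, tuple[int, ...]] = {
    "3": (3, 3, 3, 3, 3),
    "4-5": (4, 5, 5),
    "6-7": (6, 7),
    "8+": (8, 10, 12, 15, 20),
}

_TRACT_START = 5  # tract begins after a 4-residue Q-free prefix


@dataclass
class Table1Fixture:
    """Deterministic toy inputs reproducing the polyQ variant-type table."""

    proteome: list[ProteinSequence]
    variants: VariantSet  # raw: duplications encoded as insertions
    id_mapping: dict[str, str]
    expected_table: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write proteome FASTA, variant TSV and id-mapping TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "fixture_proteome.fasta",
            "variants": outdir / "fixture_variants.tsv",
            "mapping": outdir / "fixture_idmap.tsv",
        }
        write_proteome_fasta(self.proteome, paths["proteome"])
        write_variant_table(self.variants, paths["variants"])
        with open(paths["mapping"], "w") as fh:
            fh.write("ensembl_protein_id\tuniprot_acc\n")
            for ens, acc in sorted(self.id_mapping.items()):
                fh.write(f"{ens}\t{acc}\n")
        return paths


def _split_allele_counts(n: int, total: int) -> list[int]:
    base, rem = divmod(total, n)
    return [base + 1] * rem + [base] * (n - rem)


def expected_polyq_table() -> pd.DataFrame:
    """The published table as key-level tabulation reports it.

    Rows sharing (length class, type label) — the two length-3 "Gln > Lys"
    entries — are pooled; rows are sorted within class by descending site
    count with the label as tie-break, matching ``classify.tabulate``.
    """
    df = pd.DataFrame(TABLE1_ROWS, columns=["length_class", "type_label", "n_sites",
                                            "sum_allele_count"])
    df = (
        df.groupby(["length_class", "type_label"], as_index=False)[
            ["n_sites", "sum_allele_count"]
        ].sum()
    )
    order = {"3": 0, "4-5": 1, "6-7": 2, "8+": 3}
    df["_c"] = df["length_class"].map(order)
    df = df.sort_values(["_c", "n_sites", "type_label"], ascending=[True, False, True])
    return df.drop(columns="_c").reset_index(drop=True)


def table1_fixture() -> Table1Fixture:
    """Build the deterministic fixture behind the worked example.

    One synthetic protein per polyQ tract; each published (class, type)
    cell is realised as that many distinct variant sites at enumerated
    tract positions / spans, with the published summed allele count split
    across sites.  Duplications are written as raw insertions whose
    inserted glutamines copy the immediately preceding reference residues,
    so only correct context-based refinement recovers the published
    duplication counts.  No randomness: repeated calls are identical.
    """
    proteins: list[ProteinSequence] = []
    tract_of: dict[str, list[tuple[str, int]]] = {c: [] for c in _FIXTURE_TRACTS}
    i = 0
    for cls, lengths in _FIXTURE_TRACTS.items():
        for L in lengths:
            pid = f"QFIX{i:03d}"
            seq = "MSTA" + "Q" * L + "LENVDARTSPIKW"
            proteins.append(ProteinSequence(protein_id=pid, sequence=seq))
            tract_of[cls].append((pid, L))
            i += 1

    def positions(cls: str) -> Iterator[tuple[str, int]]:
        for pid, L in tract_of[cls]:
            for off in range(L):
                yield (pid, _TRACT_START + off)

    def deletions(cls: str) -> Iterator[tuple[str, int, int]]:
        for pid, L in tract_of[cls]:
            for span in range(1, L + 1):
                for off in range(L - span + 1):
                    yield (pid, _TRACT_START + off, span)

    def duplications(cls: str) -> Iterator[tuple[str, int, str]]:
        # anchor at offset k may copy up to k+1 preceding glutamines
        for pid, L in tract_of[cls]:
            for k in range(L):
                for j in range(1, k + 2):
                    yield (pid, _TRACT_START + k, "Q" * j)

    iters: dict[tuple, Iterator] = {}
    records: list[VariantRecord] = []
    for cls, label, n_sites, total_ac in TABLE1_ROWS:
        acs = _split_allele_counts(n_sites, total_ac)
        if label.startswith("Gln > "):
            alt = _AA1[label.split(" > ")[1]]
            it = iters.setdefault((cls, "missense", alt), positions(cls))
            for ac in acs:
                pid, pos = next(it)
                records.append(VariantRecord(ensembl_id(pid), "Q", pos, "missense",
                                             alt_aa=alt, allele_count=ac))
        elif label == "Deletion":
            it = iters.setdefault((cls, "deletion"), deletions(cls))
            for ac in acs:
                pid, pos, span = next(it)
                records.append(VariantRecord(ensembl_id(pid), "Q", pos, "deletion",
                                             span=span, allele_count=ac))
        elif label == "Duplication":
            it = iters.setdefault((cls, "duplication"), duplications(cls))
            for ac in acs:
                pid, pos, ins = next(it)
                records.append(VariantRecord(ensembl_id(pid), "Q", pos, "insertion",
                                             inserted_seq=ins, allele_count=ac))
        elif label == "Insertion":
            it = iters.setdefault((cls, "insertion"), positions(cls))
            for ac in acs:
                pid, pos = next(it)
                records.append(VariantRecord(ensembl_id(pid), "Q", pos, "insertion",
                                             inserted_seq="P", allele_count=ac))
        elif label in ("Frameshift", "STOP"):
            vtype = "frameshift" if label == "Frameshift" else "stop"
            it = iters.setdefault((cls, vtype), positions(cls))
            for ac in acs:
                pid, pos = next(it)
                records.append(VariantRecord(ensembl_id(pid), "Q", pos, vtype,
                                             allele_count=ac))
        else:  # pragma: no cover - table rows are fixed above
            raise ValueError(f"unhandled label {label!r}")

    return Table1Fixture(
        proteome=proteins,
        variants=VariantSet(records=records, source_label="merged", ac_threshold=10),
        id_mapping={ensembl_id(p.protein_id): p.protein_id for p in proteins},
        expected_table=expected_polyq_table(),
    )


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, as recorded in generator manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(spec: SyntheticSpec, paths: Iterable[str | Path], out: str | Path) -> None:
    """Record the generating spec, seed, and per-file checksums."""
    payload = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
        "files": {str(p): file_checksum(p) for p in paths},
    }
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
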