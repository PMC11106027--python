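"""Classification of variants inside homorepeats of one residue.

Produces the per-length-class table of variant types observed within polyQ
(or any other homorepeat residue): for each (length class, variant-type
label), the number of distinct variant sites and their summed allele count.
Missense labels use three-letter amino-acid codes ("Gln > Arg"); indel and
nonsense types use capitalised names ("Deletion", "Duplication",
"Frameshift", "Insertion", "STOP").
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .scan import Homorepeat, LENGTH_CLASSES
from .variants import VariantRecord, VariantSet

#: one-letter -> three-letter amino-acid codes (title case, as printed).
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_TYPE_LABELS = {
    "deletion": "Deletion",
    "duplication": "Duplication",
    "insertion": "Insertion",
    "frameshift": "Frameshift",
    "stop": "STOP",
}

TABLE_COLUMNS = ("length_class", "type_label", "n_sites", "sum_allele_count")


def assign_variants_to_repeats(
    repeats: Sequence[Homorepeat],
    vs: VariantSet,
    aa: str = "Q",
) -> list[tuple[Homorepeat, VariantRecord]]:
    """All (repeat, variant) pairs with interval intersection, for repeats
    of residue ``aa``.

    A variant whose interval spans two repeats yields one pair per repeat
    (class statistics are per-repeat).
    """
    by_protein = vs.by_protein()
    pairs: list[tuple[Homorepeat, VariantRecord]] = []
    for rep in repeats:
        if rep.aa != aa:
            continue
        for rec in by_protein.get(rep.protein_id, ()):
            lo, hi = rec.interval
            if lo <= rep.end and hi >= rep.start:
                pairs.append((rep, rec))
    return pairs


def classify_in_repeat(v: VariantRecord) -> str:
    """Type label for a variant assigned to a repeat.

    Insertion-to-duplication refinement is expected to have been applied
    before classification (see ``variants.refine_duplications``).
    """
    if v.vtype == "missense":
        try:
            return f"{AA3[v.ref_aa]} > {AA3[v.alt_aa]}"
        except KeyError as exc:
            raise ValueError(f"non-standard residue in missense record: {exc}") from exc
    try:
        return _TYPE_LABELS[v.vtype]
    except KeyError as exc:
        raise ValueError(f"unknown variant type {v.vtype!r}") from exc


def tabulate(pairs: Iterable[tuple[Homorepeat, VariantRecord]]) -> pd.DataFrame:
    """Aggregate assigned pairs into the per-class variant-type table.

    For each (repeat length class, type label): ``n_sites`` counts distinct
    variant keys (position + type + alternate/insert + span) and
    ``sum_allele_count`` sums their allele counts.  A variant key counts
    once per class even if it intersects several repeats of that class.
    Rows are sorted within class by descending ``n_sites`` (label as the
    deterministic tie-break).
    """
    per_cell: dict[tuple[str, str], dict] = {}
    for rep, rec in pairs:
        cell = (rep.length_class, classify_in_repeat(rec))
        entry = per_cell.setdefault(cell, {"keys": set(), "ac": {}})
        entry["keys"].add(rec.key)
        entry["ac"][rec.key] = rec.allele_count
    rows = [
        {
            "length_class": cls,
            "type_label": label,
            "n_sites": len(entry["keys"]),
            "sum_allele_count": sum(entry["ac"].values()),
        }
        for (cls, label), entry in per_cell.items()
    ]
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if df.empty:
        return df
    order = {c: i for i, c in enumerate(LENGTH_CLASSES)}
    df["_c"] = df["length_class"].map(order)
    df = df.sort_values(
        ["_c", "n_sites", "type_label"], ascending=[True, False, True]
    ).drop(columns="_c").reset_index(drop=True)
    return df


def dup_del_ratio(
    table: pd.DataFrame,
    classes: Iterable[str],
    by: str = "allele_count",
    numerator: str = "deletion",
) -> float:
    """Ratio of deletion to duplication prevalence over selected classes.

    ``by`` selects the metric: ``"sites"`` (distinct variant sites) or
    ``"allele_count"`` (summed allele counts).  ``numerator`` may be
    ``"deletion"`` (deletions per duplication) or ``"duplication"`` (the
    inverse).  Returns NaN when the denominator is zero.
    """
    col = {"sites": "n_sites", "allele_count": "sum_allele_count"}[by]
    sel = table[table["length_class"].isin(set(classes))]
    dele = int(sel.loc[sel["type_label"] == "Deletion", col].sum())
    dup = int(sel.loc[sel["type_label"] == "Duplication", col].sum())
    num, den = (dele, dup) if numerator == "deletion" else (dup, dele)
    return num / den if den else float("nan")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"length_class": str})
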