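"""Homorepeat-variant overlap frequencies and the random-region baseline.

The central question is whether homorepeats accumulate population variants
more often than random protein regions of the same length.  Observed
overlap frequencies (fraction of repeats intersecting at least one variant,
per length class) are compared with frequencies for length-distribution-
matched random regions sampled uniformly over the proteome; the ratio is
the fold enrichment.

All intervals are 1-based inclusive; overlap is interval intersection of
the variant's affected interval with the repeat or region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import LENGTH_CLASSES, Homorepeat, ProteinSequence, length_class
from .variants import VariantRecord, VariantSet


@dataclass(frozen=True)
class Region:
    """A protein interval, 1-based inclusive (random baseline regions)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region [{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class OverlapSummary:
    """Per-length-class overlap counts and frequencies for observed repeats."""

    per_class: pd.DataFrame  # columns: length_class, n_repeats, n_overlapping, frequency
    overall_frequency: float


@dataclass
class BaselineSummary:
    """Random-region baseline frequencies and fold enrichments per class."""

    per_class: pd.DataFrame  # length_class, n_regions, n_overlapping, frequency, fold_enrichment
    rng_seed: int


def variant_interval(v: VariantRecord) -> tuple[int, int]:
    """Affected 1-based inclusive interval of a variant (insertion = anchor)."""
    return v.interval


def overlaps(region: Region | Homorepeat, v: VariantRecord) -> bool:
    """True iff the variant's interval intersects the region's interval."""
    if region.protein_id != v.protein_id:
        raise ValueError(
            f"cross-protein overlap test: {region.protein_id} vs {v.protein_id}"
        )
    lo, hi = v.interval
    return lo <= region.end and hi >= region.start


class _VariantIndex:
    """Per-protein variant intervals, sorted for fast any-overlap queries."""

    def __init__(self, vs: VariantSet):
        self._starts: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        per_protein: dict[str, list[tuple[int, int]]] = {}
        for rec in vs.records:
            per_protein.setdefault(rec.protein_id, []).append(rec.interval)
        for pid, ivals in per_protein.items():
            ivals.sort()
            starts = np.array([i[0] for i in ivals], dtype=np.int64)
            ends = np.array([i[1] for i in ivals], dtype=np.int64)
            self._starts[pid] = starts
            # running max of interval ends, so a prefix query suffices
            self._maxend[pid] = np.maximum.accumulate(ends)

    def any_overlap(self, protein_id: str, start: int, end: int) -> bool:
        starts = self._starts.get(protein_id)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, end, side="right"))
        return i > 0 and int(self._maxend[protein_id][i - 1]) >= start


def overlap_frequency(repeats: Sequence[Homorepeat], vs: VariantSet) -> OverlapSummary:
    """Fraction of repeats intersecting >= 1 variant, overall and per class.

    A repeat counts once no matter how many variants hit it.
    """
    if not repeats:
        raise ValueError("empty repeat set")
    index = _VariantIndex(vs)
    n = {c: 0 for c in LENGTH_CLASSES}
    hit = {c: 0 for c in LENGTH_CLASSES}
    total_hit = 0
    for r in repeats:
        cls = r.length_class
        n[cls] += 1
        if index.any_overlap(r.protein_id, r.start, r.end):
            hit[cls] += 1
            total_hit += 1
    rows = [
        {
            "length_class": c,
            "n_repeats": n[c],
            "n_overlapping": hit[c],
            "frequency": hit[c] / n[c] if n[c] else float("nan"),
        }
        for c in LENGTH_CLASSES
    ]
    return OverlapSummary(
        per_class=pd.DataFrame(rows),
        overall_frequency=total_hit / len(repeats),
    )


def sample_random_regions(
    proteome: Sequence[ProteinSequence],
    length_sample: Sequence[int],
    n: int = 10000,
    seed: int = 0,
) -> list[Region]:
    """Sample ``n`` random regions matching an empirical length distribution.

    Each region is drawn by (i) resampling a length from ``length_sample``
    with replacement, then (ii) placing it uniformly over all valid
    (protein, start) pairs — longer proteins are proportionally more likely,
    as for uniformly random regions of a proteome.  Regions may overlap each
    other and may coincide with true repeats.  Fully reproducible given the
    seed.
    """
    if not length_sample:
        raise ValueError("length_sample is empty")
    rng = np.random.default_rng(seed)
    lengths_arr = np.asarray(length_sample, dtype=np.int64)
    plens = np.array([len(p) for p in proteome], dtype=np.int64)
    max_plen = int(plens.max())
    ids = [p.protein_id for p in proteome]

    drawn = rng.choice(lengths_arr, size=n, replace=True)
    regions: list[Region] = []
    # placement weights depend only on the region length; cache per length
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for L in drawn:
        L = int(L)
        tries = 0
        while L > max_plen:
            tries += 1
            if tries > 1000:
                raise RuntimeError(f"no protein can hold a region of length {L}")
            L = int(rng.choice(lengths_arr))
        if L not in cache:
            slots = np.maximum(plens - L + 1, 0)
            cum = np.cumsum(slots)
            cache[L] = (slots, cum)
        slots, cum = cache[L]
        u = rng.integers(0, cum[-1])  # uniform over all valid placements
        pi = int(np.searchsorted(cum, u, side="right"))
        offset = int(u - (cum[pi - 1] if pi else 0))
        regions.append(Region(protein_id=ids[pi], start=offset + 1, end=offset + L))
    return regions


def baseline_overlap(
    regions_by_class: Mapping[str, Sequence[Region]],
    vs: VariantSet,
    observed: OverlapSummary,
    rng_seed: int = 0,
) -> BaselineSummary:
    """Baseline overlap frequency per class and fold enrichment vs observed.

    Fold enrichment is observed frequency / baseline frequency; reported as
    NaN where the baseline frequency is zero.
    """
    index = _VariantIndex(vs)
    obs = observed.per_class.set_index("length_class")
    rows = []
    for cls, regions in regions_by_class.items():
        n_hit = sum(index.any_overlap(r.protein_id, r.start, r.end) for r in regions)
        freq = n_hit / len(regions) if regions else float("nan")
        obs_freq = float(obs.loc[cls, "frequency"]) if cls in obs.index else float("nan")
        fold = obs_freq / freq if freq and freq > 0 else float("nan")
        rows.append(
            {
                "length_class": cls,
                "n_regions": len(regions),
                "n_overlapping": n_hit,
                "frequency": freq,
                "fold_enrichment": fold,
            }
        )
    return BaselineSummary(per_class=pd.DataFrame(rows), rng_seed=rng_seed)


def class_baseline(
    repeats: Sequence[Homorepeat],
    proteome: Sequence[ProteinSequence],
    vs: VariantSet,
    observed: OverlapSummary,
    n: int = 10000,
    seed: int = 0,
) -> BaselineSummary:
    """Convenience: per class, resample lengths from the class's observed
    repeat lengths and measure the baseline with ``n`` regions each."""
    lengths: dict[str, list[int]] = {c: [] for c in LENGTH_CLASSES}
    for r in repeats:
        lengths[r.length_class].append(r.length)
    regions_by_class = {}
    ss = np.random.SeedSequence(seed)
    for cls, child in zip(LENGTH_CLASSES, ss.spawn(len(LENGTH_CLASSES))):
        if lengths[cls]:
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            regions_by_class[cls] = sample_random_regions(
                proteome, lengths[cls], n=n, seed=sub_seed
            )
    return baseline_overlap(regions_by_class, vs, observed, rng_seed=seed)


def per_aa_overlap(
    repeats: Sequence[Homorepeat],
    vs: VariantSet,
    class_filter: str | None = None,
) -> pd.DataFrame:
    """Per-residue fraction of repeats overlapping >= 1 variant.

    Residues with zero repeats (after the optional class filter) are
    omitted.  Returns a DataFrame with columns aa, n_repeats,
    n_overlapping, frequency.
    """
    index = _VariantIndex(vs)
    n: dict[str, int] = {}
    hit: dict[str, int] = {}
    for r in repeats:
        if class_filter is not None and r.length_class != class_filter:
            continue
        n[r.aa] = n.get(r.aa, 0) + 1
        if index.any_overlap(r.protein_id, r.start, r.end):
            hit[r.aa] = hit.get(r.aa, 0) + 1
    rows = [
        {"aa": aa, "n_repeats": n[aa], "n_overlapping": hit.get(aa, 0),
         "frequency": hit.get(aa, 0) / n[aa]}
        for aa in sorted(n)
    ]
    return pd.DataFrame(rows, columns=["aa", "n_repeats", "n_overlapping", "frequency"])


def proteome_variant_coverage(
    vs: VariantSet,
    proteome: Sequence[ProteinSequence],
    anchors_only: bool = False,
) -> float:
    """Fraction of proteome residues intersected by >= 1 variant interval.

    By default full affected intervals count (a 3-residue deletion covers 3
    positions); ``anchors_only`` restricts to first affected positions.
    """
    lens = {p.protein_id: len(p) for p in proteome}
    covered: dict[str, set[int]] = {}
    for rec in vs.records:
        plen = lens.get(rec.protein_id)
        if plen is None:
            continue
        lo, hi = rec.interval
        if anchors_only:
            hi = lo
        hi = min(hi, plen)
        covered.setdefault(rec.protein_id, set()).update(range(lo, hi + 1))
    n_covered = sum(len(s) for s in covered.values())
    total = sum(lens.values())
    return n_covered / total if total else 0.0


def aa_frequency_profile(
    vs: VariantSet,
    proteome: Sequence[ProteinSequence],
) -> pd.DataFrame:
    """Reference-residue frequencies of variants vs the proteome background.

    Returns one row per standard amino acid with the normalised variant
    profile, the proteome background profile, and their ratio.
    """
    from .scan import STANDARD_AA

    if not vs.records:
        raise ValueError("empty variant set")
    var_counts = {aa: 0 for aa in STANDARD_AA}
    for rec in vs.records:
        if rec.ref_aa in var_counts:
            var_counts[rec.ref_aa] += 1
    bg_counts = {aa: 0 for aa in STANDARD_AA}
    for p in proteome:
        for aa in p.sequence:
            if aa in bg_counts:
                bg_counts[aa] += 1
    var_total = sum(var_counts.values()) or 1
    bg_total = sum(bg_counts.values()) or 1
    rows = []
    for aa in STANDARD_AA:
        vf = var_counts[aa] / var_total
        bf = bg_counts[aa] / bg_total
        rows.append(
            {"aa": aa, "variant_freq": vf, "background_freq": bf,
             "ratio": vf / bf if bf else float("nan")}
        )
    return pd.DataFrame(rows)
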