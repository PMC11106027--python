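"""Overlap frequencies, random-region baseline, proteome-wide statistics."""

import numpy as np
import pytest
from scipy import stats

from polyxpop.overlap import (
    Region,
    aa_frequency_profile,
    baseline_overlap,
    class_baseline,
    overlap_frequency,
    overlaps,
    per_aa_overlap,
    proteome_variant_coverage,
    sample_random_regions,
    variant_interval,
)
from polyxpop.scan import Homorepeat, ProteinSequence, scan_proteome
from polyxpop.variants import VariantRecord, VariantSet


def mk_var(pid, pos, vtype="missense", span=1, ac=50, **kw):
    if vtype == "missense":
        kw.setdefault("alt_aa", "R")
    if vtype in ("insertion", "duplication"):
        kw.setdefault("inserted_seq", "Q")
    return VariantRecord(pid, "Q", pos, vtype, span=span, allele_count=ac, **kw)


class TestIntervalsAndOverlap:
    def test_variant_intervals(self):
        assert variant_interval(mk_var("P", 10)) == (10, 10)
        assert variant_interval(mk_var("P", 10, "deletion", span=3)) == (10, 12)
        assert variant_interval(mk_var("P", 10, "insertion")) == (10, 10)

    @pytest.mark.parametrize("pos,span,expected", [(7, 1, True), (8, 1, False),
                                                   (6, 4, True), (1, 3, False), (1, 4, True)])
    def test_boundary_overlap(self, pos, span, expected):
        rep = Homorepeat("P", "Q", 4, 7)
        v = mk_var("P", pos, "deletion", span=span)
        assert overlaps(rep, v) is expected

    def test_cross_protein_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="cross-protein"):
            overlaps(Homorepeat("P1", "Q", 1, 4), mk_var("P2", 2))


class TestOverlapFrequency:
    def test_single_repeat_hit(self):
        rep = [Homorepeat("P", "Q", 1, 4)]
        vs = VariantSet([mk_var("P", 2)])
        summary = overlap_frequency(rep, vs)
        row = summary.per_class.set_index("length_class").loc["4-5"]
        assert row["frequency"] == 1.0
        assert summary.overall_frequency == 1.0

    def test_no_variants_all_zero(self):
        rep = [Homorepeat("P", "Q", 1, 4), Homorepeat("P", "A", 10, 12)]
        summary = overlap_frequency(rep, VariantSet([]))
        assert summary.overall_frequency == 0.0

    def test_repeat_counts_once_despite_many_hits(self):
        rep = [Homorepeat("P", "Q", 1, 8)]
        vs = VariantSet([mk_var("P", i) for i in range(1, 9)])
        assert overlap_frequency(rep, vs).overall_frequency == 1.0

    def test_empty_repeat_set_errors(self):
        with pytest.raises(ValueError):
            overlap_frequency([], VariantSet([]))


def iid_variants(proteome, p, seed):
    """Place missense variants iid per position at rate p (test helper)."""
    rng = np.random.default_rng(seed)
    records = []
    for prot in proteome:
        for pos0 in np.flatnonzero(rng.random(len(prot)) < p):
            ref = prot.sequence[pos0]
            alt = "R" if ref != "R" else "K"
            records.append(VariantRecord(prot.protein_id, ref, int(pos0) + 1,
                                         "missense", alt_aa=alt, allele_count=10))
    return VariantSet(records)


@pytest.fixture(scope="module")
def flat_proteome():
    rng = np.random.default_rng(1234)
    letters = np.array(list("ACDEFGHIKLMNPRSTVWY"))  # Q-free background
    return [
        ProteinSequence(f"B{i:03d}", "".join(rng.choice(letters, size=400)))
        for i in range(100)
    ]


@pytest.fixture(scope="module")
def big_proteome():
    """200k residues: large enough that the realised variant rate and
    region-sharing noise are small next to the binomial sampling error."""
    rng = np.random.default_rng(4321)
    letters = np.array(list("ACDEFGHIKLMNPRSTVWY"))
    return [
        ProteinSequence(f"C{i:03d}", "".join(rng.choice(letters, size=800)))
        for i in range(250)
    ]


class TestRandomRegions:
    def test_forced_placement(self):
        prot = [ProteinSequence("P", "A" * 10)]
        regions = sample_random_regions(prot, [10], n=20, seed=1)
        assert all((r.start, r.end) == (1, 10) for r in regions)

    def test_seed_determinism(self, flat_proteome):
        a = sample_random_regions(flat_proteome, [3, 8, 16], n=500, seed=42)
        assert a == sample_random_regions(flat_proteome, [3, 8, 16], n=500, seed=42)
        assert a != sample_random_regions(flat_proteome, [3, 8, 16], n=500, seed=43)

    def test_length_histogram_matches_sample(self, flat_proteome):
        lengths = [3] * 50 + [8] * 30 + [16] * 20
        regions = sample_random_regions(flat_proteome, lengths, n=10000, seed=9)
        got = np.array([sum(r.length == L for r in regions) for L in (3, 8, 16)])
        expected = np.array([0.5, 0.3, 0.2]) * 10000
        assert stats.chisquare(got, expected).pvalue > 0.01

    def test_impossible_length_aborts(self):
        prot = [ProteinSequence("P", "A" * 5)]
        with pytest.raises(RuntimeError):
            sample_random_regions(prot, [10], n=5, seed=1)


class TestCalibration:
    def test_overlap_frequency_matches_closed_form(self, big_proteome):
        """Under iid placement at rate p, a length-L region overlaps >= 1
        variant with probability 1 - (1-p)^L."""
        p, L, n = 0.02, 8, 10000
        vs = iid_variants(big_proteome, p, seed=5)
        hit = {(v.protein_id, v.position) for v in vs.records}
        regions = sample_random_regions(big_proteome, [L], n=n, seed=6)
        observed = np.mean([
            any((r.protein_id, pos) in hit for pos in range(r.start, r.end + 1))
            for r in regions
        ])
        q = 1 - (1 - p) ** L
        assert abs(observed - q) < 3 * np.sqrt(q * (1 - q) / n)


class TestBaseline:
    def test_fold_arithmetic(self):
        import pandas as pd
        from polyxpop.overlap import OverlapSummary
        obs = OverlapSummary(
            per_class=pd.DataFrame([{"length_class": "8+", "n_repeats": 10,
                                     "n_overlapping": 4, "frequency": 0.34}]),
            overall_frequency=0.34,
        )
        prot = [ProteinSequence("P", "A" * 100)]
        # 10 regions, exactly 1 overlapping -> baseline 0.10, fold 3.4
        regions = [Region("P", s, s + 7) for s in (1, 11, 21, 31, 41, 51, 61, 71, 81, 91)]
        vs = VariantSet([mk_var("P", 3)])
        base = baseline_overlap({"8+": regions}, vs, obs)
        row = base.per_class.iloc[0]
        assert row["frequency"] == pytest.approx(0.10)
        assert row["fold_enrichment"] == pytest.approx(3.4)

    def test_observed_equals_baseline_gives_fold_one(self):
        import pandas as pd
        from polyxpop.overlap import OverlapSummary
        obs = OverlapSummary(
            per_class=pd.DataFrame([{"length_class": "3", "n_repeats": 1,
                                     "n_overlapping": 0, "frequency": 0.5}]),
            overall_frequency=0.5,
        )
        prot = ProteinSequence("P", "A" * 10)
        regions = [Region("P", 1, 3), Region("P", 5, 7)]
        vs = VariantSet([mk_var("P", 2)])
        base = baseline_overlap({"3": regions}, vs, obs)
        assert base.per_class.iloc[0]["fold_enrichment"] == pytest.approx(1.0)

    def test_zero_baseline_reports_nan_fold(self):
        import pandas as pd
        from polyxpop.overlap import OverlapSummary
        obs = OverlapSummary(
            per_class=pd.DataFrame([{"length_class": "3", "n_repeats": 1,
                                     "n_overlapping": 1, "frequency": 1.0}]),
            overall_frequency=1.0,
        )
        base = baseline_overlap({"3": [Region("P", 1, 3)]}, VariantSet([]), obs)
        assert np.isnan(base.per_class.iloc[0]["fold_enrichment"])

    def test_determinism_of_class_baseline(self, flat_proteome):
        reps = [Homorepeat(p.protein_id, "A", 10, 17) for p in flat_proteome[:30]]
        vs = iid_variants(flat_proteome, 0.01, seed=2)
        obs = overlap_frequency(reps, vs)
        b1 = class_baseline(reps, flat_proteome, vs, obs, n=500, seed=77)
        b2 = class_baseline(reps, flat_proteome, vs, obs, n=500, seed=77)
        assert b1.per_class.equals(b2.per_class)


class TestProteomeStats:
    PROTEOME = [ProteinSequence("P", "Q" * 100)]

    def test_single_position_coverage(self):
        vs = VariantSet([mk_var("P", 10)])
        assert proteome_variant_coverage(vs, self.PROTEOME) == pytest.approx(0.01)

    def test_same_position_counted_once(self):
        vs = VariantSet([mk_var("P", 10), mk_var("P", 10, "stop")])
        assert proteome_variant_coverage(vs, self.PROTEOME) == pytest.approx(0.01)

    def test_deletion_span_counts_every_position(self):
        vs = VariantSet([mk_var("P", 10, "deletion", span=3)])
        assert proteome_variant_coverage(vs, self.PROTEOME) == pytest.approx(0.03)
        assert proteome_variant_coverage(vs, self.PROTEOME, anchors_only=True) == \
            pytest.approx(0.01)

    def test_coverage_brute_force_on_random_set(self, flat_proteome):
        vs = iid_variants(flat_proteome, 0.01, seed=8)
        got = proteome_variant_coverage(vs, flat_proteome)
        positions = {(r.protein_id, r.position) for r in vs.records}
        assert got == pytest.approx(len(positions) / (100 * 400))

    def test_per_aa_overlap_only_present_residues(self):
        reps = [Homorepeat("P", "Q", 1, 4)]
        vs = VariantSet([mk_var("P", 2)])
        df = per_aa_overlap(reps, vs)
        assert list(df["aa"]) == ["Q"] and df.iloc[0]["frequency"] == 1.0

    def test_aa_profile_uniform_sampling_ratios_near_one(self, flat_proteome):
        rng = np.random.default_rng(3)
        records = []
        for _ in range(4000):
            pi = rng.integers(0, len(flat_proteome))
            prot = flat_proteome[pi]
            pos = int(rng.integers(1, len(prot) + 1))
            ref = prot.residue(pos)
            alt = "R" if ref != "R" else "K"
            records.append(VariantRecord(prot.protein_id, ref, pos, "missense",
                                         alt_aa=alt, allele_count=10))
        df = aa_frequency_profile(VariantSet(records), flat_proteome)
        present = df[df["background_freq"] > 0.01]
        for _, row in present.iterrows():
            se = np.sqrt(row["background_freq"] * (1 - row["background_freq"]) / 4000)
            assert abs(row["variant_freq"] - row["background_freq"]) < 4 * se

    def test_aa_profile_empty_set_errors(self, flat_proteome):
        with pytest.raises(ValueError):
            aa_frequency_profile(VariantSet([]), flat_proteome)
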