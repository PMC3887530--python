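"""ChIP track scaling, peak consistency, promoter/body calls, co-binding."""

import numpy as np
import pandas as pd
import pytest

from antagde.binding import (
    BindingCalls,
    PeakSet,
    binding_enrichment_in_sets,
    call_body_bound,
    call_promoter_bound,
    cobinding_venn,
    consistent_peaks,
    scale_chip_track,
    to_annotation,
    to_internal,
)
from antagde.core import GeneSet, ValidationError
from antagde.io import read_bed, write_bed


def peakset(rows, factor="F", replicate="rep1"):
    return PeakSet(factor, replicate, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def random_annotation(rng, n_genes, span=100_000):
    tss = rng.integers(1000, span, n_genes)
    strand = rng.choice(["+", "-"], n_genes)
    length = rng.integers(500, 3000, n_genes)
    start = np.where(strand == "+", tss, tss - length + 1)
    return pd.DataFrame(
        {
            "chrom": rng.choice(["I", "X"], n_genes),
            "strand": strand,
            "tss": tss,
            "start": start,
            "end": start + length - 1,
        },
        index=[f"g{i}" for i in range(n_genes)],
    )


def random_peaks(rng, n_peaks, span=100_000, max_width=2000):
    start = rng.integers(0, span, n_peaks)
    width = rng.integers(1, max_width, n_peaks)
    return pd.DataFrame(
        {"chrom": rng.choice(["I", "X"], n_peaks), "start": start, "end": start + width}
    )


class TestScaleChipTrack:
    def test_definitional_postcondition(self):
        rng = np.random.default_rng(51)
        out = scale_chip_track(rng.normal(3, 2, 501))
        assert np.median(out) == pytest.approx(1.0)
        assert np.median(np.abs(out - np.median(out))) == pytest.approx(1.0)

    def test_hand_computation(self):
        out = scale_chip_track([0.0, 1.0, 2.0, 3.0, 4.0])
        # median 2, deviations (2,1,0,1,2) -> MAD 1; already MAD 1, shift to median 1
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0, 2.0, 3.0])

    def test_fixed_point(self):
        vals = np.array([-1.0, 0.0, 1.0, 2.0, 3.0])  # median 1, MAD 1
        np.testing.assert_allclose(scale_chip_track(vals), vals)

    def test_zero_mad_rejected(self):
        with pytest.raises(ValidationError):
            scale_chip_track([1.0, 1.0, 1.0, 5.0])


class TestConsistentPeaks:
    def test_identical_replicates_keep_everything(self):
        rows = [("I", 10, 50), ("I", 100, 200), ("X", 5, 25)]
        out = consistent_peaks([peakset(rows), peakset(rows, replicate="rep2")])
        assert len(out) == 3

    def test_disjoint_replicates_empty(self):
        out = consistent_peaks(
            [peakset([("I", 0, 10)]), peakset([("I", 50, 60)], replicate="rep2")]
        )
        assert len(out) == 0

    def test_reference_coordinates_kept(self):
        out = consistent_peaks(
            [peakset([("I", 10, 100)]), peakset([("I", 90, 200)], replicate="rep2")]
        )
        assert out.intervals.iloc[0][["start", "end"]].tolist() == [10, 100]

    def test_matches_brute_force_pairwise_scan(self):
        """Randomized toy intervals vs an O(n²) overlap scan, many cases."""
        rng = np.random.default_rng(52)
        for _ in range(30):
            ref = random_peaks(rng, 40, span=5000)
            others = [random_peaks(rng, 40, span=5000) for _ in range(2)]
            sets = [peakset(ref)] + [peakset(o, replicate=f"rep{i + 2}") for i, o in enumerate(others)]
            got = consistent_peaks(sets, min_overlap=1)
            kept = set(map(tuple, got.intervals.to_numpy()))
            ref_sorted = peakset(ref).intervals  # same sorted order as PeakSet applies
            expected = set()
            for row in ref_sorted.itertuples(index=False):
                for other in others:
                    hit = (
                        (other["chrom"] == row.chrom)
                        & (np.minimum(other["end"], row.end) - np.maximum(other["start"], row.start) >= 1)
                    ).any()
                    if hit:
                        expected.add((row.chrom, row.start, row.end))
                        break
            assert kept == expected

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            consistent_peaks([peakset([("I", 0, 10)])])


class TestPromoterBound:
    def test_peak_covering_full_window_is_bound(self):
        ann = pd.DataFrame(
            {"chrom": ["I"], "strand": ["+"], "tss": [1000], "start": [1000], "end": [2000]},
            index=["g0"],
        )
        # window is [500, 1500] 1-based; internal [499, 1500)
        peaks = peakset([("I", 499, 1500)])
        assert call_promoter_bound(peaks, ann).promoter_bound["g0"]

    def test_overlap_just_below_threshold_not_bound(self):
        ann = pd.DataFrame(
            {"chrom": ["I"], "strand": ["+"], "tss": [1000], "start": [1000], "end": [2000]},
            index=["g0"],
        )
        window_start_internal = 1000 - 500 - 1  # 499
        calls_199 = call_promoter_bound(peakset([("I", 300, window_start_internal + 199)]), ann)
        calls_200 = call_promoter_bound(peakset([("I", 300, window_start_internal + 200)]), ann)
        assert not calls_199.promoter_bound["g0"]
        assert calls_200.promoter_bound["g0"]

    def test_per_peak_rule_abutting_fragments(self):
        """Two abutting 150 bp fragments (300 bp union) do not bind; one 200 bp peak does."""
        ann = pd.DataFrame(
            {"chrom": ["I"], "strand": ["+"], "tss": [1000], "start": [1000], "end": [2000]},
            index=["g0"],
        )
        frag = peakset([("I", 600, 750), ("I", 750, 900)])
        single = peakset([("I", 600, 800)])
        assert not call_promoter_bound(frag, ann).promoter_bound["g0"]
        assert call_promoter_bound(single, ann).promoter_bound["g0"]

    def test_matches_brute_force_interval_scan(self):
        """≥1000 random gene/peak configurations vs direct interval arithmetic."""
        rng = np.random.default_rng(53)
        n_cases = 0
        for _ in range(40):
            ann = random_annotation(rng, 30)
            peaks = random_peaks(rng, 25)
            got = call_promoter_bound(peakset(peaks), ann).promoter_bound
            for gene, row in ann.iterrows():
                w_start, w_end = row["tss"] - 500 - 1, row["tss"] + 500
                bound = False
                for p in peaks.itertuples(index=False):
                    if p.chrom != row["chrom"]:
                        continue
                    if min(p.end, w_end) - max(p.start, w_start) >= 200:
                        bound = True
                        break
                assert got[gene] == bound
                n_cases += 1
        assert n_cases >= 1000

    def test_monotone_in_min_overlap(self):
        rng = np.random.default_rng(54)
        ann = random_annotation(rng, 40)
        peaks = peakset(random_peaks(rng, 30))
        strict = call_promoter_bound(peaks, ann, min_overlap=400).promoter_bound
        loose = call_promoter_bound(peaks, ann, min_overlap=100).promoter_bound
        assert (loose | ~strict).all()  # strict ⇒ loose

    def test_peak_order_invariance(self):
        rng = np.random.default_rng(55)
        ann = random_annotation(rng, 20)
        peaks = random_peaks(rng, 20)
        a = call_promoter_bound(peakset(peaks), ann).promoter_bound
        b = call_promoter_bound(peakset(peaks.iloc[::-1].reset_index(drop=True)), ann).promoter_bound
        assert (a == b).all()

    def test_missing_tss_rejected(self):
        ann = pd.DataFrame(
            {"chrom": ["I"], "strand": ["+"], "tss": [np.nan], "start": [1.0], "end": [10.0]},
            index=["g0"],
        )
        with pytest.raises(ValidationError):
            call_promoter_bound(peakset([("I", 0, 10)]), ann)


class TestBodyBound:
    def test_full_cover_bound_any_fraction(self):
        ann = pd.DataFrame(
            {"chrom": ["I"], "strand": ["+"], "tss": [100], "start": [100], "end": [600]},
            index=["g0"],
        )
        peaks = peakset([("I", 0, 1000)])
        for frac in (0.01, 0.5, 1.0):
            assert call_body_bound(peaks, ann, min_fraction=frac).body_bound["g0"]

    def test_no_peaks_on_chromosome_not_bound(self):
        ann = pd.DataFrame(
            {"chrom": ["X"], "strand": ["+"], "tss": [100], "start": [100], "end": [600]},
            index=["g0"],
        )
        assert not call_body_bound(peakset([("I", 0, 1000)]), ann).body_bound["g0"]

    def test_tiled_coverage_matches_per_base_count(self):
        rng = np.random.default_rng(56)
        for _ in range(20):
            ann = random_annotation(rng, 10, span=5000)
            peaks = random_peaks(rng, 15, span=6000, max_width=800)
            got = call_body_bound(peakset(peaks), ann, min_fraction=0.5).body_bound
            for gene, row in ann.iterrows():
                g_start, g_end = to_internal(int(row["start"]), int(row["end"]))
                base = np.zeros(g_end - g_start, dtype=bool)
                for p in peaks.itertuples(index=False):
                    if p.chrom != row["chrom"]:
                        continue
                    lo, hi = max(p.start, g_start), min(p.end, g_end)
                    if hi > lo:
                        base[lo - g_start : hi - g_start] = True
                assert got[gene] == (base.mean() >= 0.5)

    def test_invalid_fraction_rejected(self):
        ann = random_annotation(np.random.default_rng(57), 3)
        with pytest.raises(ValidationError):
            call_body_bound(peakset([("I", 0, 10)]), ann, min_fraction=1.5)


class TestCoordinateRoundTrip:
    def test_conversion_inverse(self):
        for start, end in [(1, 1), (1, 100), (500, 1500)]:
            assert to_annotation(*to_internal(start, end)) == (start, end)

    def test_bed_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(58)
        iv = random_peaks(rng, 25).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        p1 = tmp_path / "a.bed"
        p2 = tmp_path / "b.bed"
        write_bed(iv, p1)
        write_bed(read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCobindingAndEnrichment:
    @staticmethod
    def calls_from(genes, universe, factor="F", where="promoter"):
        flags = pd.Series([g in genes for g in universe], index=list(universe))
        kwargs = {"promoter_bound": flags} if where == "promoter" else {"body_bound": flags}
        return BindingCalls(factor=factor, **kwargs)

    def test_identical_calls_full_overlap(self):
        universe = [f"g{i}" for i in range(15)]
        a = self.calls_from(universe[:6], universe, "A", "body")
        b = self.calls_from(universe[:6], universe, "B")
        venn = cobinding_venn(a, b, universe, "body", "promoter")
        assert venn["both"] == 6 and venn["a_only"] == 0 and venn["b_only"] == 0

    def test_toy_universe_matches_enumeration(self):
        import math

        universe = [f"g{i}" for i in range(15)]
        a = self.calls_from(universe[:6], universe, "A", "body")
        b = self.calls_from(universe[4:9], universe, "B")
        venn = cobinding_venn(a, b, universe, "body", "promoter")
        brute = sum(
            math.comb(6, j) * math.comb(9, 5 - j) / math.comb(15, 5) for j in range(2, 6)
        )
        assert venn["both"] == 2
        assert venn["overlap_test"].p == pytest.approx(brute, rel=1e-12)

    def test_independent_calls_p_roughly_uniform(self):
        rng = np.random.default_rng(59)
        universe = [f"g{i}" for i in range(400)]
        ps = []
        for _ in range(40):
            a = self.calls_from(set(rng.choice(universe, 80, replace=False)), universe, "A", "body")
            b = self.calls_from(set(rng.choice(universe, 80, replace=False)), universe, "B")
            ps.append(cobinding_venn(a, b, universe, "body", "promoter")["overlap_test"].p)
        assert 0.2 < np.mean(ps) < 0.8  # null p-values not skewed

    def test_set_of_all_bound_genes_fully_observed(self):
        universe = [f"g{i}" for i in range(30)]
        bound = frozenset(universe[:12])
        res = binding_enrichment_in_sets(
            {"F": bound}, {"S": GeneSet("S", bound)}, universe
        )
        assert res[0].observed == 12

    def test_planted_binding_enrichment_pattern(self, default_sim, default_peaks):
        """Germline-heavy A-down genes promoter-enriched, soma-heavy A-up depleted."""
        from antagde.binding import call_promoter_bound, consistent_peaks

        _, _, annotation, _, truth = default_sim
        reps = default_peaks["LIN-54"]
        merged = consistent_peaks(reps)
        calls = call_promoter_bound(merged, annotation)
        bound = frozenset(calls.promoter_bound.index[calls.promoter_bound])
        sets = {
            "A-down": truth.genes_of_class("A-down"),
            "A-up": truth.genes_of_class("A-up"),
        }
        res = {
            r.category: r
            for r in binding_enrichment_in_sets({"LIN-54": bound}, sets, annotation.index)
        }
        assert res["LIN-54 in A-down"].p_enrichment < 1e-10
        assert res["LIN-54 in A-up"].p_depletion < 1e-3

    def test_universe_violation_rejected(self):
        universe = ["g0", "g1"]
        calls = self.calls_from(["g0", "zz"], ["g0", "g1", "zz"], "A", "body")
        with pytest.raises(ValidationError):
            cobinding_venn(calls, self.calls_from(["g0"], universe, "B"), universe, "body", "promoter")
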