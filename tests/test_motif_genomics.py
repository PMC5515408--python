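import numpy as np
import pandas as pd
import pytest

from eboxscape import canonical, motif_genomics as mg, revcomp, synthetic_data as sd
from eboxscape.errors import InvalidArgumentError, SchemaError


def _peaks(rows):
    return pd.DataFrame(rows, columns=sd.PEAK_COLUMNS)


def _hits(motif, positions, chrom="chr1", strand="+"):
    return pd.DataFrame(
        {
            "motif": canonical(motif),
            "chrom": chrom,
            "start": positions,
            "end": [p + 6 for p in positions],
            "strand": strand,
        }
    )


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

class TestScanMotifs:
    def test_palindrome_single_hit_per_position(self):
        hits = mg.scan_motifs({"chr1": "AACGTTAACGTT"}, ["AACGTT"])
        assert list(hits["start"]) == [0, 6]
        assert set(hits["strand"]) == {"+"}

    def test_single_occurrence(self):
        hits = mg.scan_motifs({"chr1": "CACGTG"}, ["CACGTG"])
        assert len(hits) == 1

    def test_both_strands_for_non_palindrome(self):
        # CACGTT at 0 (+); its revcomp AACGTG at 8 (-)
        hits = mg.scan_motifs({"chr1": "CACGTTGGAACGTG"}, ["CACGTT"])
        assert len(hits) == 2
        assert set(zip(hits["start"], hits["strand"])) == {(0, "+"), (8, "-")}
        assert set(hits["motif"]) == {"CACGTT"}

    def test_overlapping_occurrences(self):
        hits = mg.scan_motifs({"chr1": "CACACACATG"}, ["CACATG"])
        # forward CACATG at 4; revcomp CATGTG absent
        assert list(hits["start"]) == [4]
        assert hits["motif"].iloc[0] == "CATGTG"  # canonical printed form

    def test_n_runs_skipped(self):
        hits = mg.scan_motifs({"chr1": "CACNTGCACGTG"}, ["CACGTG"])
        assert list(hits["start"]) == [6]

    def test_invalid_motif(self):
        with pytest.raises(InvalidArgumentError):
            mg.scan_motifs({"chr1": "ACGT"}, ["CACNTG"])

    def test_matches_brute_force_oracle(self, small_genome, brute_count):
        motifs = ["CACGTG", "AACGTT", "CACGTT", "CATGTG", "GGATCC"]
        hits = mg.scan_motifs(small_genome, motifs)
        for m in motifs:
            expected = sum(brute_count(seq, canonical(m)) for seq in small_genome.values())
            assert (hits["motif"] == canonical(m)).sum() == expected

    def test_strand_symmetry(self, small_genome):
        # scanning a motif and its reverse complement yields identical hit sets
        a = mg.scan_motifs(small_genome, ["CACGTT"])
        b = mg.scan_motifs(small_genome, ["AACGTG"])
        pd.testing.assert_frame_equal(a, b)

    def test_genome_counts(self, small_genome):
        counts = mg.genome_motif_counts(small_genome, ["CACGTG", "AACGTT"])
        hits = mg.scan_motifs(small_genome, ["CACGTG", "AACGTT"])
        for m, c in counts.items():
            assert c == (hits["motif"] == m).sum()


# ---------------------------------------------------------------------------
# summits / strata
# ---------------------------------------------------------------------------

class TestMakeSummits:
    def test_basic_arithmetic(self):
        peaks = _peaks([("chr1", 800, 1300, 1000, 5.0, 1e-10, "highMYC", "p1")])
        s = mg.make_summits(peaks, 100)
        assert (s["start"].iloc[0], s["end"].iloc[0]) == (900, 1100)

    def test_clamped_at_zero(self):
        peaks = _peaks([("chr1", 0, 300, 50, 5.0, 1e-10, "highMYC", "p1")])
        s = mg.make_summits(peaks, 100)
        assert (s["start"].iloc[0], s["end"].iloc[0]) == (0, 150)

    def test_clamped_at_chrom_end(self):
        peaks = _peaks([("chr1", 900, 1000, 980, 5.0, 1e-10, "highMYC", "p1")])
        s = mg.make_summits(peaks, 100, chrom_sizes={"chr1": 1000})
        assert (s["start"].iloc[0], s["end"].iloc[0]) == (880, 1000)

    def test_extended_radius_width(self):
        peaks = _peaks([("chr1", 0, 5000, 2000, 5.0, 1e-10, "highMYC", "p1")])
        s = mg.make_summits(peaks, 350)
        assert s["end"].iloc[0] - s["start"].iloc[0] == 700

    def test_height_carried_through(self):
        peaks = _peaks([("chr1", 800, 1300, 1000, 7.5, 1e-10, "highMYC", "p1")])
        s = mg.make_summits(peaks, 100)
        assert s["height"].iloc[0] == 7.5


class TestTopFractionPeaks:
    def _random_peaks(self, n, seed):
        rng = np.random.default_rng(seed)
        return _peaks(
            [
                ("chr1", i * 1000, i * 1000 + 500, i * 1000 + 250,
                 float(rng.uniform(1, 10)), float(rng.uniform(1e-20, 1e-9)),
                 "highMYC", f"p{i}")
                for i in range(n)
            ]
        )

    def test_fraction_one_identity(self):
        peaks = self._random_peaks(10, 0)
        top = mg.top_fraction_peaks(peaks, 1.0)
        assert set(top["id"]) == set(peaks["id"])

    def test_ceil_rule(self):
        peaks = self._random_peaks(9, 1)
        assert len(mg.top_fraction_peaks(peaks, 0.33)) == 3

    def test_matches_sort_and_slice_oracle(self):
        import math

        for seed in range(5):
            peaks = self._random_peaks(17, seed)
            top = mg.top_fraction_peaks(peaks, 0.33)
            expected = peaks.sort_values("pvalue").head(math.ceil(0.33 * 17))
            assert set(top["id"]) == set(expected["id"])

    def test_invalid_fraction(self):
        with pytest.raises(InvalidArgumentError):
            mg.top_fraction_peaks(self._random_peaks(5, 0), 0.0)


class TestStratifyByFold:
    def test_nine_peaks_tertiles(self):
        peaks = _peaks(
            [("chr1", i * 100, i * 100 + 50, i * 100 + 25, float(h), 1e-10, "x", f"p{h}")
             for i, h in enumerate(range(1, 10))]
        )
        strata = mg.stratify_by_fold(peaks)
        assert sorted(strata["Low"]["height"]) == [1, 2, 3]
        assert sorted(strata["Medium"]["height"]) == [4, 5, 6]
        assert sorted(strata["High"]["height"]) == [7, 8, 9]

    def test_equal_heights_stable_by_id(self):
        peaks = _peaks(
            [("chr1", i * 100, i * 100 + 50, i * 100 + 25, 2.0, 1e-10, "x", f"p{i:02d}")
             for i in range(6)]
        )
        strata = mg.stratify_by_fold(peaks)
        assert list(strata["Low"]["id"]) == ["p00", "p01"]
        assert list(strata["High"]["id"]) == ["p04", "p05"]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        peaks = _peaks(
            [("chr1", i * 100, i * 100 + 50, i * 100 + 25, float(rng.uniform(1, 9)),
              1e-10, "x", f"p{i}") for i in range(20)]
        )
        strata = mg.stratify_by_fold(peaks)
        ids = sum((list(s["id"]) for s in strata.values()), [])
        assert sorted(ids) == sorted(peaks["id"])
        sizes = [len(s) for s in strata.values()]
        assert max(sizes) - min(sizes) <= 1


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

class TestNormalizedFrequency:
    def test_whole_genome_coverage_gives_one(self, small_genome):
        motifs = ["CACGTG", "AACGTT"]
        hits = mg.scan_motifs(small_genome, motifs)
        counts = mg.genome_motif_counts(small_genome, motifs)
        regions = pd.DataFrame(
            [{"chrom": c, "start": 0, "end": len(s)} for c, s in small_genome.items()]
        )
        enr = mg.normalized_frequency(regions, hits, counts)
        assert np.allclose(enr["normalized_frequency"], 1.0)

    def test_empty_regions_gives_zero(self, small_genome):
        motifs = ["CACGTG"]
        hits = mg.scan_motifs(small_genome, motifs)
        counts = mg.genome_motif_counts(small_genome, motifs)
        enr = mg.normalized_frequency(pd.DataFrame(columns=["chrom", "start", "end"]), hits, counts)
        assert (enr["normalized_frequency"] == 0.0).all()

    def test_hand_counted_toy_case(self):
        # 10 kb genome: CACGTG planted at 100, 150, 5000; GGATCC at 120, 7000.
        seq = ["A"] * 10_000
        for pos, motif in [(100, "CACGTG"), (150, "CACGTG"), (5000, "CACGTG"),
                           (120, "GGATCC"), (7000, "GGATCC")]:
            seq[pos:pos + 6] = list(motif)
        genome = {"chr1": "".join(seq)}
        hits = mg.scan_motifs(genome, ["CACGTG", "GGATCC"])
        counts = mg.genome_motif_counts(genome, ["CACGTG", "GGATCC"])
        assert counts == {"CACGTG": 3, "GGATCC": 2}
        # region [90, 160) contains CACGTG@100,150 and GGATCC@120
        regions = pd.DataFrame([{"chrom": "chr1", "start": 90, "end": 160}])
        enr = mg.normalized_frequency(regions, hits, counts).set_index("motif")
        assert enr.loc["CACGTG", "hits_in_regions"] == 2
        assert enr.loc["CACGTG", "normalized_frequency"] == pytest.approx(2 / 3)
        assert enr.loc["GGATCC", "normalized_frequency"] == pytest.approx(1 / 2)

    def test_partial_containment_excluded(self):
        genome = {"chr1": "A" * 50 + "CACGTG" + "A" * 50}
        hits = mg.scan_motifs(genome, ["CACGTG"])
        counts = {"CACGTG": 1}
        # region covers only 5 of the 6 bases
        regions = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 55}])
        enr = mg.normalized_frequency(regions, hits, counts)
        assert enr["hits_in_regions"].iloc[0] == 0

    def test_overlapping_regions_count_instance_once(self):
        genome = {"chr1": "A" * 50 + "CACGTG" + "A" * 50}
        hits = mg.scan_motifs(genome, ["CACGTG"])
        regions = pd.DataFrame(
            [{"chrom": "chr1", "start": 40, "end": 70}, {"chrom": "chr1", "start": 45, "end": 75}]
        )
        enr = mg.normalized_frequency(regions, hits, {"CACGTG": 1})
        assert enr["hits_in_regions"].iloc[0] == 1

    def test_absent_motif_omitted_with_warning(self, small_genome):
        hits = mg.scan_motifs(small_genome, ["CACGTG"])
        with pytest.warns(UserWarning, match="absent"):
            enr = mg.normalized_frequency(
                pd.DataFrame(columns=["chrom", "start", "end"]), hits,
                {"CACGTG": 10, "AAAAAA": 0},
            )
        assert list(enr["motif"]) == ["CACGTG"]

    def test_bounds_invariant(self, small_genome):
        motifs = ["CACGTG", "AACGTT", "CATGTG"]
        hits = mg.scan_motifs(small_genome, motifs)
        counts = mg.genome_motif_counts(small_genome, motifs)
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 40_000, size=30)
        regions = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
        enr = mg.normalized_frequency(regions, hits, counts)
        assert enr["normalized_frequency"].between(0, 1).all()


# ---------------------------------------------------------------------------
# co-occurrence / annotation
# ---------------------------------------------------------------------------

def _brute_contains(region, hits):
    rs, re_ = region["start"], region["end"]
    for h in hits.itertuples(index=False):
        if h.chrom == region["chrom"] and h.start >= rs and h.end <= re_:
            return True
    return False


class TestCooccurrence:
    def test_region_with_both(self):
        regions = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        cells = mg.cooccurrence_partition(regions, _hits("CACGTG", [10]), _hits("AACGTT", [50]))
        assert cells == {"A_only": 0, "B_only": 0, "both": 1, "neither": 0}

    def test_cells_sum_to_region_count(self):
        rng = np.random.default_rng(11)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": rng.integers(0, 5000, 50)}
        ).assign(end=lambda d: d["start"] + 200)
        ha = _hits("CACGTG", rng.integers(0, 5200, 30))
        hb = _hits("AACGTT", rng.integers(0, 5200, 30))
        cells = mg.cooccurrence_partition(regions, ha, hb)
        assert sum(cells.values()) == 50

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            regions = pd.DataFrame(
                {"chrom": "chr1", "start": rng.integers(0, 2000, 15)}
            ).assign(end=lambda d: d["start"] + rng.integers(10, 300, 15))
            ha = _hits("CACGTG", rng.integers(0, 2300, 10))
            hb = _hits("AACGTT", rng.integers(0, 2300, 10))
            cells = mg.cooccurrence_partition(regions, ha, hb)
            expect = {"A_only": 0, "B_only": 0, "both": 0, "neither": 0}
            for _, reg in regions.iterrows():
                a, b = _brute_contains(reg, ha), _brute_contains(reg, hb)
                key = "both" if a and b else "A_only" if a else "B_only" if b else "neither"
                expect[key] += 1
            assert cells == expect


class TestAnnotateRegions:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame(
            [
                ("chr1", 10_000, 18_000, "geneA", "+", 10_000),
                ("chr1", 30_000, 40_000, "geneB", "-", 39_999),
                ("chr2", 5_000, 9_000, "geneC", "+", 5_000),
            ],
            columns=sd.GENE_COLUMNS,
        )

    def _regions(self, apexes, chrom="chr1"):
        return pd.DataFrame(
            [
                {"chrom": chrom, "start": a - 100, "end": a + 100, "apex": a,
                 "id": f"r{i}"}
                for i, a in enumerate(apexes)
            ]
        )

    def test_promoter_within_window(self, genes):
        ann = mg.annotate_regions(self._regions([11_500]), genes)
        assert ann["category"].iloc[0] == "promoter"

    def test_intragenic_far_from_tss(self, genes):
        ann = mg.annotate_regions(self._regions([15_000]), genes)
        assert ann["category"].iloc[0] == "intragenic"

    def test_hand_worked_layout(self, genes):
        apexes = [500, 9_000, 10_500, 15_000, 25_000, 31_000, 38_500, 41_000, 47_000, 12_100]
        expected = [
            "intergenic",   # 500: far from everything
            "promoter",     # 9000: 1 kb upstream of geneA TSS
            "promoter",     # 10500: inside geneA but within 2 kb of TSS
            "intragenic",   # 15000: geneA body
            "intergenic",   # 25000
            "intragenic",   # 31000: geneB body, 9 kb from its TSS (at 39999)
            "promoter",     # 38500: within 2 kb of geneB TSS
            "promoter",     # 41000: 1 kb past geneB TSS
            "intergenic",   # 47000
            "intragenic",   # 12100: geneA body, 2.1 kb from TSS
        ]
        ann = mg.annotate_regions(self._regions(apexes), genes)
        assert list(ann["category"]) == expected

    def test_signed_distance_strand_aware(self, genes):
        ann = mg.annotate_regions(self._regions([10_500]), genes)
        assert ann["nearest_gene"].iloc[0] == "geneA"
        assert ann["tss_distance"].iloc[0] == 500
        ann2 = mg.annotate_regions(self._regions([39_499]), genes)
        assert ann2["nearest_gene"].iloc[0] == "geneB"
        assert ann2["tss_distance"].iloc[0] == 500  # downstream on - strand

    def test_empty_gene_set_all_intergenic(self):
        ann = mg.annotate_regions(
            self._regions([100, 5000]), pd.DataFrame(columns=sd.GENE_COLUMNS)
        )
        assert (ann["category"] == "intergenic").all()

    def test_categories_partition(self, genes):
        rng = np.random.default_rng(5)
        ann = mg.annotate_regions(self._regions(rng.integers(0, 50_000, 100)), genes)
        assert ann["category"].isin(["promoter", "intragenic", "intergenic"]).all()
        assert len(ann) == 100


# ---------------------------------------------------------------------------
# condition comparison / spatial / coverage
# ---------------------------------------------------------------------------

class TestConditionFoldChange:
    def _summits(self, apexes, heights, condition):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "start": a - 100, "end": a + 100, "apex": a,
                 "height": h, "pvalue": 1e-10, "condition": condition,
                 "id": f"{condition}{i}"}
                for i, (a, h) in enumerate(zip(apexes, heights))
            ]
        )

    def test_identical_sets_give_one(self):
        s = self._summits([1000, 3000], [5.0, 6.0], "x")
        hits = _hits("CACGTG", [990, 2990])
        fc = mg.condition_fold_change(s, s, {"CACGTG": hits}, "count")
        assert fc["fold_change"].iloc[0] == pytest.approx(1.0)
        fc2 = mg.condition_fold_change(s, s, {"CACGTG": hits}, "mean_height")
        assert fc2["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_reported_infinite(self):
        high = self._summits([1000], [5.0], "h")
        low = self._summits([90_000], [5.0], "l")  # no motif there
        hits = _hits("CACGTG", [990])
        with pytest.warns(UserWarning, match="zero denominator"):
            fc = mg.condition_fold_change(high, low, {"CACGTG": hits}, "count")
        assert np.isinf(fc["fold_change"].iloc[0])

    def test_dose_response_exact_enumeration(self, affinity):
        # sigma_h = 0: occupancy is exactly c/(c+kd); choose doses spanning the
        # detection threshold for the low-affinity site only
        g = sd.gen_genome(1, 300_000, gc=0.5, seed=21)
        g, truth = sd.plant_sites(
            g, [("CACGTG", 40), ("AACGTT", 40)], min_gap=500, seed=21, affinity=affinity
        )
        model = sd.SyntheticPeakModel(
            concentrations={"lowMYC": 0.1, "highMYC": 1.0}, theta_det=0.2, sigma_h=0.0, seed=0
        )
        # exact occupancy enumeration oracle
        for motif, kd in (("CACGTG", 1 / 25), ("AACGTT", 1.0)):
            for cond, c in (("lowMYC", 0.1), ("highMYC", 1.0)):
                theta = c / (c + kd)
                n_emit = len(
                    sd.gen_peaks(truth[truth["motif"] == motif], model, cond)
                )
                assert n_emit == (40 if theta > 0.2 else 0)
        peaks_low = sd.gen_peaks(truth, model, "lowMYC")
        peaks_high = sd.gen_peaks(truth, model, "highMYC")
        sizes = {c: len(s) for c, s in g.items()}
        sh = mg.make_summits(peaks_high, 100, sizes)
        sl = mg.make_summits(peaks_low, 100, sizes)
        hits = mg.scan_motifs(g, ["CACGTG", "AACGTT"])
        by_motif = {m: hits[hits["motif"] == m] for m in ("CACGTG", "AACGTT")}
        with pytest.warns(UserWarning):
            fc = mg.condition_fold_change(sh, sl, by_motif, "count").set_index("motif")
        # low-affinity fold change strictly exceeds high-affinity fold change
        assert fc.loc["AACGTT", "fold_change"] > fc.loc["CACGTG", "fold_change"]
        # all 40 planted sites emit in both conditions; background instances
        # inside the extra high-dose summits can only nudge the ratio upward
        assert 1.0 <= fc.loc["CACGTG", "fold_change"] <= 1.25

    def test_invalid_mode(self):
        s = self._summits([1000], [5.0], "x")
        with pytest.raises(InvalidArgumentError):
            mg.condition_fold_change(s, s, {}, "median")


class TestSpatialDistribution:
    def _summits(self, apexes):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": a - 100, "end": a + 100, "apex": a, "id": f"s{i}"}
             for i, a in enumerate(apexes)]
        )

    def test_motifs_at_apex_fill_central_bin(self):
        apexes = [1000, 3000, 5000]
        hits = _hits("CACGTG", [a - 3 for a in apexes])  # midpoint == apex
        h = mg.spatial_distribution(self._summits(apexes), hits, bin_size=10, window=100)
        central = h[(h["offset_lo"] <= 0) & (h["offset_hi"] > 0)]
        assert central["count"].iloc[0] == 3
        assert h["count"].sum() == 3

    def test_totals_match_brute_force(self):
        rng = np.random.default_rng(17)
        apexes = rng.integers(500, 50_000, 20)
        hits = _hits("CACGTG", rng.integers(0, 50_500, 200))
        h = mg.spatial_distribution(self._summits(apexes), hits, bin_size=10, window=100)
        brute = 0
        for a in apexes:
            mids = hits["start"].to_numpy() + 3
            brute += int(np.sum((mids - a >= -100) & (mids - a < 100)))
        assert h["count"].sum() == brute
        assert np.allclose(h["per_summit"], h["count"] / 20)

    def test_uniform_jitter_roughly_flat(self):
        rng = np.random.default_rng(19)
        apexes = np.arange(100, 2_000_000, 1000)
        offsets = rng.integers(-100, 95, size=len(apexes))
        hits = _hits("CACGTG", apexes + offsets - 3)
        h = mg.spatial_distribution(self._summits(list(apexes)), hits, bin_size=20, window=100)
        expected = len(apexes) / len(h)
        assert (np.abs(h["count"] - expected) < 5 * np.sqrt(expected)).all()

    def test_empty_summits_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mg.spatial_distribution(pd.DataFrame(columns=["chrom", "apex", "id"]), _hits("CACGTG", [1]))


class TestTopkCoverage:
    def _summits(self, apexes):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": a - 100, "end": a + 100, "apex": a, "id": f"s{i}"}
             for i, a in enumerate(apexes)]
        )

    def test_all_hexamers_give_full_coverage(self, small_genome):
        from eboxscape._seq import all_kmers

        # any 200 bp window of iid sequence contains some hexamer
        summits = pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": s + 200, "apex": s + 100, "id": f"s{s}"}
             for s in (0, 10_000, 20_000)]
        )
        motifs = list(all_kmers(6))
        hits = mg.scan_motifs(small_genome, motifs)
        assert mg.topk_coverage(summits, hits, motifs) == 1.0

    def test_empty_motif_list(self):
        s = self._summits([1000])
        assert mg.topk_coverage(s, _hits("CACGTG", [1]), []) == 0.0

    def test_empty_summits_error(self):
        with pytest.raises(InvalidArgumentError):
            mg.topk_coverage(pd.DataFrame(columns=["chrom", "start", "end"]), _hits("CACGTG", [1]), ["CACGTG"])

    def test_fraction_counts_regions(self):
        s = self._summits([1000, 5000, 9000])
        hits = _hits("CACGTG", [990, 4990])
        assert mg.topk_coverage(s, hits, ["CACGTG"]) == pytest.approx(2 / 3)
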