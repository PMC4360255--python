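from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from polyamap.io import SequenceRecord
from polyamap.motifs import (
    WINDOW_PRESETS,
    DEFAULT_DOWNSTREAM_ELEMENTS,
    all_kmers,
    count_sites_with_motif,
    enrichment_ratio,
    genome_kmer_frequencies,
    known_element_scan,
    motif_position_profile,
    motif_rank,
    site_tetramer_distribution,
    two_proportion_chisq,
)
from polyamap.site_mapper import site_to_index

RNG = np.random.default_rng(17)


def _random_region():
    return "".join(RNG.choice(list("ACGT"), 201))


def _region_with(motif, pos, base_region=None):
    region = base_region or ("C" * 201)
    i = site_to_index(pos)
    return region[:i] + motif + region[i + len(motif) :]


def naive_sites_with_motif(regions, motif, window):
    """Per-site brute-force scan over eligible start indices."""
    starts = [site_to_index(p) for p in window.positions()]
    starts = [i for i in starts if i + len(motif) <= 201]
    return sum(any(r[i : i + len(motif)] == motif for i in starts) for r in regions)


class TestCountSitesWithMotif:
    def test_direct_percentage(self):
        regions = [_region_with("AATAAA", -30) for _ in range(6)] + [
            "C" * 201 for _ in range(4)
        ]
        table = count_sites_with_motif(regions, 6, WINDOW_PRESETS["hexamer_up50"])
        assert table.loc["AATAAA", "pct_sites"] == pytest.approx(60.0)
        assert table.loc["AATAAA", "motif_rna"] == "AAUAAA"

    def test_two_copies_count_once(self):
        region = _region_with("AATAAA", -30, _region_with("AATAAA", -45))
        table = count_sites_with_motif([region], 6, WINDOW_PRESETS["hexamer_up50"])
        assert table.loc["AATAAA", "n_sites_with_copy"] == 1

    def test_window_membership_is_first_base_only(self):
        # first base at -1: footprint crosses the site, still counted
        region = _region_with("AATAAA", -1)
        table = count_sites_with_motif([region], 6, WINDOW_PRESETS["hexamer_up50"])
        assert table.loc["AATAAA", "n_sites_with_copy"] == 1

    def test_matches_naive_oracle_on_random_regions(self):
        regions = [_random_region() for _ in range(40)]
        window = WINDOW_PRESETS["hexamer_up50"]
        table = count_sites_with_motif(regions, 6, window)
        for motif in ("AATAAA", "TTTTTT", "TGTAAC", "ACGTAC"):
            assert table.loc[motif, "n_sites_with_copy"] == naive_sites_with_motif(
                regions, motif, window
            )

    def test_enumerates_full_alphabet(self):
        regions = [_random_region() for _ in range(5)]
        hexamers = count_sites_with_motif(regions, 6, WINDOW_PRESETS["hexamer_up50"])
        tetramers = count_sites_with_motif(regions, 4, WINDOW_PRESETS["downstream50"])
        assert len(hexamers) == 4096
        assert len(tetramers) == 256
        assert sorted(hexamers["rank"]) == list(range(1, 4097))


class TestMotifRank:
    def test_most_frequent_is_rank_one(self):
        regions = [_region_with("AATAAA", -30, _random_region()) for _ in range(9)] + [
            _random_region()
        ]
        table = count_sites_with_motif(regions, 6, WINDOW_PRESETS["hexamer_up50"])
        assert motif_rank(table, "AATAAA") == 1
        assert motif_rank(table, "AAUAAA") == 1  # RNA spelling accepted

    def test_absent_motif_ranks_below_present_ones(self):
        regions = [_region_with("AATAAA", -30)]
        table = count_sites_with_motif(regions, 6, WINDOW_PRESETS["hexamer_up50"])
        n_present = int((table["n_sites_with_copy"] > 0).sum())
        assert motif_rank(table, "GGGGGG") > n_present

    def test_wrong_length_rejected(self):
        regions = [_random_region()]
        table = count_sites_with_motif(regions, 6, WINDOW_PRESETS["hexamer_up50"])
        with pytest.raises(ValueError):
            motif_rank(table, "AATA")


class TestMotifPositionProfile:
    def test_planted_position_recovered(self, plant_run):
        spec, _, result = plant_run
        profile = result.profiles["AATAAA"]
        assert profile.peak_position == spec.plantings[0].position == -21
        frac = spec.plantings[0].fraction
        se = 100 * np.sqrt(frac * (1 - frac) / spec.n_genes)
        assert abs(profile.pct.max() - 100 * frac) <= 3 * se

    def test_overlap_counting_on_homopolymer(self):
        region = "T" * 201
        profile = motif_position_profile([region], "TTTTTT")
        assert np.allclose(profile.pct, 100.0)
        assert profile.accumulated_pct == 100.0 * len(profile.positions)
        assert profile.accumulated_pct >= profile.pct.max()

    def test_absent_motif_all_zero(self):
        profile = motif_position_profile(["C" * 201], "AATAAA")
        assert np.all(profile.pct == 0) and profile.accumulated_pct == 0

    def test_conservation_of_start_counts(self):
        regions = [_random_region() for _ in range(10)]
        k = 4
        total = 0
        for motif in all_kmers(k):
            profile = motif_position_profile(regions, motif)
            total += round(profile.accumulated_pct * len(regions) / 100)
        eligible = sum(1 for p in range(-100, 102) if p != 0 and site_to_index(p) + k <= 201)
        assert total == len(regions) * eligible


class TestSiteTetramers:
    def test_slice_at_site(self):
        region = _region_with("TTT", -3, "C" * 201)
        region = region[:100] + "A" + region[101:]  # site base A
        table = site_tetramer_distribution([region])
        assert table.loc["TTTA", "n_sites_with_copy"] == 1

    def test_four_distinct_tetramers(self):
        regions = []
        for tet in ("TTTA", "AACA", "GACA", "CTCA"):
            region = "C" * 97 + tet + "G" * 100
            regions.append(region)
        table = site_tetramer_distribution(regions)
        for tet in ("TTTA", "AACA", "GACA", "CTCA"):
            assert table.loc[tet, "pct_sites"] == pytest.approx(25.0)
        assert table["pct_sites"].sum() == pytest.approx(100.0)

    def test_matches_direct_extraction(self):
        regions = [_random_region() for _ in range(30)]
        table = site_tetramer_distribution(regions)
        oracle = Counter(r[97:101] for r in regions)
        for tet, count in oracle.items():
            assert table.loc[tet, "n_sites_with_copy"] == count


class TestKnownElementScan:
    def test_default_element_list(self):
        assert DEFAULT_DOWNSTREAM_ELEMENTS == [
            "TTATTT", "CCTCCC", "TGTGTG", "GTGTGT", "TGTTTG", "ATGCGT",
        ]

    def test_planted_element_enriched(self):
        regions = [
            _region_with("TGTTTG", 5) if i < 30 else _random_region()
            for i in range(100)
        ]
        scan = known_element_scan(regions)
        assert scan.loc["TGTTTG", "verdict"] == "enriched"
        assert scan.loc["TGTTTG", "pct_sites"] >= 30.0

    def test_absent_element_zero(self):
        scan = known_element_scan(["C" * 201])
        assert scan.loc["ATGCGT", "pct_sites"] == 0.0


class TestGenomeKmers:
    def test_homopolymer_conflation(self):
        table = genome_kmer_frequencies([SequenceRecord("c", "", "AAAAAAA")], 6)
        assert table.count("AAAAAA") == 2  # overlapping count of 7 A's

    def test_total_count_without_n(self):
        seq = _random_region()
        table = genome_kmer_frequencies([SequenceRecord("c", "", seq)], 6)
        assert int(table.pooled_counts.sum()) == len(seq) - 5

    def test_matches_naive_tally_on_10kb(self):
        seq = "".join(RNG.choice(list("ACGT"), 10_000))
        table = genome_kmer_frequencies([SequenceRecord("c", "", seq)], 4)
        oracle = Counter(seq[i : i + 4] for i in range(len(seq) - 3))
        for motif in all_kmers(4):
            assert table.count(motif) == oracle.get(motif, 0)

    def test_non_overlapping_mode(self):
        table = genome_kmer_frequencies([SequenceRecord("c", "", "A" * 12)], 6,
                                        overlapping=False)
        assert table.count("AAAAAA") == 2  # 12 A's -> exactly two disjoint copies
        overlapping = genome_kmer_frequencies([SequenceRecord("c", "", "A" * 12)], 6)
        assert overlapping.count("AAAAAA") == 7

    def test_n_windows_skipped(self):
        table = genome_kmer_frequencies([SequenceRecord("c", "", "AAN" + "A" * 6)], 6)
        assert int(table.pooled_counts.sum()) == 1  # only the final window is N-free


class TestEnrichment:
    def test_arithmetic(self):
        assert enrichment_ratio(50.0, 0.001) == pytest.approx(500.0)
        assert enrichment_ratio(0.0, 0.01) == 0.0
        assert np.isnan(enrichment_ratio(10.0, 0.0))

    def test_planted_signal_exceeds_100x(self, plant_dataset, plant_run):
        spec, genome, _, _ = plant_dataset
        _, _, result = plant_run
        table = result.motif_tables["hexamer_up50"]
        genome_table = genome_kmer_frequencies(genome, 6)
        ratio = enrichment_ratio(
            float(table.loc["AATAAA", "pct_sites"]),
            float(genome_table.pooled_freq["AATAAA"]),
        )
        assert ratio > 100.0


class TestTwoProportionChisq:
    def test_identical_proportions(self):
        stat, p = two_proportion_chisq(50, 100, 50, 100)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        # counts reconstructed from printed percentages: 11.60% of 389 vs
        # 7.08% of 579 site-tetramer carriers
        for x1, n1, x2, n2 in [(45, 389, 41, 579), (3, 10, 9, 11), (120, 400, 95, 500)]:
            stat, p = two_proportion_chisq(x1, n1, x2, n2)
            ref = chi2_contingency(
                [[x1, n1 - x1], [x2, n2 - x2]], correction=False
            )
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_extreme_difference_significant(self):
        _, p = two_proportion_chisq(0, 10, 10, 10)
        assert p < 0.001

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_chisq(0, 10, 0, 10)

    @given(st.integers(1, 30), st.integers(1, 30))
    def test_symmetry(self, x1, x2):
        stat_ab, p_ab = two_proportion_chisq(x1, 31, x2, 31)
        stat_ba, p_ba = two_proportion_chisq(x2, 31, x1, 31)
        assert stat_ab == pytest.approx(stat_ba) and p_ab == pytest.approx(p_ba)
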