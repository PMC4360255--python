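import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import entropy

from polyamap.composition import (
    BaseFrequencyMatrix,
    average_matrices,
    find_peak,
    information_content,
    position_base_frequencies,
    seqlogo_heights,
    summarize_uauau,
)
from polyamap.site_mapper import site_to_index


def _matrix_from_freqs(freqs_by_pos):
    """Build a 201-wide matrix with given (A,C,G,T) columns, default uniform."""
    counts = np.full((4, 201), 0.25)
    for pos, col in freqs_by_pos.items():
        counts[:, site_to_index(pos)] = col
    positions = np.array([p for p in range(-100, 102) if p != 0])
    return BaseFrequencyMatrix(positions=positions, counts=counts, denom=np.ones(201))


class TestPositionBaseFrequencies:
    def test_all_a_regions(self):
        m = position_base_frequencies(["A" * 201] * 2)
        assert np.allclose(m.base_freq("A"), 1.0)
        assert np.all(m.denom == 2)

    def test_uniform_position(self):
        regions = [b + "C" * 200 for b in "ACGT"]
        m = position_base_frequencies(regions)
        assert np.allclose(m.column(-100), [0.25, 0.25, 0.25, 0.25])

    def test_n_excluded_from_numerator_and_denominator(self):
        m = position_base_frequencies(["A" * 201, "N" + "A" * 200])
        assert m.denom[0] == 1 and m.column(-100)[0] == 1.0
        assert m.denom[1] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_base_frequencies([])

    def test_recovers_planted_template_within_3se(self, plant_dataset):
        spec, _, _, truth = plant_dataset
        windows = [g.window201 for g in truth.genes]
        m = position_base_frequencies(windows)
        n = len(windows)
        # compare against the expected post-planting frequencies
        template = spec.template.copy()
        frac = spec.plantings[0].fraction
        start = site_to_index(spec.plantings[0].position)
        expected = template.copy()
        for offset, base in enumerate(spec.plantings[0].motif):
            col = start + offset
            onehot = np.zeros(4)
            onehot["ACGT".index(base)] = 1.0
            expected[:, col] = frac * onehot + (1 - frac) * template[:, col]
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.max(np.abs(m.freq - expected)) <= np.max(3 * se + 1e-12)

    def test_concatenation_equals_pooled_average(self):
        rng = np.random.default_rng(3)
        sets = [
            ["".join(rng.choice(list("ACGT"), 201)) for _ in range(5)],
            ["".join(rng.choice(list("ACGT"), 201)) for _ in range(9)],
        ]
        pooled = average_matrices(
            [position_base_frequencies(s) for s in sets], mode="pooled"
        )
        direct = position_base_frequencies(sets[0] + sets[1])
        assert np.allclose(pooled.freq, direct.freq)


class TestInformationContent:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((1, 0, 0, 0), 2.0),  # single base: maximal conservation
            ((0.25, 0.25, 0.25, 0.25), 0.0),  # uniform: no information
            ((0.5, 0.5, 0, 0), 1.0),
        ],
    )
    def test_reference_values(self, p, expected):
        assert information_content(p) == pytest.approx(expected, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            information_content((1.2, -0.2, 0, 0))

    def test_non_probability_rejected(self):
        with pytest.raises(ValueError):
            information_content((0.5, 0.2, 0.1, 0.1))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=4, max_size=4))
    def test_random_columns_in_0_2(self, raw):
        p = np.array(raw) / np.sum(raw)
        p = p / p.sum()
        ic = information_content(p)
        assert 0.0 <= ic <= 2.0


class TestSeqlogoHeights:
    def test_all_a_column(self):
        m = _matrix_from_freqs({-1: (1, 0, 0, 0)})
        h = seqlogo_heights(m)
        assert np.allclose(h[:, site_to_index(-1)], [2, 0, 0, 0])

    def test_uniform_column_zero(self):
        h = seqlogo_heights(_matrix_from_freqs({}))
        assert np.allclose(h, 0.0)

    def test_column_sums_equal_independent_ic(self):
        rng = np.random.default_rng(11)
        counts = rng.dirichlet(np.ones(4), size=201).T
        positions = np.array([p for p in range(-100, 102) if p != 0])
        m = BaseFrequencyMatrix(positions=positions, counts=counts, denom=np.ones(201))
        h = seqlogo_heights(m)
        # second implementation: log2(J) minus Shannon entropy in bits
        ic_oracle = np.log2(4) - entropy(m.freq, base=2, axis=0)
        assert np.allclose(h.sum(axis=0), ic_oracle, atol=1e-12)


class TestFindPeak:
    def test_planted_a_bump(self):
        m = _matrix_from_freqs({-21: (0.6, 0.2, 0.1, 0.1), -20: (0.4, 0.2, 0.2, 0.2)})
        peak = find_peak(m, "A", (-30, -10))
        assert peak.peak_position == -21
        assert peak.peak_frequency == pytest.approx(60.0)

    def test_flat_upstream_tie_breaks_toward_site(self):
        m = _matrix_from_freqs({})
        assert find_peak(m, "T", (-15, -2)).peak_position == -2
        assert find_peak(m, "T", (2, 40)).peak_position == 2

    def test_planted_u_bump_recovered(self, plant_run):
        _, _, result = plant_run
        peak = find_peak(result.matrix, "T", (-15, -2))
        assert peak.peak_position == -7


class TestSummarizeUauau:
    def test_plant_like_components(self, plant_run):
        spec, _, result = plant_run
        pattern = result.pattern
        assert pattern.uar.peak_position == -21
        assert pattern.second_uur.peak_position == -7
        assert pattern.site_a_pct > 75.0
        assert pattern.dur.plateau  # flat downstream U richness, no sharp peak

    def test_animal_like_components(self, animal_run):
        _, _, result = animal_run
        assert result.pattern.uar.peak_position == -18
        assert result.pattern.second_uur.peak_position == -9
        assert result.pattern.dur.peak_position == 19
        assert not result.pattern.dur.plateau

    def test_flat_matrix_all_plateaus(self):
        pattern = summarize_uauau(_matrix_from_freqs({}))
        assert pattern.first_uur.plateau and pattern.uar.plateau
        assert pattern.second_uur.plateau and pattern.dur.plateau


class TestAverageMatrices:
    def test_mean_of_identical_is_identity(self):
        m = _matrix_from_freqs({-21: (0.6, 0.2, 0.1, 0.1)})
        out = average_matrices([m, m], mode="species_mean")
        assert np.allclose(out.freq, m.freq)

    def test_species_mean_of_opposites(self):
        a = _matrix_from_freqs({-1: (1, 0, 0, 0)})
        b = _matrix_from_freqs({-1: (0, 1, 0, 0)})
        out = average_matrices([a, b], mode="species_mean")
        assert np.allclose(out.column(-1), [0.5, 0.5, 0, 0])

    def test_pooled_differs_from_species_mean_hand_computed(self):
        # 2 sites all-A vs 6 sites all-C at one position
        positions = np.array([p for p in range(-100, 102) if p != 0])
        a = BaseFrequencyMatrix(positions, np.tile([[2], [0], [0], [0]], 201), np.full(201, 2))
        b = BaseFrequencyMatrix(positions, np.tile([[0], [6], [0], [0]], 201), np.full(201, 6))
        mean = average_matrices([a, b], mode="species_mean")
        pooled = average_matrices([a, b], mode="pooled")
        assert np.allclose(mean.column(-1), [0.5, 0.5, 0, 0])
        assert np.allclose(pooled.column(-1), [0.25, 0.75, 0, 0])  # 2/8 vs 6/8

    def test_mixed_widths_rejected(self):
        m = _matrix_from_freqs({})
        narrow = BaseFrequencyMatrix(
            positions=np.array([1, 2]), counts=np.full((4, 2), 0.25), denom=np.ones(2)
        )
        with pytest.raises(ValueError):
            average_matrices([m, narrow])
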