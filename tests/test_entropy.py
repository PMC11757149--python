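"""Column entropies, sliding-window profiles and logo matrices."""

import numpy as np
import pytest

from motifcons import (
    CONSENSUS,
    ColumnProfile,
    OrthologousWindowSet,
    column_entropy,
    logo_matrix,
    pooled_window_values,
    window_scan,
)


def _window_set(rows, group="with_site", flank=12):
    return OrthologousWindowSet(
        ids=tuple(f"s{i}" for i in range(len(rows))),
        rows=tuple(rows),
        group=group,
        flank=flank,
    )


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 1, "C": 1, "G": 1, "T": 1}, 2.0),
            ({"A": 4}, 0.0),
            ({"A": 2, "C": 2}, 1.0),
            ([3, 1, 0, 0], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
        ],
    )
    def test_reference_values(self, counts, expected):
        assert column_entropy(counts) == pytest.approx(expected)

    def test_all_gap_column_is_missing_not_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            column_entropy({"A": 0})

    def test_single_observation_column_flagged_missing_in_profile(self):
        profile = ColumnProfile.from_rows(["A-", "-C"])
        assert np.isnan(profile.entropies).all()
        assert profile.totals.tolist() == [1.0, 1.0]


class TestWindowScan:
    def test_window_count_matches_flank_and_step(self):
        rows = ["A" * 12 + CONSENSUS + "G" * 12] * 3
        profiles = window_scan(_window_set(rows), width=6, step=1)
        assert len(profiles["five_prime"]) == 7  # 12 - 6 + 1
        assert len(profiles["three_prime"]) == 7
        tiled = window_scan(_window_set(rows), width=6, step=6)
        assert len(tiled["five_prime"]) == 2

    def test_identical_group_profiles_are_zero(self):
        rows = ["ACGTACGTACGT" + CONSENSUS + "TTGGCCAATTGG"] * 4
        profiles = window_scan(_window_set(rows))
        for prof in profiles.values():
            assert np.allclose(prof.values, 0.0)

    def test_two_rows_differing_everywhere_give_one_bit(self):
        rows = ["A" * 12 + CONSENSUS + "G" * 12,
                "C" * 12 + CONSENSUS + "T" * 12]
        profiles = window_scan(_window_set(rows))
        for prof in profiles.values():
            assert np.allclose(prof.values, 1.0)

    def test_window_means_equal_direct_recomputation(self, default_panel):
        """Each window value is the arithmetic mean of its member column entropies."""
        from motifcons import extract_windows

        with_set, _ = extract_windows(
            list(default_panel.records), "with_01",
            default_panel.spec.motif_start, flank=12,
        )
        profiles = window_scan(with_set, width=6, step=1)
        for side, prof in profiles.items():
            cols = ColumnProfile.from_rows(with_set.flank_rows(side)).entropies
            for start, value in zip(prof.window_starts, prof.values):
                member = cols[start : start + 6]
                assert value == pytest.approx(np.mean(member[np.isfinite(member)]))

    def test_flank_shorter_than_width_rejected(self):
        rows = ["AAA" + CONSENSUS + "GGG"] * 2
        with pytest.raises(ValueError, match="at least 6"):
            window_scan(_window_set(rows, flank=3), width=6)

    def test_missing_columns_excluded_with_effective_count(self):
        # first flank column all-gap -> missing; windows skip it
        rows = ["-" + "A" * 11 + CONSENSUS + "G" * 12,
                "-" + "A" * 11 + CONSENSUS + "G" * 12]
        profiles = window_scan(_window_set(rows))
        first = profiles["five_prime"]
        assert first.n_columns_effective[0] == 5
        assert first.values[0] == pytest.approx(0.0)

    def test_pooled_values_drop_missing(self):
        rows = ["------" + "A" * 6 + CONSENSUS + "G" * 12] * 2
        profiles = window_scan(_window_set(rows), width=6, step=6)
        pooled = pooled_window_values(profiles.values())
        assert np.isfinite(pooled).all()
        assert len(pooled) == 3  # one five-prime window lost to the gap block


class TestLogoMatrix:
    def test_invariant_and_uniform_positions(self):
        rows = ["A" * 7 + CONSENSUS + "A" * 7,
                "C" * 7 + CONSENSUS + "C" * 7,
                "G" * 7 + CONSENSUS + "G" * 7,
                "T" * 7 + CONSENSUS + "T" * 7]
        matrix = logo_matrix(_window_set(rows, flank=7))
        assert matrix.information[0] == pytest.approx(0.0)     # uniform flank
        assert matrix.information[7] == pytest.approx(2.0)     # invariant centre
        assert np.allclose(matrix.frequencies.sum(axis=1), 1.0)

    @pytest.mark.parametrize("n", [5, 50, 500])
    def test_small_sample_correction_shrinks_with_n(self, n):
        rows = ["A" * 7 + CONSENSUS + "A" * 7] * n
        wset = _window_set(rows, flank=7)
        plain = logo_matrix(wset, small_sample_correction=False)
        corrected = logo_matrix(wset, small_sample_correction=True)
        gap = plain.information - corrected.information
        assert np.all(gap >= -1e-12)
        assert np.allclose(gap, 3.0 / (2.0 * np.log(2.0) * n))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            logo_matrix(_window_set([], flank=7))
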