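"""Shoulder index, relative expression and motif-phenotype association."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifcons import (
    motif_phenotype_association,
    relative_expression,
    relative_expression_table,
    shoulder_index,
    shoulder_index_table,
)
from motifcons.phenotype import average_technical_replicates

lengths = st.floats(min_value=0.1, max_value=1e4,
                    allow_nan=False, allow_infinity=False)
scales = st.floats(min_value=1e-3, max_value=1e3,
                   allow_nan=False, allow_infinity=False)


class TestShoulderIndex:
    @pytest.mark.parametrize(
        "l1, l2, w, expected",
        [(5.0, 5.0, 2.0, 0.0), (3.0, 1.0, 2.0, 45.0), (1.0, 3.0, 2.0, -45.0)],
    )
    def test_reference_angles(self, l1, l2, w, expected):
        assert shoulder_index(l1, l2, w) == pytest.approx(expected)

    def test_radians_flag(self):
        assert shoulder_index(3.0, 1.0, 2.0, degrees=False) == pytest.approx(np.pi / 4)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            shoulder_index(1.0, 1.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(lengths, lengths, lengths)
    def test_antisymmetry(self, l1, l2, w):
        assert shoulder_index(l1, l2, w) == pytest.approx(
            -shoulder_index(l2, l1, w), abs=1e-9
        )

    @settings(max_examples=200, derandomize=True)
    @given(lengths, lengths, lengths, scales)
    def test_scale_invariance(self, l1, l2, w, c):
        assert shoulder_index(c * l1, c * l2, c * w) == pytest.approx(
            shoulder_index(l1, l2, w), abs=1e-6
        )

    def test_angles_bounded(self):
        assert -90 < shoulder_index(1e9, 0.0, 1e-3) < 90

    def test_table_helper(self):
        df = pd.DataFrame({"L1": [3.0], "L2": [1.0], "W": [2.0]})
        assert shoulder_index_table(df)["shoulder_index"].iloc[0] == pytest.approx(45.0)


class TestRelativeExpression:
    @pytest.mark.parametrize("dct, expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_reference_ratios(self, dct, expected):
        assert relative_expression(dct) == pytest.approx(expected)

    def test_log2_identity_and_monotonicity(self):
        dct = np.linspace(-5, 5, 41)
        ratio = relative_expression(dct)
        assert np.allclose(np.log2(ratio), -dct)
        assert np.all(np.diff(ratio) < 0)

    def test_non_finite_delta_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            relative_expression(np.nan)

    def test_table_requires_reference(self):
        with pytest.raises(ValueError, match="ct_reference"):
            relative_expression_table(pd.DataFrame({"ct_target": [20.0]}))

    def test_table_values(self):
        df = pd.DataFrame({"ct_target": [21.0, 18.0], "ct_reference": [20.0, 20.0]})
        out = relative_expression_table(df)
        assert out["relative_expression"].tolist() == pytest.approx([0.5, 4.0])

    def test_technical_replicates_averaged_on_ct_scale(self):
        df = pd.DataFrame(
            {"sample_id": ["s1", "s1", "s2"],
             "ct_target": [21.0, 23.0, 20.0],
             "ct_reference": [20.0, 20.0, 20.0]}
        )
        out = average_technical_replicates(df)
        assert out.loc[out["sample_id"] == "s1", "ct_target"].iloc[0] == 22.0
        assert out.loc[out["sample_id"] == "s1", "n_replicates"].iloc[0] == 2


def oracle_fisher_two_sided(a, b, c, d):
    """Hypergeometric enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)
    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def _species_table(counts):
    rows = []
    for (motif, shape), k in counts.items():
        for _ in range(k):
            rows.append({"species": f"s{len(rows)}", "motif_present": motif,
                         "shape_change": shape})
    return pd.DataFrame(rows)


class TestAssociation:
    def test_perfect_concordance(self):
        table = _species_table({(True, True): 21, (False, False): 28})
        assoc = motif_phenotype_association(table)
        assert assoc.concordance == 1.0
        assert assoc.counts.tolist() == [[21, 0], [0, 28]]

    def test_balanced_table_fisher_p(self):
        table = _species_table({(True, True): 3, (False, False): 3})
        assoc = motif_phenotype_association(table)
        assert assoc.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_missing_labels_excluded_with_warning(self):
        table = _species_table({(True, True): 2, (False, False): 2})
        table["shape_change"] = table["shape_change"].astype(object)
        table.loc[0, "shape_change"] = None
        with pytest.warns(UserWarning, match="missing labels"):
            assoc = motif_phenotype_association(table)
        assert assoc.n == 3 and assoc.n_excluded == 1

    def test_fisher_matches_enumeration_small_tables(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if 0 < a + b + c + d <= 8 and (a + c) and (b + d):
                            table = _species_table(
                                {(True, True): a, (True, False): b,
                                 (False, True): c, (False, False): d}
                            )
                            assoc = motif_phenotype_association(table)
                            assert assoc.p_value == pytest.approx(
                                oracle_fisher_two_sided(a, b, c, d)
                            ), (a, b, c, d)

    def test_shuffled_labels_match_permutation_expectation(self):
        """Mean concordance under label shuffling equals the fixed-margin value."""
        table = _species_table({(True, True): 21, (False, False): 28})
        rng = np.random.default_rng(99)
        shape = table["shape_change"].to_numpy().copy()
        concordances = []
        for _ in range(1000):
            rng.shuffle(shape)
            shuffled = table.assign(shape_change=shape)
            concordances.append(motif_phenotype_association(shuffled).concordance)
        n = len(table)
        r1 = table["motif_present"].sum()
        c1 = table["shape_change"].sum()
        expected = (r1 * c1 + (n - r1) * (n - c1)) / n**2
        assert np.mean(concordances) == pytest.approx(expected, abs=0.02)
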