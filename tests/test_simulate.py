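"""Synthetic-data generator contracts: determinism, embedded ground truth."""

import numpy as np
import pytest

from motifcons import (
    CdsSpec,
    MorphoSpec,
    PanelSpec,
    find_motif,
    relative_expression,
    shoulder_index,
    simulate_cds_alignment,
    simulate_ct,
    simulate_measurements,
    simulate_promoter_panel,
)
from motifcons.simulate import RejectionSamplingError


class TestPromoterPanel:
    def test_study_group_sizes(self, default_panel):
        counts = default_panel.truth["group"].value_counts()
        assert counts["with_site"] == 21
        assert counts["without_site"] == 28
        assert len(default_panel.records) == 49

    def test_with_site_rows_have_exactly_one_match_at_truth_coordinate(
        self, default_panel
    ):
        truth = default_panel.truth.set_index("species_id")
        for rec in default_panel.records:
            hits = find_motif(rec)
            if truth.loc[rec.id, "group"] == "with_site":
                assert len(hits) == 1
                assert hits[0].start == truth.loc[rec.id, "center_start"]
            else:
                assert hits == []

    def test_zero_substitution_collapses_flanks(self):
        panel = simulate_promoter_panel(
            PanelSpec(sub_prob_with=0.0, sub_prob_without=0.0, seed=4)
        )
        spec = panel.spec
        lo, hi = spec.motif_start, spec.motif_start + 6
        flanks = {rec.residues[:lo] + rec.residues[hi:] for rec in panel.records}
        assert len(flanks) == 1  # identical within and across groups

    def test_fasta_output_is_byte_identical_across_reruns(self, tmp_path):
        spec = PanelSpec(seed=21)
        paths = []
        for name in ("a.fasta", "b.fasta"):
            panel = simulate_promoter_panel(spec)
            path = tmp_path / name
            panel.to_fasta(path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_seeds_echoed_into_outputs(self, tmp_path, default_panel):
        assert (default_panel.truth["seed"] == default_panel.spec.seed).all()
        path = tmp_path / "panel.fasta"
        default_panel.to_fasta(path)
        assert f"seed={default_panel.spec.seed}" in path.read_text()

    def test_canned_mutant_center_used_when_requested(self):
        panel = simulate_promoter_panel(PanelSpec(mutant_center="ATATAA", seed=2))
        without = panel.truth[panel.truth["group"] == "without_site"]
        assert (without["center_seq"] == "ATATAA").all()

    def test_unsatisfiable_center_constraint_fails_loudly(self):
        with pytest.raises(RejectionSamplingError, match="center_mut_prob"):
            simulate_promoter_panel(
                PanelSpec(center_mut_prob=0.0, seed=0, max_retries=10)
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_with_site": 0},
            {"sub_prob_with": 1.5},
            {"motif": "CTG"},
            {"flank_len": 3},
            {"mutant_center": "CTGTCA"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PanelSpec(**kwargs)


class TestCdsAlignment:
    def test_every_codon_fourfold(self):
        cds = simulate_cds_alignment(
            CdsSpec(n_genes=3, n_codons=10, fourfold_fraction=1.0, seed=1)
        )
        assert cds.true_fourfold_columns == tuple(range(2, 30, 3))

    def test_alignment_is_gap_free_and_codon_sized(self, default_cds):
        for rec in default_cds.records:
            assert "-" not in rec.residues
            assert len(rec.residues) == 3 * default_cds.spec.n_codons

    def test_no_fourfold_codons_warns(self):
        with pytest.warns(UserWarning, match="fourfold"):
            simulate_cds_alignment(
                CdsSpec(n_genes=2, n_codons=10, fourfold_fraction=0.0, seed=1)
            )

    def test_determinism(self):
        spec = CdsSpec(seed=33)
        a = simulate_cds_alignment(spec)
        b = simulate_cds_alignment(spec)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]


class TestMeasurements:
    def test_row_counts_and_labels(self):
        df = simulate_measurements(MorphoSpec(n_fruits=20, seed=1))
        assert len(df) == 40  # two genotypes by default
        assert set(df["genotype"]) == {"CrWT", "site_deletion"}

    def test_noise_free_symmetric_fruit_has_zero_shoulder_index(self):
        spec = MorphoSpec(
            genotypes={"flat": (100.0, 100.0, 300.0)}, noise_sd=0.0,
            n_fruits=5, seed=0,
        )
        df = simulate_measurements(spec)
        theta = shoulder_index(df["L1"], df["L2"], df["W"])
        assert np.allclose(theta, 0.0)

    def test_widths_stay_positive_under_heavy_noise(self):
        spec = MorphoSpec(
            genotypes={"g": (5.0, 5.0, 5.0)}, noise_sd=50.0, n_fruits=50, seed=3
        )
        df = simulate_measurements(spec)
        assert (df["W"] > 0).all()
        assert (df[["L1", "L2"]] >= 0).all().all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MorphoSpec(n_fruits=0)


class TestCt:
    def test_noise_free_delta_ct_gives_exact_ratio(self):
        df = simulate_ct(n=4, delta_ct_mean=1.0, sd=0.0, seed=0)
        assert np.allclose(relative_expression(df["delta_ct"]), 0.5)

    def test_reference_gene_recorded(self):
        df = simulate_ct(n=3, seed=1)
        assert (df["reference_gene"] == "CrUBQ10").all()
        assert np.allclose(df["ct_target"] - df["ct_reference"], df["delta_ct"])

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="at least 1"):
            simulate_ct(n=0)
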