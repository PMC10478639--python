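"""Confidence detection, B-factor conversion, pruning and segment cleanup."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrprep import (
    ConfidenceKind,
    ConfidenceProfile,
    ConversionParams,
    bfactor_to_rmsd,
    convert_to_bfactors,
    detect_confidence_kind,
    plddt_to_rmsd,
    prune_low_confidence,
    remove_short_segments,
    rmsd_to_bfactor,
    trim_to_target,
)
from mrprep.confidence import alignment_ranges, chain_segments, profile_from_model
from mrprep.model_io import AtomRecord, PredictedModel, ResidueRecord


def _ca_chain(values, chain_id="A", start=1, spacing=3.8, gaps_after=()):
    """Calpha-only chain; residues after an index in gaps_after jump 20 A."""
    residues, x = [], 0.0
    for i, v in enumerate(values):
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                seq_id=start + i,
                res_name="ALA",
                atoms=[AtomRecord("CA", "C", x, 0.0, 0.0, 1.0, float(v))],
            )
        )
        x += 20.0 if (i + 1) in gaps_after else spacing
    return PredictedModel(chains={chain_id: residues})


class TestDetectKind:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.93, 0.41, 0.88], ConfidenceKind.PLDDT1),
            ([88.0, 42.0, 91.5], ConfidenceKind.PLDDT100),
            ([0.8, 1.4, 3.9], ConfidenceKind.RMSD_ANGSTROM),
            ([30.0, 110.0, 45.0], ConfidenceKind.BFACTOR_ALREADY),
        ],
    )
    def test_heuristic_classification(self, values, expected):
        assert detect_confidence_kind(values) is expected

    def test_declared_kind_overrides_heuristic(self):
        assert (
            detect_confidence_kind([0.8, 1.4, 3.9], ConfidenceKind.RMSD_ANGSTROM)
            is ConfidenceKind.RMSD_ANGSTROM
        )

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="invalid confidence values"):
            detect_confidence_kind([5.0, -1.0])


class TestConversionClosedForms:
    def test_midpoint_maps_to_scale_exactly(self):
        # exponent is exactly zero at the midpoint
        assert plddt_to_rmsd(0.70) == 1.5

    def test_full_confidence(self):
        assert plddt_to_rmsd(1.0) == pytest.approx(1.5 * math.exp(-1.2), rel=1e-12)

    def test_zero_confidence_hits_the_cap(self):
        assert 1.5 * math.exp(2.8) == pytest.approx(24.66, abs=0.01)
        assert plddt_to_rmsd(0.0) == 20.0

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError, match="pLDDT out of range"):
            plddt_to_rmsd(p)

    def test_rmsd_to_bfactor_values(self):
        assert rmsd_to_bfactor(0.0) == 0.0
        assert rmsd_to_bfactor(1.5) == pytest.approx(8 * math.pi**2 / 3 * 2.25, rel=1e-12)
        assert rmsd_to_bfactor(0.4518) == pytest.approx(
            8 * math.pi**2 / 3 * 0.4518**2, rel=1e-12
        )

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError, match="invalid rmsd"):
            rmsd_to_bfactor(-0.1)

    @given(st.floats(min_value=0.0, max_value=20.0))
    def test_bfactor_round_trip(self, r):
        assert bfactor_to_rmsd(rmsd_to_bfactor(r)) == pytest.approx(r, rel=1e-9, abs=1e-12)

    def test_conversion_strictly_monotone(self):
        grid = np.arange(0.0, 100.05, 0.1) / 100.0
        rmsd = [plddt_to_rmsd(p) for p in grid]
        b = [rmsd_to_bfactor(r) for r in rmsd]
        uncapped = [r < 20.0 for r in rmsd]
        for i in range(1, len(grid)):
            assert rmsd[i] <= rmsd[i - 1]
            assert b[i] <= b[i - 1]
            if uncapped[i] and uncapped[i - 1]:
                assert b[i] < b[i - 1]


class TestConvertToBfactors:
    def test_plddt70_residue_gets_midpoint_b(self):
        model = _ca_chain([70.0, 90.0])
        out = convert_to_bfactors(model)
        expected = 8 * math.pi**2 / 3 * 2.25
        assert out.raw_confidences()[0] == pytest.approx(expected, rel=1e-9)

    def test_higher_confidence_gets_lower_b(self):
        out = convert_to_bfactors(_ca_chain([90.0, 50.0]))
        b90, b50 = out.raw_confidences()
        assert b90 < b50

    def test_bfactor_already_is_identity(self):
        model = _ca_chain([30.0, 110.0, 45.0])  # detected as plain B factors
        out = convert_to_bfactors(model)
        assert out.raw_confidences() == model.raw_confidences()
        assert out.source_tag == model.source_tag

    def test_rmsd_profile_goes_straight_to_b(self):
        model = _ca_chain([1.5, 0.5])
        profile = ConfidenceProfile(ConfidenceKind.RMSD_ANGSTROM, [1.5, 0.5])
        out = convert_to_bfactors(model, profile)
        assert out.raw_confidences()[0] == pytest.approx(rmsd_to_bfactor(1.5))

    def test_misaligned_profile_rejected(self):
        profile = ConfidenceProfile(ConfidenceKind.PLDDT100, [70.0])
        with pytest.raises(ValueError, match="length mismatch"):
            convert_to_bfactors(_ca_chain([70.0, 80.0]), profile)

    def test_input_model_is_untouched(self):
        model = _ca_chain([70.0, 90.0])
        convert_to_bfactors(model)
        assert model.raw_confidences() == [70.0, 90.0]


class TestPrune:
    def test_boundary_residue_at_70_is_kept(self):
        model = _ca_chain([95.0, 69.9, 70.0, 30.0])
        pruned = prune_low_confidence(model)
        assert [r.seq_id for r in pruned.residues()] == [1, 3]

    def test_threshold_zero_is_identity(self):
        model = _ca_chain([95.0, 69.9, 70.0, 30.0])
        assert prune_low_confidence(model, threshold=0.0).n_residues == 4

    def test_idempotent(self):
        model = _ca_chain([95.0, 69.9, 70.0, 30.0])
        once = prune_low_confidence(model)
        twice = prune_low_confidence(once)
        assert [r.key for r in twice.residues()] == [r.key for r in once.residues()]

    def test_plddt_fraction_scale_threshold_is_rescaled(self):
        model = _ca_chain([0.95, 0.699, 0.70, 0.30])
        pruned = prune_low_confidence(model)
        assert [r.seq_id for r in pruned.residues()] == [1, 3]

    def test_rmsd_profile_requires_explicit_threshold(self):
        model = _ca_chain([0.8, 1.4, 3.9])
        profile = profile_from_model(model)
        assert profile.kind is ConfidenceKind.RMSD_ANGSTROM
        with pytest.raises(ValueError, match="threshold kind mismatch"):
            prune_low_confidence(model, profile)
        kept = prune_low_confidence(model, profile, rmsd_threshold=1.5)
        assert [r.seq_id for r in kept.residues()] == [1, 2]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=60),
        st.floats(min_value=0.0, max_value=100.0),
    )
    def test_matches_brute_force_filter(self, values, threshold):
        model = _ca_chain(values)
        profile = ConfidenceProfile(ConfidenceKind.PLDDT100, values)
        pruned = prune_low_confidence(model, profile, threshold=threshold)
        expected = [i + 1 for i, v in enumerate(values) if v >= threshold]
        assert [r.seq_id for r in pruned.residues()] == expected


class TestRemoveShortSegments:
    def test_short_middle_segment_removed(self):
        values = [80.0] * 97
        model = _ca_chain(values, gaps_after=(40, 42))  # segments 40 / 2 / 55
        assert [len(s) for s in chain_segments(model)] == [40, 2, 55]
        cleaned = remove_short_segments(model)
        assert cleaned.n_residues == 95
        assert [len(s) for s in chain_segments(cleaned)] == [40, 55]

    def test_min_len_one_is_identity(self):
        model = _ca_chain([80.0] * 10, gaps_after=(2,))
        assert remove_short_segments(model, min_len=1).n_residues == 10

    def test_spatial_gap_forces_a_break(self):
        model = _ca_chain([80.0] * 10, gaps_after=(2,))  # 8 A-plus jump after res 2
        cleaned = remove_short_segments(model)
        assert [r.seq_id for r in cleaned.residues()] == list(range(3, 11))

    def test_numbering_gap_forces_a_break(self):
        front = _ca_chain([80.0] * 2)
        back = _ca_chain([80.0] * 8, start=20)
        model = PredictedModel(chains={"A": front.chains["A"] + back.chains["A"]})
        cleaned = remove_short_segments(model)
        assert cleaned.n_residues == 8

    def test_resegmenting_output_is_a_fixed_point(self):
        model = _ca_chain([80.0] * 30, gaps_after=(5, 7, 20, 22))
        cleaned = remove_short_segments(model)
        assert all(len(s) >= 3 for s in chain_segments(cleaned))
        again = remove_short_segments(cleaned)
        assert [r.key for r in again.residues()] == [r.key for r in cleaned.residues()]


class TestTrim:
    def test_inclusive_range_membership(self):
        model = _ca_chain([80.0] * 6, start=9)  # residues 9..14
        trimmed = trim_to_target(model, [("A", 10, 12)])
        assert [r.seq_id for r in trimmed.residues()] == [10, 11, 12]

    def test_empty_range_list_empties_the_model(self):
        assert trim_to_target(_ca_chain([80.0] * 3), []).n_residues == 0

    def test_overlapping_ranges_behave_as_union(self):
        model = _ca_chain([80.0] * 10)
        a = trim_to_target(model, [("A", 1, 5), ("A", 3, 8)])
        b = trim_to_target(model, [("A", 1, 8)])
        assert [r.key for r in a.residues()] == [r.key for r in b.residues()]

    def test_unknown_chain_rejected(self):
        with pytest.raises(ValueError, match="unknown chain"):
            trim_to_target(_ca_chain([80.0] * 3), [("B", 1, 2)])

    def test_alignment_ranges_cover_the_matched_region(self):
        model = _ca_chain([80.0] * 8)
        for res, letter in zip(model.residues(), "ACDEFGHI"):
            res.res_name = {
                "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU",
                "F": "PHE", "G": "GLY", "H": "HIS", "I": "ILE",
            }[letter]
        ranges = alignment_ranges(model, "ACDEFGHI")
        trimmed = trim_to_target(model, ranges)
        assert trimmed.n_residues == 8
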