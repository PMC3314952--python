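"""Random-coil references, secondary shifts, SSP scoring and region helicity."""

import numpy as np
import pandas as pd
import pytest

from coiltools import (HelixRegions, ProteinSequence, RandomCoilReference,
                       ShiftTable, random_coil_shifts, read_nmrstar_shifts,
                       region_helicity, secondary_shifts, ssp_profile,
                       urea_difference_shifts)
from coiltools.errors import ShiftTableError
from coiltools.shifts import FULL_HELIX_SHIFT, SSPProfile

NMRSTAR_FIXTURE = """\
data_synthetic_fixture

save_assigned_chemical_shifts
   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts

   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Seq_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Atom_type
      _Atom_chem_shift.Val
      _Atom_chem_shift.Val_err

      1  2  GLU  CA  C  56.61  0.05
      2  3  LEU  CA  C  55.12  0.05
      3  4  LYS  CA  C  56.24  0.05
      4  4  LYS  QB  H   1.70  0.05

   stop_
save_
"""


class TestNmrStarReader:
    def test_minimal_fixture(self, tmp_path):
        path = tmp_path / "shifts.str"
        path.write_text(NMRSTAR_FIXTURE)
        table = read_nmrstar_shifts(path)
        assert len(table) == 3  # the QB row is outside the nucleus vocabulary
        assert set(table.data["nucleus"]) == {"CA"}
        assert table.data.loc[0, "shift_ppm"] == pytest.approx(56.61)
        assert table.data.loc[0, "residue_type"] == "E"

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.str"
        duplicated = NMRSTAR_FIXTURE.replace(
            "      4  4  LYS  QB  H   1.70  0.05",
            "      4  2  GLU  CA  C  56.70  0.05")
        path.write_text(duplicated)
        with pytest.raises(ShiftTableError, match="residue 2"):
            read_nmrstar_shifts(path)

    def test_missing_loop_rejected(self, tmp_path):
        path = tmp_path / "empty.str"
        path.write_text("data_nothing\n")
        with pytest.raises(ShiftTableError, match="no assigned"):
            read_nmrstar_shifts(path)


class TestRandomCoilShifts:
    def test_homopolymer_equals_base(self, coil_reference):
        seq = ProteinSequence("poly", "E" * 10)
        table = random_coil_shifts(seq, coil_reference, nuclei=("CA",))
        np.testing.assert_allclose(table.data["shift_ppm"],
                                   coil_reference.base[("E", "CA")])

    def test_temperature_independent_without_coefficients(self, variant,
                                                          coil_reference):
        cold = random_coil_shifts(variant, coil_reference, temperature_k=278.0)
        warm = random_coil_shifts(variant, coil_reference, temperature_k=308.0)
        np.testing.assert_allclose(cold.data["shift_ppm"],
                                   warm.data["shift_ppm"])

    def test_neighbor_flip_affects_only_two_positions_each_side(self):
        base = {(aa, "CA"): 50.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        ref = RandomCoilReference(
            base=base,
            neighbor={("CA", -2, "G"): 0.1, ("CA", -1, "G"): 0.2,
                      ("CA", 1, "G"): 0.3, ("CA", 2, "G"): 0.4})
        seq_a = ProteinSequence("a", "E" * 11)
        seq_b = ProteinSequence("b", "E" * 5 + "G" + "E" * 5)
        shifts_a = random_coil_shifts(seq_a, ref, nuclei=("CA",))
        shifts_b = random_coil_shifts(seq_b, ref, nuclei=("CA",))
        delta = (shifts_b.data["shift_ppm"] - shifts_a.data["shift_ppm"]).abs()
        changed = set(shifts_b.data.loc[delta > 0, "residue_index"])
        assert changed == {4, 5, 7, 8}  # within +/-2 of the flipped residue 6


def _table(records, **kw):
    return ShiftTable(pd.DataFrame(
        records, columns=["residue_index", "residue_type", "nucleus",
                          "shift_ppm"]), **kw)


class TestSecondaryShifts:
    def test_round_trip_identity_zero(self, variant, coil_reference):
        coil = random_coil_shifts(variant, coil_reference)
        deltas = secondary_shifts(coil, coil)
        np.testing.assert_allclose(deltas["delta_ppm"], 0.0)

    def test_constant_offset(self, variant, coil_reference):
        coil = random_coil_shifts(variant, coil_reference, nuclei=("CA",))
        shifted = coil.data.copy()
        shifted["shift_ppm"] += 0.5
        deltas = secondary_shifts(ShiftTable(shifted), coil)
        np.testing.assert_allclose(deltas["delta_ppm"], 0.5)

    def test_zero_overlap_rejected(self, coil_reference):
        a = _table([(1, "A", "CA", 52.0)])
        b = _table([(9, "A", "CA", 52.0)])
        with pytest.raises(ShiftTableError):
            secondary_shifts(a, b)

    def test_helix_region_offset_confined(self, variant, coil_reference):
        coil = random_coil_shifts(variant, coil_reference, nuclei=("CA",))
        data = coil.data.copy()
        helix = (data["residue_index"] >= 65) & (data["residue_index"] <= 79)
        data.loc[helix, "shift_ppm"] += 2.6  # full-helix Calpha offset
        deltas = secondary_shifts(ShiftTable(data), coil)
        positive = deltas.loc[deltas["delta_ppm"] > 1.0, "residue_index"]
        assert set(positive) == set(range(65, 80))


class TestUreaDifferenceShifts:
    def test_identical_tables_zero(self, variant, coil_reference):
        table = random_coil_shifts(variant, coil_reference)
        diff = urea_difference_shifts(table, table)
        np.testing.assert_allclose(diff["delta_ppm"], 0.0)
        assert not diff["atypical"].any()

    def test_antisymmetry(self, variant, coil_reference, rng):
        native = random_coil_shifts(variant, coil_reference)
        perturbed = native.data.copy()
        perturbed["shift_ppm"] += rng.normal(0, 0.2, len(perturbed))
        urea = ShiftTable(perturbed)
        forward = urea_difference_shifts(native, urea)["delta_ppm"]
        backward = urea_difference_shifts(urea, native)["delta_ppm"]
        np.testing.assert_allclose(forward, -backward, atol=1e-12)

    def test_large_ca_difference_flagged(self):
        a = _table([(1, "A", "CA", 54.0), (2, "A", "CB", 22.0)])
        b = _table([(1, "A", "CA", 52.5), (2, "A", "CB", 19.0)])
        diff = urea_difference_shifts(a, b)
        flagged = diff.loc[diff["atypical"], "nucleus"]
        assert list(flagged) == ["CA"]  # CB excursions are not flagged


def _delta_frame(fraction, start=1, end=40):
    rows = []
    for residue in range(start, end + 1):
        rows.append((residue, "E", "CA", fraction * FULL_HELIX_SHIFT["CA"]))
        rows.append((residue, "E", "CB", fraction * FULL_HELIX_SHIFT["CB"]))
    return pd.DataFrame(rows, columns=["residue_index", "residue_type",
                                       "nucleus", "delta_ppm"])


class TestSspProfile:
    def test_zero_deltas_give_zero_scores(self):
        profile = ssp_profile(_delta_frame(0.0))
        np.testing.assert_allclose(profile.scores, 0.0)

    @pytest.mark.parametrize("fraction", [1.0, 0.15])
    def test_uniform_fraction_recovered_pointwise(self, fraction):
        profile = ssp_profile(_delta_frame(fraction))
        np.testing.assert_allclose(profile.scores, fraction, atol=1e-12)

    def test_scores_clamped(self):
        profile = ssp_profile(_delta_frame(2.5), outlier_factor=10.0)
        assert profile.scores.max() <= 1.0
        assert profile.scores.min() >= -1.0

    def test_sheet_fraction_is_negative(self):
        rows = [(r, "E", "CA", -1.4 * 0.5) for r in range(1, 21)]
        rows += [(r, "E", "CB", 2.2 * 0.5) for r in range(1, 21)]
        frame = pd.DataFrame(rows, columns=["residue_index", "residue_type",
                                            "nucleus", "delta_ppm"])
        profile = ssp_profile(frame)
        np.testing.assert_allclose(profile.scores, -0.5, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ssp_profile(_delta_frame(0.1), window=4)

    def test_translation_invariance(self):
        shifted = _delta_frame(0.3, start=101, end=140)
        reference = _delta_frame(0.3, start=1, end=40)
        np.testing.assert_allclose(ssp_profile(shifted).scores,
                                   ssp_profile(reference).scores)


class TestRegionHelicity:
    def test_constant_score_mean(self):
        residues = np.arange(60, 85)
        profile = SSPProfile(residues, np.full(len(residues), 0.163),
                             window=5, nuclei=("CA", "CB"))
        helicity = region_helicity(profile, HelixRegions({"IV": (65, 79)}))
        assert helicity["IV"] == pytest.approx(16.3)

    def test_zero_scores_zero_percent(self):
        residues = np.arange(1, 88)
        profile = SSPProfile(residues, np.zeros(87), window=5, nuclei=("CA",))
        helicity = region_helicity(profile)
        assert all(v == 0.0 for v in helicity.values())

    def test_empty_region_rejected(self):
        profile = SSPProfile(np.arange(1, 11), np.zeros(10), window=5,
                             nuclei=("CA",))
        with pytest.raises(ShiftTableError):
            region_helicity(profile, HelixRegions({"IV": (65, 79)}))
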