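import numpy as np
import pandas as pd
import pytest

from orgcontact import contact3d, synthetic
from orgcontact.volume_io import LabelVolume

from oracles import bfs_band_counts, shell_mask_bruteforce


class TestExtractShell:
    def test_cube_shell_count(self, cube_volume):
        shell = contact3d.extract_shell(cube_volume)
        assert int((shell.data > 0).sum()) == 10**3 - 8**3  # 488

    def test_single_voxel_is_its_own_shell(self):
        data = np.zeros((5, 5, 5), np.uint8)
        data[2, 2, 2] = 1
        shell = contact3d.extract_shell(LabelVolume(data, 8))
        np.testing.assert_array_equal(shell.data, data)

    def test_one_voxel_plate_entirely_shell(self):
        data = np.zeros((7, 9, 9), np.uint8)
        data[3, 1:8, 1:8] = 1
        shell = contact3d.extract_shell(LabelVolume(data, 8))
        np.testing.assert_array_equal(shell.data, data)

    def test_shell_subset_and_erosion_complement(self, ball_scene):
        mito, *_ = ball_scene
        shell = contact3d.extract_shell(mito)
        assert np.all(mito.data[shell.data > 0] == shell.data[shell.data > 0])
        core = (mito.data > 0) & ~(shell.data > 0)
        reshell = contact3d.extract_shell(
            LabelVolume(core.astype(np.uint8), mito.voxel_size_nm)
        )
        assert np.all((reshell.data > 0) <= (core > 0))

    def test_boundary_touching_face_is_shell(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[0:4, 1:5, 1:5] = 1  # touches z = 0
        shell = contact3d.extract_shell(LabelVolume(data, 8))
        assert np.all(shell.data[0, 1:5, 1:5] == 1)

    def test_matches_bruteforce_neighbour_scan(self, ball_scene):
        mito, *_ = ball_scene
        shell = contact3d.extract_shell(mito)
        np.testing.assert_array_equal(shell.data > 0, shell_mask_bruteforce(mito.data))

    def test_planewise_mode_thin_z_plate(self):
        # a 3-voxel-thick plate normal to z: plane-wise erosion never removes
        # along z, so the plate interior survives in-plane erosion only
        data = np.zeros((9, 12, 12), np.uint8)
        data[3:6, 2:10, 2:10] = 1
        shell = contact3d.extract_shell(LabelVolume(data, 8), mode="planewise_xy")
        assert shell.data[4, 5, 5] == 0  # in-plane interior is not shell
        vol3d = contact3d.extract_shell(LabelVolume(data, 8), mode="volume3d")
        assert vol3d.data[4, 5, 5] == 0 and vol3d.data[3, 5, 5] == 1


class TestBandContact:
    def test_partner_beyond_inner_band(self):
        """ER at city-block gap 4 voxels (first reached at step 5 > 3):
        zero 0-24 nm contact, positive 25-56 nm contact."""
        spec = synthetic.SceneSpec(
            shape=(36, 36, 36),
            mitochondria=[synthetic.MitoSpec("ball", center=(18.0, 18.0, 18.0), radius=6.0)],
            er_structures=[synthetic.ERSpec("wrapped_shell", attached_to=1, gap_voxels=4)],
        )
        mito, er, *_ = synthetic.generate_scene(spec)
        rec = contact3d.band_contact(mito, er)
        assert rec["fraction_0_24nm"].iloc[0] == 0.0
        assert rec["fraction_25_56nm"].iloc[0] > 0.0

    def test_no_partner_all_zero(self, cube_volume):
        empty = LabelVolume(np.zeros_like(cube_volume.data), 8)
        rec = contact3d.band_contact(cube_volume, empty)
        assert rec["fraction_0_24nm"].iloc[0] == 0.0
        assert rec["fraction_25_56nm"].iloc[0] == 0.0

    def test_full_face_sheet_matches_bruteforce(self):
        """Cube with a coplanar full-face ER sheet at gap 1: 0-24 nm contact
        equals the brute-force geodesic city-block count."""
        data = np.zeros((20, 20, 20), np.uint8)
        data[5:13, 5:13, 5:13] = 1
        er = np.zeros_like(data)
        er[5:13, 5:13, 14] = 1  # gap 1 voxel from the x = 12 face
        mito = LabelVolume(data, 8)
        partner = LabelVolume(er, 8)
        rec = contact3d.band_contact(mito, partner, bands_nm=[(0, 24)])
        oracle = bfs_band_counts(data, er > 0, [(0, 3)])
        assert rec["contact_voxels_0_24nm"].iloc[0] == oracle[1][0]
        assert rec["contact_voxels_0_24nm"].iloc[0] > 0

    def test_shape_mismatch_rejected(self, cube_volume):
        other = LabelVolume(np.zeros((5, 5, 5), np.uint8), 8)
        with pytest.raises(ValueError, match="shape mismatch"):
            contact3d.band_contact(cube_volume, other)

    def test_non_multiple_band_floored_with_warning(self, cube_volume):
        er = LabelVolume(np.zeros_like(cube_volume.data), 8)
        with pytest.warns(UserWarning, match="flooring"):
            contact3d.band_contact(cube_volume, er, bands_nm=[(0, 20)])

    def test_band_exclusivity_and_monotone_cumulative(self, ball_scene):
        mito, er, *_ = ball_scene
        one = contact3d.band_contact(mito, er, bands_nm=[(0, 56)])
        two = contact3d.band_contact(mito, er, bands_nm=[(0, 24), (25, 56)])
        total = two["contact_voxels_0_24nm"] + two["contact_voxels_25_56nm"]
        assert (total == one["contact_voxels_0_56nm"]).all()
        assert (two["fraction_0_24nm"] <= one["fraction_0_56nm"] + 1e-12).all()

    def test_overlapping_partner_counts_at_distance_zero(self):
        data = np.zeros((12, 12, 12), np.uint8)
        data[3:9, 3:9, 3:9] = 1
        er = np.zeros_like(data)
        er[3:9, 3:9, 8] = 1  # ER drawn on the mito face itself
        rec = contact3d.band_contact(
            LabelVolume(data, 8), LabelVolume(er, 8), bands_nm=[(0, 24)]
        )
        assert rec["contact_voxels_0_24nm"].iloc[0] >= 36

    def test_two_mitochondria_independent_accounting(self):
        spec = synthetic.SceneSpec(
            shape=(40, 40, 40),
            mitochondria=[
                synthetic.MitoSpec("ball", center=(12.0, 20.0, 20.0), radius=5.0),
                synthetic.MitoSpec("ball", center=(29.0, 20.0, 20.0), radius=5.0),
            ],
            er_structures=[
                synthetic.ERSpec("wrapped_shell", attached_to=1, gap_voxels=1)
            ],
        )
        mito, er, *_ = synthetic.generate_scene(spec)
        rec = contact3d.band_contact(mito, er).set_index("mito_id")
        assert rec.loc[1, "fraction_0_24nm"] > 0.5
        assert rec.loc[2, "fraction_0_24nm"] == 0.0


class TestDistanceProfile:
    def test_cumulative_matches_band_totals(self, ball_scene):
        mito, er, *_ = ball_scene
        prof = contact3d.distance_profile(mito, er, max_nm=56)
        bands = contact3d.band_contact(mito, er, bands_nm=[(0, 24), (25, 56)])
        total_24 = bands["contact_voxels_0_24nm"].sum()
        total_56 = total_24 + bands["contact_voxels_25_56nm"].sum()
        assert prof.cumulative[2] == total_24  # step 3 = 24 nm
        assert prof.cumulative[6] == total_56  # step 7 = 56 nm

    def test_adjacent_coextensive_plate_all_at_step_one(self):
        # ER plate directly adjacent to a coextensive 1-voxel mito plate:
        # every shell voxel is at distance 1, nothing new afterwards
        data = np.zeros((12, 12, 12), np.uint8)
        data[3:9, 3:9, 5] = 1
        er = np.zeros_like(data)
        er[3:9, 3:9, 6] = 1
        prof = contact3d.distance_profile(LabelVolume(data, 8), LabelVolume(er, 8), 56)
        assert prof.new_counts[0] == 36
        assert prof.new_counts[1:].sum() == 0

    def test_wrapped_shell_gap6_modal_step_seven(self):
        """Gap 6 voxels -> first contact at step 7, the 49-56 nm bin."""
        spec = synthetic.SceneSpec(
            shape=(44, 44, 44),
            mitochondria=[synthetic.MitoSpec("ball", center=(22.0, 22.0, 22.0), radius=7.0)],
            er_structures=[synthetic.ERSpec("wrapped_shell", attached_to=1, gap_voxels=6)],
        )
        mito, er, *_ = synthetic.generate_scene(spec)
        prof = contact3d.distance_profile(mito, er, max_nm=56)
        assert prof.modal_step() == 7
        assert prof.new_counts[:6].sum() == 0

    def test_counts_nonnegative_cumulative_monotone(self, ball_scene):
        mito, er, *_ = ball_scene
        prof = contact3d.distance_profile(mito, er, max_nm=56)
        assert (prof.new_counts >= 0).all()
        assert (np.diff(prof.cumulative) >= 0).all()


class TestSheetContact:
    def test_full_er_mask_identity(self, ball_scene):
        mito, er, *_ = ball_scene
        direct = contact3d.band_contact(mito, er, bands_nm=[(0, 56)])
        sheet = contact3d.sheet_contact(mito, er, band_nm=(0, 56))
        pd.testing.assert_frame_equal(direct, sheet)

    def test_empty_sheet_mask_zero(self, ball_scene):
        mito, er, *_ = ball_scene
        empty = LabelVolume(np.zeros_like(er.data), er.voxel_size_nm)
        rec = contact3d.sheet_contact(mito, empty)
        assert rec["fraction_0_56nm"].iloc[0] == 0.0

    def test_sheet_mask_subtraction_matches_oracle(self, ball_scene):
        """Sheets = ER minus an arbitrary 'tubule' sub-mask: fractions match
        the brute-force band count on the reduced mask."""
        mito, er, *_ = ball_scene
        sheets = er.data.copy()
        sheets[:, :, :24] = 0  # declare one hemisphere tubules
        sheets_vol = LabelVolume(sheets, er.voxel_size_nm)
        rec = contact3d.sheet_contact(mito, sheets_vol)
        oracle = bfs_band_counts(mito.data, sheets > 0, [(0, 7)])
        assert rec.set_index("mito_id")["contact_voxels_0_56nm"].to_dict() == {
            k: v[0] for k, v in oracle.items()
        }


class TestPrevalence:
    def _records(self, counts):
        return pd.DataFrame(
            {
                "mito_id": range(1, len(counts) + 1),
                "shell_voxels": [100] * len(counts),
                "contact_voxels_0_24nm": counts,
                "fraction_0_24nm": [c / 100 for c in counts],
            }
        )

    def test_half_touched(self):
        assert contact3d.contact_prevalence(self._records([0, 0, 5, 9])) == 0.5

    def test_threshold_above_all(self):
        assert contact3d.contact_prevalence(self._records([1, 2]), min_voxels=10) == 0.0

    def test_zero_threshold_all(self):
        assert contact3d.contact_prevalence(self._records([0, 0]), min_voxels=0) == 1.0

    def test_fraction_threshold(self):
        rec = self._records([5, 60])
        assert contact3d.contact_prevalence(rec, min_fraction=0.5) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contact3d.contact_prevalence(self._records([]))
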