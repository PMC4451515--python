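"""Hydrogen bonds, native fraction, HB maps, Rg and RMSD."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import felscape as fs
from felscape.errors import ConfigError


def _two_residue_frame(distance, with_h=None):
    """Donor on residue 1, acceptor on residue 5 at the given separation.

    ``with_h``: optional D-H...A angle (degrees) realised by a hydrogen
    placed 0.1 nm from the donor.
    """
    names = ["BB", "DON", "BB", "ACC"]
    resids = [1, 1, 5, 5]
    coords = [
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0],
        [distance, 1.0, 0.0],
        [distance, 0.0, 0.0],
    ]
    if with_h is not None:
        # hydrogen between donor and acceptor; angle(D-H...A) as requested
        ang = np.radians(180.0 - with_h)
        coords.append([0.1 * np.cos(ang), 0.1 * np.sin(ang), 0.0])
        names.append("H1'")
        resids.append(1)
    frame = fs.StructureFrame(
        atom_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        coords=np.array(coords),
    )
    if with_h is not None:
        frame.elements[-1] = "H"
    return frame


class TestDetectHbonds:
    def test_pair_inside_default_criterion(self):
        hbs = fs.detect_hbonds(_two_residue_frame(0.29))
        assert [(h.donor_res, h.acceptor_res) for h in hbs] == [(1, 5)]

    def test_pair_outside_cutoff(self):
        assert fs.detect_hbonds(_two_residue_frame(0.50)) == []

    def test_angle_filter_applies_only_with_hydrogens(self):
        near_linear = _two_residue_frame(0.29, with_h=170.0)
        bent = _two_residue_frame(0.29, with_h=90.0)
        assert len(fs.detect_hbonds(near_linear)) == 1
        assert fs.detect_hbonds(bent) == []

    def test_toy_certain_pairs_detected_exactly(self):
        spec = fs.ToyEnsembleSpec(
            n_nucleotides=12, n_frames=5,
            hb_probabilities={(1, 7): 1.0, (3, 9): 1.0}, seed=8,
        )
        frames, _ = fs.generate_toy_ensemble(spec)
        for frame in frames:
            found = {h.pair for h in fs.detect_hbonds(frame)}
            assert found == {(1, 7), (3, 9)}

    def test_frame_without_donors_warns_and_returns_empty(self):
        frame = fs.StructureFrame(
            atom_names=np.array(["BB"], dtype=object),
            residue_ids=np.array([1]),
            coords=np.zeros((1, 3)),
        )
        with pytest.warns(UserWarning):
            assert fs.detect_hbonds(frame) == []


class TestNativeFraction:
    @pytest.mark.parametrize("n_formed,expected", [(10, 1.0), (0, 0.0), (9, 0.9)])
    def test_fraction_counts_formed_native_bonds(self, n_formed, expected):
        pairs = {(i, i + 10): (1.0 if i <= n_formed else 0.0)
                 for i in range(1, 11)}
        spec = fs.ToyEnsembleSpec(
            n_nucleotides=20, n_frames=3, hb_probabilities=pairs, seed=1
        )
        frames, _ = fs.generate_toy_ensemble(spec)
        for frame in frames:
            assert fs.native_hb_fraction(frame, spec.native_hb_list) == expected

    def test_empty_native_list_is_config_error(self):
        with pytest.raises(ConfigError):
            fs.native_hb_fraction(_two_residue_frame(0.29), [])


class TestHBMap:
    def test_single_frame_entries_are_binary(self):
        spec = fs.ToyEnsembleSpec(
            n_nucleotides=10, n_frames=1,
            hb_probabilities={(2, 7): 1.0, (3, 8): 0.0}, seed=2,
        )
        frames, _ = fs.generate_toy_ensemble(spec)
        hbmap = fs.hb_probability_map(frames)
        values = np.unique(hbmap.probabilities)
        assert set(values).issubset({0.0, 1.0})
        assert hbmap.entry(2, 7) == 1.0
        assert hbmap.entry(7, 2) == 1.0  # symmetric
        assert hbmap.entry(3, 8) == 0.0

    def test_pair_in_one_of_two_frames(self):
        on = fs.ToyEnsembleSpec(
            n_nucleotides=10, n_frames=1, hb_probabilities={(2, 7): 1.0}, seed=3
        )
        off = fs.ToyEnsembleSpec(
            n_nucleotides=10, n_frames=1, hb_probabilities={(2, 7): 0.0}, seed=3
        )
        frames = fs.generate_toy_ensemble(on)[0] + fs.generate_toy_ensemble(off)[0]
        assert fs.hb_probability_map(frames).entry(2, 7) == 0.5

    def test_bernoulli_probability_recovered(self):
        spec = fs.ToyEnsembleSpec(
            n_nucleotides=10, n_frames=1200,
            hb_probabilities={(2, 7): 0.3}, seed=4,
        )
        frames, _ = fs.generate_toy_ensemble(spec)
        hbmap = fs.hb_probability_map(frames)
        # 3-sigma binomial interval at n = 1200
        assert abs(hbmap.entry(2, 7) - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 1200)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        frame = fs.StructureFrame(
            atom_names=np.array(["BB", "BB"], dtype=object),
            residue_ids=np.array([1, 2]),
            coords=np.array([[0.0, 0, 0], [1.2, 0, 0]]),
        )
        assert fs.radius_of_gyration(frame) == pytest.approx(0.6)

    def test_unit_square_corners(self):
        frame = fs.StructureFrame(
            atom_names=np.array(["BB"] * 4, dtype=object),
            residue_ids=np.arange(1, 5),
            coords=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float),
        )
        assert fs.radius_of_gyration(frame) == pytest.approx(np.sqrt(2) / 2)

    def test_matches_direct_sum_oracle(self, rng):
        coords = rng.normal(size=(50, 3))
        frame = fs.StructureFrame(
            atom_names=np.array(["BB"] * 50, dtype=object),
            residue_ids=np.arange(1, 51),
            coords=coords,
        )
        com = coords.mean(axis=0)
        brute = np.sqrt(sum(np.sum((r - com) ** 2) for r in coords) / 50)
        assert abs(fs.radius_of_gyration(frame) - brute) < 1e-12

    @given(seed=st.integers(0, 2**31 - 1))
    def test_rigid_invariance_and_linear_scaling(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(20, 3))
        frame = fs.StructureFrame(
            atom_names=np.array(["BB"] * 20, dtype=object),
            residue_ids=np.arange(1, 21),
            coords=coords,
        )
        rot = Rotation.random(random_state=seed % 2**32).as_matrix()
        moved = frame.with_coords(coords @ rot.T + rng.normal(size=3))
        scaled = frame.with_coords(coords * 2.5)
        rg = fs.radius_of_gyration(frame)
        assert fs.radius_of_gyration(moved) == pytest.approx(rg, rel=1e-10)
        assert fs.radius_of_gyration(scaled) == pytest.approx(2.5 * rg, rel=1e-10)

    def test_single_atom_is_zero_not_error(self):
        frame = fs.StructureFrame(
            atom_names=np.array(["BB"], dtype=object),
            residue_ids=np.array([1]),
            coords=np.zeros((1, 3)),
        )
        assert fs.radius_of_gyration(frame) == 0.0


class TestRMSD:
    def test_identical_frames_zero(self, rng):
        a = rng.normal(size=(30, 3))
        assert fs.rmsd(a, a, superpose=False) == 0.0
        assert fs.rmsd(a, a, superpose=True) < 1e-10

    def test_rigid_transform_invisible_to_superposition(self, rng):
        a = rng.normal(size=(30, 3))
        rot = Rotation.random(random_state=1).as_matrix()
        b = a @ rot.T + np.array([3.0, -2.0, 1.0])
        assert fs.rmsd(a, b, superpose=True) < 1e-10
        assert fs.rmsd(a, b, superpose=False) > 1.0

    def test_single_displacement_closed_form(self, rng):
        a = rng.normal(size=(25, 3))
        b = a.copy()
        b[7] += np.array([0.3, 0.0, 0.0])
        assert fs.rmsd(a, b, superpose=False) == pytest.approx(0.3 / np.sqrt(25))

    @given(seed=st.integers(0, 2**31 - 1))
    def test_symmetry_and_superposition_never_hurts(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 15, 3))
        assert fs.rmsd(a, b) == pytest.approx(fs.rmsd(b, a), rel=1e-8, abs=1e-10)
        assert fs.rmsd(a, b, superpose=True) <= fs.rmsd(a, b, superpose=False) + 1e-12

    def test_atom_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fs.rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestEvaluateCVs:
    def test_hb_counts_and_rg_columns(self):
        spec = fs.ToyEnsembleSpec(
            n_nucleotides=12, n_frames=4,
            hb_probabilities={(1, 7): 1.0, (2, 8): 1.0}, seed=5,
        )
        frames, _ = fs.generate_toy_ensemble(spec)
        cfg = fs.AnalysisConfig(
            native_hb_list=[(1, 7, "DON", "ACC"), (2, 8, "DON", "ACC")],
            cv_definitions=[
                {"name": "nhb", "hb_subset": [(1, 7), (2, 8)]},
                {"name": "rg", "rg": True},
            ],
        )
        series = fs.evaluate_cvs(frames, cfg)
        assert series.names == ["nhb", "rg"]
        np.testing.assert_array_equal(series["nhb"], 2.0)
        assert (series["rg"] > 0).all()
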