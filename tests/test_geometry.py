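"""Geometric observables: oracles, guards and rigid-motion invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from kvgate.errors import SelectionError, UndefinedTorsionError
from kvgate.geometry import (
    DistanceSeries,
    ResidueSelector,
    apply_rigid_transform,
    classify_salt_bridge,
    count_waters_within,
    dihedral,
    distance,
    histogram_series,
    kink_angle,
    min_NO_distance,
    min_NO_series,
    residue_pair_distance,
    salt_bridge_pair,
    sidechain_chi,
)

from conftest import make_traj


def brute_force_dihedral(p1, p2, p3, p4):
    """Independent oracle: project the outer bonds onto the plane normal to
    the central bond and take the signed planar angle."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b2 = p3 - p2
    b2u = b2 / np.linalg.norm(b2)
    v = (p1 - p2) - np.dot(p1 - p2, b2u) * b2u
    w = (p4 - p3) - np.dot(p4 - p3, b2u) * b2u
    cos = np.dot(v, w) / (np.linalg.norm(v) * np.linalg.norm(w))
    sign = np.sign(np.dot(np.cross(v, w), b2u))
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return sign * ang if sign != 0 else ang


def brute_force_min_no(npos, opos):
    best = np.inf
    for a in npos:
        for b in opos:
            best = min(best, float(np.linalg.norm(np.asarray(a) - np.asarray(b))))
    return best


class TestDistance:
    def test_elementary_values(self):
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
        assert distance((1.5, -2, 7), (1.5, -2, 7)) == 0.0

    def test_isometry_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        R = Rotation.random(random_state=1).as_matrix()
        t = rng.normal(size=3)
        assert distance(R @ a + t, R @ b + t) == pytest.approx(distance(a, b), abs=1e-12)


class TestResiduePairDistance:
    def test_single_frame_exact_distance(self):
        traj = make_traj([
            ("A", "ILE", 308, "CA", (0.0, 0.0, 0.0)),
            ("C", "ILE", 308, "CA", (7.7, 0.0, 0.0)),
        ])
        s = residue_pair_distance(traj, ResidueSelector("A", 308),
                                  ResidueSelector("C", 308), "CA")
        assert s.values.tolist() == [7.7]
        assert s.sd == 0.0

    def test_expected_name_guard(self):
        traj = make_traj([("A", "SER", 308, "CA", (0.0, 0.0, 0.0)),
                          ("C", "ILE", 308, "CA", (7.7, 0.0, 0.0))])
        with pytest.raises(SelectionError, match="SER"):
            residue_pair_distance(traj, ResidueSelector("A", 308, "ILE"),
                                  ResidueSelector("C", 308, "ILE"), "CA")

    def test_missing_atom_names_residue_and_atom(self, wt_small):
        with pytest.raises(SelectionError, match="CZ"):
            residue_pair_distance(wt_small, ResidueSelector("A", 308),
                                  ResidueSelector("C", 308), "CZ")

    def test_mean_sd_recomputable_from_values(self, wt_small):
        s = residue_pair_distance(wt_small, ResidueSelector("A", 308, "ILE"),
                                  ResidueSelector("C", 308, "ILE"), "CA")
        assert s.mean == pytest.approx(float(np.mean(s.values)), abs=0)
        assert s.sd == pytest.approx(float(np.std(s.values)), abs=0)

    def test_recovers_generator_target(self, wt_traj):
        s = residue_pair_distance(wt_traj, ResidueSelector("A", 308, "ILE"),
                                  ResidueSelector("C", 308, "ILE"), "CA")
        assert abs(s.mean - 14.1) < 3 * 0.5 / np.sqrt(wt_traj.n_frames)


class TestSaltBridge:
    def _arg_asp(self, npos, opos):
        recs = [("A", "ARG", 297, n, p) for n, p in zip(("NE", "NH1", "NH2"), npos)]
        recs += [("B", "ASP", 288, o, p) for o, p in zip(("OD1", "OD2"), opos)]
        return make_traj(recs)

    def test_constructed_minimum(self):
        traj = self._arg_asp(
            npos=[(0, 0, 5), (0, 0, 2.6), (4, 4, 4)],
            opos=[(0, 0, 0), (9, 9, 9)],
        )
        d = min_NO_distance(traj.frame(0), ResidueSelector("A", 297),
                            ResidueSelector("B", 288))
        assert d == pytest.approx(2.6)

    def test_equal_pairs_tie_is_harmless(self):
        traj = self._arg_asp(npos=[(3, 0, 0)] * 3, opos=[(0, 0, 0)] * 2)
        assert min_NO_distance(traj.frame(0), ResidueSelector("A", 297),
                               ResidueSelector("B", 288)) == pytest.approx(3.0)

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            npos = rng.uniform(-5, 5, (3, 3))
            opos = rng.uniform(-5, 5, (2, 3))
            traj = self._arg_asp(npos=list(map(tuple, npos)), opos=list(map(tuple, opos)))
            got = min_NO_distance(traj.frame(0), ResidueSelector("A", 297),
                                  ResidueSelector("B", 288))
            assert got == pytest.approx(brute_force_min_no(npos, opos), abs=1e-12)

    def test_missing_sidechain_atom_is_selection_error(self):
        traj = make_traj([("A", "ARG", 297, "NE", (0, 0, 0)),
                          ("B", "ASP", 288, "OD1", (3, 0, 0)),
                          ("B", "ASP", 288, "OD2", (4, 0, 0))])
        with pytest.raises(SelectionError, match="NH1"):
            min_NO_series(traj, ResidueSelector("A", 297), ResidueSelector("B", 288))

    @pytest.mark.parametrize("mean,expected", [(2.6, True), (3.2, False), (3.0, False)])
    def test_classification_is_strict_at_the_cutoff(self, mean, expected):
        series = DistanceSeries("x", np.full(10, mean))
        assert classify_salt_bridge(series) is expected

    def test_occupancy_fraction_reported(self, mutant_traj):
        pair = salt_bridge_pair(mutant_traj, ResidueSelector("C", 296, "ARG"),
                                ResidueSelector("D", 271, "ASP"))
        assert pair.formed
        assert 0.9 < pair.occupancy <= 1.0


class TestDihedral:
    def test_planar_anti_is_plus_180(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_planar_syn_is_zero(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_right_angle_sign_fixed_by_convention(self):
        # agrees with mdtraj/MDAnalysis on this configuration
        val = dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1))
        assert val == pytest.approx(-90.0)
        assert val == pytest.approx(
            brute_force_dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)))

    def test_collinear_bonds_are_undefined(self):
        with pytest.raises(UndefinedTorsionError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-5, 5).filter(lambda x: abs(x) > 1e-3),
                    min_size=12, max_size=12))
    def test_chain_reversal_preserves_the_torsion(self, flat):
        # a torsion angle reads the same from either chain end (IUPAC)
        p = np.array(flat).reshape(4, 3)
        try:
            fwd = dihedral(*p)
            rev = dihedral(*p[::-1])
        except UndefinedTorsionError:
            return
        if abs(abs(fwd) - 180.0) < 1e-6:
            assert abs(rev) == pytest.approx(abs(fwd), abs=1e-6)
        else:
            assert rev == pytest.approx(fwd, abs=1e-6)


class TestSidechainChi:
    def _residue(self, cg):
        return make_traj([
            ("A", "ILE", 308, "N", (1.0, 0.0, 0.0)),
            ("A", "ILE", 308, "CA", (0.0, 0.0, 0.0)),
            ("A", "ILE", 308, "CB", (0.0, 1.5, 0.0)),
            ("A", "ILE", 308, "CG1", cg),
        ])

    def test_exact_trans_geometry_gives_180(self):
        traj = self._residue((-1.0, 2.5, 0.0))
        chi = sidechain_chi(traj, ResidueSelector("A", 308), 1)
        assert chi.values[0] == pytest.approx(180.0)

    def test_matches_dihedral_composition(self, wt_small):
        chi = sidechain_chi(wt_small, ResidueSelector("A", 308, "ILE"), 1)
        f = wt_small.frame(3)
        expected = dihedral(f.atom_position("A", 308, "N"),
                            f.atom_position("A", 308, "CA"),
                            f.atom_position("A", 308, "CB"),
                            f.atom_position("A", 308, "CG1"))
        assert chi.values[3] == pytest.approx(expected, abs=1e-12)

    def test_unsupported_combination_names_residue_type(self, wt_small):
        with pytest.raises(SelectionError, match="SER"):
            sidechain_chi(wt_small, ResidueSelector("A", 269, "SER"), 2)

    def test_values_wrapped_to_half_open_interval(self, mutant_small):
        chi = sidechain_chi(mutant_small, ResidueSelector("A", 269, "TYR"), 1)
        assert np.all(chi.values > -180.0)
        assert np.all(chi.values <= 180.0)

    def test_deletion_mutant_shifts_tyr_chi1_mode(self, wt_small, mutant_small):
        wt_chi = sidechain_chi(wt_small, ResidueSelector("A", 270, "TYR"), 1)
        mut_chi = sidechain_chi(mutant_small, ResidueSelector("A", 269, "TYR"), 1)
        assert abs(wt_chi.circular_mean - (-65.0)) < 10.0
        assert abs(abs(mut_chi.circular_mean) - 180.0) < 10.0


class TestKinkAngle:
    def test_collinear_is_180(self):
        traj = make_traj([("A", "TRP", 294, "N", (0.0, 0.0, 0.0)),
                          ("A", "PRO", 314, "N", (0.0, 0.0, 5.0)),
                          ("A", "VAL", 325, "N", (0.0, 0.0, 10.0))])
        assert kink_angle(traj.frame(0), "A") == pytest.approx(180.0)

    def test_right_angle(self):
        traj = make_traj([("A", "TRP", 294, "N", (0.0, 0.0, 0.0)),
                          ("A", "PRO", 314, "N", (0.0, 0.0, 5.0)),
                          ("A", "VAL", 325, "N", (5.0, 0.0, 5.0))])
        assert kink_angle(traj.frame(0), "A") == pytest.approx(90.0)

    def test_matches_arccos_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w, p, v = rng.uniform(-10, 10, (3, 3))
            traj = make_traj([("A", "TRP", 294, "N", tuple(w)),
                              ("A", "PRO", 314, "N", tuple(p)),
                              ("A", "VAL", 325, "N", tuple(v))])
            v1, v2 = w - p, v - p
            cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            expected = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            assert kink_angle(traj.frame(0), "A") == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_undefined(self):
        traj = make_traj([("A", "TRP", 294, "N", (0.0, 0.0, 5.0)),
                          ("A", "PRO", 314, "N", (0.0, 0.0, 5.0)),
                          ("A", "VAL", 325, "N", (5.0, 0.0, 5.0))])
        with pytest.raises(UndefinedTorsionError):
            kink_angle(traj.frame(0), "A")

    def test_mutant_numbering_resolved_through_map(self, mutant_small):
        # mutant carries W293/P313/V324; the WT-numbered call must find them
        val = kink_angle(mutant_small.frame(0), "B")
        assert 0.0 <= val <= 180.0


class TestWaterCount:
    def test_no_waters_gives_zero(self):
        traj = make_traj([("A", "ILE", 308, "CA", (0.0, 0.0, 0.0))])
        assert count_waters_within(traj.frame(0), ResidueSelector("A", 308)) == 0

    def test_counts_only_waters_inside_cutoff(self):
        recs = [("A", "ILE", 308, "CA", (0.0, 0.0, 0.0))]
        recs += [("S", "HOH", i + 1, "O", (6.0, 0.0, float(i))) for i in range(5)]
        recs += [("S", "HOH", i + 6, "O", (12.0, 0.0, float(i))) for i in range(3)]
        traj = make_traj(recs)
        assert count_waters_within(traj.frame(0), ResidueSelector("A", 308), 8.0) == 5

    def test_generator_shell_contract(self, wt_small):
        r = ResidueSelector("A", 308, "ILE")
        for i in (0, 57, 119):
            assert count_waters_within(wt_small.frame(i), r, 8.0) == 50


class TestHistogram:
    def test_constant_series_single_occupied_bin(self):
        centers, freqs = histogram_series(np.full(64, 3.7), 0.5)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(freqs) == 1

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=200),
           st.floats(0.01, 5.0))
    def test_frequencies_sum_to_one(self, values, width):
        _, freqs = histogram_series(values, width)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_circular_binning_does_not_split_the_wrap(self):
        from scipy.stats import circmean

        rng = np.random.default_rng(9)
        values = np.mod(180.0 + 5.0 * rng.standard_normal(2000) + 180.0, 360.0) - 180.0
        centers, freqs = histogram_series(values, 5.0, circular=True)
        # oracle: unwrap by hand onto a split-free shifted domain, bin linearly
        mu = circmean(values, low=-180.0, high=180.0)
        manual = np.mod(values - mu + 180.0, 360.0) - 180.0
        o_centers, o_freqs = histogram_series(manual, 5.0, circular=False)
        np.testing.assert_allclose(freqs, o_freqs, atol=1e-12)
        wrapped_back = np.mod(o_centers + mu + 180.0, 360.0) - 180.0
        np.testing.assert_allclose(np.sort(centers), np.sort(wrapped_back), atol=1e-9)
        # the mode bin holds the central mass rather than half of it
        assert freqs.max() > 0.3


class TestRigidMotionInvariance:
    def test_observables_invariant_under_rotation_translation(self, wt_small):
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([13.0, -7.0, 42.0])
        moved = apply_rigid_transform(wt_small, R, t)
        a, b = ResidueSelector("A", 308, "ILE"), ResidueSelector("C", 308, "ILE")
        d0 = residue_pair_distance(wt_small, a, b, "CA")
        d1 = residue_pair_distance(moved, a, b, "CA")
        np.testing.assert_allclose(d1.values, d0.values, atol=1e-9)
        chi0 = sidechain_chi(wt_small, a, 1).values
        chi1 = sidechain_chi(moved, a, 1).values
        np.testing.assert_allclose(chi1, chi0, atol=1e-9)
        k0 = kink_angle(wt_small.frame(5), "D")
        k1 = kink_angle(moved.frame(5), "D")
        assert k1 == pytest.approx(k0, abs=1e-9)
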