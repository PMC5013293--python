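"""Contact detection, block occupancy, temporal classification, COM traces."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import protofil as pf
from protofil.contacts import OccupancyMatrix
from protofil.errors import ConfigurationError, PartialBlockWarning, StructureError
from protofil.structures import build_protomer


def _two_residue_frame(gap: float) -> pf.DimerFrame:
    a = build_protomer("A", "A", [(1, "GLY", [("CA", [0.0, 0.0, 0.0])])])
    b = build_protomer("B", "B", [(1, "GLY", [("CA", [0.0, 0.0, gap])])])
    return pf.DimerFrame(0.0, a, b)


def test_cutoff_threshold_semantics():
    assert len(pf.find_contacts(_two_residue_frame(4.9))) == 1
    assert len(pf.find_contacts(_two_residue_frame(5.1))) == 0
    assert pf.find_contacts(_two_residue_frame(100.0)) == {}


def test_contact_distance_is_symmetric_and_labeled():
    contacts = pf.find_contacts(_two_residue_frame(3.0))
    (pair, dist), = contacts.items()
    assert pair == (("A", 1, "GLY"), ("B", 1, "GLY"))
    assert dist == 3.0


def _random_frame(rng, n_res=12, atoms_per=3, spread=8.0):
    def prot(label, offset):
        specs = []
        for r in range(1, n_res + 1):
            atoms = [(n, rng.normal(scale=spread, size=3) + offset)
                     for n in ("CA", "CB", "CG")[:atoms_per]]
            specs.append((r, "ALA", atoms))
        return build_protomer(label, label, specs)

    return pf.DimerFrame(0.0, prot("A", np.zeros(3)), prot("B", np.array([0, 0, 6.0 * rng.random() + 2])))


def test_kdtree_equals_bruteforce_on_random_frames(rng):
    for _ in range(50):
        frame = _random_frame(rng)
        fast = pf.find_contacts(frame, method="kdtree")
        slow = pf.find_contacts(frame, method="brute")
        assert fast.keys() == slow.keys()
        for k in fast:
            assert fast[k] == slow[k]


def test_contacts_invariant_under_global_rigid_motion(rng):
    frame = _random_frame(rng)
    base = pf.find_contacts(frame)
    moved = frame.transformed(Rotation.random(rng=rng).as_matrix(), rng.normal(scale=50, size=3))
    assert pf.find_contacts(moved).keys() == base.keys()


def test_hydrogens_excluded_by_default():
    a = build_protomer("A", "A", [(1, "GLY", [("CA", [0, 0, 0]), ("HA", [0, 0, 3.0])])])
    b = build_protomer("B", "B", [(1, "GLY", [("CA", [0, 0, 10.0]), ("HA", [0, 0, 6.0])])])
    frame = pf.DimerFrame(0.0, a, b)
    assert len(pf.find_contacts(frame, heavy_only=True)) == 0
    assert len(pf.find_contacts(frame, heavy_only=False)) == 1


@given(st.integers(0, 1000))
def test_doubling_cutoff_is_monotone(seed):
    rng = np.random.default_rng(seed)
    frame = _random_frame(rng, n_res=6)
    for cutoff in (2.5, 5.0):
        assert len(pf.find_contacts(frame, cutoff)) <= len(pf.find_contacts(frame, 2 * cutoff))


def test_contact_count_series_planted():
    plan = tuple(
        pf.ContactPlanEntry(r, r, windows=((0.0, 100.0),)) for r in (10, 20, 30, 40, 50, 60, 70)
    )
    spec = pf.TrajectorySpec(n_frames=16, dt_ns=2.5, noise_sigma_A=0.0, contact_plan=plan,
                             n_residues=120, seed=4)
    traj, _ = pf.simulate_dimer_trajectory(spec)
    counts = pf.contact_count_series(traj)
    np.testing.assert_array_equal(counts, 7)


def test_empty_interface_series_zero():
    spec = pf.TrajectorySpec(n_frames=4, dt_ns=2.5, noise_sigma_A=0.0, n_residues=60)
    traj, _ = pf.simulate_dimer_trajectory(spec)
    np.testing.assert_array_equal(pf.contact_count_series(traj), 0)


# ------------------------------------------------------------------- occupancy

def test_occupancy_rows_and_conservation():
    plan = (
        pf.ContactPlanEntry(10, 10, windows=((0.0, 100.0),)),       # on then off
        pf.ContactPlanEntry(20, 20, windows=((0.0, 200.0),)),       # always on
    )
    spec = pf.TrajectorySpec(n_frames=80, dt_ns=2.5, noise_sigma_A=0.0, contact_plan=plan,
                             n_residues=120, seed=1)
    traj, gt = pf.simulate_dimer_trajectory(spec)
    occ = pf.occupancy_matrix(traj, block_ns=12.5)
    assert occ.occupancy.shape == (2, 16)
    by_seq = {(p[0][1], p[1][1]): occ.occupancy[i] for i, p in enumerate(occ.pairs)}
    np.testing.assert_allclose(by_seq[(20, 20)], 1.0)
    np.testing.assert_allclose(by_seq[(10, 10)], [1.0] * 8 + [0.0] * 8)
    # conservation: sum(occupancy * frames_per_block) = total frames in contact
    for key, sched in gt.contact_schedule.items():
        total = (by_seq[key] * occ.frames_per_block).sum()
        assert total == sched.sum()


def test_occupancy_half_block_presence_threshold():
    # in contact in exactly half of each block's frames
    plan = (pf.ContactPlanEntry(10, 10, windows=tuple((25.0 * k, 25.0 * k + 12.5) for k in range(4))),)
    spec = pf.TrajectorySpec(n_frames=40, dt_ns=2.5, noise_sigma_A=0.0, contact_plan=plan,
                             n_residues=120, seed=1)
    traj, _ = pf.simulate_dimer_trajectory(spec)
    occ = pf.occupancy_matrix(traj, block_ns=25.0)
    np.testing.assert_allclose(occ.occupancy, 0.5)
    assert occ.presence().all()  # present at threshold 0.5


def test_partial_final_block_dropped_with_warning():
    plan = (pf.ContactPlanEntry(10, 10, windows=((0.0, 1000.0),)),)
    spec = pf.TrajectorySpec(n_frames=42, dt_ns=2.5, noise_sigma_A=0.0, contact_plan=plan,
                             n_residues=120, seed=1)
    traj, _ = pf.simulate_dimer_trajectory(spec)  # 105 ns = 8 blocks + 5 ns (< half a block)
    with pytest.warns(PartialBlockWarning):
        occ = pf.occupancy_matrix(traj, block_ns=12.5)
    assert occ.n_blocks == 8
    assert occ.frames_per_block.sum() == 40

    traj2, _ = pf.simulate_dimer_trajectory(
        pf.TrajectorySpec(n_frames=3, dt_ns=2.5, noise_sigma_A=0.0, n_residues=60)
    )
    with pytest.raises(ConfigurationError, match="block"):
        pf.occupancy_matrix(traj2, block_ns=12.5)


# ---------------------------------------------------------------- classification

def _toy_occ(pattern) -> OccupancyMatrix:
    pair = (("A", 1, "ALA"), ("B", 2, "ALA"))
    return OccupancyMatrix(
        pairs=[pair],
        block_edges_ns=np.array([0.0, 12.5, 25.0, 37.5]),
        occupancy=np.array([[float(p) for p in pattern]]),
        frames_per_block=np.array([10, 10, 10]),
    )


def _oracle_label(wt, var):
    """Independent restatement of the three temporal rules on a 3-block toy
    where block 0 is the early window and block 2 the late window."""
    orange = wt[0] and not wt[2] and not any(var)
    purple = all(var) and wt[2]
    pink = any(var) and not any(wt)
    if orange:
        return "nontwisted_specific"
    if purple:
        return "twisted_general"
    if pink:
        return "variant_specific"
    return "unclassified"


def test_classifier_truth_table_exhaustive():
    """All 2^6 presence patterns on a 3-block toy match the rule oracle, and
    the three specific rules never overlap."""
    for wt_bits in range(8):
        for var_bits in range(8):
            wt = [bool(wt_bits >> i & 1) for i in range(3)]
            var = [bool(var_bits >> i & 1) for i in range(3)]
            cls = pf.classify_contacts(
                _toy_occ(wt), _toy_occ(var), early_end_ns=12.5, late_start_ns=25.0
            )
            got = cls.labels[(1, 2)]
            assert got == _oracle_label(wt, var), (wt, var)
            orange = wt[0] and not wt[2] and not any(var)
            purple = all(var) and wt[2]
            pink = any(var) and not any(wt)
            assert orange + purple + pink <= 1


def test_classifier_spec_examples():
    # present in WT early blocks only, never in variant -> nontwisted_specific
    assert pf.classify_contacts(
        _toy_occ([1, 0, 0]), _toy_occ([0, 0, 0]), 12.5, 25.0
    ).labels[(1, 2)] == "nontwisted_specific"
    # present in all variant blocks and late WT blocks -> twisted_general
    assert pf.classify_contacts(
        _toy_occ([0, 0, 1]), _toy_occ([1, 1, 1]), 12.5, 25.0
    ).labels[(1, 2)] == "twisted_general"
    # present only in some variant blocks -> variant_specific
    assert pf.classify_contacts(
        _toy_occ([0, 0, 0]), _toy_occ([0, 1, 0]), 12.5, 25.0
    ).labels[(1, 2)] == "variant_specific"
    # present in WT early and late, intermittent variant -> unclassified
    assert pf.classify_contacts(
        _toy_occ([1, 1, 1]), _toy_occ([0, 1, 0]), 12.5, 25.0
    ).labels[(1, 2)] == "unclassified"


def test_classifier_block_width_mismatch():
    bad = OccupancyMatrix(
        pairs=[(("A", 1, "ALA"), ("B", 2, "ALA"))],
        block_edges_ns=np.array([0.0, 10.0, 20.0, 30.0]),
        occupancy=np.zeros((1, 3)),
        frames_per_block=np.array([10, 10, 10]),
    )
    with pytest.raises(ConfigurationError, match="block widths"):
        pf.classify_contacts(_toy_occ([1, 0, 0]), bad)


def test_preset_groups_recovered_at_zero_noise():
    occ = {}
    for name in ("wt-like", "variant-like"):
        traj, _ = pf.simulate_dimer_trajectory(pf.preset_spec(name, seed=5, noise_sigma_A=0.0))
        occ[name] = pf.occupancy_matrix(traj)
    cls = pf.classify_contacts(occ["wt-like"], occ["variant-like"])
    assert cls.labels[(10, 10)] == "nontwisted_specific"
    assert cls.labels[(20, 20)] == "twisted_general"
    assert cls.labels[(30, 30)] == "variant_specific"
    assert cls.labels[(40, 40)] == "unclassified"


# -------------------------------------------------------------------- COM trace

def test_com_distance_hand_cases():
    a = build_protomer("A", "A", [(1, "GLY", [("CA", [0, 0, 0])])])
    b = build_protomer("B", "B", [(1, "GLY", [("CA", [3.0, 4.0, 0])])])
    traj = pf.Trajectory([pf.DimerFrame(0.0, a, b)], 1.0)
    assert pf.residue_com_distance(traj, 1, 1).com_distance_A[0] == 5.0

    # two equal-mass atoms at (0,0,0),(2,0,0) vs one at (1,3,0): COM distance 3
    a2 = build_protomer("A", "A", [(1, "GLY", [("CA", [0, 0, 0]), ("CB", [2.0, 0, 0])])])
    b2 = build_protomer("B", "B", [(1, "GLY", [("CA", [1.0, 3.0, 0])])])
    traj2 = pf.Trajectory([pf.DimerFrame(0.0, a2, b2)], 1.0)
    assert abs(pf.residue_com_distance(traj2, 1, 1).com_distance_A[0] - 3.0) < 1e-12


def test_com_distance_bridge_break_detected_within_one_frame():
    t_break = 50.0
    plan = (pf.ContactPlanEntry(67, 97, windows=((0.0, t_break),), on_distance_A=3.5,
                                off_distance_A=9.0),)
    spec = pf.TrajectorySpec(n_frames=80, dt_ns=1.25, noise_sigma_A=0.5, contact_plan=plan,
                             n_residues=120, seed=9)
    traj, _ = pf.simulate_dimer_trajectory(spec)
    trace = pf.residue_com_distance(traj, 67, 97)
    crossed = np.flatnonzero(trace.com_distance_A > 6.0)
    assert abs(traj.times_ns[crossed[0]] - t_break) <= spec.dt_ns
    assert np.all(trace.com_distance_A[: crossed[0]] < 4.0)


def test_com_distance_missing_residue_error():
    spec = pf.TrajectorySpec(n_frames=2, dt_ns=1.0, noise_sigma_A=0.0, n_residues=50)
    traj, _ = pf.simulate_dimer_trajectory(spec)
    with pytest.raises(StructureError, match="residue 999"):
        pf.residue_com_distance(traj, 999, 1)
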