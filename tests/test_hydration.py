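"""Occupancy, wetting kinetics, chain extraction, energy profiles."""

import numpy as np
import pandas as pd
import pytest

from cageflux import (
    HydrationTrajectory,
    energy_profile,
    extract_chains,
    generate_chain_frames,
    occupancy_histogram,
    wetting_transitions,
)
from cageflux.hydration import ATOM_COLUMNS


def trajectory_with_counts(counts, segment=(-5.0, 5.0)):
    """Frames whose in-segment oxygen count per frame is prescribed."""
    rows = []
    for f, n in enumerate(counts):
        for i in range(n):
            rows.append((f, i, "O", 0.0, 0.0, -4.0 + 8.0 * i / max(n, 1)))
        # one decoy oxygen far outside the segment
        rows.append((f, 999, "O", 0.0, 0.0, 50.0))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return HydrationTrajectory(atoms=atoms, segment=segment)


class TestOccupancy:
    def test_always_dry_channel(self):
        traj = trajectory_with_counts([0] * 30)
        stats = occupancy_histogram(traj)
        assert stats.histogram == {0: 1.0}
        assert stats.mode == 0
        assert stats.wetted_fraction == 0.0

    def test_prescribed_histogram_and_mode(self):
        counts = [17] * 80 + [9] * 10 + [23] * 10
        stats = occupancy_histogram(trajectory_with_counts(counts))
        assert stats.histogram[17] == pytest.approx(0.8)
        assert stats.histogram[9] == pytest.approx(0.1)
        assert stats.mode == 17
        assert sum(stats.histogram.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_counting_oracle(self, rng):
        # random oxygen clouds vs an explicit per-frame loop
        rows = []
        for f in range(40):
            for i in range(rng.integers(0, 30)):
                x, y, z = rng.uniform(-20, 20, size=3)
                rows.append((f, i, "O", x, y, z))
            rows.append((f, 999, "O", 0.0, 0.0, 100.0))
        atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        traj = HydrationTrajectory(atoms=atoms, segment=(-5.0, 5.0))
        stats = occupancy_histogram(traj)

        oracle = []
        for f in sorted(atoms["frame"].unique()):
            sub = atoms[(atoms["frame"] == f) & (atoms["atom"] == "O")]
            oracle.append(int(((sub["z_A"] >= -5.0) & (sub["z_A"] < 5.0)).sum()))
        assert list(stats.counts) == oracle

    def test_half_open_segment_boundary(self):
        rows = [
            (0, 1, "O", 0.0, 0.0, -5.0),  # at lo: counted
            (0, 2, "O", 0.0, 0.0, 5.0),  # at hi: not counted
        ]
        traj = HydrationTrajectory(
            atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS), segment=(-5.0, 5.0)
        )
        assert list(occupancy_histogram(traj).counts) == [1]

    def test_empty_trajectory_rejected(self):
        atoms = pd.DataFrame([], columns=ATOM_COLUMNS)
        traj = HydrationTrajectory(atoms=atoms, segment=(-5.0, 5.0))
        with pytest.raises(ValueError, match="empty"):
            occupancy_histogram(traj)

    def test_mode_tie_breaks_toward_smallest_count(self):
        stats = occupancy_histogram(trajectory_with_counts([0, 0, 3, 3]))
        assert stats.mode == 0


class TestWetting:
    def test_constant_series_is_one_episode(self):
        stats = wetting_transitions([5, 5, 5, 5])
        assert stats.n_transitions == 0
        assert stats.episodes == [("filled", 0, 4)]

    def test_alternating_series_run_lengths(self):
        stats = wetting_transitions([0, 5, 0, 5], empty_threshold=0)
        assert stats.n_transitions == 3
        assert len(stats.episodes) == 4
        assert [s for s, _, _ in stats.episodes] == [
            "empty", "filled", "empty", "filled",
        ]

    def test_episode_durations_partition_the_record(self):
        series = [0, 0, 4, 4, 4, 0, 9, 9]
        stats = wetting_transitions(series)
        assert sum(d for _, _, d in stats.episodes) == len(series)

    def test_threshold_shifts_the_binarisation(self):
        stats = wetting_transitions([1, 1, 5, 5], empty_threshold=1)
        assert stats.episodes[0][0] == "empty"
        assert stats.n_transitions == 1

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            wetting_transitions([0, 1], empty_threshold=-1)


class TestChains:
    def test_single_file_identity(self):
        frames = generate_chain_frames(1, 8, orientation=(1,))
        chains = extract_chains(frames.trajectory.frame(0))
        assert len(chains) == 1
        assert len(chains[0]) == 8
        assert abs(chains[0].dipole_order) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_arms", [2, 3, 4])
    def test_branched_chains_match_generator_ground_truth(self, n_arms):
        frames = generate_chain_frames(n_arms, 5)
        chains = extract_chains(frames.trajectory.frame(0))
        assert len(chains) == len(frames.expected_chains)

        def canon(ids):
            return min(tuple(ids), tuple(reversed(ids)))

        assert {canon(c.mol_ids) for c in chains} == {
            canon(e) for e in frames.expected_chains
        }
        for c in chains:
            assert abs(c.dipole_order) == pytest.approx(1.0, abs=1e-9)
            if n_arms >= 3:
                # every chain shares the branch-node water
                assert c.node_mol_id == frames.node_mol_id

    def test_opposite_orientations_give_opposite_dipole_signs(self):
        frames = generate_chain_frames(4, 5, orientation=(1, -1, 1, -1))
        chains = extract_chains(frames.trajectory.frame(0))
        gt = frames.ground_truth
        arm_of = {
            tuple(gt[gt["arm_id"] == a].sort_values("position")["mol_id"]): a
            for a in range(4)
        }
        signs = {arm_of[c.mol_ids]: np.sign(c.dipole_order) for c in chains}
        assert signs == {0: 1.0, 1: -1.0, 2: 1.0, 3: -1.0}

    def test_far_apart_waters_give_no_chains(self):
        rows = [(0, i, "O", 10.0 * i, 0.0, 0.0) for i in range(5)]
        frame = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        assert extract_chains(frame, angle_cutoff_deg=None) == []

    def test_missing_hydrogens_fall_back_with_warning(self):
        rows = [(0, i, "O", 2.8 * i, 0.0, 0.0) for i in range(4)]
        frame = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        with pytest.warns(UserWarning, match="no hydrogens"):
            chains = extract_chains(frame, angle_cutoff_deg=140.0)
        assert len(chains) == 1
        assert chains[0].dipole_order is None

    def test_decomposition_conserves_waters_and_edges(self, rng):
        # jittered branched network: no chain shares an edge; every
        # degree<=2 water appears in at most one chain
        frames = generate_chain_frames(4, 6, jitter_sd_A=0.25, seed=3)
        chains = extract_chains(frames.trajectory.frame(0), angle_cutoff_deg=None)
        edges = set()
        for c in chains:
            for a, b in zip(c.mol_ids, c.mol_ids[1:]):
                e = frozenset((a, b))
                assert e not in edges
                edges.add(e)
        membership: dict[int, int] = {}
        for c in chains:
            for m in c.mol_ids:
                membership[m] = membership.get(m, 0) + 1
        node = frames.node_mol_id
        for m, count in membership.items():
            if m != node:
                assert count <= 2  # interior waters sit in one chain;
                # a non-junction water can terminate two walks at most


class TestEnergyProfile:
    def test_constant_series_is_flat(self):
        series = {str(i): [3.0] * 10 for i in range(1, 6)}
        prof = energy_profile(series)
        assert np.allclose(prof.mean_energy_kj_mol, 3.0)
        assert all(b == 0.0 for b in prof.barriers_kj_mol.values())
        assert prof.symmetric

    def test_window_barrier_and_symmetry(self):
        # trailing means (0, 6.04, -10, 6.04, 0): the first-window barrier
        # is 6.04 kJ/mol and the profile is mirror-symmetric
        series = {}
        for label, mean in zip("12345", (0.0, 6.04, -10.0, 6.04, 0.0)):
            series[label] = [99.0] * 5 + [mean] * 5  # equilibration junk first
        prof = energy_profile(series, equilibration_fraction=0.5)
        assert prof.barriers_kj_mol["1-2"] == pytest.approx(6.04)
        assert prof.barriers_kj_mol["2-3"] == pytest.approx(-16.04)
        assert prof.symmetric

    def test_asymmetric_profile_detected(self):
        series = {"1": [0.0], "2": [26.33], "3": [-5.0], "4": [12.0], "5": [0.0]}
        prof = energy_profile(series, equilibration_fraction=0.0)
        assert not prof.symmetric

    def test_trailing_mean_matches_brute_force_oracle(self, rng):
        series = {"p": rng.normal(size=37)}
        frac = 0.5
        prof = energy_profile(series, equilibration_fraction=frac)
        n_keep = int(np.ceil((1 - frac) * 37))
        assert prof.mean_energy_kj_mol[0] == pytest.approx(
            np.mean(series["p"][-n_keep:])
        )

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            energy_profile({})
        with pytest.raises(ValueError):
            energy_profile({"1": []})
        with pytest.raises(ValueError):
            energy_profile({"1": [1.0]}, equilibration_fraction=1.0)
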