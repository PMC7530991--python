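"""Forward-model generators: shrinkage ODE, wetting CTMC, chain frames."""

import numpy as np
import pytest
from scipy import stats

from cageflux import (
    ChainFrames,
    OccupancyGroundTruth,
    ShrinkageGroundTruth,
    VesicleSpec,
    extract_chains,
    generate_chain_frames,
    simulate_occupancy,
    simulate_shrinkage,
)
from cageflux.constants import V_W_M3_PER_MOL


class TestShrinkage:
    def test_zero_permeability_gives_flat_zero_signal(self, standard_vesicle):
        truth = ShrinkageGroundTruth(0.0, 0.0)
        res = simulate_shrinkage(standard_vesicle, truth, rescale=False)
        assert np.all(res.trace.signal == 0.0)
        assert np.all(res.volume_channel == 1.0)

    def test_long_time_volume_reaches_osmotic_equilibrium(self, standard_vesicle):
        # V(inf)/V0 -> c_in0/c_out = 0.5 for 0.2 -> 0.4 Osm/L
        truth = ShrinkageGroundTruth(0.0, 300.0)
        res = simulate_shrinkage(standard_vesicle, truth, duration_s=10.0)
        assert res.volume_channel[-1] == pytest.approx(0.5, rel=1e-5)

    def test_initial_slope_matches_analytic_derivative(self, standard_vesicle):
        pf = 200.0
        truth = ShrinkageGroundTruth(0.0, pf)
        res = simulate_shrinkage(
            standard_vesicle, truth, n_points=4001, duration_s=0.4
        )
        t = res.trace.times_s
        v = res.volume_channel
        # second-order one-sided difference at t = 0
        dt = t[1] - t[0]
        slope = (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * dt)
        expected = (
            -pf * 1e-6
            * standard_vesicle.s_over_v0_per_m
            * V_W_M3_PER_MOL
            * standard_vesicle.delta_osm * 1e3
        )
        assert slope == pytest.approx(expected, rel=1e-3)

    def test_volume_bounded_and_signal_monotone(self, standard_vesicle):
        truth = ShrinkageGroundTruth(20.0, 400.0, channel_fraction=0.6)
        res = simulate_shrinkage(standard_vesicle, truth, duration_s=5.0)
        lo = standard_vesicle.c_in0_osm / standard_vesicle.c_out_osm
        for v in (res.volume_channel, res.volume_lipid):
            assert np.all(v <= 1.0 + 1e-12)
            assert np.all(v >= lo - 1e-6)
        # non-decreasing up to the integrator's absolute tolerance near
        # the osmotic-equilibrium plateau
        assert np.all(np.diff(res.noiseless_signal) >= -1e-8)

    def test_seeded_reproducibility_bit_identical(self, standard_vesicle):
        truth = ShrinkageGroundTruth(10.0, 300.0, 0.7, noise_sd=0.02, seed=42)
        a = simulate_shrinkage(standard_vesicle, truth)
        b = simulate_shrinkage(standard_vesicle, truth)
        assert np.array_equal(a.trace.signal, b.trace.signal)

    def test_swelling_regime_rejected(self):
        with pytest.raises(ValueError, match="swelling"):
            VesicleSpec(200.0, c_in0_osm=0.4, c_out_osm=0.2)

    def test_nonpositive_duration_rejected(self, standard_vesicle):
        with pytest.raises(ValueError, match="duration"):
            simulate_shrinkage(
                standard_vesicle, ShrinkageGroundTruth(0.0, 100.0), duration_s=0.0
            )


class TestOccupancy:
    def test_absorbing_filled_state(self):
        truth = OccupancyGroundTruth(
            wetting_rate_per_s=100.0, dewetting_rate_per_s=1e-9,
            n_frames=2000, seed=0,
        )
        series = simulate_occupancy(truth)
        assert np.all(series.counts >= 1)

    def test_symmetric_rates_give_half_filled_fraction(self):
        truth = OccupancyGroundTruth(5.0, 5.0, n_frames=50_000, seed=7)
        series = simulate_occupancy(truth)
        frac = np.mean(series.counts > 0)
        # binomial-ish sampling error on correlated frames; generous band
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_dwell_means_match_exponential_law(self):
        truth = OccupancyGroundTruth(2.0, 8.0, n_frames=100_000, seed=11)
        series = simulate_occupancy(truth)
        for dwells, rate in (
            (series.dwell_times_filled_s, 8.0),
            (series.dwell_times_empty_s, 2.0),
        ):
            mean = dwells.mean()
            se = dwells.std(ddof=1) / np.sqrt(len(dwells))
            assert abs(mean - 1.0 / rate) < 3.0 * se

    def test_dwell_distributions_pass_exponential_gof(self):
        truth = OccupancyGroundTruth(2.0, 8.0, n_frames=100_000, seed=23)
        series = simulate_occupancy(truth)
        for dwells, rate in (
            (series.dwell_times_filled_s, 8.0),
            (series.dwell_times_empty_s, 2.0),
        ):
            _, p = stats.kstest(dwells, "expon", args=(0, 1.0 / rate))
            assert p > 0.01

    def test_reproducible_and_emissions_truncated_at_one(self):
        truth = OccupancyGroundTruth(3.0, 3.0, filled_mean_count=2.0,
                                     n_frames=5000, seed=5)
        a = simulate_occupancy(truth)
        b = simulate_occupancy(truth)
        assert np.array_equal(a.counts, b.counts)
        filled = a.counts[a.counts > 0]
        assert filled.min() >= 1  # Poisson jitter truncated at 1

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            OccupancyGroundTruth(0.0, 1.0)


class TestChainFrames:
    def test_single_arm_is_one_chain_of_requested_length(self):
        frames = generate_chain_frames(1, 8, orientation=(1,))
        assert isinstance(frames, ChainFrames)
        assert frames.node_mol_id is None
        assert frames.ground_truth["mol_id"].nunique() == 8

    def test_four_arms_share_one_node_water(self):
        frames = generate_chain_frames(4, 5)
        gt = frames.ground_truth
        assert gt["mol_id"].nunique() == 21  # 4*5 arm waters + 1 node
        assert frames.node_mol_id == 0
        # the node belongs to every arm's chain
        assert set(gt[gt["mol_id"] == 0]["arm_id"]) == {0, 1, 2, 3}

    def test_large_jitter_breaks_chains(self):
        frames = generate_chain_frames(1, 8, orientation=(1,),
                                       jitter_sd_A=5.0, seed=2)
        chains = extract_chains(frames.trajectory.frame(0), angle_cutoff_deg=None)
        assert all(len(c) < 8 for c in chains)

    def test_seeded_reproducibility(self):
        a = generate_chain_frames(3, 4, jitter_sd_A=0.3, seed=9)
        b = generate_chain_frames(3, 4, jitter_sd_A=0.3, seed=9)
        assert a.trajectory.atoms.equals(b.trajectory.atoms)

    @pytest.mark.parametrize("bad", [{"n_arms": 5}, {"o_o_spacing_A": 4.0}])
    def test_invalid_geometry_rejected(self, bad):
        kwargs = dict(n_arms=2, waters_per_arm=4)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_chain_frames(**kwargs)

    def test_too_many_outward_arms_rejected(self):
        # the node water has only two hydrogens to donate
        with pytest.raises(ValueError, match="outward"):
            generate_chain_frames(3, 4, orientation=(1, 1, 1))
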