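import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antnet.errors import ConfigError
from antnet.metrics import HexGrid, home_range_90
from antnet.synthetic import (
    ColonyConfig,
    generate_block_network,
    generate_cohort,
    generate_colony,
    generate_maturity_profile,
    generate_planted_network,
    generate_queen_schedule,
    generate_trajectories,
)


class TestColonyConfig:
    def test_defaults_valid(self):
        ColonyConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_workers": 3},
            {"planted_split": 0.0},
            {"planted_split": 1.0},
            {"q_in": 0.1, "q_out": 0.2},
            {"q_in": 0.2, "q_out": 0.2},
            {"intermediate_fraction": 1.0},
            {"duration_hours": 1},
            {"queen_archetype": "royalty"},
            {"arena_dims": (0.0, 10.0)},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigError):
            ColonyConfig(**kwargs)


class TestPlantedNetwork:
    def test_zero_between_rate(self):
        net, labels = generate_planted_network(20, 0.5, 1.0, 0.0, hours=24, seed=0)
        cross = labels[:, None] != labels[None, :]
        assert net.W[cross].sum() == 0.0

    def test_determinism(self):
        a, _ = generate_planted_network(20, 0.5, 2.0, 0.2, seed=11)
        b, _ = generate_planted_network(20, 0.5, 2.0, 0.2, seed=11)
        assert np.array_equal(a.W, b.W)

    def test_counts_are_symmetric_integers(self):
        net, _ = generate_planted_network(15, 0.4, 2.0, 0.2, seed=1)
        assert np.array_equal(net.W, net.W.T)
        assert np.array_equal(net.W, np.round(net.W))
        assert (np.diag(net.W) == 0).all()

    @pytest.mark.parametrize("kwargs", [{"n": 3}, {"q_in": 0.1, "q_out": 0.2}])
    def test_invalid(self, kwargs):
        base = dict(n=10, split=0.5, q_in=2.0, q_out=0.2)
        base.update(kwargs)
        with pytest.raises(ConfigError):
            generate_planted_network(**base)

    def test_block_network_three_blocks(self):
        net, labels = generate_block_network([5, 5, 5], 2.0, 0.0, hours=24, seed=0)
        assert sorted(np.bincount(labels)) == [5, 5, 5]
        cross = labels[:, None] != labels[None, :]
        assert net.W[cross].sum() == 0.0


class TestMaturityProfile:
    def test_zero_intermediate(self):
        v = generate_maturity_profile(50, 0.0, seed=0)
        assert np.sum((v > 0.25) & (v < 0.75)) == 0

    def test_exact_intermediate_count(self):
        v = generate_maturity_profile(100, 0.20, seed=1)
        assert np.sum((v > 0.25) & (v < 0.75)) == 20

    def test_imbalance_by_direct_count(self):
        v = generate_maturity_profile(100, 0.39, high_low_imbalance=0.44, seed=2)
        n_high = np.sum(v > 0.9)
        n_low = np.sum(v < 0.1)
        # n_ext = 61 -> n_low = 25, n_high = 36 = 1.44 * 25 exactly
        assert n_low == 25
        assert n_high == 36

    def test_infeasible_rejected(self):
        with pytest.raises(ConfigError):
            generate_maturity_profile(4, 0.5, high_low_imbalance=10.0, seed=0)

    def test_values_in_unit_interval(self):
        v = generate_maturity_profile(200, 0.3, seed=3)
        assert ((v >= 0) & (v <= 1)).all()


class TestQueenSchedule:
    def test_specialist_two_partners_full_conservation(self):
        from antnet.queen_kinetics import identity_conservation

        hc = generate_queen_schedule("specialist", 20, 10, seed=0, n_partners=2)
        assert all(len(c) == 2 for c in hc.counts)
        assert identity_conservation(hc) == 1.0

    def test_unknown_archetype(self):
        with pytest.raises(ConfigError):
            generate_queen_schedule("paragon", 20, 10, seed=0)

    def test_hub_contacts_more_workers_than_specialist(self):
        from antnet.queen_kinetics import workers_per_hour

        hub = generate_queen_schedule("hub", 50, 24, seed=1,
                                      target_total=500.0, strength_sd=100.0)
        spec = generate_queen_schedule("specialist", 50, 24, seed=1,
                                       target_total=500.0)
        assert workers_per_hour(hub, 50) >= workers_per_hour(spec, 50)

    def test_hours_minimum(self):
        with pytest.raises(ConfigError):
            generate_queen_schedule("hub", 20, 1, seed=0)


class TestTrajectories:
    def test_zero_step_scale_single_hexagon(self):
        cfg = ColonyConfig(n_workers=4, duration_hours=2, seed=0)
        colony = generate_colony(cfg)
        det = generate_trajectories(
            colony, step_scale_by_maturity=lambda m: 0.0, seed=1, n_frames=50
        )
        grid = HexGrid(width=cfg.arena_dims[0], height=cfg.arena_dims[1],
                       body_length=cfg.body_length)
        sub = det[det["ant_id"] == "w000"]
        hr = home_range_90(sub[["x", "y"]].to_numpy(), grid)
        assert len(hr.hexes) == 1

    def test_determinism(self):
        cfg = ColonyConfig(n_workers=4, duration_hours=2, seed=0)
        colony = generate_colony(cfg)
        a = generate_trajectories(colony, seed=5, n_frames=30)
        b = generate_trajectories(colony, seed=5, n_frames=30)
        pd.testing.assert_frame_equal(a, b)

    def test_positions_inside_arena(self):
        cfg = ColonyConfig(n_workers=4, duration_hours=2, seed=2)
        colony = generate_colony(cfg, n_frames=100)
        det = colony.detections
        assert (det["x"] >= 0).all() and (det["x"] <= cfg.arena_dims[0]).all()
        assert (det["y"] >= 0).all() and (det["y"] <= cfg.arena_dims[1]).all()

    def test_home_range_grows_with_maturity(self):
        """Low- vs high-maturity cohorts measured with the real estimator."""
        cfg = ColonyConfig(n_workers=40, duration_hours=2, seed=3,
                           intermediate_fraction=0.0)
        colony = generate_colony(cfg)
        grid = HexGrid(width=cfg.arena_dims[0], height=cfg.arena_dims[1],
                       body_length=cfg.body_length)
        det = generate_trajectories(colony, seed=4, n_frames=300)
        props = {0: [], 1: []}
        for ant in colony.worker_ids:
            m = colony.truth_maturity[ant]
            sub = det[(det["ant_id"] == ant) & (det["arena"] == "nest")]
            if len(sub) == 0:
                continue
            hr = home_range_90(sub[["x", "y"]].to_numpy(), grid)
            props[int(m > 0.5)].append(hr.proportion_of_arena)
        assert np.mean(props[1]) > np.mean(props[0])


class TestColony:
    def test_edge_matrix_invariants(self):
        colony = generate_colony(ColonyConfig(n_workers=12, duration_hours=4, seed=1))
        W = colony.edge_counts.to_numpy()
        assert np.array_equal(W, W.T)
        assert (np.diag(W) == 0).all()
        assert (W >= 0).all()
        assert np.array_equal(W, np.round(W))

    def test_determinism_byte_identical(self, tmp_path):
        cfg = ColonyConfig(n_workers=10, duration_hours=3, seed=9)
        for d in ("a", "b"):
            generate_colony(cfg, n_frames=40).write(tmp_path / d)
        for name in ("edges.csv", "detections.csv", "metadata.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_roster_alignment(self):
        colony = generate_colony(
            ColonyConfig(n_workers=8, duration_hours=2, seed=2), n_frames=20
        )
        assert set(colony.detections["ant_id"]) <= set(colony.edge_counts.index)
        assert ((colony.foraging_proportion >= 0) &
                (colony.foraging_proportion <= 1)).all()

    def test_log_normal_strength_shape(self):
        """Skewness of log worker strengths stays near 0 across seeds."""
        skews = []
        for seed in range(10):
            colony = generate_colony(
                ColonyConfig(n_workers=60, duration_hours=12, seed=seed)
            )
            s = colony.network().strengths()
            s = s[:-1]  # workers only (queen is last)
            skews.append(stats.skew(np.log(s[s > 0])))
        assert abs(np.mean(skews)) < 0.5

    def test_low_detection_worker_planted(self):
        colony = generate_colony(
            ColonyConfig(n_workers=10, duration_hours=2, seed=0),
            low_detection_worker=3,
        )
        assert colony.detection_count.iloc[3] < colony.detection_count.iloc[0]


class TestCohort:
    def test_minimum_size(self):
        with pytest.raises(ConfigError):
            generate_cohort(2, 1.0, seed=0)

    def test_structure(self):
        cohort = generate_cohort(
            5, 2.0, seed=1,
            base_config=ColonyConfig(n_workers=10, duration_hours=3),
        )
        assert len(cohort) == 5
        assert len({c.config.colony_id for c in cohort}) == 5
        assert all(c.config.species is not None for c in cohort)
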