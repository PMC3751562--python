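"""Protocol-level tests: development, conversion, recovery and sweeps.

Lattices here are kept small (8x8 to 12x12) -- large enough for pattern
statistics, small enough for a fast suite; the acceptance tests exercise
the full 30x30 tissue.
"""

import collections

import numpy as np
import pytest

from pancfate.integrate import population_average
from pancfate.model import ModelParams, Y, Z
from pancfate.scenarios import (
    ADULT_STATE,
    EMBRYO_STATE,
    ScenarioSpec,
    commitment_times,
    conversion_spec,
    neighbor_pair_fraction,
    recovery_spec,
    run_conversion,
    run_density_sweep,
    run_development,
    run_recovery,
    run_scenario,
    run_shape_sweep,
    shuffled_pair_fraction,
)


class TestPresets:
    def test_initial_condition_presets(self):
        np.testing.assert_array_equal(EMBRYO_STATE, [1, 0, 0, 0])
        np.testing.assert_array_equal(ADULT_STATE, [0, 0, 1, 0])

    def test_factory_schedules(self):
        assert conversion_spec("stab").schedule == ((0.0, {"b": 0.0}),)
        assert conversion_spec("both").schedule == ((0.0, {"a": 0.0, "b": 0.0}),)
        assert conversion_spec("inhibition").schedule == ((0.0, {"a": 0.0}),)
        with pytest.raises(ValueError):
            conversion_spec("nope")
        with pytest.raises(ValueError):
            recovery_spec(t_rec=0.0)

    def test_determinism_equal_specs_equal_results(self):
        spec = conversion_spec("stab", width=8, height=8, replicates=2, seed=3, t_end=40)
        r1, r2 = run_scenario(spec), run_scenario(spec)
        np.testing.assert_array_equal(r1.islet_fraction, r2.islet_fraction)
        np.testing.assert_array_equal(r1.conversion_fraction, r2.conversion_fraction)


@pytest.fixture(scope="module")
def dev():
    return run_development(width=10, height=10, t_end=100, seed=2,
                           keep_trajectories=True, record_every=5)


@pytest.fixture(scope="module")
def runs():
    kw = dict(width=12, height=12, replicates=3, seed=5, t_end=150)
    return {v: run_conversion(variant=v, **kw) for v in ("stab", "both", "inhibition")}


class TestDevelopment:
    def test_transient_promiscuous_x_expression(self, dev):
        # X rises to intermediate levels in all cells, then falls back as
        # fates commit and the upstream inducer is shut down
        pa = population_average(dev.trajectories[0])
        assert pa.X.max() > 0.05
        assert pa.t[pa.X.idxmax()] < 30
        assert pa.X.iloc[-1] < 0.01

    def test_final_pattern_contains_both_fates_scattered(self, dev):
        counts = collections.Counter(dev.final_fates[0])
        assert counts["acinar"] > 0 and counts["islet"] > 0
        assert counts["progenitor"] == 0
        # islet cells are scattered, not clumped: adjacent islet-islet pairs
        # do not exceed the spatially shuffled expectation
        members = dev.final_states[0][:, Z] > 0.5
        obs = neighbor_pair_fraction(dev.tissues[0], members)
        null = shuffled_pair_fraction(dev.tissues[0], int(members.sum()),
                                      np.random.default_rng(0), 200)
        assert obs <= null.mean() + null.std()

    def test_acinar_fate_spreads_by_homeogenetic_induction(self, dev):
        # acinar commitments occur next to earlier-committed acinar cells
        # more often than under a spatial shuffle of commitment times
        traj = dev.trajectories[0]
        tissue = dev.tissues[0]
        t_commit = commitment_times(traj, Y)
        committed = np.isfinite(t_commit)

        def frac_with_earlier_neighbor(times):
            t_first = np.nanmin(times[committed])
            num = den = 0
            for i in np.nonzero(committed)[0]:
                if times[i] == t_first:
                    continue
                den += 1
                if any(committed[j] and times[j] < times[i] for j in tissue.neighbors[i]):
                    num += 1
            return num / den

        obs = frac_with_earlier_neighbor(t_commit)
        rng = np.random.default_rng(0)
        idx = np.nonzero(committed)[0]
        null = []
        for _ in range(200):
            perm = t_commit.copy()
            perm[idx] = t_commit[idx][rng.permutation(idx.size)]
            null.append(frac_with_earlier_neighbor(perm))
        assert obs > np.mean(null)

    def test_without_noise_symmetry_never_breaks(self):
        res = run_development(width=10, height=10, t_end=100, seed=2,
                              params=ModelParams(eta_x=0.0, eta_y=0.0))
        assert np.ptp(res.final_states[0], axis=0).max() == 0.0
        assert len(set(res.final_fates[0])) == 1


class TestConversion:
    def test_loss_of_stabilization_converts_everything(self, runs):
        np.testing.assert_array_equal(runs["stab"].conversion_fraction, 1.0)
        assert all(set(f) == {"islet"} for f in runs["stab"].final_fates)

    def test_additional_loss_of_inhibition_is_strictly_faster(self, runs):
        # paired seeds: identical tissues and noise streams
        assert np.all(runs["both"].time_to_half < runs["stab"].time_to_half)

    def test_losing_inhibition_alone_preserves_acinar_identity(self, runs):
        np.testing.assert_array_equal(runs["inhibition"].conversion_fraction, 0.0)
        assert all(set(f) == {"acinar"} for f in runs["inhibition"].final_fates)

    def test_nascent_islet_cells_alternate_spatially(self):
        # when the first quarter has committed, adjacent islet-islet pairs
        # are rarer than in a spatial shuffle (lateral inhibition pattern)
        res = run_conversion(variant="stab", width=12, height=12, replicates=1,
                             seed=7, t_end=150, keep_trajectories=True)
        traj = res.trajectories[0]
        frac = res.islet_fraction[0]
        i25 = np.nonzero(frac >= 0.25)[0][0]
        members = traj.states[i25][:, Z] > 0.5
        obs = neighbor_pair_fraction(res.tissues[0], members)
        null = shuffled_pair_fraction(res.tissues[0], int(members.sum()),
                                      np.random.default_rng(1), 200)
        assert obs < null.mean()


class TestRecovery:
    def test_early_recovery_reinstates_a_mixed_pattern(self):
        res = run_recovery(t_rec=5.0, width=12, height=12, replicates=2, seed=9, t_end=150)
        for fates, outcome in zip(res.final_fates, res.outcomes):
            counts = collections.Counter(fates)
            assert counts["acinar"] > 0 and counts["islet"] > 0
            assert outcome == "mixed_redecision"

    def test_late_recovery_reverts_nothing(self):
        res = run_recovery(t_rec=100.0, width=12, height=12, replicates=2, seed=9, t_end=150)
        np.testing.assert_array_equal(res.conversion_fraction, 1.0)
        assert res.outcomes == ["completed"] * 2

    def test_intermediate_recovery_arrests_conversion(self):
        recovered = run_recovery(t_rec=25.0, width=12, height=12, replicates=2, seed=9, t_end=150)
        unrecovered = run_conversion(variant="stab", width=12, height=12,
                                     replicates=2, seed=9, t_end=150)
        assert np.all(recovered.conversion_fraction < unrecovered.conversion_fraction)

    def test_very_early_recovery_returns_to_acinar(self):
        res = run_recovery(t_rec=3.0, width=12, height=12, replicates=1, seed=9, t_end=150)
        assert res.outcomes == ["arrested"]
        assert set(res.final_fates[0]) == {"acinar"}


class TestSweeps:
    def test_density_sweep_table_and_limits(self):
        table = run_density_sweep([0.15, 0.85], [1.0], replicates=4, seed=1, t_end=100,
                                  spec=ScenarioSpec(width=10, height=10, init="adult"))
        assert list(table.columns) == ["density", "b", "n_replicates",
                                       "mean_conversion_fraction", "se"]
        sparse = table.loc[table.density == 0.15, "mean_conversion_fraction"].item()
        dense = table.loc[table.density == 0.85, "mean_conversion_fraction"].item()
        assert sparse > dense

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            run_density_sweep([], [1.0])
        with pytest.raises(ValueError):
            run_density_sweep([0.5], [1.0], replicates=0)

    def test_isolated_cell_always_converts(self):
        # an isolated cell receives no stabilizing signal at all: Ybar = 0
        # makes the acinar state untenable at any b
        single = np.zeros((2, 2), dtype=bool)
        single[0, 0] = True
        table = run_shape_sweep([single], params=ModelParams(b=2000.0),
                                replicates=2, seed=0, t_end=100)
        assert table.mean_conversion_fraction.item() == 1.0

    def test_full_lattice_retains_acinar_at_moderate_b(self):
        res = run_scenario(ScenarioSpec(name="density_sweep", init="adult",
                                        width=8, height=8, density=1.0,
                                        params=ModelParams(b=1.0),
                                        t_end=100, replicates=2, seed=0))
        np.testing.assert_array_equal(res.conversion_fraction, 0.0)

    def test_chain_converts_more_than_compact_block(self):
        # equal cell count, different compactness: the chain's end cells
        # are stabilized by a single neighbour and unravel at b=0.1
        chain = np.zeros((1, 8), dtype=bool)
        chain[0, 1:7] = True
        block = np.zeros((4, 5), dtype=bool)
        block[1:3, 1:4] = True
        table = run_shape_sweep([chain, block], params=ModelParams(b=0.1),
                                replicates=3, seed=0, t_end=150)
        assert table.n_cells.nunique() == 1
        assert table.mean_neighbors[0] < table.mean_neighbors[1]
        assert table.mean_conversion_fraction[0] > table.mean_conversion_fraction[1]

    def test_unequal_mask_sizes_warn(self):
        small = np.zeros((2, 2), dtype=bool)
        small[0, 0] = True
        big = np.ones((2, 2), dtype=bool)
        with pytest.warns(UserWarning, match="unequal cell counts"):
            run_shape_sweep([small, big], replicates=1, seed=0, t_end=1.0)
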