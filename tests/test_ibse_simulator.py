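"""Individual-based simulator: event semantics and exact invariants."""

import numpy as np
import pytest
from scipy import stats

from wolfallee.ibse_simulator import (
    DISPERSAL_LOG_MEANS,
    FEMALE,
    MALE,
    SimConfig,
    WolfState,
    _draw_moves,
    _new_tally,
    age_and_cull,
    fall_dispersal,
    initialize,
    lethal_control,
    mate_finding,
    reproduce,
    repetition_seed,
    risk_mortality,
    run_experiment,
    run_repetition,
    winter_dispersal,
)
from wolfallee.landscape import Landscape


def _flat_landscape(risk_value, n=12, cell_km=5.0):
    return Landscape(
        cell_km=cell_km,
        risk=np.full((n, n), float(risk_value)),
        region_code=np.zeros((n, n), dtype=int),
        depredation_cells=(),
    )


class TestInitialize:
    def test_default_founding(self, default_landscape, rng):
        scape, tmap = default_landscape
        state = initialize(scape, tmap, SimConfig(), rng)
        assert len(state) == 40
        assert state.breeder.all()
        occupied = set(state.territory.tolist())
        assert len(occupied) == 20
        regions = {tmap.territories[t].region for t in occupied}
        assert regions == {"MN"}
        assert state.age.min() >= 2 and state.age.max() <= 5

    def test_scaled_founding(self, default_landscape, rng):
        scape, tmap = default_landscape
        state = initialize(
            scape, tmap, SimConfig(init_breeding_pairs=1), rng
        )
        assert len(state) == 2
        assert len(set(state.territory.tolist())) == 1

    def test_no_mn_territories_errors(self, default_landscape, rng):
        scape, tmap = default_landscape
        from wolfallee.landscape import TerritoryMap

        wi_only = TerritoryMap(
            territories=tuple(tmap.by_region("WI")), cell_km=tmap.cell_km
        )
        with pytest.raises(ValueError, match="Minnesota"):
            initialize(scape, wi_only, SimConfig(), rng)


class TestMateFinding:
    def _loners(self, tmap, positions, sexes, parents=None):
        state = WolfState()
        parents = parents or [(-1, -1)] * len(positions)
        for (x, y), sex, (mo, fa) in zip(positions, sexes, parents):
            state.add([sex], [3], [mo], [fa], [x], [y], [-1], [False])
        return state

    def test_nearby_unrelated_pair_establishes(self, default_landscape, rng):
        scape, tmap = default_landscape
        t = tmap.territories[0]
        pos = [(t.center_x + 2, t.center_y), (t.center_x - 8, t.center_y)]
        state = self._loners(tmap, pos, [FEMALE, MALE])
        mate_finding(state, scape, tmap, SimConfig(perception_territories=1), rng)
        assert state.breeder.sum() == 2
        assert state.territory[0] == state.territory[1] >= 0

    def test_out_of_radius_no_pairing(self, default_landscape, rng):
        scape, tmap = default_landscape
        t = tmap.territories[0]
        pos = [(t.center_x, t.center_y), (t.center_x + 40, t.center_y)]
        state = self._loners(tmap, pos, [FEMALE, MALE])
        mate_finding(state, scape, tmap, SimConfig(perception_territories=1), rng)
        assert state.breeder.sum() == 0

    def test_siblings_never_pair(self, default_landscape, rng):
        scape, tmap = default_landscape
        t = tmap.territories[0]
        pos = [(t.center_x, t.center_y), (t.center_x + 5, t.center_y)]
        state = self._loners(
            tmap, pos, [FEMALE, MALE], parents=[(7, 8), (7, 8)]
        )
        mate_finding(state, scape, tmap, SimConfig(perception_territories=5), rng)
        assert state.breeder.sum() == 0

    def test_widowed_breeder_recruits_within_radius(self, default_landscape, rng):
        scape, tmap = default_landscape
        t = tmap.territories[0]
        state = WolfState()
        state.add([FEMALE], [4], [-1], [-1], [t.center_x], [t.center_y], [t.id], [True])
        state.add([MALE], [3], [-1], [-1], [t.center_x + 10], [t.center_y], [-1], [False])
        mate_finding(state, scape, tmap, SimConfig(perception_territories=1), rng)
        assert state.breeder.all()
        assert state.territory[1] == t.id


class TestDispersalKernel:
    @pytest.mark.parametrize(
        "name, log_mean, median_km",
        [("low", 3.23, 25.3), ("ave", 3.92, 50.4), ("high", 4.61, 100.5)],
    )
    def test_median_distances(self, name, log_mean, median_km, rng):
        assert DISPERSAL_LOG_MEANS[name] == log_mean
        cfg = SimConfig(dispersal_log_mean=log_mean)
        dx, dy = _draw_moves(100_000, cfg, rng)
        d = np.hypot(dx, dy)
        assert np.median(d) == pytest.approx(median_km, rel=0.01)

    def test_mean_exceeds_median_lognormally(self, rng):
        # lognormal mean e^(mu + s^2/2) =~ 83.9 km for the average kernel
        cfg = SimConfig(dispersal_log_mean=3.92)
        dx, dy = _draw_moves(100_000, cfg, rng)
        d = np.hypot(dx, dy)
        assert d.mean() == pytest.approx(np.exp(3.92 + 1.01**2 / 2), rel=0.03)

    def test_kolmogorov_smirnov_against_lognormal(self, rng):
        cfg = SimConfig(dispersal_log_mean=3.92)
        dx, dy = _draw_moves(100_000, cfg, rng)
        d = np.hypot(dx, dy)
        res = stats.kstest(np.log(d), "norm", args=(3.92, 1.01))
        assert res.pvalue > 0.01

    def test_directions_uniform(self, rng):
        dx, dy = _draw_moves(50_000, SimConfig(), rng)
        theta = np.arctan2(dy, dx)
        res = stats.kstest(theta, "uniform", args=(-np.pi, 2 * np.pi))
        assert res.pvalue > 0.01


class TestReproduce:
    def _paired_state(self, tmap, n_pairs):
        state = WolfState()
        for t in tmap.territories[:n_pairs]:
            state.add(
                [FEMALE, MALE], [3, 3], [-1, -1], [-1, -1],
                [t.center_x] * 2, [t.center_y] * 2, [t.id] * 2, [True] * 2,
            )
        return state

    def test_litter_distribution(self, default_landscape, rng):
        _, tmap = default_landscape
        births = 0
        litters = 0
        for _ in range(34):
            state = self._paired_state(tmap, 300)
            tally = _new_tally()
            reproduce(state, tmap, SimConfig(), rng, tally)
            births += tally["births"]
            litters += 300
        assert births / litters == pytest.approx(5.41, abs=0.06)

    def test_pup_sex_ratio(self, default_landscape, rng):
        _, tmap = default_landscape
        state = self._paired_state(tmap, 300)
        for _ in range(10):
            reproduce(state, tmap, SimConfig(), rng, _new_tally())
        pups = state.age == 0
        ratio = state.sex[pups].mean()
        assert 0.48 <= ratio <= 0.52

    def test_lone_breeder_no_pups(self, default_landscape, rng):
        _, tmap = default_landscape
        t = tmap.territories[0]
        state = WolfState()
        state.add([FEMALE], [3], [-1], [-1], [t.center_x], [t.center_y], [t.id], [True])
        tally = _new_tally()
        reproduce(state, tmap, SimConfig(), rng, tally)
        assert tally["births"] == 0

    def test_pups_carry_pedigree(self, default_landscape, rng):
        _, tmap = default_landscape
        state = self._paired_state(tmap, 1)
        reproduce(state, tmap, SimConfig(), rng, _new_tally())
        pups = np.flatnonzero(state.age == 0)
        assert len(pups) > 0
        assert set(state.mother[pups]) == {state.wid[0]}
        assert set(state.father[pups]) == {state.wid[1]}


class TestLethalControl:
    def _zone_state(self, scape, n):
        ix, iy = scape.depredation_cells[0]
        state = WolfState()
        x = (ix + 0.5) * scape.cell_km
        y = (iy + 0.5) * scape.cell_km
        state.add(
            [MALE] * n, [3] * n, [-1] * n, [-1] * n,
            [x] * n, [y] * n, [-1] * n, [False] * n,
        )
        return state

    def test_ten_percent_removed(self, default_landscape, rng):
        scape, _ = default_landscape
        state = self._zone_state(scape, 60)
        tally = _new_tally()
        lethal_control(state, scape, SimConfig(), rng, tally, last_winter_wi=400)
        assert tally["deaths_control"] == 40
        assert len(state) == 20

    def test_below_trigger_no_control(self, default_landscape, rng):
        scape, _ = default_landscape
        state = self._zone_state(scape, 60)
        tally = _new_tally()
        lethal_control(state, scape, SimConfig(), rng, tally, last_winter_wi=349)
        assert tally["deaths_control"] == 0
        assert len(state) == 60

    def test_shortfall_logged_when_zones_sparse(self, default_landscape, rng):
        scape, _ = default_landscape
        state = self._zone_state(scape, 10)
        tally = _new_tally()
        lethal_control(state, scape, SimConfig(), rng, tally, last_winter_wi=400)
        assert tally["deaths_control"] == 10
        assert tally["control_shortfall"] == 30


class TestFallDispersal:
    def _pack(self, tmap, size):
        t = tmap.territories[0]
        state = WolfState()
        state.add(
            [FEMALE, MALE], [5, 5], [-1, -1], [-1, -1],
            [t.center_x] * 2, [t.center_y] * 2, [t.id] * 2, [True, True],
        )
        n = size - 2
        state.add(
            [FEMALE] * n, list(range(1, n + 1)), [state.wid[0]] * n,
            [state.wid[1]] * n, [t.center_x] * n, [t.center_y] * n,
            [t.id] * n, [False] * n,
        )
        return state, t

    def test_excess_over_cap_disperses(self, default_landscape, rng):
        scape, tmap = default_landscape
        state, t = self._pack(tmap, 13)
        tally = _new_tally()
        fall_dispersal(state, scape, tmap, SimConfig(), rng, tally)
        moved = (
            tally["deaths_fall"] + tally["emigrants"]
            + int(((state.territory == -1)).sum())
        )
        assert moved == 3
        assert (state.territory == t.id).sum() == 10

    def test_youngest_chosen_first(self, default_landscape, rng):
        scape, tmap = default_landscape
        state, t = self._pack(tmap, 13)
        before_ids = state.wid[np.argsort(state.age)][:3]  # three youngest
        tally = _new_tally()
        fall_dispersal(state, scape, tmap, SimConfig(), rng, tally)
        staying = state.wid[state.territory == t.id]
        assert not np.isin(before_ids, staying).any()

    def test_small_pack_untouched(self, default_landscape, rng):
        scape, tmap = default_landscape
        state, t = self._pack(tmap, 9)
        tally = _new_tally()
        fall_dispersal(state, scape, tmap, SimConfig(), rng, tally)
        assert len(state) == 9
        assert (state.territory == t.id).sum() == 9

    def test_breeders_never_forced_out(self, default_landscape, rng):
        scape, tmap = default_landscape
        state, t = self._pack(tmap, 14)
        fall_dispersal(state, scape, tmap, SimConfig(), rng, _new_tally())
        assert state.breeder.sum() == 2
        assert (state.territory[state.breeder] == t.id).all()


class TestRiskMortality:
    def test_binomial_oracle(self, rng):
        scape = _flat_landscape(0.25, n=20)
        state = WolfState()
        n = 10_000
        state.add(
            [MALE] * n, [3] * n, [-1] * n, [-1] * n,
            rng.uniform(0, 100, n), rng.uniform(0, 100, n),
            [-1] * n, [False] * n,
        )
        tally = _new_tally()
        risk_mortality(state, scape, rng, tally)
        assert 7350 <= len(state) <= 7650  # +-3 binomial sd around 7500

    def test_risk_boundaries(self, rng):
        for risk, survivors in [(0.0, 50), (1.0, 0)]:
            scape = _flat_landscape(risk)
            state = WolfState()
            state.add(
                [MALE] * 50, [3] * 50, [-1] * 50, [-1] * 50,
                [10.0] * 50, [10.0] * 50, [-1] * 50, [False] * 50,
            )
            risk_mortality(state, scape, rng, _new_tally())
            assert len(state) == survivors


class TestAging:
    def test_max_age_enforced(self, rng):
        state = WolfState()
        state.add(
            [MALE, FEMALE], [11, 3], [-1, -1], [-1, -1],
            [10.0, 10.0], [10.0, 10.0], [-1, -1], [False, False],
        )
        tally = _new_tally()
        age_and_cull(state, SimConfig(), tally)
        assert len(state) == 1
        assert state.age[0] == 4
        assert tally["deaths_age"] == 1

    def test_empty_population_noop(self):
        state = WolfState()
        age_and_cull(state, SimConfig(), _new_tally())
        assert len(state) == 0


class TestWinterDispersal:
    def test_emigrants_replaced_one_for_one(self, default_landscape, rng):
        scape, _ = default_landscape
        state = WolfState()
        n = 200
        # solitary loners sprinkled near the western edge: some will cross
        state.add(
            [MALE] * n, [3] * n, [-1] * n, [-1] * n,
            rng.uniform(0, 30, n), rng.uniform(0, scape.height_km, n),
            [-1] * n, [False] * n,
        )
        tally = _new_tally()
        winter_dispersal(state, scape, SimConfig(dispersal_log_mean=4.61), rng, tally)
        assert tally["emigrants"] > 0  # the point of the setup
        assert tally["immigrants"] == tally["emigrants"]
        assert len(state) == n
        immigrants = state.mother == -1
        assert immigrants.all()  # all unrelated by construction here

    def test_pack_wolves_stay(self, default_landscape, rng):
        scape, tmap = default_landscape
        t = tmap.territories[5]
        state = WolfState()
        state.add(
            [FEMALE, MALE, FEMALE], [3, 3, 1], [-1, -1, 0], [-1, -1, 1],
            [t.center_x] * 3, [t.center_y] * 3, [t.id] * 3,
            [True, True, False],
        )
        x_before = state.x.copy()
        winter_dispersal(state, scape, SimConfig(), rng, _new_tally())
        np.testing.assert_array_equal(state.x, x_before)


class TestRepetition:
    def test_same_seed_bit_identical(self, default_landscape):
        scape, tmap = default_landscape
        cfg = SimConfig(seed=404, horizon_years=12)
        f1 = run_repetition(scape, tmap, cfg).frame
        f2 = run_repetition(scape, tmap, cfg).frame
        assert f1.equals(f2)

    def test_lethal_landscape_extinction(self, default_landscape):
        _, tmap = default_landscape
        scape = _flat_landscape(1.0, n=100)
        traj = run_repetition(scape, tmap, SimConfig(seed=1))
        assert traj.frame.n_total.iloc[-1] == 0
        assert len(traj.frame) <= 2

    def test_accounting_identity(self, default_landscape):
        scape, tmap = default_landscape
        traj = run_repetition(scape, tmap, SimConfig(seed=9, horizon_years=20))
        assert traj.check_accounting()

    def test_structural_invariants_along_run(self, default_landscape):
        """Breeder uniqueness, age cap, pack cap, pedigree rule."""
        scape, tmap = default_landscape
        cfg = SimConfig(seed=21, horizon_years=18)
        rng = np.random.default_rng(cfg.seed)
        state = initialize(scape, tmap, cfg, rng)
        from wolfallee.ibse_simulator import _census_row

        for _year in range(cfg.horizon_years):
            mate_finding(state, scape, tmap, cfg, rng)
            winter_dispersal(state, scape, cfg, rng, _new_tally())
            mate_finding(state, scape, tmap, cfg, rng)
            # at most one breeder per sex per territory
            for tid in set(state.territory[state.breeder].tolist()):
                m = state.breeder & (state.territory == tid)
                assert m.sum() <= 2
                assert state.sex[m].sum() in (0, 1, m.sum())
                if m.sum() == 2:
                    i, j = np.flatnonzero(m)
                    assert state.sex[i] != state.sex[j]
                    # breeding pairs are unrelated at pairing time
                    assert state.unrelated_matrix_row(i)[j]
            reproduce(state, tmap, cfg, rng, _new_tally())
            lethal_control(state, scape, cfg, rng, _new_tally(), 0)
            fall_dispersal(state, scape, tmap, cfg, rng, _new_tally())
            assert state.pack_sizes(len(tmap)).max() <= cfg.pack_cap
            risk_mortality(state, scape, rng, _new_tally())
            age_and_cull(state, cfg, _new_tally())
            assert len(state) == 0 or state.age.max() < 12
            if len(state) == 0:
                break


class TestExperiment:
    def test_scenario_grid_scaling(self, default_landscape):
        scape, tmap = default_landscape
        results = run_experiment(
            scape, tmap,
            scenarios=[(1, "ave"), (3, "high")],
            reps=2, base_seed=5,
            config_kwargs={"horizon_years": 6},
        )
        assert len(results) == 4
        seeds = [s["seed"] for s, _ in results]
        assert len(set(seeds)) == 4  # distinct derived seeds

    def test_serial_parallel_equivalence(self, default_landscape):
        scape, tmap = default_landscape
        kw = dict(
            scenarios=[(2, "low")], reps=3, base_seed=7,
            config_kwargs={"horizon_years": 8},
        )
        serial = run_experiment(scape, tmap, n_jobs=1, **kw)
        parallel = run_experiment(scape, tmap, n_jobs=2, **kw)
        for (sa, ta), (sb, tb) in zip(serial, parallel):
            assert sa == sb
            assert ta.frame.equals(tb.frame)

    def test_seed_scheme_stable(self):
        assert repetition_seed(0, 0, 0) == repetition_seed(0, 0, 0)
        assert repetition_seed(0, 0, 0) != repetition_seed(0, 0, 1)
        assert 0 <= repetition_seed(123, 14, 99) < 2**31

    def test_perception_monotonicity(self, default_landscape):
        """Wider perception must not hurt median population size."""
        scape, tmap = default_landscape
        kw = dict(reps=10, base_seed=3, config_kwargs={"horizon_years": 22})
        lo = run_experiment(scape, tmap, scenarios=[(1, "ave")], **kw)
        hi = run_experiment(scape, tmap, scenarios=[(5, "ave")], **kw)
        med = lambda rs: np.median([t.frame.n_total.iloc[-1] for _, t in rs])
        assert med(hi) >= med(lo)
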