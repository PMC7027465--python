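"""Event semantics, exactness oracles and invariants of the simulator."""

import math

import numpy as np
import pytest

from fragsim import (
    ExplosionError,
    RateConstants,
    ResourceFieldSpec,
    ScenarioConfig,
    Simulation,
    TorusLandscape,
    make_landscape,
    torus_distance,
    wellmixed_ode_reference,
)

TINY = 1e-300  # effectively-off rate that still satisfies positivity


def make_sim(landscape, rates=None, scenario=None, seed=0, **kw):
    return Simulation(landscape, rates, scenario, seed=seed, **kw)


def inject_satiated(sim, species, x, y):
    iid = sim._next_id
    sim._next_id += 1
    sim.individuals[iid] = [species, x, y, 1, 0]
    sim.satiated.add(iid)
    return iid


class TestChannelRates:
    def test_empty_state(self, intact_landscape):
        sim = make_sim(intact_landscape, scenario=ScenarioConfig(S=4))
        r = sim.channel_rates()
        V2 = intact_landscape.V**2
        assert r["immigration"] == pytest.approx(sim.rates.immigration_rate * V2)
        assert r["patch_birth"] == pytest.approx(sim.rates.patch_birth_rate * V2)
        for name in ("patch_death", "production", "decay", "consumption",
                     "satiation_loss", "death", "reproduction", "movement"):
            assert r[name] == 0.0

    def test_one_satiated_individual(self, intact_landscape):
        sim = make_sim(intact_landscape, scenario=ScenarioConfig(S=4))
        inject_satiated(sim, 0, 5.0, 5.0)
        r = sim.channel_rates()
        assert r["reproduction"] == pytest.approx(sim.rates.reproduction_rate)
        assert r["satiation_loss"] == pytest.approx(sim.rates.satiation_loss_rate)
        assert r["consumption"] == 0.0
        assert r["death"] == 0.0

    def test_consumption_counts_matching_inrange_pairs(self, intact_landscape):
        # 2 deprived individuals x 3 matching in-range particles -> 6 pairs
        sim = make_sim(intact_landscape, scenario=ScenarioConfig(S=4))
        for dx in (0.2, 0.4, 0.6):
            sim._add_particle(0, 5.0 + dx, 5.0)
        sim._add_deprived(0, 5.0, 5.0)
        sim._add_deprived(1, 5.0, 5.2)
        # a far-away individual and a satiated one contribute no pairs
        sim._add_deprived(2, 15.0, 15.0)
        inject_satiated(sim, 3, 5.0, 5.0)
        assert sim.K_pairs == 6
        expected = 6 * sim.rates.consumption_rate
        assert sim.channel_rates()["consumption"] == pytest.approx(expected)

    def test_movement_rate_only_in_active_mode(self, intact_landscape):
        passive = make_sim(intact_landscape, scenario=ScenarioConfig(S=4))
        passive._add_deprived(0, 1.0, 1.0)
        assert passive.channel_rates()["movement"] == 0.0
        active = make_sim(
            intact_landscape,
            scenario=ScenarioConfig(S=4, dispersal_mode="active"),
        )
        active._add_deprived(0, 1.0, 1.0)
        assert active.channel_rates()["movement"] == pytest.approx(
            active.rates.movement_rate
        )


class TestEventSemantics:
    def test_death_removes_exactly_one_deprived(self, intact_landscape):
        sim = make_sim(intact_landscape, scenario=ScenarioConfig(S=4))
        for i in range(5):
            sim._add_deprived(i % 4, 1.0 + i, 2.0)
        before = sim.entity_counts()
        sim._ev_death()
        after = sim.entity_counts()
        assert after["deprived"] == before["deprived"] - 1
        assert after["satiated"] == before["satiated"]
        assert after["particles"] == before["particles"]

    def test_hostile_offspring_in_matrix_is_killed(self):
        land = make_landscape(N=1, C=0.01, V=50.0, seed=3,
                              matrix_mode="hostile")
        f = land.fragments[0]
        rates = RateConstants(dispersal_scale=25.0)
        sim = make_sim(land, rates,
                       ScenarioConfig(S=4, delta=25.0, matrix_mode="hostile"))
        inject_satiated(sim, 0, f.x, f.y)
        kills = births = 0
        for _ in range(300):
            n0 = len(sim.individuals)
            sim._ev_reproduction()
            if len(sim.individuals) == n0:
                kills += 1
            else:
                births += 1
        # with delta >> fragment radius nearly every offspring lands outside
        assert kills > 0
        assert sim.counters["killed_by_matrix"] == kills
        for rec in sim.individuals.values():
            if rec[3] == 0:
                assert land.contains(rec[1], rec[2])

    def test_habitable_production_into_matrix_is_thinned(self):
        land = make_landscape(N=1, C=0.01, V=50.0, seed=3,
                              matrix_mode="habitable")
        sim = make_sim(land, scenario=ScenarioConfig(S=4))
        f = land.fragments[0]
        # patch sitting just inside the fragment edge: some production
        # targets fall outside and must be rejected
        sim.patch_type.append(0)
        sim.patch_x.append(f.x + f.r * 0.9)
        sim.patch_y.append(f.y)
        sim.patch_can.append(True)
        for _ in range(400):
            sim._ev_production()
        assert sim.counters["production_thinned"] > 0
        assert len(sim.particle_list) + sim.counters["production_thinned"] == 400
        for pid in sim.particle_list:
            _, px, py = sim.particles[pid]
            assert land.contains(px, py)

    def test_consumption_transitions_and_conserves(self, intact_landscape):
        sim = make_sim(intact_landscape, scenario=ScenarioConfig(S=4))
        sim._add_particle(0, 5.0, 5.0)
        sim._add_deprived(0, 5.1, 5.0)
        sim._ev_consumption()
        counts = sim.entity_counts()
        assert counts == {"patches": 0, "particles": 0, "deprived": 0,
                          "satiated": 1}
        assert sim.K_pairs == 0

    def test_immigration_uniform_species(self, intact_landscape):
        sim = make_sim(intact_landscape, scenario=ScenarioConfig(S=4), seed=11)
        for _ in range(2000):
            sim._ev_immigration()
        species = np.array([r[0] for r in sim.individuals.values()])
        freq = np.bincount(species, minlength=4) / len(species)
        assert np.all(np.abs(freq - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 2000))


class TestStepAndRun:
    def test_same_seed_bitwise_identical(self, small_landscape):
        snaps = []
        for _ in range(2):
            sim = make_sim(small_landscape, scenario=ScenarioConfig(S=4, T=30),
                           seed=42)
            snaps.append(sim.run(T=30, snapshot_times=(15, 30))[-1])
        a, b = snaps
        assert np.array_equal(a.species, b.species)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.satiated, b.satiated)
        assert np.array_equal(a.particle_x, b.particle_x)
        assert a.counters == b.counters

    def test_snapshot_times_are_honoured(self, small_landscape):
        sim = make_sim(small_landscape, scenario=ScenarioConfig(S=4, T=20))
        snaps = sim.run(T=20, snapshot_times=(5, 10, 20))
        assert [s.time for s in snaps] == [5, 10, 20]

    def test_absorbing_state_fast_forwards(self, intact_landscape):
        rates = RateConstants(patch_birth_rate=TINY, immigration_rate=0.0,
                              particle_production_rate=TINY)
        sim = make_sim(intact_landscape, rates, ScenarioConfig(S=4, T=50))
        snaps = sim.run(T=50, snapshot_times=(25, 50))
        assert [s.time for s in snaps] == [25, 50]
        assert snaps[-1].n_individuals == 0

    def test_explosion_raises_with_channel_name(self, intact_landscape):
        rates = RateConstants(immigration_rate=10.0)
        sim = make_sim(intact_landscape, rates, ScenarioConfig(S=4, T=100),
                       entity_cap=5)
        with pytest.raises(ExplosionError, match="immigration"):
            sim.run(T=100)

    def test_channel_bookkeeping_per_event(self, small_landscape):
        sim = make_sim(small_landscape, scenario=ScenarioConfig(S=4, T=1e9),
                       seed=2)
        prev_counters = dict(sim.counters)
        prev_counts = sim.entity_counts()
        for _ in range(2000):
            if not sim.step():
                break
            cur = dict(sim.counters)
            fired = [c for c in prev_counters
                     if cur[c] > prev_counters[c]
                     and c not in ("production_thinned", "killed_by_matrix")]
            assert len(fired) == 1
            chan = fired[0]
            counts = sim.entity_counts()
            d = {k: counts[k] - prev_counts[k] for k in counts}
            thin = cur["production_thinned"] - prev_counters["production_thinned"]
            kill = cur["killed_by_matrix"] - prev_counters["killed_by_matrix"]
            expected = {
                "patch_birth": {"patches": 1},
                "patch_death": {"patches": -1},
                "production": {"particles": 0 if thin else 1},
                "decay": {"particles": -1},
                "consumption": {"particles": -1, "deprived": -1, "satiated": 1},
                "satiation_loss": {"deprived": 1, "satiated": -1},
                "death": {"deprived": -1},
                "reproduction": {"deprived": 0 if kill else 1},
                "movement": {"deprived": -1 if kill else 0},
                "immigration": {"deprived": 0 if kill else 1},
            }[chan]
            for k, v in d.items():
                assert v == expected.get(k, 0), (chan, d)
            prev_counters, prev_counts = cur, counts
        total_by_channel = sum(
            sim.counters[c]
            for c in sim.counters
            if c not in ("production_thinned", "killed_by_matrix")
        )
        assert total_by_channel == sim.total_events


def ctmc_mean_absorption(rate_matrix):
    """Mean time to absorption from each transient state.

    ``rate_matrix[i][j]`` is the rate from transient state i to transient
    state j (off-diagonal), and absorption is whatever rate is missing from
    the row total ``rate_matrix[i][i]`` (the exit rate).  Solves the
    first-step equations Q m = -1 directly.
    """
    Q = np.asarray(rate_matrix, dtype=float)
    n = Q.shape[0]
    A = Q.copy()
    for i in range(n):
        A[i, i] = -Q[i, i]
    return np.linalg.solve(A, -np.ones(n))


class TestExtinctionTimeOracle:
    def test_single_individual_two_state_chain(self, intact_landscape):
        # satiated -> deprived at sigma, deprived -> dead at d; reproduction
        # and resources effectively off, no immigration
        sigma, d = 0.5, 0.25
        rates = RateConstants(
            patch_birth_rate=TINY, particle_production_rate=TINY,
            consumption_rate=TINY, satiation_loss_rate=sigma,
            death_rate=d, reproduction_rate=TINY, immigration_rate=0.0,
        )
        # exit rates on the diagonal, transition rates off it:
        # state 0 = satiated (-> state 1 at sigma), state 1 = deprived
        expected = ctmc_mean_absorption([[sigma, sigma], [0.0, d]])[0]
        assert expected == pytest.approx(1 / sigma + 1 / d)
        times = []
        for rep in range(400):
            sim = make_sim(intact_landscape, rates, ScenarioConfig(S=4),
                           seed=rep)
            inject_satiated(sim, 0, 5.0, 5.0)
            while sim.individuals:
                sim.step()
            times.append(sim.t)
        mc_mean = np.mean(times)
        mc_se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(mc_mean - expected) <= 3 * mc_se


class TestDispersalKernel:
    @pytest.mark.parametrize("delta", [1.0, 3.0])
    def test_offspring_displacement_variance_scales(self, delta):
        V = 1000.0
        spec = ResourceFieldSpec(n_types=1, amplitude=0.0)
        land = TorusLandscape(V=V, fragments=[], matrix_mode="habitable",
                              resource_spec=spec, intact=True)
        sim = make_sim(land, RateConstants(),
                       ScenarioConfig(S=4, delta=delta), seed=77)
        inject_satiated(sim, 0, V / 2, V / 2)
        disp = []
        for _ in range(10_000):
            sim._ev_reproduction()
            iid = sim._next_id - 1
            rec = sim.individuals[iid]
            disp.append((rec[1] - V / 2, rec[2] - V / 2))
            sim._remove_deprived(iid)
        disp = np.array(disp)
        var = disp.var(axis=0).mean()
        assert var == pytest.approx(delta**2, rel=0.05)


class TestSpatialConsistency:
    def test_pair_counts_match_brute_force(self, rng):
        land = make_landscape(N=4, C=0.2, V=20.0, seed=9)
        sim = make_sim(land, scenario=ScenarioConfig(S=8, T=1e9), seed=5)
        for _ in range(5000):
            sim.step()
        U = sim.rates.utilisation_radius
        total = 0
        for rec in (sim.individuals[i] for i in sim.deprived):
            t = sim.group_of(rec[0])
            k = 0
            for pid in sim.particle_list:
                pt, px, py = sim.particles[pid]
                if pt == t and torus_distance(
                    (rec[1], rec[2]), (px, py), 20.0
                ) <= U:
                    k += 1
            assert k == rec[4]
            total += k
        assert total == sim.K_pairs


class TestMatrixInvariants:
    def test_hostile_matrix_excludes_individuals(self):
        land = make_landscape(N=4, C=0.1, V=20.0, seed=13,
                              matrix_mode="hostile")
        sim = make_sim(land,
                       scenario=ScenarioConfig(S=4, matrix_mode="hostile"),
                       seed=3)
        for i in range(10_000):
            sim.step()
            if i % 500 == 0 and sim.individuals:
                xs = np.array([r[1] for r in sim.individuals.values()])
                ys = np.array([r[2] for r in sim.individuals.values()])
                assert np.all(land.contains(xs, ys))
        if sim.individuals:
            xs = np.array([r[1] for r in sim.individuals.values()])
            ys = np.array([r[2] for r in sim.individuals.values()])
            assert np.all(land.contains(xs, ys))

    @pytest.mark.parametrize("matrix_mode", ["habitable", "hostile"])
    def test_particles_confined_to_habitat(self, matrix_mode):
        land = make_landscape(N=4, C=0.1, V=20.0, seed=13,
                              matrix_mode=matrix_mode)
        sim = make_sim(land,
                       scenario=ScenarioConfig(S=4, matrix_mode=matrix_mode),
                       seed=4)
        for _ in range(8000):
            sim.step()
        for pid in sim.particle_list:
            _, px, py = sim.particles[pid]
            assert land.contains(px, py)


class TestNeutralSymmetry:
    def test_species_abundances_exchangeable(self):
        from scipy.stats import ks_2samp

        spec = ResourceFieldSpec(n_types=1, amplitude=0.0)
        land = TorusLandscape(V=20.0, fragments=[], matrix_mode="habitable",
                              resource_spec=spec, intact=True)
        abund = []
        for rep in range(16):
            sim = make_sim(land, scenario=ScenarioConfig(S=4, T=120),
                           seed=500 + rep)
            snap = sim.run(T=120, snapshot_times=(120,))[-1]
            abund.append(np.bincount(snap.species, minlength=4))
        abund = np.array(abund)
        stat = ks_2samp(abund[:, 0], abund[:, 1])
        assert stat.pvalue > 0.01


class TestScenarioValidation:
    def test_active_hostile_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(dispersal_mode="active", matrix_mode="hostile")

    def test_species_pool_divisibility(self, small_landscape):
        with pytest.raises(ValueError, match="divisible"):
            make_sim(small_landscape, scenario=ScenarioConfig(S=6))

    def test_matrix_mode_mismatch_rejected(self, small_landscape):
        with pytest.raises(ValueError, match="disagree"):
            make_sim(small_landscape,
                     scenario=ScenarioConfig(S=4, matrix_mode="hostile"))

    def test_species_type_blocks(self, small_landscape):
        sim = make_sim(small_landscape, scenario=ScenarioConfig(S=8))
        groups = [sim.group_of(s) for s in range(8)]
        assert groups == [0, 0, 1, 1, 2, 2, 3, 3]


class TestWellMixedReference:
    def test_immigration_death_balance_closed_form(self):
        rates = RateConstants(particle_production_rate=TINY,
                              immigration_rate=0.01, death_rate=0.2)
        eq = wellmixed_ode_reference(rates, area=100.0, n_types=1)
        assert eq["deprived"] == pytest.approx(0.01 * 100 / 0.2, rel=1e-6)
        assert eq["satiated"] == pytest.approx(0.0, abs=1e-9)

    def test_no_consumption_means_no_satiated(self):
        rates = RateConstants(consumption_rate=TINY)
        eq = wellmixed_ode_reference(rates, area=100.0, n_types=1)
        assert eq["satiated"] == pytest.approx(0.0, abs=1e-6)

    def test_patch_equilibrium_closed_form(self):
        rates = RateConstants()
        eq = wellmixed_ode_reference(rates, area=100.0, n_types=4)
        expected = 4 * rates.patch_birth_rate * 100 / rates.patch_death_rate
        assert eq["patches"] == pytest.approx(expected, rel=1e-9)


class TestRateValidation:
    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(death_rate=0.0)
        with pytest.raises(ValueError):
            RateConstants(immigration_rate=-1.0)
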