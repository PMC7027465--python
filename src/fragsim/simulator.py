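"""Exact stochastic simulation of the spatial resource-competition model.

The model is a continuous-time Markov process on locally finite spatial
configurations of three entity kinds living on a V x V torus:

* **resource patches** are born following per-type intensity fields and die
  at a constant per-patch rate;
* **resource particles** are produced by patches into a top-hat
  neighbourhood of radius ``G`` (production is *thinned*: a particle whose
  target position falls in the matrix is never established) and decay at a
  constant per-particle rate;
* **individuals** of ``S`` species are either resource-deprived or
  resource-satiated.  A deprived individual consumes any particle of its
  resource type within the top-hat utilisation radius ``U`` (pairwise rate
  ``consumption_rate`` per in-range pair), becoming satiated.  Satiated
  individuals produce deprived offspring at a Gaussian(delta) displacement
  and relax back to the deprived state; deprived individuals die at a
  constant rate, and (in the active-dispersal mode) relocate by
  Gaussian(delta) jumps.  Deprived immigrants of uniformly random species
  arrive at rate ``immigration_rate`` per unit area.

Under a *hostile* matrix any deprived individual whose new location falls
outside habitat is killed on the spot; under a *habitable* matrix only
resource production is confined to habitat.

The sampler is an exact Gillespie scheme: per-channel aggregate rates,
exponential waiting times, uniform selection within a channel.  Consumption
pairs are maintained incrementally with uniform-grid spatial indices (cell
size = utilisation radius), so every event costs O(neighbourhood).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .landscape import TorusLandscape

__all__ = [
    "RateConstants",
    "ScenarioConfig",
    "Snapshot",
    "Simulation",
    "simulate",
    "wellmixed_ode_reference",
    "ExplosionError",
    "OracleError",
]

CHANNELS = (
    "patch_birth",
    "patch_death",
    "production",
    "decay",
    "consumption",
    "satiation_loss",
    "death",
    "reproduction",
    "movement",
    "immigration",
)


class ExplosionError(RuntimeError):
    """Entity count exceeded the configured cap; names the hottest channel."""


class OracleError(RuntimeError):
    """The mean-field reference failed to converge."""


@dataclass(frozen=True)
class RateConstants:
    """Positive rate constants and kernel scales of the model.

    Defaults were calibrated (scripts/calibrate.py) so that an intact 30x30
    landscape with 8 species keeps the whole species pool alive to T = 400
    with several hundred individuals — small enough for desk-scale
    experiments.  Mean offspring per satiation bout is
    reproduction_rate / satiation_loss_rate = 2.
    """

    patch_birth_rate: float = 4e-4  # per unit area and time, per resource type
    patch_death_rate: float = 0.01  # per patch
    particle_production_rate: float = 0.5  # per patch
    particle_decay_rate: float = 0.025  # per particle
    consumption_rate: float = 0.5  # per in-range deprived/particle pair
    satiation_loss_rate: float = 0.125  # per satiated individual
    death_rate: float = 0.1  # per deprived individual
    reproduction_rate: float = 0.25  # per satiated individual
    movement_rate: float = 0.5  # per deprived individual (active mode)
    immigration_rate: float = 1e-3  # per unit area
    production_radius: float = 1.0  # top-hat kernel G
    utilisation_radius: float = 1.0  # top-hat kernel U
    dispersal_scale: float = 1.0  # Gaussian kernels B and M (delta)

    def __post_init__(self):
        for name in (
            "patch_birth_rate",
            "patch_death_rate",
            "particle_production_rate",
            "particle_decay_rate",
            "consumption_rate",
            "satiation_loss_rate",
            "death_rate",
            "reproduction_rate",
            "movement_rate",
            "production_radius",
            "utilisation_radius",
            "dispersal_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.immigration_rate < 0:
            raise ValueError("immigration_rate must be nonnegative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Community scenario: dispersal mode/scale, species pool, horizon."""

    S: int = 8
    delta: float = 1.0
    dispersal_mode: str = "passive"
    matrix_mode: str | None = None  # None: take from the landscape
    T: float = 400.0
    snapshot_times: tuple[float, ...] | None = None  # default: (T,)
    initial: str = "empty"  # or "wellmixed"

    def __post_init__(self):
        if self.dispersal_mode not in ("passive", "active"):
            raise ValueError(f"unknown dispersal_mode {self.dispersal_mode!r}")
        if self.matrix_mode not in (None, "habitable", "hostile"):
            raise ValueError(f"unknown matrix_mode {self.matrix_mode!r}")
        if self.dispersal_mode == "active" and self.matrix_mode == "hostile":
            raise ValueError(
                "the active-dispersal / hostile-matrix combination is excluded"
            )
        if self.S < 1:
            raise ValueError("species pool S must be >= 1")


class _IndexedList:
    """List with O(1) membership removal and uniform random choice."""

    __slots__ = ("items", "pos")

    def __init__(self):
        self.items: list = []
        self.pos: dict = {}

    def add(self, item) -> None:
        self.pos[item] = len(self.items)
        self.items.append(item)

    def discard(self, item) -> None:
        i = self.pos.pop(item)
        last = self.items.pop()
        if last != item:
            self.items[i] = last
            self.pos[last] = i

    def choose(self, rng: random.Random):
        return self.items[rng.randrange(len(self.items))]

    def __len__(self):
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


class _HabitatIndex:
    """Pure-python point-in-habitat test with per-cell fragment candidates."""

    __slots__ = ("V", "n", "cell", "cands", "intact")

    def __init__(self, landscape: TorusLandscape):
        self.V = V = landscape.V
        self.intact = getattr(landscape, "intact", False) or not landscape.fragments
        if self.intact:
            self.n = 1
            self.cell = V
            self.cands = [[]]
            return
        radii = [f.r for f in landscape.fragments]
        target = max(min(radii), V / 128.0)
        self.n = n = max(1, int(V / target))
        self.cell = s = V / n
        half_diag = s * math.sqrt(0.5)
        cx = (np.arange(n) + 0.5) * s
        fx = np.array([f.x for f in landscape.fragments])
        fy = np.array([f.y for f in landscape.fragments])
        fr = np.array([f.r for f in landscape.fragments])
        dx = np.abs(cx[:, None] - fx[None, :])
        dx = np.minimum(dx, V - dx)
        dy = np.abs(cx[:, None] - fy[None, :])
        dy = np.minimum(dy, V - dy)
        self.cands = []
        for ix in range(n):
            for iy in range(n):
                near = dx[ix] ** 2 + dy[iy] ** 2 <= (fr + half_diag) ** 2
                self.cands.append(
                    [(fx[j], fy[j], fr[j] ** 2) for j in np.flatnonzero(near)]
                )

    def __call__(self, x: float, y: float) -> bool:
        if self.intact:
            return True
        V = self.V
        n = self.n
        ix = int(x / self.cell)
        iy = int(y / self.cell)
        if ix >= n:
            ix = n - 1
        if iy >= n:
            iy = n - 1
        for fx, fy, r2 in self.cands[ix * n + iy]:
            dx = x - fx
            if dx < 0.0:
                dx = -dx
            if dx > V - dx:
                dx = V - dx
            dy = y - fy
            if dy < 0.0:
                dy = -dy
            if dy > V - dy:
                dy = V - dy
            if dx * dx + dy * dy <= r2:
                return True
        return False


@dataclass
class Snapshot:
    """State of the process at a fixed time: entity tables and counters."""

    time: float
    species: np.ndarray  # individuals
    x: np.ndarray
    y: np.ndarray
    satiated: np.ndarray  # bool per individual
    particle_type: np.ndarray
    particle_x: np.ndarray
    particle_y: np.ndarray
    patch_type: np.ndarray
    patch_x: np.ndarray
    patch_y: np.ndarray
    counters: dict

    def individuals_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "species": self.species,
                "x": self.x,
                "y": self.y,
                "satiated": self.satiated,
            }
        )

    @property
    def n_individuals(self) -> int:
        return len(self.species)


from ._grid import SpatialGrid  # noqa: E402  (kept near its sole consumer)


class Simulation:
    """Exact event-driven sampler bound to one landscape and scenario."""

    def __init__(
        self,
        landscape: TorusLandscape,
        rates: RateConstants | None = None,
        scenario: ScenarioConfig | None = None,
        seed: int = 0,
        entity_cap: int = 500_000,
    ):
        self.landscape = landscape
        self.rates = rates or RateConstants()
        self.scenario = scenario or ScenarioConfig()
        self.entity_cap = entity_cap
        self.rng = random.Random(seed)
        self.seed = seed

        spec = landscape.resource_spec
        self.n_types = spec.n_types
        self.S = self.scenario.S
        if self.S % self.n_types:
            raise ValueError(
                f"S={self.S} must be divisible by the number of resource "
                f"types ({self.n_types})"
            )
        self.matrix_mode = self.scenario.matrix_mode or landscape.matrix_mode
        if self.scenario.matrix_mode and (
            self.scenario.matrix_mode != landscape.matrix_mode
        ):
            raise ValueError("scenario and landscape matrix modes disagree")
        if self.scenario.dispersal_mode == "active" and self.matrix_mode == "hostile":
            raise ValueError(
                "the active-dispersal / hostile-matrix combination is excluded"
            )
        self.hostile = self.matrix_mode == "hostile"
        self.active = self.scenario.dispersal_mode == "active"
        self.delta = self.scenario.delta
        self.V = V = landscape.V

        r = self.rates
        self.U = r.utilisation_radius
        self.U2 = self.U**2
        self.G = r.production_radius
        # patch-birth totals: each type integrates to patch_birth_rate * V^2
        self.patch_birth_total = self.n_types * r.patch_birth_rate * V * V
        self.immigration_total = r.immigration_rate * V * V

        # per-type sinusoid parameters for rejection sampling of patch sites
        self._flat = spec.n_types == 1 or spec.amplitude == 0.0
        if not self._flat:
            self._profiles = []
            for t in range(self.n_types):
                u = (np.arange(4096) + 0.5) * (V / 4096)
                raw = spec._raw_profile(u, t, V)
                self._profiles.append(
                    (spec.amplitude, spec.wavenumber, spec.phase(t),
                     spec.exponent, float(raw.max()))
                )
            self._axis = spec.axis

        self._habitat = _HabitatIndex(landscape)
        # patch can-produce flag: disk of radius G intersects some fragment
        self._fx = [f.x for f in landscape.fragments]
        self._fy = [f.y for f in landscape.fragments]
        self._frG = [(f.r + self.G) ** 2 for f in landscape.fragments]
        self._land_intact = self._habitat.intact

        # state ------------------------------------------------------------
        self.t = 0.0
        self._next_id = 0
        self.patch_type: list[int] = []
        self.patch_x: list[float] = []
        self.patch_y: list[float] = []
        self.patch_can: list[bool] = []
        self.particles: dict[int, tuple] = {}
        self.particle_list = _IndexedList()
        self.part_grid = [SpatialGrid(V, self.U) for _ in range(self.n_types)]
        self.individuals: dict[int, list] = {}
        self.deprived = _IndexedList()
        self.satiated = _IndexedList()
        self.ind_grid = [SpatialGrid(V, self.U) for _ in range(self.n_types)]
        self.K_pairs = 0  # total in-range matching (deprived, particle) pairs
        self.counters = {c: 0 for c in CHANNELS}
        self.counters["production_thinned"] = 0
        self.counters["killed_by_matrix"] = 0
        self.total_events = 0
        self._avg_window: tuple[float, float] | None = None
        self._avg_acc = {"patches": 0.0, "particles": 0.0, "deprived": 0.0,
                         "satiated": 0.0}

        if self.scenario.initial == "wellmixed":
            self._warm_start()
        elif self.scenario.initial != "empty":
            raise ValueError(f"unknown initial condition {self.scenario.initial!r}")

    # -- helpers ------------------------------------------------------------

    def group_of(self, species: int) -> int:
        """Resource type consumed by a species (contiguous equal blocks)."""
        return species * self.n_types // self.S

    def _can_produce(self, x: float, y: float) -> bool:
        if self._land_intact:
            return True
        V = self.V
        for fx, fy, rG2 in zip(self._fx, self._fy, self._frG):
            dx = x - fx
            if dx < 0.0:
                dx = -dx
            if dx > V - dx:
                dx = V - dx
            dy = y - fy
            if dy < 0.0:
                dy = -dy
            if dy > V - dy:
                dy = V - dy
            if dx * dx + dy * dy <= rG2:
                return True
        return False

    def _sample_patch_site(self, t: int) -> tuple[float, float]:
        rng = self.rng
        V = self.V
        if self._flat:
            return rng.uniform(0.0, V), rng.uniform(0.0, V)
        A, w, phi, p, raw_max = self._profiles[t]
        two_pi_w = 2.0 * math.pi * w / V
        while True:
            u = rng.uniform(0.0, V)
            s = 1.0 + A * math.sin(two_pi_w * u + phi)
            raw = s**p if s > 0.0 else 0.0
            if rng.random() * raw_max < raw:
                break
        v = rng.uniform(0.0, V)
        return (u, v) if self._axis == 0 else (v, u)

    def _add_particle(self, t: int, x: float, y: float) -> None:
        pid = self._next_id
        self._next_id += 1
        self.particles[pid] = (t, x, y)
        self.particle_list.add(pid)
        self.part_grid[t].insert(pid, x, y)
        U2 = self.U2
        V = self.V
        inds = self.individuals
        for iid in self.ind_grid[t].query(x, y):
            rec = inds[iid]
            dx = x - rec[1]
            if dx < 0.0:
                dx = -dx
            if dx > V - dx:
                dx = V - dx
            dy = y - rec[2]
            if dy < 0.0:
                dy = -dy
            if dy > V - dy:
                dy = V - dy
            if dx * dx + dy * dy <= U2:
                rec[4] += 1
                self.K_pairs += 1

    def _remove_particle(self, pid: int) -> None:
        t, x, y = self.particles.pop(pid)
        self.particle_list.discard(pid)
        self.part_grid[t].remove(pid, x, y)
        U2 = self.U2
        V = self.V
        inds = self.individuals
        for iid in self.ind_grid[t].query(x, y):
            rec = inds[iid]
            dx = x - rec[1]
            if dx < 0.0:
                dx = -dx
            if dx > V - dx:
                dx = V - dx
            dy = y - rec[2]
            if dy < 0.0:
                dy = -dy
            if dy > V - dy:
                dy = V - dy
            if dx * dx + dy * dy <= U2:
                rec[4] -= 1
                self.K_pairs -= 1

    def _count_in_range(self, t: int, x: float, y: float) -> int:
        U2 = self.U2
        V = self.V
        parts = self.particles
        k = 0
        for pid in self.part_grid[t].query(x, y):
            _, px, py = parts[pid]
            dx = x - px
            if dx < 0.0:
                dx = -dx
            if dx > V - dx:
                dx = V - dx
            dy = y - py
            if dy < 0.0:
                dy = -dy
            if dy > V - dy:
                dy = V - dy
            if dx * dx + dy * dy <= U2:
                k += 1
        return k

    def _add_deprived(self, species: int, x: float, y: float) -> None:
        iid = self._next_id
        self._next_id += 1
        t = self.group_of(species)
        k = self._count_in_range(t, x, y)
        self.individuals[iid] = [species, x, y, 0, k]
        self.deprived.add(iid)
        self.ind_grid[t].insert(iid, x, y)
        self.K_pairs += k

    def _remove_deprived(self, iid: int) -> None:
        rec = self.individuals.pop(iid)
        self.deprived.discard(iid)
        self.ind_grid[self.group_of(rec[0])].remove(iid, rec[1], rec[2])
        self.K_pairs -= rec[4]

    def _warm_start(self) -> None:
        """Draw initial counts from the mean-field equilibrium, uniform sites."""
        eq = wellmixed_ode_reference(self.rates, self.V**2, n_types=self.n_types)
        rng = self.rng
        V = self.V

        def poisson(mean: float) -> int:
            # Knuth sampler; means here are modest
            if mean <= 0:
                return 0
            L = math.exp(-mean)
            k, p = 0, 1.0
            while True:
                p *= rng.random()
                if p <= L:
                    return k
                k += 1

        for _ in range(poisson(eq["patches"])):
            t = rng.randrange(self.n_types)
            x, y = self._sample_patch_site(t)
            self.patch_type.append(t)
            self.patch_x.append(x)
            self.patch_y.append(y)
            self.patch_can.append(self._can_produce(x, y))
        for _ in range(poisson(eq["particles"])):
            t = rng.randrange(self.n_types)
            while True:
                x, y = rng.uniform(0.0, V), rng.uniform(0.0, V)
                if self._habitat(x, y):
                    break
            self._add_particle(t, x, y)
        for state_name, mean in (("deprived", eq["deprived"]),
                                 ("satiated", eq["satiated"])):
            for _ in range(poisson(mean)):
                s = rng.randrange(self.S)
                while True:
                    x, y = rng.uniform(0.0, V), rng.uniform(0.0, V)
                    if not self.hostile or self._habitat(x, y):
                        break
                if state_name == "deprived":
                    self._add_deprived(s, x, y)
                else:
                    iid = self._next_id
                    self._next_id += 1
                    self.individuals[iid] = [s, x, y, 1, 0]
                    self.satiated.add(iid)

    # -- rates and stepping --------------------------------------------------

    def channel_rates(self) -> dict[str, float]:
        """Current total rate of every event channel."""
        r = self.rates
        n_patches = len(self.patch_type)
        return {
            "patch_birth": self.patch_birth_total,
            "patch_death": r.patch_death_rate * n_patches,
            "production": r.particle_production_rate * n_patches,
            "decay": r.particle_decay_rate * len(self.particle_list),
            "consumption": r.consumption_rate * self.K_pairs,
            "satiation_loss": r.satiation_loss_rate * len(self.satiated),
            "death": r.death_rate * len(self.deprived),
            "reproduction": r.reproduction_rate * len(self.satiated),
            "movement": (
                r.movement_rate * len(self.deprived) if self.active else 0.0
            ),
            "immigration": self.immigration_total,
        }

    def entity_counts(self) -> dict[str, int]:
        return {
            "patches": len(self.patch_type),
            "particles": len(self.particle_list),
            "deprived": len(self.deprived),
            "satiated": len(self.satiated),
        }

    def step(self) -> bool:
        """Execute one event.  Returns False from an absorbing state."""
        rates = self.channel_rates()
        total = sum(rates.values())
        if total <= 0.0:
            return False
        rng = self.rng
        dt = rng.expovariate(total)
        t_prev = self.t
        self.t = t_prev + dt
        if self._avg_window is not None:
            t0, t1 = self._avg_window
            overlap = min(self.t, t1) - max(t_prev, t0)
            if overlap > 0.0:
                acc = self._avg_acc
                acc["patches"] += overlap * len(self.patch_type)
                acc["particles"] += overlap * len(self.particle_list)
                acc["deprived"] += overlap * len(self.deprived)
                acc["satiated"] += overlap * len(self.satiated)

        u = rng.random() * total
        acc_rate = 0.0
        chan = None
        for name in CHANNELS:
            acc_rate += rates[name]
            if u < acc_rate:
                chan = name
                break
        if chan is None:  # numerical fallthrough
            chan = "immigration"
        self.counters[chan] += 1
        self.total_events += 1
        getattr(self, "_ev_" + chan)()

        n_ent = (len(self.patch_type) + len(self.particle_list)
                 + len(self.individuals))
        if n_ent > self.entity_cap:
            hottest = max(rates, key=rates.get)
            raise ExplosionError(
                f"entity count {n_ent} exceeded cap {self.entity_cap} at "
                f"t={self.t:.2f}; hottest channel: {hottest}"
            )
        return True

    # -- event handlers ------------------------------------------------------

    def _ev_patch_birth(self) -> None:
        t = self.rng.randrange(self.n_types)
        x, y = self._sample_patch_site(t)
        self.patch_type.append(t)
        self.patch_x.append(x)
        self.patch_y.append(y)
        self.patch_can.append(self._can_produce(x, y))

    def _ev_patch_death(self) -> None:
        i = self.rng.randrange(len(self.patch_type))
        for lst in (self.patch_type, self.patch_x, self.patch_y, self.patch_can):
            lst[i] = lst[-1]
            lst.pop()

    def _ev_production(self) -> None:
        rng = self.rng
        i = rng.randrange(len(self.patch_type))
        if not self.patch_can[i]:
            self.counters["production_thinned"] += 1
            return
        rad = self.G * math.sqrt(rng.random())
        theta = rng.random() * 2.0 * math.pi
        x = (self.patch_x[i] + rad * math.cos(theta)) % self.V
        y = (self.patch_y[i] + rad * math.sin(theta)) % self.V
        if not self._habitat(x, y):
            self.counters["production_thinned"] += 1
            return
        self._add_particle(self.patch_type[i], x, y)

    def _ev_decay(self) -> None:
        self._remove_particle(self.particle_list.choose(self.rng))

    def _ev_consumption(self) -> None:
        rng = self.rng
        target = rng.random() * self.K_pairs
        inds = self.individuals
        acc = 0.0
        chosen = None
        for iid in self.deprived.items:
            k = inds[iid][4]
            if k:
                acc += k
                chosen = iid
                if acc > target:
                    break
        rec = inds[chosen]
        t = self.group_of(rec[0])
        x, y = rec[1], rec[2]
        U2 = self.U2
        V = self.V
        parts = self.particles
        cands = []
        for pid in self.part_grid[t].query(x, y):
            _, px, py = parts[pid]
            dx = x - px
            if dx < 0.0:
                dx = -dx
            if dx > V - dx:
                dx = V - dx
            dy = y - py
            if dy < 0.0:
                dy = -dy
            if dy > V - dy:
                dy = V - dy
            if dx * dx + dy * dy <= U2:
                cands.append(pid)
        pid = cands[rng.randrange(len(cands))]
        self._remove_particle(pid)  # also decrements rec[4] and K_pairs
        # deprived -> satiated
        self.deprived.discard(chosen)
        self.ind_grid[t].remove(chosen, x, y)
        self.K_pairs -= rec[4]
        rec[4] = 0
        rec[3] = 1
        self.satiated.add(chosen)

    def _ev_satiation_loss(self) -> None:
        iid = self.satiated.choose(self.rng)
        rec = self.individuals[iid]
        self.satiated.discard(iid)
        rec[3] = 0
        t = self.group_of(rec[0])
        k = self._count_in_range(t, rec[1], rec[2])
        rec[4] = k
        self.K_pairs += k
        self.deprived.add(iid)
        self.ind_grid[t].insert(iid, rec[1], rec[2])

    def _ev_death(self) -> None:
        self._remove_deprived(self.deprived.choose(self.rng))

    def _ev_reproduction(self) -> None:
        rng = self.rng
        iid = self.satiated.choose(rng)
        rec = self.individuals[iid]
        x = (rec[1] + rng.gauss(0.0, self.delta)) % self.V
        y = (rec[2] + rng.gauss(0.0, self.delta)) % self.V
        if self.hostile and not self._habitat(x, y):
            self.counters["killed_by_matrix"] += 1
            return
        self._add_deprived(rec[0], x, y)

    def _ev_movement(self) -> None:
        rng = self.rng
        iid = self.deprived.choose(rng)
        rec = self.individuals[iid]
        x = (rec[1] + rng.gauss(0.0, self.delta)) % self.V
        y = (rec[2] + rng.gauss(0.0, self.delta)) % self.V
        if self.hostile and not self._habitat(x, y):
            self.counters["killed_by_matrix"] += 1
            self._remove_deprived(iid)
            return
        t = self.group_of(rec[0])
        self.ind_grid[t].remove(iid, rec[1], rec[2])
        self.K_pairs -= rec[4]
        rec[1], rec[2] = x, y
        k = self._count_in_range(t, x, y)
        rec[4] = k
        self.K_pairs += k
        self.ind_grid[t].insert(iid, x, y)

    def _ev_immigration(self) -> None:
        rng = self.rng
        s = rng.randrange(self.S)
        x = rng.uniform(0.0, self.V)
        y = rng.uniform(0.0, self.V)
        if self.hostile and not self._habitat(x, y):
            self.counters["killed_by_matrix"] += 1
            return
        self._add_deprived(s, x, y)

    # -- trajectories --------------------------------------------------------

    def snapshot(self, at_time: float | None = None) -> Snapshot:
        inds = list(self.individuals.values())
        return Snapshot(
            time=self.t if at_time is None else at_time,
            species=np.array([r[0] for r in inds], dtype=np.int64),
            x=np.array([r[1] for r in inds], dtype=float),
            y=np.array([r[2] for r in inds], dtype=float),
            satiated=np.array([bool(r[3]) for r in inds], dtype=bool),
            particle_type=np.array(
                [self.particles[p][0] for p in self.particle_list], dtype=np.int64
            ),
            particle_x=np.array(
                [self.particles[p][1] for p in self.particle_list], dtype=float
            ),
            particle_y=np.array(
                [self.particles[p][2] for p in self.particle_list], dtype=float
            ),
            patch_type=np.array(self.patch_type, dtype=np.int64),
            patch_x=np.array(self.patch_x, dtype=float),
            patch_y=np.array(self.patch_y, dtype=float),
            counters=dict(self.counters),
        )

    def run(
        self,
        T: float | None = None,
        snapshot_times: tuple[float, ...] | None = None,
        average_window: tuple[float, float] | None = None,
    ) -> list[Snapshot]:
        """Advance to time T, capturing snapshots at the requested times."""
        T = self.scenario.T if T is None else T
        if snapshot_times is None:
            snapshot_times = self.scenario.snapshot_times or (T,)
        snap_times = sorted(set(snapshot_times))
        if snap_times and snap_times[-1] > T:
            raise ValueError("snapshot times must not exceed the horizon T")
        self._avg_window = average_window
        snapshots: list[Snapshot] = []
        pending = list(snap_times)
        while self.t < T:
            rates = self.channel_rates()
            total = sum(rates.values())
            if total <= 0.0:
                # absorbing configuration: nothing can happen, fast-forward
                t_new = pending[0] if pending else T
                self._advance_clock_only(self.t, t_new)
                self.t = t_new
            else:
                t_before = self.t
                # tentative event time is needed before applying the event so
                # that snapshots see the pre-event state
                dt = -math.log(1.0 - self.rng.random()) / total
                t_event = t_before + dt
                while pending and pending[0] <= t_event and pending[0] <= T:
                    snapshots.append(self.snapshot(at_time=pending.pop(0)))
                if t_event > T:
                    self._advance_clock_only(t_before, T)
                    self.t = T
                    break
                self._apply_prepicked(total, rates, t_before, t_event)
                continue
            while pending and pending[0] <= self.t:
                snapshots.append(self.snapshot(at_time=pending.pop(0)))
        while pending:
            snapshots.append(self.snapshot(at_time=pending.pop(0)))
        return snapshots

    def _advance_clock_only(self, t_prev: float, t_new: float) -> None:
        if self._avg_window is not None:
            t0, t1 = self._avg_window
            overlap = min(t_new, t1) - max(t_prev, t0)
            if overlap > 0.0:
                acc = self._avg_acc
                acc["patches"] += overlap * len(self.patch_type)
                acc["particles"] += overlap * len(self.particle_list)
                acc["deprived"] += overlap * len(self.deprived)
                acc["satiated"] += overlap * len(self.satiated)

    def _apply_prepicked(
        self, total: float, rates: dict, t_prev: float, t_event: float
    ) -> None:
        self._advance_clock_only(t_prev, t_event)
        self.t = t_event
        rng = self.rng
        u = rng.random() * total
        acc_rate = 0.0
        chan = "immigration"
        for name in CHANNELS:
            acc_rate += rates[name]
            if u < acc_rate:
                chan = name
                break
        self.counters[chan] += 1
        self.total_events += 1
        getattr(self, "_ev_" + chan)()
        n_ent = (len(self.patch_type) + len(self.particle_list)
                 + len(self.individuals))
        if n_ent > self.entity_cap:
            hottest = max(rates, key=rates.get)
            raise ExplosionError(
                f"entity count {n_ent} exceeded cap {self.entity_cap} at "
                f"t={self.t:.2f}; hottest channel: {hottest}"
            )

    def time_averages(self) -> dict[str, float]:
        """Mean entity counts over the averaging window passed to run()."""
        if self._avg_window is None:
            raise ValueError("run() was not given an average_window")
        t0, t1 = self._avg_window
        span = min(self.t, t1) - t0
        if span <= 0:
            raise ValueError("averaging window not yet entered")
        return {k: v / span for k, v in self._avg_acc.items()}


def simulate(
    landscape: TorusLandscape,
    rates: RateConstants | None = None,
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    **run_kwargs,
) -> list[Snapshot]:
    """Run one exact trajectory; returns the requested snapshots."""
    sim = Simulation(landscape, rates, scenario, seed=seed)
    return sim.run(**run_kwargs)


def wellmixed_ode_reference(
    rates: RateConstants,
    area: float,
    n_types: int = 1,
    t_max: float = 50_000.0,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Equilibrium mean counts of the mean-field (well-mixed) rate equations.

    Valid as a reference for the spatial process when both top-hat kernels
    cover the whole torus (every particle is in range of every matching
    individual).  Per resource type, with p, q, d, s the mean counts of
    patches, particles, deprived and satiated individuals:

        p' = lambda0 * area - mu_p * p
        q' = nu * p - mu_q * q - c * q * d
        d' = alpha * area / n_types + (b + sigma) * s - d_rate * d - c * q * d
        s' = c * q * d - sigma * s

    Totals over types are returned.  Integration runs until the RHS norm
    falls below ``tol``; failure raises :class:`OracleError`.
    """
    from scipy.integrate import solve_ivp

    r = rates
    p_eq = r.patch_birth_rate * area / r.patch_death_rate

    def rhs(_, yv):
        q, d, s = yv
        cons = r.consumption_rate * q * d
        return [
            r.particle_production_rate * p_eq - r.particle_decay_rate * q - cons,
            r.immigration_rate * area / n_types
            + (r.reproduction_rate + r.satiation_loss_rate) * s
            - r.death_rate * d
            - cons,
            cons - r.satiation_loss_rate * s,
        ]

    sol = solve_ivp(rhs, (0.0, t_max), [0.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-12, atol=1e-12)
    if not sol.success:
        raise OracleError(f"mean-field integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    resid = max(abs(v) for v in rhs(0.0, y_end))
    if resid > tol * max(1.0, max(abs(v) for v in y_end)):
        raise OracleError(
            f"mean-field equations did not reach equilibrium (residual {resid:g})"
        )
    q, d, s = y_end
    return {
        "patches": n_types * p_eq,
        "particles": n_types * q,
        "deprived": n_types * d,
        "satiated": n_types * s,
    }
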