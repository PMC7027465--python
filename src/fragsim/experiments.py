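"""Factorial experiment orchestration and census extraction.

The study design crosses a landscape grid (number of fragments N, habitat
cover C, replicate landscapes) with community scenarios (dispersal scale
delta x dispersal/matrix mode, the active/hostile combination excluded).
Each run produces three censuses of resource-satiated individuals at the
census snapshot: per fragment, per whole landscape, and per fixed-radius
sampling window centred in each sufficiently large fragment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import (
    DEFAULT_COVERS,
    DEFAULT_FRAGMENT_COUNTS,
    DEFAULT_REPLICATES,
    LandscapeDesignPoint,
    ResourceFieldSpec,
    TorusLandscape,
    build_landscape_design,
    derive_seed,
    make_landscape,
)
from .simulator import RateConstants, ScenarioConfig, Simulation, Snapshot

__all__ = [
    "CommunityScenario",
    "default_scenarios",
    "build_full_design",
    "run_manifest_row",
    "census_fragments",
    "census_landscape",
    "census_windows",
    "sample_one_site",
]

DEFAULT_DELTAS = (1.0, 3.0, 10.0)
DEFAULT_MODES = (
    ("passive", "habitable"),
    ("passive", "hostile"),
    ("active", "habitable"),
)


@dataclass(frozen=True)
class CommunityScenario:
    """One cell of the community-scenario grid."""

    delta: float
    dispersal_mode: str
    matrix_mode: str

    def __post_init__(self):
        if self.dispersal_mode == "active" and self.matrix_mode == "hostile":
            raise ValueError(
                "the active-dispersal / hostile-matrix combination is excluded"
            )

    @property
    def label(self) -> str:
        code = {"passive": {"habitable": "P", "hostile": "H"},
                "active": {"habitable": "A"}}[self.dispersal_mode][self.matrix_mode]
        return f"{code}{self.delta:g}"


def default_scenarios(
    deltas=DEFAULT_DELTAS, modes=DEFAULT_MODES
) -> list[CommunityScenario]:
    """The 3 dispersal scales x 3 dispersal/matrix modes = 9 scenarios."""
    return [
        CommunityScenario(delta=d, dispersal_mode=dm, matrix_mode=mm)
        for d, (dm, mm) in itertools.product(deltas, modes)
    ]


def build_full_design(
    landscape_design: list[LandscapeDesignPoint] | None = None,
    scenarios: list[CommunityScenario] | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Manifest with one row per (scenario, N, C, replicate).

    Landscape seeds depend only on (N, C, replicate), so the same replicate
    landscape is shared across scenarios; simulation seeds additionally key
    on the scenario label, so trajectories are independent across scenarios
    yet individually reproducible.
    """
    if landscape_design is None:
        landscape_design = build_landscape_design(master_seed=master_seed)
    if scenarios is None:
        scenarios = default_scenarios()
    rows = []
    for sc in scenarios:
        for dp in landscape_design:
            rows.append(
                {
                    "scenario": sc.label,
                    "delta": sc.delta,
                    "dispersal_mode": sc.dispersal_mode,
                    "matrix_mode": sc.matrix_mode,
                    "N": dp.N,
                    "C": dp.C,
                    "replicate": dp.replicate,
                    "landscape_seed": dp.seed,
                    "sim_seed": derive_seed(
                        master_seed, "sim", sc.label, dp.N, float(dp.C), dp.replicate
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    """Censuses and bookkeeping from one manifest row."""

    row: dict
    landscape: TorusLandscape
    snapshot: Snapshot
    fragment_census: pd.DataFrame
    landscape_census: pd.DataFrame
    window_census: pd.DataFrame
    counters: dict = field(default_factory=dict)


def run_manifest_row(
    row: dict | pd.Series,
    V: float,
    S: int,
    T: float,
    rates: RateConstants | None = None,
    resource_spec: ResourceFieldSpec | None = None,
    tau: float = 1.0,
    entity_cap: int = 500_000,
) -> RunResult:
    """Generate the row's landscape, simulate to T, and census the snapshot."""
    land = make_landscape(
        N=int(row["N"]),
        C=float(row["C"]),
        V=V,
        seed=int(row["landscape_seed"]),
        matrix_mode=row["matrix_mode"],
        resource_spec=resource_spec,
    )
    scenario = ScenarioConfig(
        S=S,
        delta=float(row["delta"]),
        dispersal_mode=row["dispersal_mode"],
        T=T,
    )
    sim = Simulation(land, rates, scenario, seed=int(row["sim_seed"]),
                     entity_cap=entity_cap)
    snap = sim.run(T=T, snapshot_times=(T,))[-1]
    key = {k: row[k] for k in ("scenario", "N", "C", "replicate")}
    return RunResult(
        row=dict(row),
        landscape=land,
        snapshot=snap,
        fragment_census=census_fragments(snap, land, key=key),
        landscape_census=census_landscape(snap, S, key=key),
        window_census=census_windows(snap, land, tau=tau, key=key),
        counters=dict(snap.counters),
    )


def _with_key(df: pd.DataFrame, key: dict | None) -> pd.DataFrame:
    if key:
        for k, v in reversed(list(key.items())):
            df.insert(0, k, v)
    return df


def census_fragments(
    snapshot: Snapshot, landscape: TorusLandscape, key: dict | None = None
) -> pd.DataFrame:
    """Per-(fragment, species) counts of resource-satiated individuals.

    Deprived individuals are ignored; satiated individuals in the matrix
    (possible only under a habitable matrix) belong to no fragment and are
    excluded here, though they still count in the landscape census.
    """
    rows = []
    sat = snapshot.satiated
    if sat.any():
        frag = landscape.fragment_of(snapshot.x[sat], snapshot.y[sat])
        spc = snapshot.species[sat]
        keep = frag >= 0
        if np.any(keep):
            df = pd.DataFrame({"fragment": frag[keep], "species": spc[keep]})
            rows = (
                df.groupby(["fragment", "species"]).size().rename("count")
                .reset_index()
            )
    if isinstance(rows, list):
        rows = pd.DataFrame(columns=["fragment", "species", "count"])
    return _with_key(rows, key)


def census_landscape(
    snapshot: Snapshot, S: int, key: dict | None = None
) -> pd.DataFrame:
    """Whole-torus satiated count per species (all S species, zeros kept)."""
    counts = np.zeros(S, dtype=np.int64)
    sat = snapshot.satiated
    if sat.any():
        uniq, n = np.unique(snapshot.species[sat], return_counts=True)
        counts[uniq] = n
    df = pd.DataFrame({"species": np.arange(S), "count": counts})
    return _with_key(df, key)


def landscape_richness(landscape_census: pd.DataFrame) -> int:
    """Number of species with at least one satiated individual present."""
    return int((landscape_census["count"] >= 1).sum())


def census_windows(
    snapshot: Snapshot,
    landscape: TorusLandscape,
    tau: float = 1.0,
    key: dict | None = None,
) -> pd.DataFrame:
    """Satiated counts within radius-tau windows centred in large fragments.

    Only fragments with radius >= tau are eligible (the window then
    intersects a single fragment).  Zero-count (window, species) pairs are
    omitted; windows with no individuals still appear via the eligibility
    table returned by :func:`eligible_windows`.
    """
    if tau <= 0:
        raise ValueError("window radius tau must be positive")
    rows = []
    frames = eligible_windows(landscape, tau)
    sat = snapshot.satiated
    xs, ys, spc = snapshot.x[sat], snapshot.y[sat], snapshot.species[sat]
    for _, w in frames.iterrows():
        if len(xs):
            dx = np.abs(xs - w.x)
            dx = np.minimum(dx, landscape.V - dx)
            dy = np.abs(ys - w.y)
            dy = np.minimum(dy, landscape.V - dy)
            inside = dx * dx + dy * dy <= tau * tau
            uniq, n = np.unique(spc[inside], return_counts=True)
        else:
            uniq, n = np.array([], dtype=int), np.array([], dtype=int)
        for s, c in zip(uniq, n):
            rows.append(
                {"window": int(w.fragment), "fragment": int(w.fragment),
                 "species": int(s), "count": int(c)}
            )
    df = pd.DataFrame(rows, columns=["window", "fragment", "species", "count"])
    return _with_key(df, key)


def eligible_windows(landscape: TorusLandscape, tau: float = 1.0) -> pd.DataFrame:
    """One window per fragment with radius >= tau, centred at its centre."""
    ft = landscape.fragment_table()
    return ft[ft["r"] >= tau].reset_index(drop=True)


DIRECTIONAL_CELLS = (
    # matrix_mode, N, C — the scaled-down fragmentation contrasts plus two
    # extra habitable cells that spread habitat amount for the regression
    ("hostile", 1, 0.04),
    ("hostile", 64, 0.04),
    ("habitable", 1, 0.32),
    ("habitable", 16, 0.32),
    ("habitable", 4, 0.04),
    ("habitable", 16, 0.04),
)


def directional_experiment(
    master_seed: int = 0,
    R: int = 20,
    V: float = 50.0,
    S: int = 32,
    T: float = 200.0,
    delta: float = 1.0,
    tau: float = 1.0,
    rates: RateConstants | None = None,
    cells=DIRECTIONAL_CELLS,
    entity_cap: int = 500_000,
):
    """Scaled-down replication of the fragmentation contrasts.

    Runs R replicates of each (matrix_mode, N, C) cell at short dispersal
    and returns (richness table, sample-site table, landscape list).  The
    richness table carries landscape richness per replicate; sample sites
    (one uniformly chosen radius-tau window per habitable-matrix replicate)
    feed the habitat-amount regression.  Landscape geometry is shared
    across matrix modes within a (N, C, replicate) triple.
    """
    rates = rates or RateConstants()
    rich_rows = []
    site_rows = []
    landscapes: list[TorusLandscape] = []
    for matrix_mode, N, C in cells:
        for rep in range(1, R + 1):
            land_seed = derive_seed(master_seed, "land", N, float(C), rep)
            sim_seed = derive_seed(
                master_seed, "sim", matrix_mode, N, float(C), rep
            )
            land = make_landscape(N=N, C=C, V=V, seed=land_seed,
                                  matrix_mode=matrix_mode)
            scenario = ScenarioConfig(S=S, delta=delta,
                                      dispersal_mode="passive", T=T)
            sim = Simulation(land, rates, scenario, seed=sim_seed,
                             entity_cap=entity_cap)
            snap = sim.run(T=T, snapshot_times=(T,))[-1]
            key = {"matrix_mode": matrix_mode, "N": N, "C": C, "replicate": rep}
            lc = census_landscape(snap, S)
            rich_rows.append({**key, "richness": landscape_richness(lc)})
            if matrix_mode == "habitable":
                wc = census_windows(snap, land, tau=tau)
                site_rng = np.random.default_rng(
                    derive_seed(master_seed, "site", N, float(C), rep)
                )
                site = sample_one_site(land, wc, site_rng, tau=tau)
                if site is not None:
                    site_rows.append(
                        {**site, "landscape_idx": len(landscapes), **key}
                    )
                    landscapes.append(land)
    richness = pd.DataFrame(rich_rows)
    sites = pd.DataFrame(site_rows)
    return richness, sites, landscapes


HABITAT_AMOUNT_CELLS = ((4, 0.01), (16, 0.04), (4, 0.16), (4, 0.48))


def habitat_amount_experiment(
    master_seed: int = 0,
    R: int = 25,
    V: float = 50.0,
    S: int = 32,
    T: float = 200.0,
    delta: float = 3.0,
    tau: float = 1.0,
    rates: RateConstants | None = None,
    cells=HABITAT_AMOUNT_CELLS,
    entity_cap: int = 500_000,
):
    """Independent sample sites for the habitat-amount regression.

    Passive dispersal, habitable matrix, intermediate dispersal scale by
    default; the (N, C) cells spread local habitat amount over more than a
    decade so the regression has leverage.  One uniformly chosen radius-tau
    sample site per replicate landscape (sites are independent across
    landscapes).  Returns (sites table, landscape list).
    """
    rates = rates or RateConstants()
    site_rows = []
    landscapes: list[TorusLandscape] = []
    for N, C in cells:
        for rep in range(1, R + 1):
            land_seed = derive_seed(master_seed, "haland", N, float(C), rep)
            sim_seed = derive_seed(master_seed, "hasim", N, float(C), rep)
            land = make_landscape(N=N, C=C, V=V, seed=land_seed,
                                  matrix_mode="habitable")
            scenario = ScenarioConfig(S=S, delta=delta,
                                      dispersal_mode="passive", T=T)
            sim = Simulation(land, rates, scenario, seed=sim_seed,
                             entity_cap=entity_cap)
            snap = sim.run(T=T, snapshot_times=(T,))[-1]
            wc = census_windows(snap, land, tau=tau)
            site_rng = np.random.default_rng(
                derive_seed(master_seed, "hasite", N, float(C), rep)
            )
            site = sample_one_site(land, wc, site_rng, tau=tau)
            if site is not None:
                site_rows.append(
                    {**site, "landscape_idx": len(landscapes),
                     "N": N, "C": C, "replicate": rep}
                )
                landscapes.append(land)
    return pd.DataFrame(site_rows), landscapes


def sample_one_site(
    landscape: TorusLandscape,
    window_census: pd.DataFrame,
    rng: np.random.Generator,
    tau: float = 1.0,
) -> dict | None:
    """Pick one eligible window uniformly at random (one site per replicate).

    Returns a record with the window centre, its species richness, and the
    area of the containing fragment, or None when no fragment is large
    enough to contain a window.
    """
    elig = eligible_windows(landscape, tau)
    if len(elig) == 0:
        return None
    i = int(rng.integers(len(elig)))
    w = elig.iloc[i]
    frag_id = int(w.fragment)
    if len(window_census):
        sub = window_census[window_census["window"] == frag_id]
        richness = int((sub["count"] >= 1).sum())
    else:
        richness = 0
    return {
        "x": float(w.x),
        "y": float(w.y),
        "richness": richness,
        "fragment": frag_id,
        "fragment_area": float(w.area),
    }
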