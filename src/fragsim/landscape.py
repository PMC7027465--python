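"""Fragmented torus landscapes.

The simulation arena is a two-dimensional torus of side ``V`` (periodic
boundaries avoid edge effects).  Habitat is a set of ``N`` pairwise disjoint
circular fragments; everything else is the *matrix*, which is either
habitable (resource-free but survivable) or hostile (lethal on entry for
resource-deprived individuals).  Resource production is spatially structured
by per-type sinusoidal intensity fields whose totals are equal in an intact
landscape, so that no resource type is globally advantaged.

This module provides landscape construction, habitat-membership queries,
resource-intensity evaluation, Monte-Carlo estimation of habitat amount in
local landscapes (radius-r balls around sample sites), and the factorial
landscape design used by the experiments module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Fragment",
    "ResourceFieldSpec",
    "TorusLandscape",
    "LandscapeDesignPoint",
    "torus_distance",
    "make_fragments",
    "point_in_habitat",
    "resource_intensity",
    "estimate_local_habitat",
    "build_landscape_design",
    "PlacementError",
]

DEFAULT_FRAGMENT_COUNTS = tuple(4**k for k in range(6))
DEFAULT_COVERS = tuple(sorted({0.48, *(2.0**a / 100.0 for a in range(-3, 6))}))
DEFAULT_REPLICATES = 100


class PlacementError(RuntimeError):
    """Raised when disjoint fragment placement fails (C/N too dense)."""


def _wrap_delta(d: np.ndarray | float, V: float):
    """Signed coordinate difference reduced to [-V/2, V/2)."""
    return (np.asarray(d) + 0.5 * V) % V - 0.5 * V


def torus_distance(p, q, V: float) -> float | np.ndarray:
    """Minimal wrap-around Euclidean distance between points on a V x V torus.

    ``p`` and ``q`` are (x, y) pairs or arrays of shape (..., 2).
    """
    if V <= 0:
        raise ValueError(f"torus side must be positive, got V={V}")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dx = _wrap_delta(p[..., 0] - q[..., 0], V)
    dy = _wrap_delta(p[..., 1] - q[..., 1], V)
    out = np.hypot(dx, dy)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Fragment:
    """A circular habitat fragment centred at (x, y) with radius r."""

    x: float
    y: float
    r: float

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError(f"fragment radius must be positive, got {self.r}")

    @property
    def area(self) -> float:
        return math.pi * self.r**2


@dataclass(frozen=True)
class ResourceFieldSpec:
    """Per-type sinusoidal resource-intensity fields on the torus.

    The intensity of type ``t`` at position ``(x, y)`` is

        lambda_t(x, y) = baseline * c_t * max(0, 1 + amplitude *
                         sin(2*pi*wavenumber*u/V + phase_t)) ** exponent

    where ``u`` is the coordinate along ``axis`` and the phases are evenly
    spaced over the types.  The per-type normalisation constants ``c_t`` are
    chosen so that every type integrates to ``baseline * V**2`` over an
    intact landscape: total resource production is identical across types.
    ``exponent > 1`` makes the gradient nonlinear (peaked rather than purely
    sinusoidal).  With ``n_types=1`` the field is flat (the neutral,
    single-resource variant).
    """

    n_types: int = 4
    baseline: float = 1.0
    amplitude: float = 1.0
    wavenumber: int = 1
    exponent: float = 2.0
    axis: int = 0
    phases: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.baseline < 0:
            raise ValueError("baseline intensity must be nonnegative")
        if self.phases is not None and len(self.phases) != self.n_types:
            raise ValueError("phases must have length n_types")

    def phase(self, type_id: int) -> float:
        if self.phases is not None:
            return self.phases[type_id]
        return 2.0 * math.pi * type_id / self.n_types

    def _raw_profile(self, u: np.ndarray, type_id: int, V: float) -> np.ndarray:
        s = 1.0 + self.amplitude * np.sin(
            2.0 * math.pi * self.wavenumber * u / V + self.phase(type_id)
        )
        return np.maximum(s, 0.0) ** self.exponent

    def normalisation(self, type_id: int, V: float, n_grid: int = 4096) -> float:
        """c_t such that the field integrates to baseline * V**2."""
        if self.n_types == 1 and self.amplitude == 0.0:
            return 1.0
        u = (np.arange(n_grid) + 0.5) * (V / n_grid)
        mean = float(self._raw_profile(u, type_id, V).mean())
        if mean <= 0:
            raise ValueError("degenerate resource profile integrates to zero")
        return 1.0 / mean

    def intensity(self, type_id: int, x, y, V: float) -> float | np.ndarray:
        if not 0 <= type_id < self.n_types:
            raise IndexError(f"resource type {type_id} out of range")
        if self.n_types == 1:
            out = np.broadcast_to(np.float64(self.baseline), np.shape(x)).copy()
            return float(out) if out.ndim == 0 else out
        u = np.asarray(x if self.axis == 0 else y, dtype=float)
        c = self.normalisation(type_id, V)
        out = self.baseline * c * self._raw_profile(u % V, type_id, V)
        return float(out) if out.ndim == 0 else out

    def max_intensity(self, type_id: int, V: float, n_grid: int = 4096) -> float:
        u = (np.arange(n_grid) + 0.5) * (V / n_grid)
        return float(self.intensity(type_id, u, np.zeros(n_grid), V).max())


def resource_intensity(spec: ResourceFieldSpec, type_id: int, p, V: float):
    """Intensity (patch-birth rate density) of resource type ``type_id`` at p."""
    p = np.asarray(p, dtype=float)
    return spec.intensity(type_id, p[..., 0], p[..., 1], V)


@dataclass
class TorusLandscape:
    """A V x V torus partitioned into disjoint circular fragments and matrix."""

    V: float
    fragments: list[Fragment]
    matrix_mode: str = "habitable"
    resource_spec: ResourceFieldSpec = field(default_factory=ResourceFieldSpec)
    seed: int | None = None
    #: full-cover landscape: a disk of area V^2 wraps around the torus, so
    #: C = 1 is represented explicitly as "every point is habitat"
    intact: bool = False

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError("V must be positive")
        if self.matrix_mode not in ("habitable", "hostile"):
            raise ValueError(f"unknown matrix_mode {self.matrix_mode!r}")
        self._fx = np.array([f.x for f in self.fragments], dtype=float)
        self._fy = np.array([f.y for f in self.fragments], dtype=float)
        self._fr = np.array([f.r for f in self.fragments], dtype=float)

    # -- geometry ----------------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def cover(self) -> float:
        """Habitat cover fraction sum(pi r_i^2) / V^2."""
        if self.intact:
            return 1.0
        return float(np.pi * np.sum(self._fr**2) / self.V**2)

    @property
    def habitat_area(self) -> float:
        return float(np.pi * np.sum(self._fr**2))

    def contains(self, x, y):
        """Habitat membership of point(s); vectorised over x, y."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.intact:
            out = np.ones(np.broadcast_shapes(x.shape, y.shape), dtype=bool)
            return bool(out) if out.ndim == 0 else out
        if self._fr.size == 0:
            out = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=bool)
            return bool(out) if out.ndim == 0 else out
        dx = _wrap_delta(x[..., None] - self._fx, self.V)
        dy = _wrap_delta(y[..., None] - self._fy, self.V)
        out = np.any(dx * dx + dy * dy <= self._fr**2, axis=-1)
        return bool(out) if out.ndim == 0 else out

    def fragment_of(self, x, y) -> int | np.ndarray:
        """Index of the fragment containing each point, -1 in the matrix."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.intact:
            out = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=np.int64)
            return int(out) if out.ndim == 0 else out
        dx = _wrap_delta(x[..., None] - self._fx, self.V)
        dy = _wrap_delta(y[..., None] - self._fy, self.V)
        inside = dx * dx + dy * dy <= self._fr**2
        # fragments are disjoint: at most one can contain a point
        idx = np.where(inside.any(axis=-1), inside.argmax(axis=-1), -1)
        return int(idx) if idx.ndim == 0 else idx

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        spec = self.resource_spec
        return {
            "V": self.V,
            "matrix_mode": self.matrix_mode,
            "fragments": [{"x": f.x, "y": f.y, "r": f.r} for f in self.fragments],
            "resource_spec": {
                "n_types": spec.n_types,
                "baseline": spec.baseline,
                "amplitude": spec.amplitude,
                "wavenumber": spec.wavenumber,
                "exponent": spec.exponent,
                "axis": spec.axis,
                "phases": list(spec.phases) if spec.phases is not None else None,
            },
            "seed": self.seed,
            "intact": self.intact,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TorusLandscape":
        rs = d.get("resource_spec", {})
        phases = rs.get("phases")
        spec = ResourceFieldSpec(
            n_types=rs.get("n_types", 4),
            baseline=rs.get("baseline", 1.0),
            amplitude=rs.get("amplitude", 1.0),
            wavenumber=rs.get("wavenumber", 1),
            exponent=rs.get("exponent", 2.0),
            axis=rs.get("axis", 0),
            phases=tuple(phases) if phases is not None else None,
        )
        frags = [Fragment(f["x"], f["y"], f["r"]) for f in d["fragments"]]
        return cls(
            V=d["V"],
            fragments=frags,
            matrix_mode=d.get("matrix_mode", "habitable"),
            resource_spec=spec,
            seed=d.get("seed"),
            intact=d.get("intact", False),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TorusLandscape":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def fragment_table(self):
        """Fragments as a DataFrame (id, x, y, r, area)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "fragment": np.arange(self.n_fragments),
                "x": self._fx,
                "y": self._fy,
                "r": self._fr,
                "area": np.pi * self._fr**2,
            }
        )


def point_in_habitat(landscape: TorusLandscape, p) -> bool | np.ndarray:
    """True iff point ``p`` (or each row of an array) lies inside a fragment."""
    p = np.asarray(p, dtype=float)
    return landscape.contains(p[..., 0], p[..., 1])


def make_fragments(
    N: int,
    C: float,
    V: float,
    rng: np.random.Generator,
    radius_sigma: float = 0.0,
    max_attempts: int = 100_000,
) -> list[Fragment]:
    """Place N disjoint circular fragments of total cover C on a V x V torus.

    Radii are equal, r = sqrt(C V^2 / (N pi)), unless ``radius_sigma > 0``,
    in which case radii are lognormal with that log-scale sigma, rescaled so
    the total area is exactly C V^2.  Centres are drawn uniformly with
    rejection until all pairwise torus centre distances are at least the sum
    of radii (disjointness).  Placement is retried from scratch up to
    ``max_attempts`` total draws; failure raises :class:`PlacementError`.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 < C <= 1:
        raise ValueError("cover C must be in (0, 1]")
    if V <= 0:
        raise ValueError("V must be positive")

    if radius_sigma > 0:
        raw = np.exp(rng.normal(0.0, radius_sigma, size=N))
        radii = raw * math.sqrt(C * V**2 / (math.pi * np.sum(raw**2)))
        radii = np.sort(radii)[::-1]  # place large fragments first
    else:
        radii = np.full(N, math.sqrt(C * V**2 / (N * math.pi)))

    xs = np.empty(N)
    ys = np.empty(N)
    attempts = 0
    placed = 0
    while placed < N:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {N} disjoint fragments with cover {C} on a "
                f"{V}x{V} torus after {max_attempts} attempts"
            )
        attempts += 1
        x, y = rng.uniform(0.0, V, size=2)
        if placed:
            dx = _wrap_delta(x - xs[:placed], V)
            dy = _wrap_delta(y - ys[:placed], V)
            if np.any(dx * dx + dy * dy < (radii[placed] + radii[:placed]) ** 2):
                continue
        xs[placed], ys[placed] = x, y
        placed += 1
    return [Fragment(float(x), float(y), float(r)) for x, y, r in zip(xs, ys, radii)]


def make_landscape(
    N: int,
    C: float,
    V: float,
    seed: int | None = None,
    matrix_mode: str = "habitable",
    resource_spec: ResourceFieldSpec | None = None,
    radius_sigma: float = 0.0,
) -> TorusLandscape:
    """Convenience constructor: place fragments from a seed and wrap them."""
    rng = np.random.default_rng(seed)
    if N == 1 and C == 1.0:
        # full cover: every point is habitat (a single disk of area V^2
        # would wrap around the torus, so the intact case is explicit)
        frags = [Fragment(V / 2, V / 2, math.sqrt(V**2 / math.pi))]
        return TorusLandscape(
            V=V,
            fragments=frags,
            matrix_mode=matrix_mode,
            resource_spec=resource_spec or ResourceFieldSpec(),
            seed=seed,
            intact=True,
        )
    frags = make_fragments(N, C, V, rng, radius_sigma=radius_sigma)
    return TorusLandscape(
        V=V,
        fragments=frags,
        matrix_mode=matrix_mode,
        resource_spec=resource_spec or ResourceFieldSpec(),
        seed=seed,
    )


def estimate_local_habitat(
    landscape: TorusLandscape,
    center,
    r: float,
    n_samples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of habitat area within torus distance r of center.

    For ``r <= V/2`` the radius-r ball embeds injectively in the torus, so we
    sample uniformly in the disk and return ``pi r^2`` times the habitat hit
    fraction.  For larger radii the disk wraps onto itself; to count every
    torus location exactly once we instead sample uniformly over the whole
    torus and test ball membership with the torus metric, returning ``V^2``
    times the hit fraction.  Both estimators are unbiased.
    """
    if r <= 0:
        raise ValueError("local-landscape radius must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng or np.random.default_rng()
    cx, cy = float(center[0]), float(center[1])
    V = landscape.V
    if r <= V / 2:
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_samples)
        rad = r * np.sqrt(rng.uniform(0.0, 1.0, size=n_samples))
        x = (cx + rad * np.cos(theta)) % V
        y = (cy + rad * np.sin(theta)) % V
        frac = float(np.mean(landscape.contains(x, y)))
        return math.pi * r**2 * frac
    x = rng.uniform(0.0, V, size=n_samples)
    y = rng.uniform(0.0, V, size=n_samples)
    dx = _wrap_delta(x - cx, V)
    dy = _wrap_delta(y - cy, V)
    in_ball = dx * dx + dy * dy <= r * r
    hit = in_ball & landscape.contains(x, y)
    return V**2 * float(np.mean(hit))


@dataclass(frozen=True)
class LandscapeDesignPoint:
    """One cell of the factorial landscape design."""

    N: int
    C: float
    replicate: int
    seed: int


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic per-run seed (< 2^31) from a master seed and keys.

    Floats are keyed by their IEEE bit pattern so that e.g. C = 0.48 hashes
    stably across platforms.
    """
    ints = []
    for k in keys:
        if isinstance(k, float):
            ints.append(np.frombuffer(np.float64(k).tobytes(), dtype=np.uint32))
        elif isinstance(k, str):
            b = k.encode()
            b = b.ljust(-(-len(b) // 4) * 4, b"\0")
            ints.append(np.frombuffer(b, dtype=np.uint32))
        else:
            ints.append(np.array([int(k) & 0xFFFFFFFF], dtype=np.uint32))
    entropy = [int(master_seed)] + [int(v) for arr in ints for v in np.atleast_1d(arr)]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def build_landscape_design(
    fragment_counts: Sequence[int] = DEFAULT_FRAGMENT_COUNTS,
    covers: Sequence[float] = DEFAULT_COVERS,
    n_replicates: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
) -> list[LandscapeDesignPoint]:
    """Cartesian product of fragment counts, covers and replicates.

    Defaults reproduce the factorial design N in {4^k : 0<=k<=5}, C in
    {0.48} union {2^a/100 : -3<=a<=5}, 100 replicates -> 6000 design points.
    Each point carries a reproducible seed derived from the master seed.
    """
    design = []
    for N in fragment_counts:
        for C in covers:
            for rep in range(1, n_replicates + 1):
                design.append(
                    LandscapeDesignPoint(
                        N=N,
                        C=C,
                        replicate=rep,
                        seed=derive_seed(master_seed, "land", N, float(C), rep),
                    )
                )
    return design
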