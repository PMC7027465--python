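"""SLOSS curves and species-fragmented-area relationship (SFAR) tables.

The SLOSS ("single large or several small") analysis accumulates habitat
fragments from smallest to largest and from largest to smallest, plotting
cumulative species number against cumulative habitat amount.  The signed
area ``I`` between the two curves, normalised by the total cover ``C``,
summarises the effect of fragmentation *per se*: ``I/C > 0`` means several
small fragments hold more species than a single large one of the same total
area, ``I/C < 0`` the reverse, and ``I/C = 0`` is the pure sample-area
(habitat-amount) expectation.

Two accumulation conventions are provided.  ``union`` (default) counts the
number of *distinct* species present in the first k fragments of each
replicate and averages those curves over replicates, so the curve saturates
at the realised species pool.  ``sum_of_averages`` computes S_k as the sum
over the first k sorted fragments of the replicate-averaged per-fragment
species counts; this is the literal cumulative formula but double-counts
species shared between fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SlossCurvePair",
    "SlossStatistic",
    "sloss_curves",
    "sloss_integral",
    "sfar_table",
]


@dataclass
class SlossCurvePair:
    """Cumulative (habitat, species) curves for both sort orders.

    Arrays include the (0, 0) anchor.  ``A`` values are cumulative habitat,
    as a fraction of the landscape area V^2 (so the last value is the cover
    C) unless the pair was built with ``x_axis='absolute'``.
    """

    A_increasing: np.ndarray
    S_increasing: np.ndarray
    A_decreasing: np.ndarray
    S_decreasing: np.ndarray
    mode: str = "union"
    x_axis: str = "cover_fraction"


@dataclass
class SlossStatistic:
    """Signed area between the two SLOSS curves and its normalised value."""

    I: float
    I_over_C: float
    C: float


def _sorted_fragments(areas: pd.DataFrame, decreasing: bool) -> pd.DataFrame:
    # area ties broken by fragment id (ascending in both orders, so that
    # identical fragments yield exactly coincident curves)
    df = areas.sort_values(
        ["area", "fragment"], ascending=[not decreasing, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def _replicate_curve(
    census: pd.DataFrame, areas: pd.DataFrame, decreasing: bool, mode: str
):
    """Cumulative (areas, species) for one replicate, without the anchor."""
    order = _sorted_fragments(areas, decreasing)
    A = np.cumsum(order["area"].to_numpy(dtype=float))
    present = census[census["count"] >= 1]
    by_frag = {
        f: set(g["species"]) for f, g in present.groupby("fragment")
    }
    if mode == "union":
        seen: set = set()
        S = np.empty(len(order))
        for i, f in enumerate(order["fragment"]):
            seen |= by_frag.get(f, set())
            S[i] = len(seen)
    elif mode == "sum_of_averages":
        S = np.cumsum([len(by_frag.get(f, ())) for f in order["fragment"]])
    else:
        raise ValueError(f"unknown SLOSS mode {mode!r}")
    return A, S.astype(float)


def sloss_curves(
    fragment_census: pd.DataFrame,
    fragment_areas: pd.DataFrame,
    V: float | None = None,
    mode: str = "union",
    x_axis: str = "cover_fraction",
) -> SlossCurvePair:
    """Replicate-averaged SLOSS curve pair.

    Parameters
    ----------
    fragment_census
        Columns (replicate, fragment, species, count); zero counts may be
        omitted.
    fragment_areas
        Columns (replicate, fragment, area); every fragment of every
        replicate landscape, including empty ones.
    V
        Torus side; required for ``x_axis='cover_fraction'``.
    mode
        'union' or 'sum_of_averages' (see module docstring).
    """
    if len(fragment_areas) == 0:
        raise ValueError("fragment_areas is empty")
    if x_axis not in ("cover_fraction", "absolute"):
        raise ValueError(f"unknown x_axis {x_axis!r}")
    if x_axis == "cover_fraction" and V is None:
        raise ValueError("V is required for the cover-fraction axis")

    reps = sorted(fragment_areas["replicate"].unique())
    n_frags = fragment_areas.groupby("replicate").size()
    if n_frags.nunique() != 1:
        raise ValueError("replicates disagree on fragment count")

    out = {}
    for decreasing in (False, True):
        A_all, S_all = [], []
        for rep in reps:
            ar = fragment_areas[fragment_areas["replicate"] == rep]
            ce = fragment_census[fragment_census.get("replicate", -1) == rep] \
                if "replicate" in fragment_census.columns else fragment_census
            A, S = _replicate_curve(ce, ar, decreasing, mode)
            A_all.append(A)
            S_all.append(S)
        A_mean = np.mean(A_all, axis=0)
        S_mean = np.mean(S_all, axis=0)
        if x_axis == "cover_fraction":
            A_mean = A_mean / V**2
        out[decreasing] = (
            np.concatenate([[0.0], A_mean]),
            np.concatenate([[0.0], S_mean]),
        )
    return SlossCurvePair(
        A_increasing=out[False][0],
        S_increasing=out[False][1],
        A_decreasing=out[True][0],
        S_decreasing=out[True][1],
        mode=mode,
        x_axis=x_axis,
    )


def sloss_integral(curves: SlossCurvePair, C: float | None = None) -> SlossStatistic:
    """Trapezoid integral I of (increasing - decreasing) and I/C.

    Positive I means the smallest-first accumulation dominates: several
    small fragments outperform a single large one.  The curves must share
    their endpoints (both orders exhaust the same fragments).
    """
    Ai, Si = curves.A_increasing, curves.S_increasing
    Ad, Sd = curves.A_decreasing, curves.S_decreasing
    scale = max(abs(Ai[-1]), abs(Si[-1]), 1.0)
    if (
        abs(Ai[-1] - Ad[-1]) > 1e-9 * scale
        or abs(Si[-1] - Sd[-1]) > 1e-9 * scale
    ):
        raise ValueError("SLOSS curves do not share endpoints")
    grid = np.union1d(Ai, Ad)
    inc = np.interp(grid, Ai, Si)
    dec = np.interp(grid, Ad, Sd)
    I = float(np.trapezoid(inc - dec, grid))
    if C is None:
        C = float(Ai[-1])
    if C <= 0:
        raise ValueError("total cover C must be positive")
    return SlossStatistic(I=I, I_over_C=I / C, C=C)


def sfar_table(landscape_censuses: pd.DataFrame) -> pd.DataFrame:
    """Mean landscape richness per design cell.

    Input columns: (N, C, replicate, species, count), optionally a
    'scenario' column which is kept as an extra group key.  Richness of a
    replicate is the number of species with count >= 1; the table reports
    its mean and Monte-Carlo standard error over replicates.
    """
    keys = [k for k in ("scenario", "N", "C") if k in landscape_censuses.columns]
    if not keys:
        raise ValueError("need at least one of scenario/N/C columns")
    rich = (
        landscape_censuses.assign(present=landscape_censuses["count"] >= 1)
        .groupby(keys + ["replicate"])["present"]
        .sum()
        .rename("richness")
        .reset_index()
    )
    def _sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (
        rich.groupby(keys)["richness"]
        .agg(richness_mean="mean", richness_sem=_sem, n_replicates="size")
        .reset_index()
    )
    return out


def plot_sloss(curves: SlossCurvePair, ax=None):
    """Plot the two cumulative curves (smallest-first vs largest-first)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curves.A_increasing, curves.S_increasing, color="tab:orange",
            label="smallest first")
    ax.plot(curves.A_decreasing, curves.S_decreasing, color="tab:blue",
            label="largest first")
    ax.set_xlabel(
        "cumulative habitat cover"
        if curves.x_axis == "cover_fraction"
        else "cumulative habitat area"
    )
    ax.set_ylabel("cumulative species number")
    ax.legend()
    return ax


def plot_sfar(table: pd.DataFrame, ax=None):
    """Log-log landscape richness vs cover, one line per fragment count."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for N, sub in table.groupby("N"):
        sub = sub.sort_values("C")
        ax.errorbar(sub["C"], sub["richness_mean"], yerr=sub["richness_sem"],
                    marker="o", label=f"N={N}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("habitat cover C")
    ax.set_ylabel("mean landscape richness")
    ax.legend()
    return ax
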