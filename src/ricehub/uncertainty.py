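"""Polyhedral uncertainty sets built from simulated production series.

The pipeline turns a per-region daily production series into

1. a *scenario dataset* — either every simulated (day, value) point, or only
   the highest 15% of values (the less conservative scenario);
2. a *nominal* series — the per-day mean, the value the optimizer treats as
   the expected production;
3. a *deviation cloud* — points (t, u) with u = value - nominal(t);
4. a bounded polyhedron {zeta : M zeta <= q}, the 2-D convex hull of the
   deviation cloud, one per region and scenario.

Each hull edge becomes one inequality a*t + b*u <= c (rows of M are unit
normals).  The robust counterpart consumes the 1-D slice of this set at a
chosen planning day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PHASE_COVID

__all__ = [
    "PolyhedralSet",
    "ScenarioDataset",
    "DeviationCloud",
    "select_scenario",
    "nominal_series",
    "deviations",
    "build_polyhedron",
    "contains",
]


# ---------------------------------------------------------------------------
# polyhedral sets


@dataclass(frozen=True)
class PolyhedralSet:
    """Polyhedron {zeta : M zeta <= q} with rows normalized to unit norm.

    For the 2-D production sets zeta = (t, u): day index and deviation in
    tons.  ``vertices`` stores the generating hull vertices (counter-
    clockwise) when the set was built from a point cloud.
    """

    M: np.ndarray
    q: np.ndarray
    vertices: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.M, dtype=float))
        q = np.asarray(self.q, dtype=float).ravel()
        if M.shape[0] != q.shape[0]:
            raise ValueError("M and q row counts differ")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "q", q)

    @property
    def n_rows(self) -> int:
        return self.M.shape[0]

    @property
    def dim(self) -> int:
        return self.M.shape[1]

    def contains(self, point, tol: float = 1e-9) -> bool:
        """Membership test M zeta <= q with relative tolerance."""
        point = np.asarray(point, dtype=float).ravel()
        if point.shape[0] != self.dim:
            raise ValueError("dimension mismatch")
        slack = tol * np.maximum(1.0, np.abs(self.q))
        return bool(np.all(self.M @ point <= self.q + slack))

    def slice_u(self, t: float, tol: float = 1e-9) -> tuple[float, float]:
        """Interval {u : (t, u) in set} of a 2-D (t, u) set at fixed day t.

        Raises ValueError if the slice is empty or unbounded.
        """
        if self.dim != 2:
            raise ValueError("slice_u requires a 2-D (t, u) set")
        lo, hi = -math.inf, math.inf
        for (a, b), c in zip(self.M, self.q):
            if abs(b) < 1e-14:
                if a * t > c + tol * max(1.0, abs(c)):
                    raise ValueError(f"day t={t} lies outside the set")
            else:
                bound = (c - a * t) / b
                if b > 0:
                    hi = min(hi, bound)
                else:
                    lo = max(lo, bound)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError("slice is unbounded; set has no finite u-range here")
        if lo > hi + tol * max(1.0, abs(hi)):
            raise ValueError(f"day t={t} lies outside the set")
        return (min(lo, hi), hi)

    def render(self, var: str = "u", axis: str = "t") -> list[str]:
        """Human-readable inequality rows, u <= m*t + k style where possible."""
        lines = []
        for (a, b), c in zip(self.M, self.q):
            if abs(b) < 1e-14:
                op = "<=" if a > 0 else ">="
                lines.append(f"{axis} {op} {c / a:.7f}")
            else:
                m, k = -a / b, c / b
                op = "<=" if b > 0 else ">="
                sign = "+" if k >= 0 else "-"
                lines.append(f"{var} {op} {m:.7f}*{axis} {sign} {abs(k):.5f}")
        return lines


def contains(pset: PolyhedralSet, point, tol: float = 1e-9) -> bool:
    return pset.contains(point, tol=tol)


# ---------------------------------------------------------------------------
# scenario construction


@dataclass
class ScenarioDataset:
    """Per-region set of (day, value) production points for one scenario."""

    scenario: str  # "all_data" | "top15"
    region: str
    points: pd.DataFrame  # columns: day, value, repetition


@dataclass
class DeviationCloud:
    """Per-region deviations u = value - nominal(day), as (t, u) points."""

    region: str
    points: np.ndarray  # (n, 2) array of (t, u)


TOP15_FRACTION = 0.15


def select_scenario(series: pd.DataFrame, mode: str, phase: str = PHASE_COVID) -> dict[str, ScenarioDataset]:
    """Build per-region scenario datasets from a production series.

    mode="all_data" keeps every (day, value) point across repetitions;
    mode="top15" keeps the ceil(0.15 n) largest values per region, ties
    broken by earlier day then lower repetition index.  Points keep their
    original day index (the top-15% filter destroys day contiguity).
    """
    if mode not in ("all_data", "top15"):
        raise ValueError(f"unknown scenario mode {mode!r}")
    df = series
    if "phase" in df.columns and (df["phase"] == phase).any():
        df = df[df["phase"] == phase]
    if df.empty:
        raise ValueError("empty production series")
    out: dict[str, ScenarioDataset] = {}
    for region, grp in df.groupby("region", sort=False):
        pts = grp.rename(columns={"production_tons": "value"})[
            ["day", "value", "repetition"]
        ].reset_index(drop=True)
        if mode == "top15":
            n_keep = math.ceil(TOP15_FRACTION * len(pts))
            pts = (
                pts.sort_values(["value", "day", "repetition"], ascending=[False, True, True])
                .head(n_keep)
                .reset_index(drop=True)
            )
        out[str(region)] = ScenarioDataset(scenario=mode, region=str(region), points=pts)
    return out


def nominal_series(dataset: ScenarioDataset) -> pd.Series:
    """Per-day mean of the dataset values (the nominal production)."""
    return dataset.points.groupby("day")["value"].mean()


def deviations(dataset: ScenarioDataset, nominal: pd.Series) -> DeviationCloud:
    """Deviation cloud u = value - nominal(day) for every point of the dataset."""
    days = dataset.points["day"].to_numpy()
    missing = set(days) - set(nominal.index)
    if missing:
        raise ValueError(f"days missing from nominal series: {sorted(missing)[:5]}")
    u = dataset.points["value"].to_numpy() - nominal.loc[days].to_numpy()
    pts = np.column_stack([days.astype(float), u])
    return DeviationCloud(region=dataset.region, points=pts)


# ---------------------------------------------------------------------------
# convex hull -> inequality system


def _monotone_chain(points: np.ndarray) -> np.ndarray:
    """2-D convex hull, counter-clockwise, collinear points dropped."""
    pts = np.unique(points, axis=0)
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1])


DEGENERATE_PAD = 1e-6


def build_polyhedron(cloud: DeviationCloud | np.ndarray, pad: float = DEGENERATE_PAD) -> PolyhedralSet:
    """Convex hull of a (t, u) cloud as an inequality system M zeta <= q.

    Each hull edge contributes one row oriented to contain the interior;
    rows are normalized to unit normal length.  Degenerate clouds (all
    points collinear) are represented as a 2-row slab around the supporting
    line, padded by ``pad`` tons so the set has interior.
    """
    pts = cloud.points if isinstance(cloud, DeviationCloud) else np.asarray(cloud, dtype=float)
    pts = np.atleast_2d(pts)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct points to build a polyhedron")

    hull = _monotone_chain(uniq)
    if len(hull) < 3:
        # collinear: slab normal to the segment direction
        p0 = uniq[0]
        rel = uniq - p0
        span = uniq[np.argmax(np.abs(rel).sum(axis=1))] - p0
        span = span / np.max(np.abs(span))  # rescale first: avoids underflow
        d = span / np.linalg.norm(span)
        n = np.array([-d[1], d[0]])
        M = np.vstack([n, -n])
        q = np.array([n @ p0 + pad, -(n @ p0) + pad])
        return PolyhedralSet(M=M, q=q, vertices=_monotone_chain(uniq))

    rows, rhs = [], []
    m = len(hull)
    for idx in range(m):
        p1, p2 = hull[idx], hull[(idx + 1) % m]
        e = p2 - p1
        a, b = e[1], -e[0]
        norm = math.hypot(a, b)
        rows.append([a / norm, b / norm])
        rhs.append((a * p1[0] + b * p1[1]) / norm)
    return PolyhedralSet(M=np.array(rows), q=np.array(rhs), vertices=hull)


# ---------------------------------------------------------------------------
# set files


def write_set_file(pset: PolyhedralSet, path) -> None:
    """Write a set as delimited rows a,b,c of a*t + b*u <= c, with the
    human-readable inequality rendering as leading comment lines."""
    with open(path, "w") as fh:
        for line in pset.render():
            fh.write(f"# {line}\n")
        fh.write("a,b,c\n")
        for (a, b), c in zip(pset.M, pset.q):
            fh.write(f"{float(a)!r},{float(b)!r},{float(c)!r}\n")


def read_set_file(path) -> PolyhedralSet:
    rows = pd.read_csv(path, comment="#")
    return PolyhedralSet(M=rows[["a", "b"]].to_numpy(), q=rows["c"].to_numpy())
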