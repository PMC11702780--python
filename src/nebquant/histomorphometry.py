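"""Muscle fiber cross-section morphometry and fiber-type composition.

Fiber outlines (traced on dystrophin-stained sections) arrive as planar
polygons.  Per fiber the module computes the area (shoelace formula) and the
minimum Feret diameter — the smallest caliper width over all orientations,
the standard fiber-size metric because it is robust to oblique sectioning.
Tiny outlines (area below a threshold, default 300 in the native unit) are
discarded as segmentation artifacts, sizes are binned into half-open
minimum-Feret classes, and fiber-type call tables (I/IIa/IIx/IIb) are
summarized as per-sample percentages with group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

FIBER_TYPES = ("I", "IIa", "IIx", "IIb")


@dataclass
class FiberOutline:
    fiber_id: str
    vertices: np.ndarray  # (n, 2), ordered boundary; closing edge implied
    unit: str = "um"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        v = _collapse_repeats(v)
        if v.shape[0] < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        self.vertices = v

    def validate_simple(self) -> None:
        """Raise if the outline self-intersects (O(n^2) segment check)."""
        if not _is_simple(self.vertices):
            raise ValueError(f"fiber {self.fiber_id}: polygon self-intersects")


@dataclass
class FiberMetrics:
    fiber_id: str
    area: float
    min_feret: float
    unit: str = "um"


def _collapse_repeats(v: np.ndarray) -> np.ndarray:
    keep = np.ones(len(v), dtype=bool)
    keep[1:] = np.any(v[1:] != v[:-1], axis=1)
    v = v[keep]
    if len(v) > 1 and np.all(v[0] == v[-1]):  # explicit closure
        v = v[:-1]
    return v


def _is_simple(v: np.ndarray) -> bool:
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def crosses(a, b, c, d) -> bool:
        def orient(p, q, r):
            return np.sign((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))
        return (orient(a, b, c) != orient(a, b, d)) and (orient(c, d, a) != orient(c, d, b))

    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):  # adjacent edges share a vertex
                continue
            if crosses(*segs[i], *segs[j]):
                return False
    return True


def polygon_area(outline: FiberOutline | np.ndarray) -> float:
    """Absolute shoelace area; independent of vertex orientation."""
    v = outline.vertices if isinstance(outline, FiberOutline) else _collapse_repeats(np.asarray(outline, float))
    if len(v) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def min_feret(outline: FiberOutline | np.ndarray) -> float:
    """Minimum Feret (caliper) diameter by rotating calipers on the hull.

    The minimum projection width of a convex polygon is attained
    perpendicular to one of its edges, so it suffices to scan hull edges and
    take, for each, the farthest hull vertex from the supporting line.
    Equals the min Feret of the raw (possibly non-convex) outline because
    caliper width only sees the convex hull.
    """
    v = outline.vertices if isinstance(outline, FiberOutline) else _collapse_repeats(np.asarray(outline, float))
    try:
        hull = ConvexHull(v)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) polygon") from exc
    pts = v[hull.vertices]
    n = len(pts)
    best = np.inf
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        ex, ey = q - p
        norm = np.hypot(ex, ey)
        if norm == 0:
            continue
        # distances of all hull points from the line through this edge
        d = np.abs((ex * (pts[:, 1] - p[1]) - ey * (pts[:, 0] - p[0])) / norm)
        best = min(best, float(d.max()))
    if not np.isfinite(best):
        raise ValueError("degenerate polygon")
    return best


def compute_metrics(outlines: list[FiberOutline]) -> list[FiberMetrics]:
    return [
        FiberMetrics(o.fiber_id, polygon_area(o), min_feret(o), unit=o.unit)
        for o in outlines
    ]


def filter_fibers(metrics: list[FiberMetrics], min_area: float = 300.0) -> list[FiberMetrics]:
    """Discard fibers with area strictly below ``min_area`` (artifacts)."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return [m for m in metrics if m.area >= min_area]


def bin_by_min_feret(
    metrics: list[FiberMetrics] | np.ndarray,
    bin_width: float = 5.0,
    origin: float = 0.0,
) -> pd.DataFrame:
    """Histogram of minimum Feret diameters in half-open bins [lo, hi).

    Returns a DataFrame with bin_left, bin_right, count and relative
    frequency (summing to 1 unless the input is empty).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(metrics) and isinstance(next(iter(metrics)), FiberMetrics):
        values = np.array([m.min_feret for m in metrics], dtype=float)
    else:
        values = np.asarray(metrics, dtype=float)
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count", "frequency"])
    idx = np.floor((values - origin) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    left = origin + np.arange(n_bins) * bin_width
    return pd.DataFrame(
        {
            "bin_left": left,
            "bin_right": left + bin_width,
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )


def type_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fiber-type percentages from a long call table.

    ``calls`` needs columns ``sample_id`` and ``type`` (values among
    I, IIa, IIx, IIb); one row per fiber.  Percentages per sample sum to
    100.
    """
    missing = {"sample_id", "type"} - set(calls.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(calls["type"]) - set(FIBER_TYPES)
    if bad:
        raise ValueError(f"unknown fiber types: {sorted(bad)}")
    counts = pd.crosstab(calls["sample_id"], calls["type"]).reindex(
        columns=list(FIBER_TYPES), fill_value=0
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero fibers")
    return 100.0 * counts.div(totals, axis=0)


def summarize_proportions(
    per_sample: pd.DataFrame, groups: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Group mean and SD of per-sample fiber-type percentages.

    ``groups`` maps sample_id to a group label (e.g. genotype); without it a
    single overall summary is returned.
    """
    df = per_sample.copy()
    if groups is None:
        df["group"] = "all"
    else:
        df["group"] = pd.Series(groups).reindex(df.index)
    out = df.groupby("group").agg(["mean", "std"])
    out.columns = [f"{t}_{stat}" for t, stat in out.columns]
    return out
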