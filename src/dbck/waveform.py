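"""Flagellar centerline extraction and head-frame alignment.

The centerline of a single sperm flagellum is traced from a grayscale
image (threshold -> skeletonize -> longest geodesic path through the
skeleton pixel graph), smoothed, and expressed as an
arclength-parametrized polyline in nanometres. `align_to_head_frame`
rotates/translates (and, when the chirality marker demands it, mirrors)
the polyline so that the head long axis lies along +x, the neck sits at
the origin, and +y is the sperm's right side. `resample` puts the
polyline on a uniform arclength grid, the form required by the
sliding-filament computations downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from ._geom import unit

__all__ = [
    "Polyline",
    "HeadFrame",
    "Waveform",
    "trace_centerline",
    "align_to_head_frame",
    "resample",
]


@dataclass
class Polyline:
    """An ordered chain of 2-D points (nm) with cumulative arclength."""

    points: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 2:
            raise ValueError("a polyline needs at least 2 points")
        if np.any(self.segment_lengths <= 0):
            raise ValueError("consecutive points must be distinct")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength per point, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


@dataclass
class HeadFrame:
    """The rigid (plus optional mirror) transform into head coordinates."""

    origin: np.ndarray           # neck point in the source frame (nm)
    x_axis: np.ndarray           # unit vector mapped onto +x
    flipped: bool = False        # whether a mirror flip about x was applied

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        if abs(np.linalg.norm(self.x_axis) - 1.0) > 1e-12:
            self.x_axis = unit(self.x_axis)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map points from the source frame into the head frame."""
        pts = np.asarray(pts, dtype=float)
        if pts.ndim == 1:
            return self.apply(pts[None, :])[0]
        ex = self.x_axis
        ey = np.array([-ex[1], ex[0]])
        out = np.column_stack([(pts - self.origin) @ ex,
                               (pts - self.origin) @ ey])
        if self.flipped:
            out = out * np.array([1.0, -1.0])
        return out


@dataclass
class Waveform:
    """Head-frame centerline on a uniform arclength grid.

    ``s`` starts at 0 with constant spacing ``ds``; the point at s=0 is
    the neck (the origin of the head frame).
    """

    s: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.s) == len(self.x) == len(self.y)):
            raise ValueError("s, x, y must have equal length")
        if len(self.s) < 2:
            raise ValueError("waveform needs at least 2 samples")
        if abs(self.s[0]) > 1e-9:
            raise ValueError("s must start at 0")
        steps = np.diff(self.s)
        if np.ptp(steps) > 1e-9 * max(1.0, steps[0]):
            raise ValueError("s grid must be uniform")

    @property
    def ds(self) -> float:
        return float(self.s[1] - self.s[0])

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def mirrored(self) -> "Waveform":
        """The specimen mirrored about the head axis (y -> -y)."""
        return Waveform(self.s.copy(), self.x.copy(), -self.y)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    rows, cols = np.nonzero(skel)
    nodes = set(zip(rows.tolist(), cols.tolist()))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (r, c) in nodes:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in nodes:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _prune_spurs(g: nx.Graph, min_len: float) -> None:
    """Remove endpoint branches shorter than `min_len` pixels (in place)."""
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        for ep in endpoints:
            if ep not in g:
                continue
            chain = [ep]
            cur, prev = ep, None
            length = 0.0
            while g.degree(cur) <= 2:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["weight"]
                prev, cur = cur, nxt
                if g.degree(cur) > 2:
                    break
                chain.append(cur)
            # only prune genuine spurs that hang off a junction
            if g.degree(cur) > 2 and length < min_len:
                g.remove_nodes_from(chain)
                changed = True


def _smooth_moving_average(pts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks near the ends so the
    tips are kept (a hard requirement for arclength fidelity)."""
    if window <= 1 or len(pts) < 3:
        return pts
    half = window // 2
    out = np.empty_like(pts)
    n = len(pts)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = pts[i - h:i + h + 1].mean(axis=0)
    return out


def trace_centerline(
    image: np.ndarray,
    seed_point: tuple[float, float],
    pixel_size_nm: float,
    smooth_window: int = 5,
    spur_length_px: float = 10.0,
    min_length_px: float = 10.0,
    crop_at_seed: bool = False,
) -> Polyline:
    """Trace the flagellar centerline from a grayscale image.

    Parameters
    ----------
    image
        2-D grayscale image, one specimen.
    seed_point
        (col, row) pixel coordinate on or near the flagellum; the traced
        path starts at the skeleton endpoint nearest this point.
    pixel_size_nm
        Physical pixel size; the output polyline is in nm with
        x = col * pixel_size_nm, y = row * pixel_size_nm.
    smooth_window
        Moving-average window (samples) applied to the pixel chain.
    spur_length_px
        Skeleton side-branches shorter than this are pruned.
    min_length_px
        Minimum acceptable path length; shorter skeletons raise.
    crop_at_seed
        If True, return only the portion of the path from the vertex
        nearest the seed to the far end (drops e.g. the head skeleton).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.max() <= img.min():
        raise ValueError("no foreground: image is constant")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise ValueError("no foreground after thresholding")
    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        raise ValueError("no foreground: empty skeleton")
    # keep the connected component nearest the seed
    seed_rc = (float(seed_point[1]), float(seed_point[0]))
    comps = list(nx.connected_components(g))
    best = min(comps, key=lambda comp: min(
        (n[0] - seed_rc[0]) ** 2 + (n[1] - seed_rc[1]) ** 2 for n in comp))
    g = g.subgraph(best).copy()
    _prune_spurs(g, spur_length_px)
    if g.number_of_nodes() < 2:
        raise ValueError("skeleton too short after pruning")
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if not endpoints:  # a cycle: break at the node nearest the seed
        start = min(g.nodes, key=lambda n: (n[0] - seed_rc[0]) ** 2 +
                    (n[1] - seed_rc[1]) ** 2)
    else:
        start = min(endpoints, key=lambda n: (n[0] - seed_rc[0]) ** 2 +
                    (n[1] - seed_rc[1]) ** 2)
    dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
    far = max(dist, key=dist.get)
    if dist[far] < min_length_px:
        raise ValueError(
            f"no skeleton path of at least {min_length_px} px")
    path = nx.dijkstra_path(g, start, far, weight="weight")
    pts_px = np.array([(c, r) for (r, c) in path], dtype=float)
    if crop_at_seed:
        seed_xy = np.array([seed_point[0], seed_point[1]], dtype=float)
        i0 = int(np.argmin(np.linalg.norm(pts_px - seed_xy, axis=1)))
        # keep the longer side of the path from the seed vertex
        if i0 < len(pts_px) - 1 - i0:
            pts_px = pts_px[i0:]
        else:
            pts_px = pts_px[:i0 + 1][::-1]
    pts_px = _smooth_moving_average(pts_px, smooth_window)
    # collapse any duplicates the smoothing may create
    keep = np.concatenate([[True],
                           np.linalg.norm(np.diff(pts_px, axis=0),
                                          axis=1) > 1e-12])
    return Polyline(pts_px[keep] * float(pixel_size_nm))


def align_to_head_frame(
    polyline: Polyline,
    head_axis: np.ndarray,
    neck_point: np.ndarray,
    pc_on_left: bool = False,
) -> tuple[Polyline, HeadFrame]:
    """Rotate/translate a polyline into the head-anchored frame.

    ``head_axis`` is the unit vector of the head long axis (the
    direction mapped onto +x); ``neck_point`` becomes the origin. If
    ``pc_on_left`` the specimen is mirror-flipped about the x-axis so
    the proximal centriole ends up on the sperm's right (+y), the COSA
    convention; the flip is recorded in the returned HeadFrame.
    """
    frame = HeadFrame(origin=np.asarray(neck_point, dtype=float),
                      x_axis=unit(head_axis), flipped=bool(pc_on_left))
    return Polyline(frame.apply(polyline.points)), frame


def resample(polyline: Polyline, ds: float) -> Waveform:
    """Resample a polyline onto the uniform grid 0, ds, 2ds, ...

    Linear interpolation along arclength; total length is preserved to
    within one grid step.
    """
    total = polyline.length
    if not 0 < ds < total:
        raise ValueError(f"ds must lie in (0, {total}); got {ds}")
    s_in = polyline.arclength
    n = int(np.floor(total / ds + 1e-9)) + 1
    grid = np.arange(n) * ds
    x = np.interp(grid, s_in, polyline.points[:, 0])
    y = np.interp(grid, s_in, polyline.points[:, 1])
    return Waveform(grid, x, y)
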