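"""Signed nanometric measurements of sperm-neck substructures.

Works on two input kinds: landmark tables (endpoints of the proximal
centriole (PC) axis, distal centriole (DC) rods, DC microtubule edges,
segmented-column (SC) chains, neck midline and head axis) and raw
localization point clouds of the DC rods (STORM-style).

Sign conventions (specimen oriented by COSA: PC on the sperm's right,
+y; larger rod on the left, −y):

* rod / microtubule / SC displacement ``d`` is the projection of
  (right − left) on the *rostral* direction of the neck midline:
  positive when the right-side structure sits more rostral ("higher")
  than the left, negative when lower.
* PC lateral shift is the signed perpendicular offset of the PC
  midpoint from the neck midline, positive on the right, negative on
  the left.
* angles are signed, in degrees, in (−180, 180].

Every signed metric is odd under a mirror flip of the specimen.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from ._geom import (perp_distance_to_line, rotation_matrix, signed_angle,
                    signed_lateral_offset, unit)

__all__ = [
    "NeckLandmarks",
    "RodPointCloud",
    "NeckMetrics",
    "profile_extent_50",
    "rod_sliding",
    "pc_metrics",
    "head_neck_angle",
    "sc_metrics",
    "mt_distances_from_pc_centerline",
    "roi_sum_intensity",
    "compute_neck_metrics",
]

DEFAULT_BIN_NM = 20.0
DEFAULT_ROI_DIAMETER_NM = 1500.0

# Multi-point landmark fields stored as (k, 2) arrays; two-point axes are
# ordered rostral-first.
_POINT_FIELDS = (
    "neck_midline", "head_axis", "pc_axis", "rod_left", "rod_right",
    "mt_left", "mt_right", "mt_center", "sc_left", "sc_right",
    "bars_left", "bars_right",
)


@dataclass
class NeckLandmarks:
    """Neck landmark coordinates (nm) for one specimen.

    Two-point axes (``neck_midline``, ``head_axis``, ``pc_axis``,
    ``rod_*``, ``bars_*``) are ordered [rostral, caudal]. ``mt_*`` are
    single rostral endpoints. ``sc_*`` hold the ordered segment
    positions, numbered from the topmost (most rostral) segment as 1.
    Optional fields may be None; metrics depending on them are skipped.
    """

    neck_midline: np.ndarray
    head_axis: np.ndarray
    pc_axis: Optional[np.ndarray] = None
    rod_left: Optional[np.ndarray] = None
    rod_right: Optional[np.ndarray] = None
    mt_left: Optional[np.ndarray] = None
    mt_right: Optional[np.ndarray] = None
    mt_center: Optional[np.ndarray] = None
    sc_left: Optional[np.ndarray] = None
    sc_right: Optional[np.ndarray] = None
    bars_left: Optional[np.ndarray] = None
    bars_right: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in _POINT_FIELDS:
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))
        for rod_name in ("rod_left", "rod_right"):
            rod = getattr(self, rod_name)
            if rod is not None and np.allclose(rod[0], rod[1]):
                raise ValueError(f"{rod_name} endpoints coincide")

    # -- frame operations ------------------------------------------------
    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "NeckLandmarks":
        """Apply p -> R p + t to every stored point."""
        out = {}
        for name in _POINT_FIELDS:
            val = getattr(self, name)
            out[name] = None if val is None else val @ rotation.T + translation
        return NeckLandmarks(**out)

    def to_frame(self, frame) -> "NeckLandmarks":
        """Map all points through a waveform.HeadFrame."""
        out = {}
        for name in _POINT_FIELDS:
            val = getattr(self, name)
            out[name] = None if val is None else frame.apply(val)
        return NeckLandmarks(**out)

    def mirrored(self) -> "NeckLandmarks":
        """Mirror about the head axis (negate y); left/right labels swap."""
        flip = np.array([1.0, -1.0])
        def m(v):
            return None if v is None else v * flip
        return NeckLandmarks(
            neck_midline=m(self.neck_midline),
            head_axis=m(self.head_axis),
            pc_axis=m(self.pc_axis),
            rod_left=m(self.rod_right),
            rod_right=m(self.rod_left),
            mt_left=m(self.mt_right),
            mt_right=m(self.mt_left),
            mt_center=m(self.mt_center),
            sc_left=m(self.sc_right),
            sc_right=m(self.sc_left),
            bars_left=m(self.bars_right),
            bars_right=m(self.bars_left),
        )

    def with_noise(self, sd: float, rng: np.random.Generator) -> "NeckLandmarks":
        """Add i.i.d. Gaussian noise (sd nm) to every coordinate."""
        out = {}
        for name in _POINT_FIELDS:
            val = getattr(self, name)
            out[name] = None if val is None else val + rng.normal(0.0, sd,
                                                                  val.shape)
        return NeckLandmarks(**out)

    # -- directions ------------------------------------------------------
    @property
    def rostral_dir(self) -> np.ndarray:
        """Unit rostral direction of the neck midline."""
        return unit(self.neck_midline[0] - self.neck_midline[1])

    @property
    def head_rostral_dir(self) -> np.ndarray:
        return unit(self.head_axis[0] - self.head_axis[1])


@dataclass
class RodPointCloud:
    """Raw localizations of one DC rod (ThunderSTORM-like columns)."""

    xyz: np.ndarray        # (N, 3), nm
    intensity: np.ndarray  # (N,)
    side: str              # "left" | "right"

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.xyz.shape[0] == 0:
            raise ValueError("empty localization cloud")
        if self.xyz.shape[1] == 2:  # allow 2-D input, pad z
            self.xyz = np.column_stack([self.xyz, np.zeros(len(self.xyz))])
        if not np.isfinite(self.xyz).all():
            raise ValueError("non-finite localization coordinates")
        if len(self.intensity) != len(self.xyz):
            raise ValueError("intensity length mismatch")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def xy(self) -> np.ndarray:
        """Beat-plane projection (the beat is planar; z is kept only for
        extent measurements along z)."""
        return self.xyz[:, :2]

    def mirrored(self) -> "RodPointCloud":
        flip = np.array([1.0, -1.0, 1.0])
        other = "right" if self.side == "left" else "left"
        return RodPointCloud(self.xyz * flip, self.intensity.copy(), other)


@dataclass
class NeckMetrics:
    """One specimen's neck measurements (nm and degrees)."""

    d_rod_rostral: Optional[float] = None
    d_rod_caudal: Optional[float] = None
    d_mt_rostral: Optional[float] = None
    rod_length_left: Optional[float] = None
    rod_length_right: Optional[float] = None
    rod_width_left: Optional[float] = None
    rod_width_right: Optional[float] = None
    pc_dc_angle: Optional[float] = None
    pc_lateral_shift: Optional[float] = None
    head_neck_angle: Optional[float] = None
    sc_segment_d: Optional[np.ndarray] = None
    sc_inter_segment_angles: Optional[np.ndarray] = None
    mt_dist_left: Optional[float] = None
    mt_dist_center: Optional[float] = None
    mt_dist_right: Optional[float] = None

    def as_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                for i, vi in enumerate(v, start=1):
                    out[f"{f.name}_{i}"] = float(vi)
            else:
                out[f.name] = v
        return out


# ---------------------------------------------------------------------------
# localization-cloud morphometry
# ---------------------------------------------------------------------------

def profile_extent_50(cloud: RodPointCloud, axis: np.ndarray,
                      bin_nm: float = DEFAULT_BIN_NM,
                      use_z: bool = False) -> float:
    """Structure extent along ``axis`` by the 50%-of-peak rule.

    Localizations are projected on the axis and binned into an
    intensity-weighted histogram (the rendered-image line profile). The
    extent is the distance between the 50%-of-first-peak crossing
    outward (rostral of the first local maximum) and the corresponding
    crossing outward of the last local maximum, with linear
    interpolation between bin centers. Invariant to rescaling all
    intensities by a positive constant.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be positive")
    if len(cloud.xyz) < 10:
        raise ValueError("need at least 10 localizations")
    axis = np.asarray(axis, dtype=float)
    if use_z:
        pts = cloud.xyz
        if len(axis) == 2:
            axis = np.append(axis, 0.0)
    else:
        pts = cloud.xy
        axis = axis[:2]
    t = pts @ unit(axis)
    if np.ptp(t) == 0:
        raise ValueError("all points project identically: no profile")
    nbins = max(3, int(np.ceil(np.ptp(t) / bin_nm)))
    hist, edges = np.histogram(t, bins=nbins, weights=cloud.intensity)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if hist.max() <= 0:
        raise ValueError("no local maximum in intensity profile")
    # genuine peaks only: prominence-gated so shot-noise bumps in the
    # tails never count as the "first" or "last" intensity peak
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(hist, prominence=0.25 * hist.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(hist))])
    first, last = peaks[0], peaks[-1]

    def cross_out(peak: int, direction: int) -> float:
        level = 0.5 * hist[peak]
        i = peak
        while 0 <= i + direction < len(hist) and hist[i + direction] >= level:
            i += direction
        j = i + direction
        if j < 0 or j >= len(hist):
            # profile never drops below half within the data: clip at the
            # outer edge of the terminal bin
            return float(edges[0] if direction < 0 else edges[-1])
        # linear interpolation between bin centers i and j
        f = (hist[i] - level) / (hist[i] - hist[j])
        return float(centers[i] + f * (centers[j] - centers[i]))

    lo = cross_out(first, -1)
    hi = cross_out(last, +1)
    return hi - lo


def _rod_axes(landmarks: NeckLandmarks, side: str) -> tuple[np.ndarray, np.ndarray]:
    rod = getattr(landmarks, f"rod_{side}")
    if rod is None:
        raise ValueError(f"rod_{side} endpoints missing")
    along = unit(rod[0] - rod[1])
    across = rotation_matrix(np.pi / 2) @ along
    return along, across


def rod_extents(cloud: RodPointCloud, landmarks: NeckLandmarks,
                bin_nm: float = DEFAULT_BIN_NM,
                method: str = "profile") -> tuple[float, float]:
    """(length, width) of a rod cloud along/across its landmark axis.

    ``method='profile'`` uses the 50%-peak rule on the rendered line
    profile (default); ``method='range'`` uses the raw localization
    span.
    """
    along, across = _rod_axes(landmarks, cloud.side)
    if method == "profile":
        return (profile_extent_50(cloud, along, bin_nm),
                profile_extent_50(cloud, across, bin_nm))
    if method == "range":
        t1 = cloud.xy @ along
        t2 = cloud.xy @ across
        return float(np.ptp(t1)), float(np.ptp(t2))
    raise ValueError("method must be 'profile' or 'range'")


# ---------------------------------------------------------------------------
# landmark metrics
# ---------------------------------------------------------------------------

def rod_sliding(landmarks: NeckLandmarks) -> tuple[float, float, Optional[float]]:
    """(d_rod_caudal, d_rod_rostral, d_mt_rostral), signed nm.

    d = projection of (right − left) on the rostral direction of the
    neck midline, evaluated at the matching endpoints. The DC
    microtubules are connected to the axoneme, so only their rostral
    distance is measured.
    """
    if landmarks.rod_left is None or landmarks.rod_right is None:
        raise ValueError("rod endpoints missing")
    u = landmarks.rostral_dir
    d_rostral = float((landmarks.rod_right[0] - landmarks.rod_left[0]) @ u)
    d_caudal = float((landmarks.rod_right[1] - landmarks.rod_left[1]) @ u)
    d_mt = None
    if landmarks.mt_left is not None and landmarks.mt_right is not None:
        d_mt = float((landmarks.mt_right - landmarks.mt_left) @ u)
    return d_caudal, d_rostral, d_mt


def pc_metrics(landmarks: NeckLandmarks) -> tuple[float, float]:
    """(pc_dc_angle in degrees, pc_lateral_shift in signed nm).

    The angle is the signed angle from the neck-midline rostral
    direction to the PC-axis rostral direction; the lateral shift is
    the signed perpendicular offset of the PC midpoint from the neck
    midline (right positive, left negative).
    """
    if landmarks.pc_axis is None:
        raise ValueError("pc_axis missing")
    u = landmarks.rostral_dir
    v = unit(landmarks.pc_axis[0] - landmarks.pc_axis[1])
    angle = np.degrees(signed_angle(u, v))
    midpoint = landmarks.pc_axis.mean(axis=0)
    shift = signed_lateral_offset(midpoint, landmarks.neck_midline[1], u)
    return float(angle), float(shift)


def head_neck_angle(landmarks: NeckLandmarks) -> float:
    """Signed angle (degrees) from the head long axis to the neck midline."""
    return float(np.degrees(signed_angle(landmarks.head_rostral_dir,
                                         landmarks.rostral_dir)))


def sc_metrics(landmarks: NeckLandmarks) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment displacement and inter-segment angles of the SCs.

    Returns (d, angles): ``d[i]`` is the signed rostral displacement of
    right segment i+1 relative to left segment i+1 (same convention as
    rod sliding). ``angles[i]`` is the signed angle (degrees) between
    the vector from segment-pair midpoint i+1 to midpoint i+2 and the
    caudal direction of the neck midline; with 9 segments this yields 8
    angles, and a chain bent between segments 8 and 9 shows its largest
    angle in the last entry.
    """
    if landmarks.sc_left is None or landmarks.sc_right is None:
        raise ValueError("SC chains missing")
    if len(landmarks.sc_left) != len(landmarks.sc_right):
        raise ValueError("SC chains have unequal segment counts")
    u = landmarks.rostral_dir
    d = (landmarks.sc_right - landmarks.sc_left) @ u
    mid = 0.5 * (landmarks.sc_left + landmarks.sc_right)
    vec = np.diff(mid, axis=0)             # rostral->caudal chain vectors
    caudal = -u
    angles = np.array([np.degrees(signed_angle(caudal, v)) for v in vec])
    return np.asarray(d, dtype=float), angles


def mt_distances_from_pc_centerline(
        landmarks: NeckLandmarks) -> tuple[float, float, float]:
    """Distances (nm) from the PC long-axis line to the left, center and
    right DC microtubule rostral endpoints."""
    if landmarks.pc_axis is None:
        raise ValueError("pc_axis missing")
    for name in ("mt_left", "mt_center", "mt_right"):
        if getattr(landmarks, name) is None:
            raise ValueError(f"{name} missing")
    p0 = landmarks.pc_axis[1]
    direction = landmarks.pc_axis[0] - landmarks.pc_axis[1]
    return tuple(
        perp_distance_to_line(getattr(landmarks, name), p0, direction)
        for name in ("mt_left", "mt_center", "mt_right"))


def roi_sum_intensity(image: np.ndarray, center_nm: np.ndarray,
                      pixel_size_nm: float,
                      diameter_nm: float = DEFAULT_ROI_DIAMETER_NM) -> float:
    """Pixel-sum intensity inside a round ROI (default 1.5 µm diameter).

    ``center_nm`` is (x, y) in the image's nm coordinates
    (x = col * pixel_size, y = row * pixel_size); a pixel contributes
    when its center falls inside the disc.
    """
    img = np.asarray(image, dtype=float)
    cx, cy = float(center_nm[0]), float(center_nm[1])
    r = diameter_nm / 2.0
    rows = np.arange(img.shape[0]) * pixel_size_nm
    cols = np.arange(img.shape[1]) * pixel_size_nm
    mask = ((cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2) <= r ** 2
    if not mask.any():
        raise ValueError("ROI does not cover any pixel center")
    return float(img[mask].sum())


def compute_neck_metrics(landmarks: NeckLandmarks,
                         clouds: Optional[dict] = None,
                         bin_nm: float = DEFAULT_BIN_NM) -> NeckMetrics:
    """All landmark (and optionally cloud) metrics for one specimen.

    Metrics whose landmarks are missing are left as None rather than
    raising, so partially annotated specimens degrade gracefully.
    """
    m = NeckMetrics()
    m.head_neck_angle = head_neck_angle(landmarks)
    if landmarks.rod_left is not None and landmarks.rod_right is not None:
        m.d_rod_caudal, m.d_rod_rostral, m.d_mt_rostral = rod_sliding(landmarks)
    if landmarks.pc_axis is not None:
        m.pc_dc_angle, m.pc_lateral_shift = pc_metrics(landmarks)
        if all(getattr(landmarks, n) is not None
               for n in ("mt_left", "mt_center", "mt_right")):
            (m.mt_dist_left, m.mt_dist_center,
             m.mt_dist_right) = mt_distances_from_pc_centerline(landmarks)
    if landmarks.sc_left is not None and landmarks.sc_right is not None:
        m.sc_segment_d, m.sc_inter_segment_angles = sc_metrics(landmarks)
    if clouds:
        for side, cloud in clouds.items():
            try:
                length, width = rod_extents(cloud, landmarks, bin_nm)
            except ValueError:
                continue
            setattr(m, f"rod_length_{side}", length)
            setattr(m, f"rod_width_{side}", width)
    return m
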