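"""Seeded generator of synthetic sperm specimens with known ground truth.

The study populations this generator emulates are snap-frozen swimming
bovine sperm: static snapshots of a left-biased beat. Each specimen is
driven by a single latent phase coordinate ψ in [−1, +1] (−1 = extreme
sharp-left, +1 = extreme right), drawn uniformly within a class-specific
sub-interval:

    sharp_left  [−1.0, −0.7]     mild_left   [−0.7, −0.2]
    straight    [−0.2,  0.2]     slight_right [0.2,  0.6]

No specimen is ever generated beyond +0.6, so sharp right bends do not
occur — by construction, mirroring the surveyed population. The default
class weights are the surveyed frequencies 15/30/36/19 %.

All imposed neck deformations are affine in ψ, metric = −ψ·(swing/1.25),
where 1.25 = E[ψ | slight_right] − E[ψ | sharp_left]; each ``swing``
parameter is therefore exactly the expected sharp-left-minus-slight-right
group contrast, the quantity reported for the real populations:
rostral rod sliding 300 nm, PC–neck angle 24°, PC lateral shift 170 nm,
head–neck kink 45°.

The flagellar centerline is built from a tangent-angle profile
θ(s) = θ_neck·exp(−s/ℓ) + θ_bend(ψ)·w(s) + A_θ·sin(2πs/λ + π/2), with
w a smooth neck-to-tip envelope. θ_bend(ψ) is calibrated (by root-finding,
cached) so that the normalized deflection D = ȳ/L at the ψ class
boundaries equals the classifier thresholds exactly — noise-free
specimens therefore classify back to their true class.

Coordinates are nm; the internal construction frame is the head frame
(head long axis +x, neck at origin, +y = sperm's right); a random rigid
pose is applied so downstream alignment is exercised. One master seed;
per-specimen streams are derived by counter, so population membership
is stable when only n changes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from . import cosa, slidingmodel
from ._geom import rotation_matrix
from .neckmetrics import NeckLandmarks, RodPointCloud
from .waveform import Polyline, resample

__all__ = [
    "SynthParams",
    "SpermSpecimen",
    "TruthRecord",
    "Raster",
    "PSI_INTERVALS",
    "PSI_CONTRAST",
    "make_waveform",
    "make_neck_landmarks",
    "make_rod_cloud",
    "make_specimen",
    "make_population",
    "rasterize_specimen",
]

# ψ sub-interval per bend class (within-class variability of bend phase)
PSI_INTERVALS: dict[cosa.Category, tuple[float, float]] = {
    cosa.Category.SHARP_LEFT: (-1.0, -0.7),
    cosa.Category.MILD_LEFT: (-0.7, -0.2),
    cosa.Category.STRAIGHT: (-0.2, 0.2),
    cosa.Category.SLIGHT_RIGHT: (0.2, 0.6),
}
# expected ψ contrast between the slight-right and sharp-left groups
PSI_CONTRAST = 1.25

DEFAULT_CLASS_WEIGHTS = (0.15, 0.30, 0.36, 0.19)  # surveyed frequencies

# --- fixed neck geometry of the construction (nm) --------------------------
NECK_LENGTH = 800.0          # neck midline length
HEAD_LENGTH = 9000.0         # head long axis
HEAD_WIDTH = 4400.0
ROD_LATERAL = 100.0          # rod center offset from midline
ROD_LEN_LEFT = 500.0         # left rod longer/thicker than right
ROD_LEN_RIGHT = 350.0
ROD_WIDTH_LEFT = 120.0
ROD_WIDTH_RIGHT = 90.0
ROD_ROSTRAL0 = 150.0         # rostral-end station of the left rod
MT_LATERAL = 130.0           # DC microtubule edge offset
MT_ROSTRAL0 = 180.0
MT_CENTER_PROTRUSION = 80.0  # central mt protrudes rostrally, tracks the PC
PC_BASE_OFFSET = 150.0       # PC midpoint baseline lateral offset (right)
PC_LENGTH = 400.0
PC_ROSTRAL0 = 450.0
SC_SPACING = 100.0           # segmented-column segment spacing
SC_LATERAL = 180.0
SC_ROSTRAL0 = 400.0
SC_N_SEGMENTS = 9
SC_BEND_MAX_DEG = 25.0       # chain bend between segments 8 and 9, left bends
BAR_HALF_GAP = 30.0
BAR_LEN_LEFT = 250.0
BAR_LEN_RIGHT = 300.0        # right bar longer (opposite asymmetry to rods)
NECK_DECAY_NM = 2000.0       # arclength scale over which the kink relaxes
ROD_Z_SD = 50.0              # out-of-plane spread of rod clouds


@dataclass
class SynthParams:
    """Ground-truth parameters of a synthetic population.

    Swing parameters are expected sharp-left-minus-slight-right group
    contrasts (see module docstring); lengths nm, angles degrees.
    """

    n_specimens: int = 248
    class_weights: tuple = DEFAULT_CLASS_WEIGHTS
    flagellum_length: float = 50_000.0
    wavelength: float = 25_000.0
    amplitude_by_class: dict = field(default_factory=lambda: {
        c: 4000.0 for c in cosa.CATEGORIES})
    rod_slide_span: float = 300.0    # nm; surveyed 263–328 nm
    pc_angle_swing: float = 24.0     # degrees
    pc_lateral_span: float = 170.0   # nm; surveyed 140–200 nm
    head_kink_swing: float = 45.0    # degrees
    landmark_noise_sd: float = 10.0  # nm
    localization_noise_sd: float = 15.0  # nm
    localizations_per_rod: int = 800
    pixel_size: float = 100.0        # nm
    ds: float = 100.0                # centerline sample spacing, nm
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if len(w) != 4 or np.any(w < 0):
            raise ValueError("class_weights must be 4 non-negative values")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1 within 1e-9")
        self.class_weights = tuple(float(x) for x in w)
        if self.flagellum_length <= 0:
            raise ValueError("flagellum_length must be positive")
        for name in ("rod_slide_span", "pc_angle_swing", "pc_lateral_span",
                     "head_kink_swing", "landmark_noise_sd",
                     "localization_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if isinstance(self.amplitude_by_class, (int, float)):
            self.amplitude_by_class = {
                c: float(self.amplitude_by_class) for c in cosa.CATEGORIES}
        else:
            self.amplitude_by_class = {
                cosa.Category(k): float(v)
                for k, v in dict(self.amplitude_by_class).items()}

    # per-ψ imposed deformations ------------------------------------------
    def truth_for_psi(self, psi: float) -> "TruthRecord":
        k = 1.0 / PSI_CONTRAST
        d = -psi * self.rod_slide_span * k
        kink = -psi * self.head_kink_swing * k
        sc_bend = -SC_BEND_MAX_DEG * max(0.0, -psi)
        return TruthRecord(
            psi=float(psi),
            d_rostral=d,
            d_caudal=d + (ROD_LEN_LEFT - ROD_LEN_RIGHT),
            d_mt_rostral=d,
            pc_dc_angle=-psi * self.pc_angle_swing * k,
            pc_lateral_shift=-psi * self.pc_lateral_span * k,
            head_neck_angle=kink,
            sc_segment_d=d,
            sc_bend_angle=sc_bend,
        )


@dataclass
class TruthRecord:
    """Noise-free imposed deformation parameters (recoverable targets)."""

    psi: float
    d_rostral: float          # nm
    d_caudal: float           # nm
    d_mt_rostral: float       # nm
    pc_dc_angle: float        # degrees
    pc_lateral_shift: float   # nm (relative to the PC's baseline offset)
    head_neck_angle: float    # degrees
    sc_segment_d: float       # nm, shared by all segments
    sc_bend_angle: float      # degrees, between segments 8 and 9


@dataclass
class SpermSpecimen:
    specimen_id: str
    beat_class_true: cosa.BeatClass
    centerline: np.ndarray          # (N, 2) lab-frame nm
    head_axis: np.ndarray           # lab-frame unit vector mapped to +x
    head_centroid: np.ndarray
    neck_origin: np.ndarray
    landmarks: NeckLandmarks        # lab frame, with landmark noise
    landmarks_true: NeckLandmarks   # lab frame, noise-free
    rod_clouds: dict                # side -> RodPointCloud (lab frame)
    truth: TruthRecord
    pose_angle: float = 0.0


@dataclass
class Raster:
    """A rasterized specimen image with its nm coordinate mapping."""

    pixels: np.ndarray       # 2-D float, 0..1
    pixel_size_nm: float
    origin_nm: np.ndarray    # nm coordinate of pixel (row 0, col 0) center

    def to_nm(self, col: np.ndarray, row: np.ndarray) -> np.ndarray:
        return np.column_stack([
            self.origin_nm[0] + np.asarray(col) * self.pixel_size_nm,
            self.origin_nm[1] + np.asarray(row) * self.pixel_size_nm])


# ---------------------------------------------------------------------------
# bend-profile calibration
# ---------------------------------------------------------------------------

_PSI_KNOTS = (-1.0, -0.7, -0.2, 0.2, 0.6)


def _deflection_targets(t1: float, t2: float) -> tuple:
    """Target D = ȳ/L at the ψ knots.

    The interior knots pin D to the classifier thresholds exactly; the
    outer knots only need to stay beyond them (sharp-left shapes curl,
    which saturates how negative the mean deflection can get, so the
    ψ=−1 target uses a fixed margin rather than a linear continuation).
    """
    slope_mid = 2 * t1 / 0.4
    return (-t2 - 0.02, -t2, -t1, t1, t1 + 0.4 * slope_mid)


def _theta_profile(s: np.ndarray, psi: float, theta_bend: float,
                   params: SynthParams, amplitude_nm: float) -> np.ndarray:
    L = params.flagellum_length
    t = s / L
    envelope = 3 * t ** 2 - 2 * t ** 3
    theta_neck = np.radians(params.truth_for_psi(psi).head_neck_angle)
    a_theta = 2 * np.pi * amplitude_nm / params.wavelength
    # quarter-period phase: the oscillation's contribution to the mean
    # deflection is zero to first order, so class separation is carried
    # by the bend term alone
    return (theta_neck * np.exp(-s / NECK_DECAY_NM)
            + theta_bend * envelope
            + a_theta * np.sin(2 * np.pi * s / params.wavelength + np.pi / 2))


def _centerline_from_theta(s: np.ndarray, theta: np.ndarray) -> np.ndarray:
    x = cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    y = cumulative_trapezoid(np.sin(theta), s, initial=0.0)
    return np.column_stack([x, y])


def _deflection_of(pts: np.ndarray, ds: float) -> float:
    """Normalized deflection D = ȳ/L computed exactly as the classifier
    does: resample the polyline, then take the signed arclength mean."""
    wf = resample(Polyline(pts), ds)
    tv = slidingmodel.tail_variables(wf)
    return tv.y_bar / float(wf.s[-1])


_BEND_CACHE: dict = {}


def _calibration_key(params: SynthParams) -> tuple:
    amps = tuple(params.amplitude_by_class[c] for c in cosa.CATEGORIES)
    return (params.flagellum_length, params.wavelength, amps,
            params.head_kink_swing, params.ds)


def bend_knots(params: SynthParams,
               t1: float = cosa.DEFAULT_T1,
               t2: float = cosa.DEFAULT_T2) -> dict:
    """θ_bend at the ψ knots for each class, solved so that D(ψ_knot)
    equals the classifier threshold targets. Cached per geometry."""
    key = _calibration_key(params) + (t1, t2)
    if key in _BEND_CACHE:
        return _BEND_CACHE[key]
    targets = dict(zip(_PSI_KNOTS, _deflection_targets(t1, t2)))
    s = np.arange(0.0, params.flagellum_length + params.ds / 2, params.ds)

    def solve(psi: float, amplitude: float) -> float:
        target = targets[psi]

        def f(theta_bend: float) -> float:
            theta = _theta_profile(s, psi, theta_bend, params, amplitude)
            return _deflection_of(_centerline_from_theta(s, theta),
                                  params.ds) - target

        return brentq(f, -3.0, 3.0, xtol=1e-10)

    knots: dict = {}
    for cat in cosa.CATEGORIES:
        lo, hi = PSI_INTERVALS[cat]
        amp = params.amplitude_by_class[cat]
        knots[cat] = ((lo, solve(lo, amp)), (hi, solve(hi, amp)))
    _BEND_CACHE[key] = knots
    return knots


def _bend_angle(psi: float, category: cosa.Category,
                params: SynthParams) -> float:
    (lo, b_lo), (hi, b_hi) = bend_knots(params)[category]
    f = (psi - lo) / (hi - lo)
    return b_lo + f * (b_hi - b_lo)


# ---------------------------------------------------------------------------
# specimen construction (head frame)
# ---------------------------------------------------------------------------

def _category_of(beat_class) -> cosa.Category:
    if isinstance(beat_class, cosa.BeatClass):
        return beat_class.category
    return cosa.Category(beat_class)


def make_waveform(beat_class, params: SynthParams,
                  rng: np.random.Generator,
                  psi: Optional[float] = None) -> np.ndarray:
    """Head-frame centerline (N, 2) for one specimen of a bend class.

    ψ is drawn uniformly in the class sub-interval unless given. The
    sharp-left family has the largest negative mean deflection; the
    slight-right family a small positive one; no class produces a
    sharp right bend.
    """
    category = _category_of(beat_class)
    if params.flagellum_length <= 0:
        raise ValueError("flagellum_length must be positive")
    if psi is None:
        lo, hi = PSI_INTERVALS[category]
        psi = float(rng.uniform(lo, hi))
    theta_bend = _bend_angle(psi, category, params)
    s = np.arange(0.0, params.flagellum_length + params.ds / 2, params.ds)
    theta = _theta_profile(s, psi, theta_bend, params,
                           params.amplitude_by_class[category])
    return _centerline_from_theta(s, theta)


def _neck_frame(truth: TruthRecord) -> tuple[np.ndarray, np.ndarray]:
    """(rostral, rightward) unit vectors of the neck midline in the head
    frame; the neck is tilted by the head–neck angle."""
    kink = np.radians(truth.head_neck_angle)
    rhat = rotation_matrix(kink) @ np.array([-1.0, 0.0])
    yhat = rotation_matrix(-np.pi / 2) @ rhat
    return rhat, yhat


def make_neck_landmarks(beat_class, params: SynthParams,
                        rng: np.random.Generator,
                        psi: Optional[float] = None,
                        ) -> tuple[NeckLandmarks, NeckLandmarks, TruthRecord]:
    """(noisy landmarks, noise-free landmarks, truth record), head frame.

    Deformations are affine in ψ (see module docstring); i.i.d.
    Gaussian noise of sd ``landmark_noise_sd`` is added per coordinate
    of the noisy copy only.
    """
    category = _category_of(beat_class)
    if psi is None:
        lo, hi = PSI_INTERVALS[category]
        psi = float(rng.uniform(lo, hi))
    truth = params.truth_for_psi(psi)
    rhat, yhat = _neck_frame(truth)
    origin = np.zeros(2)

    def at(rostral: float, lateral: float) -> np.ndarray:
        return origin + rostral * rhat + lateral * yhat

    d = truth.d_rostral
    lam = truth.pc_lateral_shift
    # neck midline, centered on the origin
    neck = np.array([at(NECK_LENGTH / 2, 0), at(-NECK_LENGTH / 2, 0)])
    # head axis along +x (the head frame *is* the head's frame)
    head_base = np.array([-NECK_LENGTH / 2, 0.0])
    head = np.array([head_base + [-HEAD_LENGTH, 0.0], head_base])
    # DC rods: right rod slides rostrally by d relative to the left
    rod_l_ro = at(ROD_ROSTRAL0, -ROD_LATERAL)
    rod_r_ro = at(ROD_ROSTRAL0 + d, ROD_LATERAL)
    rod_left = np.array([rod_l_ro, rod_l_ro - ROD_LEN_LEFT * rhat])
    rod_right = np.array([rod_r_ro, rod_r_ro - ROD_LEN_RIGHT * rhat])
    # DC microtubule edges (rostral endpoints); the central microtubule
    # protrudes rostrally and tracks the PC's lateral shift
    mt_left = at(MT_ROSTRAL0, -MT_LATERAL)
    mt_right = at(MT_ROSTRAL0 + d, MT_LATERAL)
    mt_center = at(MT_ROSTRAL0 + MT_CENTER_PROTRUSION, lam)
    # PC: rocked by the PC–DC angle about its midpoint, shifted laterally
    pc_mid = at(PC_ROSTRAL0, PC_BASE_OFFSET + lam)
    pc_dir = rotation_matrix(np.radians(truth.pc_dc_angle)) @ rhat
    pc_axis = np.array([pc_mid + PC_LENGTH / 2 * pc_dir,
                        pc_mid - PC_LENGTH / 2 * pc_dir])
    # segmented columns: right chain displaced rostrally by d; chains bend
    # between segments 8 and 9 for left-bent specimens
    stations = SC_ROSTRAL0 - SC_SPACING * np.arange(SC_N_SEGMENTS)
    sc_left = np.array([at(st, -SC_LATERAL) for st in stations])
    sc_right = np.array([at(st + d, SC_LATERAL) for st in stations])
    lateral_kick = SC_SPACING * np.tan(np.radians(truth.sc_bend_angle))
    sc_left[-1] += lateral_kick * yhat
    sc_right[-1] += lateral_kick * yhat
    # bars: static relative to each other, tracking the PC laterally
    bars = {}
    for side, off, blen in (("left", -BAR_HALF_GAP, BAR_LEN_LEFT),
                            ("right", BAR_HALF_GAP, BAR_LEN_RIGHT)):
        ro = at(ROD_ROSTRAL0 - 50.0, lam + off)
        bars[side] = np.array([ro, ro - blen * rhat])

    clean = NeckLandmarks(
        neck_midline=neck, head_axis=head, pc_axis=pc_axis,
        rod_left=rod_left, rod_right=rod_right,
        mt_left=mt_left, mt_right=mt_right, mt_center=mt_center,
        sc_left=sc_left, sc_right=sc_right,
        bars_left=bars["left"], bars_right=bars["right"])
    noisy = clean.with_noise(params.landmark_noise_sd, rng) \
        if params.landmark_noise_sd > 0 else clean
    return noisy, clean, truth


def make_rod_cloud(landmarks: NeckLandmarks, side: str,
                   params: SynthParams,
                   rng: np.random.Generator,
                   n_localizations: Optional[int] = None) -> RodPointCloud:
    """Localization cloud of one DC rod.

    Points are drawn uniformly along the rod segment with a uniform
    lateral spread of the rod's width, then jittered isotropically with
    ``localization_noise_sd``. The left rod is longer and thicker than
    the right (the conserved asymmetry the chirality normalization
    relies on).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    n = params.localizations_per_rod if n_localizations is None \
        else int(n_localizations)
    if n <= 0:
        raise ValueError("need a positive number of localizations")
    rod = getattr(landmarks, f"rod_{side}")
    if rod is None:
        raise ValueError(f"rod_{side} endpoints missing")
    axis = rod[0] - rod[1]
    if np.linalg.norm(axis) == 0:
        raise ValueError("degenerate rod of zero length")
    across = rotation_matrix(np.pi / 2) @ (axis / np.linalg.norm(axis))
    width = ROD_WIDTH_LEFT if side == "left" else ROD_WIDTH_RIGHT
    t = rng.uniform(0.0, 1.0, n)
    lat = rng.uniform(-width / 2, width / 2, n)
    xy = rod[1] + t[:, None] * axis + lat[:, None] * across
    z = rng.uniform(-width / 2, width / 2, n)
    sd = params.localization_noise_sd
    if sd > 0:
        xy = xy + rng.normal(0.0, sd, xy.shape)
        z = z + rng.normal(0.0, sd, n)
    intensity = rng.gamma(2.0, 500.0, n)
    return RodPointCloud(np.column_stack([xy, z]), intensity, side)


# ---------------------------------------------------------------------------
# population assembly
# ---------------------------------------------------------------------------

def _specimen_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def make_specimen(index: int, params: SynthParams,
                  category: Optional[cosa.Category] = None) -> SpermSpecimen:
    """Build specimen `index` of the population (deterministic in
    (seed, index); independent of n_specimens)."""
    rng = _specimen_rng(params.seed, index)
    if category is None:
        weights = np.asarray(params.class_weights, dtype=float)
        category = cosa.CATEGORIES[int(rng.choice(4, p=weights))]
    lo, hi = PSI_INTERVALS[category]
    psi = float(rng.uniform(lo, hi))
    centerline = make_waveform(category, params, rng, psi=psi)
    noisy, clean, truth = make_neck_landmarks(category, params, rng, psi=psi)
    clouds = {side: make_rod_cloud(clean, side, params, rng)
              for side in ("left", "right")}
    # subtype of the true class, from the noise-free kink
    subtype = cosa.Subtype.NONE
    if category in (cosa.Category.SHARP_LEFT, cosa.Category.MILD_LEFT):
        subtype = (cosa.Subtype.TYPE1
                   if abs(truth.head_neck_angle) >= cosa.DEFAULT_KINK_DEG
                   else cosa.Subtype.TYPE2)
    # random rigid lab pose
    pose_angle = float(rng.uniform(0.0, 2 * np.pi))
    R = rotation_matrix(pose_angle)
    T = rng.uniform(-20_000.0, 20_000.0, 2)
    head_base = np.array([-NECK_LENGTH / 2, 0.0])
    return SpermSpecimen(
        specimen_id=f"sp{index:05d}",
        beat_class_true=cosa.BeatClass(category, subtype),
        centerline=centerline @ R.T + T,
        head_axis=R @ np.array([1.0, 0.0]),
        head_centroid=(head_base + np.array([-HEAD_LENGTH / 2, 0.0])) @ R.T + T,
        neck_origin=T.copy(),
        landmarks=noisy.transformed(R, T),
        landmarks_true=clean.transformed(R, T),
        rod_clouds={
            side: RodPointCloud(
                np.column_stack([cloud.xy @ R.T + T, cloud.xyz[:, 2]]),
                cloud.intensity, side)
            for side, cloud in clouds.items()},
        truth=truth,
        pose_angle=pose_angle,
    )


def make_population(params: SynthParams,
                    category: Optional[cosa.Category] = None
                    ) -> list[SpermSpecimen]:
    """Generate the full population (optionally a single forced class)."""
    if params.n_specimens <= 0:
        raise ValueError("n_specimens must be positive")
    bend_knots(params)  # warm the calibration cache once
    return [make_specimen(i, params, category=category)
            for i in range(params.n_specimens)]


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_specimen(specimen: SpermSpecimen, pixel_size_nm: float,
                       line_width_nm: float = 300.0,
                       include_head: bool = True,
                       margin_nm: float = 2000.0) -> Raster:
    """Render a specimen as a grayscale image (values in [0, 1]).

    The centerline is drawn with a Gaussian cross-section of FWHM
    ``line_width_nm``; the head is a filled ellipse. The image covers
    the specimen with ``margin_nm`` on every side.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    pts = specimen.centerline
    path_len = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if pixel_size_nm > path_len:
        raise ValueError("pixel_size_nm exceeds the flagellum length")
    corners = [pts]
    if include_head:
        c = specimen.head_centroid
        r = max(HEAD_LENGTH, HEAD_WIDTH) / 2
        corners.append(np.array([c - r, c + r]))
    allpts = np.vstack(corners)
    lo = allpts.min(axis=0) - margin_nm
    hi = allpts.max(axis=0) + margin_nm
    ncols = int(np.ceil((hi[0] - lo[0]) / pixel_size_nm)) + 1
    nrows = int(np.ceil((hi[1] - lo[1]) / pixel_size_nm)) + 1
    img = np.zeros((nrows, ncols), dtype=float)

    def to_px(p: np.ndarray) -> tuple[int, int]:
        col = int(round((p[0] - lo[0]) / pixel_size_nm))
        row = int(round((p[1] - lo[1]) / pixel_size_nm))
        return row, col

    for a, b in zip(pts[:-1], pts[1:]):
        r0, c0 = to_px(a)
        r1, c1 = to_px(b)
        rr, cc = draw_line(r0, c0, r1, c1)
        img[np.clip(rr, 0, nrows - 1), np.clip(cc, 0, ncols - 1)] = 1.0
    sigma_px = line_width_nm / 2.355 / pixel_size_nm
    img = gaussian_filter(img, sigma_px)
    if img.max() > 0:
        img = img / img.max()
    if include_head:
        # rendered separately so the thin blurred flagellum ridge and the
        # filled head reach comparable peak intensities
        head = np.zeros_like(img)
        hr, hc = to_px(specimen.head_centroid)
        angle = np.arctan2(specimen.head_axis[1], specimen.head_axis[0])
        rr, cc = draw_ellipse(hr, hc,
                              HEAD_WIDTH / 2 / pixel_size_nm,
                              HEAD_LENGTH / 2 / pixel_size_nm,
                              shape=img.shape, rotation=-angle)
        head[rr, cc] = 1.0
        head = gaussian_filter(head, sigma_px)
        if head.max() > 0:
            head = head / head.max()
        img = np.maximum(img, head)
    return Raster(pixels=img, pixel_size_nm=float(pixel_size_nm),
                  origin_nm=lo.astype(float))
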