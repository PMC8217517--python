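"""Centriole orientation-based sperm analysis (COSA).

Snap-frozen sperm roll, so bend direction is only comparable across
cells after each cell's chirality is normalized using the conserved
neck asymmetry: the proximal centriole (PC) sits on the sperm's right
of the head midline and the larger DC rod on the left.
`normalize_orientation` mirrors a specimen about its head axis whenever
the marker indicates the PC is on the left, recording the flip.

`classify_bend` assigns one of the four bend categories — sharp left,
mild left, straight, slight right — from the normalized deflection
D = ȳ / L (the head-frame mean deflection over the traced length).
The category thresholds T1 (straight vs. mild) and T2 (mild vs. sharp)
are conventions, not measurements: the original survey was by eye.
They default to 0.03 and 0.12 of the flagellum length, matched to the
synthetic generator's class-phase boundaries so noise-free synthetic
classes round-trip exactly. Left-bend cells carry a Type 1/2 subtype:
Type 1 when the head–neck kink dominates (|head–neck angle| >= K,
default 30°), Type 2 otherwise (kink plus mid-piece bend).

A sharp *right* deflection (D >= T2) is reported as slight_right with a
warning — in the study population it never occurs, and its absence is a
finding, not an impossibility.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from . import slidingmodel
from .neckmetrics import NeckLandmarks, head_neck_angle
from .waveform import HeadFrame, Polyline, Waveform, align_to_head_frame, resample

__all__ = [
    "Category",
    "Subtype",
    "BeatClass",
    "OrientedSpecimen",
    "SharpRightWarning",
    "normalize_orientation",
    "classify_bend",
    "population_distribution",
    "DEFAULT_T1",
    "DEFAULT_T2",
    "DEFAULT_KINK_DEG",
]

DEFAULT_T1 = 0.03      # |D| below: straight (fraction of flagellum length)
DEFAULT_T2 = 0.12      # |D| above, leftward: sharp left
DEFAULT_KINK_DEG = 30.0  # Type 1 vs Type 2 kink cutoff


class Category(str, Enum):
    SHARP_LEFT = "sharp_left"
    MILD_LEFT = "mild_left"
    STRAIGHT = "straight"
    SLIGHT_RIGHT = "slight_right"


CATEGORIES: tuple[Category, ...] = (
    Category.SHARP_LEFT, Category.MILD_LEFT, Category.STRAIGHT,
    Category.SLIGHT_RIGHT)


class Subtype(str, Enum):
    TYPE1 = "type1"
    TYPE2 = "type2"
    NONE = "none"


class SharpRightWarning(UserWarning):
    """Raised when a specimen shows a sharp rightward deflection."""


@dataclass
class BeatClass:
    category: Category
    subtype: Subtype = Subtype.NONE

    def __post_init__(self) -> None:
        self.category = Category(self.category)
        self.subtype = Subtype(self.subtype)
        if self.subtype is not Subtype.NONE and self.category not in (
                Category.SHARP_LEFT, Category.MILD_LEFT):
            raise ValueError("subtype applies only to left-bend categories")


@dataclass
class OrientedSpecimen:
    """A specimen in the head frame after chirality normalization."""

    waveform: Waveform
    landmarks: Optional[NeckLandmarks]
    flip_applied: bool
    frame: Optional[HeadFrame] = None
    specimen_id: Optional[str] = None


def _neck_offset(landmarks: NeckLandmarks, point: np.ndarray) -> float:
    """Signed lateral offset of a point from the neck midline (+ = the
    sperm's right). The neck midline, not the head axis, carries the
    left/right reference: a strong head–neck kink tilts the whole neck,
    so raw head-frame y would misjudge sides."""
    from ._geom import signed_lateral_offset
    return signed_lateral_offset(point, landmarks.neck_midline[1],
                                 landmarks.rostral_dir)


def _pc_side(landmarks: NeckLandmarks) -> Optional[float]:
    """+1 if the PC midpoint lies right of the neck midline, -1 left."""
    if landmarks.pc_axis is None:
        return None
    off = _neck_offset(landmarks, landmarks.pc_axis.mean(axis=0))
    if abs(off) < 1e-9:
        return None
    return float(np.sign(off))


def _rod_side(landmarks: NeckLandmarks, tol: float = 1e-6) -> Optional[float]:
    """Side of the longer rod relative to the neck midline (-1 = left,
    where it belongs after normalization)."""
    if landmarks.rod_left is None or landmarks.rod_right is None:
        return None
    rods = {}
    for name in ("rod_left", "rod_right"):
        rod = getattr(landmarks, name)
        length = float(np.linalg.norm(rod[0] - rod[1]))
        side = np.sign(_neck_offset(landmarks, rod.mean(axis=0)))
        rods[name] = (length, side)
    (la, sa), (lb, sb) = rods["rod_left"], rods["rod_right"]
    if abs(la - lb) <= tol * max(la, lb):
        return None
    return float(sa if la > lb else sb)


def normalize_orientation(specimen=None, *, waveform: Waveform = None,
                          landmarks: NeckLandmarks = None,
                          ds: float = slidingmodel.DEFAULT_DS_NM,
                          specimen_id: Optional[str] = None) -> OrientedSpecimen:
    """Bring a specimen into the COSA frame (PC right, larger rod left).

    Accepts either a generator-style specimen object (attributes
    ``centerline``, ``head_axis``, ``neck_origin``, ``landmarks``,
    optionally ``specimen_id``) in arbitrary lab coordinates, or an
    already head-framed ``waveform`` + ``landmarks`` pair. A mirror
    flip about the head axis is applied iff the chirality marker (PC
    side; rod-size asymmetry as fallback) indicates the PC is on the
    sperm's left. Applying the operation twice is the identity.
    """
    if specimen is not None:
        poly = Polyline(np.asarray(specimen.centerline, dtype=float))
        aligned, frame = align_to_head_frame(
            poly, specimen.head_axis, specimen.neck_origin)
        wf = resample(aligned, ds)
        lm = specimen.landmarks.to_frame(frame)
        sid = specimen_id or getattr(specimen, "specimen_id", None)
    else:
        if waveform is None:
            raise ValueError("provide a specimen or a waveform")
        wf, lm, frame = waveform, landmarks, None
        sid = specimen_id

    flip = False
    if lm is not None:
        side = _pc_side(lm)
        if side is None:
            side_rod = _rod_side(lm)
            if side_rod is None:
                raise ValueError(
                    "no usable chirality marker: PC side undefined and "
                    "rods equal within tolerance")
            # larger rod belongs on -y; if it sits on +y, flip
            flip = side_rod > 0
        else:
            flip = side < 0
    if flip:
        wf = wf.mirrored()
        if lm is not None:
            lm = lm.mirrored()
        if frame is not None:
            frame = HeadFrame(frame.origin, frame.x_axis,
                              flipped=not frame.flipped)
    return OrientedSpecimen(waveform=wf, landmarks=lm, flip_applied=flip,
                            frame=frame, specimen_id=sid)


def classify_bend(oriented: OrientedSpecimen,
                  t1: float = DEFAULT_T1,
                  t2: float = DEFAULT_T2,
                  kink_deg: float = DEFAULT_KINK_DEG,
                  with_subtype: bool = True) -> BeatClass:
    """Assign the four-category bend class of an oriented specimen.

    D = ȳ / L with ȳ the signed head-frame mean deflection and L the
    traced flagellum length; left is negative. D <= -t2: sharp left;
    -t2 < D <= -t1: mild left; |D| < t1: straight; D >= t1: slight
    right (a value D >= t2 additionally raises SharpRightWarning).
    """
    wf = oriented.waveform
    tv = slidingmodel.tail_variables(wf)
    length = float(wf.s[-1])
    D = tv.y_bar / length
    if D <= -t2:
        category = Category.SHARP_LEFT
    elif D <= -t1:
        category = Category.MILD_LEFT
    elif D < t1:
        category = Category.STRAIGHT
    else:
        category = Category.SLIGHT_RIGHT
        if D >= t2:
            warnings.warn("sharp rightward deflection observed",
                          SharpRightWarning, stacklevel=2)
    subtype = Subtype.NONE
    if with_subtype and category in (Category.SHARP_LEFT, Category.MILD_LEFT):
        if oriented.landmarks is None:
            raise ValueError("head–neck angle unavailable: landmarks "
                             "required for Type 1/2 subtyping")
        angle = head_neck_angle(oriented.landmarks)
        subtype = Subtype.TYPE1 if abs(angle) >= kink_deg else Subtype.TYPE2
    return BeatClass(category, subtype)


@dataclass
class PopulationDistribution:
    counts: dict
    fractions: dict
    n: int

    def as_tuple(self) -> tuple[float, float, float, float]:
        return tuple(self.fractions[c] for c in CATEGORIES)


def population_distribution(
        classes: Sequence[BeatClass | Category | str]) -> PopulationDistribution:
    """Counts and fractions per bend category (fractions sum to 1)."""
    if len(classes) == 0:
        raise ValueError("empty class list")
    cats = [Category(c.category if isinstance(c, BeatClass) else c)
            for c in classes]
    counter = Counter(cats)
    n = len(cats)
    counts = {c: int(counter.get(c, 0)) for c in CATEGORIES}
    fractions = {c: counts[c] / n for c in CATEGORIES}
    return PopulationDistribution(counts=counts, fractions=fractions, n=n)
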