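"""Sliding-filament quantities of a planar flagellar waveform.

The flagellum is abstracted as two filaments r±(s) = r(s) ± (a/2) n̂(s)
separated by the flagellar diameter ``a`` normal to the centerline.
Because the two filaments run along rails of different contour length
wherever the centerline curves, geometry forces an arclength mismatch

    Δ(s) = a (θ(s) − θ₀),

where θ(s) is the tangent angle of the centerline with respect to the
head-frame x-axis and θ₀ = θ(0). The signed curvature is κ(s) = dθ/ds.
The basal offset Δ₀ is fixed at 0: Δ(s) captures only the mismatch
caused by waveform curvature; basal sliding is measured independently
from neck landmarks, never inferred here.

Arclength averages of y(s), Δ(s) and κ(s) — the tail variables ȳ, Δ̄,
κ̄ — are *signed* means, so a population with a left-biased beat shows
all three skewed negative (left = −y).

Defaults: a = 600 nm (the flagellar diameter of bovine sperm used for
the sliding computation), grid spacing ds = 100 nm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = [
    "DEFAULT_DIAMETER_NM",
    "DEFAULT_DS_NM",
    "SlidingProfile",
    "TailVariables",
    "tangent_angle",
    "signed_curvature",
    "interfilament_sliding",
    "sliding_profile",
    "tail_variables",
]

DEFAULT_DIAMETER_NM = 600.0
DEFAULT_DS_NM = 100.0


@dataclass
class SlidingProfile:
    """θ(s), κ(s) and Δ(s) on the waveform's arclength grid."""

    s: np.ndarray          # nm
    theta: np.ndarray      # rad
    kappa: np.ndarray      # rad/nm
    delta: np.ndarray      # nm
    theta0: float          # rad
    a: float               # nm
    delta0: float = 0.0    # nm, fixed basal offset

    @property
    def deltaT(self) -> float:
        """Total interfilament sliding at the tip: Δ₀ + Δ(L)."""
        return self.delta0 + float(self.delta[-1])


@dataclass
class TailVariables:
    """Arclength means of the signed waveform profiles."""

    y_bar: float       # nm
    delta_bar: float   # nm
    kappa_bar: float   # rad/µm
    theta0: float      # rad


def _arclength_mean(values: np.ndarray, s: np.ndarray) -> float:
    return float(np.trapezoid(values, s) / (s[-1] - s[0]))


def tangent_angle(wf: Waveform) -> tuple[np.ndarray, float]:
    """Unwrapped tangent angle θ(s) and θ₀ from central differences."""
    if len(wf.s) < 3:
        raise ValueError("need at least 3 samples for tangent angles")
    dx = np.gradient(wf.x, wf.ds, edge_order=2)
    dy = np.gradient(wf.y, wf.ds, edge_order=2)
    if np.any(np.hypot(dx, dy) == 0):
        raise ValueError("duplicate consecutive points: tangent undefined")
    theta = np.unwrap(np.arctan2(dy, dx))
    return theta, float(theta[0])


def signed_curvature(theta: np.ndarray, ds: float) -> np.ndarray:
    """κ(s) = dθ/ds by central differences (one-sided at the ends).

    Under the COSA head frame a leftward bend (toward −y) yields
    negative κ.
    """
    if len(theta) < 3:
        raise ValueError("need at least 3 samples for curvature")
    return np.gradient(np.asarray(theta, dtype=float), ds, edge_order=2)


def interfilament_sliding(theta: np.ndarray, theta0: float,
                          a: float = DEFAULT_DIAMETER_NM) -> np.ndarray:
    """Δ(s) = a (θ(s) − θ₀); Δ(0) = 0 by construction."""
    if a <= 0:
        raise ValueError("flagellar diameter a must be positive")
    return a * (np.asarray(theta, dtype=float) - theta0)


def sliding_profile(wf: Waveform,
                    a: float = DEFAULT_DIAMETER_NM) -> SlidingProfile:
    """Compute the full sliding-filament profile of a head-frame waveform."""
    theta, theta0 = tangent_angle(wf)
    kappa = signed_curvature(theta, wf.ds)
    delta = interfilament_sliding(theta, theta0, a)
    return SlidingProfile(s=wf.s, theta=theta, kappa=kappa, delta=delta,
                          theta0=theta0, a=a)


def tail_variables(wf: Waveform, a: float = DEFAULT_DIAMETER_NM,
                   absolute: bool = False) -> TailVariables:
    """ȳ, Δ̄ and κ̄ of a head-frame waveform.

    With ``absolute=True`` the means are taken over |y|, |Δ|, |κ|
    (provided for exploratory use; the signed means are the default and
    the quantities used throughout).
    """
    prof = sliding_profile(wf, a)
    y = np.abs(wf.y) if absolute else wf.y
    delta = np.abs(prof.delta) if absolute else prof.delta
    kappa = np.abs(prof.kappa) if absolute else prof.kappa
    return TailVariables(
        y_bar=_arclength_mean(y, wf.s),
        delta_bar=_arclength_mean(delta, wf.s),
        kappa_bar=_arclength_mean(kappa, wf.s) * 1000.0,  # rad/nm -> rad/µm
        theta0=prof.theta0,
    )
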