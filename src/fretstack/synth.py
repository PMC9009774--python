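"""Synthetic donor/acceptor stacks with known ground truth.

Emulates the data regime the pipeline targets: a single bright elongated
cell (a growing tube rendered as a capsule with a Gaussian cross-section)
on a smooth quadratic shading background, Gaussian sensor read noise, a
static rigid dual-view misalignment of the acceptor channel, per-channel
exponential photobleaching of the object signal, and a tip-focused
acceptor/donor ratio gradient so the ratio stage has a non-trivial known
answer.  Every random draw comes from one seeded generator, so a given
spec and seed reproduce bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ImageStack
from .ratio import RigidTransform, apply_rigid_transform


@dataclass
class FixtureSpec:
    """Parameters of a synthetic dual-channel time-lapse.

    The quadratic background is ``b(x, y) = a0 + a1 x + a2 y + a3 x^2 +
    a4 x y + a5 y^2`` (counts); the default coefficients span ~200 counts
    peak-to-peak over a 640x480 frame.  The object is a capsule from
    ``tail`` to ``tip`` (the tip advances ``tip_velocity`` px/frame) with a
    Gaussian cross-section of scale ``half_width / 2``; its true mask is
    the set of pixels within ``half_width`` of the axis.  The acceptor
    object signal is the donor signal times ``1 + ratio_gradient *
    exp(-d_tip^2 / (2 gradient_length^2))``, a tip-focused ratio profile.
    Bleaching multiplies the object (not the background) by
    ``exp(-rate * t)`` per channel.  The acceptor frame is warped by the
    inverse of ``channel_offset`` before noise, so ``channel_offset`` is
    exactly the transform a registration step should recover.
    """

    height: int = 480
    width: int = 640
    n_frames: int = 20
    bit_depth: int = 16
    bg_coeffs: tuple[float, float, float, float, float, float] = (
        150.0, 0.12, 0.13, 1.5e-4, 0.0, 0.0,
    )
    noise_sigma: float = 5.0
    poisson_noise: bool = False
    tail: tuple[float, float] | None = None   # default: (0.16 w, 0.5 h)
    tip: tuple[float, float] | None = None    # default: (0.56 w, 0.5 h)
    tip_velocity: tuple[float, float] = (2.0, 0.0)
    half_width: float = 18.0
    peak: float = 2000.0
    ratio_gradient: float = 0.5
    gradient_length: float = 60.0
    channel_offset: tuple[float, float, float] = (3.0, -2.0, math.radians(1.0))
    donor_bleach_rate: float = 0.03
    acceptor_bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if self.tail is None:
            self.tail = (0.16 * self.width, 0.5 * self.height)
        if self.tip is None:
            self.tip = (0.56 * self.width, 0.5 * self.height)
        if not (0 <= self.tail[0] < self.width and 0 <= self.tail[1] < self.height):
            raise ValueError("object tail outside the frame")
        if self.half_width * 2 >= min(self.height, self.width):
            raise ValueError("object larger than the frame")


@dataclass
class GroundTruth:
    """Noiseless truth stored alongside a generated fixture."""

    background: np.ndarray            # (h, w) shading surface, counts
    object_masks: np.ndarray          # (n, h, w) bool, donor-geometry object support
    background_region: np.ndarray     # (n, h, w) bool, object contribution < 0.5 counts
    true_ratio: np.ndarray            # (n, h, w) acceptor/donor object ratio profile
    true_transform: RigidTransform    # aligns the acceptor channel onto the donor
    donor_decay: np.ndarray           # (n,) multiplicative object decay per frame
    acceptor_decay: np.ndarray
    noise_sigma: float
    foreground_fraction: float        # mean fraction of pixels inside the object mask
    object_peak: float = 0.0          # peak object intensity of donor frame 0

    def as_arrays(self) -> dict[str, np.ndarray]:
        """Flat dict of arrays for HDF5 storage."""
        t = self.true_transform
        return {
            "background": self.background,
            "object_masks": self.object_masks.astype(np.uint8),
            "background_region": self.background_region.astype(np.uint8),
            "true_ratio": self.true_ratio,
            "transform": np.array([t.dx, t.dy, t.theta]),
            "donor_decay": self.donor_decay,
            "acceptor_decay": self.acceptor_decay,
            "noise_sigma": np.array(self.noise_sigma),
            "foreground_fraction": np.array(self.foreground_fraction),
            "object_peak": np.array(self.object_peak),
        }


def _segment_distance(xx, yy, p0, p1):
    """Distance from every pixel to the segment p0-p1."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    if L2 == 0:
        return np.hypot(xx - p0[0], yy - p0[1])
    t = ((xx - p0[0]) * vx + (yy - p0[1]) * vy) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(xx - (p0[0] + t * vx), yy - (p0[1] + t * vy))


def generate_fixture(spec: FixtureSpec) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render the donor and (misaligned) acceptor stacks plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w, n = spec.height, spec.width, spec.n_frames
    maxv = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16

    xx, yy = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    a0, a1, a2, a3, a4, a5 = spec.bg_coeffs
    background = a0 + a1 * xx + a2 * yy + a3 * xx**2 + a4 * xx * yy + a5 * yy**2

    t_idx = np.arange(n, dtype=np.float64)
    donor_decay = np.exp(-spec.donor_bleach_rate * t_idx)
    acceptor_decay = np.exp(-spec.acceptor_bleach_rate * t_idx)

    offset = RigidTransform(*spec.channel_offset)
    misalign = offset.inverse()

    donor = np.empty((n, h, w), dtype=dtype)
    acceptor = np.empty((n, h, w), dtype=dtype)
    masks = np.empty((n, h, w), dtype=bool)
    bg_region = np.empty((n, h, w), dtype=bool)
    true_ratio = np.empty((n, h, w), dtype=np.float32)
    sigma_cross = spec.half_width / 2.0

    for t in range(n):
        tip_t = (
            spec.tip[0] + spec.tip_velocity[0] * t,
            spec.tip[1] + spec.tip_velocity[1] * t,
        )
        dist = _segment_distance(xx, yy, spec.tail, tip_t)
        profile = np.exp(-(dist**2) / (2.0 * sigma_cross**2))
        masks[t] = dist <= spec.half_width
        d_tip = np.hypot(xx - tip_t[0], yy - tip_t[1])
        ratio_field = 1.0 + spec.ratio_gradient * np.exp(
            -(d_tip**2) / (2.0 * spec.gradient_length**2)
        )
        true_ratio[t] = ratio_field.astype(np.float32)

        donor_obj = spec.peak * profile * donor_decay[t]
        # pixels where the object's Gaussian tail is below half a count: the
        # true background-only region used when judging residuals
        bg_region[t] = spec.peak * profile < 0.5
        acceptor_obj = donor_obj * ratio_field * (acceptor_decay[t] / donor_decay[t])

        donor_clean = background + donor_obj
        acceptor_clean = apply_rigid_transform(background + acceptor_obj, misalign)

        donor_frame = donor_clean + (
            rng.normal(0.0, spec.noise_sigma, (h, w)) if spec.noise_sigma > 0 else 0.0
        )
        acceptor_frame = acceptor_clean + (
            rng.normal(0.0, spec.noise_sigma, (h, w)) if spec.noise_sigma > 0 else 0.0
        )
        if spec.poisson_noise:
            donor_frame = rng.poisson(np.clip(donor_frame, 0, None)).astype(np.float64)
            acceptor_frame = rng.poisson(np.clip(acceptor_frame, 0, None)).astype(np.float64)

        donor[t] = np.clip(np.rint(donor_frame), 0, maxv).astype(dtype)
        acceptor[t] = np.clip(np.rint(acceptor_frame), 0, maxv).astype(dtype)

    ids = np.arange(n)
    truth = GroundTruth(
        background=background,
        object_masks=masks,
        background_region=bg_region,
        true_ratio=true_ratio,
        true_transform=offset,
        donor_decay=donor_decay,
        acceptor_decay=acceptor_decay,
        noise_sigma=spec.noise_sigma,
        foreground_fraction=float(masks.mean()),
        object_peak=float(spec.peak),
    )
    return (
        ImageStack(donor, spec.bit_depth, ids, "donor"),
        ImageStack(acceptor, spec.bit_depth, ids, "acceptor"),
        truth,
    )
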