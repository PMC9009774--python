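"""Ratio-image construction from registered donor/acceptor stacks.

In a dual-view acquisition the donor and acceptor channels land on
different halves of the sensor, so a static rigid misalignment (shift +
small rotation) separates them.  The stacks are registered by a rigid
transform, denoised with a small-kernel bilateral filter, binarized with
Otsu's threshold per channel, cleaned of small border-touching components,
and divided to give the acceptor/donor ratio on the joint foreground mask.
A robust 10th-90th percentile rescaling maps the ratio to 8-bit for
display, so single extreme outliers cannot compress the visible dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.registration import phase_cross_correlation

#: metric flag names set during ratio processing
FLAG_REGISTRATION_WARN = "registration_warn"
FLAG_EMPTY_MASK = "empty_mask"
FLAG_DONOR_ZERO = "donor_zero_pixels"
FLAG_FLAT_RESCALE = "flat_rescale"


@dataclass
class RigidTransform:
    """Rigid motion: rotation ``theta`` (radians) about the image center
    followed by translation ``(dx, dy)`` in pixels (x = columns, y = rows)."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    converged: bool = field(default=True, compare=False)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return abs(self.dx) < tol and abs(self.dy) < tol and abs(self.theta) < tol

    def inverse(self) -> "RigidTransform":
        # composition inverse under apply_rigid_transform's convention:
        # theta negates and the translation is counter-rotated
        c, s = math.cos(self.theta), math.sin(self.theta)
        dy = -(c * self.dy + s * self.dx)
        dx = -(c * self.dx - s * self.dy)
        return RigidTransform(dx=dx, dy=dy, theta=-self.theta)


def apply_rigid_transform(image: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Warp ``image`` by a rigid transform (inverse mapping, bilinear, zero fill).

    The forward map sends input pixel ``p`` (x, y about the image center) to
    ``R(theta) p + (dx, dy)``; output pixels sample the input at the inverse
    location.  Returns float64.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    cy, cx = (h - 1) / 2, (w - 1) / 2
    c, s = math.cos(transform.theta), math.sin(transform.theta)
    # inverse rotation in (row, col) = (y, x) coordinates
    M = np.array([[c, s], [-s, c]])
    center = np.array([cy, cx])
    t = np.array([transform.dy, transform.dx])
    offset = center - M @ (center + t)
    return ndi.affine_transform(img, M, offset=offset, order=1, mode="constant", cval=0.0)


def _masked_ncc(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    av, bv = a[valid], b[valid]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def _self_quotient(img: np.ndarray, smooth_sigma: float, quotient_sigma: float) -> np.ndarray:
    """Illumination-invariant rendering: lightly smoothed image divided by a
    heavily smoothed copy.  Cancels smooth multiplicative fields (shading,
    spatially varying donor/acceptor ratio) that would otherwise bias an
    intensity-correlation registration criterion.  The denominator is
    clamped at 5 percent of its maximum so that near-zero regions (e.g. the
    background of an already background-subtracted frame) do not blow the
    quotient up into amplified noise."""
    sm = ndi.gaussian_filter(img, smooth_sigma)
    base = ndi.gaussian_filter(sm, quotient_sigma)
    floor = max(1e-6, 0.05 * float(base.max()))
    return sm / np.maximum(base, floor)


def estimate_rigid_transform(
    reference: np.ndarray,
    moving: np.ndarray,
    max_theta: float = math.radians(10.0),
    max_shift: float = 10.0,
    illumination_invariant: bool = True,
    quotient_sigma: float = 20.0,
    border_margin: int | None = None,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Translation is initialized by sub-pixel cross-correlation (plain, not
    phase-whitened: whitening is unreliable on smooth low-texture frames),
    then (dx, dy, theta) are refined by maximizing the normalized
    cross-correlation of the warped moving frame against the reference.
    The criterion is evaluated on self-quotient renderings of both frames
    (see :func:`_self_quotient`) and excludes a border margin, so neither
    channel-specific smooth intensity fields nor the zero-filled strip a
    prior dual-view warp leaves at the frame edge can bias the optimum.
    On optimizer failure the identity is returned with ``converged=False``
    so the frame can be flagged in the metrics.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving frames must share a shape")
    h, w = ref.shape
    if illumination_invariant:
        R = _self_quotient(ref, 1.5, quotient_sigma)
        M = _self_quotient(mov, 1.5, quotient_sigma)
        margin = int(2.25 * quotient_sigma) if border_margin is None else border_margin
    else:
        R, M = ref, mov
        margin = 12 if border_margin is None else border_margin
    margin = max(2, min(margin, h // 4, w // 4))

    try:
        shift, _, _ = phase_cross_correlation(R, M, upsample_factor=20, normalization=None)
        dy0, dx0 = float(shift[0]), float(shift[1])
    except Exception:
        dy0 = dx0 = 0.0

    support = np.ones_like(M)
    interior = np.zeros(R.shape, dtype=bool)
    interior[margin:-margin, margin:-margin] = True

    def cost(p):
        t = RigidTransform(dx=p[0], dy=p[1], theta=p[2])
        warped = apply_rigid_transform(M, t)
        valid = (apply_rigid_transform(support, t) > 0.999) & interior
        if valid.sum() < 0.25 * interior.sum():
            return 1.0
        return -_masked_ncc(R, warped, valid)

    # guard against a pathological correlation peak
    x0 = min(([dx0, dy0, 0.0], [0.0, 0.0, 0.0]), key=cost)
    try:
        res = optimize.minimize(
            cost,
            x0=np.array(x0),
            method="Powell",
            bounds=[
                (x0[0] - max_shift, x0[0] + max_shift),
                (x0[1] - max_shift, x0[1] + max_shift),
                (-max_theta, max_theta),
            ],
            options={"xtol": 1e-4, "ftol": 1e-8},
        )
        if not res.success or not np.all(np.isfinite(res.x)):
            return RigidTransform(converged=False)
        dx, dy, theta = (float(v) for v in res.x)
    except Exception:
        return RigidTransform(converged=False)
    return RigidTransform(dx=dx, dy=dy, theta=theta)


def bilateral_smooth(
    frame: np.ndarray, sigma_space: float = 2.0, sigma_range: float = 100.0
) -> np.ndarray:
    """Edge-preserving bilateral filter.

    Each output pixel is the weighted mean of its square neighbourhood
    (radius ``ceil(3 * sigma_space)``, reflect padding), with weights equal
    to a spatial Gaussian in the pixel offset times a Gaussian in the
    intensity difference, normalized to unit sum.  Flat-region noise is
    averaged away while step edges (intensity jumps >> sigma_range) are kept
    because cross-edge neighbours receive negligible range weight.

    Returns float64; constant frames pass through unchanged.
    """
    if sigma_space <= 0 or sigma_range <= 0:
        raise ValueError("bilateral sigmas must be positive")
    f = np.asarray(frame, dtype=np.float64)
    radius = max(1, int(math.ceil(3.0 * sigma_space)))
    padded = np.pad(f, radius, mode="reflect")
    num = np.zeros_like(f)
    den = np.zeros_like(f)
    h, w = f.shape
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            ws = math.exp(-(di * di + dj * dj) / (2.0 * sigma_space**2))
            shifted = padded[radius + di : radius + di + h, radius + dj : radius + dj + w]
            wgt = ws * np.exp(-((shifted - f) ** 2) / (2.0 * sigma_range**2))
            num += wgt * shifted
            den += wgt
    return num / den


def otsu_threshold(frame: np.ndarray) -> tuple[float | None, np.ndarray]:
    """Otsu's threshold (maximum between-class variance) and the binary mask
    ``frame > threshold``.

    A constant frame has no threshold: returns ``(None, empty mask)`` so the
    caller can flag the frame.
    """
    f = np.asarray(frame)
    if f.min() == f.max():
        return None, np.zeros(f.shape, dtype=bool)
    thr = float(threshold_otsu(f))
    return thr, f > thr


def remove_boundary_singularities(
    mask: np.ndarray, area_frac: float = 0.01
) -> np.ndarray:
    """Delete small connected components that touch the image border.

    Border-touching 8-connected components smaller than ``area_frac`` of the
    frame area are removed (these are the spill-over "singularities" of a
    dual-view edge or dust at the frame boundary); the largest component is
    always retained so the principal object survives even when it touches
    the border.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m.copy()
    labels = cc_label(m, connectivity=2)
    n = labels.max()
    areas = np.bincount(labels.ravel())[1:]
    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    principal = int(np.argmax(areas)) + 1
    min_area = area_frac * m.size
    keep = np.ones(n + 1, dtype=bool)
    for cid in range(1, n + 1):
        if cid != principal and border[cid] and areas[cid - 1] < min_area:
            keep[cid] = False
    return keep[labels] & m


@dataclass
class RatioFrame:
    """Acceptor/donor ratio for one frame.

    ``ratio`` is finite and >= 0 inside ``mask`` and exactly 0 outside;
    masked pixels where the donor is 0 are set to 0 and counted in
    ``n_donor_zero``.
    """

    ratio: np.ndarray
    mask: np.ndarray
    n_donor_zero: int = 0
    display: np.ndarray | None = None
    flags: frozenset[str] = frozenset()


def compute_ratio(
    acceptor: np.ndarray, donor: np.ndarray, mask: np.ndarray
) -> RatioFrame:
    """Pixelwise acceptor/donor ratio on the joint foreground mask."""
    acc = np.asarray(acceptor, dtype=np.float64)
    don = np.asarray(donor, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if acc.shape != don.shape or acc.shape != m.shape:
        raise ValueError("acceptor, donor and mask must share a shape")
    flags = set()
    if not m.any():
        flags.add(FLAG_EMPTY_MASK)
    valid = m & (don > 0)
    n_zero = int(m.sum() - valid.sum())
    if n_zero:
        flags.add(FLAG_DONOR_ZERO)
    ratio = np.zeros_like(acc)
    ratio[valid] = acc[valid] / don[valid]
    return RatioFrame(ratio=ratio, mask=m, n_donor_zero=n_zero, flags=frozenset(flags))


def robust_rescale(
    ratio: np.ndarray,
    mask: np.ndarray,
    p_lo: float = 10.0,
    p_hi: float = 90.0,
) -> tuple[np.ndarray, frozenset[str]]:
    """Map the masked ratio values' [p_lo, p_hi] percentile span to 8-bit.

    Percentiles are computed over foreground pixels only, so a single
    extreme outlier cannot set the display scale; values outside the span
    clip to 0/255 and background stays 0.  A flat frame (P_lo == P_hi) is
    rendered mid-gray on the mask and flagged.
    """
    r = np.asarray(ratio, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    out = np.zeros(r.shape, dtype=np.uint8)
    if not m.any():
        return out, frozenset({FLAG_EMPTY_MASK})
    lo, hi = np.percentile(r[m], [p_lo, p_hi])
    if hi <= lo:
        out[m] = 128
        return out, frozenset({FLAG_FLAT_RESCALE})
    scaled = np.clip((r - lo) / (hi - lo) * 255.0, 0, 255)
    out[m] = np.rint(scaled[m]).astype(np.uint8)
    return out, frozenset()
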