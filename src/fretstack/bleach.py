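"""Photobleaching correction from the median frame-intensity trend.

Fluorophores bleach irreversibly under illumination, so the foreground
median intensity of a channel decays over a time-lapse.  A regularized
linear or exponential trend ``M(t)`` is fitted to the median trace over a
user-chosen frame range; the lower bound of that range defines the onset of
bleaching.  Frames from the onset on are rescaled by the multiplicative
factor ``c(t) = M(onset) / M(t)`` (1 before onset), flattening the trend
while leaving short-term signal fluctuations in place.

The exponential model is fitted as a linear regression on ``ln M`` — a
deterministic closed form adequate for monotone decays.  "Regularized"
means an optional ridge (L2) penalty on the slope/rate term only; the
default ``ridge_lambda = 0`` reproduces ordinary least squares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ImageStack


@dataclass
class BleachModel:
    """Fitted bleaching trend plus per-frame correction factors.

    ``params`` is ``(intercept a, slope b)`` for the linear model
    ``M(t) = a + b t`` or ``(amplitude A, rate k)`` for the exponential
    model ``M(t) = A exp(-k t)``.  ``factors[i]`` is the multiplicative
    correction for ``frame_ids[i]``: exactly 1 before the onset and
    ``M(onset)/M(t)`` from the onset on, always finite and positive.
    """

    model_kind: str
    params: tuple[float, float]
    fit_range: tuple[int, int]
    frame_ids: np.ndarray
    factors: np.ndarray

    @property
    def onset(self) -> int:
        return self.fit_range[0]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if self.model_kind == "linear":
            a, b = self.params
            return a + b * t
        A, k = self.params
        return A * np.exp(-k * t)


def _ridge_line(t: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    """Least squares for y = a + b t with an L2 penalty ``lam`` on b only."""
    n = len(t)
    St, Stt = t.sum(), (t * t).sum()
    Sy, Sty = y.sum(), (t * y).sum()
    A = np.array([[n, St], [St, Stt + lam]])
    a, b = np.linalg.solve(A, np.array([Sy, Sty]))
    return float(a), float(b)


def fit_bleach(
    medians: np.ndarray,
    fit_range: tuple[int, int],
    model_kind: str = "exponential",
    ridge_lambda: float = 0.0,
    frame_ids: np.ndarray | None = None,
) -> BleachModel:
    """Fit the bleaching trend to a median-intensity trace.

    Parameters
    ----------
    medians : array
        Median frame intensity per frame (must be positive over the fit
        range for the exponential model).
    fit_range : (lo, hi)
        Inclusive frame-id interval used for the fit; ``lo`` is the onset
        of bleaching.
    model_kind : {"linear", "exponential"}
    ridge_lambda : float
        L2 penalty on the slope (linear) or rate (exponential) term; 0
        gives plain least squares.
    frame_ids : array, optional
        Frame ids for each entry of ``medians`` (defaults to 0..n-1); the
        time axis of the fit, so discontinuous stacks keep their original
        spacing.
    """
    y = np.asarray(medians, dtype=np.float64)
    if frame_ids is None:
        frame_ids = np.arange(len(y))
    frame_ids = np.asarray(frame_ids)
    if model_kind not in ("linear", "exponential"):
        raise ValueError(f"model_kind must be linear|exponential, got {model_kind!r}")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    lo, hi = fit_range
    sel = (frame_ids >= lo) & (frame_ids <= hi)
    if sel.sum() < 3:
        raise ValueError(f"fit range {lo}-{hi} covers {int(sel.sum())} frames; need >= 3")
    t, yf = frame_ids[sel].astype(np.float64), y[sel]

    if model_kind == "linear":
        a, b = _ridge_line(t, yf, ridge_lambda)
        params = (a, b)
    else:
        if np.any(yf <= 0):
            raise ValueError("exponential bleach fit requires positive medians over the fit range")
        a, b = _ridge_line(t, np.log(yf), ridge_lambda)
        params = (float(np.exp(a)), float(-b))

    model = BleachModel(
        model_kind=model_kind,
        params=params,
        fit_range=(int(lo), int(hi)),
        frame_ids=frame_ids.copy(),
        factors=np.ones(len(frame_ids)),
    )
    pred = model.predict(frame_ids.astype(np.float64))
    m_onset = float(model.predict(float(lo)))
    after = frame_ids >= lo
    if m_onset <= 0 or np.any(pred[after] <= 0):
        raise ValueError("fitted trend is non-positive at corrected frames; cannot form factors")
    factors = np.ones(len(frame_ids))
    factors[after] = m_onset / pred[after]
    model.factors = factors
    return model


def apply_bleach(stack: ImageStack, model: BleachModel, logger=None) -> ImageStack:
    """Multiply each frame by its correction factor (integer stacks saturate
    at the bit-depth maximum; saturation is logged)."""
    if not np.array_equal(model.frame_ids, stack.frame_ids):
        raise ValueError("bleach model frame_ids do not match the stack")
    out = np.empty_like(stack.frames)
    maxv = stack.max_value
    n_sat = 0
    for i in range(stack.n_frames):
        scaled = np.rint(stack.frames[i].astype(np.float64) * model.factors[i])
        n_sat += int((scaled > maxv).sum())
        out[i] = np.clip(scaled, 0, maxv).astype(stack.frames.dtype)
    if n_sat and logger is not None:
        logger.warning("bleach correction saturated %d pixels at %d", n_sat, maxv)
    return stack.with_frames(out)


def correct_ratio_stack(
    ratio_frames: np.ndarray,
    donor_model: BleachModel | None,
    acceptor_model: BleachModel | None,
) -> np.ndarray:
    """Apply bleach correction to a ratio stack.

    The ratio scales as ``c_acceptor / c_donor`` (an unselected channel
    contributes factor 1).  When both channels carry the same factors the
    quotient is exactly 1 for every frame and the ratio stack is returned
    bit-identical — common bleaching cancels in a ratiometric measurement.
    """
    r = np.asarray(ratio_frames, dtype=np.float64)
    n = r.shape[0]
    fa = acceptor_model.factors if acceptor_model is not None else np.ones(n)
    fd = donor_model.factors if donor_model is not None else np.ones(n)
    if len(fa) != n or len(fd) != n:
        raise ValueError("bleach factors do not match the number of ratio frames")
    quotient = fa / fd
    if np.all(quotient == 1.0):
        return r.copy()
    return r * quotient[:, None, None]
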