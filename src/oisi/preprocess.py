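"""Raw-stack preprocessing: spatial smoothing, illumination correction, trial averaging.

The correction targets the dominant artifact of widefield imaging — slow,
spatially shared illumination fluctuations.  A reference region assumed free
of evoked response provides the shared profile I_ref(t) (mean over reference
pixels); each pixel is corrected as

    I_corr(t) = I(t) - alpha * I_ref(t),      alpha = < I(t) / I_ref(t) >_t

with alpha estimated per pixel over the whole trial (optionally over the
baseline window only).  A purely multiplicative fluctuation shared with the
reference region is removed exactly by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import FrameStack, ROIMask, TrialSet

__all__ = [
    "spatial_filter",
    "illumination_correct",
    "average_trials",
    "default_reference_mask",
]

#: kernel truncation radius in units of sigma
_TRUNCATE = 4.0


def spatial_filter(stack: FrameStack, sigma_px: float = 2.0) -> FrameStack:
    """Per-frame 2-D Gaussian smoothing (normalized kernel, reflect boundary).

    The default sigma of 2 px matches the analysis scale of ~35 um pixels.
    """
    if not np.isfinite(sigma_px) or sigma_px <= 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px}")
    smoothed = ndimage.gaussian_filter(
        stack.data, sigma=(0.0, sigma_px, sigma_px), mode="reflect", truncate=_TRUNCATE
    )
    return stack.with_data(smoothed)


def default_reference_mask(
    frame_shape: tuple[int, int],
    margin_px: int = 10,
    exclude: ROIMask | None = None,
) -> ROIMask:
    """Border-frame reference region: the outer ``margin_px`` pixels.

    Stands in for an operator-drawn response-free region; any known or
    candidate active region can be excluded explicitly.
    """
    h, w = frame_shape
    if margin_px <= 0 or 2 * margin_px >= min(h, w):
        raise ValueError(f"margin_px {margin_px} invalid for frame {frame_shape}")
    mask = np.ones((h, w), dtype=bool)
    mask[margin_px : h - margin_px, margin_px : w - margin_px] = False
    if exclude is not None:
        mask &= ~exclude.mask
    return ROIMask(mask=mask, role="reference")


def illumination_correct(
    stack: FrameStack,
    reference: ROIMask,
    alpha_window: str = "full",
) -> FrameStack:
    """Subtract the scaled reference time profile from every pixel.

    ``alpha_window`` selects the averaging window for alpha: ``"full"``
    (whole trial, the default) or ``"baseline"`` (pre-stimulus frames only).
    Returns a signed stack in camera counts.
    """
    if reference.role != "reference":
        raise ValueError("illumination correction needs a mask with role='reference'")
    if reference.mask.shape != stack.frame_shape:
        raise ValueError("reference mask shape does not match the frames")
    if alpha_window not in ("full", "baseline"):
        raise ValueError(f"unknown alpha_window {alpha_window!r}")

    i_ref = stack.data[:, reference.mask].mean(axis=1)
    if np.any(i_ref <= 0):
        raise ValueError("reference intensity is zero or negative at some frame")
    if np.any(i_ref < 0.01 * np.median(i_ref)):
        raise ValueError("reference intensity drops below 1% of its median")

    ratio = stack.data / i_ref[:, None, None]
    if alpha_window == "baseline":
        ratio = ratio[stack.protocol.baseline_slice()]
    alpha = ratio.mean(axis=0)
    corrected = stack.data - alpha[None, :, :] * i_ref[:, None, None]
    return stack.with_data(corrected)


def average_trials(trials: TrialSet) -> FrameStack:
    """Per-frame arithmetic mean across trials (shapes checked by TrialSet).

    Accumulates in extended precision so the result is independent of trial
    order down to the last float64 bit.
    """
    acc = np.zeros(trials.trials[0].shape, dtype=np.longdouble)
    for tr in trials.trials:
        acc += tr.data
    mean = (acc / trials.n_trials).astype(float)
    return trials.trials[0].with_data(mean)
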