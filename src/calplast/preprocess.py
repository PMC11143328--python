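"""Rigid motion correction, ΔF/F computation, and temporal smoothing.

The preprocessing chain mirrors standard practice for GCaMP imaging of
Purkinje-cell dendrites: whole-frame rigid registration by cross-correlation,
baseline normalization ``ΔF/F = (F_t − F_0)/F_0`` with ``F_0`` the 20th
percentile of the full fluorescence trace, and a five-frame centered moving
average to suppress shot noise before event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "ShiftSeries",
    "motion_correct",
    "compute_dff",
    "smooth",
]


@dataclass
class FluorescenceTrace:
    """Raw fluorescence time series ``F_t`` for one ROI.

    Parameters
    ----------
    values : ndarray
        Mean fluorescence over the ROI mask, one sample per frame.
    frame_rate : float
        Acquisition rate in Hz.
    """

    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from trace start."""
        return np.arange(self.values.size) / self.frame_rate


@dataclass
class DffTrace:
    """Baseline-normalized fluorescence trace (ΔF/F).

    ``f0`` is the baseline used for normalization; it must be positive or
    ΔF/F is undefined.
    """

    values: np.ndarray
    f0: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


@dataclass
class ShiftSeries:
    """Per-frame rigid displacement estimated by registration.

    ``shifts[k] = (dy, dx)`` is the displacement of frame ``k`` relative to
    the reference (the translation that was applied to the reference to
    produce the frame).  ``scores`` holds the normalized cross-correlation at
    the chosen peak; ``valid[k]`` is False where the shift was undefined
    (zero-variance frame) and reported as (0, 0).
    """

    shifts: np.ndarray
    scores: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.shifts), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.shifts) == len(self.scores) == len(self.valid)):
            raise ValueError("shifts, scores and valid must have equal length")


def _signed_argmax_shift(xc: np.ndarray) -> tuple[int, int]:
    """Map the argmax of a circular cross-correlogram to signed (dy, dx)."""
    ny, nx = xc.shape
    iy, ix = np.unravel_index(int(np.argmax(xc)), xc.shape)
    dy = iy - ny if iy > ny // 2 else iy
    dx = ix - nx if ix > nx // 2 else ix
    return int(dy), int(dx)


def motion_correct(
    stack: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, ShiftSeries]:
    """Rigid registration of a frame stack by whole-frame cross-correlation.

    Each frame's integer displacement relative to ``reference`` is the argmax
    of their circular cross-correlation (means subtracted); the frame is then
    translated back by that displacement.  Shifts are whole pixels only — the
    registration is deliberately rigid.

    Parameters
    ----------
    stack : ndarray, shape (n_frames, ny, nx)
        Frame stack in acquisition order.
    reference : ndarray, optional
        Registration target.  Defaults to the mean of the whole stack; a
        typical pipeline passes the mean of the first trial's frames.

    Returns
    -------
    corrected : ndarray
        Stack with each frame translated to the reference, same dtype rules
        as the input promoted to float.
    shifts : ShiftSeries
        Estimated per-frame (dy, dx), peak correlation score, and a validity
        flag (False for zero-variance frames, which get shift (0, 0)).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_frames, ny, nx)")
    if reference is None:
        reference = stack.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != stack.shape[1:]:
        raise ValueError("reference must have the same shape as each frame")

    ref0 = reference - reference.mean()
    ref_norm = np.linalg.norm(ref0)
    fref = np.conj(np.fft.fft2(ref0))

    n = stack.shape[0]
    corrected = np.empty_like(stack)
    shifts = np.zeros((n, 2), dtype=int)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)

    for k in range(n):
        frame = stack[k]
        f0 = frame - frame.mean()
        f_norm = np.linalg.norm(f0)
        if f_norm == 0 or ref_norm == 0:
            # flat frame: displacement undefined, report (0, 0) and flag it
            corrected[k] = frame
            scores[k] = np.nan
            valid[k] = False
            continue
        xc = np.fft.ifft2(fref * np.fft.fft2(f0)).real
        dy, dx = _signed_argmax_shift(xc)
        shifts[k] = (dy, dx)
        scores[k] = xc.max() / (ref_norm * f_norm)
        corrected[k] = np.roll(frame, (-dy, -dx), axis=(0, 1))

    return corrected, ShiftSeries(shifts=shifts, scores=scores, valid=valid)


def compute_dff(trace: FluorescenceTrace, percentile: float = 20.0) -> DffTrace:
    """ΔF/F normalization with a percentile baseline.

    ``F_0`` is the 20th percentile of the whole trace (linear interpolation
    between order statistics); the output is ``(F_t − F_0)/F_0``.  Baselines
    ≤ 0 make ΔF/F undefined and raise.

    The percentile is taken over the trace as passed in: concatenate trials
    first for a per-session baseline (the default analysis), or call per
    trial for a per-trial baseline.
    """
    f0 = float(np.percentile(trace.values, percentile))
    if f0 <= 0:
        raise ValueError(
            f"baseline undefined: {percentile:g}th percentile is {f0:g} <= 0"
        )
    return DffTrace(
        values=(trace.values - f0) / f0, f0=f0, frame_rate=trace.frame_rate
    )


def smooth(trace: DffTrace, window: int = 5) -> DffTrace:
    """Centered moving-average smoothing.

    ``window`` must be odd so the average is centered; at the boundaries the
    window shrinks to the available samples (no padding values are invented),
    so the output length equals the input length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = trace.values.size
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    kernel = np.ones(window)
    sums = np.convolve(trace.values, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return DffTrace(values=sums / counts, f0=trace.f0, frame_rate=trace.frame_rate)
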