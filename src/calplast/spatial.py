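"""Spatial quantification of dendritic potentiation along linescans.

A linescan profile assigns each pixel along the dendritic cross-section a
response value (mean over trials of the within-window maximum ΔF/F).  After
normalizing a pre/post-tetanus pair by the pre-tetanus maximum, the
cumulative length CL(f) is the total dendritic length (μm) whose normalized
response reaches level f; Δlength(f) = CL_post(f) − CL_pre(f) measures the
tetanus-induced spatial expansion at each level.  The *hotspot* band
(normalized level > 0.9) captures the parallel-fibre-responsive segment; the
*off-hotspot* band (0.3–0.67) captures spread of potentiation beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinescanProfile",
    "CumulativeCurve",
    "DeltaLengthCurve",
    "RegionBands",
    "extract_profile",
    "normalize_pair",
    "cumulative_length",
    "delta_length",
    "band_metrics",
    "exclude_global_responders",
    "default_levels",
    "resample_polyline",
]

#: level-grid step for cumulative-length curves (normalized ΔF/F)
LEVEL_STEP = 0.01


@dataclass
class LinescanProfile:
    """Per-pixel response profile along a dendritic linescan.

    values : ΔF/F (raw or normalized) per linescan pixel.
    pixel_len : μm per linescan pixel (the reslice output spacing, ~15 μm).
    condition : 'pre', 'early_post' or 'late_post'.
    """

    values: np.ndarray
    pixel_len: float
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")
        if self.pixel_len <= 0:
            raise ValueError("pixel_len must be positive")

    @property
    def total_length(self) -> float:
        return self.pixel_len * self.values.size


@dataclass
class CumulativeCurve:
    """CL(f): dendritic length at or above each fluorescence level."""

    levels: np.ndarray
    lengths: np.ndarray
    pixel_len: float
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.levels.shape != self.lengths.shape:
            raise ValueError("levels and lengths must align")


@dataclass
class DeltaLengthCurve:
    """Δlength(f) between two cumulative-length curves on a shared grid.

    ``orientation='post_minus_pre'`` (the default) makes spatial expansion
    positive; the opposite sign convention is selectable.
    """

    levels: np.ndarray
    delta: np.ndarray
    pixel_len: float
    orientation: str = "post_minus_pre"


@dataclass
class RegionBands:
    """Hotspot and off-hotspot level bands on the normalized scale.

    The hotspot band is the open interval above ``hotspot_level`` (strictly
    > 0.9 by convention); the off-hotspot band is the closed interval
    [0.3, 0.67].  The two bands are disjoint by construction.
    """

    hotspot_level: float = 0.9
    off_band: tuple[float, float] = (0.3, 0.67)

    def __post_init__(self) -> None:
        lo, hi = self.off_band
        if not lo < hi:
            raise ValueError("off band must be an increasing interval")
        if hi >= self.hotspot_level:
            raise ValueError("bands must be disjoint (off band below hotspot level)")

    def hotspot_mask(self, levels: np.ndarray) -> np.ndarray:
        return np.asarray(levels) > self.hotspot_level

    def off_mask(self, levels: np.ndarray) -> np.ndarray:
        levels = np.asarray(levels)
        lo, hi = self.off_band
        return (levels >= lo) & (levels <= hi)


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an ordered polyline at fixed arc-length spacing.

    ``points`` are (y, x) vertices in pixel coordinates; the result is the
    sequence of (y, x) sample positions every ``spacing`` units along the
    line, starting at the first vertex.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline needs at least two (y, x) vertices")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, arc[-1] + 1e-9, spacing)
    ys = np.interp(targets, arc, pts[:, 0])
    xs = np.interp(targets, arc, pts[:, 1])
    return np.column_stack([ys, xs])


def extract_profile(
    linescan: np.ndarray,
    frame_rate: float,
    stim_times: np.ndarray | list[float],
    window_len: float = 0.2,
    pixel_len: float = 15.0,
    condition: str = "pre",
) -> LinescanProfile:
    """Collapse a pixels×time linescan map to a per-pixel response profile.

    For each trial the within-window maximum ΔF/F is taken at every pixel
    (window ``[stim, stim + window_len)`` on the map's concatenated
    timeline); the profile is the mean of those maxima over trials.
    """
    m = np.asarray(linescan, dtype=float)
    if m.ndim != 2:
        raise ValueError("linescan map must be 2-D (pixels × frames)")
    stim_times = np.atleast_1d(np.asarray(stim_times, dtype=float))
    if stim_times.size == 0:
        raise ValueError("need at least one trial")
    t = np.arange(m.shape[1]) / frame_rate
    per_trial = []
    for s in stim_times:
        in_win = (t >= s) & (t < s + window_len)
        if not in_win.any():
            raise ValueError(f"window at {s:g} s contains no samples")
        per_trial.append(m[:, in_win].max(axis=1))
    return LinescanProfile(
        values=np.mean(per_trial, axis=0), pixel_len=pixel_len, condition=condition
    )


def normalize_pair(
    pre: LinescanProfile, post: LinescanProfile
) -> tuple[LinescanProfile, LinescanProfile]:
    """Normalize both profiles by the pre-tetanus maximum.

    After normalization the pre profile peaks at exactly 1; the post profile
    may exceed 1 where responses potentiated.  Already-normalized input
    passes through unchanged (the operation is idempotent).
    """
    m = float(pre.values.max())
    if m <= 0:
        raise ValueError("pre-tetanus maximum must be positive")
    return (
        LinescanProfile(pre.values / m, pre.pixel_len, pre.condition),
        LinescanProfile(post.values / m, post.pixel_len, post.condition),
    )


def default_levels(*profiles: LinescanProfile, step: float = LEVEL_STEP) -> np.ndarray:
    """Shared level grid from 0 to the largest profile maximum, step 0.01."""
    top = max(float(p.values.max()) for p in profiles)
    n = int(np.ceil(max(top, 0.0) / step))
    return np.arange(n + 1) * step


def cumulative_length(
    profile: LinescanProfile, levels: np.ndarray | None = None
) -> CumulativeCurve:
    """Cumulative dendritic length at or above each fluorescence level.

    ``CL(f) = pixel_len × #{pixels with value ≥ f}``: non-increasing in f,
    equal to the total profile length at f = 0, and zero above the profile
    maximum.  Pixel location is deliberately discarded — the statistic
    measures how much dendrite reaches a response level, not where.
    """
    if levels is None:
        levels = default_levels(profile)
    levels = np.asarray(levels, dtype=float)
    counts = (profile.values[None, :] >= levels[:, None]).sum(axis=1)
    return CumulativeCurve(
        levels=levels,
        lengths=profile.pixel_len * counts.astype(float),
        pixel_len=profile.pixel_len,
        condition=profile.condition,
    )


def delta_length(
    pre_curve: CumulativeCurve,
    post_curve: CumulativeCurve,
    orientation: str = "post_minus_pre",
) -> DeltaLengthCurve:
    """Pointwise difference of two cumulative-length curves.

    With the default orientation (post − pre) a positive Δlength means the
    tetanus expanded the dendritic extent reaching that level.
    """
    if pre_curve.levels.shape != post_curve.levels.shape or not np.allclose(
        pre_curve.levels, post_curve.levels
    ):
        raise ValueError("curves must share the same level grid")
    if orientation == "post_minus_pre":
        d = post_curve.lengths - pre_curve.lengths
    elif orientation == "pre_minus_post":
        d = pre_curve.lengths - post_curve.lengths
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return DeltaLengthCurve(
        levels=pre_curve.levels.copy(),
        delta=d,
        pixel_len=pre_curve.pixel_len,
        orientation=orientation,
    )


def band_metrics(
    curve: DeltaLengthCurve, bands: RegionBands | None = None
) -> tuple[float, float]:
    """Mean Δlength over the hotspot and off-hotspot level bands.

    Returns ``(hotspot_mean, offhotspot_mean)`` in μm.  Raises when a band
    contains no grid levels.
    """
    if bands is None:
        bands = RegionBands()
    hot = bands.hotspot_mask(curve.levels)
    off = bands.off_mask(curve.levels)
    if not hot.any():
        raise ValueError("no grid levels inside the hotspot band")
    if not off.any():
        raise ValueError("no grid levels inside the off-hotspot band")
    return float(curve.delta[hot].mean()), float(curve.delta[off].mean())


def exclude_global_responders(
    profiles: list[LinescanProfile],
    inclusion_level: float = 0.9,
    coverage_cutoff: float = 0.9,
) -> list[int]:
    """Indices of profiles that do NOT respond across the whole cross-section.

    A normalized profile whose fraction of pixels above ``inclusion_level``
    strictly exceeds ``coverage_cutoff`` responds essentially everywhere, so
    hotspot and off-hotspot regions cannot be distinguished and the cell is
    dropped.  Coverage exactly at the cutoff is retained.
    """
    kept = []
    for i, prof in enumerate(profiles):
        coverage = float((prof.values > inclusion_level).mean())
        if not coverage > coverage_cutoff:
            kept.append(i)
    return kept
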