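"""Reading and writing the external formats: TIFF stacks, ROI masks,
session manifests, and tidy CSV tables."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "Roi",
    "RoiSet",
    "extract_roi_traces",
    "SessionManifest",
    "session_to_frame",
    "frame_to_sessions",
]

ROI_KINDS = ("dendrite", "soma", "ais", "linescan_polyline")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (n_frames, ny, nx) array.

    Pages are returned in acquisition order with the stored dtype; a
    truncated or unreadable page raises with the page index in the message.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = []
        for i, page in enumerate(tif.pages):
            try:
                frames.append(page.asarray())
            except Exception as exc:  # corrupt page: name it
                raise IOError(f"{path}: failed to read TIFF page {i}: {exc}") from exc
    if not frames:
        raise IOError(f"{path}: TIFF file contains no pages")
    return np.stack(frames, axis=0)


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (n_frames, ny, nx) array as a multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_frames, ny, nx)")
    tifffile.imwrite(Path(path), stack)


@dataclass
class Roi:
    """One region of interest: id, boolean mask on the imaging grid, kind."""

    roi_id: str
    mask: np.ndarray
    kind: str = "dendrite"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {ROI_KINDS}")


@dataclass
class RoiSet:
    """A collection of ROIs sharing one imaging grid."""

    rois: list[Roi]

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    @classmethod
    def from_label_image(cls, labels: np.ndarray, kind: str = "dendrite") -> "RoiSet":
        """Build ROIs from a label image: one ROI per nonzero label value."""
        labels = np.asarray(labels)
        ids = np.unique(labels)
        ids = ids[ids != 0]
        return cls([Roi(roi_id=str(int(v)), mask=labels == v, kind=kind) for v in ids])

    @classmethod
    def from_polygons(
        cls, polygons: dict[str, list[list[float]]], shape: tuple[int, int],
        kind: str = "dendrite",
    ) -> "RoiSet":
        """Rasterize (y, x) polygon vertex lists onto an image grid."""
        from skimage.draw import polygon2mask

        rois = []
        for roi_id, verts in polygons.items():
            pts = np.asarray(verts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"ROI {roi_id!r}: vertices must be (y, x) pairs")
            rois.append(Roi(roi_id=roi_id, mask=polygon2mask(shape, pts), kind=kind))
        return cls(rois)


def extract_roi_traces(stack: np.ndarray, rois: RoiSet) -> dict[str, np.ndarray]:
    """Per-ROI raw fluorescence: mean over the mask pixels in each frame."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_frames, ny, nx)")
    out = {}
    for roi in rois:
        if roi.mask.shape != stack.shape[1:]:
            raise ValueError(f"ROI {roi.roi_id!r}: mask shape does not match frames")
        if not roi.mask.any():
            raise ValueError(f"ROI {roi.roi_id!r}: empty mask")
        out[roi.roi_id] = stack[:, roi.mask].mean(axis=1)
    return out


@dataclass
class SessionManifest:
    """Protocol metadata for one recording.

    trial_bounds are half-open frame-index intervals [start, end), ascending
    and non-overlapping; stim_time is seconds from trial start; condition is
    one of pre / early_post / late_post per trial.
    """

    frame_rate: float
    trial_bounds: list[tuple[int, int]]
    stim_time: list[float]
    condition: list[str]
    stim_intensity: list[float] | None = None
    modality: str = "PF"
    regime_label: str = ""
    pixel_size: float = 1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        n = len(self.trial_bounds)
        if len(self.stim_time) != n or len(self.condition) != n:
            raise ValueError("per-trial fields must have one entry per trial")
        if self.stim_intensity is not None and len(self.stim_intensity) != n:
            raise ValueError("per-trial fields must have one entry per trial")
        prev_end = -1
        for s, e in self.trial_bounds:
            if not s < e:
                raise ValueError(f"trial bounds ({s}, {e}) must be increasing")
            if s < prev_end:
                raise ValueError("trial bounds must be ascending and non-overlapping")
            prev_end = e
        for c in self.condition:
            if c not in ("pre", "early_post", "late_post"):
                raise ValueError(f"unknown condition label {c!r}")

    @property
    def n_trials(self) -> int:
        return len(self.trial_bounds)

    @property
    def n_frames(self) -> int:
        return self.trial_bounds[-1][1] if self.trial_bounds else 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["trial_bounds"] = [list(b) for b in self.trial_bounds]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionManifest":
        """Load a manifest from JSON (or YAML, by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        d["trial_bounds"] = [tuple(b) for b in d["trial_bounds"]]
        return cls(**d)


def session_to_frame(sessions: dict[str, dict[str, "np.ndarray"]]) -> pd.DataFrame:
    """Long table of raw traces: (cell, condition, trial, frame, f).

    ``sessions[condition][cell]`` is a 2-D array (n_trials, n_frames).
    """
    rows = []
    for cond, cells in sessions.items():
        for cell, arr in cells.items():
            arr = np.asarray(arr)
            for k in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "cell": cell,
                            "condition": cond,
                            "trial": k,
                            "frame": np.arange(arr.shape[1]),
                            "f": arr[k],
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def frame_to_sessions(df: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """Inverse of :func:`session_to_frame`."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for (cond, cell), sub in df.groupby(["condition", "cell"], sort=False):
        trials = []
        for _, tr in sub.groupby("trial", sort=True):
            trials.append(tr.sort_values("frame")["f"].to_numpy())
        out.setdefault(cond, {})[cell] = np.stack(trials)
    return out
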