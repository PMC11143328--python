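"""High-level chains from simulated or extracted traces to summary statistics.

These helpers wire the stage modules together the way the standard analysis
runs: concatenate a cell's trials, compute one ΔF/F baseline for the whole
session, smooth, split back into trials, detect events, classify each trial
against the response window, and summarize.  The command-line interface and
the recovery tests both go through this path.
"""

from __future__ import annotations

import numpy as np

from calplast.events import (
    DetectionParams,
    EventStats,
    TrialRecord,
    classify_trial,
    detect_events,
    summarize,
)
from calplast.plasticity import PlasticityResult, normalize_to_baseline
from calplast.preprocess import DffTrace, FluorescenceTrace, compute_dff, smooth
from calplast.synth import Session

__all__ = [
    "dff_trials",
    "analyze_session",
    "analyze_plasticity",
]


def dff_trials(
    session: Session,
    smooth_window: int = 5,
    f0: float | None = None,
    percentile: float = 20.0,
) -> list[DffTrace]:
    """Per-trial smoothed ΔF/F traces with a session-wide baseline.

    Trials are concatenated, ΔF/F is computed with the 20th-percentile
    baseline of the concatenated trace (or a caller-supplied ``f0``, e.g.
    shared across pre/post sessions), the result is smoothed, and the trace
    is split back into trials.
    """
    concat = session.concatenated()
    if f0 is None:
        dff = compute_dff(concat, percentile=percentile)
    else:
        if f0 <= 0:
            raise ValueError("f0 must be positive")
        dff = DffTrace(
            values=(concat.values - f0) / f0, f0=f0, frame_rate=concat.frame_rate
        )
    sm = smooth(dff, window=smooth_window)
    n_frames = session.trials[0].values.size
    out = []
    for k in range(len(session.trials)):
        out.append(
            DffTrace(
                values=sm.values[k * n_frames: (k + 1) * n_frames],
                f0=sm.f0,
                frame_rate=sm.frame_rate,
            )
        )
    return out


def analyze_session(
    session: Session,
    params: DetectionParams | None = None,
    mode: str = "peak_amplitude",
    smooth_window: int = 5,
    f0: float | None = None,
) -> tuple[EventStats, list[TrialRecord]]:
    """Detect, classify and summarize every trial of one session."""
    if params is None:
        params = DetectionParams()
    traces = dff_trials(session, smooth_window=smooth_window, f0=f0)
    records = []
    for k, (trial, trace) in enumerate(zip(session.trials, traces)):
        events = detect_events(trace, params)
        records.append(
            classify_trial(
                trace,
                events,
                stim_time=trial.stim_time,
                trial_id=k,
                intensity=trial.intensity,
                condition=trial.condition,
            )
        )
    return summarize(records, mode=mode), records


def analyze_plasticity(
    sessions: dict[str, Session],
    params: DetectionParams | None = None,
    mode: str = "peak_amplitude",
    smooth_window: int = 5,
    cell_id: str = "",
    shared_f0: bool = True,
) -> PlasticityResult:
    """Normalized post-tetanus amplitude and probability for one cell.

    With ``shared_f0`` (the default, matching the practice of concatenating
    all trials of a recording before baseline estimation) a single
    20th-percentile baseline is computed over every condition's trials and
    applied to each; otherwise each condition gets its own baseline.
    """
    if "pre" not in sessions:
        raise ValueError("sessions must include a 'pre' condition")
    f0 = None
    if shared_f0:
        all_vals = np.concatenate(
            [t.values for cond in sessions.values() for t in cond.trials]
        )
        f0 = float(np.percentile(all_vals, 20.0))
        if f0 <= 0:
            raise ValueError("baseline undefined on concatenated sessions")
    stats = {
        cond: analyze_session(
            sess, params=params, mode=mode, smooth_window=smooth_window, f0=f0
        )[0]
        for cond, sess in sessions.items()
    }
    return normalize_to_baseline(stats, cell_id=cell_id)
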