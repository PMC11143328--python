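"""Calcium-event detection, trial classification, and the shuffled-window null.

Events are local maxima of the smoothed ΔF/F trace that clear both an
absolute height threshold and a topographic-prominence threshold (default
0.09 ΔF/F each, roughly one SD of the pre-stimulus baseline).  A trial is
*responsive* when at least one detected peak falls inside the response
window, by convention the half-open interval [stimulus onset, onset+200 ms).
Spontaneous activity is quantified by the same detector applied to 200 ms
windows drawn at random from the pre-stimulus period (−4.5 to −0.5 s
relative to the stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from calplast.preprocess import DffTrace

__all__ = [
    "DetectionParams",
    "CalciumEvent",
    "TrialRecord",
    "EventStats",
    "detect_events",
    "classify_trial",
    "shuffled_null",
    "summarize",
]

#: length of the response / shuffling window, seconds
RESPONSE_WINDOW_S = 0.2
#: range for shuffled-window sampling, seconds relative to stimulus onset
SHUFFLE_RANGE_S = (-4.5, -0.5)


@dataclass
class DetectionParams:
    """Thresholds for event detection and responder classification.

    threshold, prominence : ΔF/F units; a peak must clear both.
    inclusion_criterion : ΔF/F; the calcium-event inclusion level used by the
        weak-responder filter (kept independent of the detection threshold).
    """

    threshold: float = 0.09
    prominence: float = 0.09
    inclusion_criterion: float = 0.9

    def __post_init__(self) -> None:
        if not (self.threshold > 0 and self.prominence > 0 and self.inclusion_criterion > 0):
            raise ValueError("all detection parameters must be positive")


@dataclass
class CalciumEvent:
    """One detected event: peak time (s), ΔF/F at the peak, prominence."""

    peak_time: float
    amplitude: float
    prominence: float
    peak_index: int = 0


@dataclass
class TrialRecord:
    """Per-trial detection outcome against the response window."""

    trial_id: int
    stim_time: float
    window: tuple[float, float]
    events: list[CalciumEvent]
    responsive: bool
    max_in_window: float
    intensity: float | None = None
    condition: str | None = None


@dataclass
class EventStats:
    """Per-cell, per-condition response summary.

    probability : responsive trials / total trials.
    amplitude_mean : mean detected-peak amplitude over responsive trials
        (``mode='peak_amplitude'``) or mean max-in-window over all trials
        (``mode='max_in_window'``); NaN when no trial contributes.
    """

    probability: float
    amplitude_mean: float
    n_trials: int
    mode: str = "peak_amplitude"
    amplitude_sem: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def detect_events(trace: DffTrace, params: DetectionParams | None = None) -> list[CalciumEvent]:
    """Detect calcium events on a (smoothed) ΔF/F trace.

    A sample is an event peak when it is a local maximum whose height is at
    least ``params.threshold`` and whose topographic prominence is at least
    ``params.prominence``.  Plateau maxima are attributed to their earliest
    frame.  The first and last samples cannot be peaks (no neighbour on one
    side).  Events are returned in time order; an empty list is a valid
    result.
    """
    if params is None:
        params = DetectionParams()
    x = trace.values
    idx, props = find_peaks(
        x,
        height=params.threshold,
        prominence=params.prominence,
        plateau_size=(1, None),
    )
    # earliest-frame convention for flat peaks
    peaks = props["left_edges"]
    return [
        CalciumEvent(
            peak_time=float(p / trace.frame_rate),
            amplitude=float(x[p]),
            prominence=float(prom),
            peak_index=int(p),
        )
        for p, prom in zip(peaks, props["prominences"])
    ]


def classify_trial(
    trace: DffTrace,
    events: list[CalciumEvent],
    stim_time: float,
    window_len: float = RESPONSE_WINDOW_S,
    trial_id: int = 0,
    intensity: float | None = None,
    condition: str | None = None,
) -> TrialRecord:
    """Classify one trial as responsive or not against the response window.

    The window is half-open, ``[stim_time, stim_time + window_len)``; a trial
    is responsive iff some detected peak time falls inside it.
    ``max_in_window`` is read from the ΔF/F trace itself, independent of
    detection, so sub-threshold responses are still quantified.
    """
    duration = trace.values.size / trace.frame_rate
    if not 0.0 <= stim_time < duration:
        raise ValueError(
            f"stim_time {stim_time:g} s outside trial bounds [0, {duration:g})"
        )
    lo, hi = stim_time, stim_time + window_len
    responsive = any(lo <= ev.peak_time < hi for ev in events)
    t = trace.times
    in_win = (t >= lo) & (t < hi)
    if not in_win.any():
        raise ValueError("response window contains no samples")
    return TrialRecord(
        trial_id=trial_id,
        stim_time=stim_time,
        window=(lo, hi),
        events=list(events),
        responsive=bool(responsive),
        max_in_window=float(trace.values[in_win].max()),
        intensity=intensity,
        condition=condition,
    )


def shuffled_null(
    traces: list[DffTrace],
    stim_times: list[float] | np.ndarray | float,
    n_windows: int,
    seed: int | np.random.Generator,
    params: DetectionParams | None = None,
    sample_range: tuple[float, float] = SHUFFLE_RANGE_S,
    window_len: float = RESPONSE_WINDOW_S,
    event_times: list[np.ndarray] | None = None,
) -> EventStats:
    """Spontaneous-event statistics from randomly placed pre-stimulus windows.

    ``n_windows`` windows of ``window_len`` seconds are drawn uniformly (with
    replacement, over trials and start times) so that each window lies fully
    inside ``[stim + sample_range[0], stim + sample_range[1]]``.  The
    reported probability is the fraction of windows containing at least one
    event peak; the amplitude is the mean of the ΔF/F maximum within each
    window (the shuffled analogue of max-in-window).

    Events are detected on the traces by default.  ``event_times`` (one
    array of peak times per trial, seconds) substitutes a known event
    process — e.g. simulation ground truth, or peaks vetted by manual
    correction — which isolates the window-sampling statistics from the
    detector's temporal resolution (transients closer than roughly the
    kernel decay merge under the prominence criterion).

    Raises if the sampling range extends before the start of a trial.
    """
    if params is None:
        params = DetectionParams()
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stim = np.broadcast_to(np.asarray(stim_times, dtype=float), (len(traces),))

    if event_times is None:
        peak_times = [
            np.array([e.peak_time for e in detect_events(tr, params)])
            for tr in traces
        ]
    else:
        if len(event_times) != len(traces):
            raise ValueError("event_times must have one entry per trial")
        peak_times = [np.asarray(t, dtype=float) for t in event_times]

    lo_off, hi_off = sample_range
    if hi_off - lo_off < window_len:
        raise ValueError("sampling range shorter than the window")
    for tr, s in zip(traces, stim):
        if s + lo_off < 0:
            raise ValueError(
                f"sampling range starts at {s + lo_off:g} s, before trial start"
            )

    which = rng.integers(0, len(traces), size=n_windows)
    starts = rng.uniform(lo_off, hi_off - window_len, size=n_windows)
    hits = 0
    maxima = np.empty(n_windows)
    for k in range(n_windows):
        i = which[k]
        t0 = stim[i] + starts[k]
        pt = peak_times[i]
        if pt.size and np.any((pt >= t0) & (pt < t0 + window_len)):
            hits += 1
        t = traces[i].times
        in_win = (t >= t0) & (t < t0 + window_len)
        maxima[k] = traces[i].values[in_win].max()
    return EventStats(
        probability=hits / n_windows,
        amplitude_mean=float(maxima.mean()),
        amplitude_sem=float(maxima.std(ddof=1) / np.sqrt(n_windows)) if n_windows > 1 else float("nan"),
        n_trials=n_windows,
        mode="max_in_window",
    )


def summarize(trials: list[TrialRecord], mode: str = "peak_amplitude") -> EventStats:
    """Per-cell EventStats over a set of trials.

    probability = responsive trials / total trials.

    mode='peak_amplitude' (electrical parallel-fibre and climbing-fibre
    analyses): amplitude is the mean over *responsive* trials of the largest
    detected-peak amplitude inside the response window.
    mode='max_in_window' (tactile and compartment analyses, where slow
    low-amplitude events escape the detector): amplitude is the mean over
    *all* trials of the trace maximum in the window.
    """
    if not trials:
        raise ValueError("summarize requires at least one trial")
    if mode not in ("peak_amplitude", "max_in_window"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(trials)
    p = sum(tr.responsive for tr in trials) / n
    if mode == "peak_amplitude":
        amps = [
            max(ev.amplitude for ev in tr.events if tr.window[0] <= ev.peak_time < tr.window[1])
            for tr in trials
            if tr.responsive
        ]
    else:
        amps = [tr.max_in_window for tr in trials]
    amps_arr = np.asarray(amps, dtype=float)
    mean = float(amps_arr.mean()) if amps_arr.size else float("nan")
    sem = (
        float(amps_arr.std(ddof=1) / np.sqrt(amps_arr.size))
        if amps_arr.size > 1
        else float("nan")
    )
    return EventStats(
        probability=p, amplitude_mean=mean, amplitude_sem=sem, n_trials=n, mode=mode
    )
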