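"""Synthetic imaging sessions with ground truth for every pipeline stage.

The generator reproduces the statistical structure of awake two-photon
recordings from Purkinje-cell dendrites: 10 s trials at 31 Hz with an
electrical parallel-fibre stimulus at 5 s, or 20 s trials at 62 Hz with a
tactile airpuff at 10 s; spontaneous calcium events as a homogeneous Poisson
process at ~1.1 Hz; an at-most-one evoked event per trial whose probability
(~0.25→0.37) and ΔF/F amplitude rise with stimulus intensity; tetanus-induced
gain changes under three plasticity regimes; linescan profiles with a
localized hotspot; rigid-shifted movies; and correlated
dendrite/soma/axon-initial-segment amplitude sets.

Every generator records the ground truth (event times and amplitudes, regime
gains, true shifts, target correlation) needed by its module's recovery
tests, and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from calplast.preprocess import FluorescenceTrace

__all__ = [
    "SimConfig",
    "RegimeSpec",
    "GroundTruth",
    "TrialTrace",
    "Session",
    "generate_trial_session",
    "generate_intensity_series",
    "generate_plasticity_session",
    "generate_linescan_pair",
    "generate_movie",
    "generate_compartment_data",
    "stimulus_train_span",
    "event_kernel",
]

#: session-stream keys so pre/post sessions draw from independent substreams
_CONDITION_STREAM = {"pre": 0, "early_post": 1, "late_post": 2}

#: nominal baseline fluorescence (arbitrary camera units) used to convert the
#: simulated ΔF/F signal into a raw trace: F_t = F_BASE * (1 + signal + noise)
F_BASE = 1000.0


def stimulus_train_span(n_pulses: int = 8, rate_hz: float = 100.0) -> float:
    """Duration in seconds spanned by a pulse train (first to last pulse).

    The electrical parallel-fibre test stimulus is eight 0.3 ms pulses at
    100 Hz, spanning (8−1)/100 = 0.07 s, i.e. the 0–70 ms portion of the
    0–200 ms response window.
    """
    if n_pulses < 1 or rate_hz <= 0:
        raise ValueError("need n_pulses >= 1 and rate_hz > 0")
    return (n_pulses - 1) / rate_hz


@dataclass
class SimConfig:
    """Parameters of one simulated test session.

    Defaults follow the electrical parallel-fibre protocol: 10 s trials at
    31 Hz with the stimulus at 5 s, spontaneous events at 1.1 Hz, evoked
    probability rising 0.25→0.37 and peak ΔF/F rising linearly across the
    four test intensities (μA).  Switch ``frame_rate=62, trial_len=20,
    stim_time=10`` for the tactile protocol.
    """

    n_trials: int = 12
    frame_rate: float = 31.0
    trial_len: float = 10.0
    stim_time: float = 5.0
    spont_rate: float = 1.1
    evoked_prob_by_intensity: dict[float, float] = field(
        default_factory=lambda: {10.0: 0.25, 20.0: 0.29, 30.0: 0.33, 50.0: 0.37}
    )
    evoked_amp_by_intensity: dict[float, float] = field(
        default_factory=lambda: {10.0: 0.44, 20.0: 0.58, 30.0: 0.72, 50.0: 1.00}
    )
    kernel_rise: float = 0.05
    kernel_decay: float = 0.4
    evoked_latency: float = 0.03
    latency_jitter_sd: float = 0.01
    spont_amp_mean: float = 0.6
    spont_amp_sd: float = 0.2
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.frame_rate <= 0 or self.trial_len <= 0:
            raise ValueError("frame_rate and trial_len must be positive")
        if not 0 <= self.stim_time < self.trial_len:
            raise ValueError("stim_time must lie within the trial")
        for name in ("spont_rate", "noise_sd", "latency_jitter_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.kernel_rise <= 0 or self.kernel_decay <= self.kernel_rise:
            raise ValueError("need 0 < kernel_rise < kernel_decay")
        for i, p in self.evoked_prob_by_intensity.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"evoked probability {p!r} at intensity {i!r} not in [0, 1]")
        if set(self.evoked_amp_by_intensity) != set(self.evoked_prob_by_intensity):
            raise ValueError("probability and amplitude maps must share intensities")

    @property
    def intensities(self) -> list[float]:
        return sorted(self.evoked_prob_by_intensity)

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_len * self.frame_rate))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RegimeSpec:
    """Gains of one plasticity regime applied to post-tetanus sessions.

    ``hotspot_gain`` scales the parallel-fibre-responsive hotspot,
    ``offhotspot_gain`` the rest of the dendrite, ``probability_gain`` the
    evoked response probability.  The whole-dendrite ROI amplitude gain is
    the mean of the two spatial gains (the ROI spans hotspot and
    off-hotspot segments alike).
    """

    name: str
    hotspot_gain: float = 1.0
    offhotspot_gain: float = 1.0
    probability_gain: float = 1.0

    _PRESETS = {
        # wild type: synaptic LTP plus intrinsic amplification
        "both": dict(hotspot_gain=1.5, offhotspot_gain=1.3, probability_gain=1.25),
        # SK2-KO phenotype: synaptic mechanisms only, potentiation stays local
        "local_only": dict(hotspot_gain=1.5, offhotspot_gain=1.0, probability_gain=1.1),
        # CaMKII-TT305/6VA phenotype: intrinsic mechanisms only, widespread
        "global_only": dict(hotspot_gain=1.15, offhotspot_gain=1.3, probability_gain=1.2),
        "control": dict(hotspot_gain=1.0, offhotspot_gain=1.0, probability_gain=1.0),
    }

    def __post_init__(self) -> None:
        if min(self.hotspot_gain, self.offhotspot_gain, self.probability_gain) <= 0:
            raise ValueError("regime gains must be positive")
        if self.name == "control" and not (
            self.hotspot_gain == self.offhotspot_gain == self.probability_gain == 1.0
        ):
            raise ValueError("control regime must have all gains equal to 1")
        if self.name == "local_only" and self.offhotspot_gain != 1.0:
            raise ValueError("local_only regime must leave off-hotspot gain at 1")

    @classmethod
    def preset(cls, name: str) -> "RegimeSpec":
        try:
            return cls(name=name, **cls._PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown regime {name!r}; choose from {sorted(cls._PRESETS)}"
            ) from None

    @property
    def roi_amplitude_gain(self) -> float:
        """Effective gain on the whole-dendrite ROI amplitude."""
        return 0.5 * (self.hotspot_gain + self.offhotspot_gain)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    event_times / event_amps are per-trial arrays (seconds from trial start,
    ΔF/F at the continuous-time kernel peak); evoked[k] is True when trial k
    received an evoked event.  For plasticity sessions the per-condition
    truths are nested under ``sessions``.
    """

    event_times: list[np.ndarray] = field(default_factory=list)
    event_amps: list[np.ndarray] = field(default_factory=list)
    evoked: list[bool] = field(default_factory=list)
    regime: RegimeSpec | None = None
    true_shifts: np.ndarray | None = None
    target_r: float | None = None
    amp_gain: float | None = None
    prob_gain: float | None = None
    hotspot_mask: np.ndarray | None = None
    sessions: dict[str, "GroundTruth"] = field(default_factory=dict)


@dataclass
class TrialTrace:
    """One simulated trial: raw fluorescence plus its protocol metadata."""

    values: np.ndarray
    frame_rate: float
    stim_time: float
    intensity: float | None
    condition: str

    def as_fluorescence(self) -> FluorescenceTrace:
        return FluorescenceTrace(values=self.values, frame_rate=self.frame_rate)


@dataclass
class Session:
    """A block of trials sharing a condition label (pre / early / late post)."""

    trials: list[TrialTrace]
    config: SimConfig
    condition: str = "pre"

    def concatenated(self) -> FluorescenceTrace:
        """All trials joined along time, for per-session baseline estimation."""
        return FluorescenceTrace(
            values=np.concatenate([t.values for t in self.trials]),
            frame_rate=self.config.frame_rate,
        )


def event_kernel(
    times: np.ndarray, rise: float = 0.05, decay: float = 0.4
) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient.

    ``k(t) = (exp(−t/decay) − exp(−t/rise)) / k_max`` for t ≥ 0, zero before,
    truncated to zero beyond six decay constants so that sparse traces have
    an exactly-zero baseline.  Defaults (50 ms rise, 400 ms decay) are
    GCaMP6f-like and configurable.
    """
    if rise <= 0 or decay <= rise:
        raise ValueError("need 0 < rise < decay")
    t = np.asarray(times, dtype=float)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out = np.where(
        (t >= 0) & (t <= 6 * decay),
        (np.exp(-np.clip(t, 0, None) / decay) - np.exp(-np.clip(t, 0, None) / rise)) / peak,
        0.0,
    )
    return out


def _render_trial(
    cfg: SimConfig, times: np.ndarray, amps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Raw fluorescence for one trial from event times/amplitudes plus noise."""
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    signal = np.zeros_like(t)
    for t_ev, a in zip(times, amps):
        signal += a * event_kernel(t - t_ev, cfg.kernel_rise, cfg.kernel_decay)
    noise = rng.standard_normal(t.size) * cfg.noise_sd if cfg.noise_sd > 0 else 0.0
    return F_BASE * (1.0 + signal + noise)


def _draw_trial_events(
    cfg: SimConfig,
    evoked_p: float,
    evoked_amp: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    n_sp = rng.poisson(cfg.spont_rate * cfg.trial_len)
    sp_times = np.sort(rng.uniform(0.0, cfg.trial_len, size=n_sp))
    sp_amps = np.clip(
        rng.normal(cfg.spont_amp_mean, cfg.spont_amp_sd, size=n_sp), 0.15, None
    )
    evoked = bool(rng.random() < evoked_p)
    if evoked:
        latency = cfg.evoked_latency
        if cfg.latency_jitter_sd > 0:
            latency = max(0.0, latency + rng.normal(0.0, cfg.latency_jitter_sd))
        t_ev = cfg.stim_time + latency
        times = np.append(sp_times, t_ev)
        amps = np.append(sp_amps, evoked_amp)
    else:
        times, amps = sp_times, sp_amps
    return times, amps, evoked


def generate_trial_session(
    config: SimConfig,
    intensity: float | None = None,
    condition: str = "pre",
    regime: RegimeSpec | None = None,
    stream: int = 0,
) -> tuple[Session, GroundTruth]:
    """Simulate one block of stimulus trials at a single test intensity.

    Each trial carries homogeneous-Poisson spontaneous events at
    ``spont_rate`` plus, with the configured probability, exactly one evoked
    event at ``stim_time + latency``.  Events are rendered as
    difference-of-exponential kernels on a flat baseline; Gaussian noise of
    ``noise_sd`` (ΔF/F units) is added and the whole signal is expressed as a
    raw fluorescence trace so the full preprocessing chain applies.

    ``regime`` (optional) multiplies the evoked amplitude by its ROI gain
    and the evoked probability by its probability gain — used for
    post-tetanus sessions.  ``stream`` selects an independent substream of
    the configured seed so that pre/post sessions are separately
    reproducible.
    """
    if intensity is None:
        intensity = config.intensities[-1]
    if intensity not in config.evoked_prob_by_intensity:
        raise ValueError(f"intensity {intensity!r} not in the configured maps")
    p = config.evoked_prob_by_intensity[intensity]
    a = config.evoked_amp_by_intensity[intensity]
    if regime is not None:
        p = min(1.0, p * regime.probability_gain)
        a = a * regime.roi_amplitude_gain
    rng = np.random.default_rng([config.seed, stream])

    trials: list[TrialTrace] = []
    truth = GroundTruth(regime=regime)
    for _ in range(config.n_trials):
        times, amps, evoked = _draw_trial_events(config, p, a, rng)
        trials.append(
            TrialTrace(
                values=_render_trial(config, times, amps, rng),
                frame_rate=config.frame_rate,
                stim_time=config.stim_time,
                intensity=intensity,
                condition=condition,
            )
        )
        truth.event_times.append(times)
        truth.event_amps.append(amps)
        truth.evoked.append(evoked)
    return Session(trials=trials, config=config, condition=condition), truth


def generate_intensity_series(
    config: SimConfig, condition: str = "pre"
) -> dict[float, tuple[Session, GroundTruth]]:
    """One session per configured test intensity (for dependence analysis)."""
    return {
        inten: generate_trial_session(
            config, intensity=inten, condition=condition, stream=100 + k
        )
        for k, inten in enumerate(config.intensities)
    }


def generate_plasticity_session(
    config: SimConfig, regime: RegimeSpec, intensity: float | None = None
) -> tuple[dict[str, Session], GroundTruth]:
    """Pre / early-post / late-post test blocks around a simulated tetanus.

    The pre block uses the configured evoked parameters unchanged; both post
    blocks have the evoked amplitude multiplied by the regime's ROI gain and
    the evoked probability by its probability gain (capped at 1).  Each block
    draws from its own substream of the seed.
    """
    sessions: dict[str, Session] = {}
    truth = GroundTruth(
        regime=regime,
        amp_gain=regime.roi_amplitude_gain,
        prob_gain=regime.probability_gain,
    )
    for cond, stream in _CONDITION_STREAM.items():
        reg = None if cond == "pre" else regime
        sess, t = generate_trial_session(
            config, intensity=intensity, condition=cond, regime=reg, stream=stream
        )
        sessions[cond] = sess
        truth.sessions[cond] = t
    return sessions, truth


def generate_linescan_pair(
    n_pixels: int,
    pixel_len: float,
    hotspot_center: int,
    hotspot_width: float,
    regime: RegimeSpec,
    seed: int | np.random.Generator,
    baseline: float = 0.15,
    peak: float = 1.2,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Pre/post-tetanus linescan response profiles with a localized hotspot.

    The pre profile is a flat dendritic baseline plus a Gaussian bump of SD
    ``hotspot_width`` pixels centred on ``hotspot_center`` whose peak is the
    profile maximum.  Hotspot membership is defined as pre-tetanus value
    above 0.9 of the profile maximum; the post profile multiplies hotspot
    pixels by ``hotspot_gain`` and the rest by ``offhotspot_gain``.
    Independent Gaussian noise of ``noise_sd`` (ΔF/F units) is added to both
    profiles.  Values are ΔF/F per linescan pixel; ``pixel_len`` (μm) is
    carried by the caller into the spatial module.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if hotspot_width <= 0:
        raise ValueError("hotspot_width must be positive")
    if not 0 <= hotspot_center < n_pixels:
        raise ValueError("hotspot_center must lie in [0, n_pixels)")
    if pixel_len <= 0:
        raise ValueError("pixel_len must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    i = np.arange(n_pixels, dtype=float)
    pre_clean = baseline + (peak - baseline) * np.exp(
        -((i - hotspot_center) ** 2) / (2.0 * hotspot_width**2)
    )
    hotspot = pre_clean > 0.9 * pre_clean.max()
    post_clean = np.where(
        hotspot, pre_clean * regime.hotspot_gain, pre_clean * regime.offhotspot_gain
    )
    pre = pre_clean + (rng.standard_normal(n_pixels) * noise_sd if noise_sd > 0 else 0.0)
    post = post_clean + (rng.standard_normal(n_pixels) * noise_sd if noise_sd > 0 else 0.0)
    truth = GroundTruth(regime=regime, hotspot_mask=hotspot)
    return pre, post, truth


def generate_movie(
    base_image: np.ndarray,
    shifts: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Frame stack built by rigid translation of a base image.

    Frame ``k`` is the base image circularly translated by ``shifts[k] =
    (dy, dx)`` with Gaussian noise of SD ``noise_sd`` (absolute image units)
    added.  Shifts must stay within ±¼ of each image dimension so the
    registration search is unambiguous.
    """
    base = np.asarray(base_image, dtype=float)
    if base.ndim != 2:
        raise ValueError("base_image must be 2-D")
    shifts = np.asarray(shifts)
    if shifts.ndim != 2 or shifts.shape[1] != 2:
        raise ValueError("shifts must have shape (n_frames, 2)")
    ny, nx = base.shape
    if np.any(np.abs(shifts[:, 0]) > ny // 4) or np.any(np.abs(shifts[:, 1]) > nx // 4):
        raise ValueError("shifts exceed a quarter of the image extent")
    if noise_sd < 0 or not np.isfinite(noise_sd):
        raise ValueError("noise_sd must be finite and >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    int_shifts = np.round(shifts).astype(int)
    frames = np.empty((len(int_shifts), ny, nx))
    for k, (dy, dx) in enumerate(int_shifts):
        frame = np.roll(base, (dy, dx), axis=(0, 1))
        if noise_sd > 0:
            frame = frame + rng.standard_normal(base.shape) * noise_sd
        frames[k] = frame
    return frames, GroundTruth(true_shifts=int_shifts)


def generate_compartment_data(
    n_cells: int,
    target_r: float,
    seed: int | np.random.Generator,
    dendrite_mean: float = 1.0,
    dendrite_sd: float = 0.3,
    soma_scale: float = 0.5,
    ais_scale: float = 0.3,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Paired dendrite / soma / AIS maximum-amplitude sets.

    Soma and AIS amplitudes are built from the dendritic draw through a
    shared-factor Gaussian model so that the population Pearson correlation
    of each against the dendrite equals ``target_r``.  Scales reflect the
    smaller transients seen outside the dendrite; Pearson correlation is
    unaffected by them.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [-1, 1]")
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    z0 = rng.standard_normal(n_cells)
    z1 = rng.standard_normal(n_cells)
    z2 = rng.standard_normal(n_cells)
    mix = np.sqrt(1.0 - target_r**2)
    dend = dendrite_mean + dendrite_sd * z0
    soma = soma_scale * (1.0 + 0.3 * (target_r * z0 + mix * z1))
    ais = ais_scale * (1.0 + 0.3 * (target_r * z0 + mix * z2))
    data = {"dendrite": dend, "soma": soma, "ais": ais}
    return data, GroundTruth(target_r=target_r)
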