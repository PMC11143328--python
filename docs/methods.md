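# Methods

This note records the models, conventions and defaults behind `calplast`,
what the synthetic generator does and does not emulate, and the choices
made where the underlying protocol leaves the design open.

## Signal model and preprocessing

A recording is a stack of frames at 31 Hz (electrical parallel-fibre
protocol: 10 s trials, stimulus at 5 s) or 62 Hz (tactile protocol: 20 s
trials, stimulus at 10 s).  Registration is deliberately rigid: each
frame's integer (dy, dx) displacement is the argmax of its circular
cross-correlation with a reference frame (means subtracted, FFT-based), and
the frame is rolled back by that displacement.  Sub-pixel registration is
out of scope; the registration reference defaults to the stack mean, and a
pipeline will typically pass the mean of the first trial's frames.
Zero-variance frames have no defined displacement; they are passed through
with shift (0, 0) and flagged.

Per ROI, the raw trace F_t is the mean over mask pixels.  ΔF/F uses
F₀ = 20th percentile of the trace, computed over all trials of a recording
concatenated (per-condition baselines are available as an option; the
command-line pipeline shares one F₀ across pre- and post-tetanus blocks).
The percentile convention is linear interpolation between order statistics
— the most common definition; the underlying protocol does not state one.
Traces are smoothed with a five-frame centred moving average; at the
boundaries the window shrinks to the available samples, which preserves
trace length without inventing data.

## Event detection and response statistics

Events are local maxima of the smoothed ΔF/F trace with height ≥ 0.09 and
topographic prominence ≥ 0.09 (≈ one SD of the pre-stimulus baseline in
the data this emulates).  Prominence is the standard topographic
definition; plateau maxima are attributed to their earliest frame; the
first and last samples can never be peaks.  Detection is verified against
an exhaustive brute-force scan in the test suite.

A trial is responsive iff a detected peak time lies in the half-open
window [stimulus onset, onset + 0.2 s) — peaks, not onsets, define
membership, and the right edge is excluded.  `max_in_window` is taken from
the trace regardless of detection so sub-threshold responses remain
quantified.  Response probability is responsive/total trials.  Two
amplitude conventions coexist, as in the protocols this implements:
detected-peak amplitude averaged over responsive trials (electrical
PF/climbing-fibre analyses) and max-in-window averaged over all trials
(tactile and compartment analyses, whose slow, small events evade a fixed
criterion).  Event amplitude is the ΔF/F value at the peak sample — no
baseline-to-peak re-referencing, since detection already operates on ΔF/F.

The spontaneous null draws 200 ms windows uniformly, with replacement,
from [stim − 4.5 s, stim − 0.5 s]; the default window count equals the
number of stimulus trials (the protocol does not state a count), and any
count can be requested.  The probability of at least one event in a window
of length w under a homogeneous Poisson process of rate λ is
1 − exp(−λw); at λ = 1.1 Hz and w = 0.2 s this is 0.197, and inverting it
on the measured window probability recovers the spontaneous rate.

**Detector temporal resolution.**  With the default kernel (below) and the
0.09 prominence rule, two transients closer than roughly the kernel decay
(~350 ms) merge into a single detected peak: the valley between them is
shallower than the prominence criterion.  At a 1.1 Hz spontaneous rate
this absorbs roughly a quarter of events, so the *detected* window
probability sits below the Poisson closed form.  The interactive
manual-correction step of the original workflow compensated for exactly
this; a deterministic pipeline cannot, so `shuffled_null` accepts
precomputed event times (simulation ground truth, or externally vetted
peaks) to separate the window-sampling statistics from detector
resolution.  The calibration suite uses that path; a dedicated test pins
the merging behaviour itself.

## Plasticity quantification

Stimulus-intensity dependence: Pearson correlation of the five condition
points (spontaneous, then four ascending intensities) against their rank
0–4 — rank, not physical intensity, so μA and psi designs are comparable.
A cell is dependent iff r > 0.5 with the correlation p below the cutoff.
The protocol prints the rule as "R > 0.5 and p < 0.5"; whether 0.5 is a
typo for 0.05 is not stated, so the conventional 0.05 is the default and
the printed 0.5 is selectable (`p_cutoff`).  Degenerate (zero-variance)
response vectors leave r undefined and are labelled independent with a
flag.

Post-tetanus amplitude and probability are divided by the pre-tetanus
values; cells with no pre-tetanus responses cannot be normalized, are
excluded with a log message, and belong in the weak-responder pathway:
cells whose pre-tetanus mean max-in-window amplitude is strictly below
2 × 0.9 = 1.8 ΔF/F (double the calcium-event inclusion criterion).  The
detection threshold (0.09) and the inclusion criterion (0.9) are kept as
independent parameters; their relation is not specified by the protocol.

The linear conversion rate = P/window maps the printed window
probabilities to the printed rates (0.22 → 1.1 Hz, 0.25 → 1.25 Hz,
0.37 → 1.85 Hz).  It is exact only in the small-P limit of the Poisson
model; it is provided as the protocol defines it.

## Spatial statistic

Linescan profiles hold one response value per pixel along the dendritic
cross-section (default spacing 15 μm, matching the reslice output spacing
of the original workflow); from a pixels×time map the per-pixel value is
the within-window maximum averaged over trials (the protocol does not
state this summary; max-in-window is the default and the summary is
selectable).  Profile pairs are normalized by the pre-tetanus maximum, so
the pre profile peaks at 1 and potentiated post profiles may exceed it.

CL(f) = pixel_len × #{pixels ≥ f} on a level grid from 0 to the largest
profile maximum in steps of 0.01 (the protocol plots continuous curves
without stating a grid).  CL uses ≥ at grid levels; the hotspot band is
strictly > 0.9 and the off-hotspot band is [0.3, 0.67], both on the
normalized scale.  Δlength = CL_post − CL_pre, so expansion is positive;
the opposite sign convention appears in one figure legend of the source
protocol and is available as `orientation="pre_minus_post"`.  Cells
responding across the whole cross-section (> 90 % of pixels above the
hotspot level; the protocol states the rule only qualitatively) are
excluded, since hotspot and off-hotspot cannot be distinguished; coverage
exactly at the cutoff is retained.

## Synthetic sessions

The generator emulates the statistical structure of the recordings:

- **Trials** — spontaneous events as a homogeneous Poisson process
  (default 1.1 Hz) plus an at-most-one Bernoulli evoked event per trial
  (matching the per-trial responsive/non-responsive dichotomy), with
  evoked probability rising 0.25 → 0.37 and peak amplitude rising
  linearly across the four test intensities.
- **Kernel** — unit-peak difference of exponentials, rise 50 ms, decay
  400 ms (GCaMP6f-like; no kernel is reported by the protocol, so these
  are stand-ins and configurable), truncated beyond six decay constants so
  sparse traces have an exactly-zero baseline.  Evoked latency 30 ms with
  10 ms Gaussian jitter, likewise a configurable stand-in.
- **Traces** — rendered as raw fluorescence F = F₀(1 + signal + noise)
  with Gaussian noise in ΔF/F units (default SD 0.03), so the full
  preprocessing chain applies.  Spontaneous amplitudes are Gaussian
  (mean 0.6, SD 0.2, floored at 0.15 ΔF/F) — comparable to evoked events,
  as observed.
- **Plasticity regimes** — multiplicative gains: `both` (hotspot 1.5,
  off-hotspot 1.3, probability 1.25), `local_only` (1.5, 1.0, 1.1),
  `global_only` (1.15, 1.3, 1.2), `control` (all 1).  Magnitudes are
  chosen to be realistic for tetanus-induced potentiation of PF responses
  (tens of per cent); only their qualitative pattern carries meaning.  The
  whole-dendrite ROI amplitude gain is the mean of the two spatial gains,
  since the ROI spans hotspot and off-hotspot segments alike.
- **Linescans** — flat baseline (0.15 ΔF/F) plus a Gaussian hotspot bump
  (peak 1.2 ΔF/F, SD 2.5 pixels over 40 pixels × 15 μm by default);
  hotspot membership is pre-tetanus value above 0.9 of the maximum, and
  the post profile applies the regime's two gains by membership.
- **Movies** — a base image circularly translated by known integer shifts
  plus Gaussian noise (shifts capped at ±¼ of the extent so registration
  is unambiguous).
- **Compartments** — dendrite/soma/AIS amplitudes from a shared-factor
  Gaussian model with exact population correlation `target_r` against the
  dendrite.

Reproducibility: one PCG64 stream per session keyed by (seed, stream), so
pre/early/late blocks are independently reproducible and a fixed seed
gives bit-identical output.  Every generator returns the ground truth its
recovery test needs (event times/amplitudes, gains, shifts, hotspot mask,
target correlation).

What the generator does **not** emulate: biophysical dendrite geometry or
a point-spread function, spike trains (simple/complex spikes), bleaching,
neuropil contamination, non-rigid motion, or heavy-tailed noise.  Passing
recovery tests therefore demonstrate correctness of the analysis chain
under the stated statistical structure, not robustness to every artefact
of real recordings.

## Statistics

One-way ANOVA is computed from the textbook sums-of-squares decomposition
(with two groups F = t² against the pooled-variance t test).  Two-way
factorial ANOVA is fit by OLS with Type II sums of squares by default —
suitable for the unbalanced designs that arise in practice; the SS type is
configurable.  The two-way repeated-measures variant requires a fully
balanced within-subject design and rejects anything else rather than
silently approximating.  Tukey HSD uses the Tukey–Kramer harmonic-mean
correction for unequal group sizes.  Kruskal–Wallis uses midranks with the
standard tie correction (H ≡ 0 for identical samples, where the tie
correction would otherwise leave 0/0).  Dunn's pairwise z statistics on
pooled midranks are Šidák-adjusted, p_adj = 1 − (1 − p)^m over the m
pairs, which never falls below the raw p.  Compartment coupling is the
Pearson correlation across cells of trial-averaged max-in-window
amplitudes (no event detection, as somatic/AIS kinetics differ from
dendritic ones); it requires at least three cells.

## Problem sizes and numerical notes

The test and acceptance suites run at desk scale, chosen so every check is
statistically decisive: oracle equivalence on 1,000 random traces and
1,000 random profiles; 10,000-window null calibration (3-binomial-SE
band); gain recovery on 50 noisy cells (noise SD 0.05); regime signatures
on 50 linescan cells per regime (noise SD 0.02, flatness tolerance half a
pixel, 7.5 μm); 15-frame movies at 10 % dynamic-range noise; 5,000
permutations against analytic ANOVA p-values.  Monte-Carlo assertions use
3σ bands on single statistics and tighter mean-over-replicate bounds where
a single draw would fail by chance too often.

Known limitations: integer-pixel registration only; the detector's
~350 ms pair-resolution limit (above); the linear rate conversion's
small-P bias; normalization requires a strictly positive pre-tetanus
response; and the cumulative-length statistic discards pixel location by
design, so it measures extent, not position, of potentiation.
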