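# calplast

Analysis pipeline for two-photon calcium imaging of receptive-field
plasticity in cerebellar Purkinje cells — from raw frame stacks and ROI
masks to event statistics, pre/post-tetanus plasticity quantification, and
the cumulative-length spatial statistic that distinguishes local from
widespread dendritic potentiation.  A synthetic-session generator with full
ground truth makes every stage testable without any imaging data.

## The problem

Purkinje-cell dendrites respond to parallel-fibre (PF) input — driven
either by direct electrical stimulation or by tactile stimuli relayed
through the mossy-fibre pathway — with localized calcium transients
reported by GCaMP6f.  Repetitive stimulation (a tetanus) potentiates these
responses; synaptic long-term potentiation and intrinsic-excitability
plasticity contribute differently to *how far* the potentiation spreads
along the dendrite.  Quantifying this requires a chain of standard but
exacting steps:

1. **Preprocessing** — rigid motion correction by whole-frame
   cross-correlation; ΔF/F = (F_t − F₀)/F₀ with F₀ the 20th percentile of
   each concatenated fluorescence trace; five-frame moving-average
   smoothing.
2. **Event detection** — local maxima of the smoothed ΔF/F trace with
   height ≥ 0.09 and topographic prominence ≥ 0.09 (≈ 1 SD of the
   pre-stimulus baseline).
3. **Trial classification** — a trial is *responsive* when a detected peak
   falls in the half-open response window [stimulus, stimulus + 200 ms);
   response probability P = responsive / total trials.  The spontaneous
   null draws 200 ms windows uniformly from −4.5 to −0.5 s before the
   stimulus.  With the linear conversion rate = P/window, the spontaneous
   P = 0.22 corresponds to 1.1 Hz and the evoked range 0.25–0.37 to
   1.25–1.85 Hz.
4. **Plasticity quantification** — post-tetanus amplitude and probability
   normalized by the pre-tetanus value; stimulus-intensity dependence
   classified by the Pearson correlation of the five condition points
   (spontaneous + four intensities) with the R > 0.5 rule; weak responders
   selected below 1.8 ΔF/F (double the 0.9 ΔF/F event-inclusion
   criterion).
5. **Spatial statistic** — linescan profiles normalized by the pre-tetanus
   maximum; the cumulative length CL(f) is the dendritic length at or above
   fluorescence level f, and Δlength(f) = CL_post(f) − CL_pre(f) measures
   expansion.  The hotspot band (> 0.9) captures the PF-responsive
   segment, the off-hotspot band (0.3–0.67) the spread beyond it.
6. **Statistics** — one/two-way (repeated-measures) ANOVA with Tukey HSD,
   Kruskal–Wallis with Dunn–Šidák post-hocs, Pearson compartment
   correlations (dendrite vs soma and axon initial segment).

## Worked example

Simulate a population of cells under the *local-only* plasticity regime
(synaptic potentiation without intrinsic amplification: the hotspot gains
1.5×, the rest of the dendrite is unchanged), run the full pipeline, and
recover the regime's signature:

```python
import numpy as np
from calplast import synth, pipeline, spatial

regime = synth.RegimeSpec.preset("local_only")

norm_late = []
for c in range(20):
    cfg = synth.SimConfig(n_trials=12, noise_sd=0.03, seed=100 + c)
    blocks, truth = synth.generate_plasticity_session(cfg, regime)
    res = pipeline.analyze_plasticity(blocks)
    norm_late.append(res.norm_amplitude["late_post"])
print(f"true ROI amplitude gain: {truth.amp_gain:.2f}")
print(f"recovered normalized amplitude (late post, n=20 cells): "
      f"{np.mean(norm_late):.2f} +/- {np.std(norm_late, ddof=1)/np.sqrt(20):.2f}")

hots, offs = [], []
for c in range(20):
    pre, post, _ = synth.generate_linescan_pair(40, 15.0, 20, 2.5, regime,
                                                seed=100 + c, noise_sd=0.02)
    a, b = spatial.normalize_pair(spatial.LinescanProfile(pre, 15.0),
                                  spatial.LinescanProfile(post, 15.0, "late_post"))
    lv = spatial.default_levels(a, b)
    d = spatial.delta_length(spatial.cumulative_length(a, lv),
                             spatial.cumulative_length(b, lv))
    hot, off = spatial.band_metrics(d)
    hots.append(hot); offs.append(off)
print(f"hotspot-band mean dlength    : {np.mean(hots):6.1f} um")
print(f"off-hotspot-band mean dlength: {np.mean(offs):6.1f} um")
```

Output:

```
true ROI amplitude gain: 1.25
recovered normalized amplitude (late post, n=20 cells): 1.29 +/- 0.08
hotspot-band mean dlength    :   35.1 um
off-hotspot-band mean dlength:    0.3 um
```

The pipeline recovers the simulated whole-dendrite amplitude gain (1.25)
within its sampling error, and the spatial statistic shows the local-only
fingerprint: the dendritic length above the hotspot level grows by ~35 μm
while the off-hotspot band stays flat — potentiation without spread.  Under
the *global-only* regime the off-hotspot band expands instead.

The same chain is available from the shell:

```bash
calplast --seed 3 --out demo simulate
calplast --out demo preprocess
calplast --out demo detect
calplast --out demo plasticity
calplast --out demo spatial
calplast --out demo stats --test anova1
calplast --out demo report
```

which leaves tidy CSV tables (`events.csv`, `trials.csv`, `summary.csv`,
`normalized.csv`, `curves.csv`, `bands.csv`, …) and a `report.json` in
`demo/`.

## Layout

| module                | contents                                                        |
| --------------------- | --------------------------------------------------------------- |
| `calplast.synth`      | synthetic sessions, linescan pairs, movies, compartment data    |
| `calplast.io`         | TIFF stacks, ROI masks, session manifests, tidy tables          |
| `calplast.preprocess` | motion correction, ΔF/F, smoothing                              |
| `calplast.events`     | detection, trial classification, shuffled null, summaries       |
| `calplast.plasticity` | dependence classification, normalization, weak responders       |
| `calplast.spatial`    | linescan profiles, CL(f), Δlength, band metrics                 |
| `calplast.stats`      | ANOVA, Tukey HSD, Kruskal–Wallis, Dunn–Šidák, correlations      |
| `calplast.pipeline`   | stage chaining used by the CLI and the recovery tests           |

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical conventions.
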