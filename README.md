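# mitofuse

Quantification of mitochondrial fusion dynamics from two-channel
photoactivation time-lapse assays (matrix-targeted photoactivatable GFP +
matrix-targeted DsRed), together with a ground-truthed simulator of
mitochondrial network dynamics so that every analysis stage can be
validated without microscope data.

## Who this is for

Labs running the mtPA-GFP/mtDsRed fusion assay: a 2-photon pulse applied to
5×5 µm regions of a cell simultaneously photoactivates matrix PA-GFP and
photobleaches matrix DsRed. Because both probes are soluble matrix
proteins, activated GFP spreads only through lumenally continuous
mitochondria, and every fusion between a "green-only" (activated, bleached)
mitochondrion and an unbleached red one mixes their content. The package
turns such recordings (TIFF stacks, 2 channels, typically 512×512 px at
0.25 frames/s) into the assay's standard readouts:

- **Matrix continuity** — the time course of the ratio
  F(mtPA-GFP)/F(mtDsRed) averaged over each region of photoactivation
  (RPA), normalized to the first post-activation frame, and its decay at
  500 s (`decay_500s = 1 − R(500 s)`; larger = more connected), plus the
  count of suprathreshold GFP pixels spreading outside the activation
  squares (threshold set by a 0.1% false-positive rule on pre-activation
  noise).
- **Fusion activity, pixel-loss readout** — per-frame counts of GFP-only
  pixels (above the pooled-series Otsu threshold in the GFP channel, below
  it in the red channel, after 3×3 despeckling), fit by a single
  exponential *y = a·e^(−bx)*; the decay constant *b* or the half-time
  ln(2)/*b* measures fusion activity.
- **Fusion events** — object-level detection of abrupt, complementary
  inter-mitochondrial exchange of the two fluorophores between contacting
  tracks; events are classified transient ("kiss-and-run", with duration)
  vs complete, and end-to-end / end-to-side / side-to-side; summaries
  report events per run and per minute over the 8-min window.
- **Motility** — the frame-differencing index: both channels summed,
  successive frames subtracted, both thresholded at the constant 32 (8-bit
  scale); the index is median(difference counts)/median(summed counts).
- **Colocalization** — percentage of Otsu-mask-A pixels inside Otsu mask B
  (binary Manders-style co-occurrence), for immunostaining overlap.
- **Sequence scramble test** — exact Smith–Waterman local alignment
  (BLOSUM62, gap open 11 / extend 1) of two proteins, with empirical
  significance from composition-preserving scrambles of each sequence.

The simulator (`mitofuse.sim`) models mitochondria as mobile capsule
segments carrying DsRed and dark/bright PA-GFP pools; fusion joins
segments into components, fission splits them, and matrix content
equilibrates within components one frame after each topology change. It
renders realistic two-channel series (PSF blur, shot noise, photoactivation
and bleaching) and logs exact ground truth for every event.

## Worked example

Simulate a motile, fusing network patch (40 segments in a 19.2 µm field,
three 25 µm² activation squares, 8-min recording at 0.25 frames/s) and run
the analyses:

```python
from mitofuse import (SimParams, simulate, gfp_only_decay, detect_fusion_events,
                      summarize_fusion, rpa_decay, motility_index)

params = SimParams(
    n_segments=40, field_um=19.2, seg_len_um_mean=1.2, seg_len_um_sd=0.4,
    n_pre_frames=5, n_post_frames=120,
    k_fuse_per_contact_s=0.01, k_fiss_per_junction_s=0.006,
    diffusion_um2_s=0.003,
    act_rois=((2.0, 2.0, 5.0), (12.0, 3.0, 5.0), (6.5, 11.5, 5.0)),
    seed=42,
)
run = simulate(params)
fit = gfp_only_decay(run.series)
summary = summarize_fusion(detect_fusion_events(run.series), window_s=480.0)
tc = rpa_decay(run.series)
mot = motility_index(run.series)
```

Output for this seed:

```
ground-truth fusions (post-activation): 44
GFP-only decay: b = 1.21e-03 /s, half-time = 573 s, R2 = 0.83
detected events: 1 (0.12/min), transient fraction = 1.00, mean duration = 4 s
RPA ratio decay at 500 s: 0.36
motility index: 0.42
```

Reading it: the GFP-only pixel count halves in ~570 s — an actively fusing
network (an inert one fits half-times of thousands of seconds); the RPA
ratio lost 36% by 500 s, i.e. a well-connected matrix. Note that the
object-level detector reports only the events that are *resolvable* — in a
crowded scene most fusions happen between touching objects segmented as
one, which is exactly why the pixel-loss half-time, not the event count, is
the assay's primary quantitative readout (the event detector is validated
on scenes with well-separated events, where its recall and precision
exceed 0.8 — see `tests/test_acceptance.py`).

A command-line interface mirrors the library:

```
mitofuse simulate --out sim_out --seed 1          # TIFF + sidecar + truth CSV
mitofuse analyze config.yaml                      # config-driven multi-cell run
mitofuse motility sim_out/sim.tif
mitofuse coloc stainA.tif stainB.tif
mitofuse seqperm a.fasta b.fasta --n-each 100 --seed 1
mitofuse report cells.csv                         # group means ± s.e.m., Welch t / ANOVA
```

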