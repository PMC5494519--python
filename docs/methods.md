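# Methods

## The assay being modeled

A 2-photon pulse applied to 25 µm² squares of a cell expressing
matrix-targeted photoactivatable GFP (mtPA-GFP) and matrix-targeted DsRed
does two things at once: it switches the PA-GFP in the pulsed region from
dark to bright, and it photobleaches the DsRed there. Both probes are
soluble matrix proteins, so from that moment on the activated GFP can move
only through lumenally continuous mitochondria, and each fusion between an
activated ("green-only") mitochondrion and an unbleached red one mixes the
two matrix pools. Two families of readouts follow: continuity measures
(how far activated GFP spreads, how fast the in-square GFP/DsRed ratio
dilutes) and fusion measures (how fast the green-only pixel population is
consumed; discrete exchange events between tracked objects).

Frame-index convention used throughout: frames `0 .. t_act−1` are
pre-activation, the pulse falls between frames `t_act−1` and `t_act`, and
`t_act` is the first post-activation frame. All ROIs are 0-based
(row, col) half-open rectangles.

## Simulator

Mitochondria are capsule segments (fixed width, default 0.3 µm) in a
square 2-D field, each carrying three conserved pools: DsRed, dark PA-GFP,
bright PA-GFP (initialized at `density_per_um` × length, default
1 a.u./µm). Segments joined by fusion junctions form connected
components; the junction graph is a forest because fusion only joins
distinct components, so every fission splits one.

Per frame, in a fixed, seeded order:

1. **Mixing** — each pool is redistributed within every component in
   proportion to segment length. This equilibrates whatever changed in the
   *previous* frame (fusion, activation), so mixing is instantaneous at
   frame resolution but appears one frame after its cause. Rationale: the
   4-s frame interval is long against matrix-protein diffusion within an
   organelle, but the just-activated frame must still show the unmixed
   state, as the camera would.
2. **Motion** — each component receives one rigid Gaussian displacement
   with per-axis variance 2·D·Δt, reflected at the field boundary (the
   cell confines mitochondria; without reflection, segments leak off the
   field and masquerade as signal loss).
3. **Fission** — every junction breaks independently with probability
   1 − exp(−k_fiss·Δt).
4. **Fusion** — every segment pair from different components whose capsule
   boundaries come within `contact_dist_um` (default 0.3 µm) fuses with
   probability 1 − exp(−k_fuse·Δt); candidates are processed in ascending
   (id, id) order and a segment fuses at most once per frame.
5. **Activation** (only at `t_act`) — segments whose centroid lies in an
   activation square move all dark PA-GFP to bright and keep
   `bleach_survival` (default 0.2) of their DsRed. The true activation
   efficiency and bleach depth are instrument properties; both are
   parameters, not claims.

Ground truth: every fusion is logged with frame, partners, contact
geometry (end/side classification from the closest-point parameters) and
typed *transient* if the same junction breaks later in the recording (the
fused interval is its duration) or *complete* otherwise. The ground-truth
event frame is the fusion frame + 1 — the first frame at which mixed
content is visible, which is what any image-based detector can time.

Rendering draws each capsule with per-pixel intensity proportional to
amount per unit length (integrated capsule intensity equals the amount),
then applies Gaussian PSF blur (default σ 0.15 µm), Poisson shot noise
scaled by `photons_per_unit` (a non-finite value disables noise — used by
the noiseless oracle experiments), a constant background, and quantization
to 8 or 16 bits. Dynamics and rendering consume two independent streams
derived from one seed; identical parameters and seed give bit-identical
runs.

Scripted scenes (`staged_fusion_run`) place donor/acceptor pairs on a grid
and fuse them at chosen, well-separated frames, optionally with scripted
fission after a chosen duration. They exist because stochastic runs cannot
guarantee the "≥ 5 frames apart, resolvable pair" regime in which an event
detector can be graded event-by-event.

### What the simulator does and does not emulate

It reproduces the acquisition geometry (default 512×512 px at 0.1 µm/px,
0.25 frames/s, 5×5 µm squares, 8-min post-activation window), matrix
content mixing, bleaching, PSF and shot noise, and motility at the
component level. It does not model directed motor transport, 3-D optics,
cristae substructure, intra-component diffusion gradients, or photophysics
beyond the single bleach step. Passing tests on synthetic data therefore
validate the *pipeline arithmetic and its response to known ground truth*,
not the biological fidelity of any particular parameter value.

## Image processing

- **Despeckle** — 3×3 median filter, edge-replicated borders.
- **Series Otsu** — one threshold per channel per series, from the
  histogram pooled over the selected frames (default: the post-activation
  frames; pre-activation GFP frames are near-empty and would bias the
  split), restricted to the cell ROI. Exhaustive between-class-variance
  search over all native gray levels for 8-bit data, ties toward the
  lowest level; 16-bit data is binned to 1,024 coarse bins and the exact
  level recovered by search within the winning bin's neighbourhood. Masks
  use the strict split `pixel > t`. Pooling makes the threshold invariant
  to frame order and keeps masks comparable across time.
- **Noise-ratio threshold** — the smallest gray level at which at most
  0.1% of in-cell pre-activation pixels satisfy `pixel ≥ t`. Before the
  pulse the GFP channel is pure noise, so this pins the false-positive
  rate of the spreading mask at 1/1000. The ≥ convention is fixed by the
  rule's boundary cases (an identically zero channel yields t = 1).

## Continuity readouts

`rpa_decay` computes, per activation square and post-activation frame, the
ratio of ROI-mean GFP to ROI-mean DsRed, normalizes to the first
post-activation frame, averages squares within a cell, and reports
`decay_500s = 1 − R(500 s)` (linear interpolation between bracketing
frames; when the recording is shorter the last frame is used and flagged).
Larger decay = more connected matrix. The DsRed denominator must exceed a
floor (default: background + 3σ of pre-activation noise, estimated from
the pre-activation GFP channel, which contains only noise) — a
bleached-out square has no defined ratio. Normalizing at the first
post-activation frame makes the metric invariant to global linear
intensity rescales and makes "1 − R" and "R(0) − R" coincide.

`spreading_curve` counts suprathreshold GFP pixels outside all activation
squares per frame, using the noise-ratio threshold.

The simulator provides a closed-form oracle: for a static network the
normalized ratio relaxes from the unmixed just-activated state to full
equilibration, so the predicted decay is `1 − ratio_eq/ratio_0` computed
directly from the content ledger of the ROI-resident segments
(`predicted_dilution_decay`), independent of rendering and thresholds.

## Fusion readouts

**Pixel loss.** Post-activation frames are despeckled; one Otsu threshold
per channel is set on the pooled despeckled series; green-only = GFP mask
AND NOT red mask, restricted to the cell ROI. The count time course (x in
seconds from activation) is fit by unweighted least squares to
*y = a·e^(−bx)*, initialized from a log-linear regression on the positive
counts (zeros stay in the objective); non-convergence falls back to the
log-linear estimate with a flag. Half-time ln(2)/*b* is reported as +∞
when *b* ≤ 0 (flagged, not an error: a non-fusing cell is a valid
observation). *x* is seconds, not frame index, because half-times are
meaningful in seconds.

**Event detection.** Post-activation frames are segmented with the union
of the two channel masks, labeled (8-connectivity), and tracked by maximal
pixel overlap; a merged object inherits the larger parent's track id, a
split re-assigns by overlap. A fusion event requires abrupt (one frame
interval), complementary exchange between contacting tracks (masks within
2 px): donor mean GFP down and mean DsRed up by at least δ, acceptor the
opposite — either across a label merge (measured on the pre-merge
footprints) or between tracks that stay separate. δ is 20% of the track's
intensity range per channel, floored at 5 gray levels (8-bit scale) so
flat noisy tracks cannot trigger by coincidence. Transient = the pair
separates again within the recording (duration = separation − fusion
time). Orientation compares each object's contact locus (nearest-pixel
pair between the two pre-fusion masks) with its own skeleton endpoints:
both within 3 px of an endpoint → end_to_end, one → end_to_side, neither →
side_to_side. The three-class scheme is a documented convention; the
endpoint radius absorbs the ~2 px offset between a mask boundary and its
skeleton.

Known limitation: in crowded scenes most fusions occur between objects
already segmented as one label and are invisible to any object-level
detector. Detector performance is therefore specified and validated on
scripted scenes with resolvable, well-separated events; on stochastic
dense scenes the pixel-loss half-time is the readout of record.

**Summaries** report event count, per-run and per-minute rates over the
recording window (default 480 s = 8 min), mean transient duration,
transient fraction and orientation counts.

## Motility and colocalization

The motility index sums the two channels (16-bit data is max-normalized to
8 bits first, because the constant threshold is defined on an 8-bit
scale), takes absolute differences of successive summed frames, thresholds
both series at the constant 32, and reports median(difference
counts)/median(summed counts), plus the mean intensity of suprathreshold
summed pixels as a bleaching/expression QC. Absolute (unsigned)
differences are used; a frozen scene scores exactly 0.

Colocalization is the percentage of Otsu-mask-A pixels inside Otsu mask B
— binary co-occurrence, not intensity-weighted, since the fraction of
marker-A area overlapping a compartment is the quantity of interest and it
is monotone under dilation of B.

## Sequence scramble test

Exact affine-gap Smith–Waterman (BLOSUM62; gap of length L costs
11 + L; the unknown residue X scores 0 against everything) gives the
observed local-alignment score of two proteins; the null distribution is
built from `n_each` composition-preserving Fisher–Yates scrambles of each
sequence (scrambled B vs A, scrambled A vs B), and the exceedance fraction
|{null ≥ observed}|/|null| is the empirical significance. Exact DP rather
than a heuristic search makes the null reproducible from the seed; raw
scores are rank-equivalent to bit scores within a fixed scheme, so no
Karlin–Altschul conversion is applied. The alignment engine is
Biopython's `PairwiseAligner`; its correctness here is checked against a
brute-force enumeration of all local alignments on short sequences.

## Pipeline and statistics

Config-driven runs (YAML) execute the enabled stages per cell, writing
per-cell curves and one metric row per cell (with an input content hash);
a stage failure is recorded in the row and the run continues. The cell is
the unit of replication: group tables report mean ± s.e.m. over cells,
with Welch's (unequal-variance) t test for two groups — chosen over the
pooled-variance form because equal variances cannot be assumed across
patient lines — and one-way ANOVA for several.

## Validation experiments and problem sizes

The canonical experiments live in `mitofuse.experiments` and are run by
both `tests/test_acceptance.py` and `scripts/acceptance.py`. Simulated
scenes are 160×160 px (16 µm at 0.1 µm/px) with 120 segments of ~0.8 µm
and three 25 µm² activation squares — about 30 activated objects, enough
for the pixel-count decay to be quasi-continuous while a full sweep stays
a desk-scale computation; the acquisition-faithful 512×512 default remains
available for data-scale runs.

Two motility regimes are deliberate:

- the **half-time rate response** (and its zero-fusion specificity
  control) uses a quasi-static network (D = 0.0005 µm²/s, no fission), so
  the fitted half-time responds to the per-contact fusion hazard alone and
  a fusion-free network shows no decay beyond residual overlap noise;
- the **event-count correlation** uses a churning network (D = 0.002
  µm²/s, k_fiss = 0.008 /s, i.e. fused-state lifetimes of ~125 s, the
  scale of observed transient-fusion durations). Partner renewal makes
  successive events transfer fresh content; without it, static pairs
  re-fuse repeatedly and inflate the event count without advancing the
  decay, which decouples the two quantities.

Fusion-rate sweeps span 0.0005–0.01 /s per contact (20×). Hazard
calibration uses a two-segment pair in permanent contact against an exact
Markov recursion mirroring the per-frame trial order. Continuity checks
use noiseless static networks (shot noise off, high fluorophore density so
quantization is negligible) on jittered-grid initial conditions, which
guarantee activation-square occupancy. Detector scoring uses scripted
scenes (10 pairs, ≥ 6-frame spacing, SNR ≥ 10) matched to ground truth by
frame (±1) and contact location.

## Numerical notes

- Fluorophore redistribution is exactly conservative per component up to
  floating-point summation (validated to 1e−9 relative over 100-frame
  runs).
- Fitted *b* below 1e−12 /s is reported as half-time +∞ rather than a
  meaninglessly large number.
- Otsu ties break toward the lowest gray level; noise-ratio thresholds
  count `≥ t` as suprathreshold; Otsu masks use `> t`.
- Degenerate inputs raise informative errors: single-valued images (no
  separable classes), missing pre-activation frames, bleached-out ROIs,
  empty colocalization masks, dark motility series, invalid residues.
- Segment-pair contact uses exact segment–segment distance with a KD-tree
  prefilter; the candidate order (ascending id pairs) and the per-frame
  draw order are part of the reproducibility contract.
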