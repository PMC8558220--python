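# Methods

## The excitation model

The simulator is an event-driven caricature of atrial excitation, not a
reaction–diffusion or ionic model. Its purpose is controllable ground
truth: every quantity the analysis chain estimates (beat times,
per-pixel activation times, origin sites, rates, pauses) exists exactly
in the simulator's event log.

Pacemakers are point sources with a phase clock. A clock that reaches
the pacemaker's intrinsic period fires; a wavefront that arrives at the
pacemaker's site first resets the clock to zero. This single reset rule
produces the two emergent behaviors the analyses probe: overdrive
suppression (a faster SAR resets a slower AVC forever, so every beat
originates at the SAR) and the escape rhythm (silencing the SAR lets
the AVC fire at its own period from its own site). A firing at site *s*
and time *t* excites pixel *p* at `t + |p−s|·pixel_size / v` (eikonal
propagation at constant velocity *v*), unless *p* was excited within
the refractory period; concurrent waves race and each pixel takes the
earliest admissible arrival (implemented as a single event heap over
firings and arrivals). Sinus pauses are skipped scheduled firings: the
pacemaker stays quiescent for `pause_duration`, then its clock restarts,
so one skip lengthens the inter-beat interval from `T` to
`T + pause_duration + T`.

Simultaneity at t = 0 is resolved by convention: each pacemaker has a
`phase_offset_ms` (time of first scheduled firing, default 0), and the
canonical two-pacemaker configuration starts the latent AVC mid-diastole
(offset = half its period). Without such an offset both sites would fire
together at the first instant, which no physiological hierarchy would
show; the offset just needs to exceed the propagation time from the
dominant site.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| grid | 128×64 px (camera 128×128 split-frame) | acquisition geometry of the targeted recordings |
| pixel size | 10 µm | embryonic atrium ~0.5 mm across a 64-px sheet |
| frame rate | 52 Hz | acquisition rate of the targeted recordings |
| conduction velocity | 10 µm/ms (~1 cm/s) | immature embryonic myocardium; resolves the wave over several frames at 52 Hz |
| SAR period | 341 ms (176 bpm) | control 48-hpf rate |
| AVC period | 600 ms | the real escape rate is not quantified; a placeholder clearly slower than the SAR |
| refractory period | 200 ms | shorter than every pacing period used; longer than the AP |
| upstroke / APD | 20 ms / 150 ms | embryonic atrial AP scale |
| camera baselines | 30 000 counts per channel | ~half well depth of a 16-bit camera; gives per-pixel ratio SNR ≈ 12, matching the SNR ≥ 10 regime the recovery guarantees are stated for |
| fractional FRET change | 5% per channel | small-signal voltage sensor |
| noise | Poisson shot + Gaussian read (20 counts) | EMCCD-like |

The action-potential template is a logistic upstroke (steepness chosen
so the 10–90% rise time is ~80% of the nominal upstroke duration — the
nominal duration should describe the actual rise), a plateau over 30%
of the remaining AP duration, then exponential repolarization, zero
outside `[0, APD]`. Its maximal slope sits at half the upstroke
duration, which is the fiducial the activation-time estimator should
recover.

## Voltage extraction

The ratio is oriented acceptor/donor so depolarization increases it;
the opposite orientation only flips plot polarity, since activation
times depend on the signal monotonically. Channel registration
maximizes the *magnitude* of the Pearson correlation of the time-mean
images: FRET channel pairs are anti-correlated by construction, so the
signed correlation of a perfectly co-registered pair is −1. Two guards
make registration fail safe rather than silently wrong: a small
quadratic shift penalty (10⁻³ per px²) and a minimum |r| of 0.3 below
which the images are declared too featureless to register and left
unshifted (with a warning). Shifts are applied circularly; for the
few-pixel misalignments of an image splitter only border pixels touch
wrapped content.

The Wiener filter follows the classic pixelwise adaptive form: local
mean μ and variance σ² over a 3×3 window, noise power ν² defaulting to
the image mean of σ², output `μ + max(σ²−ν²,0)/σ²·(x−μ)` and exactly μ
where σ² = 0. Borders replicate the edge pixel rather than zero-pad:
zero padding would make the filter alter constant frames at their
borders, breaking the identity-on-constants contract; interior pixels
are identical under either convention (verified against
`scipy.signal.wiener` on the interior in the tests).

Per-pixel normalization is exact min–max by default (every in-mask
pixel attains 0 and 1 somewhere in time), with percentile options for
heavy-tailed noise. Flat pixels (vessel lumen, background inside a
hand-drawn mask) become NaN rather than raising — real masks contain
them.

## Activation mapping

Beat windows come from the mask-mean trace (not per pixel), keeping
per-beat maps consistent across pixels. Activation time is the frame of
maximal dV/dt within the window (central differences; ties break to the
earlier frame, since activation is a first-crossing event), refined to
sub-frame precision by a parabola through the three derivative samples
around the maximum. At 52 Hz a frame is 19.2 ms, so refinement matters:
on noiseless templates the mean timing error is ~1 ms refined vs ~5 ms
unrefined. Pixels whose maximal dV/dt falls below 3× a robust
(MAD-based) estimate of the derivative noise are dropped as unmappable;
maps with under 10% valid pixels are flagged low-quality.

Origin calls cluster the earliest `early_quantile` (default 5%) of
pixels by connectivity and merge clusters within `merge_radius`. Two
estimator details exist because timing noise (~1 ms) is comparable to
the inter-pixel conduction delay (1 ms at defaults): the map is first
smoothed with a 3×3 NaN-aware mean, and `consensus_origin` averages the
per-beat primary sites over a run — per-beat calls jitter by a pixel or
two, and beats are nearly independent measurements of the same site.
The earliest site is the primary origin; later ones are ectopic foci.

Conduction velocity is the inverse gradient magnitude of a least-squares
plane fit, which is exact for planar waves; for a point source near the
mapped region the directional spread of the gradient biases the plane
fit fast, so the estimate is a validation metric for planar geometry,
not a general CV mapper.

## Rhythm statistics

Heart rate uses the mean inter-beat interval (per-beat weighting);
beat-count-over-span is exposed implicitly via the beat series. Pauses
are intervals above k×median (k = 2): the median is robust to the very
pauses being flagged, and no principled threshold is published for this
preparation. The Wilcoxon rank-sum test reports the rank sum W of the
first sample and a two-sided p: by full enumeration of rank assignments
(null distribution cached per group-size pair) when n ≤ 12 without
ties, otherwise a normal approximation with tie-corrected variance and
0.5 continuity correction. The two routes agree within 0.02 in the
decision-relevant tail (exact p ≤ 0.2) for groups of 3–7 and over the
whole range for groups of ≥5; mid-distribution (p near 0.7) the gap can
reach ~0.04 for the smallest groups — an intrinsic property of the
normal approximation, documented rather than hidden.

## Gene-set algebra

Thresholds are strict inequalities (a row at log2FC = 2.0 or
padj = 0.05 exactly is excluded). Ortholog maps may be many-to-many; a
gene counts once per disease term no matter how many of its orthologs
carry the term, and the "unique" tally deduplicates gene ids across
terms. Genes without orthologs are reported unmapped, never counted.
All operations are order-independent set algebra and are tested against
nested-loop oracles on planted tables.

## What the synthetic data does and does not emulate

Emulated: split-frame two-channel geometry, 16-bit quantization, shot
and read noise, FRET polarity, propagation delays, refractoriness,
pacemaker hierarchy with jitter and pauses, per-embryo rate sampling at
stated mean ± SEM, DE tables with boundary-straddling null genes and
planted overlaps.

Not emulated: motion and contraction artefacts, photobleaching,
spatially varying expression/illumination, curved 3D heart geometry,
wavefront curvature from anisotropic conduction, endocardial layers,
and any real transcriptome structure (correlated expression, realistic
p-value distributions). Passing tests therefore certify the numerics of
the chain under the stated noise model — not robustness to motion or
optical artefacts, which real recordings add on top.

## Problem sizes

Unit and property tests run on 32×32 sheets for 3–8 s; the
study-condition analyses and the acceptance script use 48–64 px sheets
for 12–15 s and 20 s single-pixel traces, sizes at which every check
completes in seconds while leaving several frames across the activation
map and ≥19 beats per run.

## Known limitations

- The event-driven model has no wavefront curvature memory or source–
  sink mismatch; ectopic-focus competition is therefore all-or-none.
- Activation-time refinement assumes one upstroke per window; double
  potentials (wave collisions inside a window) keep only the larger
  derivative peak.
- The exact rank-sum enumeration is practical to n ≤ 12; beyond that
  the continuity-corrected normal approximation is used, as in the
  standard implementations.
- Escape-rate defaults are placeholders: the study conditions fix the
  SAR rate and the group statistics, but no measured AVC intrinsic rate
  exists to calibrate against.
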