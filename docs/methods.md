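# Methods

This note documents the models, rules and numerical choices behind
`nociscope`, and what the synthetic-data generator does and does not
emulate.

## Signal model and trace processing

Fluorescence from a cell ROI is corrected for out-of-focus and neighbour
contamination by subtracting the surrounding annulus ("doughnut") signal:
`corrected(t) = f_cell(t) − r·(f_annulus(t) − median(f_annulus))`.  The
annulus is median re-centred so the subtraction removes its *fluctuation*
without shifting the cell's absolute brightness, which the ΔF/F baseline
depends on; the contamination scale `r` defaults to 1.0.  ΔF/F (%) uses
`F0` estimated per episode, by default the 10th percentile (robust to
activity within the episode); a pre-stimulus mean is available as an
alternative.  No convention for `F0` is canonical in this kind of data, so
both are exposed in config.  A non-positive `F0` is an error naming the
cell rather than a silent NaN.

Transient detection operates per episode — detection, baselines and the
"preceding minimum" never cross an episode boundary, and the first/last
sample of an episode cannot be a peak (prominence is undefined at an
edge).  Candidates are local maxima; prominence follows the standard
definition (height above the higher of the two minima flanking the peak out
to the nearest higher sample or the episode edge), computed by
`scipy.signal.peak_prominences`.  Thresholds are minima (inclusive):
prominence ≥ 4 % and absolute peak ≥ 4 % for spontaneous activity, 5 %
prominence for heat, 5 %/20 % for brush time-locking.  The inter-peak
interval (0.6 s) is enforced in samples, rounding half-up (3 samples at
5 Hz); when two candidates collide, the larger prominence wins, then the
earlier peak — the rule is arbitrary but pinned by tests.  An event's
amplitude is peak minus its preceding local minimum, found by walking back
down the rising edge (strictly decreasing backwards); its end is the first
post-peak sample below 10 % of the amplitude above that onset baseline.
The test suite holds this detector to *exact* agreement (indices,
prominences, amplitudes) with an independent exhaustive implementation on
a thousand random traces.

No smoothing is applied before detection; at the default noise level the
4 % absolute-peak rule sits at 4 σ and keeps the false-event rate below
about one per 100 s, which the suite verifies.

## Response scoring

Heat responses are gated by onset: the transient's preceding minimum must
lie inside the stimulation window (inclusive).  The response magnitude is
the trapezoidal AUC of ΔF/F above the onset-baseline from onset to end at
the native 5 Hz — the 10 %-of-peak end criterion is interpreted relative to
the onset baseline (peak *amplitude*), making onset, end and hence the
integration span invariant under trace scaling.  When several qualifying
peaks fall in one window, the largest is scored and overlapping spans are
merged (first onset to last end).  Responsiveness is a strict inequality:
AUC > 3.5 %·mean × duration.  The strict comparison is evaluated with a
1 × 10⁻⁹ absolute guard so that a response equal to the threshold up to
float rounding — e.g. an exact-boundary rectangle integrated by trapezoid —
is classed non-responsive, as "exceeds" requires.  Mechanosensitivity is
likewise strict (> 15 % amplitude), while the brush-cell rule is inclusive
(time-locked on ≥ 50 % of brushes, "at least half").

The polymodality ratio compares the maximal *responsive* peak amplitude per
modality by default (a common unit across heat and mechanical responses);
AUC can be selected instead.  A ratio of exactly 5:1 or 1:5 is not
polymodal.  A cell with a missing modality is untestable, not a
non-responder, and raises rather than guessing.

## Transcriptomic decoding

Expression calls are ternary (negative/weak/strong) per gene.  Decoding is
an ordered first-match rule list — mirroring a manual decision tree and
trivially auditable — where each rule requires level sets per gene
("strong", "positive" = weak-or-strong, "negative") and may forbid levels.
Weak calls count as positive unless a rule demands strong.  A cell whose
matched rule references an untested gene is conservatively unclassified.
The shipped table covers all ten classes, is anchored to well-established
markers (*Mrgprd* → NP1, *Mlc1* → NP2B, *Nppb*+*Sst* → NP3, *Trpm8* →
TRPM8, *Calca*/*Trpv1* → PEP, *S100b* for myelinated classes) and is
flagged `provisional: true` in its YAML serialization: it is a documented
default for synthetic work and should be replaced with a study-specific
table for real recordings.  Round-trip identity (canonical pattern →
decode) holds for every class and is pinned by tests.

## Population statistics

Class percentages divide responders positive for a class by responders
*tested* for that class — denominators differ per class because not every
probe set is run in every animal — so raw percentages need not sum to 100;
stacked shares renormalize them.  PGE2 comparisons are two-tailed paired
t-tests over longitudinally tracked cells (per-mouse aggregation can be
layered on the returned tables); genotype comparisons are Welch t-tests
with Welch–Satterthwaite degrees of freedom, one-tailed (KO < WT) for heat
attenuation and two-tailed for spontaneous activity.  Holm–Šidák step-down
correction (`1 − (1 − p₍ᵢ₎)^(m−i+1)` with monotonicity enforcement, via
statsmodels and re-verified against the formula in tests) is applied across
classes.  Identical paired vectors return t = 0, p = 1 by convention
rather than NaN.  Calibration is checked by simulation: under a 10-class
Gaussian global null the corrected family-wise error is ≤ 5 % (1,000
replicates), and the generator's configured PGE2 effect is detected with
power ≥ 0.9 at 60 cells per affected class through the full
simulate-detect-test pipeline (40 replicates; sizes chosen to keep the
default suite fast).

## Registration

The guide-post fit is the closed-form least-squares scaled rotation
(Procrustes/Umeyama); degenerate configurations (< 3 pairs, collinear
landmarks, duplicate points) are rejected by name.  The morph is an
interpolating thin-plate spline on the similarity-pre-aligned coordinates
— `scipy.interpolate.RBFInterpolator` with the thin-plate kernel and zero
smoothing, which reproduces every landmark to ~10⁻¹² px; a smoothing
parameter is exposed, and piecewise-affine (exact affine for exactly three
landmarks) is available as a faster alternative.  Label transfer maps ISH
centroids through the model and matches greedily one-to-one by ascending
distance; pairs beyond `max_dist` are dropped and exact-distance ties are
discarded as ambiguous.  Greedy matching is auditable and sufficient at
cell-level (not pixel-level) registration accuracy; optimal assignment
would be a drop-in extension.  Multi-round ISH composes per-round models
and reports composite residuals at shared landmarks.  Coordinates are
pixel-space, origin top-left, x rightward, y downward.

With correspondence jitter at 20 % of the nearest-neighbour spacing, a
cell's own jittered ROI is occasionally no longer its nearest neighbour, so
no matcher can assign every cell correctly; the meaningful figure of merit
is the precision of the assignments made under the `max_dist` gate (half
the nearest-neighbour spacing), which exceeds 99 % on the default synthetic
field while matching ≥ 75 % of cells.

## The synthetic-data generator

The generator defines the study conditions for all validation: protocols
(40-s episodes at 5 Hz, 30 °C baseline holds, brush and pinch series, one
4-s pulse per temperature in {37, 39, 42, 45, 50} °C, ≥ 105 s unstimulated),
populations over the ten classes (uniform frequencies by default; the
empirical abundances of any particular dataset are not modelled), traces,
expression panels and deformed guide-post fields.

Calcium events are difference-of-exponentials kernels (rise 0.15 s, decay
1.0 s — GCaMP6f-like; any fast-rise/slow-decay kernel is acceptable and
both constants are parameters) scaled by per-cell amplitudes, with
additive Gaussian noise of 1 % ΔF/F so the 4–5 % thresholds sit at 4–5 σ.
Spontaneous events are a homogeneous Poisson process at the
condition-specific class rate with amplitudes ~N(10, 3) % clipped at 1 %.
Class tuning profiles are *direction-correct defaults, not fitted
magnitudes*: LTMRs are brush-responsive and heat-insensitive, nociceptor
classes are graded across the temperature range, only Aδ-NOC/PEP/NP2A/NP3
gain spontaneous activity after PGE2 (2–3 events/min versus ~0.05 at
baseline), warm sensitization multiplies heat amplitudes in the
TRPV1-expressing classes, and *Trpv1* knockout removes the configured
fraction of each class's heat response (0.8–0.9 in PEP/NP2A/NP3).  All
tests assert recovery of these *configured* effects, never any particular
empirical values.  Functional-category ground truth is assigned from the
realized per-cell draws with the same ratio rule the analysis applies.

Guide-post fields place points quasi-uniformly with a minimum-spacing
rejection rule; the ISH-to-in-vivo map is a similarity transform plus a
smooth sinusoidal displacement field plus i.i.d. jitter, with a flagged
guide-post subset of known correspondence.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: pixel-level movies and ROI segmentation
(activity maps are exercised on toy stacks only), motion artefacts,
photobleaching and baseline drift, bursty or correlated firing,
receptive-field geometry (every responder cell answers every stimulus of
its modality), spike-to-calcium nonlinearity, and realistic ISH
segmentation error beyond independent per-gene call corruption.

## Problem sizes and determinism

Default validation sizes: 1,000 random traces for detector/oracle
agreement, 2,000 cells for category and decoder recovery, 1,000 null
replicates and 40 power replicates for the statistics, 20 guide-posts at
2 px jitter for similarity recovery, and 150-point fields for transfer;
these keep the full suite under a minute of simulation-heavy work while
leaving Monte-Carlo margins far from the asserted bounds.  Every stochastic
stage takes an explicit seed; the pipeline derives per-stage seeds from one
root seed, builds all outputs in memory before writing, and is
byte-identical across repeated runs of the same config — which the suite
asserts literally on the emitted files.
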