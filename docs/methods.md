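# Methods

## Overview

`quadconn` measures seed-based brain connectivity four ways — evoked
potentials (CCEP), stimulation BOLD (DES-fMRI), resting-state BOLD
correlation (rsfMRI) and lattice tractography (dMRI) — and quantifies their
pairwise consistency as Pearson r^2 over common targets.  Because real
multimodal intracranial data cannot ship with the package, every claim is
validated on a synthetic phantom whose four datasets derive from one known
weighted network; the phantom is first-class, tested code.

## The structural solver

**Transition probabilities.**  The unit sphere is partitioned into the 26
spherical Voronoi cells of the lattice-neighbor directions (offsets in
{-1,0,1}^3 scaled by the voxel size in mm, so anisotropic voxels are
handled; cell areas are integrated once on a deterministic Fibonacci
lattice of 2e5 points and cached — the fractions sum to 1 exactly because
the points partition).  FOD amplitudes are stored as *cell-integrated*
masses: channel d holds the FOD mass inside cell d, so a uniform-density
FOD has amplitudes equal to the solid-angle fractions.  The probability of
stepping from voxel v to neighbor n is then amplitude(n) renormalized over
in-mask neighbors; steps out of the mask get probability 0.  In-mask voxels
with no usable FOD mass fall back to isotropic with a warning.

**Pathway score.**  score(P) = max over lattice paths seed -> P of the
product of step probabilities.  This is the infinite-trial limit of
sampled-walk tractography when the strongest path is retained, and is
computed exactly by best-first (Dijkstra-type) expansion, valid because
every step multiplies by a factor in (0,1].  Ties keep the
lexicographically smallest (flat-index) predecessor, making backtracked
tracks deterministic.  Two independent cross-checks ship with the package:
an exhaustive depth-first path enumeration with dominance pruning (exact on
small grids; pruning a branch whose running product cannot beat the best
known value at its head voxel is sound because any suffix multiplies both
alternatives equally), and a vectorized Monte-Carlo walker oracle whose
best sampled product is a lower bound on the solver score by construction.

**Display scale.**  Raw products decay exponentially with path length, so
gray-matter maps are reported on a monotone 0-10 log scale:
`10 * (1 - ln s / ln floor)` clipped at 0, with floor = 1e-12; a score of 1
maps to 10, anything at or below the floor to 0.  The floor only shifts and
scales the log — it does not reorder values.  Whether the score should be
normalized by path length is left open deliberately; the unnormalized
product is implemented.

## CCEP scoring

Epochs are cut at 1 kHz around each 1 Hz pulse; pulses alternate polarity.
The stimulation artifact is polarity-odd while the evoked response is
polarity-even, so a plain mean over balanced trials cancels the artifact
exactly (a 21/20 imbalance leaves artifact/41, recorded in provenance).
Outlier trials are removed *before* averaging: each trial's RMS deviation
is computed against the per-sample median waveform of its own polarity
group — computing deviations against the pooled median is not robust,
because a single large transient overlapping the artifact window can flip
the pooled per-sample median to one polarity's artifact and inflate the MAD
until nothing is rejected.  Trials beyond median + k*MAD (k = 5) of the
pooled deviation distribution are discarded, capped at 50% removal.

A scalar baseline (mean over a 40 ms window ending 5 ms before the
stimulus; the gap avoids artifact bleed) is subtracted, and the score is
the mean (or rectified mean) voltage over a post-stimulus window: 10-15 ms
for comparisons against structural connectivity (first-pass excitation),
20-120 ms against the slower functional measures.  Cross-modal comparisons
use the rectified mean by default, mirroring the use of |t| on the fMRI
axis; the signed option exists.

## rsfMRI and DES-fMRI

The seed waveform is the mean of the 3x3x3 neighborhood of the seed voxel
(truncated at grid edges) excluding CSF voxels; the map is the Pearson r to
every gray-matter voxel, after per-voxel polynomial detrending (order 1 by
default — the published nuisance pipeline is out of scope).  Zero-variance
voxels are missing, not zero.

The DES design is an alternating off/on boxcar (32 s blocks, four
on-blocks, TR 2 s, 150 volumes) convolved with a single-gamma HRF (peak 5 s,
shape 6, unit peak) and an intercept; fitting is voxelwise OLS with
t = beta/SE and df = volumes - regressors, no autocorrelation correction
(noted as an extension).  Zero-residual voxels get a +/-inf sentinel rather
than silently huge t.  Maps are stored unthresholded.

## Cross-modal comparison

Volumetric maps are sampled at contact positions as the mean of in-mask
voxels within 2.5 mm (one voxel); targets within 10 mm of the stimulation
midpoint are excluded, as are the stimulating contacts.  Pairs missing in
either modality are dropped and counted.  r^2 and the two-sided p come from
the product-moment formula with t = r*sqrt((n-2)/(1-r^2)) on n-2 df
(delegated to `scipy.stats.pearsonr`; hand-computed toys pin the values in
tests).  Sessions are pooled by concatenating aligned pairs before one
global r^2, unweighted and without per-session normalization (a
normalization flag exists); p-values are reported unadjusted.

## The phantom

One `PhantomConfig` fixes the study conditions; the same seed always
rebuilds the identical phantom bit-for-bit (a global `SeedSequence` is
spawned into per-stage generators).

**Geometry.**  36^3 voxels at 2.5 mm.  Node 0 (the hub, carrying the
stimulating pair) sits at the grid center jittered by up to +-3 voxels per
axis (implantation position varies between sessions; the jitter also makes
independently drawn networks spatially independent).  Satellite nodes are
placed along lattice *edge-direction antipodal classes* — one direction per
class, random class subset and sign — at equal Chebyshev distance 6, with
straight digitized bundles.  This is a deliberate control: all hub bundles
then have the same step count and lattice-symmetric geometry, and no two
bundles share an FOD axis at the hub, so differences in the pathway score
reflect coupling strength rather than lattice-direction discretization
artifacts (path step count varies with angle on a lattice) or antipodal
lobe mixing.  Networks with more than 7 nodes extend to face and corner
classes, mixing geometry classes; the equal-geometry guarantee then no
longer holds.  The brain is a sphere of radius 0.47*grid — generous so
every patch stays well interior, because mask-boundary renormalization of
transition probabilities would otherwise bias scores toward nodes near the
edge.  Bundle voxels outside patches are white matter; a small CSF pocket
is placed away from patches and bundles; everything else inside the sphere
is gray matter.

**Weights.**  Edge weights are evenly spaced over (0.30, 0.95) and
assigned to edges in random order — a dose-design choice: iid draws produce
near-ties whose rank statistics measure tie-breaking noise rather than
method error.  An iid-uniform mode exists.  The shared latent quantity of
all modalities is the *path strength*: the max over graph paths of the
product of edge weights (computed via networkx shortest paths under -log w).

**FODs.**  On-bundle voxels get an antipodally symmetric Watson-like lobe
`a_d ∝ omega_d * exp(kappa*w*(u_d.t)^2)` along the bundle chord tangent
(kappa = 20 by default; kappa = 0 is exactly isotropic; voxels on several
bundles mix lobes in proportion to edge weight); all other voxels are
isotropic.

**Resting BOLD.**  Node latents are unit-variance AR(1) series (rho = 0.5
at TR 2 s) mixed so their correlation matrix *equals* the path-strength
matrix (eigenvalue-clipped to PSD — exact for trees, the default topology);
non-node brain voxels carry independent AR(1) fluctuations; white noise of
sd `sigma_bold` (default 0.1) is added across the brain.  The direct
identification corr(node_i, node_j) = path strength makes the latent truth
the one quantity every modality shares.

**Evoked recordings.**  40 pulses at 1 Hz, 1 kHz sampling.  Each trial: a
polarity-signed decaying artifact (800 uV, tau 3 ms), plus — at contacts
whose containing patch is network-connected to the hub — a fixed biphasic
template (downward peak at 100 ms, upward at 230 ms, latency +10 ms per
extra path edge; whether amplitude should fall with synaptic distance is
left a knob) scaled by 120 uV * path strength, plus white noise
(`sigma_ccep`, default 5 uV).  A configurable fraction of trials (default
0.1) is corrupted with 20x hanning bursts at random times, with the
corrupted indices recorded.

**Stimulation BOLD.**  Activation amplitude at each connected patch is
`des_amp * path strength` times the same HRF-convolved design used for
fitting; each non-hub node's sign is negative with probability 0.25
(emulating robust deactivation); noise is temporally *white* (so the GLM
null calibration is exactly Student-t; the rsfMRI latents, by contrast, are
AR(1)).  No signal is ever written into CSF.

**Electrodes.**  Two adjacent stim contacts on the hub patch (the second
along a face direction, never on a bundle), one recording contact at each
satellite center, and the remainder on random gray-matter voxels *on the
satellites' shell radius* — emulating a grid array at uniform distance from
the stimulation site.  The shell placement is another control: every
seed-based measure shares a distance-from-seed profile, and placing targets
at matched distance keeps that common gradient from inflating (or, in the
null experiment, fabricating) cross-modal correlation.  Coordinate jitter
(`jitter_mm`, default 0) displaces recorded positions only.

## Experiments

*Shared-network condition* (consistency recovery): 20 phantom sessions at
low noise (`sigma_bold` 0.05, `sigma_ccep` 0.5 uV, kappa 40 — strongly
concentrated FODs so orientation dispersion contributes no score noise),
one contact target per node, pooled; all six pairwise r^2 come out >= 0.9.
*Independent-networks condition*: per session, four phantoms with distinct
networks on one grid; each modality is measured on its own phantom and
sampled at a common 32-contact table; 600 pooled targets give all six
r^2 < 0.01.  Together these operationalize the interpretation that a low
observed cross-modal r^2 reflects genuinely inconsistent underlying
networks rather than pipeline error.

*Rank recovery*: per session, Spearman between ground-truth path strength
and each measure at the node targets, averaged over 100 sessions at
`sigma_bold` = 0.2 (the demanding end of the stated range): CCEP, DES-fMRI
and dMRI are essentially exact; rsfMRI averages ~0.97, limited by the
sampling error of a 132-volume correlation estimate, not by sensor noise.

Problem sizes (4^3/5^3 oracle grids, 36^3 phantoms, 20 and 100 sessions,
1e4 null voxels, 1e5 walkers) are chosen so the full suite and the
acceptance script each run in minutes on one CPU.

## What the phantom does and does not show

It emulates: one latent network expressed in four noisy instruments with
their real units, windows, designs and artifacts; polarity-locked artifact
and motion outliers; crossing fiber bundles; registration jitter;
deactivation.  It does not emulate: anatomy, k-space/EPI physics,
physiological noise spectra, spatially varying HRFs, polysynaptic latency
structure, or distance-dependent connectivity priors — so passing tests
demonstrate correctness of the measures and comparisons, not performance
on patient data.  Known limitations: per-step probability saturates for
strongly concentrated FODs (compressing the dMRI scale at high coupling);
the max-product score ignores path multiplicity (a sum-over-paths variant
is a noted alternative); OLS ignores temporal autocorrelation; pooling is
unweighted across sessions.
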