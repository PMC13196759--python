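# Methods

`photokin` reimplements, as a tested pipeline over synthetic inputs, the
computational analyses used to characterize light-evoked locomotion
(photokinesis) in surface- and cave-dwelling *Astyanax mexicanus*: locomotor
scoring under alternating light/dark epochs, hybrid-cross trait structure,
a brain-region volume–behavior correlation screen, stimulus-tuned clustering
of calcium traces, and a voxelwise activity-map comparison.  This note
records the models, defaults, and design choices, and what the synthetic
generators do and do not emulate.

## The photokinesis index

Raw tracking (well id, time, x, y at a fixed frame rate; 25 fps by default)
is converted to distance moved per 30-s bin.  Steps shorter than a jitter
threshold (default 0.1 mm) are zeroed as centroid noise; a trailing partial
bin is dropped.  For each light transition, the transition delta is the mean
binned distance in the window after the transition minus the window before
(one 30-s bin per side by default; configurable).  Deltas are averaged
across transitions of each type, and the index is

    PI = (Δt_on→off − Δt_off→on) / (Δt_on→off + Δt_off→on)

so PI = +1 marks a purely dark-activated (surface-like) fish and −1 a purely
light-activated (cave-like) fish.  Numerical guards:

- Fish missing a transition type, or whose summed transition change has
  magnitude below `denom_epsilon` (default 10⁻⁶ mm), are flagged invalid
  with a reason and excluded from group statistics rather than producing an
  unbounded ratio.
- The boundary between dark acclimation and the first light epoch is not an
  alternating-cycle transition and is excluded by default
  (`skip_acclimation`).
- Deltas are averaged before the ratio (delta-first).  A `per_transition`
  flag instead computes the index per paired transition and averages,
  since either reading of "average transition periods" is defensible.
- The PI is a ratio statistic: when the denominator is noise-dominated its
  sampling distribution is heavy-tailed, and when the off-trigger delta is
  negative (a sustained response collapsing at the transition) the ratio can
  exceed ±1.  Group means are therefore reported with SDs, and monotonicity
  checks in the test suite use the median.

Group comparisons use a fixed procedure: Shapiro–Wilk normality is
reported per group as a diagnostic but does not switch the test; two groups
are compared by
Welch's t-test (the unequal-variance form is the robust default), more than
two by one-way ANOVA with Tukey-HSD-adjusted pairwise p-values.  Raw
pairwise p-values use the pooled-variance t with N−k degrees of freedom so
that the Tukey-adjusted value is never smaller than the raw one.  Groups
that are identical and constant return F = 0, p = 1 rather than NaN.

## Synthetic locomotion

No generative model of larval swimming is implied by the assay itself, so
the generator adopts a minimal latent speed model per frame:

    speed = max(0, baseline + 1[state = trigger]·(sustained + transient·e^(−Δt/τ)) + noise)

with Δt the time since the triggering epoch began.  Defaults: baseline
0.8 mm/s, transient gain 2.0 mm/s, τ = 20 s, per-frame Gaussian noise SD
1.5 mm/s, sustained gain 0.  The transient-dominant default reflects the
"light-searching" burst at a transition and makes the noiseless index
exactly ±1, which pins the scoring pipeline to a closed form; a sustained
component remains a first-class parameter (its noiseless index exceeds +1
because the off-trigger delta goes negative — see the guard discussion
above).  Positions integrate speed along a heading random walk (0.35
rad/frame) inside a reflective square well (half-width 3.2 mm, roughly a
96-well-plate well).  Reflection is implemented as per-axis triangle-wave
folding of the unconstrained path, which is the exact one-dimensional
billiard solution and vectorizes; a disk-shaped wall would need a
sequential bounce loop for no statistical gain at these step sizes.  With
rectified noise, E[speed] has the closed form mΦ(m/σ) + σφ(m/σ), which the
tests use as the analytic oracle for binned activity (in an unbounded arena,
where binned distance equals integrated speed exactly).

The assay schedule is 30 min of dark acclimation followed by three 5-min
light / 5-min dark cycles (cycle count configurable; three is the default
for a one-hour assay).

## Hybrid crosses

Trait variation is modeled additively over k equal-effect loci (default
k = 4): the genetic value g = (# surface alleles)/(2k) is 1 in surface
parentals, 0 in cave parentals, exactly ½ in F1 (all loci heterozygous), and
Binomial-distributed in F2 with Var(g) = 1/(8k).  Per-fish environmental
noise (SD 0.06) adds to g, clipped to [0, 1].  A fish's locomotor model is
the g-weighted mixture of the surface (dark-triggered) and cave
(light-triggered) responses, with baseline and noise interpolating linearly.
Under the symmetric transient default the noiseless index is exactly
2g − 1, so F1 sits midway between parentals and the F2 index variance is
4·Var(g) plus environmental terms — the classic intermediate-F1 /
wide-variance-F2 signature, with k the single interpretable knob.

## Region-volume screen

Volumes are an input (atlas registration and segmentation are out of
scope).  The generator plants `volume = mean + slope·PI + N(0, sd)` per
region; `slope_for_correlation` converts a target population Pearson r into
the slope (r·σ_v/(σ_PI·√(1−r²))).  The default screen has 20 atlas-like
regions with r = −0.5 planted in the tegmentum, hypothalamus, and posterior
tuberculum and 17 null regions.  The screen itself runs a simple linear
regression of volume on PI per region (Pearson r, slope, intercept, raw p)
after an inner join on fish id (fish missing either measurement are dropped
and logged; at least 10 fish required).  Atlas-wide screens of this kind
rarely standardize multiple-testing control, so the screen reports
Benjamini–Hochberg q alongside raw p and sorts by q; constant-volume
regions are flagged and excluded from the BH family.

## Calcium-trace tuning and clustering

The imaging protocol is 60 s of no light followed by four 30-s ON/OFF cycle
pairs (300 s; 5 Hz frames by default).  Normalization is ΔF/F with f₀ the
mean over the no-light lead-in — the upstream suite's normalization is not
specified, and the lead-in is the only stimulus-free stretch.  Tuning
features are per-epoch mean ΔF/F over the eight post-lead-in epochs; a
neuron's preference is the larger of the ON and OFF summary means, with a
dead-band of 0.05 ΔF/F below which it is called untuned, so noise-level
differences are not labeled.  Clustering is agglomerative with Ward linkage
on Euclidean distance over the per-epoch vector, cut to at most
`max_clusters` = 5 flat clusters (matching the upstream suite's
`max_cluster = 5`); linkage and metric are otherwise unspecified upstream,
and Ward is deterministic and variance-minimizing.  Clusters are renumbered
by descending size with ties broken by smallest member index, making output
labels order-independent; the upstream suite's internal cluster numbering
cannot be reproduced, so "cluster 4/5"-style identities map only by tuning,
not by number.  The synthetic generator convolves the preferred-state
indicator with a single-exponential kernel (τ = 1.8 s, nuclear-GCaMP6s-like;
the true indicator kinetics are not stated) via the exact first-order
recursive filter, so epoch means follow a closed-form exponential average
used as a test oracle.  Population contrasts are Welch t-tests per
cluster × light condition with BH adjustment across the family.

## Voxelwise activity map

Only the statistical core of activity mapping is reimplemented: per-voxel
two-sided Mann–Whitney rank-sum between two groups of spatially congruent
volumes, BH q-values, and a signed mask (+1 where group A is higher by
median difference, −1 where lower, 0 where q > 0.05).  The exact null
distribution is enumerated when total n ≤ 10; otherwise the tie-corrected
normal approximation is used (the reported statistic is the tie-corrected z
without continuity shift, so it negates exactly under group swap).  Voxels
where all observations tie return p = 1, z = 0.  No spatial smoothing is
applied by default; an optional Gaussian pre-smoothing (σ in μm) is
available since smoothing is standard in volumetric mapping — it is an
approximation, not a reproduction, of any specific upstream filter.  Label
volumes use integer labels with 0 as background; region summaries report
signed significant fractions only and leave region-level inference to the
user.  Phantoms plant spherical blobs of fixed effect size in group A over
Gaussian background noise.

## Reproducibility

All randomness derives from a single integer seed split into named
substreams (`SeedSequence([seed, crc32(name)])`), so each generator is
bitwise-reproducible and insensitive to call order.  The demo pipeline
(`run_pipeline` / `photokin demo`) writes a manifest with the configuration,
a 16-hex-character sha256 configuration hash (stamped on every CSV as a
leading comment and in NIfTI `descrip` headers), package versions, and
output checksums; reruns with the same configuration are byte-identical.

## Problem sizes and limitations

Defaults in tests and the acceptance script use cohorts of 50 fish per
parental generation and 199 F2 fish (the screen's planted-correlation
recovery is calibrated at n = 199), 100 neurons across five planted tuning
clusters, and 40×40×20 voxel phantoms with 10 subjects per group — sizes
chosen so every Monte-Carlo check has comfortable statistical resolution on
a single CPU.

What passing tests show is that the pipeline recovers planted structure
under its own generative assumptions.  The generators do not emulate:
bout-structured (autocorrelated) swimming — frame noise is white, so real
per-fish PI spread is wider than simulated; circadian or habituation
drifts; indicator bleaching, motion artifacts, or neuropil contamination in
traces; spatial noise correlation or registration error in volumes, which
makes the independent-voxel FDR guarantee optimistic for real maps.  Real
assay cohorts show far wider per-fish PI dispersion (population mean
indices well inside ±1) than the white-noise generator produces; the
synthetic defaults are built to reproduce the sign, ordering, and variance
structure of population differences, not realistic per-fish spread.
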