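# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design choices were made.

## The ugof statistic

For a sequence of onset times t_1 < … < t_n and a candidate beat
frequency f (Hz), theoretical beats lie at `anchor + k/f` for all
integers k. Each element scores

    ugof_i = |Δ_i| / Δ_max = 2 f · min_k | t_i − anchor − k/f |,

a ratio in [0, 1]: 0 on a beat, 1 exactly halfway between two beats.
Implementation: the phase `(t_i − anchor)·f` is reduced with `round`,
giving the signed fractional deviation in [−1/2, 1/2] directly; the
result is clipped to [0, 1] to absorb last-ulp rounding. An element
exactly halfway (|Δ| = Δ_max) scores exactly 1 regardless of which
adjacent beat is "nearest" — the reduction is numerically stable there.
Silent beats (grid positions without an element) are never scored, which
is what makes the statistic insensitive to element count and skipped
beats.

**Anchor convention.** The beat grid is anchored at the first onset, so
the first element always scores 0 and phase is not a free parameter.
An optional phase-optimization mode (`optimize_phase=True`) instead
minimizes mean ugof over the anchor; since the objective is piecewise
linear in phase with vertices where some element sits exactly on a beat,
the exact minimizer is found by evaluating all n element phases. The
chosen anchor is always reported in the result, never applied silently.
Single-element sequences are defined (ugof 0 by the convention) but
flagged as uninformative.

One consequence of the anchor convention matters for validation: the
anchor element's structural zero makes mean ugof scale with (n−1)/n, a
real but artifactual trend with element count. Validation of the
*statistic's* independence from element count therefore anchors at the
synthetic generator's true grid origin (recorded in the sequence
metadata), isolating the statistic from the anchor-phase artifact.
Real-data analyses, where no true grid is known, use the first-onset
anchor throughout.

## Modeled ugof distributions, z-scores

The reference distribution for a dataset is built by evaluating mean
ugof for **every (sequence, grid-frequency) pair** over a dense grid,
default 0.1–100 Hz in 0.01 Hz steps (9,991 frequencies; a 49-sequence
dataset yields 489,559 values). One value per (sequence, frequency) —
not per element — is the default granularity; element-level pooling is
available via `per_element=True`. Mean and standard deviation of this
distribution standardize any single ugof:

    z = (ugof − mean) / sd,   p = Φ(z)  (lower tail).

Only negative z can be significant (default α = 0.05): a positive z with
small upper-tail mass would mean a significantly *worse* fit than
expected and is never flagged. The normal approximation is taken as
given; a degenerate distribution (sd = 0) is an error, and summary
pathologies are logged as advisories rather than re-tested formally.

Because the fit can change strongly within small frequency increments,
`sensitivity_scan` evaluates mean ugof on a ±1 Hz band (default step
0.01 Hz) around any detected beat and flags whether the scan minimum
undercuts the center value — the signature of a beat estimate displaced
by, e.g., coarse spectral resolution.

## Beat estimation

**IOI beat.** Frequency = 1 / mean(IOI). The mean (not median) defines
the estimator; a median variant exists behind an option for
heavy-tailed interval distributions. Auxiliary variability metrics use
the conventional definitions: cv = sd/mean with the sample (n−1)
standard deviation (the small-sample choice; not prescribed by any
authority, so flagged here), and
nPVI = 100/(m−1) · Σ |d_k − d_{k+1}| / ((d_k + d_{k+1})/2).

**Fourier beat.** The sequence is binarized at 1000 Hz (1 ms bins; one
sample per onset, a collision is an error instructing a higher rate) and
the train's unnormalized magnitude spectrum computed, zero-padded so the
bin width does not exceed a target resolution (default 0.01 Hz, matching
the ugof grid step). The 0 Hz bin equals the onset count and is excluded
from reporting. Peak picking returns the k = 10 largest strict local
maxima in the 0.1–100 Hz band, with two suppression rules beyond the
bare local-maximum definition:

- *minimum separation* — candidates closer than the unpadded train's
  Rayleigh resolution (1/duration) to an accepted stronger peak are
  dropped, because zero-padding interpolates the spectrum and would
  otherwise report one spectral feature as several ripple maxima;
- *noise floor* — candidates below median + 3·(1.4826·MAD) of the
  in-band amplitudes are dropped: timing jitter spreads a broadband
  pedestal whose local maxima are not rhythm peaks.

Both rules are exposed as parameters and disabled by passing 0.

**Clusters.** Peaks are grouped by single-linkage on frequency with a
1 Hz default bandwidth (a chain of member-to-member gaps ≤ bandwidth
joins a cluster); the summary frequency is the amplitude-weighted mean
of the members and the summary amplitude their sum, so cluster mass is
conserved. Clusters are reported descending by summed amplitude.

**Which cluster is "the" beat.** A pulse train carries its rhythm's
energy across all harmonics of the beat, so the heaviest cluster is
often a harmonic — or a harmonic plus a noise companion — rather than
the beat itself. `select_beat_cluster` resolves this the way pitch
trackers resolve octave errors: each cluster is credited with the summed
amplitude of every cluster lying within 3% of an integer multiple of its
summary frequency, and the largest credited mass wins (ties toward lower
frequency). A candidate must itself carry ≥ 20% of the mass it claims,
which bars spurious subharmonics that merely collect other clusters'
energy. On two-regime composite fixtures this selection chooses a beat
whose mean ugof beats the IOI beat's in ≈ 98% of draws, versus ≈ 85%
for raw amplitude ranking.

## Recurrence analysis

The recurrence matrix holds |IOI_i − IOI_j| for every interval pair (the
1-D Euclidean distance); plots map 0 to the lightest color and the
maximum distance to the darkest, with optional binary thresholding. A
"break" — a candidate subunit boundary — is an adjacent-interval
difference exceeding a threshold. The automatic threshold is a two-stage
robust rule on the successive differences D:

1. fence: median(|D|) + 5 · (1.4826 · MAD(D)). Successive differencing
   inflates onset jitter by √6, and a 3·MAD rule would sit at only
   ≈ 1.9 σ of the difference noise (≈ 6% false positives per interval,
   guaranteeing over-segmentation); the 5 σ fence brings the nominal
   per-interval false-positive rate to ~10⁻⁸.
2. clearance: the threshold is raised to 3× the largest |D| *below* the
   fence, so a reported break must stand clear of the realized noise
   floor rather than beat a noisily estimated fence by a hair.

A boundary realized as one long gap interval exceeds the threshold on
both flanks, so runs of consecutive exceedances are merged and reported
by the index of the largest difference in the run. Detection is
advisory — it stands in for reading the plot by eye — and detected
subunits feed back into per-subunit beat/ugof analysis only on user
confirmation. Boundaries whose inter-regime IOI contrast is within a few
√6·σ of the jitter noise are not detectable by any threshold on D; the
validation fixtures use regime contrasts far above that floor (e.g.
10 Hz vs 4 Hz at 4 ms jitter ≈ 37 σ).

## Synthetic generator

`generate_isochronous` realizes the model the analyses assume: a fixed
grid at k/f, each beat independently silent with probability
`silent_prob` (the first beat never, so the anchor convention is well
defined), surviving onsets perturbed by i.i.d. Gaussian jitter around
their grid position — deviations from a stable theoretical beat, not an
accumulating random-walk drift — then re-sorted. If jitter pushes the
earliest onset negative the train is translated to start at 0 (all
statistics are translation invariant) and the translated grid origin is
recorded in the metadata. `generate_composite` concatenates such
regimes with a fixed silent gap and records segment slices, per-segment
grid origins and boundary interval indices as ground truth.

What the generator does **not** emulate: correlated (drifting) timing
errors, tempo curvature, measurement-dependent annotation error, element
duration/amplitude structure, or hierarchical meter. Passing tests on
these fixtures therefore validate the estimators under the isochronous
stationary-jitter model only; real recordings can deviate from that
model in all the listed ways.

Default study conditions used in validation: jitter of ~8–10% of the
beat period (annotation-realistic), silent-beat probabilities up to 0.5,
element counts 5–200, recovery runs at 2/10/30 Hz with 64 beats and 50
replicates, and 0.1 Hz transform resolution for recovery scans —
sub-0.01 Hz peak localization is statistically meaningless at ~64 beats
of 10%-period jitter, so the fine default resolution is reserved for the
ugof grid where it matters.

## Numerical notes

- ugof is exact at the halfway tie and clipped to [0, 1]; agreement with
  an extended-precision nearest-beat search is ≤ 1e−12 for sequences up
  to 20 s × 100 Hz (the double-precision phase representation itself
  limits agreement to ~2e−12 once span × frequency exceeds ~5000
  cycles).
- The distribution builder streams sums and squared sums (population
  variance over the full value set) rather than materializing all
  values.
- Grid construction uses `f_min + step·arange(n)` with
  `n = round((f_max−f_min)/step) + 1`, immune to float-step drift.
- Peak ties are broken toward lower frequency; plateau bins take the
  leftmost index.
- Reports render floats at 6 significant digits; full precision is kept
  in memory and the rounding is a rendering rule only, since the
  annotation precision of real onsets is unknown and left to the user.

## Known limitations

- Only isochronous beat models: no hierarchical meter, no tempo drift,
  no non-integer rhythm categories (IOI-ratio analyses are out of
  scope).
- The z-score machinery inherits the Gaussian description of the
  modeled ugof distribution; no multiple-testing correction is applied
  across sequences.
- Break detection and cluster selection are heuristics standing in for
  expert visual inspection; both expose their thresholds and should be
  treated as advisory on real data.
- The CLI analyzes whole files; per-subunit re-analysis after
  segmentation is a deliberate user step, not automated.
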