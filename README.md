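# ugof — universal goodness-of-fit rhythm analysis for onset sequences

Many animal vocalizations — bat isolation calls, whale echolocation
clicks, bird song — are produced on an approximately *isochronous*
(metronome-like) temporal grid. Describing such a rhythm by a single
"beat frequency" in Hz is only half the job: the other half is saying
**how well** that beat actually describes the sequence, in a way that is
comparable across sequences, datasets and estimation methods. This
package implements a rhythm-analysis toolkit for bioacousticians built
around the *ugof* (universal goodness-of-fit) statistic, operating purely
on annotated element-onset times in seconds (no audio decoding).

## The statistic

Given a candidate beat frequency *f*, lay a theoretical beat grid with
period 1/*f* over the sequence (anchored at the first onset). Each
element has a deviation |Δ| to its *nearest* theoretical beat; since an
element always lies between two beats, the largest possible deviation is
half a beat period, Δ_max = 1/(2*f*). The per-element score

    ugof = |Δ| / Δ_max  ∈ [0, 1]

is 0 when the element sits exactly on a beat and 1 when it falls exactly
halfway between two beats. Grid positions carrying no element ("silent
beats") are simply not scored, so the statistic does not degrade with
sequence length or with skipped beats. Sequence-level fit is the mean
over elements.

To judge whether a given ugof is good, the statistic is modeled over a
dense frequency grid (0.1–100 Hz in 0.01 Hz steps — 9,991 frequencies)
for every sequence in a dataset; the mean and standard deviation of the
resulting distribution turn any single ugof into a z-score and one-sided
normal p-value. Only negative z (fitting *better* than the
distribution's expectation) counts as possibly significant.

Around the statistic the package provides:

- **Beat estimation** two ways: the reciprocal mean interonset interval
  (IOI beat), and Fourier analysis of the binarized onset train
  (1 at each onset sample, 0 elsewhere) with the ten most prominent
  spectral peaks, peak clustering, and harmonic-aware selection of the
  cluster that represents the beat.
- **Sensitivity scans** of mean ugof within ±1 Hz of any detected beat,
  since the fit can change strongly within small frequency increments.
- **Recurrence matrices** of pairwise |IOI_i − IOI_j| distances with
  automatic "break" detection to locate subunit boundaries in complex,
  multi-tempo sequences.
- **A synthetic generator** of jittered isochronous trains with silent
  beats and multi-regime composites, with ground truth recorded for
  validation.

## Worked example

Simulate a two-regime sequence — forty ~10 Hz elements followed by
twelve ~3 Hz elements, with Gaussian onset jitter — then analyze it:

```sh
ugof simulate --segment 10:40:0.008 --segment 3:12:0.02 --gap 0.7 \
     --seed 11 --id song --out demo
ugof analyze demo/song.csv --out demo
ugof recurrence demo/song.csv --out demo
```

which prints:

```
song: 52 onsets, 8.329 s
song: ioi 6.123 Hz ugof 0.5373; fourier_peak 9.98 Hz ugof 0.2385; fourier_cluster 9.98 Hz ugof 0.2385
song: 1 break(s) at [38]
```

Reading the numbers: the IOI beat (1/mean IOI = 6.12 Hz) averages the
two regimes and describes *neither* — its mean ugof of 0.54 is no better
than chance placement. The Fourier peak and cluster beat land at 9.98 Hz,
the dominant regime's true rate, with a far better mean ugof of 0.24.
The ±1 Hz sensitivity scan (in `demo/song_summary.json`) refines the fit
further (minimum 0.21 at 10.00 Hz), and break detection segments the
sequence at IOI index 38 — exactly the boundary between the two regimes
(the 40-element first regime spans IOI indices 0–38). Re-running
`analyze` on the two subunits separately would then recover each
regime's own beat.

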