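"""Beat spectra of binarized onset trains; peak picking and clustering.

A sequence is encoded as a binary pulse train — 1 at each element onset,
0 elsewhere — and Fourier-transformed.  The magnitudes of the transform
form the *beat spectrum*: a peak at f Hz means an isochronous grid at f
describes much of the sequence.  For complex sequences no single peak is
adequate, so the ten most prominent peaks are reported, and nearby peaks
are grouped into clusters whose summed amplitude may describe the rhythm
better than any single member.

The 0 Hz bin always dominates (it equals the number of onsets, the sum of
the train) and is excluded from peak reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq

from .exceptions import BinCollisionError, UgofError
from .ioi import BeatEstimate
from .onset_io import OnsetSequence

logger = logging.getLogger("ugof")

#: default binarization rate: 1 ms bins resolve beats up to 100 Hz with
#: at least 10 samples per period
DEFAULT_SAMPLE_RATE = 1000.0
#: default target frequency resolution of the transform (Hz), matching the
#: step of the ugof modeling grid
DEFAULT_FREQ_RESOLUTION = 0.01
#: default peak search band (Hz), mirroring the ugof modeling grid
DEFAULT_SEARCH_BAND = (0.1, 100.0)


@dataclass
class BeatSpectrum:
    """One-sided magnitude spectrum of a binarized onset train."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    sample_rate: float
    n_points: int
    n_samples: int = 0  # pre-padding train length; 0 = unknown
    parent_id: str = "sequence"

    @property
    def resolution(self) -> float:
        """Achieved frequency-bin width, Hz."""
        return self.sample_rate / self.n_points

    @property
    def intrinsic_resolution(self) -> float:
        """Rayleigh resolution of the *unpadded* train, Hz.

        Zero-padding interpolates the spectrum but cannot separate
        structures closer than 1/duration; two local maxima within this
        limit belong to one underlying spectral feature.
        """
        n = self.n_samples or self.n_points
        return self.sample_rate / n


@dataclass
class PeakSet:
    """The k most prominent spectral peaks, descending by amplitude."""

    peaks: list[tuple[float, float]]
    k: int
    search_band: tuple[float, float]
    parent_id: str = "sequence"

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for f, _ in self.peaks])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])


@dataclass
class PeakCluster:
    """A group of nearby peaks summarized by one frequency.

    ``summary_frequency`` is the amplitude-weighted mean of the member
    frequencies; ``summary_amplitude`` their amplitude sum.
    """

    members: list[tuple[float, float]]
    summary_frequency: float
    summary_amplitude: float

    def beat(self, parent_id: str = "sequence") -> BeatEstimate:
        return BeatEstimate(frequency=self.summary_frequency,
                            method="fourier_cluster",
                            amplitude=self.summary_amplitude,
                            parent_id=parent_id)


def binarize(seq: OnsetSequence,
             sample_rate: float = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Encode onsets as a 0/1 sample train at ``sample_rate``.

    The train spans first to last onset; sample index
    ``round((t - t0) * sample_rate)`` is set to 1 for each onset.  Two
    onsets falling into one bin is an error instructing a higher rate.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    t0 = seq.onsets[0]
    n = math.ceil((seq.onsets[-1] - t0) * sample_rate) + 1
    idx = np.round((seq.onsets - t0) * sample_rate).astype(int)
    idx = np.minimum(idx, n - 1)
    if np.unique(idx).size != idx.size:
        raise BinCollisionError(
            f"sequence {seq.id!r}: two onsets map to one bin at "
            f"{sample_rate} Hz; increase sample_rate")
    train = np.zeros(n, dtype=np.int8)
    train[idx] = 1
    return train


def beat_spectrum(
    train: np.ndarray,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    freq_resolution: float = DEFAULT_FREQ_RESOLUTION,
    parent_id: str = "sequence",
) -> BeatSpectrum:
    """Magnitude spectrum of a binary train, zero-padded to a target
    frequency resolution.

    The transform length is ``max(len(train), ceil(sample_rate /
    freq_resolution))`` so the achieved bin width ``sample_rate/n_points``
    never exceeds ``freq_resolution``.  Amplitudes are unnormalized
    transform magnitudes; the 0 Hz bin therefore equals the onset count.
    """
    train = np.asarray(train)
    if freq_resolution <= 0:
        raise ValueError("freq_resolution must be > 0")
    if train.sum() == 0:
        raise UgofError("beat_spectrum: train contains no onsets")
    n_points = max(train.size, math.ceil(sample_rate / freq_resolution))
    amp = np.abs(rfft(train.astype(float), n=n_points))
    freqs = rfftfreq(n_points, d=1.0 / sample_rate)
    return BeatSpectrum(frequencies=freqs, amplitudes=amp,
                        sample_rate=sample_rate, n_points=n_points,
                        n_samples=train.size, parent_id=parent_id)


def top_peaks(
    spec: BeatSpectrum,
    k: int = 10,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
    min_separation: float | str = "auto",
    noise_floor: float | str = "auto",
) -> PeakSet:
    """The ``k`` largest strict local maxima within ``search_band``.

    Returned descending by amplitude, ties broken toward lower frequency.
    Two suppression rules keep the set to genuinely prominent peaks:

    - candidates closer than ``min_separation`` (Hz) to an already
      accepted stronger peak are dropped; the default is the unpadded
      train's Rayleigh resolution, because zero-padding interpolates the
      spectrum and a single spectral feature would otherwise be reported
      as several ripple maxima;
    - candidates below ``noise_floor`` are dropped; the default is a
      robust fence over the in-band amplitudes (median + 3·scaled MAD),
      since timing jitter spreads a broadband noise pedestal whose local
      maxima are not rhythm peaks.

    Pass ``0`` for either to disable it.  The 0 Hz bin can never appear
    (it is not a local maximum candidate and the default band excludes
    it).  A spectrum with no qualifying maxima in the band — e.g. the
    flat spectrum of a single onset — yields an empty PeakSet with a
    warning.
    """
    f_lo, f_hi = search_band
    sep = (spec.intrinsic_resolution if min_separation == "auto"
           else float(min_separation))
    a = spec.amplitudes
    in_band = a[(spec.frequencies >= f_lo) & (spec.frequencies <= f_hi)]
    if noise_floor == "auto" and in_band.size:
        med = np.median(in_band)
        floor = float(med + 3 * 1.4826 * np.median(np.abs(in_band - med)))
    else:
        floor = 0.0 if noise_floor == "auto" else float(noise_floor)
    # strict local maxima over the full spectrum, then band-filter
    interior = np.flatnonzero((a[1:-1] > a[:-2]) & (a[1:-1] > a[2:])) + 1
    freqs = spec.frequencies[interior]
    mask = ((freqs >= f_lo) & (freqs <= f_hi)
            & (a[interior] > floor))
    cand_idx = interior[mask]
    if cand_idx.size == 0:
        logger.warning("WARN sequence %r: no spectral peaks in band "
                       "[%g, %g] Hz", spec.parent_id, f_lo, f_hi)
        return PeakSet(peaks=[], k=k, search_band=search_band,
                       parent_id=spec.parent_id)
    order = np.lexsort((spec.frequencies[cand_idx], -a[cand_idx]))
    kept: list[int] = []
    for i in cand_idx[order]:
        fi = spec.frequencies[i]
        if all(abs(fi - spec.frequencies[j]) >= sep for j in kept):
            kept.append(int(i))
        if len(kept) == k:
            break
    peaks = [(float(spec.frequencies[i]), float(a[i])) for i in kept]
    return PeakSet(peaks=peaks, k=k, search_band=search_band,
                   parent_id=spec.parent_id)


def cluster_peaks(peaks: PeakSet, bandwidth: float = 1.0) -> list[PeakCluster]:
    """Single-linkage grouping of peaks along the frequency axis.

    Two peaks belong to one cluster iff a chain of member-to-member
    frequency gaps, each <= ``bandwidth``, connects them.  Clusters are
    returned descending by summed amplitude; the summary frequency is the
    amplitude-weighted mean of the members.
    """
    if len(peaks) == 0:
        return []
    pts = sorted(peaks.peaks, key=lambda p: p[0])
    groups: list[list[tuple[float, float]]] = [[pts[0]]]
    for p in pts[1:]:
        if p[0] - groups[-1][-1][0] <= bandwidth:
            groups[-1].append(p)
        else:
            groups.append([p])
    clusters = []
    for g in groups:
        f = np.array([p[0] for p in g])
        a = np.array([p[1] for p in g])
        clusters.append(PeakCluster(
            members=g,
            summary_frequency=float(np.average(f, weights=a)),
            summary_amplitude=float(a.sum()),
        ))
    clusters.sort(key=lambda c: (-c.summary_amplitude, c.summary_frequency))
    return clusters


def select_beat_cluster(
    clusters: list[PeakCluster],
    rel_tol: float = 0.03,
    max_harmonic: int = 10,
    min_own_share: float = 0.2,
) -> PeakCluster | None:
    """Pick the cluster that best represents the underlying beat.

    A pulse train spreads its rhythm's energy across the harmonics of the
    beat frequency, so the heaviest cluster is often a harmonic (or a
    harmonic plus a noise companion) rather than the beat itself.  Each
    cluster is credited with the summed amplitude of every cluster lying
    within ``rel_tol`` of an integer multiple (up to ``max_harmonic``) of
    its summary frequency; the largest credited mass wins (ties toward
    lower frequency).  A candidate must itself carry at least
    ``min_own_share`` of the mass it claims, which rejects spurious
    subharmonics that merely collect other clusters' energy.  This is
    the spectral-peak analogue of harmonic-sum pitch disambiguation.
    """
    if not clusters:
        return None
    best: PeakCluster | None = None
    best_key = (-np.inf, np.inf)
    for c in clusters:
        f0 = c.summary_frequency
        mass = 0.0
        for d in clusters:
            m = round(d.summary_frequency / f0)
            if 1 <= m <= max_harmonic and \
                    abs(d.summary_frequency - m * f0) <= rel_tol * m * f0:
                mass += d.summary_amplitude
        if c.summary_amplitude < min_own_share * mass:
            continue
        key = (mass, -f0)
        if key > best_key:
            best, best_key = c, key
    return best


def fourier_beats(
    seq: OnsetSequence,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    freq_resolution: float = DEFAULT_FREQ_RESOLUTION,
    k: int = 10,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
    bandwidth: float = 1.0,
) -> tuple[BeatEstimate | None, BeatEstimate | None, PeakSet,
           list[PeakCluster]]:
    """Convenience pipeline: binarize → spectrum → peaks → clusters.

    Returns (top-peak beat, cluster beat, PeakSet, clusters); the cluster
    beat comes from :func:`select_beat_cluster` (harmonic disambiguation)
    and both beat estimates are ``None`` when no peak exists
    (single-onset sequences).
    """
    train = binarize(seq, sample_rate)
    spec = beat_spectrum(train, sample_rate, freq_resolution,
                         parent_id=seq.id)
    peaks = top_peaks(spec, k=k, search_band=search_band)
    clusters = cluster_peaks(peaks, bandwidth=bandwidth)
    peak_beat = None
    cluster_beat = None
    if len(peaks):
        f, a = peaks.peaks[0]
        peak_beat = BeatEstimate(frequency=f, method="fourier_peak",
                                 amplitude=a, parent_id=seq.id)
    chosen = select_beat_cluster(clusters)
    if chosen is not None:
        cluster_beat = chosen.beat(parent_id=seq.id)
    return peak_beat, cluster_beat, peaks, clusters
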