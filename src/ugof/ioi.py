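"""Interonset-interval (IOI) statistics and the IOI-based beat estimate.

The simplest description of a sequence's tempo is the reciprocal of its
average interonset interval: a sequence whose elements are on average
0.1 s apart is "beating" at 10 Hz.  This module computes IOI series, the
IOI beat frequency, and the two conventional IOI variability metrics
(coefficient of variation and the normalized pairwise variability index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError
from .onset_io import OnsetSequence


@dataclass
class IoiSeries:
    """Successive onset differences for one sequence, in seconds."""

    ioi: np.ndarray
    parent_id: str = "sequence"

    def __post_init__(self) -> None:
        self.ioi = np.asarray(self.ioi, dtype=float)
        if np.any(self.ioi <= 0):
            raise ValueError("all interonset intervals must be > 0")

    def __len__(self) -> int:
        return int(self.ioi.size)


@dataclass
class BeatEstimate:
    """A candidate beat frequency in Hz with its provenance.

    ``method`` is one of ``ioi``, ``fourier_peak``, ``fourier_cluster`` or
    ``user``; ``amplitude`` carries the spectral amplitude for the Fourier
    methods and is ``None`` otherwise.
    """

    frequency: float
    method: str
    amplitude: float | None = None
    parent_id: str = "sequence"

    _METHODS = frozenset({"ioi", "fourier_peak", "fourier_cluster", "user"})

    def __post_init__(self) -> None:
        if not (np.isfinite(self.frequency) and self.frequency > 0):
            raise ValueError(f"beat frequency must be finite and > 0, "
                             f"got {self.frequency}")
        if self.method not in self._METHODS:
            raise ValueError(f"unknown beat method {self.method!r}")


def compute_iois(seq: OnsetSequence) -> IoiSeries:
    """Successive differences of the onset times.

    Raises :class:`InsufficientDataError` for sequences of fewer than two
    onsets — a single event has no interval.
    """
    if len(seq) < 2:
        raise InsufficientDataError(
            f"sequence {seq.id!r}: need >= 2 onsets for IOIs, have {len(seq)}")
    return IoiSeries(ioi=np.diff(seq.onsets), parent_id=seq.id)


def ioi_beat(seq: OnsetSequence, use_median: bool = False) -> BeatEstimate:
    """Beat frequency as the reciprocal of the average IOI.

    The mean IOI defines the beat; ``use_median`` switches to the median
    as a robustness option (never the default).
    """
    series = compute_iois(seq)
    central = np.median(series.ioi) if use_median else np.mean(series.ioi)
    return BeatEstimate(frequency=1.0 / float(central), method="ioi",
                        parent_id=seq.id)


def variability_stats(series: IoiSeries) -> dict[str, float]:
    """Coefficient of variation and nPVI of an IOI series.

    cv = sd/mean with the sample (n-1) standard deviation.  The normalized
    pairwise variability index compares each interval with its successor:

        nPVI = 100/(m-1) * sum_k |d_k - d_{k+1}| / ((d_k + d_{k+1})/2)

    Both are dimensionless, nonnegative, and exactly 0 for perfect
    isochrony.  At least two intervals are required.
    """
    d = series.ioi
    if d.size < 2:
        raise InsufficientDataError(
            f"{series.parent_id!r}: need >= 2 intervals for cv/nPVI, "
            f"have {d.size}")
    cv = float(np.std(d, ddof=1) / np.mean(d))
    pair = np.abs(np.diff(d)) / ((d[:-1] + d[1:]) / 2.0)
    npvi = float(100.0 / (d.size - 1) * np.sum(pair))
    return {"cv": cv, "npvi": npvi}
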