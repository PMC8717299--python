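"""Synthetic onset-sequence generation with known ground truth.

The generator emulates the structure rhythm analysis assumes: a fixed
isochronous beat grid from which some beats carry no element ("silent
beats") and realized onsets deviate by small Gaussian jitter around their
grid position (deviations around a stable theoretical beat, not an
accumulating random walk).  Ground truth — the true frequency, the grid
origin, which beats were dropped, and segment boundaries for composite
sequences — is recorded in the sequence's ``meta`` dict so every other
module can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .onset_io import OnsetSequence


@dataclass
class RhythmSpec:
    """Parameters of one jittered isochronous train.

    frequency : Hz of the underlying beat grid.
    n_beats : number of grid positions (>= 1).
    jitter_sd : Gaussian sd (seconds) of each onset around its grid
        position; 0 gives exact grid membership.
    silent_prob : probability a beat carries no element; the first beat is
        never silent so the anchor convention stays well defined.
    seed : random-generator seed; identical spec + seed reproduce the
        sequence exactly.
    """

    frequency: float
    n_beats: int
    jitter_sd: float = 0.0
    silent_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.silent_prob < 1.0:
            raise ValueError("silent_prob must be in [0, 1)")


def _realize(spec: RhythmSpec, rng: np.random.Generator
             ) -> tuple[np.ndarray, int]:
    """Draw onsets (possibly negative before shifting) and silent count."""
    grid = np.arange(spec.n_beats) / spec.frequency
    keep = rng.random(spec.n_beats) >= spec.silent_prob
    keep[0] = True  # anchor beat always realized
    onsets = grid[keep]
    if spec.jitter_sd > 0:
        onsets = onsets + rng.normal(0.0, spec.jitter_sd, onsets.size)
        onsets = np.sort(onsets)
    return onsets, int(spec.n_beats - keep.sum())


def generate_isochronous(spec: RhythmSpec,
                         id: str = "synthetic") -> OnsetSequence:
    """One jittered isochronous train with silent beats.

    Onsets are the surviving beats of the grid ``k/frequency`` perturbed
    by Gaussian jitter and re-sorted.  If jitter pushes the earliest onset
    negative, the whole train is translated to start at 0 (every statistic
    here is translation invariant); the translated grid origin is recorded
    in ``meta["grid_origin"]``.
    """
    rng = np.random.default_rng(spec.seed)
    onsets, n_silent = _realize(spec, rng)
    shift = -min(float(onsets[0]), 0.0)
    meta = {
        "true_frequency": spec.frequency,
        "grid_origin": shift,
        "n_beats": spec.n_beats,
        "n_silent": n_silent,
        "jitter_sd": spec.jitter_sd,
        "silent_prob": spec.silent_prob,
        "seed": spec.seed,
    }
    return OnsetSequence.from_times(onsets + shift, id=id,
                                    source="synthetic", meta=meta)


def generate_composite(
    specs: list[RhythmSpec],
    gap: float = 0.5,
    id: str = "composite",
    seed: int | None = None,
) -> OnsetSequence:
    """Concatenate several rhythm regimes into one sequence.

    Each segment is generated independently and offset so that its first
    onset follows the previous segment's last onset by ``gap`` seconds.
    ``meta`` records per-segment ground truth:

    - ``boundaries``: IOI indices of the gap intervals separating regimes
      (a detected break adjacent to such an index recovers the boundary);
    - ``segments``: per-regime true frequency, grid origin on the global
      time axis, and the slice of onset indices it occupies.

    Segments whose spec carries no seed draw child seeds from ``seed``.
    """
    if not specs:
        raise ValueError("generate_composite: empty spec list")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    children = np.random.SeedSequence(seed).spawn(len(specs))
    all_onsets: list[np.ndarray] = []
    segments = []
    boundaries: list[int] = []
    t = 0.0
    count = 0
    for spec, child in zip(specs, children):
        rng = (np.random.default_rng(spec.seed) if spec.seed is not None
               else np.random.default_rng(child))
        onsets, n_silent = _realize(spec, rng)
        offset = t - onsets[0]
        placed = onsets + offset
        if count > 0:
            boundaries.append(count - 1)
        segments.append({
            "true_frequency": spec.frequency,
            "grid_origin": float(offset),
            "onset_slice": [count, count + onsets.size],
            "n_silent": n_silent,
        })
        all_onsets.append(placed)
        count += onsets.size
        t = float(placed[-1]) + gap
    meta = {"boundaries": boundaries, "segments": segments, "gap": gap,
            "seed": seed}
    return OnsetSequence.from_times(np.concatenate(all_onsets), id=id,
                                    source="synthetic", meta=meta)
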