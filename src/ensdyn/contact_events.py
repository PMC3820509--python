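"""Contact formation/breaking event detection and trajectory segmentation.

A residue pair's contact state follows a dual-cutoff (hysteretic) rule:
the contact forms when the side-chain distance drops below the 6.5 Å
on-cutoff and breaks when it rises above the 7.5 Å off-cutoff; between the
two the previous state persists, suppressing boundary chatter.  Each
pair's boolean state series is median-filtered (half-width expressed in
frames; 14 ns at 20 ps sampling is 700 frames), transitions of the
filtered series are counted per frame, and a Gaussian kernel turns the
counts into a smooth activity curve whose peaks mark conformational
transitions; the inter-peak basins are the trajectory segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks

from .core_fit import SuperposedEnsemble
from .ensemble_io import CoordinateEnsemble

__all__ = [
    "ContactStateSeries",
    "EventSeries",
    "pair_distance_series",
    "hysteretic_contacts",
    "event_activity",
    "segment_by_activity",
]


@dataclass
class ContactStateSeries:
    """Boolean contact state per pair per frame, with the two cutoffs."""

    states: np.ndarray                    # (F, P) bool
    pairs: list[tuple[int, int]]
    on_cutoff: float = 6.5
    off_cutoff: float = 7.5
    dt: float | None = None               # ns per frame

    def __post_init__(self) -> None:
        if self.on_cutoff >= self.off_cutoff:
            raise ValueError("on-cutoff must be below off-cutoff")
        if self.states.shape[1] != len(self.pairs):
            raise ValueError("one pair per state column required")


@dataclass
class EventSeries:
    formation: np.ndarray     # (F,) counts
    breaking: np.ndarray
    total: np.ndarray         # formation + breaking
    activity: np.ndarray      # Gaussian-smoothed total
    half_width: int           # frames
    segments: list[tuple[int, int]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["frame\tformation\tbreaking\ttotal\tactivity"]
        for f in range(len(self.total)):
            lines.append(f"{f}\t{self.formation[f]}\t{self.breaking[f]}"
                         f"\t{self.total[f]}\t{self.activity[f]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def pair_distance_series(
    ensemble: CoordinateEnsemble | SuperposedEnsemble,
    pairs: list[tuple[int, int]] | None = None,
    min_separation: int = 2,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Representative side-chain distance per pair per frame.

    Distance is the minimum over side-chain heavy-atom layers (the Cβ
    layer where present, Cα as the glycine fallback).  Defaults to all
    pairs at sequence separation ≥ ``min_separation``.
    """
    atom_frames = ensemble.atom_frames
    ca = atom_frames["CA"]
    F, N = ca.shape[:2]
    sidechain = [v for k, v in sorted(atom_frames.items()) if k != "CA"]
    if pairs is None:
        pairs = [(i, j) for i, j in combinations(range(N), 2)
                 if j - i >= min_separation]
    dists = np.full((F, len(pairs)), np.inf)
    layers = sidechain or [ca]
    for A in layers:
        for B in layers:
            for p, (i, j) in enumerate(pairs):
                d = np.linalg.norm(A[:, i] - B[:, j], axis=1)
                np.fmin(dists[:, p], d, out=dists[:, p])
    # glycine (NaN side chain) fallback to Cα on both ends
    for p, (i, j) in enumerate(pairs):
        bad = ~np.isfinite(dists[:, p])
        if bad.any():
            dists[bad, p] = np.linalg.norm(ca[bad, i] - ca[bad, j], axis=1)
    return dists, pairs


def hysteretic_contacts(
    distances: np.ndarray,
    pairs: list[tuple[int, int]],
    on: float = 6.5,
    off: float = 7.5,
    mode: str = "hysteresis",
    dt: float | None = None,
) -> ContactStateSeries:
    """Dual-cutoff contact states from per-pair distance series.

    ``mode="hysteresis"`` (default): a pair forms when its distance drops
    below ``on`` and breaks when it exceeds ``off``; inside the band the
    previous state persists.  The initial state is taken from the first
    frame against the band midpoint.  ``mode="band"``: in contact iff the
    distance lies inside [on, off] — the literal distance-band reading,
    kept behind this flag.
    """
    if on >= off:
        raise ValueError("on-cutoff must be below off-cutoff")
    d = np.asarray(distances, dtype=float)
    if mode == "band":
        states = (d >= on) & (d <= off)
        return ContactStateSeries(states=states, pairs=pairs,
                                  on_cutoff=on, off_cutoff=off, dt=dt)
    if mode != "hysteresis":
        raise ValueError(f"unknown mode {mode!r}")
    F, P = d.shape
    states = np.zeros((F, P), dtype=bool)
    state = d[0] <= 0.5 * (on + off)
    for f in range(F):
        state = np.where(d[f] < on, True,
                         np.where(d[f] > off, False, state))
        states[f] = state
    return ContactStateSeries(states=states, pairs=pairs,
                              on_cutoff=on, off_cutoff=off, dt=dt)


def event_activity(
    states: ContactStateSeries,
    half_width: int,
    kernel_sigma: float | None = None,
) -> EventSeries:
    """Median-filter the state series and count transitions per frame.

    ``half_width`` is in frames; the median window is 2·half_width + 1, so
    any flicker shorter than the half-width is removed.  The activity
    curve is the Gaussian-smoothed total event count (default bandwidth:
    half the median-filter half-width).
    """
    F = states.states.shape[0]
    if half_width >= F:
        raise ValueError(
            f"half-width {half_width} ≥ trajectory length {F}")
    if kernel_sigma is None:
        kernel_sigma = max(half_width / 2.0, 1.0)
    filt = median_filter(
        states.states.astype(np.int8),
        size=(2 * half_width + 1, 1),
        mode="nearest",
    ).astype(bool)
    diff = np.diff(filt.astype(np.int8), axis=0)
    formation = np.zeros(F, dtype=int)
    breaking = np.zeros(F, dtype=int)
    formation[1:] = (diff > 0).sum(axis=1)
    breaking[1:] = (diff < 0).sum(axis=1)
    total = formation + breaking
    activity = gaussian_filter1d(total.astype(float), sigma=kernel_sigma,
                                 mode="nearest")
    return EventSeries(formation=formation, breaking=breaking, total=total,
                       activity=activity, half_width=half_width)


def segment_by_activity(events: EventSeries,
                        prominence: float = 0.3) -> list[tuple[int, int]]:
    """Cut the trajectory at activity-curve peaks into inter-peak basins.

    ``prominence`` is relative to the activity-curve maximum, so peaks must
    rise by at least that fraction of the largest burst — transitions stand
    out against the noise-floor event rate regardless of trajectory size.
    With no qualifying peaks (or a flat curve) the whole trajectory is one
    segment.  Segments are (start, end) inclusive frame ranges tiling the
    trajectory without overlap and are also stored on ``events``.
    """
    F = len(events.activity)
    peak_height = float(events.activity.max())
    if peak_height <= 0:
        events.segments = [(0, F - 1)]
        return events.segments
    peaks, _ = find_peaks(events.activity,
                          prominence=prominence * peak_height)
    bounds = [0] + [int(p) for p in peaks] + [F]
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            segments.append((a, b - 1))
    if not segments:
        segments = [(0, F - 1)]
    events.segments = segments
    return segments
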