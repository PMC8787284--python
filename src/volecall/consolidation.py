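"""Consolidating vocal segments into vocalizations.

Rodent pup calls are often emitted as bursts of segments separated by
very short silences, while successive calls are separated by much longer
ones, so the distribution of inter-segment intervals is bimodal.  The
consolidation threshold is derived from the data: build a histogram of
the silent intervals between successive segments, smooth it with a
5-point median filter, and take the first local minimum — the trough
between the within-call and between-call modes.  Segments separated by
no more than that threshold are merged into a single vocalization, with
their contours left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .segmentation import FrequencyContour, VocalSegment

__all__ = [
    "IntervalHistogram",
    "Vocalization",
    "NoTroughError",
    "interval_histogram",
    "smooth_histogram",
    "first_local_minimum",
    "consolidate",
    "vocalizations_table",
]


class NoTroughError(ValueError):
    """The smoothed interval histogram has no interior local minimum."""


@dataclass
class IntervalHistogram:
    """Histogram of silent intervals between successive segments (ms)."""

    bin_edges: np.ndarray            # contiguous from 0, ms
    counts: np.ndarray
    bin_width: float                 # ms
    smoothed_counts: np.ndarray | None = None


@dataclass
class Vocalization:
    """A gap-consolidated group of vocal segments, treated as one call."""

    segments: list[VocalSegment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a vocalization needs at least one segment")

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def source_channel(self) -> str:
        return self.segments[0].source_channel

    @property
    def contour(self) -> FrequencyContour:
        """Concatenated contour; inter-segment gaps stay as time gaps."""
        c0 = self.segments[0].contour
        if len(self.segments) == 1:
            return c0
        width = max(s.contour.freqs.shape[1] for s in self.segments)

        def pad(a: np.ndarray) -> np.ndarray:
            if a.shape[1] == width:
                return a
            out = np.full((a.shape[0], width), np.nan)
            out[:, : a.shape[1]] = a
            return out

        return FrequencyContour(
            times=np.concatenate([s.contour.times for s in self.segments]),
            freqs=np.vstack([pad(s.contour.freqs) for s in self.segments]),
            amps=np.vstack([pad(s.contour.amps) for s in self.segments]),
            frame_step_ms=c0.frame_step_ms,
        )


def _gaps_ms(segments: list[VocalSegment]) -> np.ndarray:
    starts = np.array([s.start for s in segments])
    ends = np.array([s.end for s in segments])
    if np.any(np.diff(starts) < 0):
        raise ValueError("segments must be sorted by start time")
    return np.maximum(starts[1:] - ends[:-1], 0.0) * 1e3


def interval_histogram(
    segments: list[VocalSegment], bin_width_ms: float = 10.0
) -> IntervalHistogram:
    """Histogram of the time between all pairs of successive segments.

    Gaps are ``next.start - current.end`` in ms, clipped at zero; bins are
    contiguous from 0.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to form intervals")
    # round to sub-ns so float jitter cannot move a gap across a bin edge
    gaps = np.round(_gaps_ms(segments), 6)
    n_bins = max(int(np.ceil((gaps.max() + 1e-9) / bin_width_ms)), 1)
    edges = np.arange(n_bins + 1) * bin_width_ms
    counts, _ = np.histogram(gaps, bins=edges)
    return IntervalHistogram(bin_edges=edges, counts=counts, bin_width=bin_width_ms)


def smooth_histogram(hist: IntervalHistogram, order: int = 5) -> IntervalHistogram:
    """5-point running-median smoothing with edge replication."""
    if hist.counts.size < order:
        raise ValueError(f"need at least {order} bins to smooth")
    half = order // 2
    padded = np.pad(hist.counts.astype(float), half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, order)
    return replace(hist, smoothed_counts=np.median(windows, axis=1))


def first_local_minimum(
    hist: IntervalHistogram, fallback_ms: float | None = None
) -> float:
    """Consolidation threshold: right edge of the first interior trough bin.

    The trough is the lowest-index interior run of equal smoothed counts
    whose neighboring distinct values are both greater -- i.e. a genuine
    local minimum, with a plateau resolved to its first bin (a mere pause
    in a decline does not count).  Returning the bin's right edge makes
    the printed "<= threshold" merge rule inclusive of the trough bin.
    A monotone histogram has no trough; then ``fallback_ms`` is returned
    if given, else :class:`NoTroughError` is raised.
    """
    if hist.smoothed_counts is None:
        raise ValueError("smooth the histogram first")
    s = hist.smoothed_counts
    i = 1
    while i < s.size:
        j = i
        while j + 1 < s.size and s[j + 1] == s[i]:
            j += 1
        if s[i] < s[i - 1] and j + 1 < s.size and s[j + 1] > s[i]:
            return float(hist.bin_edges[i + 1])
        i = j + 1
    if fallback_ms is not None:
        return float(fallback_ms)
    raise NoTroughError("no interior local minimum in smoothed interval histogram")


def consolidate(
    segments: list[VocalSegment], threshold_ms: float
) -> list[Vocalization]:
    """Greedy left-to-right merge of segments separated by <= threshold.

    The rule is inclusive: a gap of exactly the threshold merges.
    Contours are unaltered; every segment ends up in exactly one
    vocalization.
    """
    if threshold_ms < 0:
        raise ValueError("threshold must be non-negative")
    if not segments:
        return []
    gaps = _gaps_ms(segments)
    vocs: list[Vocalization] = []
    group = [segments[0]]
    for seg, gap in zip(segments[1:], gaps):
        if gap <= threshold_ms + 1e-9:
            group.append(seg)
        else:
            vocs.append(Vocalization(segments=group))
            group = [seg]
    vocs.append(Vocalization(segments=group))
    return vocs


def vocalizations_table(
    vocs: list[Vocalization], threshold_ms: float | None = None
) -> pd.DataFrame:
    """Tabular summary, one row per vocalization."""
    df = pd.DataFrame(
        {
            "voc_id": np.arange(len(vocs)),
            "channel": [v.source_channel for v in vocs],
            "start_s": [v.start for v in vocs],
            "end_s": [v.end for v in vocs],
            "n_segments": [v.n_segments for v in vocs],
        }
    )
    if threshold_ms is not None:
        df["threshold_used_ms"] = threshold_ms
    return df
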