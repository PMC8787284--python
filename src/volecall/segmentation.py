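"""Grouping per-frame peaks into vocal segments.

A vocal segment is a continuous unit of sound: a run of spectrogram
frames carrying at least one tonal peak, whose lowest-frequency trace is
the fundamental contour.  Segments are cut wherever the fundamental makes
an instantaneous jump of more than 8 kHz or the sound is interrupted by
more than 4 ms of silence, and segments that are too short (< 6 frames,
i.e. < 3 ms of sound) or whose median fundamental lies below 22 kHz
(almost always cage noise) are discarded.

Frame convention: a frame at time ``t`` (its analysis-window center)
covers ``[t - step/2, t + step/2)``, so a segment of ``n`` contiguous
frames has duration ``n * step`` and the silence between sounding frames
at ``t0`` and ``t1`` lasts ``t1 - t0 - step``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import FRAME_STEP_MS, SpectralFrames

__all__ = [
    "FrequencyContour",
    "VocalSegment",
    "frames_to_segments",
    "split_on_discontinuity",
    "apply_exclusions",
    "segments_table",
]

MAX_JUMP_KHZ = 8.0
MAX_GAP_MS = 4.0
MIN_FRAMES = 6
MIN_MEDIAN_FUNDAMENTAL_KHZ = 22.0


@dataclass
class FrequencyContour:
    """Per-frame tone stack of a segment (or vocalization).

    ``times`` holds the sounding frames only; internal silences show up as
    gaps larger than one frame step.  ``freqs``/``amps`` have shape
    ``(n_frames, max_traces)``, NaN-padded, each row sorted ascending by
    frequency: column 0 is the fundamental, columns 1+ are simultaneous
    higher traces.
    """

    times: np.ndarray        # seconds
    freqs: np.ndarray        # kHz
    amps: np.ndarray
    frame_step_ms: float = FRAME_STEP_MS

    def __post_init__(self) -> None:
        if self.freqs.shape != self.amps.shape or self.freqs.shape[0] != self.times.size:
            raise ValueError("contour array shapes disagree")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def fundamental(self) -> np.ndarray:
        """Lowest frequency present at each frame, kHz."""
        return self.freqs[:, 0]

    @property
    def fundamental_amplitude(self) -> np.ndarray:
        return self.amps[:, 0]

    def gaps_ms(self) -> np.ndarray:
        """Silent time between consecutive sounding frames, ms (>= 0)."""
        if self.times.size < 2:
            return np.zeros(0)
        return np.diff(self.times) * 1e3 - self.frame_step_ms

    def slice(self, lo: int, hi: int) -> "FrequencyContour":
        return FrequencyContour(
            times=self.times[lo:hi],
            freqs=self.freqs[lo:hi],
            amps=self.amps[lo:hi],
            frame_step_ms=self.frame_step_ms,
        )


@dataclass
class VocalSegment:
    """A continuous unit of sound with its frequency contour."""

    contour: FrequencyContour
    source_channel: str = "ch0"

    @property
    def start(self) -> float:
        """Onset in seconds (leading edge of the first sounding frame)."""
        return float(self.contour.times[0]) - self.contour.frame_step_ms / 2e3

    @property
    def end(self) -> float:
        """Offset in seconds (trailing edge of the last sounding frame)."""
        return float(self.contour.times[-1]) + self.contour.frame_step_ms / 2e3

    @property
    def n_frames(self) -> int:
        return self.contour.n_frames

    @property
    def median_fundamental(self) -> float:
        return float(np.median(self.contour.fundamental))


def frames_to_segments(
    frames: SpectralFrames,
    join_gap_ms: float = MAX_GAP_MS,
    channel: str | None = None,
) -> list[VocalSegment]:
    """Collect runs of sounding frames into raw vocal segments.

    Sounding frames separated by silence of at most ``join_gap_ms`` stay
    in one segment (the silent frames are simply absent from the contour);
    longer silences start a new segment.  The default matches the 4-ms
    splitting rule, so :func:`split_on_discontinuity` only has jump cuts
    left to make.
    """
    if frames.peak_freqs is None:
        raise ValueError("run detect_peaks before frames_to_segments")
    sounding = np.nonzero(frames.has_peak())[0]
    if sounding.size == 0:
        return []
    t = frames.frame_times[sounding]
    step_ms = frames.frame_step_ms
    # Break where silent time between consecutive sounding frames > join gap.
    silent_ms = np.diff(t) * 1e3 - step_ms
    breaks = np.nonzero(silent_ms > join_gap_ms + 1e-9)[0] + 1
    segments = []
    for chunk in np.split(sounding, breaks):
        contour = FrequencyContour(
            times=frames.frame_times[chunk],
            freqs=frames.peak_freqs[chunk],
            amps=frames.peak_amps[chunk],
            frame_step_ms=step_ms,
        )
        segments.append(VocalSegment(contour=contour, source_channel=channel or "ch0"))
    return segments


def split_on_discontinuity(
    segment: VocalSegment,
    max_jump_khz: float = MAX_JUMP_KHZ,
    max_gap_ms: float = MAX_GAP_MS,
) -> list[VocalSegment]:
    """Cut a segment at fundamental jumps > ``max_jump_khz`` and silences
    > ``max_gap_ms``.

    Both rules are strict ("exceeding"): a jump of exactly 8 kHz or a
    silence of exactly 4 ms does not split.  Jumps are evaluated on the
    fundamental trace only; contour values are never altered.
    """
    c = segment.contour
    if c.n_frames < 2:
        return [segment]
    jumps = np.abs(np.diff(c.fundamental))
    gaps = c.gaps_ms()
    cut = (jumps > max_jump_khz + 1e-9) | (gaps > max_gap_ms + 1e-9)
    if not cut.any():
        return [segment]
    bounds = np.concatenate(([0], np.nonzero(cut)[0] + 1, [c.n_frames]))
    return [
        VocalSegment(contour=c.slice(lo, hi), source_channel=segment.source_channel)
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]


def apply_exclusions(
    segments: list[VocalSegment],
    min_frames: int = MIN_FRAMES,
    min_median_fundamental_khz: float = MIN_MEDIAN_FUNDAMENTAL_KHZ,
) -> list[VocalSegment]:
    """Drop segments shorter than ``min_frames`` sounding frames or with a
    median fundamental strictly below ``min_median_fundamental_khz``.

    Six 0.5-ms frames correspond to 3 ms of sound; sub-22-kHz medians are
    overwhelmingly non-vocal noise.  Order is preserved.
    """
    return [
        s
        for s in segments
        if s.n_frames >= min_frames
        and s.median_fundamental >= min_median_fundamental_khz
    ]


def segments_table(segments: list[VocalSegment]) -> pd.DataFrame:
    """Tabular summary, one row per segment."""
    return pd.DataFrame(
        {
            "segment_id": np.arange(len(segments)),
            "channel": [s.source_channel for s in segments],
            "start_s": [s.start for s in segments],
            "end_s": [s.end for s in segments],
            "n_frames": [s.n_frames for s in segments],
            "median_fundamental_khz": [s.median_fundamental for s in segments],
        }
    )
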