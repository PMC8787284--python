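"""End-to-end orchestration: audio in, vocalization library out."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from . import consolidation, detection, segmentation
from .consolidation import NoTroughError, Vocalization
from .detection import AudioClip
from .segmentation import VocalSegment

__all__ = ["PipelineConfig", "extract_segments", "extract_vocalizations"]


@dataclass
class PipelineConfig:
    """All tunable knobs of the audio pipeline, YAML-round-trippable.

    Defaults implement the standard analysis: 15-125 kHz band, 0.5-ms
    frames, up to 7 peaks, 8-kHz jump and 4-ms gap splitting, 6-frame /
    22-kHz exclusions, and a data-derived consolidation threshold from a
    10-ms interval histogram (overridable with a fixed value).
    """

    bandpass_low_khz: float = 15.0
    bandpass_high_khz: float = 125.0
    frame_step_ms: float = 0.5
    threshold_z: float = 5.0
    peak_relative_floor_db: float = -25.0
    max_peaks: int = 7
    max_jump_khz: float = 8.0
    max_gap_ms: float = 4.0
    min_frames: int = 6
    min_median_fundamental_khz: float = 22.0
    bin_width_ms: float = 10.0
    consolidation_threshold_ms: float | None = None
    fallback_threshold_ms: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def extract_segments(
    clip: AudioClip, config: PipelineConfig | None = None
) -> list[VocalSegment]:
    """Band-pass, spectrogram, flatten, peak-pick, segment, split, exclude."""
    cfg = config or PipelineConfig()
    clip = detection.bandpass(clip, cfg.bandpass_low_khz, cfg.bandpass_high_khz)
    frames = detection.compute_spectrogram(
        clip,
        frame_step_ms=cfg.frame_step_ms,
        band=(cfg.bandpass_low_khz, cfg.bandpass_high_khz),
    )
    frames = detection.flatten_spectrum(frames)
    frames = detection.detect_peaks(
        frames, cfg.threshold_z, cfg.max_peaks, cfg.peak_relative_floor_db
    )
    raw = segmentation.frames_to_segments(
        frames, join_gap_ms=cfg.max_gap_ms, channel=clip.channel_id
    )
    split = [
        piece
        for seg in raw
        for piece in segmentation.split_on_discontinuity(
            seg, cfg.max_jump_khz, cfg.max_gap_ms
        )
    ]
    return segmentation.apply_exclusions(
        split, cfg.min_frames, cfg.min_median_fundamental_khz
    )


def extract_vocalizations(
    clip: AudioClip, config: PipelineConfig | None = None
) -> tuple[list[Vocalization], float, list[VocalSegment]]:
    """Full chain to a vocalization library.

    The consolidation threshold is taken from the config override when
    set, otherwise derived from the segment library's interval histogram
    (first local minimum of the smoothed histogram).  Returns
    ``(vocalizations, threshold_ms, segments)``.
    """
    cfg = config or PipelineConfig()
    segments = extract_segments(clip, cfg)
    if not segments:
        return [], float(cfg.consolidation_threshold_ms or 0.0), []
    threshold = cfg.consolidation_threshold_ms
    if threshold is None:
        if len(segments) < 2:
            threshold = cfg.fallback_threshold_ms or 0.0
        else:
            hist = consolidation.interval_histogram(segments, cfg.bin_width_ms)
            try:
                hist = consolidation.smooth_histogram(hist)
                threshold = consolidation.first_local_minimum(
                    hist, fallback_ms=cfg.fallback_threshold_ms
                )
            except (NoTroughError, ValueError):
                if cfg.fallback_threshold_ms is None:
                    raise
                threshold = cfg.fallback_threshold_ms
    vocs = consolidation.consolidate(segments, threshold)
    return vocs, float(threshold), segments
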