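"""Two-microphone source attribution.

When a pup and its mother are recorded in adjacent chambers, each with
its own microphone, loud calls bleed onto the far microphone.  Sounds
detected simultaneously on both channels are matched by temporal overlap
and attributed to the chamber on which the sound amplitude is greatest;
sounds detected on a single channel are attributed to that channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import VocalSegment

__all__ = [
    "AttributionRecord",
    "match_simultaneous",
    "attribute_side",
    "attribute_all",
]

MIN_OVERLAP_MS = 2.0


@dataclass
class AttributionRecord:
    """Outcome of side attribution for one (matched or singleton) sound."""

    segment_a: VocalSegment | None
    segment_b: VocalSegment | None
    amp_a: float
    amp_b: float
    assigned_side: str
    overlap_ms: float


def _overlap_ms(a: VocalSegment, b: VocalSegment) -> float:
    return max(0.0, (min(a.end, b.end) - max(a.start, b.start)) * 1e3)


def match_simultaneous(
    segments_a: list[VocalSegment],
    segments_b: list[VocalSegment],
    min_overlap_ms: float = MIN_OVERLAP_MS,
) -> tuple[list[tuple[VocalSegment, VocalSegment]], list[VocalSegment], list[VocalSegment]]:
    """Pair cross-channel segments that overlap in time.

    Candidate pairs with overlap >= ``min_overlap_ms`` are matched
    greedily by decreasing overlap, each segment at most once.  Returns
    ``(pairs, unmatched_a, unmatched_b)``.
    """
    candidates = []
    for i, a in enumerate(segments_a):
        for j, b in enumerate(segments_b):
            if b.start >= a.end:
                break  # segments_b is time-sorted; later ones cannot overlap
            ov = _overlap_ms(a, b)
            if ov >= min_overlap_ms:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((segments_a[i], segments_b[j]))
    singles_a = [s for i, s in enumerate(segments_a) if i not in used_a]
    singles_b = [s for j, s in enumerate(segments_b) if j not in used_b]
    return pairs, singles_a, singles_b


def _mean_amp_in_window(seg: VocalSegment, t0: float, t1: float) -> float:
    """Mean fundamental peak amplitude over frames inside [t0, t1]."""
    c = seg.contour
    mask = (c.times >= t0 - 1e-9) & (c.times <= t1 + 1e-9)
    if not mask.any():
        return 0.0
    return float(np.mean(c.fundamental_amplitude[mask]))


def attribute_side(
    pair: tuple[VocalSegment, VocalSegment],
    side_a: str = "pup",
    side_b: str = "mother",
    tie_side: str | None = None,
) -> AttributionRecord:
    """Attribute a matched pair to the louder channel.

    The amplitude statistic is the mean per-frame fundamental peak
    amplitude over the overlap window.  An exact tie goes to ``tie_side``
    (default: ``side_a``, conventionally the pup channel).
    """
    a, b = pair
    t0, t1 = max(a.start, b.start), min(a.end, b.end)
    amp_a = _mean_amp_in_window(a, t0, t1)
    amp_b = _mean_amp_in_window(b, t0, t1)
    if amp_a > amp_b:
        side = side_a
    elif amp_b > amp_a:
        side = side_b
    else:
        side = tie_side if tie_side is not None else side_a
    return AttributionRecord(
        segment_a=a,
        segment_b=b,
        amp_a=amp_a,
        amp_b=amp_b,
        assigned_side=side,
        overlap_ms=_overlap_ms(a, b),
    )


def attribute_all(
    segments_a: list[VocalSegment],
    segments_b: list[VocalSegment],
    side_a: str = "pup",
    side_b: str = "mother",
    min_overlap_ms: float = MIN_OVERLAP_MS,
) -> list[AttributionRecord]:
    """Match both channels and attribute every sound to a side.

    Singletons are attributed to their own channel with the other
    channel's amplitude recorded as 0.
    """
    pairs, singles_a, singles_b = match_simultaneous(
        segments_a, segments_b, min_overlap_ms
    )
    records = [attribute_side(p, side_a=side_a, side_b=side_b) for p in pairs]
    for s in singles_a:
        amp = _mean_amp_in_window(s, s.start, s.end)
        records.append(AttributionRecord(s, None, amp, 0.0, side_a, 0.0))
    for s in singles_b:
        amp = _mean_amp_in_window(s, s.start, s.end)
        records.append(AttributionRecord(None, s, 0.0, amp, side_b, 0.0))
    records.sort(
        key=lambda r: (r.segment_a or r.segment_b).start
    )
    return records


def attribution_table(records: list[AttributionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "voc_id": np.arange(len(records)),
            "side": [r.assigned_side for r in records],
            "amp_a": [r.amp_a for r in records],
            "amp_b": [r.amp_b for r in records],
            "overlap_ms": [r.overlap_ms for r in records],
        }
    )
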