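"""Per-vocalization acoustic features and per-animal summaries.

All features are computed on the fundamental contour: duration (end
minus start), median / high / low frequency, bandwidth (high minus low),
slope (the average time-derivative of the fundamental where the contour
exists), the modal number of harmonics, and the number of component
segments.  Per-animal summaries average each feature over all
vocalizations a pup emitted in a recording phase, so that cohort
statistics weight animals, not calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consolidation import Vocalization

__all__ = [
    "FeatureSet",
    "AnimalSummary",
    "compute_features",
    "count_harmonics",
    "per_minute_counts",
    "summarize_animal",
    "feature_variance",
    "features_table",
]

#: Half-width of the ratio window around each integer harmonic multiple.
HARMONIC_RATIO_HALFWIDTH = 0.2

#: Harmonic runs shorter than this are discarded as spurious, ms.
MIN_HARMONIC_RUN_MS = 3.0

FEATURE_COLUMNS = [
    "duration_ms",
    "median_khz",
    "low_khz",
    "high_khz",
    "bandwidth_khz",
    "slope_khz_per_ms",
    "mode_harmonics",
    "n_segments",
]


@dataclass(frozen=True)
class FeatureSet:
    """Acoustic descriptors of one vocalization."""

    duration_ms: float
    median_khz: float
    high_khz: float
    low_khz: float
    bandwidth_khz: float
    slope_khz_per_ms: float
    mode_harmonics: int
    n_segments: int


@dataclass
class AnimalSummary:
    """One pup's per-recording-phase summary row for the statistics layer."""

    pup_id: str
    age: int
    sex: str
    context: str
    total_count: int
    feature_means: dict
    feature_variances: dict
    per_minute_counts: np.ndarray


def compute_features(voc: Vocalization, signed_slope: bool = True) -> FeatureSet:
    """Compute the full feature set of one vocalization.

    Slope averages the per-frame derivative of the fundamental within
    segments; silent gaps between segments carry no derivative and are
    excluded.  ``signed_slope=False`` averages the absolute derivative
    instead (the overall frequency-modulation rate regardless of
    direction).
    """
    contour = voc.contour
    fund = contour.fundamental
    if fund.size == 0 or np.all(np.isnan(fund)):
        raise ValueError("vocalization has an empty fundamental contour")
    duration_ms = (voc.end - voc.start) * 1e3
    low = float(np.min(fund))
    high = float(np.max(fund))
    slopes: list[np.ndarray] = []
    for seg in voc.segments:
        c = seg.contour
        if c.n_frames < 2:
            continue
        d = np.diff(c.fundamental) / (np.diff(c.times) * 1e3)
        slopes.append(np.abs(d) if not signed_slope else d)
    slope = float(np.mean(np.concatenate(slopes))) if slopes else 0.0
    return FeatureSet(
        duration_ms=duration_ms,
        median_khz=float(np.median(fund)),
        high_khz=high,
        low_khz=low,
        bandwidth_khz=high - low,
        slope_khz_per_ms=slope,
        mode_harmonics=count_harmonics(voc),
        n_segments=voc.n_segments,
    )


def count_harmonics(
    voc: Vocalization,
    ratio_halfwidth: float = HARMONIC_RATIO_HALFWIDTH,
    min_run_ms: float = MIN_HARMONIC_RUN_MS,
) -> int:
    """Modal number of harmonics across the vocalization's frames.

    A higher trace at a frame counts as harmonic ``k`` (k >= 2) when its
    ratio to that frame's fundamental falls in ``[k - 0.2, k + 0.2]``.
    For each ``k``, contiguous runs of harmonic frames shorter than
    ``min_run_ms`` are discarded; the per-frame count of surviving
    harmonics is then reduced to its mode over all frames, ties resolved
    toward the lower count.
    """
    contour = voc.contour
    n = contour.n_frames
    if n == 0:
        return 0
    fund = contour.fundamental
    higher = contour.freqs[:, 1:]
    if higher.size == 0:
        return 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = higher / fund[:, None]
    k_max = int(np.floor(np.nanmax(ratios) + ratio_halfwidth)) if np.any(
        np.isfinite(ratios)
    ) else 1
    step_ms = contour.frame_step_ms
    # Frames are contiguous when separated by exactly one step (gaps break runs).
    contiguous = (
        np.abs(np.diff(contour.times) * 1e3 - step_ms) < step_ms / 4
        if n > 1
        else np.zeros(0, dtype=bool)
    )
    min_run_frames = int(np.ceil(min_run_ms / step_ms))
    per_frame = np.zeros(n, dtype=int)
    for k in range(2, max(k_max, 1) + 1):
        flag = np.any(np.abs(ratios - k) <= ratio_halfwidth + 1e-12, axis=1)
        per_frame += _filter_short_runs(flag, contiguous, min_run_frames)
    counts = np.bincount(per_frame)
    return int(np.flatnonzero(counts == counts.max())[0])  # tie -> lower count


def _filter_short_runs(
    flag: np.ndarray, contiguous: np.ndarray, min_frames: int
) -> np.ndarray:
    """Zero out runs of True shorter than ``min_frames``; time gaps break runs."""
    out = flag.copy()
    i = 0
    n = flag.size
    while i < n:
        if not flag[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flag[j + 1] and contiguous[j]:
            j += 1
        if j - i + 1 < min_frames:
            out[i : j + 1] = False
        i = j + 1
    return out


def per_minute_counts(
    vocs: list[Vocalization], session_length_s: float, bin_s: float = 60.0
) -> np.ndarray:
    """Vocalizations per time bin, assigned by onset, half-open bins."""
    n_bins = max(int(np.ceil(session_length_s / bin_s)), 1)
    counts = np.zeros(n_bins, dtype=int)
    for v in vocs:
        idx = min(int(v.start // bin_s), n_bins - 1)
        counts[idx] += 1
    return counts


def feature_variance(values) -> float:
    """Sample variance with the n - 1 denominator."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("variance needs at least 2 vocalizations")
    return float(np.var(values, ddof=1))


def features_table(vocs: list[Vocalization], **metadata) -> pd.DataFrame:
    """Per-vocalization feature table; ``metadata`` adds constant columns
    (pup_id, age, sex, context, ...)."""
    rows = []
    for i, v in enumerate(vocs):
        fs = compute_features(v)
        rows.append(
            dict(
                voc_id=i,
                start_s=v.start,
                end_s=v.end,
                duration_ms=fs.duration_ms,
                median_khz=fs.median_khz,
                low_khz=fs.low_khz,
                high_khz=fs.high_khz,
                bandwidth_khz=fs.bandwidth_khz,
                slope_khz_per_ms=fs.slope_khz_per_ms,
                mode_harmonics=fs.mode_harmonics,
                n_segments=fs.n_segments,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["voc_id", "start_s", "end_s", *FEATURE_COLUMNS],
    )
    for key, val in metadata.items():
        df[key] = val
    return df


def summarize_animal(
    features: pd.DataFrame,
    pup_id: str,
    age: int,
    sex: str,
    context: str = "isolation",
    session_length_s: float = 600.0,
    phase_start_s: float = 0.0,
) -> AnimalSummary:
    """Collapse one pup's per-vocalization features to a summary row.

    ``features`` is a :func:`features_table` frame for a single pup;
    vocalizations are assigned to the phase by onset within the half-open
    window ``[phase_start_s, phase_start_s + session_length_s)``.  A pup
    with zero vocalizations keeps count 0 with feature means/variances
    flagged missing (NaN).
    """
    in_phase = features[
        (features["start_s"] >= phase_start_s)
        & (features["start_s"] < phase_start_s + session_length_s)
    ]
    total = len(in_phase)
    means = {}
    variances = {}
    for col in FEATURE_COLUMNS:
        vals = in_phase[col].to_numpy(dtype=float)
        means[col] = float(np.mean(vals)) if total > 0 else np.nan
        variances[col] = feature_variance(vals) if total >= 2 else np.nan
    minute = np.zeros(max(int(np.ceil(session_length_s / 60.0)), 1), dtype=int)
    for t in in_phase["start_s"].to_numpy(dtype=float) - phase_start_s:
        minute[min(int(t // 60.0), minute.size - 1)] += 1
    return AnimalSummary(
        pup_id=pup_id,
        age=age,
        sex=sex,
        context=context,
        total_count=total,
        feature_means=means,
        feature_variances=variances,
        per_minute_counts=minute,
    )
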