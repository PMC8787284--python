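"""Spectral detection: from raw audio to per-frame multi-peak detections.

High-sample-rate recordings (nominally 300 kHz, so that the Nyquist
frequency clears the 125 kHz upper band edge) are band-pass filtered,
converted to a short-time magnitude spectrogram on a fixed 0.5-ms frame
grid, flattened against the stationary noise floor, and reduced to at most
seven tonal peaks per frame.  The lowest-frequency peak in each frame is
the candidate fundamental; higher peaks are candidate harmonics or
simultaneous tones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "SpectralFrames",
    "read_wav",
    "bandpass",
    "compute_spectrogram",
    "flatten_spectrum",
    "detect_peaks",
]

#: Analysis band for rodent ultrasonic vocalizations, kHz.
BAND_LOW_KHZ = 15.0
BAND_HIGH_KHZ = 125.0

#: Frame step of the spectrogram grid, ms.
FRAME_STEP_MS = 0.5

#: Analysis window length in samples (~1.7 ms at 300 kHz; ~0.59 kHz bins).
WINDOW_SAMPLES = 512

#: Maximum number of simultaneous tones retained per frame.
MAX_PEAKS = 7


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and channel identity.

    Samples are float amplitudes, nominally in [-1, 1] after
    :func:`read_wav`.  ``channel_id`` labels the microphone/chamber the
    clip came from (e.g. ``"pup"`` / ``"mother"`` or ``"ch0"``).
    """

    samples: np.ndarray
    sample_rate: float
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip holds a single channel; got ndim="
                             f"{self.samples.ndim}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in AudioClip")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0


@dataclass
class SpectralFrames:
    """Short-time spectra on a fixed frame grid, band-limited to 15-125 kHz.

    ``magnitude`` has shape ``(n_frames, n_bins)``.  After
    :func:`detect_peaks`, ``peak_freqs`` / ``peak_amps`` are
    ``(n_frames, max_peaks)`` arrays, NaN-padded, with each row sorted
    ascending by frequency so that column 0 is the candidate fundamental.
    """

    frame_times: np.ndarray          # seconds, step FRAME_STEP_MS
    frequency_bins: np.ndarray       # kHz, within [15, 125]
    magnitude: np.ndarray            # (n_frames, n_bins), >= 0
    frame_step_ms: float = FRAME_STEP_MS
    flattened: bool = False
    noise_scale: np.ndarray | None = None  # (n_bins,), robust temporal SD
    peak_freqs: np.ndarray | None = None   # (n_frames, max_peaks), kHz
    peak_amps: np.ndarray | None = None    # (n_frames, max_peaks)

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    def has_peak(self) -> np.ndarray:
        """Boolean per frame: at least one detected peak."""
        if self.peak_freqs is None:
            raise ValueError("peaks not detected yet")
        return ~np.isnan(self.peak_freqs[:, 0])


def read_wav(path) -> list[AudioClip]:
    """Read a PCM WAV file into one :class:`AudioClip` per channel.

    Integer encodings are rescaled to [-1, 1]; float WAVs pass through.
    Returns a list so mono and multi-channel files share one interface.
    """
    import struct

    try:
        rate, data = wavfile.read(path)
    except (ValueError, struct.error, EOFError) as exc:
        raise ValueError(f"unreadable or non-PCM WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path!r} contains no samples")
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 1:
        data = data[:, None]
    return [
        AudioClip(samples=data[:, ch], sample_rate=float(rate), channel_id=f"ch{ch}")
        for ch in range(data.shape[1])
    ]


def bandpass(
    clip: AudioClip,
    low_khz: float = BAND_LOW_KHZ,
    high_khz: float = BAND_HIGH_KHZ,
    order: int = 8,
) -> AudioClip:
    """Zero-phase Butterworth band-pass; out-of-band rejection >= 40 dB.

    Forward-backward filtering (``sosfiltfilt``) preserves length and
    doubles the stop-band attenuation of the order-``order`` prototype.
    """
    if not 0 < low_khz < high_khz:
        raise ValueError("need 0 < low < high")
    if high_khz * 1e3 >= clip.nyquist:
        raise ValueError(
            f"high edge {high_khz} kHz not below Nyquist {clip.nyquist / 1e3:.1f} kHz"
        )
    sos = signal.butter(
        order, [low_khz * 1e3, high_khz * 1e3], btype="bandpass",
        fs=clip.sample_rate, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, clip.samples)
    return replace(clip, samples=filtered)


def compute_spectrogram(
    clip: AudioClip,
    frame_step_ms: float = FRAME_STEP_MS,
    window_samples: int = WINDOW_SAMPLES,
    band: tuple[float, float] = (BAND_LOW_KHZ, BAND_HIGH_KHZ),
) -> SpectralFrames:
    """Hann-window magnitude spectrogram on the fixed frame grid.

    Frame times are window centers; the hop realizes ``frame_step_ms``
    exactly when ``sample_rate * frame_step_ms / 1000`` is an integer
    (150 samples at 300 kHz).  Only bins inside ``band`` are kept.
    """
    hop = int(round(clip.sample_rate * frame_step_ms / 1000.0))
    if hop < 1:
        raise ValueError("frame step shorter than one sample")
    if clip.samples.size < window_samples:
        raise ValueError(
            f"clip of {clip.samples.size} samples shorter than the "
            f"{window_samples}-sample analysis window"
        )
    win = signal.windows.hann(window_samples, sym=False)
    stft = signal.ShortTimeFFT(win, hop=hop, fs=clip.sample_rate, scale_to="magnitude")
    spec = np.abs(stft.stft(clip.samples))            # (n_bins, n_slices)
    times = stft.t(clip.samples.size)                 # window-center seconds
    # Drop padding slices whose window center lies outside the clip.
    inside = (times >= 0) & (times <= clip.duration)
    spec = spec[:, inside]
    times = times[inside]
    freqs_khz = stft.f / 1e3
    keep = (freqs_khz >= band[0]) & (freqs_khz <= band[1])
    return SpectralFrames(
        frame_times=times,
        frequency_bins=freqs_khz[keep],
        magnitude=spec[keep].T.copy(),
        frame_step_ms=frame_step_ms,
    )


def flatten_spectrum(frames: SpectralFrames) -> SpectralFrames:
    """Remove the stationary noise floor by per-bin temporal median subtraction.

    For each frequency bin, the median magnitude over all frames is
    subtracted and the result floored at zero.  A stationary broadband
    floor cancels while tonal components -- present in a minority of
    frames -- retain a positive excess.  Consequently the operator assumes
    calls occupy less than half of the frames at any given bin; it is
    idempotent on noise-only input up to that flooring.

    Alongside the flattened magnitudes, the per-bin robust temporal
    spread (1.4826 * MAD over frames) is kept as the bin's noise scale;
    peak picking thresholds against it.
    """
    floor = np.median(frames.magnitude, axis=0, keepdims=True)
    scale = 1.4826 * np.median(np.abs(frames.magnitude - floor), axis=0)
    flat = np.maximum(frames.magnitude - floor, 0.0)
    return replace(frames, magnitude=flat, flattened=True, noise_scale=scale)


def _parabolic_offset(m_prev: np.ndarray, m0: np.ndarray, m_next: np.ndarray) -> np.ndarray:
    """Sub-bin peak offset in [-0.5, 0.5] from a three-point parabola."""
    denom = m_prev - 2.0 * m0 + m_next
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (m_prev - m_next) / denom
    off = np.where(np.isfinite(off), off, 0.0)
    return np.clip(off, -0.5, 0.5)


def detect_peaks(
    frames: SpectralFrames,
    threshold_z: float = 5.0,
    max_peaks: int = MAX_PEAKS,
    relative_floor_db: float = -25.0,
) -> SpectralFrames:
    """Pick per-frame tonal peaks from the flattened spectrogram.

    A bin is a candidate if it is a local spectral maximum and exceeds
    both thresholds:

    * the frame's residual floor (median of the flattened frame) plus
      ``threshold_z`` robust standard deviations of that bin's temporal
      noise (computed in :func:`flatten_spectrum`; a per-frame MAD would
      collapse to zero once flattening floors most bins), and
    * ``relative_floor_db`` relative to the loudest bin of the frame.
      The default -25 dB sits above the Hann window's -31 dB sidelobes
      (which would otherwise register as tones when a strong call
      dominates a frame) while keeping harmonics down to ~1/18 of the
      fundamental's amplitude.

    Candidates are capped at the ``max_peaks``
    largest amplitudes -- ties broken toward lower frequency, preserving
    the fundamental -- and stored sorted ascending by frequency, so
    column 0 of ``peak_freqs`` is the candidate fundamental.
    """
    if not frames.flattened:
        raise ValueError("detect_peaks expects a flattened spectrogram")
    mag = frames.magnitude
    n_frames, n_bins = mag.shape
    # Local maxima (strict vs left, >= vs right resolves flat tops leftward).
    is_max = np.zeros_like(mag, dtype=bool)
    if n_bins >= 3:
        is_max[:, 1:-1] = (mag[:, 1:-1] > mag[:, :-2]) & (mag[:, 1:-1] >= mag[:, 2:])
    if frames.noise_scale is None:
        raise ValueError("flattened frames lack a noise scale; re-run flatten_spectrum")
    floor = np.median(mag, axis=1)
    thresh = floor[:, None] + threshold_z * frames.noise_scale[None, :]
    rel_floor = mag.max(axis=1, keepdims=True) * 10.0 ** (relative_floor_db / 20.0)
    # Absolute guard so a noiseless (zero-noise-scale) input needs real energy.
    eps = 1e-9 * max(1.0, float(mag.max(initial=0.0)))
    cand = is_max & (mag > thresh) & (mag > rel_floor) & (mag > eps)

    peak_freqs = np.full((n_frames, max_peaks), np.nan)
    peak_amps = np.full((n_frames, max_peaks), np.nan)
    bins = frames.frequency_bins
    bin_width = bins[1] - bins[0] if n_bins > 1 else 0.0
    for fr in np.nonzero(cand.any(axis=1))[0]:
        idx = np.nonzero(cand[fr])[0]
        amps = mag[fr, idx]
        if idx.size > max_peaks:
            # Stable sort on (-amp, freq): equal amplitudes keep lower bins.
            order = np.lexsort((idx, -amps))[:max_peaks]
            idx, amps = idx[order], amps[order]
        off = _parabolic_offset(mag[fr, idx - 1], mag[fr, idx], mag[fr, idx + 1])
        freqs = np.clip(bins[idx] + off * bin_width, BAND_LOW_KHZ, BAND_HIGH_KHZ)
        order = np.argsort(freqs, kind="stable")
        k = idx.size
        peak_freqs[fr, :k] = freqs[order]
        peak_amps[fr, :k] = amps[order]
    return replace(frames, peak_freqs=peak_freqs, peak_amps=peak_amps)
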