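"""Ground-truthed synthetic USV audio and cohort tables.

Every downstream stage of the pipeline is verifiable against fixtures
built here: frequency-modulated tone stacks with known contours and
harmonic structure, full sessions with Gaussian background noise,
dual-channel recordings with a known source side, cohort tables drawn
from an explicit generative model with injected age / sex / context
effects, and bimodal inter-segment-gap samples with a numerically known
density trough.

Conventions (the recordings give no amplitude calibration, so these are
this package's own): SNR is peak call amplitude over noise RMS in dB;
calls carry 1-ms raised-cosine on/off ramps so truth durations are
well-defined without spectral splatter; WAV output is 16-bit PCM at a
300 kHz default rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.io import wavfile

__all__ = [
    "CallSpec",
    "SessionTruth",
    "CohortSpec",
    "synthesize_usv",
    "synthesize_session",
    "synthesize_two_channel",
    "simulate_cohort",
    "simulate_gap_distribution",
    "write_wav",
]

DEFAULT_SAMPLE_RATE = 300_000.0
RAMP_S = 1e-3
CONTOUR_SHAPES = ("constant", "linear_chirp", "sinusoidal_FM")


@dataclass
class CallSpec:
    """One synthetic frequency-modulated call with optional harmonics.

    The fundamental sweeps from ``f_start_khz`` to ``f_end_khz`` according
    to ``contour_shape`` (for ``sinusoidal_FM`` the two give the extremes
    of one full modulation cycle).  ``n_harmonics`` higher traces are
    stacked at integer multiples of the fundamental, harmonic ``k``
    scaled by ``harmonic_amplitude_decay ** k``.
    """

    onset_s: float
    duration_s: float
    contour_shape: str = "constant"
    f_start_khz: float = 35.0
    f_end_khz: float = 35.0
    n_harmonics: int = 0
    harmonic_amplitude_decay: float = 0.5
    amplitude: float = 0.5
    channel_gain: tuple[float, float] = (1.0, 1.0)
    source_channel: int = 0

    def __post_init__(self) -> None:
        if self.contour_shape not in CONTOUR_SHAPES:
            raise ValueError(f"unknown contour shape {self.contour_shape!r}")
        if self.duration_s < 0.003:
            raise ValueError("calls must last at least 3 ms")
        lo, hi = sorted((self.f_start_khz, self.f_end_khz))
        if not (22.0 <= lo and hi <= 60.0):
            raise ValueError("fundamental must stay within 22-60 kHz")
        if not 0 <= self.n_harmonics <= 6:
            raise ValueError("n_harmonics must be 0-6")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    def fundamental_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous fundamental (kHz) at call-relative times ``t``."""
        frac = np.clip(t / self.duration_s, 0.0, 1.0)
        if self.contour_shape == "constant":
            return np.full_like(frac, self.f_start_khz)
        if self.contour_shape == "linear_chirp":
            return self.f_start_khz + (self.f_end_khz - self.f_start_khz) * frac
        center = 0.5 * (self.f_start_khz + self.f_end_khz)
        dev = 0.5 * (self.f_end_khz - self.f_start_khz)
        return center + dev * np.sin(2 * np.pi * frac)


def synthesize_usv(
    spec: CallSpec, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one call; returns ``(waveform, truth_times, truth_fund_khz)``.

    The waveform is the enveloped tone stack sampled at ``sample_rate``;
    the truth contour samples the instantaneous fundamental on a 0.5-ms
    grid of call-relative times.
    """
    top_khz = max(spec.f_start_khz, spec.f_end_khz) * (spec.n_harmonics + 1)
    if top_khz * 1e3 >= sample_rate / 2:
        raise ValueError(
            f"tone stack reaches {top_khz:.0f} kHz, at or above Nyquist "
            f"({sample_rate / 2e3:.0f} kHz)"
        )
    n = int(round(spec.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    f_hz = spec.fundamental_at(t) * 1e3
    phase = 2 * np.pi * np.cumsum(f_hz) / sample_rate
    wave = np.zeros(n)
    for k in range(spec.n_harmonics + 1):
        wave += (spec.harmonic_amplitude_decay ** k) * np.sin((k + 1) * phase)
    wave *= spec.amplitude
    # 1-ms raised-cosine on/off ramps.
    n_ramp = min(int(RAMP_S * sample_rate), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        wave[:n_ramp] *= ramp
        wave[-n_ramp:] *= ramp[::-1]
    truth_t = np.arange(0.0, spec.duration_s, 5e-4)
    return wave, truth_t, spec.fundamental_at(truth_t)


@dataclass
class SessionTruth:
    """Complete specification of a synthetic recording session."""

    calls: list[CallSpec]
    noise_floor: float = 0.005
    sample_rate: float = DEFAULT_SAMPLE_RATE
    session_length_s: float = 10.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: c.onset_s)
        for c in self.calls:
            if c.offset_s > self.session_length_s + 1e-9:
                raise ValueError(f"call at {c.onset_s}s runs past session end")
        if not self.allow_overlap:
            for prev, nxt in zip(self.calls[:-1], self.calls[1:]):
                if nxt.onset_s < prev.offset_s - 1e-9 and nxt.source_channel == prev.source_channel:
                    raise ValueError(
                        f"overlapping calls at {prev.onset_s}s and {nxt.onset_s}s"
                    )


def truth_table(truth: SessionTruth) -> pd.DataFrame:
    """One row per call: identity, timing, contour endpoints, harmonics."""
    return pd.DataFrame(
        {
            "call_id": np.arange(len(truth.calls)),
            "channel": [c.source_channel for c in truth.calls],
            "onset_s": [c.onset_s for c in truth.calls],
            "offset_s": [c.offset_s for c in truth.calls],
            "f_start_khz": [c.f_start_khz for c in truth.calls],
            "f_end_khz": [c.f_end_khz for c in truth.calls],
            "n_harmonics": [c.n_harmonics for c in truth.calls],
            "amplitude": [c.amplitude for c in truth.calls],
        }
    )


def synthesize_session(truth: SessionTruth) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a mono session: calls summed into Gaussian background noise.

    Deterministic under a fixed ``truth.seed``.  Returns the waveform and
    the truth table.
    """
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.session_length_s * truth.sample_rate))
    wave = rng.standard_normal(n) * truth.noise_floor
    for call in truth.calls:
        w, _, _ = synthesize_usv(call, truth.sample_rate)
        i0 = int(round(call.onset_s * truth.sample_rate))
        wave[i0 : i0 + w.size] += w[: n - i0]
    return wave, truth_table(truth)


def synthesize_two_channel(
    truth: SessionTruth, attenuation_db: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a dual-microphone session with known source sides.

    Each call lands at full amplitude on its ``source_channel`` and
    attenuated by ``attenuation_db`` on the far channel, emulating
    cross-chamber bleed-through.  Noise is independent per channel.
    Returns a ``(n_samples, 2)`` waveform and the truth table (its
    ``channel`` column is the source label).
    """
    if attenuation_db <= 0:
        raise ValueError("attenuation_db must be positive")
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.session_length_s * truth.sample_rate))
    wave = rng.standard_normal((n, 2)) * truth.noise_floor
    far_gain = 10.0 ** (-attenuation_db / 20.0)
    for call in truth.calls:
        w, _, _ = synthesize_usv(call, truth.sample_rate)
        i0 = int(round(call.onset_s * truth.sample_rate))
        w = w[: n - i0]
        src = call.source_channel
        wave[i0 : i0 + w.size, src] += w
        wave[i0 : i0 + w.size, 1 - src] += w * far_gain
    return wave, truth_table(truth)


def write_wav(path, waveform: np.ndarray, sample_rate: float = DEFAULT_SAMPLE_RATE) -> None:
    """Write 16-bit PCM; mono (n,) or multi-channel (n, ch) float in [-1, 1]."""
    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, int(sample_rate), np.round(clipped * 32767.0).astype(np.int16))


def random_session_truth(
    seed: int,
    n_vocalizations: int = 30,
    snr_db: float = 20.0,
    noise_floor: float = 0.005,
    segments_per_voc: tuple[int, int] = (1, 3),
    within_gap_ms: tuple[float, float] = (6.0, 25.0),
    between_gap_ms: tuple[float, float] = (150.0, 30.0),
    two_channel: bool = False,
) -> tuple[SessionTruth, pd.DataFrame]:
    """Draw a session with realistic vocalization structure and its truth.

    Each intended vocalization is a burst of 1-3 frequency-modulated
    segments separated by short silent gaps (uniform ``within_gap_ms``,
    above the 4-ms splitting rule so they stay distinct segments);
    successive vocalizations are separated by long Gaussian gaps
    (``between_gap_ms`` = (mean, sd)), giving the bimodal inter-segment
    interval structure the consolidation threshold relies on.  Segment
    amplitude realizes ``snr_db`` over ``noise_floor``.  Returns the
    :class:`SessionTruth` plus a vocalization-level truth table
    ``(voc_id, channel, onset_s, offset_s, n_segments, n_harmonics)``.
    """
    rng = np.random.default_rng(seed)
    amplitude = min(noise_floor * 10.0 ** (snr_db / 20.0), 1.0)
    shapes = ["constant", "linear_chirp", "sinusoidal_FM"]
    calls: list[CallSpec] = []
    voc_rows = []
    t = 0.1
    for vid in range(n_vocalizations):
        n_seg = int(rng.integers(segments_per_voc[0], segments_per_voc[1] + 1))
        channel = int(rng.integers(0, 2)) if two_channel else 0
        f_center = float(rng.uniform(28, 42))
        n_h = int(rng.integers(0, 3))
        onset = t
        for s in range(n_seg):
            f0 = float(np.clip(f_center + rng.uniform(-3, 3), 23, 59))
            f1 = float(np.clip(f0 + rng.uniform(-6, 6), 23, 59))
            while n_h > 0 and (n_h + 1) * max(f0, f1) >= 145.0:
                n_h -= 1
            dur = float(rng.uniform(0.015, 0.045))
            calls.append(
                CallSpec(
                    onset_s=t, duration_s=dur,
                    contour_shape=shapes[int(rng.integers(0, 3))],
                    f_start_khz=f0, f_end_khz=f1, n_harmonics=n_h,
                    amplitude=amplitude, source_channel=channel,
                )
            )
            t += dur
            if s < n_seg - 1:
                t += float(rng.uniform(*within_gap_ms)) / 1e3
        voc_rows.append(
            dict(voc_id=vid, channel=channel, onset_s=onset, offset_s=t,
                 n_segments=n_seg, n_harmonics=n_h)
        )
        t += max(float(rng.normal(*between_gap_ms)), 60.0) / 1e3
    truth = SessionTruth(
        calls=calls, noise_floor=noise_floor, session_length_s=t + 0.1, seed=seed
    )
    return truth, pd.DataFrame(voc_rows)


# --------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortSpec:
    """Generative model for per-animal cohort tables.

    Per-animal vocalization counts follow a linear age trend
    (``count_intercept`` at the youngest age, ``count_slope_per_day``
    after that) plus, in the mother-present context, an age-specific
    additive offset (``context_offsets``).  Per-animal mean median
    frequency is ``freq_base_khz`` plus ``male_freq_offset_khz`` for
    males.  Cell noise is Gaussian with the stated SDs.  Defaults mirror
    an isolation cohort of prairie vole pups: ~1800 calls per 10 min at
    P6 falling to ~600 by P16, a ~-1.5 kHz male frequency downshift, and
    a context response that crosses over from suppression at P8 to
    facilitation from P12 on.
    """

    n_per_cell: int = 8
    ages: tuple[int, ...] = (6, 8, 10, 12, 14, 16)
    sexes: tuple[str, ...] = ("M", "F")
    contexts: tuple[str, ...] = ("isolation",)
    count_intercept: float = 1800.0
    count_slope_per_day: float = -120.0
    context_offsets: dict = field(
        default_factory=lambda: {6: 0.0, 8: -670.0, 10: 150.0, 12: 450.0, 14: 450.0, 16: 350.0}
    )
    freq_base_khz: float = 34.0
    male_freq_offset_khz: float = -1.5
    count_sd: float = 700.0
    freq_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_sd <= 0 or self.freq_sd <= 0:
            raise ValueError("dispersion SDs must be positive")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for age in self.ages:
            if self.mean_count(age, self.contexts[0]) <= 0:
                raise ValueError(f"non-positive mean count at age {age}")

    def mean_count(self, age: int, context: str) -> float:
        mu = self.count_intercept + self.count_slope_per_day * (age - min(self.ages))
        if context == "mother":
            mu += self.context_offsets.get(age, 0.0)
        return mu

    def mean_freq(self, sex: str) -> float:
        return self.freq_base_khz + (self.male_freq_offset_khz if sex == "M" else 0.0)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table from the generative model.

    Returns a long-format table (one row per pup x context, columns
    ``pup_id, age, sex, context, count, median_khz``) and a truth record
    of the injected effects.  Counts are left continuous and unclipped so
    every injected cell mean is exact (clipping at zero would bias
    low-mean / high-dispersion cells); the per-pup frequency deviation is
    shared across contexts (acoustic features do not change with context
    under this model).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for age in spec.ages:
        for sex in spec.sexes:
            for i in range(spec.n_per_cell):
                pup = f"P{age}{sex}{i:02d}"
                freq_dev = rng.normal(0.0, spec.freq_sd)
                count_dev = rng.normal(0.0, spec.count_sd)
                for ctx in spec.contexts:
                    count = spec.mean_count(age, ctx) + count_dev
                    if len(spec.contexts) > 1 and ctx != spec.contexts[0]:
                        # Within-subject fluctuation on top of the shared level.
                        count += rng.normal(0.0, spec.count_sd / 2.0)
                    rows.append(
                        dict(
                            pup_id=pup,
                            age=age,
                            sex=sex,
                            context=ctx,
                            count=count,
                            median_khz=spec.mean_freq(sex) + freq_dev,
                        )
                    )
    truth = dict(
        count_intercept=spec.count_intercept,
        count_slope_per_day=spec.count_slope_per_day,
        context_offsets=dict(spec.context_offsets),
        male_freq_offset_khz=spec.male_freq_offset_khz,
        cell_count_means={
            (a, c): spec.mean_count(a, c) for a in spec.ages for c in spec.contexts
        },
    )
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# Inter-segment gap mixture


def simulate_gap_distribution(
    short_gap_mean_ms: float = 8.0,
    long_gap_mean_ms: float = 150.0,
    long_gap_sd_ms: float = 30.0,
    mix: float = 0.6,
    n: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, float | None]:
    """Sample inter-segment gaps from a bimodal mixture.

    Short within-call gaps are exponential with mean ``short_gap_mean_ms``
    and occur with probability ``mix``; long between-call gaps are
    Gaussian(``long_gap_mean_ms``, ``long_gap_sd_ms``).  Returns the
    sample and the true density-trough location in ms (``None`` when
    ``mix`` is 1, i.e. no interior trough).
    """
    if not short_gap_mean_ms < long_gap_mean_ms:
        raise ValueError("short gap mean must be below long gap mean")
    if not 0 < mix <= 1:
        raise ValueError("mix must be in (0, 1]")
    if n < 100:
        raise ValueError("need n >= 100 for a usable histogram")
    rng = np.random.default_rng(seed)
    short = rng.random(n) < mix
    sample = np.where(
        short,
        rng.exponential(short_gap_mean_ms, n),
        np.abs(rng.normal(long_gap_mean_ms, long_gap_sd_ms, n)),
    )
    if mix >= 1.0:
        return sample, None
    return sample, _mixture_trough(
        short_gap_mean_ms, long_gap_mean_ms, long_gap_sd_ms, mix
    )


def _mixture_trough(
    short_mean: float, long_mean: float, long_sd: float, mix: float
) -> float | None:
    """Numeric minimizer of the mixture density between the two modes."""

    def density(x):
        return mix * stats.expon.pdf(x, scale=short_mean) + (1 - mix) * stats.norm.pdf(
            x, long_mean, long_sd
        )

    grid = np.linspace(short_mean, long_mean, 4001)
    i = int(np.argmin(density(grid)))
    if i in (0, grid.size - 1):
        return None
    res = optimize.minimize_scalar(
        density, bracket=(grid[i - 1], grid[i], grid[i + 1])
    )
    return float(res.x)
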