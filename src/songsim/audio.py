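"""Syllable preprocessing and acoustic representations.

Two representations are produced from each syllable:

* a log-power mel spectrogram (150 bands x 170 frames) used as the input
  image of the convolutional embedding network, and
* per-frame acoustic feature contours (fundamental, peak and mean frequency,
  frequency-change, Wiener entropy, harmonicity, vibrato amplitude, plus time
  itself) used by the dynamic-time-warping comparator, together with the
  per-syllable summary statistics used for feature attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Syllable",
    "MelSpectrogram",
    "FeatureContours",
    "CONTOUR_FEATURES",
    "SUMMARY_FEATURES",
    "SUMMARY_STATISTICS",
    "preprocess_syllable",
    "mel_spectrogram",
    "extract_contours",
    "summary_statistics",
    "read_wav",
    "write_wav",
]

#: contour features available to the DTW comparator, in canonical order.
#: ``time`` is a genuine feature so that warping the time axis is penalised.
CONTOUR_FEATURES = (
    "time",
    "fundamental_frequency",
    "peak_frequency",
    "mean_frequency",
    "fundamental_change",
    "peak_change",
    "normalized_fundamental",
    "wiener_entropy",
    "harmonicity",
    "vibrato_amplitude",
)

#: features summarised per syllable (5 statistics each) for attribution.
SUMMARY_FEATURES = (
    "fundamental_frequency",
    "peak_frequency",
    "fundamental_change",
    "wiener_entropy",
    "harmonicity",
)
SUMMARY_STATISTICS = ("mean", "max", "min", "start", "end")


@dataclass
class Syllable:
    """A single mono syllable waveform."""

    id: str
    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class MelSpectrogram:
    """Log-power mel spectrogram, fixed shape 150 bands x 170 frames."""

    values: np.ndarray
    band_centers: np.ndarray

    N_MELS = 150
    N_FRAMES = 170

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.N_MELS, self.N_FRAMES):
            raise ValueError(
                f"mel spectrogram must be {self.N_MELS}x{self.N_FRAMES}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel spectrogram contains non-finite values")


@dataclass
class FeatureContours:
    """Per-frame acoustic feature contours sharing one time index."""

    syllable_id: str
    frame: pd.DataFrame  # columns = CONTOUR_FEATURES (+ 'voiced')
    voiced_fraction: float = field(default=1.0)

    def __post_init__(self) -> None:
        missing = [f for f in CONTOUR_FEATURES if f not in self.frame.columns]
        if missing:
            raise ValueError(f"contour frame missing features: {missing}")
        t = self.frame["time"].to_numpy()
        if t.size == 0:
            raise ValueError("empty contour")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    def to_array(self, features: tuple[str, ...] = CONTOUR_FEATURES) -> np.ndarray:
        """Return a (frames, features) array in the requested feature order."""
        return self.frame.loc[:, list(features)].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# WAV I/O


def read_wav(path, id: str | None = None) -> Syllable:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    name = id if id is not None else str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return Syllable(id=name, samples=data, rate=int(rate))


def write_wav(path, syllable: Syllable) -> None:
    """Write as 16-bit PCM, clipping to [-1, 1]."""
    x = np.clip(syllable.samples, -1.0, 1.0)
    wavfile.write(path, syllable.rate, (x * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_syllable(
    s: Syllable, highpass_hz: float = 100.0, fade_ms: float = 20.0
) -> Syllable:
    """High-pass filter, peak-normalise and apply raised-cosine fades.

    The syllable is high-pass filtered at ``highpass_hz`` (zero-phase 4th
    order Butterworth), peak-normalised to ``|max| = 1`` and given a
    ``fade_ms`` raised-cosine fade-in and fade-out.

    Raises
    ------
    ValueError
        If the sample rate is below 8 kHz, the syllable is no longer than
        twice the fade (the fades would overlap), or the input is silent.
    """
    if s.rate < 8000:
        raise ValueError(f"sample rate {s.rate} Hz below supported minimum 8000 Hz")
    n_fade = int(round(fade_ms / 1000.0 * s.rate))
    if s.samples.size <= 2 * n_fade:
        raise ValueError(
            f"syllable too short ({s.duration * 1000:.1f} ms) for "
            f"{fade_ms:.0f} ms fades"
        )
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=s.rate, output="sos")
    x = signal.sosfiltfilt(sos, s.samples)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("silent input")
    x = x / peak
    fade = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade))
    x[:n_fade] *= fade
    x[-n_fade:] *= fade[::-1]
    # fades can move the peak off 1.0; re-normalise so the contract holds
    x = x / np.max(np.abs(x))
    return Syllable(id=s.id, samples=x, rate=s.rate)


# ---------------------------------------------------------------------------
# Mel spectrogram

_N_FFT = 2048
_HOP = 128
_WIN_LENGTH = 512
_FMIN = 100.0
_FMAX = 16000.0
_LOG_FLOOR_DB = -80.0


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate: float, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank; returns (filters, band centre frequencies)."""
    fmax = min(fmax, rate / 2.0)
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, centre, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(centre - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - centre, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb, hz_pts[1:-1]


def _stft_power(x: np.ndarray, rate: float) -> np.ndarray:
    """Centered power STFT with window zero-padded to the FFT length."""
    pad = _N_FFT // 2
    xp = np.pad(x, pad, mode="reflect" if x.size > pad else "constant")
    win = signal.get_window("hann", _WIN_LENGTH, fftbins=True)
    n_frames = 1 + (xp.size - _N_FFT) // _HOP
    idx = np.arange(_N_FFT)[None, :] + _HOP * np.arange(n_frames)[:, None]
    frames = xp[idx]
    # apply the short window centered inside the FFT buffer
    wbuf = np.zeros(_N_FFT)
    off = (_N_FFT - _WIN_LENGTH) // 2
    wbuf[off : off + _WIN_LENGTH] = win
    spec = np.fft.rfft(frames * wbuf, axis=1)
    return (np.abs(spec) ** 2).T  # (freq, frames)


def mel_spectrogram(s: Syllable, ref_power: float | None = None) -> MelSpectrogram:
    """Log-power mel spectrogram, padded or centre-cropped to 170 frames.

    Power is expressed in dB relative to ``ref_power`` (the per-syllable
    maximum when None; pass a corpus-wide maximum for comparable scaling
    across a corpus) and floored at -80 dB.  Padding frames are set exactly
    to the floor.
    """
    pw = _stft_power(s.samples, s.rate)
    fb, centers = mel_filterbank(MelSpectrogram.N_MELS, _N_FFT, s.rate, _FMIN, _FMAX)
    mel = fb @ pw
    ref = float(np.max(mel)) if ref_power is None else float(ref_power)
    if ref <= 0:
        raise ValueError("silent input")
    db = 10.0 * np.log10(np.maximum(mel, ref * 10.0 ** (_LOG_FLOOR_DB / 10.0)) / ref)
    db = np.maximum(db, _LOG_FLOOR_DB)

    n = db.shape[1]
    target = MelSpectrogram.N_FRAMES
    if n < target:
        left = (target - n) // 2
        out = np.full((MelSpectrogram.N_MELS, target), _LOG_FLOOR_DB)
        out[:, left : left + n] = db
    else:
        left = (n - target) // 2
        out = db[:, left : left + target]
    return MelSpectrogram(values=out, band_centers=centers)


# ---------------------------------------------------------------------------
# Feature contours


def _autocorr_f0(
    seg: np.ndarray, rate: float, fmin: float, fmax: float, threshold: float
) -> tuple[float, float]:
    """Fundamental estimate from the normalised autocorrelation peak.

    Returns (f0_hz, peak_value); f0 is nan when no peak clears ``threshold``.
    """
    seg = seg - seg.mean()
    denom = float(np.dot(seg, seg))
    if denom <= 0:
        return np.nan, 0.0
    n = seg.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(seg, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    ac = ac / denom
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = min(n - 2, int(np.ceil(rate / fmin)))
    if lag_max <= lag_min:
        return np.nan, 0.0
    window = ac[lag_min : lag_max + 1]
    k = int(np.argmax(window)) + lag_min
    peak = float(ac[k])
    if peak < threshold:
        return np.nan, peak
    # parabolic interpolation around the peak lag
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom2 = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom2 if denom2 != 0 else 0.0
    lag = k + float(np.clip(delta, -0.5, 0.5))
    return rate / lag, peak


def _fill_unvoiced(values: np.ndarray, voiced: np.ndarray) -> np.ndarray:
    """Carry the last voiced value forward; back-fill leading unvoiced frames."""
    out = values.copy()
    if not voiced.any():
        return out
    idx = np.where(voiced, np.arange(values.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first = int(np.argmax(voiced))
    idx[idx < 0] = first
    return out[idx]


_ARCSIN_SLOPE_SCALE = 50_000.0  # Hz/s normalisation for the arcsin slope transform


def extract_contours(
    s: Syllable,
    step_ms: float = 5.0,
    window_ms: float = 10.0,
    f0_range: tuple[float, float] = (300.0, 4000.0),
    voicing_threshold: float = 0.45,
    vibrato_window_ms: float = 50.0,
) -> FeatureContours:
    """Per-frame acoustic feature contours of a preprocessed syllable.

    Per frame: fundamental frequency from the autocorrelation peak within
    ``f0_range`` (log Hz); peak frequency = spectral argmax (log Hz); mean
    frequency = spectral centroid (log Hz); Wiener entropy = log of the
    geometric/arithmetic mean ratio of the power spectrum (<= 0, ~0 for
    white noise); harmonicity = fraction of power within +-5% of the first 8
    harmonics of the fundamental; frequency-change features = arcsin of the
    clipped, normalised inter-frame slope; normalised fundamental = log f0
    minus the syllable-wide voiced mean; vibrato amplitude = half the
    peak-to-trough range of the linearly detrended fundamental in a sliding
    window.  Unvoiced frames carry the last voiced fundamental forward
    (leading frames back-filled); a fully unvoiced syllable uses the
    geometric midpoint of ``f0_range`` so that downstream alignment still
    has complete contours.
    """
    step = max(1, int(round(step_ms / 1000.0 * s.rate)))
    win = max(4, int(round(window_ms / 1000.0 * s.rate)))
    if s.samples.size < win:
        raise ValueError("syllable shorter than one analysis window")
    n_frames = 1 + (s.samples.size - win) // step
    window = signal.get_window("hann", win, fftbins=True)
    # zero-pad frames well beyond the window so spectral measures (peak,
    # harmonicity bands) are not quantised to coarse FFT bins
    nfft = int(2 ** np.ceil(np.log2(max(win * 8, 4096))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / s.rate)

    t = np.empty(n_frames)
    f0 = np.empty(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    peak_f = np.empty(n_frames)
    mean_f = np.empty(n_frames)
    entropy = np.empty(n_frames)
    harmonicity = np.zeros(n_frames)

    band = freqs >= 100.0  # ignore DC/sub-bass bins in spectral measures
    for i in range(n_frames):
        seg = s.samples[i * step : i * step + win]
        t[i] = (i * step + win / 2) / s.rate
        p = np.abs(np.fft.rfft(seg * window, nfft)) ** 2
        pb = p[band]
        total = pb.sum()
        if total <= 0:
            peak_f[i] = mean_f[i] = np.nan
            entropy[i] = 0.0
            f0[i] = np.nan
            continue
        peak_f[i] = freqs[band][int(np.argmax(pb))]
        mean_f[i] = float((freqs[band] * pb).sum() / total)
        # Wiener entropy: log(geometric mean / arithmetic mean) of power
        eps = total * 1e-12
        logp = np.log(pb + eps)
        entropy[i] = float(logp.mean() - np.log(pb.mean() + eps))
        fhat, _peak = _autocorr_f0(seg, s.rate, f0_range[0], f0_range[1],
                                   voicing_threshold)
        f0[i] = fhat
        if np.isfinite(fhat):
            voiced[i] = True
            mask = np.zeros_like(pb, dtype=bool)
            fr = freqs[band]
            # band half-width: +-5% of the harmonic, but never narrower than
            # the analysis window's main-lobe half-width (hann: 2 fs / win)
            lobe = 2.0 * s.rate / win
            for h in range(1, 9):
                fh = h * fhat
                if fh >= s.rate / 2:
                    break
                mask |= np.abs(fr - fh) <= max(0.05 * fh, lobe)
            harmonicity[i] = float(pb[mask].sum() / total)

    if voiced.any():
        f0 = _fill_unvoiced(f0, voiced)
    else:
        f0 = np.full(n_frames, float(np.sqrt(f0_range[0] * f0_range[1])))
    peak_f = _fill_unvoiced(peak_f, np.isfinite(peak_f))
    mean_f = _fill_unvoiced(mean_f, np.isfinite(mean_f))

    def arcsin_slope(x: np.ndarray) -> np.ndarray:
        d = np.zeros_like(x)
        if x.size > 1:
            dt = step / s.rate
            d[1:] = np.arcsin(np.clip(np.diff(x) / (dt * _ARCSIN_SLOPE_SCALE),
                                      -1.0, 1.0))
        return d

    log_f0 = np.log(f0)
    vib_half = max(1, int(round(vibrato_window_ms / 1000.0 / 2 / (step / s.rate))))
    vibrato = np.zeros(n_frames)
    for i in range(n_frames):
        lo, hi = max(0, i - vib_half), min(n_frames, i + vib_half + 1)
        seg_f0 = f0[lo:hi]
        if seg_f0.size >= 3:
            x = np.arange(seg_f0.size, dtype=np.float64)
            slope, intercept = np.polyfit(x, seg_f0, 1)
            resid = seg_f0 - (slope * x + intercept)
            vibrato[i] = 0.5 * (resid.max() - resid.min())

    voiced_mean_logf0 = log_f0[voiced].mean() if voiced.any() else log_f0.mean()
    frame = pd.DataFrame(
        {
            "time": t,
            "fundamental_frequency": log_f0,
            "peak_frequency": np.log(peak_f),
            "mean_frequency": np.log(mean_f),
            "fundamental_change": arcsin_slope(f0),
            "peak_change": arcsin_slope(peak_f),
            "normalized_fundamental": log_f0 - voiced_mean_logf0,
            "wiener_entropy": np.minimum(entropy, 0.0),
            "harmonicity": harmonicity,
            "vibrato_amplitude": vibrato,
            "voiced": voiced,
        }
    )
    return FeatureContours(
        syllable_id=s.id, frame=frame, voiced_fraction=float(voiced.mean())
    )


def summary_statistics(c: FeatureContours, duration: float) -> pd.Series:
    """26 per-syllable summary measures for feature attribution.

    Mean, max, min, start and end of each of the five summary features
    (computed over voiced frames; start/end are the first/last voiced-frame
    values), plus the log syllable length.  Fundamental and peak frequency
    are already log-transformed in the contours.
    """
    voiced = c.frame["voiced"].to_numpy(dtype=bool)
    if not voiced.any():
        raise ValueError(f"{c.syllable_id}: no voiced frames")
    if duration <= 0:
        raise ValueError("duration must be positive")
    out: dict[str, float] = {}
    for feat in SUMMARY_FEATURES:
        v = c.frame[feat].to_numpy(dtype=np.float64)[voiced]
        out[f"{feat}_mean"] = float(v.mean())
        out[f"{feat}_max"] = float(v.max())
        out[f"{feat}_min"] = float(v.min())
        out[f"{feat}_start"] = float(v[0])
        out[f"{feat}_end"] = float(v[-1])
    out["syllable_length"] = float(np.log(duration))
    return pd.Series(out)
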