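"""Radar baseband signal processing.

Raw I/Q -> chest displacement (phase demodulation), presence flags, the
16-80 Hz heart-sound band, and per-window signal quality indices used for
multi-module channel selection.

Conventions: time in seconds from recording start; all windows half-open
[t, t+W); displacement in micrometres; carrier wavelength in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "IQSeries",
    "DisplacementSignal",
    "HeartSoundSignal",
    "PresenceSeries",
    "SQISeries",
    "demodulate_displacement",
    "detect_presence",
    "extract_heart_sound",
    "compute_sqi",
    "HEART_SOUND_BAND",
]

#: heart-sound pass band, Hz
HEART_SOUND_BAND = (16.0, 80.0)

#: start of the band used as a pure-noise reference for the SQI, Hz
NOISE_BAND_START = 100.0


@dataclass
class IQSeries:
    """One radar channel's complex baseband samples."""

    samples: np.ndarray
    sampling_rate: float            # Hz
    carrier_wavelength: float       # mm (12.49 mm for the 24-GHz ISM band)
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.sampling_rate <= 160.0:
            raise ValueError("sampling_rate must exceed 160 Hz")
        if not np.all(np.isfinite(self.samples.real) & np.isfinite(self.samples.imag)):
            raise ValueError("I/Q samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class DisplacementSignal:
    values: np.ndarray              # um
    sampling_rate: float            # Hz
    valid: bool = True              # False for a degenerate (zero-radius) I/Q cloud

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class HeartSoundSignal:
    """Displacement band-limited to the 16-80 Hz heart-sound band."""

    values: np.ndarray              # um
    sampling_rate: float


@dataclass
class PresenceSeries:
    flags: np.ndarray               # {0, 1} per window
    window_length: float            # s

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=int)
        if not np.all((self.flags == 0) | (self.flags == 1)):
            raise ValueError("presence flags must be 0 or 1")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Presence flag for arbitrary times (clamped to the last window)."""
        idx = np.clip((np.asarray(t) / self.window_length).astype(int),
                      0, self.flags.size - 1)
        return self.flags[idx]


@dataclass
class SQISeries:
    """Per-window signal quality (band-power SNR) of one channel, in dB."""

    values: np.ndarray              # dB; -inf where undefined
    window_length: float            # s
    valid: np.ndarray = field(default=None)
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)


# ---------------------------------------------------------------------------
# demodulation
# ---------------------------------------------------------------------------

def _kasa_circle_fit(z: np.ndarray) -> tuple[complex, float]:
    """Algebraic least-squares circle fit (Kåsa normal equations).

    Returns (centre, radius) of the circle best fitting the I/Q cloud.
    """
    x, y = z.real, z.imag
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    radius = float(np.sqrt(max(r2, 0.0)))
    return complex(cx, cy), radius


def demodulate_displacement(iq: IQSeries) -> DisplacementSignal:
    """Arc-based phase demodulation: I/Q -> displacement in micrometres.

    The complex DC offset is estimated by a least-squares circle fit to the
    I/Q cloud and subtracted; the unwrapped phase of the centred cloud maps
    to displacement via d = theta * lambda / (4*pi).  Output is zero-mean
    over the recording.  A degenerate (zero-radius) cloud yields a flagged
    invalid all-zero signal rather than an exception.
    """
    if iq.duration < 1.0:
        raise ValueError("need at least 1 s of samples to demodulate")
    z = iq.samples
    center, radius = _kasa_circle_fit(z)
    spread = float(np.std(z))
    if radius < 1e-12 or spread < 1e-12:
        return DisplacementSignal(values=np.zeros(z.size),
                                  sampling_rate=iq.sampling_rate, valid=False)
    theta = np.unwrap(np.angle(z - center))
    d_um = theta * iq.carrier_wavelength * 1000.0 / (4.0 * np.pi)
    d_um = d_um - d_um.mean()
    return DisplacementSignal(values=d_um, sampling_rate=iq.sampling_rate)


# ---------------------------------------------------------------------------
# presence detection
# ---------------------------------------------------------------------------

def detect_presence(iq: IQSeries, window: float = 1.0,
                    threshold_db: float = 10.0) -> PresenceSeries:
    """Binary in-bed flags from windowed received-power variance.

    A window is flagged present when its I/Q variance exceeds the empty-bed
    baseline by ``threshold_db``.  The baseline is the smaller of the first
    decile of the window variances and the wideband noise power estimated
    above 100 Hz: with empty-bed periods in the recording the quietest
    windows sit at the noise floor and the two agree; without them the
    decile saturates at body-motion level and the spectral estimate keeps
    the baseline at the true empty-bed level.  An all-noise recording,
    where every window sits at the noise floor, yields all-zero flags.
    """
    if window < 1.0:
        raise ValueError("window must be >= 1 s")
    fs = iq.sampling_rate
    wlen = int(round(window * fs))
    if iq.samples.size < wlen:      # shorter than one window: single result
        wlen = iq.samples.size
    n_win = max(1, iq.samples.size // wlen)
    z = iq.samples[: n_win * wlen].reshape(n_win, wlen)
    power = np.var(z.real, axis=1) + np.var(z.imag, axis=1)
    if n_win >= 5:
        # a breathing cycle spans several 1-s windows and the I/Q cloud is
        # nearly still at the turning points; a short rolling context keeps
        # those windows flagged present
        power = np.convolve(power, np.ones(5) / 5.0, mode="same")

    nyq = fs / 2.0
    f_lo = min(NOISE_BAND_START, 0.8 * nyq)
    sos = signal.butter(4, f_lo, btype="highpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos, np.column_stack([iq.samples.real,
                                                  iq.samples.imag]), axis=0)
    noise_floor = float(np.var(hp[:, 0]) + np.var(hp[:, 1])) * nyq / (nyq - f_lo)

    baseline = max(min(float(np.percentile(power, 10)), noise_floor), 1e-30)
    flags = (power > baseline * 10.0 ** (threshold_db / 10.0)).astype(int)
    return PresenceSeries(flags=flags, window_length=window)


# ---------------------------------------------------------------------------
# heart-sound band
# ---------------------------------------------------------------------------

def _band_sos(fs: float):
    return signal.butter(4, HEART_SOUND_BAND, btype="bandpass", fs=fs, output="sos")


def extract_heart_sound(d: DisplacementSignal) -> HeartSoundSignal:
    """Zero-phase Butterworth band-pass (order 4 per direction, 16-80 Hz)."""
    if d.sampling_rate <= 2.0 * HEART_SOUND_BAND[1]:
        raise ValueError(
            f"sampling rate {d.sampling_rate} Hz violates the Nyquist bound for "
            f"the {HEART_SOUND_BAND[1]} Hz band edge (needs > {2 * HEART_SOUND_BAND[1]} Hz)"
        )
    filtered = signal.sosfiltfilt(_band_sos(d.sampling_rate), d.values)
    return HeartSoundSignal(values=filtered, sampling_rate=d.sampling_rate)


# ---------------------------------------------------------------------------
# signal quality index
# ---------------------------------------------------------------------------

def compute_sqi(d: DisplacementSignal, window: float,
                channel_id: int = 0) -> SQISeries:
    """Per-window band-power SNR of the heart-sound band, in dB.

    SQI = 10*log10(P_band / P_noise) where P_band is the 16-80 Hz power and
    P_noise is a 64-Hz-bandwidth noise estimate: the larger of the
    100 Hz-Nyquist density and the 8-12 Hz density, each rescaled to the
    pass-band width.  The mid-band reference sits above respiration and
    below the heart sounds and catches low-frequency-heavy noise (e.g. the
    1/f^2 random walk a failed phase unwrap produces) that the high band
    alone would miss.  White noise scores ~0 dB; a clean in-band tone
    scores high.  All-zero windows get a -inf sentinel and are flagged
    invalid.
    """
    fs = d.sampling_rate
    if window > d.values.size / fs:
        raise ValueError("window exceeds recording length")
    band = signal.sosfiltfilt(_band_sos(fs), d.values)
    nyq = fs / 2.0
    f_lo = min(NOISE_BAND_START, 0.8 * nyq)
    sos_hi = signal.butter(4, f_lo, btype="highpass", fs=fs, output="sos")
    noise_hi = signal.sosfiltfilt(sos_hi, d.values)
    sos_mid = signal.butter(4, (8.0, 12.0), btype="bandpass", fs=fs, output="sos")
    noise_mid = signal.sosfiltfilt(sos_mid, d.values)
    bw = HEART_SOUND_BAND[1] - HEART_SOUND_BAND[0]

    wlen = int(round(window * fs))
    n_win = max(1, d.values.size // wlen)
    p_band = np.mean(band[: n_win * wlen].reshape(n_win, wlen) ** 2, axis=1)
    p_hi = np.mean(noise_hi[: n_win * wlen].reshape(n_win, wlen) ** 2, axis=1)
    p_mid = np.mean(noise_mid[: n_win * wlen].reshape(n_win, wlen) ** 2, axis=1)
    p_noise = np.maximum(p_hi / (nyq - f_lo), p_mid / 4.0) * bw

    with np.errstate(divide="ignore", invalid="ignore"):
        sqi = 10.0 * np.log10(p_band / p_noise)
    sqi[(p_band <= 0)] = -np.inf
    sqi[(p_noise <= 0) & (p_band > 0)] = np.inf
    valid = np.isfinite(sqi) & d.valid
    return SQISeries(values=sqi, window_length=window, valid=valid,
                     channel_id=channel_id)
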