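"""Synthetic radar-bed recordings with known ground truth.

Generates multi-channel complex-baseband (I/Q) time series that mimic what a
24-GHz continuous-wave radar mounted under a hospital bed observes: chest
displacement composed of millimetre-scale respiration, micrometre-scale S1/S2
heart-sound vibrations, occasional motion artifacts, and empty-bed gaps —
plus a jittered beat-synchronous reference channel standing in for an ECG
ground truth.  Every recording carries its full ground truth so each stage of
the downstream pipeline can be validated quantitatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dsp import IQSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ReferenceBeats",
    "SyntheticRecording",
    "generate_beat_times",
    "synthesize_displacement",
    "modulate_iq",
    "generate_reference_beats",
    "simulate_recording",
    "write_recording",
    "read_recording",
]

# 24 GHz carrier -> lambda = c/f = 12.49 mm
DEFAULT_WAVELENGTH_MM = 12.49

#: fraction of the IBI after S1 at which S2 is centred (systolic fraction)
S2_FRACTION = 0.33

#: Gabor wavelet parameters for heart-sound morphology: centre frequency in
#: the middle of the 16-80 Hz heart-sound band, ~100 ms total duration.
S1_CENTER_HZ = 40.0
S1_SIGMA_S = 0.1 / 6.0  # Gaussian envelope; +-3 sigma spans ~100 ms

#: deterministic per-channel displacement gain (geometry: modules sit at
#: different offsets from the chest, so they see different amplitudes)
CHANNEL_GAINS = (1.0, 0.85, 0.7, 0.55)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic radar-bed recording.

    Amplitudes are physical: respiration in mm, heart sounds in um.  Per
    channel SNR is the ratio of carrier power to complex noise power in dB.
    """

    duration: float = 300.0           # s
    n_channels: int = 4
    sampling_rate: float = 2000.0     # Hz
    carrier_wavelength: float = DEFAULT_WAVELENGTH_MM  # mm
    base_hr: float = 75.0             # bpm
    hrv_sd: float = 2.0               # bpm, white beat-to-beat variability
    drift_innovation_sd: float | None = None  # bpm, AR(1) innovation; default 0.05*hrv_sd
    resp_rate: float = 14.0           # breaths/min
    resp_amplitude: float = 1.0       # mm
    s1_amplitude: float = 30.0        # um
    s2_amplitude: float = 15.0        # um
    channel_snr: tuple = (30.0, 20.0, 15.0, 10.0)  # dB per channel
    artifact_rate: float = 6.0        # events/hour
    absence_intervals: tuple = ()     # list of [start, end) seconds
    ves_fraction: float = 0.0         # fraction of beats with VES-disturbed IBIs
    sves_fraction: float = 0.0
    trend_knots: tuple = ()           # optional (time_s, bpm_offset) knots
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError("duration must be positive and finite")
        if self.sampling_rate < 200.0:
            raise ValueError(
                "sampling_rate must be >= 200 Hz (margin over the 80 Hz band edge)"
            )
        if not np.isfinite(self.base_hr) or self.base_hr <= 0:
            raise ValueError("base_hr must be positive and finite")
        if self.carrier_wavelength <= 0:
            raise ValueError("carrier_wavelength must be positive")
        if not 0.0 <= self.ves_fraction + self.sves_fraction < 1.0:
            raise ValueError("ves_fraction + sves_fraction must be in [0, 1)")
        for name in ("resp_amplitude", "s1_amplitude", "s2_amplitude", "hrv_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.channel_snr) < self.n_channels:
            raise ValueError("channel_snr must provide one value per channel")

    def channel_gain(self, channel: int) -> float:
        if channel < len(CHANNEL_GAINS):
            return CHANNEL_GAINS[channel]
        return CHANNEL_GAINS[-1]


@dataclass
class GroundTruth:
    """True beat structure underlying a synthetic recording."""

    beat_times: np.ndarray          # S1 onsets, s, strictly increasing
    s2_offsets: np.ndarray          # s after each S1
    true_hr: np.ndarray             # bpm on a 1-s grid
    beat_labels: np.ndarray         # 'normal' | 'VES' | 'SVES' per beat
    artifact_intervals: list = field(default_factory=list)
    absence_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.s2_offsets = np.asarray(self.s2_offsets, dtype=float)
        self.beat_labels = np.asarray(self.beat_labels)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.beat_labels.shape != self.beat_times.shape:
            raise ValueError("beat_labels must align 1:1 with beat_times")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def n_affected_ibis(self) -> int:
        """Number of IBIs perturbed by extrasystoles (two per event)."""
        n_events = int(np.sum(self.beat_labels != "normal"))
        return 2 * n_events


@dataclass
class ReferenceBeats:
    """Beat-synchronous reference channel (emulated ECG annotations)."""

    times: np.ndarray               # s
    resolution_hz: float = 1000.0   # nominal digitisation rate of the reference

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class SyntheticRecording:
    channels: list                  # list[IQSeries]
    ground_truth: GroundTruth
    reference_beats: ReferenceBeats
    config: SimulationConfig

    def __post_init__(self) -> None:
        n = {ch.samples.size for ch in self.channels}
        fs = {ch.sampling_rate for ch in self.channels}
        if len(n) > 1 or len(fs) > 1:
            raise ValueError("all channels must share duration and sampling rate")


# ---------------------------------------------------------------------------
# beat model
# ---------------------------------------------------------------------------

def _hr_profile(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Mean heart rate on a 1-s grid: base + AR(1) drift + optional trend."""
    n = int(np.ceil(config.duration)) + 2
    drift = np.empty(n)
    drift[0] = 0.0
    innov_sd = (config.drift_innovation_sd if config.drift_innovation_sd is not None
                else 0.05 * config.hrv_sd)
    innov = rng.normal(0.0, innov_sd, size=n)
    for k in range(1, n):
        drift[k] = 0.99 * drift[k - 1] + innov[k]
    hr = config.base_hr + drift
    if config.trend_knots:
        knots = np.asarray(config.trend_knots, dtype=float)
        hr = hr + np.interp(np.arange(n), knots[:, 0], knots[:, 1],
                            left=knots[0, 1], right=knots[-1, 1])
    return np.clip(hr, 30.0, 200.0)


def generate_beat_times(config: SimulationConfig) -> GroundTruth:
    """Draw ground-truth S1 times from the stochastic heart-rate profile.

    Each IBI is 60/HR with HR = base + slow AR(1) drift + white Gaussian
    beat-to-beat variability of SD ``hrv_sd`` (clipped to [30, 200] bpm).
    Ventricular extrasystoles arrive early by 40% of the preceding IBI and
    are followed by a compensatory pause; supraventricular ones arrive 20%
    early.  Each event therefore perturbs the two adjacent IBIs, so
    ``ves_fraction`` (the target fraction of *affected* beats) maps to
    ``ves_fraction * n / 2`` injected events.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EA7]))
    hr_grid = _hr_profile(config, rng)

    times = []
    t = float(rng.uniform(0.05, 0.6))
    while t < config.duration:
        mean_hr = hr_grid[min(int(t), hr_grid.size - 1)]
        hr_inst = float(np.clip(mean_hr + rng.normal(0.0, config.hrv_sd), 30.0, 200.0))
        times.append(t)
        t += 60.0 / hr_inst
    beat_times = np.asarray(times)
    n = beat_times.size
    labels = np.full(n, "normal", dtype=object)

    # extrasystoles: shift the event beat earlier, preserving the following
    # beat time (short IBI + compensatory pause; total time conserved)
    for frac, label, advance in ((config.ves_fraction, "VES", 0.40),
                                 (config.sves_fraction, "SVES", 0.20)):
        n_events = int(round(frac * n / 2.0))
        if n_events == 0 or n < 4:
            continue
        candidates = np.arange(1, n - 1)
        candidates = candidates[labels[candidates] == "normal"]
        rng.shuffle(candidates)
        chosen: list[int] = []
        taken = set()
        for idx in candidates:
            if len(chosen) >= n_events:
                break
            if {idx - 1, idx, idx + 1} & taken:
                continue
            chosen.append(int(idx))
            taken.update((idx - 1, idx, idx + 1))
        for idx in chosen:
            prev_ibi = beat_times[idx] - beat_times[idx - 1]
            beat_times[idx] -= advance * prev_ibi
            labels[idx] = label

    ibis = np.diff(beat_times)
    s2 = np.empty(n)
    s2[:-1] = S2_FRACTION * ibis
    s2[-1] = S2_FRACTION * (ibis[-1] if n > 1 else 60.0 / config.base_hr)

    true_hr = hr_grid[: int(np.ceil(config.duration))]
    return GroundTruth(
        beat_times=beat_times,
        s2_offsets=s2,
        true_hr=true_hr,
        beat_labels=labels,
        absence_intervals=[list(iv) for iv in config.absence_intervals],
    )


# ---------------------------------------------------------------------------
# chest-surface displacement
# ---------------------------------------------------------------------------

def _gabor(t: np.ndarray, center: float, amplitude: float,
           f0: float = S1_CENTER_HZ, sigma: float = S1_SIGMA_S) -> np.ndarray:
    u = t - center
    return amplitude * np.exp(-0.5 * (u / sigma) ** 2) * np.cos(2 * np.pi * f0 * u)


def synthesize_displacement(truth: GroundTruth, config: SimulationConfig,
                            channel: int = 0) -> np.ndarray:
    """Chest displacement seen by one radar module, in micrometres.

    Respiration sinusoid (mm scale) + per-beat S1/S2 Gabor wavelets (um
    scale, channel-specific gain) + occasional motion artifacts; identically
    zero during absence intervals.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    gain = config.channel_gain(channel)

    d = np.zeros(n)
    if config.resp_amplitude > 0:
        f_resp = config.resp_rate / 60.0
        d += 1000.0 * config.resp_amplitude * np.sin(2 * np.pi * f_resp * t)

    half = 4.0 * S1_SIGMA_S  # wavelet support half-width
    for bt, s2off in zip(truth.beat_times, truth.s2_offsets):
        for center, amp in ((bt, config.s1_amplitude),
                            (bt + s2off, config.s2_amplitude)):
            if amp <= 0:
                continue
            i0 = max(0, int((center - half) * fs))
            i1 = min(n, int((center + half) * fs) + 1)
            if i1 > i0:
                d[i0:i1] += gain * _gabor(t[i0:i1], center, amp)

    # motion artifacts: mm-scale smooth bumps, Poisson arrivals.  Body
    # movement is common-mode — the same events hit every channel, scaled
    # by the channel gain — so the event stream is channel-independent.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA27]))
    n_art = rng.poisson(config.artifact_rate * config.duration / 3600.0)
    artifact_intervals = []
    for _ in range(n_art):
        tc = rng.uniform(0.0, config.duration)
        width = rng.uniform(0.2, 0.8)
        amp_mm = rng.uniform(1.0, 4.0) * rng.choice([-1.0, 1.0])
        i0 = max(0, int((tc - 4 * width) * fs))
        i1 = min(n, int((tc + 4 * width) * fs) + 1)
        if i1 > i0:
            u = t[i0:i1] - tc
            d[i0:i1] += 1000.0 * gain * amp_mm * np.exp(-0.5 * (u / width) ** 2)
        artifact_intervals.append([max(0.0, tc - 4 * width),
                                   min(config.duration, tc + 4 * width)])
    truth.artifact_intervals = sorted(artifact_intervals)

    for start, end in config.absence_intervals:
        i0, i1 = max(0, int(start * fs)), min(n, int(end * fs))
        d[i0:i1] = 0.0
    return d


# ---------------------------------------------------------------------------
# I/Q modulation
# ---------------------------------------------------------------------------

def modulate_iq(displacement_um: np.ndarray, config: SimulationConfig,
                channel: int = 0) -> IQSeries:
    """Map displacement onto complex baseband via CW interferometry.

    I/Q = A*exp(i * 4*pi*d / lambda) + DC offset + circular Gaussian noise
    scaled to the channel's SNR.  The phase-displacement relation is the
    exact inverse of :func:`radarhr.dsp.demodulate_displacement`.

    SNR is carrier power over noise power in a 1-kHz reference bandwidth
    (a noise *density*), so the in-band noise seen by the heart-sound
    filter does not depend on the chosen sampling rate.
    """
    snr_db = config.channel_snr[channel]
    if not np.isfinite(snr_db):
        noise_power = 0.0
    else:
        noise_power = 10.0 ** (-snr_db / 10.0) * config.sampling_rate / 1000.0
        if noise_power < 0:
            raise ValueError("SNR amplitude scaling must be positive")

    d_mm = np.asarray(displacement_um, dtype=float) / 1000.0
    phase = 4.0 * np.pi * d_mm / config.carrier_wavelength
    z = np.exp(1j * phase)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x10, channel]))
    offset = 0.5 * np.exp(1j * 2 * np.pi * rng.uniform())
    z = z + offset
    if noise_power > 0:
        sd = np.sqrt(noise_power / 2.0)
        z = z + rng.normal(0.0, sd, z.size) + 1j * rng.normal(0.0, sd, z.size)

    return IQSeries(
        samples=z,
        sampling_rate=config.sampling_rate,
        carrier_wavelength=config.carrier_wavelength,
        channel_id=channel,
    )


# ---------------------------------------------------------------------------
# reference channel
# ---------------------------------------------------------------------------

def generate_reference_beats(truth: GroundTruth, jitter_sd: float = 0.0,
                             seed: int = 0) -> ReferenceBeats:
    """Reference beat times = truth + Gaussian jitter (``jitter_sd`` in ms).

    Beats inside absence intervals are dropped (the reference device sees no
    subject either).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    times = truth.beat_times.copy()
    if jitter_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEC6]))
        times = times + rng.normal(0.0, jitter_sd / 1000.0, times.size)
        times = np.sort(times)
    mask = np.ones(times.size, dtype=bool)
    for start, end in truth.absence_intervals:
        mask &= ~((times >= start) & (times < end))
    return ReferenceBeats(times=times[mask])


# ---------------------------------------------------------------------------
# full recording
# ---------------------------------------------------------------------------

def simulate_recording(config: SimulationConfig,
                       ref_jitter_ms: float = 5.0) -> SyntheticRecording:
    """Generate all channels plus ground truth and the reference channel."""
    truth = generate_beat_times(config)
    channels = []
    for c in range(config.n_channels):
        d = synthesize_displacement(truth, config, channel=c)
        channels.append(modulate_iq(d, config, channel=c))
    ref = generate_reference_beats(truth, jitter_sd=ref_jitter_ms, seed=config.seed)
    return SyntheticRecording(channels=channels, ground_truth=truth,
                              reference_beats=ref, config=config)


# ---------------------------------------------------------------------------
# file I/O (CSV per channel + ground truth + JSON sidecar)
# ---------------------------------------------------------------------------

def write_recording(rec: SyntheticRecording, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch in rec.channels:
        n = ch.samples.size
        t = np.arange(n) / ch.sampling_rate
        data = np.column_stack([t, ch.samples.real, ch.samples.imag])
        np.savetxt(outdir / f"channel_{ch.channel_id}.csv", data,
                   delimiter=",", header="time_s,i,q", comments="", fmt="%.9g")
    with open(outdir / "ground_truth.csv", "w") as fh:
        fh.write("beat_time_s,label\n")
        for bt, lab in zip(rec.ground_truth.beat_times, rec.ground_truth.beat_labels):
            fh.write(f"{bt:.6f},{lab}\n")
    with open(outdir / "reference_beats.csv", "w") as fh:
        fh.write("beat_time_s\n")
        for bt in rec.reference_beats.times:
            fh.write(f"{bt:.6f}\n")
    cfg = asdict(rec.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
    return outdir


def read_recording(indir: str | Path) -> SyntheticRecording:
    indir = Path(indir)
    with open(indir / "config.json") as fh:
        cfg = json.load(fh)
    for k in ("channel_snr", "absence_intervals", "trend_knots"):
        if k in cfg:
            cfg[k] = tuple(tuple(v) if isinstance(v, list) else v for v in cfg[k])
    config = SimulationConfig(**cfg)

    channels = []
    for c in range(config.n_channels):
        path = indir / f"channel_{c}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing channel file: {path}")
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        channels.append(IQSeries(samples=arr[:, 1] + 1j * arr[:, 2],
                                 sampling_rate=config.sampling_rate,
                                 carrier_wavelength=config.carrier_wavelength,
                                 channel_id=c))
    gt = np.genfromtxt(indir / "ground_truth.csv", delimiter=",",
                       skip_header=1, dtype=None, encoding="utf-8")
    gt = np.atleast_1d(gt)
    beat_times = np.array([row[0] for row in gt], dtype=float)
    labels = np.array([row[1] for row in gt], dtype=object)
    ibis = np.diff(beat_times)
    s2 = np.empty(beat_times.size)
    if ibis.size:
        s2[:-1] = S2_FRACTION * ibis
        s2[-1] = S2_FRACTION * ibis[-1]
    truth = GroundTruth(beat_times=beat_times, s2_offsets=s2,
                        true_hr=np.full(int(np.ceil(config.duration)), config.base_hr),
                        beat_labels=labels,
                        absence_intervals=[list(iv) for iv in config.absence_intervals])
    ref_times = np.loadtxt(indir / "reference_beats.csv", skiprows=1, ndmin=1)
    ref = ReferenceBeats(times=ref_times)
    return SyntheticRecording(channels=channels, ground_truth=truth,
                              reference_beats=ref, config=config)
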