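"""S1/S2 heart-sound detection with a duration-constrained HSMM.

The decoder models the cardiac cycle as the fixed four-state loop
S1 -> systole -> S2 -> diastole -> S1 with Gaussian state-duration
distributions anchored to a coarse autocorrelation-based heart-rate
estimate, and Gaussian emissions over envelope features of the 16-80 Hz
heart-sound signal.  A duration-dependent Viterbi pass returns the
maximum-likelihood state sequence; S1/S2 event times are the midpoints of
the decoded sound segments.  Interbeat intervals (IBIs) are the times
between consecutive S1 events.

No parameters are fitted: the duration and emission parameters are fixed
heuristics (configuration, not training), which also means arrhythmic beats
with altered heart-sound morphology are out of model — a documented
limitation mirrored by the annotation-driven exclusions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .dsp import HeartSoundSignal, SQISeries

__all__ = [
    "EnvelopeFeatures",
    "HSMMModel",
    "BeatSequence",
    "CoarseHR",
    "extract_envelope_features",
    "coarse_hr_estimate",
    "build_hsmm_model",
    "hsmm_segment",
    "compute_ibis",
    "select_best_channel",
    "merge_beats",
]

#: feature/decoding frame rate, Hz
FEATURE_RATE = 50.0

# state indices, fixed cycle order
S1, SYS, S2, DIA = 0, 1, 2, 3
STATE_NAMES = ("S1", "systole", "S2", "diastole")


@dataclass
class EnvelopeFeatures:
    """Homomorphic + analytic-signal envelopes at the decoding frame rate.

    Both envelopes are z-scored over the segment they were extracted from.
    """

    homomorphic: np.ndarray
    analytic: np.ndarray
    frame_rate: float = FEATURE_RATE
    t0: float = 0.0                  # absolute time of the first frame, s

    def __post_init__(self) -> None:
        self.homomorphic = np.asarray(self.homomorphic, dtype=float)
        self.analytic = np.asarray(self.analytic, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.homomorphic.size)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class CoarseHR:
    bpm: float
    low_confidence: bool = False


@dataclass
class HSMMModel:
    """Four-state model: per-state Gaussian durations (s) and emissions.

    Sound states (S1, S2) expect high envelopes, interval states low ones.
    Systole and diastole duration means are tied to the coarse heart period.
    """

    dur_mean: np.ndarray             # s, per state
    dur_sd: np.ndarray               # s, per state
    dur_max: np.ndarray              # s, caps (mean + 3 sd)
    emit_mean: np.ndarray            # (4, 2): per state, per feature
    emit_sd: np.ndarray              # (4, 2)
    emission_weight: float = 0.3     # tempering of the emission loglik

    def __post_init__(self) -> None:
        if np.any(self.dur_sd <= 0):
            raise ValueError("duration SDs must be positive")
        if self.emission_weight <= 0:
            raise ValueError("emission_weight must be positive")


def build_hsmm_model(coarse_hr: float) -> HSMMModel:
    """Heuristic parameterization anchored to the coarse heart period T.

    S1 lasts 120 +- 25 ms, S2 90 +- 25 ms; systole (S1 onset to S2 onset,
    minus the S1 sound) has mean 0.33*T - 120 ms and diastole takes the
    remainder of the cycle.  Caps at mean + 3 SD keep the Viterbi search
    bounded.  The emission log-likelihood is tempered (weight < 1) so the
    duration model — the reliable rhythm prior — dominates when the
    envelopes are noisy.
    """
    if not 30.0 <= coarse_hr <= 180.0:
        raise ValueError("coarse_hr must lie in [30, 180] bpm")
    t_cycle = 60.0 / coarse_hr
    dur_mean = np.array([
        0.120,
        max(0.33 * t_cycle - 0.120, 0.04),
        0.090,
        max(0.67 * t_cycle - 0.090, 0.06),
    ])
    dur_sd = np.array([0.025, max(0.05 * t_cycle, 0.02), 0.025,
                       max(0.10 * t_cycle, 0.03)])
    dur_max = dur_mean + 3.0 * dur_sd
    emit_mean = np.array([
        [1.5, 1.5],      # S1: strong envelope
        [-0.5, -0.5],    # systole: quiescent
        [0.8, 0.8],      # S2: weaker sound
        [-0.5, -0.5],    # diastole: quiescent
    ])
    emit_sd = np.full((4, 2), 1.0)
    return HSMMModel(dur_mean=dur_mean, dur_sd=dur_sd, dur_max=dur_max,
                     emit_mean=emit_mean, emit_sd=emit_sd)


@dataclass
class BeatSequence:
    """Detected S1/S2 events and the IBIs between consecutive S1."""

    s1_times: np.ndarray             # s, strictly increasing
    s2_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ibis: np.ndarray = field(default_factory=lambda: np.empty(0))
    source_channel: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.s1_times = np.asarray(self.s1_times, dtype=float)
        self.s2_times = np.asarray(self.s2_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        self.source_channel = np.asarray(self.source_channel, dtype=int)
        if self.s1_times.size > 1 and np.any(np.diff(self.s1_times) <= 0):
            raise ValueError("s1_times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.s1_times.size)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_envelope_features(hs: HeartSoundSignal,
                              frame_rate: float = FEATURE_RATE,
                              t0: float = 0.0) -> EnvelopeFeatures:
    """Homomorphic and analytic-signal envelopes, resampled and z-scored.

    The homomorphic envelope low-passes (first-order Butterworth, 8 Hz) the
    log of the analytic envelope and re-exponentiates, which smooths the
    oscillatory fine structure while preserving sound-burst timing.
    """
    x = np.asarray(hs.values, dtype=float)
    if x.size == 0:
        empty = np.empty(0)
        return EnvelopeFeatures(empty, empty, frame_rate, t0)
    env = np.abs(signal.hilbert(x))
    eps = 1e-12 + 1e-6 * float(np.max(env))
    sos = signal.butter(1, 8.0, btype="lowpass", fs=hs.sampling_rate, output="sos")
    hom = np.exp(signal.sosfiltfilt(sos, np.log(env + eps)))

    n_frames = int(np.floor(x.size / hs.sampling_rate * frame_rate))
    t_frames = (np.arange(n_frames) + 0.5) / frame_rate
    t_src = np.arange(x.size) / hs.sampling_rate
    hom_f = np.interp(t_frames, t_src, hom)
    ana_f = np.interp(t_frames, t_src, env)

    def robust_z(v: np.ndarray) -> np.ndarray:
        # median/MAD scaling with clipping: a single motion artifact must
        # not compress the heart-sound peaks of the rest of the window
        med = np.median(v)
        scale = 1.4826 * np.median(np.abs(v - med))
        if scale <= 0:
            scale = v.std()
        if scale <= 0:
            return np.zeros_like(v)
        return np.clip((v - med) / scale, -4.0, 10.0)

    return EnvelopeFeatures(robust_z(hom_f), robust_z(ana_f), frame_rate, t0)


# ---------------------------------------------------------------------------
# coarse heart rate
# ---------------------------------------------------------------------------

def coarse_hr_estimate(features: EnvelopeFeatures,
                       min_bpm: float = 30.0, max_bpm: float = 180.0,
                       min_peak: float = 0.2) -> CoarseHR:
    """Average HR from the autocorrelation of the homomorphic envelope.

    The peak lag is searched in [60/max_bpm, 60/min_bpm] seconds (default
    [0.33, 2.0] s, i.e. 30-180 bpm) with parabolic refinement.  If no
    normalized autocorrelation peak exceeds ``min_peak`` the estimate falls
    back to 75 bpm with a low-confidence flag.
    """
    if features.duration < 10.0:
        raise ValueError("need at least 10 s of features for a coarse HR estimate")
    x = features.homomorphic - features.homomorphic.mean()
    if np.all(x == 0):
        return CoarseHR(75.0, low_confidence=True)
    ac = signal.correlate(x, x, mode="full")[x.size - 1:]
    ac = ac / ac[0]
    fr = features.frame_rate
    lag_lo = int(np.ceil(60.0 / max_bpm * fr))
    lag_hi = min(int(np.floor(60.0 / min_bpm * fr)), ac.size - 2)
    if lag_hi <= lag_lo:
        return CoarseHR(75.0, low_confidence=True)
    seg = ac[lag_lo:lag_hi + 1]
    k = int(np.argmax(seg))
    if seg[k] < min_peak:
        return CoarseHR(75.0, low_confidence=True)
    lag = lag_lo + k
    # octave-error correction: if half the period is almost as strong,
    # the peak is a sub-harmonic — prefer the fundamental
    while lag // 2 >= lag_lo:
        half = lag // 2
        window = ac[max(lag_lo, half - 2):half + 3]
        if window.max() >= 0.7 * ac[lag]:
            lag = max(lag_lo, half - 2) + int(np.argmax(window))
        else:
            break
    # parabolic sub-frame refinement
    if 0 < lag < ac.size - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    bpm = float(np.clip(60.0 * fr / lag, min_bpm, max_bpm))
    return CoarseHR(bpm, low_confidence=False)


# ---------------------------------------------------------------------------
# duration-dependent Viterbi
# ---------------------------------------------------------------------------

def _log_duration_tables(model: HSMMModel, fr: float) -> list[np.ndarray]:
    """Discretized, normalized log duration pmfs per state (index d-1)."""
    tables = []
    for j in range(4):
        d_max = max(2, int(round(model.dur_max[j] * fr)))
        d = np.arange(1, d_max + 1)
        logp = -0.5 * ((d / fr - model.dur_mean[j]) / model.dur_sd[j]) ** 2
        p = np.exp(logp - logp.max())
        p /= p.sum()
        tables.append(np.log(np.maximum(p, 1e-300)))
    return tables


def hsmm_segment(features: EnvelopeFeatures, coarse_hr: float,
                 model: HSMMModel | None = None,
                 source_channel: int = -1) -> BeatSequence:
    """Maximum-likelihood S1/S2 segmentation by duration-dependent Viterbi.

    The decoded state sequence always follows the fixed cycle
    S1 -> systole -> S2 -> diastole.  S1 (S2) event times are the midpoints
    of the decoded S1 (S2) segments, shifted by the features' ``t0``.
    Windows shorter than one mean cycle yield an empty sequence.
    """
    if model is None:
        model = build_hsmm_model(coarse_hr)
    fr = features.frame_rate
    n = features.n_frames
    if n == 0 or features.duration < 60.0 / coarse_hr:
        return BeatSequence(s1_times=np.empty(0))

    obs = np.column_stack([features.homomorphic, features.analytic])
    # per-state Gaussian log emission, (4, n)
    logb = np.empty((4, n))
    for j in range(4):
        z = (obs - model.emit_mean[j]) / model.emit_sd[j]
        logb[j] = -0.5 * np.sum(z * z, axis=1) - np.sum(np.log(model.emit_sd[j]))
    logb *= model.emission_weight
    # cumulative sums for O(1) segment emission scores
    cumb = np.zeros((4, n + 1))
    np.cumsum(logb, axis=1, out=cumb[:, 1:])

    logdur = _log_duration_tables(model, fr)
    d_maxs = [t.size for t in logdur]
    prev_state = [DIA, S1, SYS, S2]

    neg_inf = -np.inf
    delta = np.full((n + 1, 4), neg_inf)
    delta[0, :] = 0.0                     # any state may start at frame 0
    best_d = np.zeros((n + 1, 4), dtype=np.int32)

    for t in range(1, n + 1):
        for j in range(4):
            dm = min(d_maxs[j], t)
            ds = np.arange(1, dm + 1)
            scores = (delta[t - ds, prev_state[j]]
                      + logdur[j][:dm]
                      + (cumb[j, t] - cumb[j, t - ds]))
            k = int(np.argmax(scores))
            delta[t, j] = scores[k]
            best_d[t, j] = k + 1

    # backtrack
    j = int(np.argmax(delta[n]))
    t = n
    segments = []                          # (state, start_frame, end_frame)
    while t > 0:
        d = int(best_d[t, j])
        segments.append((j, t - d, t))
        t -= d
        j = prev_state[j]
    segments.reverse()

    s1_times, s2_times = [], []
    for state, a, b in segments:
        mid = features.t0 + (a + b) / 2.0 / fr
        if state == S1:
            s1_times.append(mid)
        elif state == S2:
            s2_times.append(mid)
    s1 = np.asarray(s1_times)
    beats = BeatSequence(
        s1_times=s1,
        s2_times=np.asarray(s2_times),
        source_channel=np.full(s1.size, source_channel, dtype=int),
    )
    return compute_ibis(beats)


# ---------------------------------------------------------------------------
# IBIs
# ---------------------------------------------------------------------------

def compute_ibis(beats: BeatSequence) -> BeatSequence:
    """Fill ``ibis`` with successive S1 differences (length n_beats - 1)."""
    if beats.s1_times.size > 1 and np.any(np.diff(beats.s1_times) <= 0):
        raise ValueError("s1_times must be strictly increasing")
    beats.ibis = np.diff(beats.s1_times)
    return beats


# ---------------------------------------------------------------------------
# channel selection
# ---------------------------------------------------------------------------

def select_best_channel(sqis: list[SQISeries]) -> np.ndarray:
    """Per-window argmax of SQI across channels; ties -> lowest index.

    Windows where no channel has a valid SQI (e.g. absence) are marked -1.
    All series must share the window grid.
    """
    if not sqis:
        raise ValueError("need at least one channel")
    wl = {s.window_length for s in sqis}
    if len(wl) > 1:
        raise ValueError("SQI series must share the window length")
    n = min(s.values.size for s in sqis)
    vals = np.vstack([np.where(s.valid[:n], s.values[:n], -np.inf) for s in sqis])
    choice = np.argmax(vals, axis=0)      # argmax takes the first maximum on ties
    choice = np.where(np.all(np.isneginf(vals), axis=0), -1, choice)
    return choice.astype(int)


def merge_beats(parts: list[BeatSequence], min_separation: float = 0.25) -> BeatSequence:
    """Concatenate per-window beat sequences into one global sequence.

    Events closer than ``min_separation`` (duplicates at window seams) are
    collapsed, keeping the earlier one.
    """
    if not parts:
        return BeatSequence(s1_times=np.empty(0))
    s1 = np.concatenate([p.s1_times for p in parts])
    ch = np.concatenate([p.source_channel for p in parts])
    s2 = np.concatenate([p.s2_times for p in parts])
    order = np.argsort(s1, kind="stable")
    s1, ch = s1[order], ch[order]
    keep = np.ones(s1.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(s1):
        if t - last < min_separation:
            keep[i] = False
        else:
            last = t
    beats = BeatSequence(s1_times=s1[keep], s2_times=np.sort(s2),
                         source_channel=ch[keep])
    return compute_ibis(beats)
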