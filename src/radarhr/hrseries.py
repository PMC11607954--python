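"""Heart-rate series: aggregation, pairing, and exclusion rules.

IBIs from the beat detector are aggregated into the three HR series used in
the validation arms (5-min interval means, rolling 10-beat means, 30-beat or
30-s block means), paired against the reference series, and cleaned by the
exclusion rules: missing-radar intervals, half/double detection failures,
annotation-driven beat exclusion, and the two-stage global/local outlier
filter for long-term unvalidated monitoring.

A HR value over a set of IBIs is always 60 / mean(IBI) — the mean of the
intervals, not the mean of instantaneous rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import BeatSequence
from .dsp import PresenceSeries

__all__ = [
    "HRSeries",
    "PairedHRSeries",
    "AnnotationSet",
    "interval_mean_hr",
    "rolling_mean_hr",
    "block_mean_hr",
    "synchronize_pairs",
    "exclude_half_double",
    "apply_annotations",
    "annotation_burden",
    "should_exclude_patient",
    "global_outlier_filter",
    "local_outlier_filter",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = ("none", "missing_radar", "half_double",
                     "arrhythmia_label", "noisy_reference", "absent")

ANNOTATION_LABELS = ("wrong_detection", "noisy", "VES", "SVES", "other_arrhythmia")
ARRHYTHMIA_LABELS = ("VES", "SVES", "other_arrhythmia")


@dataclass
class HRSeries:
    """Timestamped HR values with their aggregation rule and validity mask."""

    timestamps: np.ndarray          # s
    hr: np.ndarray                  # bpm
    aggregation: str                # interval_5min | rolling_10beat | block_30beat | block_30s
    valid: np.ndarray = field(default=None)
    n_beats: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.hr)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.n_beats is None:
            self.n_beats = np.zeros(self.hr.size, dtype=int)
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if np.any(self.hr[self.valid] <= 0):
            raise ValueError("valid HR values must be positive")


@dataclass
class PairedHRSeries:
    """Time-aligned (radar, reference) HR pairs with exclusion bookkeeping.

    ``diff`` is radar - reference.  Excluded pairs carry exactly one reason
    and never enter statistics (``valid_diffs`` filters them out).
    """

    frame: pd.DataFrame             # columns: t, radar_hr, ref_hr, diff, exclusion_reason

    def __post_init__(self) -> None:
        required = {"t", "radar_hr", "ref_hr", "diff", "exclusion_reason"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"pairs frame must have columns {sorted(required)}")

    @property
    def n_pairs(self) -> int:
        return int(len(self.frame))

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["exclusion_reason"] == "none"]

    def valid_diffs(self) -> np.ndarray:
        return self.included["diff"].to_numpy()

    def exclusion_counts(self) -> dict:
        counts = self.frame["exclusion_reason"].value_counts().to_dict()
        return {r: int(counts.get(r, 0)) for r in EXCLUSION_REASONS}

    def copy(self) -> "PairedHRSeries":
        return PairedHRSeries(self.frame.copy())


@dataclass
class AnnotationSet:
    """Per-beat reference annotations (indices into the reference beats)."""

    frame: pd.DataFrame             # columns: beat_index, label

    def __post_init__(self) -> None:
        bad = set(self.frame["label"]) - set(ANNOTATION_LABELS)
        if bad:
            raise ValueError(f"unknown annotation labels: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationSet":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: list[tuple[int, str]]) -> "AnnotationSet":
        return cls(pd.DataFrame(records, columns=["beat_index", "label"]))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _ibis_inside(beats: BeatSequence, start: float, end: float) -> np.ndarray:
    """IBIs whose both endpoint beats fall inside [start, end)."""
    s1 = beats.s1_times
    if s1.size < 2:
        return np.empty(0)
    a, b = s1[:-1], s1[1:]
    mask = (a >= start) & (b < end)
    return beats.ibis[mask]


def interval_mean_hr(beats: BeatSequence, width: float = 300.0,
                     duration: float | None = None,
                     presence: PresenceSeries | None = None,
                     min_ibis: int = 10) -> HRSeries:
    """Mean HR per half-open interval of ``width`` seconds (default 5 min).

    HR = 60 / mean(IBIs fully inside the interval).  Intervals with fewer
    than ``min_ibis`` IBIs, or during which the subject was not present,
    are marked invalid.
    """
    if duration is None:
        duration = float(beats.s1_times[-1]) if beats.n_beats else 0.0
    n_int = max(1, int(np.ceil(duration / width)))
    ts = np.arange(n_int) * width
    hr = np.full(n_int, np.nan)
    valid = np.zeros(n_int, dtype=bool)
    n_b = np.zeros(n_int, dtype=int)
    for i, t0 in enumerate(ts):
        ibis = _ibis_inside(beats, t0, t0 + width)
        n_b[i] = ibis.size
        if ibis.size >= min_ibis:
            hr[i] = 60.0 / ibis.mean()
            valid[i] = True
        if presence is not None:
            t_mid = np.arange(t0, min(t0 + width, duration), presence.window_length)
            if t_mid.size and presence.at(t_mid).mean() < 0.5:
                valid[i] = False
    return HRSeries(timestamps=ts, hr=hr, aggregation="interval_5min",
                    valid=valid, n_beats=n_b)


def rolling_mean_hr(beats: BeatSequence, k: int = 10) -> HRSeries:
    """Rolling mean HR over ``k`` IBIs, timestamped at each window's end beat.

    The value at beat i (i >= k) is 60 / mean(ibis[i-k..i)).
    """
    ibis = beats.ibis
    if ibis.size < k:
        return HRSeries(timestamps=np.empty(0), hr=np.empty(0),
                        aggregation="rolling_10beat")
    csum = np.concatenate([[0.0], np.cumsum(ibis)])
    means = (csum[k:] - csum[:-k]) / k
    hr = 60.0 / means
    ts = beats.s1_times[k:]
    return HRSeries(timestamps=ts, hr=hr, aggregation="rolling_10beat",
                    n_beats=np.full(hr.size, k))


def block_mean_hr(beats: BeatSequence, k: int = 30, mode: str = "beats",
                  width: float = 30.0, duration: float | None = None) -> HRSeries:
    """Non-overlapping block means: ``k`` beats per block or ``width``-second blocks."""
    if mode == "beats":
        ibis = beats.ibis
        n_blocks = ibis.size // k
        if n_blocks == 0:
            return HRSeries(timestamps=np.empty(0), hr=np.empty(0),
                            aggregation="block_30beat")
        blocks = ibis[: n_blocks * k].reshape(n_blocks, k)
        hr = 60.0 / blocks.mean(axis=1)
        ts = beats.s1_times[np.arange(n_blocks) * k]
        return HRSeries(timestamps=ts, hr=hr, aggregation="block_30beat",
                        n_beats=np.full(hr.size, k))
    if mode == "time":
        series = interval_mean_hr(beats, width=width, duration=duration, min_ibis=1)
        series.aggregation = "block_30s"
        return series
    raise ValueError("mode must be 'beats' or 'time'")


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def synchronize_pairs(radar: HRSeries, reference: HRSeries,
                      tolerance: float | None = None) -> PairedHRSeries:
    """Time-align radar and reference HR series on their common clock.

    Interval/block series pair by identical interval start; beat-wise
    (rolling) series pair each reference beat to the nearest radar beat
    within ``tolerance`` (default half the local reference IBI).  Reference
    points with no radar partner are kept with reason ``missing_radar`` so
    exclusion counts remain additive; radar values without a reference
    partner are dropped as unverifiable.
    """
    interval_like = radar.aggregation in ("interval_5min", "block_30s")
    rows = []
    if interval_like:
        radar_map = {round(float(t), 6): i for i, t in enumerate(radar.timestamps)}
        for j, t in enumerate(reference.timestamps):
            if not reference.valid[j]:
                continue
            i = radar_map.get(round(float(t), 6))
            if i is not None and radar.valid[i]:
                rows.append((t, radar.hr[i], reference.hr[j], "none"))
            else:
                rows.append((t, np.nan, reference.hr[j], "missing_radar"))
    else:
        rt = radar.timestamps[radar.valid]
        rv = radar.hr[radar.valid]
        ref_t = reference.timestamps
        local_ibi = np.empty(ref_t.size)
        if ref_t.size > 1:
            gaps = np.diff(ref_t)
            local_ibi[:-1] = gaps
            local_ibi[-1] = gaps[-1]
        else:
            local_ibi[:] = 1.0
        for j, t in enumerate(ref_t):
            if not reference.valid[j]:
                continue
            tol = tolerance if tolerance is not None else 0.5 * local_ibi[j]
            if rt.size:
                i = int(np.searchsorted(rt, t))
                cand = [c for c in (i - 1, i) if 0 <= c < rt.size]
                dists = [abs(rt[c] - t) for c in cand]
                best = cand[int(np.argmin(dists))] if cand else None
            else:
                best = None
            if best is not None and abs(rt[best] - t) <= tol:
                rows.append((t, rv[best], reference.hr[j], "none"))
            else:
                rows.append((t, np.nan, reference.hr[j], "missing_radar"))
    frame = pd.DataFrame(rows, columns=["t", "radar_hr", "ref_hr", "exclusion_reason"])
    frame["diff"] = frame["radar_hr"] - frame["ref_hr"]
    frame = frame[["t", "radar_hr", "ref_hr", "diff", "exclusion_reason"]]
    return PairedHRSeries(frame)


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def exclude_half_double(pairs: PairedHRSeries, tol: float = 0.10,
                        literal_difference: bool = False) -> PairedHRSeries:
    """Flag pairs where the radar HR sits at half or double the reference HR.

    Low SNR makes the segmenter miss or hallucinate every second heart
    sound, effectively halving or doubling the HR.  A pair is excluded when
    the radar HR lies within ``tol`` (relative) of reference/2 or of
    2*reference.  ``literal_difference=True`` switches to the variant that
    tests the *difference* radar-reference against +-tol of half/double of
    the reference HR.  Idempotent; only pairs with reason 'none' are touched.
    """
    out = pairs.copy()
    f = out.frame
    active = (f["exclusion_reason"] == "none") & f["radar_hr"].notna()
    radar = f.loc[active, "radar_hr"].to_numpy()
    ref = f.loc[active, "ref_hr"].to_numpy()
    if literal_difference:
        d = radar - ref
        hit = (np.abs(np.abs(d) - ref / 2.0) <= tol * (ref / 2.0)) | \
              (np.abs(np.abs(d) - 2.0 * ref) <= tol * (2.0 * ref))
    else:
        hit = (np.abs(radar - ref / 2.0) <= tol * (ref / 2.0)) | \
              (np.abs(radar - 2.0 * ref) <= tol * (2.0 * ref))
    idx = f.index[active][hit]
    out.frame.loc[idx, "exclusion_reason"] = "half_double"
    return out


def apply_annotations(pairs: PairedHRSeries, ann: AnnotationSet,
                      k: int = 10) -> PairedHRSeries:
    """Exclude annotated beats and every rolling value whose window touches them.

    A label on beat ``b`` taints the IBI starting at ``b``; the ``k`` rolling
    windows containing that IBI (pair rows ``b+1 .. b+k`` by position) are
    excluded — arrhythmia labels map to reason ``arrhythmia_label``, signal
    labels (wrong_detection, noisy) to ``noisy_reference``.
    """
    out = pairs.copy()
    n = len(out.frame)
    # pair row p corresponds to the rolling value ending at beat p + k
    idx = ann.frame["beat_index"].to_numpy()
    bad = idx[(idx < 0) | (idx >= n + k)]
    if bad.size:
        raise ValueError(f"annotation beat indices out of range: {bad.tolist()}")
    reasons = np.array(["" for _ in range(n)], dtype=object)
    for b, label in zip(ann.frame["beat_index"], ann.frame["label"]):
        reason = ("arrhythmia_label" if label in ARRHYTHMIA_LABELS
                  else "noisy_reference")
        # the label taints the IBI ending at beat b, which sits in the k
        # rolling windows ending at beats b .. b+k-1 (rows b-k .. b-1)
        for p in range(max(0, int(b) - k), min(n, int(b))):
            if reasons[p] != "arrhythmia_label":
                reasons[p] = reason
    active = (out.frame["exclusion_reason"] == "none").to_numpy()
    touched = (reasons != "") & active
    out.frame.loc[out.frame.index[touched], "exclusion_reason"] = reasons[touched]
    return out


def annotation_burden(ann: AnnotationSet, n_beats: int) -> float:
    """Fraction of beats with extrasystole-affected IBIs (two per event)."""
    events = ann.frame["label"].isin(ARRHYTHMIA_LABELS)
    affected = set()
    for b in ann.frame.loc[events, "beat_index"]:
        affected.update((int(b), int(b) + 1))
    return len(affected) / n_beats if n_beats else 0.0


def should_exclude_patient(ann: AnnotationSet, n_beats: int,
                           threshold: float = 0.20) -> bool:
    """Whole-patient exclusion when the arrhythmia burden reaches ``threshold``."""
    return annotation_burden(ann, n_beats) >= threshold


# ---------------------------------------------------------------------------
# outlier filters (long-term monitoring, two-stage)
# ---------------------------------------------------------------------------

def global_outlier_filter(hr: HRSeries, lo: float = 25.0,
                          hi: float = 220.0) -> HRSeries:
    """Invalidate physiologically impossible HR values outside [lo, hi] bpm."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    valid = hr.valid & (hr.hr >= lo) & (hr.hr <= hi)
    return HRSeries(timestamps=hr.timestamps, hr=hr.hr,
                    aggregation=hr.aggregation, valid=valid, n_beats=hr.n_beats)


def local_outlier_filter(hr: HRSeries, segment: int = 60, k: float = 3.0,
                         max_iter: int = 10,
                         abs_floor: float = 5.0) -> HRSeries:
    """Iterative per-segment median/MAD outlier removal.

    The series is split into fixed consecutive blocks of ``segment``
    positions (fixed blocks keep the segmentation — and hence the filter —
    idempotent); within each, valid points with |x - median| >
    max(k * 1.4826 * MAD, ``abs_floor``) are invalidated, and the pass
    repeats until nothing is removed or ``max_iter`` is reached.  The
    absolute floor handles the degenerate MAD = 0 case (constant segments
    lose nothing).
    """
    if segment < 5:
        raise ValueError("segment must be >= 5 values")
    valid = hr.valid.copy()
    for start in range(0, valid.size, segment):
        seg_idx = np.arange(start, min(start + segment, valid.size))
        for _ in range(max_iter):
            live = seg_idx[valid[seg_idx]]
            if live.size < 3:
                break
            x = hr.hr[live]
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            thr = max(k * 1.4826 * mad, abs_floor)
            out = np.abs(x - med) > thr
            if not out.any():
                break
            valid[live[out]] = False
    return HRSeries(timestamps=hr.timestamps, hr=hr.hr,
                    aggregation=hr.aggregation, valid=valid, n_beats=hr.n_beats)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_pairs_csv(pairs: PairedHRSeries, path: str | Path,
                     start_iso: str = "1970-01-01T00:00:00") -> None:
    """HR hand-off CSV: ISO timestamp + interval start + pair + verdict."""
    start = pd.Timestamp(start_iso)
    f = pairs.frame.copy()
    f.insert(0, "timestamp_iso",
             [(start + pd.Timedelta(seconds=float(t))).isoformat() for t in f["t"]])
    f = f.rename(columns={"t": "interval_start_s", "radar_hr": "hr_radar_bpm",
                          "ref_hr": "hr_ref_bpm", "diff": "diff_bpm"})
    f["valid"] = (f["exclusion_reason"] == "none").astype(int)
    f.to_csv(path, index=False, float_format="%.6f")
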