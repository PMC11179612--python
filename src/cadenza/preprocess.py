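"""Preprocessing of raw multichannel haemodynamic recordings.

Turns 500-samples/s waveforms (arterial BP, bilateral MCA blood velocity,
ECG, capnogram) into clean, beat-averaged series resampled on a uniform
5 Hz grid, ready for transfer-function and neurovascular-coupling analysis:

1. narrow-spike removal by linear interpolation (spikes < 100 ms),
2. zero-phase 8th-order Butterworth low-pass at 20 Hz,
3. median filtering of the velocity channels,
4. Finometer re-scaling against brachial cuff systolic/diastolic values,
5. R-wave detection on the ECG with a physiologic RR gate and a
   programmatic manual-correction hook,
6. beat-to-beat averaging over each cardiac cycle, per-breath end-tidal
   CO2 resampled to beats,
7. cubic-spline interpolation onto a uniform 5 Hz grid, and
8. expression of velocity in percent of a 30 s pre-task baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, medfilt, sosfiltfilt

__all__ = [
    "Annotation",
    "RawRecording",
    "BeatSeries",
    "UniformSeries",
    "PreprocessConfig",
    "remove_spikes",
    "lowpass_filter",
    "median_filter_mcav",
    "detect_r_waves",
    "correct_beats",
    "beat_average",
    "etco2_per_beat",
    "resample_uniform",
    "normalize_percent",
    "calibrate_bp",
    "segment_labels",
    "preprocess_recording",
    "load_recording",
    "save_preprocessed",
]


@dataclass(frozen=True)
class Annotation:
    task_id: str
    onset_s: float
    duration_s: float


@dataclass
class RawRecording:
    """Raw multichannel recording with task annotations.

    channels maps name -> waveform; expected names are ``bp`` (mmHg),
    ``mcav_left``/``mcav_right`` (cm/s), ``ecg`` (a.u.), ``etco2`` (mmHg).
    """

    sample_rate: float
    channels: dict[str, np.ndarray]
    annotations: list[Annotation] = field(default_factory=list)
    brachial: tuple[float, float] | None = None  # (systolic, diastolic) mmHg

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        for ann in self.annotations:
            if ann.onset_s < 0 or ann.onset_s + ann.duration_s > self.duration_s + 1e-9:
                raise ValueError(f"annotation {ann.task_id} outside record duration")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class BeatSeries:
    """Beat-to-beat means; arrays are per cardiac cycle [beat_i, beat_{i+1})."""

    beat_times: np.ndarray  # length n_beats; per-beat arrays length n_beats - 1
    map_mmHg: np.ndarray
    mcav_left: np.ndarray
    mcav_right: np.ndarray
    rr_interval_s: np.ndarray
    hr_bpm: np.ndarray
    etco2_mmHg: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        n = len(self.beat_times) - 1
        for name in ("map_mmHg", "mcav_left", "mcav_right", "rr_interval_s", "hr_bpm", "etco2_mmHg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length n_beats - 1")


@dataclass
class UniformSeries:
    """Uniformly resampled 5 Hz series with per-sample segment labels."""

    rate: float
    t0: float
    map_mmHg: np.ndarray
    mcav_left: np.ndarray
    mcav_right: np.ndarray
    hr_bpm: np.ndarray
    etco2_mmHg: np.ndarray
    mcav_left_pct: np.ndarray | None = None
    mcav_right_pct: np.ndarray | None = None
    segment_labels: np.ndarray | None = None

    @property
    def time_s(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.map_mmHg)) / self.rate


@dataclass(frozen=True)
class PreprocessConfig:
    spike_max_width_ms: float = 100.0
    spike_mad_k: float = 8.0
    lowpass_cutoff_hz: float = 20.0
    lowpass_order: int = 8
    median_kernel: int = 5
    rr_gate_s: tuple[float, float] = (0.3, 2.0)
    resample_rate: float = 5.0
    baseline_window_s: float = 30.0
    calibration_window_s: float = 30.0


# ---------------------------------------------------------------------------
# artefact removal


def remove_spikes(
    waveform: np.ndarray,
    sample_rate: float,
    max_width_ms: float = 100.0,
    mad_k: float = 8.0,
) -> tuple[np.ndarray, dict]:
    """Remove narrow spikes (< ``max_width_ms``) by linear interpolation.

    Detection: first differences exceeding ``mad_k`` robust standard
    deviations (MAD-based) mark spike boundaries; consecutive boundary
    pairs bracket a candidate interval.  Intervals narrower than the
    width threshold are replaced by the straight chord between the last
    good sample before and the first good sample after; wider intervals
    are only reported.  Intervals touching the record edge are held at
    the nearest good value.  All untouched samples are returned
    bit-identical.
    """
    if max_width_ms <= 0:
        raise ValueError("max_width_ms must be > 0")
    x = np.asarray(waveform, dtype=float).copy()
    n = len(x)
    max_w = max(1, int(round(max_width_ms * 1e-3 * sample_rate)))
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    thr = mad_k * 1.4826 * mad
    report = {"n_spikes_removed": 0, "n_wide_flagged": 0, "edge_regions": 0, "intervals": []}
    if thr <= 0 or not np.any(np.abs(d) > thr):
        return x, report
    big = np.flatnonzero(np.abs(d) > thr)  # diff k sits between samples k and k+1
    # classify intervals: (start, stop inclusive, kind)
    intervals: list[tuple[int, int, str]] = []
    i = 0
    while i < len(big):
        k = big[i]
        if i + 1 < len(big) and big[i + 1] - k <= 2 * max_w:
            # entry/exit boundary pair brackets the spike body
            a, b = k + 1, big[i + 1]
            kind = "narrow" if (b - a + 1) < max_w else "wide"
            intervals.append((a, b, kind))
            i += 2
        else:
            # unpaired boundary: edge spike or isolated step
            if k < max_w:
                intervals.append((0, k, "edge_lead"))
            elif n - 1 - k < max_w:
                intervals.append((k + 1, n - 1, "edge_trail"))
            else:
                intervals.append((k, k + 1, "step"))
            i += 1
    # usability gate counts samples the cleaner would touch or distrust
    # (narrow spikes, edge regions, lone steps); wide intervals are
    # reported but left untouched and do not void the recording
    n_suspect = sum(b - a + 1 for a, b, kind in intervals if kind != "wide")
    if n_suspect / n > 0.10:
        raise ValueError("signal unusable: more than 10% of samples flagged as artefact")
    for a, b, kind in intervals:
        report["intervals"].append(
            {"start_s": a / sample_rate, "stop_s": b / sample_rate, "kind": kind}
        )
        if kind == "narrow":
            lo, hi = a - 1, b + 1
            x[a : b + 1] = np.interp(np.arange(a, b + 1), [lo, hi], [x[lo], x[hi]])
            report["n_spikes_removed"] += 1
        elif kind == "edge_lead":
            x[: b + 1] = x[b + 1]
            report["edge_regions"] += 1
        elif kind == "edge_trail":
            x[a:] = x[a - 1]
            report["edge_regions"] += 1
        else:  # wide or step: report only
            report["n_wide_flagged"] += 1
    return x, report


def lowpass_filter(
    waveform: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = 20.0,
    order: int = 8,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward application)."""
    if not 0 < cutoff_hz < sample_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    if order % 2 != 0:
        raise ValueError("order must be even for forward-backward application")
    sos = butter(order, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(waveform, dtype=float), padlen=3 * order)


def median_filter_mcav(waveform: np.ndarray, kernel_samples: int = 5) -> np.ndarray:
    """Running median for small narrow velocity artefacts."""
    if kernel_samples < 3 or kernel_samples % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    x = np.asarray(waveform, dtype=float)
    if kernel_samples >= len(x):
        raise ValueError("kernel must be shorter than the signal")
    return medfilt(x, kernel_samples)


# ---------------------------------------------------------------------------
# cardiac cycle detection


def detect_r_waves(
    ecg: np.ndarray,
    sample_rate: float,
    rr_gate_s: tuple[float, float] = (0.3, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Detect R-wave instants with a Pan-Tompkins-style chain.

    Band-pass (5-25 Hz) -> derivative -> squaring -> moving-window
    integration -> adaptive threshold, then peak refinement on the raw
    ECG.  Returns ``(beat_times_s, out_of_gate)`` where ``out_of_gate``
    flags beats whose preceding RR interval falls outside the physiologic
    gate and should be reviewed via :func:`correct_beats`.
    """
    x = np.asarray(ecg, dtype=float)
    if len(x) < 2 * sample_rate:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(x) == 0:
        raise ValueError("no QRS found (flat signal)")
    sos = butter(2, [5.0, 25.0], btype="band", fs=sample_rate, output="sos")
    bp = sosfiltfilt(sos, x)
    feat = np.gradient(bp) ** 2
    win = max(1, int(round(0.15 * sample_rate)))
    integ = np.convolve(feat, np.ones(win) / win, mode="same")
    min_dist = max(1, int(round(0.3 * sample_rate)))
    peaks, _ = find_peaks(integ, distance=min_dist)
    if len(peaks) == 0:
        raise ValueError("no QRS found")
    heights = integ[peaks]
    # adaptive gate: QRS complexes form the upper mode of the peak-height
    # distribution; the 80th percentile sits inside that mode even when
    # noise peaks dominate in number, and is robust to lone edge artefacts
    thr = 0.3 * np.quantile(heights, 0.80)
    peaks = peaks[heights > thr]
    if len(peaks) == 0:
        raise ValueError("no QRS found")
    # refine to the raw-ECG maximum near the energy peak; the integration
    # window can delay the energy peak by up to half its width, so search
    # the classic 150 ms span
    half = max(1, int(round(0.15 * sample_rate)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    beats = np.unique(refined)
    beat_times = beats / sample_rate
    rr = np.diff(beat_times)
    out_of_gate = np.zeros(len(beat_times), dtype=bool)
    # absolute physiologic gate plus a relative criterion: an RR interval
    # deviating by more than half the typical RR marks a missed or
    # spurious beat even inside the absolute gate
    med_rr = np.median(rr) if len(rr) else 0.0
    out_of_gate[1:] = (
        (rr < rr_gate_s[0])
        | (rr > rr_gate_s[1])
        | (rr > 1.5 * med_rr)
        | (rr < 0.5 * med_rr)
    )
    return beat_times, out_of_gate


def correct_beats(
    beat_times: np.ndarray,
    insert: tuple[float, ...] = (),
    delete: tuple[float, ...] = (),
    tol_s: float = 0.05,
) -> np.ndarray:
    """Manual-correction hook: insert or delete beat marks by time.

    Mirrors the visual inspection step of beat editing; deletions match
    the nearest existing mark within ``tol_s``.
    """
    times = list(np.asarray(beat_times, dtype=float))
    for t in delete:
        diffs = [abs(b - t) for b in times]
        k = int(np.argmin(diffs))
        if diffs[k] > tol_s:
            raise ValueError(f"no beat within {tol_s} s of t={t}")
        times.pop(k)
    times.extend(float(t) for t in insert)
    out = np.array(sorted(times))
    if np.any(np.diff(out) <= 0):
        raise ValueError("corrected beat times must be strictly increasing")
    return out


# ---------------------------------------------------------------------------
# beat-domain averaging


def beat_average(waveform: np.ndarray, sample_rate: float, beat_times: np.ndarray) -> np.ndarray:
    """Mean of the waveform over each cardiac cycle [beat_i, beat_{i+1})."""
    x = np.asarray(waveform, dtype=float)
    bt = np.asarray(beat_times, dtype=float)
    if len(bt) < 2:
        raise ValueError("need at least 2 beat times")
    edges = np.round(bt * sample_rate).astype(int)
    edges = np.clip(edges, 0, len(x))
    out = np.empty(len(bt) - 1)
    for i in range(len(bt) - 1):
        a, b = edges[i], edges[i + 1]
        if b <= a:
            raise ValueError(f"beat interval {i} contains no samples")
        out[i] = x[a:b].mean()
    return out


def etco2_per_beat(
    capno: np.ndarray, sample_rate: float, beat_times: np.ndarray
) -> np.ndarray:
    """Per-breath end-tidal values interpolated to cardiac cycles.

    Breath-end maxima of the capnogram are detected per expiratory cycle,
    linearly interpolated, and evaluated at the start of each cycle; the
    first/last breath value is held constant outside the breath span.
    """
    x = np.asarray(capno, dtype=float)
    dist = max(1, int(round(1.5 * sample_rate)))
    prom = 0.25 * np.ptp(x)
    peaks, _ = find_peaks(x, distance=dist, prominence=prom)
    if len(peaks) < 2:
        raise ValueError("fewer than 2 breaths detected in capnogram")
    bt = np.asarray(beat_times, dtype=float)[:-1]
    return np.interp(bt, peaks / sample_rate, x[peaks])


def resample_uniform(beats: BeatSeries, rate: float = 5.0) -> UniformSeries:
    """Cubic-spline interpolation of per-beat values onto a uniform grid.

    The grid spans [first_beat, last_beat] at ``rate`` samples/s; each
    per-beat value is anchored at the start of its cardiac cycle.
    """
    bt = beats.beat_times[:-1]
    if np.any(np.diff(bt) <= 0):
        raise ValueError("duplicated or non-increasing beat times")
    if len(bt) < 4:
        raise ValueError("need at least 4 beats for cubic-spline resampling")
    t0 = bt[0]
    n = int(np.floor((bt[-1] - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate

    def spline(y: np.ndarray) -> np.ndarray:
        return CubicSpline(bt, y)(grid)

    return UniformSeries(
        rate=rate,
        t0=t0,
        map_mmHg=spline(beats.map_mmHg),
        mcav_left=spline(beats.mcav_left),
        mcav_right=spline(beats.mcav_right),
        hr_bpm=spline(beats.hr_bpm),
        etco2_mmHg=spline(beats.etco2_mmHg),
    )


def normalize_percent(
    mcav: np.ndarray,
    rate: float,
    t0: float,
    task_onset_s: float,
    baseline_window_s: float = 30.0,
) -> np.ndarray:
    """Express velocity in percent change from the 30 s pre-task baseline."""
    x = np.asarray(mcav, dtype=float)
    i1 = int(round((task_onset_s - t0) * rate))
    i0 = i1 - int(round(baseline_window_s * rate))
    if i0 < 0:
        raise ValueError("need at least the full baseline window before task onset")
    base = x[i0:i1].mean()
    if base <= 0:
        raise ValueError("non-positive baseline velocity")
    return 100.0 * (x - base) / base


def calibrate_bp(
    finometer: np.ndarray,
    sample_rate: float,
    brachial: tuple[float, float],
    window_s: tuple[float, float] = (0.0, 30.0),
) -> np.ndarray:
    """Linear rescale so the reference window's extremes match brachial cuff values."""
    x = np.asarray(finometer, dtype=float)
    sys_ref, dia_ref = brachial
    a, b = (int(round(w * sample_rate)) for w in window_s)
    win = x[a:b]
    hi, lo = win.max(), win.min()
    if hi == lo:
        raise ValueError("calibration window has zero pulse pressure")
    scale = (sys_ref - dia_ref) / (hi - lo)
    return scale * (x - lo) + dia_ref


def segment_labels(
    time_s: np.ndarray, annotations: list[Annotation]
) -> np.ndarray:
    """Per-sample {rest, task, recovery} labels from task annotations."""
    labels = np.full(len(time_s), "rest", dtype=object)
    for ann in annotations:
        on, off = ann.onset_s, ann.onset_s + ann.duration_s
        labels[(time_s >= on) & (time_s < off)] = "task"
        labels[time_s >= off] = "recovery"
    return labels.astype(str)


# ---------------------------------------------------------------------------
# orchestration and I/O


def preprocess_recording(
    raw: RawRecording, config: PreprocessConfig = PreprocessConfig()
) -> tuple[BeatSeries, UniformSeries, dict]:
    """Full preprocessing chain from raw waveforms to the 5 Hz series."""
    fs = raw.sample_rate
    report: dict = {"channels": {}}
    clean: dict[str, np.ndarray] = {}
    for name in ("bp", "mcav_left", "mcav_right", "etco2"):
        x, rep = remove_spikes(
            raw.channels[name], fs, config.spike_max_width_ms, config.spike_mad_k
        )
        report["channels"][name] = rep
        clean[name] = x
    for name in ("bp", "mcav_left", "mcav_right"):
        clean[name] = lowpass_filter(clean[name], fs, config.lowpass_cutoff_hz, config.lowpass_order)
    for name in ("mcav_left", "mcav_right"):
        clean[name] = median_filter_mcav(clean[name], config.median_kernel)
    if raw.brachial is not None:
        clean["bp"] = calibrate_bp(
            clean["bp"], fs, raw.brachial, (0.0, config.calibration_window_s)
        )
    beat_times, out_of_gate = detect_r_waves(raw.channels["ecg"], fs, config.rr_gate_s)
    report["n_beats"] = int(len(beat_times))
    report["n_out_of_gate"] = int(out_of_gate.sum())
    rr = np.diff(beat_times)
    beats = BeatSeries(
        beat_times=beat_times,
        map_mmHg=beat_average(clean["bp"], fs, beat_times),
        mcav_left=beat_average(clean["mcav_left"], fs, beat_times),
        mcav_right=beat_average(clean["mcav_right"], fs, beat_times),
        rr_interval_s=rr,
        hr_bpm=60.0 / rr,
        etco2_mmHg=etco2_per_beat(clean["etco2"], fs, beat_times),
    )
    uni = resample_uniform(beats, config.resample_rate)
    if raw.annotations:
        onset = raw.annotations[0].onset_s
    else:
        onset = uni.t0 + config.baseline_window_s  # baseline-only record: first 30 s
    uni.mcav_left_pct = normalize_percent(
        uni.mcav_left, uni.rate, uni.t0, onset, config.baseline_window_s
    )
    uni.mcav_right_pct = normalize_percent(
        uni.mcav_right, uni.rate, uni.t0, onset, config.baseline_window_s
    )
    uni.segment_labels = segment_labels(uni.time_s, raw.annotations)
    return beats, uni, report


def load_recording(directory: str | Path) -> RawRecording:
    """Read one recording directory (``channels.csv`` + ``meta.json``)."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    df = pd.read_csv(directory / "channels.csv")
    channels = {
        name: df[name].to_numpy(dtype=float)
        for name in ("bp", "mcav_left", "mcav_right", "ecg", "etco2")
    }
    annotations = [
        Annotation(a["task_id"], float(a["onset_s"]), float(a["duration_s"]))
        for a in meta.get("annotations", [])
    ]
    brachial = tuple(meta["brachial"]) if meta.get("brachial") else None
    return RawRecording(
        sample_rate=float(meta["sample_rate"]),
        channels=channels,
        annotations=annotations,
        brachial=brachial,
    )


def save_preprocessed(
    out_dir: str | Path, beats: BeatSeries, uni: UniformSeries, report: dict
) -> None:
    """Write ``beats.csv``, ``uniform5hz.csv`` and ``preprocess_report.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "beat_time_s": beats.beat_times[:-1],
            "map_mmHg": beats.map_mmHg,
            "mcav_left": beats.mcav_left,
            "mcav_right": beats.mcav_right,
            "rr_interval_s": beats.rr_interval_s,
            "hr_bpm": beats.hr_bpm,
            "etco2_mmHg": beats.etco2_mmHg,
        }
    ).to_csv(out_dir / "beats.csv", index=False)
    pd.DataFrame(
        {
            "time_s": uni.time_s,
            "map_mmHg": uni.map_mmHg,
            "mcav_left": uni.mcav_left,
            "mcav_right": uni.mcav_right,
            "mcav_left_pct": uni.mcav_left_pct,
            "mcav_right_pct": uni.mcav_right_pct,
            "hr_bpm": uni.hr_bpm,
            "etco2_mmHg": uni.etco2_mmHg,
            "segment": uni.segment_labels,
        }
    ).to_csv(out_dir / "uniform5hz.csv", index=False)
    (out_dir / "preprocess_report.json").write_text(json.dumps(report, indent=2))
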