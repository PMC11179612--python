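"""Synthetic haemodynamic recordings with known ground truth.

Emulates the statistical structure of a seated cognitive-task protocol:
3-min recordings (1 min rest / 1 min task / 1 min recovery) plus 5-min
baseline recordings, arterial pressure with Mayer-wave and low-frequency
spontaneous variability, cerebral blood velocity generated from pressure
through the Tiecks model at a known ARI (switching to a depressed task
ARI during the activation minute), a task-evoked neurovascular-coupling
(NVC) velocity rise of a few percent in responders, task-evoked MAP and
HR increases, and optional end-tidal CO2 drift.

Every quantity is a pure function of the spec's integer seed, so cohort
generation is reproducible bit for bit and every downstream estimator can
be tested for parameter recovery against the recorded truth.

Pressure forcing spectrum: besides the Mayer sinusoid (~0.1 Hz) and
band-limited 1/f noise (0.02-0.45 Hz) the generator adds a small
broadband "microvariability" floor up to the Nyquist frequency;
beat-to-beat pressure variability in real recordings is broadband, and
without any input power above the LF band the pressure-to-velocity
transfer function would be unidentifiable there.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Annotation, RawRecording
from .tiecks import TiecksParams, load_parameter_table, tiecks_forward

__all__ = [
    "SyntheticSpec",
    "SyntheticRecord",
    "Cohort",
    "gen_map",
    "gen_mcav",
    "nvc_curve",
    "gen_raw",
    "gen_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration; defaults are the emulated study conditions."""

    seed: int = 0
    n_subjects: int = 16
    duration_s: float = 180.0
    baseline_duration_s: float = 300.0
    rate_raw: float = 500.0
    rate: float = 5.0
    true_ari_baseline: int = 6
    true_ari_task: int = 4
    nvc_amplitude_pct: float = 6.9
    nvc_shape: str = "ramp-plateau"  # or "gamma"
    map_rise_mmHg: float = 3.5
    hr_rise_bpm: float = 6.0
    etco2_drift_mmHg: float = -0.6
    noise_sd_pct: float = 10.0  # additive MCAv noise, % of clean-signal SD
    responder_fraction: float = 0.85
    tasks: tuple[str, ...] = ("task",)
    n_visits: int = 2
    task_onset_s: float = 60.0
    task_duration_s: float = 60.0
    # physiological baselines
    map_baseline_mmHg: float = 90.0
    mcav_baseline_cm_s: float = 60.0
    hr_baseline_bpm: float = 71.0
    etco2_baseline_mmHg: float = 37.0
    # pressure variability components
    mayer_freq_hz: float = 0.1
    mayer_amp_mmHg: float = 1.5
    lf_noise_sd_mmHg: float = 2.0
    lf_band_hz: tuple[float, float] = (0.02, 0.45)
    wideband_sd_mmHg: float = 0.3
    crcp_mmHg: float = 12.0
    warmup_s: float = 60.0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.rate_raw <= 0:
            raise ValueError("rates must be > 0")
        if self.nvc_amplitude_pct < 0 or self.noise_sd_pct < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not (0 <= self.true_ari_baseline <= 9 and 0 <= self.true_ari_task <= 9):
            raise ValueError("true ARI grades must be in 0..9")


def _rng(spec: SyntheticSpec, *keys: object) -> np.random.Generator:
    """Deterministic per-purpose generator derived from the spec seed."""
    ints = [int(spec.seed) & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def _band_noise(
    rng: np.random.Generator,
    n: int,
    rate: float,
    band: tuple[float, float],
    sd: float,
    slope: float = -0.5,
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ∝ f**slope inside ``band``."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        return np.zeros(n)
    spec = np.zeros(len(freqs), dtype=complex)
    amp = freqs[sel] ** slope if slope != 0.0 else np.ones(sel.sum())
    spec[sel] = amp * np.exp(1j * rng.uniform(0, 2 * np.pi, sel.sum()))
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x / s * sd if s > 0 else x


def _task_profile(
    t: np.ndarray, onset_s: float, duration_s: float, ramp_s: float = 5.0
) -> np.ndarray:
    """Smooth 0->1->0 activation profile with raised-cosine ramps."""
    prof = np.zeros_like(t)
    off = onset_s + duration_s
    up = (t >= onset_s) & (t < onset_s + ramp_s)
    prof[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - onset_s) / ramp_s))
    prof[(t >= onset_s + ramp_s) & (t < off)] = 1.0
    down = (t >= off) & (t < off + ramp_s)
    prof[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - off) / ramp_s))
    return prof


def gen_map(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    duration_s: float | None = None,
    with_task: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a uniformly sampled mean arterial pressure series (5 Hz).

    Baseline + Mayer-wave sinusoid + band-limited 1/f noise + broadband
    microvariability floor + (optionally) a smooth task-locked rise of
    ``map_rise_mmHg`` during the task minute.  Returns ``(time_s, map)``.
    """
    if rng is None:
        rng = _rng(spec, "map")
    dur = spec.duration_s if duration_s is None else duration_s
    n = int(round(dur * spec.rate))
    t = np.arange(n) / spec.rate
    x = np.full(n, spec.map_baseline_mmHg)
    x = x + spec.mayer_amp_mmHg * np.sin(
        2 * np.pi * spec.mayer_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    x = x + _band_noise(rng, n, spec.rate, spec.lf_band_hz, spec.lf_noise_sd_mmHg)
    x = x + _band_noise(
        rng, n, spec.rate, (spec.lf_band_hz[0], spec.rate / 2), spec.wideband_sd_mmHg, slope=0.0
    )
    if with_task and spec.map_rise_mmHg:
        x = x + spec.map_rise_mmHg * _task_profile(t, spec.task_onset_s, spec.task_duration_s)
    return t, x


def nvc_curve(
    t: np.ndarray,
    onset_s: float,
    duration_s: float,
    amplitude_pct: float,
    shape: str = "ramp-plateau",
) -> np.ndarray:
    """Task-evoked velocity response template, in percent of baseline.

    ``ramp-plateau``: 3 s linear rise to the plateau, 5 s linear decay
    after task end.  ``gamma``: gamma-density time course peaking a few
    seconds after onset, scaled to ``amplitude_pct`` at its maximum.
    """
    curve = np.zeros_like(t)
    if shape == "ramp-plateau":
        ramp, decay = 3.0, 5.0
        off = onset_s + duration_s
        rel = t - onset_s
        rising = (rel >= 0) & (rel < ramp)
        curve[rising] = rel[rising] / ramp
        curve[(t >= onset_s + ramp) & (t < off)] = 1.0
        falling = (t >= off) & (t < off + decay)
        curve[falling] = 1.0 - (t[falling] - off) / decay
    elif shape == "gamma":
        k, theta = 3.0, 2.5
        rel = np.clip(t - onset_s, 0, None)
        g = rel ** (k - 1) * np.exp(-rel / theta)
        end = onset_s + duration_s
        g[t >= end] = g[t >= end] * np.exp(-(t[t >= end] - end) / 5.0)
        if g.max() > 0:
            curve = g / g.max()
    else:
        raise ValueError(f"unknown nvc shape {shape!r}")
    return amplitude_pct * curve


def gen_mcav(
    map_series: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    responder: bool = True,
    with_task: bool = True,
    param_table: tuple[TiecksParams, ...] | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Generate bilateral MCAv from a MAP series through the Tiecks model.

    The baseline ARI drives rest and recovery; the (usually lower) task
    ARI drives the activation minute.  Responders additionally receive
    the NVC percent-rise curve; both hemispheres get independent additive
    Gaussian noise at ``noise_sd_pct`` percent of the clean-signal SD.
    The simulation is warmed up on a mirror-padded lead-in so the
    delivered record is in steady state.  Returns ``({left, right}, truth)``.
    """
    if rng is None:
        rng = _rng(spec, "mcav")
    if param_table is None:
        param_table = load_parameter_table()
    m = np.asarray(map_series, dtype=float)
    n = len(m)
    t = np.arange(n) / spec.rate
    pad = min(int(round(spec.warmup_s * spec.rate)), n - 1)
    m_ext = np.concatenate([m[pad:0:-1], m])  # mirror lead-in
    n_base = int(round(30.0 * spec.rate))
    map_base = float(m[:n_base].mean())

    def simulate(ari: int) -> np.ndarray:
        v = tiecks_forward(
            m_ext,
            param_table[ari],
            v0=spec.mcav_baseline_cm_s,
            rate_hz=spec.rate,
            crcp_mmHg=spec.crcp_mmHg,
            map_base=map_base,
        )
        return v[pad:]

    v = simulate(spec.true_ari_baseline)
    if with_task and spec.true_ari_task != spec.true_ari_baseline:
        in_task = (t >= spec.task_onset_s) & (t < spec.task_onset_s + spec.task_duration_s)
        v = np.where(in_task, simulate(spec.true_ari_task), v)
    amplitude = spec.nvc_amplitude_pct if (responder and with_task) else 0.0
    if with_task and amplitude:
        v = v * (1.0 + nvc_curve(t, spec.task_onset_s, spec.task_duration_s, amplitude, spec.nvc_shape) / 100.0)
    out: dict[str, np.ndarray] = {}
    noise_sd = spec.noise_sd_pct / 100.0 * float(np.std(v))
    for hemi in ("left", "right"):
        out[hemi] = v + noise_sd * rng.standard_normal(n)
    truth = {
        "true_ari_baseline": spec.true_ari_baseline,
        "true_ari_task": spec.true_ari_task if with_task else spec.true_ari_baseline,
        "responder": bool(responder and with_task),
        "nvc_amplitude_pct": amplitude,
        "noise_sd_cm_s": noise_sd,
    }
    return out, truth


def gen_raw(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    responder: bool = True,
    with_task: bool = True,
    duration_s: float | None = None,
    task_id: str = "task",
    n_spikes: int = 0,
) -> tuple[RawRecording, dict]:
    """Synthesize a full 500-samples/s raw recording.

    Pulsatile BP and MCAv waveforms are built per cardiac cycle around
    the 5 Hz trajectories (the in-beat pulse shape is zero-mean so beat
    averaging recovers the trajectory), the ECG is an impulse train at
    the prescribed R-wave instants, and the capnogram is a smoothed
    square-plateau breath train.  ``n_spikes`` narrow artefacts can be
    injected into the BP channel for artefact-handling tests.
    """
    if rng is None:
        rng = _rng(spec, "raw")
    dur = spec.duration_s if duration_s is None else duration_s
    t5, map5 = gen_map(spec, rng, duration_s=dur, with_task=with_task)
    mcav5, truth = gen_mcav(map5, spec, rng, responder=responder, with_task=with_task)
    fs = spec.rate_raw
    n = int(round(dur * fs))
    tr = np.arange(n) / fs

    # heart-rate trajectory and beat times
    hr5 = np.full_like(t5, spec.hr_baseline_bpm)
    if with_task:
        hr5 = hr5 + spec.hr_rise_bpm * _task_profile(t5, spec.task_onset_s, spec.task_duration_s)
    beat_times = [0.0]
    while beat_times[-1] < dur:
        hr_now = float(np.interp(beat_times[-1], t5, hr5))
        rr = 60.0 / hr_now * (1.0 + 0.02 * float(np.clip(rng.standard_normal(), -3, 3)))
        beat_times.append(beat_times[-1] + rr)
    beat_times = np.array(beat_times[:-1])

    def pulse_shape(phase: np.ndarray) -> np.ndarray:
        # systolic peak + dicrotic bump, smoothly tapered to zero at both
        # ends of the cycle so the waveform is continuous across beats
        def s(p: np.ndarray) -> np.ndarray:
            bumps = np.exp(-(((p - 0.18) / 0.12) ** 2)) + 0.35 * np.exp(
                -(((p - 0.5) / 0.14) ** 2)
            )
            edge = np.clip(p / 0.08, 0.0, 1.0)
            return bumps * edge * edge * (3.0 - 2.0 * edge)

        grid = np.linspace(0, 1, 200, endpoint=False)
        ref = s(grid)
        return (s(phase) - ref.mean()) / (ref.max() - ref.min())

    idx = np.searchsorted(beat_times, tr, side="right") - 1
    idx = np.clip(idx, 0, len(beat_times) - 1)
    next_beat = np.append(beat_times[1:], dur)
    phase = (tr - beat_times[idx]) / (next_beat[idx] - beat_times[idx])
    pp_bp = 40.0  # pulse pressure, mmHg
    bp = np.interp(tr, t5, map5) + pp_bp * pulse_shape(phase)
    v_amp = 0.55 * spec.mcav_baseline_cm_s
    mcav_raw = {
        h: np.interp(tr, t5, mcav5[h]) + v_amp * pulse_shape(phase) for h in ("left", "right")
    }
    ecg = 0.01 * rng.standard_normal(n)
    beat_idx = np.clip(np.round(beat_times * fs).astype(int), 0, n - 1)
    ecg[beat_idx] = 1.0

    # capnogram: smoothed square plateaus at the EtCO2 trajectory
    etco2_traj = np.full_like(t5, spec.etco2_baseline_mmHg)
    if with_task:
        etco2_traj = etco2_traj + spec.etco2_drift_mmHg * _task_profile(
            t5, spec.task_onset_s, spec.task_duration_s
        )
    capno = np.full(n, 2.0)
    t_breath = 0.0
    while t_breath < dur:
        period = 4.0 * (1.0 + 0.05 * float(np.clip(rng.standard_normal(), -2, 2)))
        exp_start = t_breath + 0.35 * period
        a, b = int(exp_start * fs), int(min(t_breath + period, dur) * fs)
        if a < n:
            capno[a : min(b, n)] = float(np.interp(exp_start, t5, etco2_traj))
        t_breath += period
    smooth = int(0.4 * fs)
    capno = np.convolve(capno, np.ones(smooth) / smooth, mode="same")
    capno = capno + 0.05 * rng.standard_normal(n)

    if n_spikes:
        margin = int(2.0 * fs)
        for _ in range(n_spikes):
            pos = int(rng.integers(margin, n - margin))
            width = int(rng.integers(int(0.02 * fs), int(0.08 * fs)))
            bp[pos : pos + width] += 50.0

    annotations = (
        [Annotation(task_id, spec.task_onset_s, spec.task_duration_s)] if with_task else []
    )
    win = bp[: int(30 * fs)]
    raw = RawRecording(
        sample_rate=fs,
        channels={
            "bp": bp,
            "mcav_left": mcav_raw["left"],
            "mcav_right": mcav_raw["right"],
            "ecg": ecg,
            "etco2": capno,
        },
        annotations=annotations,
        brachial=(float(win.max()), float(win.min())),
    )
    truth = dict(truth, beat_times=beat_times)
    return raw, truth


@dataclass
class SyntheticRecord:
    subject_id: str
    task_id: str  # "baseline" or a task name
    visit: int
    truth: dict
    raw: RawRecording | None = None
    uniform: pd.DataFrame | None = None  # 5 Hz mode: time_s, map_mmHg, mcav_left, mcav_right


@dataclass
class Cohort:
    spec: SyntheticSpec
    records: list[SyntheticRecord]
    truth: pd.DataFrame


def _uniform_frame(spec: SyntheticSpec, t: np.ndarray, m: np.ndarray, v: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_s": t, "map_mmHg": m, "mcav_left": v["left"], "mcav_right": v["right"]}
    )


def gen_cohort(
    spec: SyntheticSpec,
    mode: str = "uniform",
    identical_visits: bool = False,
) -> Cohort:
    """Generate a full cohort: per subject, one baseline recording and one
    recording per task, for each visit.

    Responder status is drawn once per subject at ``responder_fraction``.
    Visit 2 re-draws the stochastic components with a visit-keyed seed
    (unless ``identical_visits``, for degenerate-reproducibility tests).
    ``mode`` is "uniform" (5 Hz series, skips waveform synthesis) or
    "raw" (full 500 samples/s recordings).
    """
    if mode not in ("uniform", "raw"):
        raise ValueError("mode must be 'uniform' or 'raw'")
    label_rng = _rng(spec, "labels")
    responders = label_rng.random(spec.n_subjects) < spec.responder_fraction
    records: list[SyntheticRecord] = []
    truth_rows = []
    for s in range(spec.n_subjects):
        subject = f"S{s:03d}"
        for visit in range(1, spec.n_visits + 1):
            vkey = 1 if identical_visits else visit
            for task in ("baseline",) + spec.tasks:
                with_task = task != "baseline"
                dur = spec.duration_s if with_task else spec.baseline_duration_s
                rng = _rng(spec, "rec", s, vkey, task)
                if mode == "raw":
                    raw, truth = gen_raw(
                        spec,
                        rng,
                        responder=bool(responders[s]),
                        with_task=with_task,
                        duration_s=dur,
                        task_id=task,
                    )
                    rec = SyntheticRecord(subject, task, visit, truth, raw=raw)
                else:
                    t, m = gen_map(spec, rng, duration_s=dur, with_task=with_task)
                    v, truth = gen_mcav(
                        m, spec, rng, responder=bool(responders[s]), with_task=with_task
                    )
                    rec = SyntheticRecord(
                        subject, task, visit, truth, uniform=_uniform_frame(spec, t, m, v)
                    )
                records.append(rec)
                truth_rows.append(
                    {
                        "subject_id": subject,
                        "task_id": task,
                        "visit": visit,
                        "responder": truth["responder"],
                        "true_ari_baseline": truth["true_ari_baseline"],
                        "true_ari_task": truth["true_ari_task"],
                        "nvc_amplitude_pct": truth["nvc_amplitude_pct"],
                    }
                )
    return Cohort(spec=spec, records=records, truth=pd.DataFrame(truth_rows))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk in the per-recording directory layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        d = out_dir / f"{rec.subject_id}_{rec.task_id}_v{rec.visit}"
        d.mkdir(exist_ok=True)
        if rec.raw is not None:
            fs = rec.raw.sample_rate
            n = rec.raw.n_samples
            df = pd.DataFrame({"time_s": np.arange(n) / fs, **rec.raw.channels})
            df.to_csv(d / "channels.csv", index=False)
            meta = {
                "sample_rate": fs,
                "annotations": [asdict(a) for a in rec.raw.annotations],
                "brachial": list(rec.raw.brachial) if rec.raw.brachial else None,
            }
            (d / "meta.json").write_text(json.dumps(meta))
        else:
            rec.uniform.to_csv(d / "uniform5hz.csv", index=False)
            meta = {
                "sample_rate": cohort.spec.rate,
                "annotations": (
                    []
                    if rec.task_id == "baseline"
                    else [
                        {
                            "task_id": rec.task_id,
                            "onset_s": cohort.spec.task_onset_s,
                            "duration_s": cohort.spec.task_duration_s,
                        }
                    ]
                ),
            }
            (d / "meta.json").write_text(json.dumps(meta))
    cohort.truth.to_json(out_dir / "truth.json", orient="records", indent=2)
    return out_dir
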