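"""Cohort orchestration: preprocess -> TFA -> ARI -> NVC -> reproducibility.

``estimate_ari_from_series`` is the single-recording core: it normalizes
pressure to the dimensionless deviation dP = (MAP - MAP0)/(MAP0 - CrCP)
and velocity to its fractional change, so that the Welch transfer
function, its integrated step response and the Tiecks templates all share
one normalization and the template fit needs no free scale factor.

``run_cohort`` walks a cohort (in memory or a directory of recording
folders), estimates per-hemisphere ARI for every recording with
segment-length settings chosen by recording type (256 samples for 3-min
task records, 512 for baseline records), classifies responders from the
task-locked percent-velocity curves, computes visit-to-visit ICC/CV
tables, and writes ``ari_batch.tsv``, ``nvc.tsv``, ``repro.tsv`` and
``run_log.json``.  Recordings whose ARI fails the coherence or NMSE gate
are kept (flagged) but excluded from group means.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, nvc, preprocess, tfa, tiecks
from .synth import Cohort

__all__ = ["RunConfig", "estimate_ari_from_series", "extract_response_curve", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    crcp_mmHg: float = tiecks.CRCP_DEFAULT_MMHG
    fit_window_s: tuple[float, float] = (0.0, 10.0)
    task_settings: tfa.TfaSettings = field(default_factory=lambda: tfa.TASK_SETTINGS)
    baseline_settings: tfa.TfaSettings = field(default_factory=lambda: tfa.BASELINE_SETTINGS)
    coherence_limit_method: str = "montecarlo"
    coherence_limit_surrogates: int = 2000
    thresholds_mode: str = "published"  # or "recalibrate"
    nvc_alpha: float = 0.10
    max_lag_s: float = 5.0
    seed: int = 1234
    icc_variant: str = "ICC(1,1)"
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)

    def __post_init__(self) -> None:
        if self.thresholds_mode not in ("published", "recalibrate"):
            raise ValueError("thresholds_mode must be 'published' or 'recalibrate'")


@lru_cache(maxsize=8)
def _templates(rate: float, segment_samples: int) -> tuple[np.ndarray, np.ndarray]:
    return tiecks.make_templates(rate, segment_samples / rate)


def estimate_ari_from_series(
    map_mmHg: np.ndarray,
    mcav: np.ndarray,
    settings: tfa.TfaSettings = tfa.TASK_SETTINGS,
    crcp_mmHg: float = tiecks.CRCP_DEFAULT_MMHG,
    fit_window_s: tuple[float, float] = (0.0, 10.0),
    mcav_is_percent: bool = False,
    coherence_limit_method: str = "montecarlo",
    coherence_limit_seed: int = 1234,
    n_surrogates: int = 2000,
) -> tuple[tiecks.AriEstimate, tfa.SpectralEstimate]:
    """Estimate the ARI of one uniform 5 Hz MAP/MCAv pair.

    Velocity may be in native units (cm/s; normalized internally against
    its first-30-s mean) or already in percent of baseline.
    """
    m = np.asarray(map_mmHg, dtype=float)
    v = np.asarray(mcav, dtype=float)
    n_base = int(round(30.0 * settings.rate))
    map0 = float(m[:n_base].mean())
    if map0 <= crcp_mmHg:
        raise ValueError("baseline MAP must exceed CrCP")
    dp = (m - map0) / (map0 - crcp_mmHg)
    if mcav_is_percent:
        v_frac = v / 100.0
    else:
        v0 = float(v[:n_base].mean())
        if v0 <= 0:
            raise ValueError("non-positive baseline velocity")
        v_frac = v / v0 - 1.0
    spec = tfa.welch_tfa(dp, v_frac, settings)
    limit = tfa.coherence_limit(
        len(m),
        settings,
        method=coherence_limit_method,
        n_surrogates=n_surrogates,
        seed=coherence_limit_seed,
    )
    mean_coh = tfa.band_mean_coherence(spec)
    h = tfa.impulse_response(spec)
    t, step = tfa.step_response(h, settings.rate)
    tt, templates = _templates(settings.rate, settings.segment_samples)
    est = tiecks.fit_ari(
        step,
        t,
        templates,
        fit_window_s,
        mean_coherence=mean_coh,
        coherence_limit=limit,
        coherence_pass=mean_coh > limit,
    )
    return est, spec


def extract_response_curve(
    time_s: np.ndarray,
    mcav: np.ndarray,
    task_onset_s: float,
    rate: float = 5.0,
    pre_s: float = 60.0,
    post_s: float = 120.0,
    subject_id: str = "",
    task_id: str = "",
    hemisphere: str = "",
    mcav_is_percent: bool = False,
) -> nvc.ResponseCurve:
    """Cut a task-locked percent-change curve (-pre_s .. +post_s) from a series.

    The curve is placed on a fixed grid relative to onset so that curves
    from different recordings are directly averageable; values are taken
    by linear interpolation (boundary values held where the recording
    ends within a second of the window edge).
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(mcav, dtype=float)
    if not mcav_is_percent:
        v = preprocess.normalize_percent(v, rate, float(t[0]), task_onset_s)
    rel = t - task_onset_s
    if rel[0] > -pre_s + 1.0 or rel[-1] < post_s - 2.0:
        raise ValueError("series does not cover the task-locked window")
    n = int(round((pre_s + post_s) * rate))
    grid = -pre_s + np.arange(n) / rate
    return nvc.ResponseCurve(
        grid, np.interp(grid, rel, v), subject_id, task_id, hemisphere
    )


# ---------------------------------------------------------------------------
# cohort runner


def _load_cohort_dir(path: Path) -> list[dict]:
    """Discover recording folders; returns dicts with lazily parsed data."""
    records = []
    for d in sorted(p for p in path.iterdir() if p.is_dir()):
        meta_file = d / "meta.json"
        if not meta_file.exists():
            continue
        try:
            subject, task, visit = d.name.rsplit("_", 2)
            visit_no = int(visit.lstrip("v"))
        except ValueError:
            subject, task, visit_no = d.name, "task", 1
        records.append({"dir": d, "subject_id": subject, "task_id": task, "visit": visit_no})
    if not records:
        raise ValueError(f"no recordings found in {path}")
    return records


def _uniform_from_record(rec, config: RunConfig):
    """Return (time_s, map, {left,right velocities in cm/s}, onset or None)."""
    if isinstance(rec, dict) and "dir" in rec:  # on-disk recording
        d = rec["dir"]
        meta = json.loads((d / "meta.json").read_text())
        anns = meta.get("annotations", [])
        onset = float(anns[0]["onset_s"]) if anns else None
        if (d / "channels.csv").exists():
            raw = preprocess.load_recording(d)
            _, uni, _ = preprocess.preprocess_recording(raw, config.preprocess)
            return uni.time_s, uni.map_mmHg, {"left": uni.mcav_left, "right": uni.mcav_right}, onset
        df = pd.read_csv(d / "uniform5hz.csv")
        return (
            df["time_s"].to_numpy(),
            df["map_mmHg"].to_numpy(),
            {"left": df["mcav_left"].to_numpy(), "right": df["mcav_right"].to_numpy()},
            onset,
        )
    # in-memory SyntheticRecord
    if rec.raw is not None:
        _, uni, _ = preprocess.preprocess_recording(rec.raw, config.preprocess)
        onset = rec.raw.annotations[0].onset_s if rec.raw.annotations else None
        return uni.time_s, uni.map_mmHg, {"left": uni.mcav_left, "right": uni.mcav_right}, onset
    df = rec.uniform
    onset = None if rec.task_id == "baseline" else 60.0
    return (
        df["time_s"].to_numpy(),
        df["map_mmHg"].to_numpy(),
        {"left": df["mcav_left"].to_numpy(), "right": df["mcav_right"].to_numpy()},
        onset,
    )


def run_cohort(
    cohort: Cohort | str | Path,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis over a cohort; returns a result bundle.

    The bundle holds ``ari`` (per recording x hemisphere), ``nvc`` (per
    subject x task x hemisphere, visit-averaged curves), ``repro`` (per
    condition ICC/CV) and ``log``.  Stage failures are recorded per
    recording and the run continues.
    """
    if isinstance(cohort, (str, Path)):
        records = _load_cohort_dir(Path(cohort))
        meta_of = lambda r: (r["subject_id"], r["task_id"], r["visit"])  # noqa: E731
    else:
        records = cohort.records
        meta_of = lambda r: (r.subject_id, r.task_id, r.visit)  # noqa: E731
    ari_rows: list[dict] = []
    curves: dict[tuple[str, str, str], list] = {}  # (task, hemi, kind) -> curves
    failures: list[dict] = []
    for rec in records:
        subject, task, visit = meta_of(rec)
        try:
            t, m, v_by_hemi, onset = _uniform_from_record(rec, config)
            settings = config.baseline_settings if task == "baseline" else config.task_settings
            for hemi, v in v_by_hemi.items():
                est, spec = estimate_ari_from_series(
                    m,
                    v,
                    settings,
                    config.crcp_mmHg,
                    config.fit_window_s,
                    coherence_limit_method=config.coherence_limit_method,
                    coherence_limit_seed=config.seed,
                    n_surrogates=config.coherence_limit_surrogates,
                )
                ari_rows.append(
                    {
                        "subject_id": subject,
                        "task_id": task,
                        "visit": visit,
                        "hemisphere": hemi,
                        "ari": est.ari,
                        "nmse": est.nmse,
                        "mean_coherence": est.mean_coherence,
                        "coherence_limit": est.coherence_limit,
                        "accepted": est.accepted,
                    }
                )
                # task-locked response curves; baseline records supply the
                # unstimulated null curves (pseudo-onset mid-record)
                pseudo_onset = onset if onset is not None else float(t[0]) + 60.0
                try:
                    curve = extract_response_curve(
                        t, v, pseudo_onset, settings.rate, 60.0, 120.0, subject, task, hemi
                    )
                    kind = "null" if task == "baseline" else "task"
                    curves.setdefault((task, hemi, kind), []).append((subject, visit, curve))
                except ValueError:
                    pass
        except Exception as exc:  # stage failure: record, continue
            failures.append({"subject_id": subject, "task_id": task, "visit": visit, "error": str(exc)})
    ari_df = pd.DataFrame(ari_rows)
    if ari_df.empty:
        raise ValueError("no recordings produced an ARI estimate")

    # --- NVC classification on visit-averaged curves ---
    thresholds = nvc.PUBLISHED_THRESHOLDS
    if config.thresholds_mode == "recalibrate":
        null_curves = [c for key, lst in curves.items() if key[2] == "null" for _, _, c in lst]
        thresholds = nvc.recalibrate_thresholds(
            null_curves, alpha=config.nvc_alpha, max_lag_s=config.max_lag_s
        )
    nvc_rows: list[dict] = []
    for (task, hemi, kind), lst in curves.items():
        if kind != "task":
            continue
        by_subject: dict[str, list] = {}
        for subject, visit, curve in lst:
            by_subject.setdefault(subject, []).append(curve)
        averaged = {
            s: nvc.ResponseCurve(
                cs[0].time_s, np.mean([c.dmcav_pct for c in cs], axis=0), s, task, hemi
            )
            for s, cs in by_subject.items()
        }
        subjects = sorted(averaged)
        if len(subjects) < 2:
            continue
        stack = np.stack([averaged[s].dmcav_pct for s in subjects])
        total = stack.sum(axis=0)
        for i, s in enumerate(subjects):
            tmpl = nvc.ResponseCurve(  # leave-one-out coherent average
                averaged[s].time_s, (total - stack[i]) / (len(subjects) - 1), "<loo>", task
            )
            try:
                met = nvc.nvc_metrics(averaged[s], tmpl, thresholds, config.max_lag_s)
            except ValueError as exc:
                failures.append({"subject_id": s, "task_id": task, "error": str(exc)})
                continue
            nvc_rows.append(
                {
                    "subject_id": s,
                    "task_id": task,
                    "hemisphere": hemi,
                    "ccf_peak": met.ccf_peak,
                    "vr": met.vr,
                    "label": met.label,
                    "ccf90": thresholds.ccf90,
                    "vr90": thresholds.vr90,
                    "provenance": thresholds.provenance,
                }
            )
    nvc_df = pd.DataFrame(nvc_rows)

    # --- reproducibility across visits (accepted estimates only) ---
    from .repro import repro_table

    accepted = ari_df[ari_df["accepted"]]
    repro_df = (
        repro_table(accepted, "ari", ("task_id", "hemisphere"), config.icc_variant)
        if accepted["visit"].nunique() >= 2
        else pd.DataFrame()
    )

    log = {
        "version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "n_recordings": len(records),
        "n_failures": len(failures),
        "failures": failures,
        "n_rejected_ari": int((~ari_df["accepted"]).sum()),
        "thresholds": {"ccf90": thresholds.ccf90, "vr90": thresholds.vr90, "provenance": thresholds.provenance},
    }
    bundle = {"ari": ari_df, "nvc": nvc_df, "repro": repro_df, "log": log}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ari_df.to_csv(out / "ari_batch.tsv", sep="\t", index=False)
        nvc_df.to_csv(out / "nvc.tsv", sep="\t", index=False)
        repro_df.to_csv(out / "repro.tsv", sep="\t", index=False)
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle
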