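"""Responder / non-responder classification of neurovascular coupling responses.

A subject's task-locked MCAv percent-change curve is compared against the
cohort's coherent average with two complementary statistics:

* **CCF peak** — maximum lagged Pearson correlation between the individual
  curve and the coherent-average template (evidence of a time-locked
  response shape);
* **variance ratio (VR)** — post- over pre-stimulation signal variance
  (an F-type statistic; evidence of a power change).

A subject is a responder (R) for a task if *either* statistic exceeds its
90% null-distribution threshold — published values CCF90 = 0.53 and
VR90 = 2.59 — and a non-responder (NoR) otherwise.  Thresholds can be
recalibrated from unstimulated (null) curves as the 90th percentile of
each statistic's null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseCurve",
    "NvcMetrics",
    "ClassifierThresholds",
    "PUBLISHED_THRESHOLDS",
    "coherent_average",
    "ccf_peak",
    "variance_ratio",
    "classify",
    "recalibrate_thresholds",
    "nvc_metrics",
]


@dataclass
class ResponseCurve:
    """Task-locked percent-change MCAv curve on a uniform grid.

    ``time_s`` is relative to task onset (negative = pre-stimulus) and the
    curve is expected to cover at least the 30 s pre-onset normalization
    window, over which its mean is ~0.
    """

    time_s: np.ndarray
    dmcav_pct: np.ndarray
    subject_id: str = ""
    task_id: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dmcav_pct = np.asarray(self.dmcav_pct, dtype=float)
        if self.time_s.shape != self.dmcav_pct.shape:
            raise ValueError("time_s and dmcav_pct must have equal length")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class ClassifierThresholds:
    ccf90: float = 0.53
    vr90: float = 2.59
    alpha: float = 0.10
    provenance: str = "published"

    def __post_init__(self) -> None:
        if not 0.0 < self.ccf90 < 1.0:
            raise ValueError("ccf90 must be in (0, 1)")
        if self.vr90 <= 0.0:
            raise ValueError("vr90 must be > 0")


#: Published 90% confidence limits of the null distributions.
PUBLISHED_THRESHOLDS = ClassifierThresholds()


@dataclass(frozen=True)
class NvcMetrics:
    ccf_peak: float
    vr: float
    label: str  # "R" or "NoR"
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)


def coherent_average(curves: list[ResponseCurve]) -> ResponseCurve:
    """Pointwise mean of task-locked curves across subjects."""
    if len(curves) < 2:
        raise ValueError("need at least 2 curves for a coherent average")
    t0 = curves[0].time_s
    for c in curves[1:]:
        if c.time_s.shape != t0.shape or not np.allclose(c.time_s, t0):
            raise ValueError("curves must share an identical time grid")
    mean = np.mean([c.dmcav_pct for c in curves], axis=0)
    return ResponseCurve(t0.copy(), mean, subject_id="<average>", task_id=curves[0].task_id)


def ccf_peak(
    individual: ResponseCurve | np.ndarray,
    template: ResponseCurve | np.ndarray,
    rate: float | None = None,
    max_lag_s: float = 5.0,
) -> tuple[float, float]:
    """Peak normalized cross-correlation within ±``max_lag_s``.

    At each lag the Pearson correlation of the overlapping samples is
    computed; returns ``(peak_value, peak_lag_s)``.  Positive lag means
    the individual curve trails the template.
    """
    if isinstance(individual, ResponseCurve):
        rate = individual.rate
        x = individual.dmcav_pct
    else:
        x = np.asarray(individual, dtype=float)
    y = template.dmcav_pct if isinstance(template, ResponseCurve) else np.asarray(template, dtype=float)
    if rate is None:
        raise ValueError("rate is required with plain-array inputs")
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be >= 0")
    if len(x) != len(y):
        raise ValueError("curves must have equal length")
    max_lag = int(round(max_lag_s * rate))
    if len(x) - max_lag < int(30 * rate):
        raise ValueError("overlapping support shorter than 30 s")
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = x[lag:] if lag else x, y[: len(y) - lag] if lag else y
        else:
            a, b = x[:lag], y[-lag:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValueError("zero-variance input in correlation window")
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag / rate


def variance_ratio(
    curve: ResponseCurve,
    pre_window_s: tuple[float, float] = (-30.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 30.0),
) -> float:
    """Post- over pre-stimulation variance of the response curve."""
    t = curve.time_s
    pre = curve.dmcav_pct[(t >= pre_window_s[0]) & (t < pre_window_s[1])]
    post = curve.dmcav_pct[(t >= post_window_s[0]) & (t < post_window_s[1])]
    if len(pre) < 10 or len(post) < 10:
        raise ValueError("each window must contain at least 10 samples")
    var_pre = float(np.var(pre, ddof=1))
    if var_pre == 0:
        raise ValueError("zero pre-stimulation variance")
    return float(np.var(post, ddof=1)) / var_pre


def classify(
    ccf_peak_value: float, vr: float, thresholds: ClassifierThresholds = PUBLISHED_THRESHOLDS
) -> str:
    """R if either statistic strictly exceeds its threshold, else NoR."""
    if not (np.isfinite(ccf_peak_value) and np.isfinite(vr)):
        raise ValueError("metrics must be finite")
    return "R" if (ccf_peak_value > thresholds.ccf90 or vr > thresholds.vr90) else "NoR"


def nvc_metrics(
    individual: ResponseCurve,
    template: ResponseCurve,
    thresholds: ClassifierThresholds = PUBLISHED_THRESHOLDS,
    max_lag_s: float = 5.0,
    pre_window_s: tuple[float, float] = (-30.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 30.0),
) -> NvcMetrics:
    """Compute both statistics and the R/NoR label for one curve."""
    peak, _ = ccf_peak(individual, template, max_lag_s=max_lag_s)
    vr = variance_ratio(individual, pre_window_s, post_window_s)
    return NvcMetrics(peak, vr, classify(peak, vr, thresholds), thresholds)


def recalibrate_thresholds(
    null_curves: list[ResponseCurve],
    alpha: float = 0.10,
    template: ResponseCurve | None = None,
    leave_one_out: bool = True,
    max_lag_s: float = 5.0,
    pre_window_s: tuple[float, float] = (-30.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 30.0),
    min_curves: int = 50,
) -> ClassifierThresholds:
    """Calibrate CCF/VR thresholds from unstimulated (null) curves.

    Each threshold is the (1-alpha) quantile of its statistic over the
    null curves.  The CCF template defaults to the coherent average of
    the null curves themselves, computed leave-one-out for the curve
    being scored so that self-correlation does not inflate the null.
    """
    if len(null_curves) < min_curves:
        raise ValueError(f"need at least {min_curves} null curves")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = len(null_curves)
    stack = np.stack([c.dmcav_pct for c in null_curves])
    total = stack.sum(axis=0)
    rate = null_curves[0].rate
    ccf_vals = np.empty(n)
    vr_vals = np.empty(n)
    for i, c in enumerate(null_curves):
        if template is not None:
            tmpl = template.dmcav_pct
        elif leave_one_out:
            tmpl = (total - stack[i]) / (n - 1)
        else:
            tmpl = total / n
        ccf_vals[i], _ = ccf_peak(c.dmcav_pct, tmpl, rate=rate, max_lag_s=max_lag_s)
        vr_vals[i] = variance_ratio(c, pre_window_s, post_window_s)
    prov = f"recalibrated(n_null={n}, loo={template is None and leave_one_out})"
    return ClassifierThresholds(
        ccf90=float(np.quantile(ccf_vals, 1.0 - alpha)),
        vr90=float(np.quantile(vr_vals, 1.0 - alpha)),
        alpha=alpha,
        provenance=prov,
    )
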