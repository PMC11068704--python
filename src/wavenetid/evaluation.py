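"""Generalization indicators: (1 - r^2), cross-correlation, cosine
similarity, spike detection and interspike-interval comparison.

The (1 - r^2)-score is the residual sum of squares normalized by the
variance of the target — zero for a perfect prediction, sensitive to small
time lags.  The un-centered normalized cross-correlation ``R(k)`` and its
zero-lag value, the cosine similarity ``S_C = R(0)``, are more forgiving of
lags.  ISI distributions compare firing structure directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .prediction import PredictionResult

__all__ = [
    "ScoreReport",
    "one_minus_r2",
    "cross_correlation",
    "cosine_similarity",
    "detect_spikes",
    "interspike_intervals",
    "isi_overlap",
    "score_prediction",
]


def one_minus_r2(y, y_hat) -> float:
    """``sum (y - y_hat)^2 / sum (y - mean(y))^2`` — 0 is a perfect fit."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("series must share a length >= 2")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("target series is constant; score undefined")
    return float(np.sum((y - y_hat) ** 2) / denom)


def cross_correlation(y, y_hat, max_lag: int):
    """Un-centered normalized cross-correlation over lags -max_lag..max_lag.

    ``R(k) = sum_m y[m] y_hat[m+k] / (||y|| ||y_hat||)`` with zero padding
    outside the record.  Returns ``(lags, R)``.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("series must share a length")
    ny, nh = np.linalg.norm(y), np.linalg.norm(y_hat)
    if ny == 0.0 or nh == 0.0:
        raise ValueError("zero-norm input")
    lags = np.arange(-max_lag, max_lag + 1)
    n = len(y)
    R = np.zeros(len(lags))
    for i, k in enumerate(lags):
        # numerator sum_m y[m] y_hat[m+k], zero padded; k=0 is the plain dot
        # product so that R(0) equals the cosine similarity bit for bit
        if k >= 0:
            R[i] = np.dot(y[: n - k], y_hat[k:]) if k < n else 0.0
        else:
            R[i] = np.dot(y[-k:], y_hat[: n + k]) if -k < n else 0.0
    return lags, R / (ny * nh)


def cosine_similarity(y, y_hat) -> float:
    """``<y, y_hat> / (||y|| ||y_hat||)`` — scale-invariant, equals R(0)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ny, nh = np.linalg.norm(y), np.linalg.norm(y_hat)
    if ny == 0.0 or nh == 0.0:
        raise ValueError("zero-norm input")
    return float(np.dot(y, y_hat) / (ny * nh))


def detect_spikes(v, dt: float, threshold: float, min_separation: float = 2.0):
    """Times (ms) of upward threshold crossings at least min_separation apart."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage series must be finite")
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        t = i * dt
        if t - last >= min_separation:
            times.append(t)
            last = t
    return np.asarray(times)


def interspike_intervals(spike_times) -> np.ndarray:
    return np.diff(np.asarray(spike_times, dtype=float))


def isi_overlap(isi_a, isi_b, bin_width: float | None = None) -> float:
    """Histogram overlap coefficient in [0, 1] on shared bins.

    Both samples are binned on a common grid (Freedman–Diaconis width on the
    pooled sample unless ``bin_width`` is given), normalized to unit mass;
    the overlap is ``sum_bins min(h_a, h_b)``.
    """
    a = np.asarray(isi_a, dtype=float)
    b = np.asarray(isi_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ISI samples must be non-empty")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if bin_width is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        bin_width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
        if bin_width <= 0:
            bin_width = max((hi - lo) / 10.0, 1e-9)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo - 0.5 * bin_width, lo + 0.5 * bin_width])
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(ha / a.size, hb / b.size).sum())


def spike_threshold_for(model_spec, settle_ms: float = 200.0, probe_ms: float = 2000.0) -> float:
    """Per-model default spike threshold.

    Midpoint between the minimum and peak voltage of a reference run at a
    suprathreshold constant current (75% of the way up the physiological
    interval), robust to subthreshold ripple.
    """
    from .neuron_models import integrate_euler, resting_state

    lo, hi = model_spec.current_interval
    i_probe = lo + 0.75 * (hi - lo)
    x0 = resting_state(model_spec, i_app=i_probe, settle_ms=settle_ms)
    n = int(round(probe_ms / model_spec.dt))
    traj = integrate_euler(model_spec, np.full(n, i_probe), x0)
    v = traj.v
    return 0.5 * (float(v.min()) + float(v.max()))


@dataclass
class ScoreReport:
    """Per-variable indicators for one prediction run."""

    one_minus_r2: dict
    cosine_similarity: dict
    cc_lags_ms: list
    cross_correlation: dict
    isi_true: list = field(default_factory=list)
    isi_pred: list = field(default_factory=list)
    isi_overlap: float | None = None
    mode: str = ""
    transient_ms: float = 0.0

    def one_minus_r2_percent(self, name: str) -> float:
        return 100.0 * self.one_minus_r2[name]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def score_prediction(
    result: PredictionResult,
    transient_ms: float = 100.0,
    max_lag_ms: float = 50.0,
    spike_threshold: float | None = None,
    voltage_output: int | None = 0,
    min_separation: float = 2.0,
) -> ScoreReport:
    """Compute all indicators, discarding an initial transient.

    ISI distributions and their overlap are computed for the voltage output
    when a spike threshold is supplied.
    """
    skip = int(round(transient_ms / result.dt))
    y = result.y_true[skip:]
    yh = result.y_hat[skip:]
    max_lag = int(round(max_lag_ms / result.dt))
    omr, sc, cc = {}, {}, {}
    lags = None
    for i, name in enumerate(result.output_names):
        omr[name] = one_minus_r2(y[:, i], yh[:, i])
        sc[name] = cosine_similarity(y[:, i], yh[:, i])
        lags, R = cross_correlation(y[:, i], yh[:, i], max_lag)
        cc[name] = R.tolist()
    report = ScoreReport(
        one_minus_r2=omr,
        cosine_similarity=sc,
        cc_lags_ms=(lags * result.dt).tolist(),
        cross_correlation=cc,
        mode=result.mode,
        transient_ms=transient_ms,
    )
    if spike_threshold is not None and voltage_output is not None:
        st_true = detect_spikes(
            y[:, voltage_output], result.dt, spike_threshold, min_separation
        )
        st_pred = detect_spikes(
            yh[:, voltage_output], result.dt, spike_threshold, min_separation
        )
        isi_t = interspike_intervals(st_true)
        isi_p = interspike_intervals(st_pred)
        report.isi_true = isi_t.tolist()
        report.isi_pred = isi_p.tolist()
        if isi_t.size and isi_p.size:
            report.isi_overlap = isi_overlap(isi_t, isi_p)
    return report
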