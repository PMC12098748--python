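"""Calcium-trace dF/F, template-matching event detection, and IEI statistics.

dF/F uses a trailing baseline: for each sample, the baseline is the mean of
the lower half of the raw fluorescence values in the preceding 10-s window
(strictly before the sample, so a transient never pollutes its own
baseline).  During warm-up, an expanding window of all previous samples is
used; the first sample uses itself (dF/F = 0 at t = 0).

Events are detected by sliding a library of difference-of-exponentials
templates along the dF/F trace and computing a time-varying Pearson
correlation; transients with template correlation > 0.85 and peak
dF/F > 0.1 are events (both thresholds configurable).

Inter-event-interval (IEI) analysis pools successive event-time differences
within cells across each group and compares groups with the two-sided
two-sample Kolmogorov-Smirnov test (asymptotic p) and per-cell means with
Welch's unpaired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synthetic import kernel_peak_time

__all__ = [
    "delta_f_over_f",
    "build_templates",
    "Template",
    "detect_events",
    "event_rate_summary",
    "pool_iei",
    "EventTrainStats",
    "ks_two_sample",
    "welch_t",
]


def delta_f_over_f(
    trace: np.ndarray,
    dt_s: float = 1.0,
    window_s: float = 10.0,
    lower_frac: float = 0.5,
) -> np.ndarray:
    """dF/F with a trailing lower-half-of-window baseline.

    For sample t, the baseline B(t) is the mean of the lowest
    ``ceil(lower_frac * k)`` of the k samples in the window (t - window_s, t)
    strictly before t.  Samples with fewer than 2 predecessors use F(first
    sample).  A non-positive baseline is a physically invalid input and an
    error.
    """
    f = np.asarray(trace, dtype=float)
    if window_s < 2 * dt_s:
        raise ValueError("window must span at least 2 samples")
    if not 0 < lower_frac <= 1:
        raise ValueError("lower_frac must lie in (0, 1]")
    w = int(round(window_s / dt_s))
    n = len(f)
    out = np.empty(n)
    for t in range(n):
        if t < 2:
            b = f[0]
        else:
            prev = f[max(0, t - w):t]
            m = math.ceil(lower_frac * len(prev))
            b = np.partition(prev, m - 1)[:m].mean()
        if b <= 0:
            raise ValueError(f"non-positive baseline at sample {t}")
        out[t] = (f[t] - b) / b
    return out


@dataclass
class Template:
    rise_tau_s: float
    decay_tau_s: float
    phase_s: float
    values: np.ndarray = field(repr=False)


def build_templates(
    rise_taus: tuple[float, ...] = (1.0, 2.0),
    decay_taus: tuple[float, ...] = (2.0, 4.0, 8.0),
    length_s: float = 10.0,
    dt_s: float = 1.0,
    phase_fracs: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75),
) -> list[Template]:
    """Library of unit-peak difference-of-exponentials transient templates.

    Each (rise, decay) pair with decay > rise yields the waveform
    ``exp(-t/decay) - exp(-t/rise)`` sampled on [0, length) and normalized to
    unit sampled peak.  Because real transients start between samples and the
    rising edge is undersampled at typical imaging rates, each waveform is
    sampled at several sub-sample onset phases (``phase_fracs`` in units of
    the sampling interval); a matched filter without phase diversity misses
    well-formed events whose onset falls mid-sample.
    """
    if any(tau <= 0 for tau in (*rise_taus, *decay_taus)):
        raise ValueError("time constants must be positive")
    t = np.arange(0.0, length_s, dt_s)
    templates = []
    for tr in rise_taus:
        for td in decay_taus:
            if td <= tr:
                continue
            for frac in phase_fracs:
                ts = t - frac * dt_s
                k = np.where(ts >= 0, np.exp(-ts / td) - np.exp(-ts / tr), 0.0)
                templates.append(Template(tr, td, frac * dt_s, k / k.max()))
    if not templates:
        raise ValueError("no valid templates: every decay tau <= rise tau")
    return templates


def _detrend_columns(length: int) -> np.ndarray:
    """Orthonormal basis of the constant + linear subspace of R^length."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(length), np.arange(length, dtype=float)]))
    return q


def _sliding_correlation(x: np.ndarray, template: np.ndarray, detrend: bool = True) -> np.ndarray:
    """Correlation of each length-L window of x with the template.

    With ``detrend`` (default) the constant + linear component is projected
    out of both window and template before the cosine similarity, which makes
    the match robust to the decaying tail of a preceding transient sitting
    under the window; without it this is the plain Pearson correlation.
    """
    L = len(template)
    windows = np.lib.stride_tricks.sliding_window_view(x, L).astype(float)
    if detrend:
        q = _detrend_columns(L)
        wm = windows - (windows @ q) @ q.T
        tm = template - q @ (q.T @ template)
    else:
        wm = windows - windows.mean(axis=1, keepdims=True)
        tm = template - template.mean()
    denom = np.sqrt((wm**2).sum(axis=1) * (tm**2).sum())
    num = wm @ tm
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    return corr


def _rise_fall_times(
    dff: np.ndarray, peak: int, dt_s: float, lo: float = 0.2, hi: float = 0.8
) -> tuple[float, float]:
    """Rise 20->80% of peak amplitude and fall peak->50%, linear interpolation."""
    amp = dff[peak]

    def _cross_back(level: float) -> float | None:
        target = level * amp
        for i in range(peak, 0, -1):
            if dff[i - 1] <= target <= dff[i]:
                frac = (target - dff[i - 1]) / (dff[i] - dff[i - 1]) if dff[i] != dff[i - 1] else 0.0
                return (i - 1 + frac) * dt_s
        return None

    def _cross_forward(level: float) -> float | None:
        target = level * amp
        for i in range(peak, len(dff) - 1):
            if dff[i] >= target >= dff[i + 1]:
                frac = (dff[i] - target) / (dff[i] - dff[i + 1]) if dff[i] != dff[i + 1] else 0.0
                return (i + frac) * dt_s
        return None

    t_lo = _cross_back(lo)
    t_hi = _cross_back(hi)
    rise = t_hi - t_lo if t_lo is not None and t_hi is not None else np.nan
    t_half = _cross_forward(0.5)
    fall = t_half - peak * dt_s if t_half is not None else np.nan
    return rise, fall


def _detect_single_pass(
    dff: np.ndarray,
    templates: list[Template],
    rho_min: float,
    amp_min: float,
    min_separation: int,
    L: int,
) -> list[tuple[int, int, float, float, int]]:
    """One matched-filter pass: (onset, peak, amplitude, correlation, template)."""
    n = len(dff)
    n_full = n - L + 1
    # truncated templates cover onsets in the final window of the trace,
    # where a full-length match is impossible
    min_overlap = max(4, L // 2)
    n_pos = n - min_overlap + 1
    best_corr = np.full(n_pos, -np.inf)
    best_tpl = np.zeros(n_pos, dtype=int)
    for ti, tpl in enumerate(templates):
        corr = _sliding_correlation(dff, tpl.values)[:n_full]
        better = corr > best_corr[:n_full]
        best_corr[:n_full][better] = corr[better]
        best_tpl[:n_full][better] = ti
        for pos in range(n_full, n_pos):
            c = _sliding_correlation(dff[pos:], tpl.values[: n - pos])[0]
            if c > best_corr[pos]:
                best_corr[pos] = c
                best_tpl[pos] = ti

    # candidate onsets = local maxima of the correlation trace above rho_min;
    # pad with -inf so maxima at the trace boundaries are found too
    padded = np.concatenate([[-np.inf], best_corr, [-np.inf]])
    peaks, _ = signal.find_peaks(padded, height=rho_min, distance=max(min_separation, 1))
    candidates = [int(p - 1) for p in peaks]

    events = []
    for onset in candidates:
        # search the dF/F peak near the matched template's own peak position,
        # so a second transient later in the window cannot steal the peak
        tpl_peak = int(np.argmax(templates[best_tpl[onset]].values))
        hi = min(onset + tpl_peak + min_separation + 1, n)
        window = dff[onset:hi]
        peak = onset + int(np.argmax(window))
        amp = dff[peak]
        if amp > amp_min:
            events.append((onset, peak, amp, best_corr[onset], best_tpl[onset]))
    return events


def detect_events(
    dff: np.ndarray,
    templates: list[Template] | None = None,
    dt_s: float = 1.0,
    rho_min: float = 0.85,
    amp_min: float = 0.1,
    min_separation: int = 2,
    n_passes: int = 2,
) -> pd.DataFrame:
    """Template-matching event detection on a dF/F series.

    Candidate onsets are local maxima of the best-over-templates sliding
    correlation above ``rho_min``; each candidate's event peak is the dF/F
    maximum near the matched template's peak position, retained when it
    exceeds ``amp_min``.  Because a transient 3-10 s after another sits on
    its neighbour's waveform and degrades the match, detection runs
    ``n_passes`` matching-pursuit passes: after each pass the fitted
    templates of accepted events are subtracted and the residual is
    re-scanned.  Events closer than ``min_separation`` samples are merged,
    keeping the higher correlation.  Returns one row per event with peak
    index/time, amplitude, template correlation and rise/fall times.
    """
    if not 0 < rho_min <= 1:
        raise ValueError("rho_min must lie in (0, 1]")
    if amp_min <= 0:
        raise ValueError("amp_min must be positive")
    dff = np.asarray(dff, dtype=float)
    if templates is None:
        templates = build_templates(dt_s=dt_s)
    L = max(len(tpl.values) for tpl in templates)
    if len(dff) < L:
        raise ValueError(f"series ({len(dff)} samples) shorter than template ({L})")

    events: list[tuple[int, int, float, float, int]] = []
    residual = dff.copy()
    for _ in range(max(n_passes, 1)):
        found = _detect_single_pass(residual, templates, rho_min, amp_min, min_separation, L)
        new = [
            ev for ev in found
            if all(abs(ev[1] - prev[1]) >= min_separation for prev in events)
        ]
        if not new:
            break
        events.extend(new)
        for onset, peak, amp, _, ti in new:
            tpl = templates[ti].values
            stop = min(onset + len(tpl), len(residual))
            residual[onset:stop] -= amp * tpl[: stop - onset]

    # merge events closer than min_separation, keeping the higher correlation
    merged: list[tuple[int, float, float, int]] = []
    for _, peak, amp, corr, ti in sorted(events, key=lambda e: e[1]):
        ev = (peak, amp, corr, ti)
        if merged and ev[0] - merged[-1][0] < min_separation:
            if ev[2] > merged[-1][2]:
                merged[-1] = ev
        else:
            merged.append(ev)

    rows = []
    for peak, amp, corr, ti in merged:
        rise, fall = _rise_fall_times(dff, peak, dt_s)
        rows.append(
            dict(
                peak_index=peak,
                peak_time_s=peak * dt_s,
                amplitude=amp,
                correlation=corr,
                rise_time_s=rise,
                fall_time_s=fall,
                rise_tau_s=templates[ti].rise_tau_s,
                decay_tau_s=templates[ti].decay_tau_s,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_index", "peak_time_s", "amplitude", "correlation",
            "rise_time_s", "fall_time_s", "rise_tau_s", "decay_tau_s",
        ],
    )


def event_rate_summary(
    events_per_neuron: list[pd.DataFrame], duration_s: float
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-neuron event counts and amplitude/kinetics means, plus group summary."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rows = []
    for i, ev in enumerate(events_per_neuron):
        n = len(ev)
        rows.append(
            dict(
                neuron=i,
                n_events=n,
                rate_hz=n / duration_s,
                mean_amplitude=ev["amplitude"].mean() if n else np.nan,
                mean_rise_s=ev["rise_time_s"].mean() if n else np.nan,
                mean_fall_s=ev["fall_time_s"].mean() if n else np.nan,
            )
        )
    table = pd.DataFrame(rows).set_index("neuron")
    counts = table["n_events"].to_numpy(dtype=float)
    summary = {
        "mean_events_per_neuron": float(counts.mean()) if len(counts) else np.nan,
        "sem_events_per_neuron": float(counts.std(ddof=1) / np.sqrt(len(counts)))
        if len(counts) > 1
        else np.nan,
    }
    return table, summary


@dataclass
class EventTrainStats:
    group: str
    event_times: list[np.ndarray]
    pooled_iei: np.ndarray
    per_cell_mean_iei: np.ndarray

    @property
    def n_pooled(self) -> int:
        return len(self.pooled_iei)


def pool_iei(trains: dict[str, list[np.ndarray]]) -> dict[str, EventTrainStats]:
    """Pool within-cell successive event-time differences per group.

    Cells with fewer than two events contribute nothing.  The pooled count is
    the sum over contributing cells of (n_events - 1).
    """
    out = {}
    for group, cells in trains.items():
        ieis = []
        means = []
        for times in cells:
            times = np.asarray(times, dtype=float)
            if len(times) < 2:
                continue
            d = np.diff(np.sort(times))
            ieis.append(d)
            means.append(d.mean())
        pooled = np.concatenate(ieis) if ieis else np.array([])
        out[group] = EventTrainStats(
            group=group,
            event_times=[np.asarray(t, dtype=float) for t in cells],
            pooled_iei=pooled,
            per_cell_mean_iei=np.array(means),
        )
    return out


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test, asymptotic p.

    D = sup |ECDF_a - ECDF_b|; p from the Kolmogorov distribution at the
    effective sample size n_a n_b / (n_a + n_b) (Smirnov's asymptotic
    formula).  An underflowing p is clamped to the smallest positive float
    (reported as "< realmin", never 0).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = len(a) * len(b) / (len(a) + len(b))
    p = float(stats.kstwo.sf(d, int(round(en))))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return d, p


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unpaired t-test (two-sided) with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
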