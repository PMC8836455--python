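"""Kinetic measurements on averaged concentration-jump responses.

Measures peak amplitude, a 20-100% single-exponential rise time constant,
a 90-10% one- or two-exponential decay (with the area-weighted time
constant reported for biexponential fits), area under the curve, paired
percent-of-control ratios, and the open-tip solution-exchange QC that
discards applications slower than 200 us.

All times are seconds and currents pA internally; report writers convert
to ms/nA for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = [
    "JumpFit",
    "RiseFit",
    "DecayFit",
    "ExchangeQC",
    "average_traces",
    "measure_peak",
    "fit_rise",
    "fit_decay",
    "area_under_curve",
    "percent_of_control",
    "measure_exchange",
    "analyze_jump",
]

EXCHANGE_LIMIT = 200e-6  # s; slower solution exchanges are discarded


@dataclass
class RiseFit:
    tau: float  # s
    amplitude: float  # pA, fitted or constrained asymptote
    exchange_limited: bool = False
    message: str = ""


@dataclass
class DecayFit:
    components: list  # [(tau_s, fractional_area), ...] sorted by tau
    weighted_tau: float  # s
    n_components: int = 1
    converged: bool = True
    message: str = ""


@dataclass
class ExchangeQC:
    """Open-tip junction-current QC for one application tool position."""

    rise_2080: float  # s
    decay_8020: float  # s
    accepted: bool = False

    def __post_init__(self):
        self.accepted = max(self.rise_2080, self.decay_8020) < EXCHANGE_LIMIT


@dataclass
class JumpFit:
    """Summary of one averaged jump response."""

    peak: float  # pA, baseline-subtracted, signed
    rise: RiseFit | None
    decay: DecayFit | None
    auc: float  # pA*s
    n_averaged: int = 1


def weighted_decay_tau(components) -> float:
    """Average of decay time constants weighted by fractional area."""
    taus = np.array([c[0] for c in components], dtype=float)
    areas = np.array([c[1] for c in components], dtype=float)
    if not math.isclose(areas.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("fractional areas must sum to 1")
    return float(np.sum(areas * taus))


# ---------------------------------------------------------------------------
# trace-level operations
# ---------------------------------------------------------------------------

def average_traces(traces):
    """Pointwise mean of traces sharing one sample grid."""
    from .synthetic_data import TraceRecord

    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("need at least two traces to average")
    if len(traces) < 5:
        warnings.warn("averaging fewer than 5 responses")
    ref = traces[0]
    for tr in traces[1:]:
        if len(tr) != len(ref) or tr.sample_rate != ref.sample_rate \
                or tr.start != ref.start:
            raise ValueError("traces must share an identical sample grid")
    mean = np.mean([tr.current for tr in traces], axis=0)
    out = TraceRecord(current=mean, sample_rate=ref.sample_rate, start=ref.start,
                      acquisition=ref.acquisition, labels=dict(ref.labels))
    out.labels["n_averaged"] = len(traces)
    return out


def _baseline(trace, baseline_window: float) -> float:
    n = max(int(round(baseline_window * trace.sample_rate)), 1)
    return float(np.mean(trace.current[:n]))


#: Gaussian sigma (samples) of the light smoothing used only to locate
#: peaks and amplitude crossings on noisy traces; fits use raw samples.
LANDMARK_SIGMA = 8.0


def _landmark_signal(x: np.ndarray, n_baseline: int) -> np.ndarray:
    """Return a lightly smoothed copy for peak/crossing detection when the
    trace is noisy; exact (noise-free) traces are used as-is so that
    sample-sharp features like exchange-limited steps stay sharp."""
    import scipy.ndimage

    noise = x[:max(n_baseline, 2)].std()
    if noise > 0.005 * max(np.abs(x).max(), 1e-30):
        return scipy.ndimage.gaussian_filter1d(x, LANDMARK_SIGMA)
    return x


def measure_peak(trace, baseline_window: float = 0.5e-3,
                 search_start: float | None = None) -> float:
    """Baseline-subtracted extremum, sign-aware (inward currents negative).

    The search starts after ``search_start`` (defaults to the end of the
    baseline window plus 0.5 ms, skipping exchange artifacts).
    """
    base = _baseline(trace, baseline_window)
    n0 = max(int(round(baseline_window * trace.sample_rate)), 1)
    x = _landmark_signal(trace.current - base, n0)
    t = trace.times - trace.start
    if search_start is None:
        search_start = baseline_window + 0.5e-3
    mask = t >= search_start
    if not mask.any():
        raise ValueError("baseline window leaves no samples to search")
    seg = x[mask]
    return float(seg[np.argmax(np.abs(seg))])


def _peak_index(x: np.ndarray, start: int) -> int:
    return start + int(np.argmax(np.abs(x[start:])))


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool,
                   lo: int, hi: int, last: bool = False) -> float:
    """Interpolated time at which y crosses ``level`` within [lo, hi)."""
    seg = y[lo:hi]
    if rising:
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if idx.size == 0:
        raise ValueError(f"no {'rising' if rising else 'falling'} crossing of level")
    i = lo + (idx[-1] if last else idx[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def fit_rise(trace, baseline_window: float = 0.5e-3,
             constrain_amplitude: bool = True) -> RiseFit:
    """Single-exponential fit of the 20-100% rising phase.

    By default the asymptote is constrained to the measured peak; rises
    spanning fewer than two sample intervals are flagged exchange-limited
    (the onset is then set by the solution exchange, not the receptor).
    """
    base = _baseline(trace, baseline_window)
    x = trace.current - base
    t = trace.times - trace.start
    n0 = max(int(round(baseline_window * trace.sample_rate)), 1)
    xl = _landmark_signal(x, n0)
    ipk = _peak_index(xl, n0)
    sign = math.copysign(1.0, xl[ipk])
    y = sign * x  # upward-going, raw (used for fitting)
    yl = sign * xl  # smoothed landmarks
    peak = yl[ipk]
    if peak <= 0:
        raise ValueError("no detectable peak")
    dt = 1.0 / trace.sample_rate

    t20 = _crossing_time(t, yl, 0.2 * peak, rising=True, lo=0, hi=ipk + 1, last=True)
    t80 = _crossing_time(t, yl, 0.8 * peak, rising=True, lo=0, hi=ipk + 1, last=True)
    if (t80 - t20) < 2 * dt:
        return RiseFit(tau=float("nan"), amplitude=sign * peak,
                       exchange_limited=True,
                       message="rise faster than two sample intervals; "
                               "limited by agonist exchange")
    seg = (t >= t20) & (t <= t[ipk])
    ts, ys = t[seg], y[seg]
    tau0 = max((t80 - t20) / math.log(4.0), dt)

    if constrain_amplitude:
        def model(tt, tau, tshift):
            return peak * (1.0 - np.exp(-(tt - tshift) / tau))
        p0 = [tau0, t20 - tau0 * math.log(1.0 / 0.8)]
        popt, _ = scipy.optimize.curve_fit(model, ts, ys, p0=p0, maxfev=5000)
        tau = abs(popt[0])
        amp = sign * peak
    else:
        def model(tt, amp_, tau, tshift):
            return amp_ * (1.0 - np.exp(-(tt - tshift) / tau))
        popt, _ = scipy.optimize.curve_fit(model, ts, ys,
                                           p0=[peak, tau0, t20], maxfev=5000)
        tau = abs(popt[1])
        amp = sign * popt[0]
    return RiseFit(tau=float(tau), amplitude=float(amp))


def _exp_sum(tt, *params):
    """Sum of decaying exponentials; params = a1, tau1, a2, tau2, ..."""
    out = np.zeros_like(tt)
    for j in range(0, len(params), 2):
        out += params[j] * np.exp(-tt / params[j + 1])
    return out


def fit_decay(trace, max_components: int = 2,
              baseline_window: float = 0.5e-3, alpha: float = 0.05) -> DecayFit:
    """Fit the 90-10% post-peak decay with one or two exponentials.

    The fit is anchored at the 90% crossing with the offset fixed at
    baseline.  The two-component model is accepted only when it improves
    the residual sum of squares significantly (F-test at ``alpha``) and
    both fractional areas are at least 5%; otherwise (or on
    non-convergence) the single exponential is reported.
    """
    base = _baseline(trace, baseline_window)
    x = trace.current - base
    t = trace.times - trace.start
    n0 = max(int(round(baseline_window * trace.sample_rate)), 1)
    xl = _landmark_signal(x, n0)
    ipk = _peak_index(xl, n0)
    sign = math.copysign(1.0, xl[ipk])
    y = sign * x
    yl = sign * xl
    peak = yl[ipk]

    t90 = _crossing_time(t, yl, 0.9 * peak, rising=False, lo=ipk, hi=len(y))
    try:
        t10 = _crossing_time(t, yl, 0.1 * peak, rising=False, lo=ipk, hi=len(y))
    except ValueError:
        t10 = float(t[-1])  # decay not complete within the sweep
    seg = (t >= t90) & (t <= t10)
    if seg.sum() < 10:
        raise ValueError("decay segment spans fewer than 10 samples")
    ts = t[seg] - t90
    ys = y[seg]

    span = max(ts[-1], 10.0 / trace.sample_rate)
    a0 = ys[0]
    tau0 = span / math.log(max(ys[0] / max(ys[-1], 1e-12 * ys[0]), 1.5))

    def fit_n(n_comp):
        if n_comp == 1:
            p0 = [a0, tau0]
        else:
            p0 = [0.6 * a0, tau0 / 3.0, 0.4 * a0, tau0 * 3.0]
        bounds = ([0.0, 1e-9] * n_comp, [np.inf, np.inf] * n_comp)
        popt, _ = scipy.optimize.curve_fit(_exp_sum, ts, ys, p0=p0,
                                           bounds=bounds, maxfev=20000)
        rss = float(np.sum((_exp_sum(ts, *popt) - ys) ** 2))
        return popt, rss

    p1, rss1 = fit_n(1)
    chosen, message, n_used = p1, "", 1
    if max_components >= 2:
        try:
            p2, rss2 = fit_n(2)
            ndata = ts.size
            df2 = ndata - 4
            if rss2 > 0 and df2 > 0:
                f = ((rss1 - rss2) / 2.0) / (rss2 / df2)
                p_f = 1.0 - scipy.stats.f.cdf(f, 2, df2)
                areas = np.array([p2[0] * p2[1], p2[2] * p2[3]])
                areas = areas / areas.sum()
                if p_f < alpha and areas.min() >= 0.05:
                    chosen, n_used = p2, 2
        except RuntimeError as err:
            message = f"two-exponential fit failed ({err}); single exponential reported"

    amps = chosen[0::2]
    taus = np.abs(chosen[1::2])
    areas = amps * taus
    areas = areas / areas.sum()
    order = np.argsort(taus)
    components = [(float(taus[i]), float(areas[i])) for i in order]
    return DecayFit(components=components,
                    weighted_tau=weighted_decay_tau(components),
                    n_components=n_used, converged=True, message=message)


def area_under_curve(trace, window: tuple[float, float] | None = None,
                     baseline_window: float = 0.5e-3,
                     baseline: float | None = None) -> float:
    """Trapezoidal integral of the baseline-subtracted current (pA*s).

    ``window`` is (t_start, t_stop) relative to the trace start; the whole
    trace is integrated when omitted.  ``baseline`` overrides the
    baseline-window estimate when given.
    """
    base = baseline if baseline is not None else _baseline(trace, baseline_window)
    x = trace.current - base
    t = trace.times - trace.start
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, x = t[mask], x[mask]
    return float(np.trapezoid(x, t))


def percent_of_control(test: float, control: float) -> float:
    """100 * test / control (e.g. pH 6.4 peak as % of same-patch pH 7.4)."""
    if control == 0:
        raise ValueError("control measurement must be non-zero")
    return 100.0 * test / control


def measure_exchange(open_tip_trace) -> ExchangeQC:
    """20-80% rise and 80-20% decay times of an open-tip junction current.

    The application passes QC only when both are faster than 200 us.
    """
    x = np.asarray(open_tip_trace.current, dtype=float)
    t = open_tip_trace.times - open_tip_trace.start
    base = float(np.mean(x[: max(len(x) // 50, 2)]))
    d = x - base
    ipk = int(np.argmax(np.abs(d)))
    sign = math.copysign(1.0, d[ipk])
    y = sign * d
    peak = y[ipk]
    plateau = y[y >= 0.9 * peak]
    if plateau.size < 2:
        raise ValueError("no plateau found in the junction current")
    amp = float(np.median(plateau))

    t20r = _crossing_time(t, y, 0.2 * amp, rising=True, lo=0, hi=ipk + 1)
    t80r = _crossing_time(t, y, 0.8 * amp, rising=True, lo=0, hi=ipk + 1)
    t80f = _crossing_time(t, y, 0.8 * amp, rising=False, lo=ipk, hi=len(y))
    t20f = _crossing_time(t, y, 0.2 * amp, rising=False, lo=ipk, hi=len(y))
    return ExchangeQC(rise_2080=t80r - t20r, decay_8020=t20f - t80f)


def analyze_jump(trace, max_components: int = 2,
                 baseline_window: float = 0.5e-3,
                 n_averaged: int = 1) -> JumpFit:
    """Full measurement bundle for one averaged jump response."""
    peak = measure_peak(trace, baseline_window)
    rise = fit_rise(trace, baseline_window)
    decay = fit_decay(trace, max_components, baseline_window)
    auc = area_under_curve(trace, baseline_window=baseline_window)
    return JumpFit(peak=peak, rise=rise, decay=decay, auc=auc,
                   n_averaged=n_averaged)
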