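"""Trace idealization, cluster segmentation and per-cluster open probability.

Single-channel current traces are converted to alternating open/shut dwell
sequences with a half-amplitude threshold-crossing rule, a fixed temporal
resolution (dead time) is imposed, and clusters of openings bounded by long
shut periods are segmented so that each cluster's open probability
(total open time / cluster duration) can be measured with desensitised
stretches excised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage

from .mechanism import CLASS_DESENS, CLASS_OPEN, CLASS_SHUT

__all__ = [
    "DwellSequence",
    "Cluster",
    "IVFit",
    "gaussian_lowpass",
    "half_amplitude_idealize",
    "impose_resolution",
    "segment_clusters",
    "cluster_popen",
    "fit_iv_slope",
]

#: sigma of a Gaussian filter (in time units) with -3 dB corner fc
GAUSSIAN_SIGMA_FACTOR = 0.1325


@dataclass
class DwellSequence:
    """Contiguous, non-overlapping dwells with class labels.

    ``durations[k]`` (s) is the length of the k-th dwell of class
    ``classes[k]``; dwells tile the interval ``[start, start + total)``.
    ``amplitude`` records the open-channel current (pA) the sequence was
    idealized at, when known.
    """

    durations: np.ndarray
    classes: np.ndarray
    start: float = 0.0
    amplitude: float | None = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.durations.shape != self.classes.shape:
            raise ValueError("durations and classes must have equal length")
        if np.any(self.durations <= 0) or not np.all(np.isfinite(self.durations)):
            raise ValueError("dwell durations must be positive and finite")

    def __len__(self) -> int:
        return self.durations.size

    @property
    def starts(self) -> np.ndarray:
        return self.start + np.concatenate(([0.0], np.cumsum(self.durations)[:-1]))

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def open_fraction(self) -> float:
        is_open = self.classes == CLASS_OPEN
        return float(self.durations[is_open].sum() / self.total_duration)

    def merge_adjacent(self) -> "DwellSequence":
        """Coalesce consecutive dwells sharing a class."""
        if len(self) == 0:
            return self
        durs, classes = [], []
        for d, c in zip(self.durations, self.classes):
            if classes and classes[-1] == c:
                durs[-1] += d
            else:
                durs.append(float(d))
                classes.append(c)
        return DwellSequence(np.array(durs), np.array(classes, dtype=object),
                            start=self.start, amplitude=self.amplitude)

    def with_classes_binarized(self) -> "DwellSequence":
        """Map desensitised (and any non-open) dwells to shut."""
        classes = np.where(self.classes == CLASS_OPEN, CLASS_OPEN, CLASS_SHUT)
        return DwellSequence(self.durations.copy(), classes.astype(object),
                            start=self.start, amplitude=self.amplitude).merge_adjacent()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start_s": self.starts,
            "duration_s": self.durations,
            "class": self.classes.astype(str),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, amplitude: float | None = None) -> "DwellSequence":
        start = float(df["start_s"].iloc[0]) if len(df) else 0.0
        return cls(df["duration_s"].to_numpy(float),
                   df["class"].to_numpy(object), start=start, amplitude=amplitude)


@dataclass
class Cluster:
    """A run of openings bounded by long shut periods.

    ``duration`` spans first opening to last closing; ``popen`` is the
    fraction of that span spent open.  ``censored`` marks clusters whose
    bounding gap is cut off by a record edge.
    """

    dwells: DwellSequence
    start: float
    duration: float
    total_open: float
    popen: float
    censored: bool = False

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("cluster duration must be positive")
        if not 0.0 <= self.popen <= 1.0:
            raise ValueError("cluster Popen must lie in [0, 1]")


@dataclass
class IVFit:
    """Single-channel current-voltage line: slope conductance and offset."""

    points: list
    slope_conductance: float  # pS
    intercept: float  # pA


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def gaussian_filter_samples(x: np.ndarray, sample_rate: float, corner: float) -> np.ndarray:
    """Zero-phase Gaussian smoothing with -3 dB corner ``corner`` (Hz)."""
    sigma = GAUSSIAN_SIGMA_FACTOR * sample_rate / corner
    return scipy.ndimage.gaussian_filter1d(x, sigma, mode="nearest")


def gaussian_lowpass(trace, corner: float):
    """Gaussian low-pass filter a trace (DC gain 1, zero phase)."""
    from .synthetic_data import TraceRecord  # local import to avoid a cycle

    if corner >= trace.sample_rate / 2:
        raise ValueError("filter corner must lie below the Nyquist frequency")
    return TraceRecord(
        current=gaussian_filter_samples(trace.current, trace.sample_rate, corner),
        sample_rate=trace.sample_rate,
        start=trace.start,
        acquisition=trace.acquisition,
        labels=dict(trace.labels),
    )


def cascade_corner(*corners: float) -> float:
    """Effective -3 dB corner of cascaded Gaussian filters."""
    return float(sum(f ** -2 for f in corners) ** -0.5)


# ---------------------------------------------------------------------------
# idealization
# ---------------------------------------------------------------------------

def estimate_levels(current: np.ndarray) -> tuple[float, float]:
    """Baseline and open-channel amplitude from the all-points histogram.

    A two-component Gaussian mixture is fitted to (a subsample of) the
    current values; the dominant mode is taken as the shut baseline and
    the mode separation as the open-channel amplitude (signed).
    """
    x = np.asarray(current, dtype=float)
    if x.size > 50000:
        x = x[:: x.size // 50000 + 1]
    from sklearn.mixture import GaussianMixture  # deferred: heavy import

    gm = GaussianMixture(n_components=2, random_state=0, n_init=2).fit(x[:, None])
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    base = means[np.argmax(weights)]
    other = means[np.argmin(weights)]
    return float(base), float(other - base)


def half_amplitude_idealize(trace, baseline: float | None = None,
                            amplitude: float | None = None) -> DwellSequence:
    """Idealize a trace by half-amplitude threshold crossing.

    The threshold sits at ``baseline + amplitude/2``; crossing times are
    interpolated linearly between samples, so dwell durations are not
    quantized to the sample interval.  When levels are not supplied they
    are estimated from the all-points histogram.
    """
    x = np.asarray(trace.current, dtype=float)
    if baseline is None or amplitude is None:
        baseline, amplitude = estimate_levels(x)
    if amplitude == 0:
        raise ValueError("open-channel amplitude must be non-zero")
    s = (x - baseline) / amplitude  # polarity-normalized: open -> ~1
    above = s > 0.5
    dt = 1.0 / trace.sample_rate
    t_end = trace.start + (x.size - 1) * dt

    if not above.any():
        warnings.warn("trace never crosses the half-amplitude threshold")
        return DwellSequence(np.array([t_end - trace.start + dt]),
                            np.array([CLASS_SHUT], dtype=object),
                            start=trace.start, amplitude=amplitude)

    flips = np.flatnonzero(np.diff(above.astype(np.int8)) != 0)
    # sub-sample crossing time between samples i and i+1
    t_cross = trace.start + dt * (flips + (0.5 - s[flips]) / (s[flips + 1] - s[flips]))

    edges = np.concatenate(([trace.start], t_cross, [t_end + dt]))
    durations = np.diff(edges)
    first = CLASS_OPEN if above[0] else CLASS_SHUT
    classes = np.empty(durations.size, dtype=object)
    classes[0::2] = first
    classes[1::2] = CLASS_OPEN if first == CLASS_SHUT else CLASS_SHUT
    keep = durations > 0
    return DwellSequence(durations[keep], classes[keep],
                        start=trace.start, amplitude=amplitude).merge_adjacent()


def impose_resolution(dwells: DwellSequence, dead_time: float) -> DwellSequence:
    """Impose a fixed temporal resolution on a dwell sequence.

    Dwells shorter than ``dead_time`` are deemed undetected and their
    duration is concatenated into the preceding resolved dwell (the
    standard retrospective rule); the output alternates strictly and
    conserves total duration exactly.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    if dead_time == 0 or len(dwells) == 0:
        return dwells
    durs = dwells.durations
    classes = dwells.classes
    resolved = np.flatnonzero(durs >= dead_time)
    if resolved.size == 0:
        cls = classes[np.argmax(durs)]
        return DwellSequence(np.array([durs.sum()]), np.array([cls], dtype=object),
                            start=dwells.start, amplitude=dwells.amplitude)
    first = resolved[0]
    out_d = [float(durs[: first + 1].sum())]  # leading unresolved join the seed
    out_c = [classes[first]]
    for k in range(first + 1, len(durs)):
        if durs[k] < dead_time or classes[k] == out_c[-1]:
            out_d[-1] += float(durs[k])
        else:
            out_d.append(float(durs[k]))
            out_c.append(classes[k])
    return DwellSequence(np.array(out_d), np.array(out_c, dtype=object),
                        start=dwells.start, amplitude=dwells.amplitude)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def segment_clusters(dwells: DwellSequence, min_gap: float = 0.100,
                     min_duration: float = 0.100,
                     keep_censored: bool = True) -> list[Cluster]:
    """Segment a dwell sequence into clusters of openings.

    Any non-open dwell (shut or desensitised) at least ``min_gap`` long
    separates clusters; clusters begin and end with open dwells and are
    discarded when shorter than ``min_duration``.  Clusters whose
    bounding gap is truncated by a record edge are kept (if long enough)
    but flagged censored.
    """
    seq = dwells.with_classes_binarized()
    if len(seq) == 0:
        return []
    durs, classes, starts = seq.durations, seq.classes, seq.starts
    is_open = classes == CLASS_OPEN
    open_idx = np.flatnonzero(is_open)
    if open_idx.size == 0:
        return []
    # shut dwells >= min_gap split the record
    gap_idx = np.flatnonzero(~is_open & (durs >= min_gap))
    bounds = np.concatenate(([-1], gap_idx, [len(seq)]))
    clusters: list[Cluster] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        inside = open_idx[(open_idx > lo) & (open_idx < hi)]
        if inside.size == 0:
            continue
        a, b = inside[0], inside[-1]
        span = float(starts[b] + durs[b] - starts[a])
        total_open = float(durs[a:b + 1][classes[a:b + 1] == CLASS_OPEN].sum())
        censored = (lo == -1 and a == 0) or (hi == len(seq) and b == len(seq) - 1)
        if span < min_duration:
            continue
        if censored and not keep_censored:
            continue
        sub = DwellSequence(durs[a:b + 1].copy(), classes[a:b + 1].copy(),
                            start=float(starts[a]), amplitude=seq.amplitude)
        clusters.append(Cluster(dwells=sub, start=float(starts[a]), duration=span,
                                total_open=total_open, popen=total_open / span,
                                censored=censored))
    return clusters


def cluster_popen(cluster: Cluster) -> float:
    """Open probability of one cluster: total open time / cluster duration."""
    return cluster.total_open / cluster.duration


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame({
        "cluster_id": np.arange(len(clusters)),
        "start_s": [c.start for c in clusters],
        "duration_s": [c.duration for c in clusters],
        "popen": [c.popen for c in clusters],
        "censored": [c.censored for c in clusters],
    })


# ---------------------------------------------------------------------------
# conductance
# ---------------------------------------------------------------------------

def fit_iv_slope(points) -> IVFit:
    """Least-squares line through (voltage mV, amplitude pA) points.

    The slope in pA/mV is converted to slope conductance in pS.
    """
    pts = [(float(v), float(i)) for v, i in points]
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    if np.unique(v).size < 2:
        raise ValueError("at least two distinct voltages are required")
    slope, intercept = np.polyfit(v, i, 1)
    return IVFit(points=pts, slope_conductance=float(slope * 1e3),
                 intercept=float(intercept))


def has_double_openings(trace, baseline: float, amplitude: float,
                        factor: float = 1.5) -> bool:
    """QC flag: any sample beyond ``factor`` times the single-channel level
    (evidence of two simultaneously open channels)."""
    s = (np.asarray(trace.current) - baseline) / amplitude
    return bool(np.any(s > factor))
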