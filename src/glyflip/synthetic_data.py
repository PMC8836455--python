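"""Synthetic electrophysiology with known ground truth.

Generates the three kinds of input the analysis stages consume:

* stochastic single-channel cluster recordings (continuous-time Markov
  trajectories rendered as noisy, Gaussian-filtered current traces, with
  the ground-truth dwell sequence retained),
* per-cell Hill-shaped concentration-response studies with cell-to-cell
  scatter and multiplicative response noise,
* deterministic macroscopic responses to millisecond agonist pulses with
  a finite solution-exchange time, propagated with piecewise matrix
  exponentials of the mechanism's generator.

Everything random is seeded; identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .concentration_response import CRCCell, CRCStudy
from .idealization import (CLASS_DESENS, CLASS_OPEN, CLASS_SHUT, DwellSequence,
                           gaussian_filter_samples, segment_clusters)
from .mechanism import (FlipMechanism, GeneratorMatrix, build_generator,
                        build_saturated_core, equilibrium_distribution)

__all__ = [
    "AcquisitionConfig",
    "JumpProtocol",
    "TraceRecord",
    "sample_trajectory",
    "simulate_cluster_recording",
    "render_current",
    "simulate_crc_study",
    "simulate_jump_response",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings for rendering/recording a current trace.

    Defaults mirror cell-attached single-channel conditions: 100 kHz
    sampling, an additional 3 kHz Gaussian filter and resampling to
    33.3 kHz for analysis.
    """

    sample_rate: float = 100e3  # Hz
    filter_corner: float | None = 3e3  # Hz, -3 dB of the Gaussian filter
    resample_rate: float | None = 100e3 / 3
    noise_sd: float = 1.0  # pA, added after filtering
    single_channel_current: float = 7.0  # pA (sign sets polarity)
    holding_potential: float = 100.0  # mV, metadata only

    def __post_init__(self):
        if self.filter_corner is not None and self.sample_rate <= 2 * self.filter_corner:
            raise ValueError("sample_rate must exceed twice the filter corner")
        if self.resample_rate is not None and self.resample_rate > self.sample_rate:
            raise ValueError("cannot resample above the acquisition rate")


@dataclass(frozen=True)
class JumpProtocol:
    """Fast-application protocol: a brief agonist pulse to an excised patch.

    The 2 ms, ~3 mM pulse with ~150 us 20-80% exchange mimics the glycine
    transient at a synapse.  ``duration`` is the total simulated sweep
    length and ``onset`` the pre-pulse baseline time.
    """

    pulse_concentration: float = 3e-3  # M
    pulse_duration: float = 2e-3  # s
    exchange_time_2080: float = 150e-6  # s
    inter_pulse_interval: float = 20.0  # s (metadata)
    n_channels: int = 500
    duration: float = 0.15  # s
    onset: float = 1e-3  # s

    def __post_init__(self):
        if self.pulse_concentration < 0:
            raise ValueError("pulse concentration must be non-negative")
        if self.exchange_time_2080 >= self.pulse_duration:
            raise ValueError("exchange time must be shorter than the pulse")
        if self.onset + self.pulse_duration >= self.duration:
            raise ValueError("sweep too short for the pulse")


@dataclass
class TraceRecord:
    """Uniformly sampled current with acquisition metadata."""

    current: np.ndarray  # pA
    sample_rate: float  # Hz (effective, after any resampling)
    start: float = 0.0  # s
    acquisition: AcquisitionConfig | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        if self.current.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("trace contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.current.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.current.size / self.sample_rate

    def __len__(self) -> int:
        return self.current.size


# ---------------------------------------------------------------------------
# stochastic trajectories
# ---------------------------------------------------------------------------

def sample_trajectory(Q: GeneratorMatrix, t_max: float, seed,
                      start_state: int | None = None) -> DwellSequence:
    """Sample one continuous-time Markov path and aggregate it into dwells.

    Sojourns are exponential with rate -Q[i,i]; jump targets follow
    Q[i,j]/-Q[i,i].  Consecutive sojourns in states of the same class are
    merged, so the output alternates between classes.  The final dwell is
    truncated at ``t_max`` (total duration is exactly ``t_max``).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    q = Q.rates
    n = q.shape[0]
    exit_rates = -np.diag(q)
    if np.any(exit_rates <= 0):
        raise ValueError("absorbing state without escape in the generator")
    jump = q - np.diag(np.diag(q))
    cum_jump = np.cumsum(jump / exit_rates[:, None], axis=1)

    rng = np.random.default_rng(seed)
    state = 0 if start_state is None else int(start_state)
    t = 0.0
    states: list[int] = []
    durs: list[float] = []
    BUF = 8192
    done = False
    while not done:
        u = rng.random(BUF)
        e = rng.exponential(1.0, BUF)
        for k in range(BUF):
            dwell = e[k] / exit_rates[state]
            if t + dwell >= t_max:
                states.append(state)
                durs.append(t_max - t)
                done = True
                break
            states.append(state)
            durs.append(dwell)
            t += dwell
            state = int(np.searchsorted(cum_jump[state], u[k], side="right"))

    classes = np.asarray([Q.state_classes[s] for s in states], dtype=object)
    return DwellSequence(np.asarray(durs), classes).merge_adjacent()


def _concat_dwells(parts: list[DwellSequence]) -> DwellSequence:
    durs = np.concatenate([p.durations for p in parts])
    classes = np.concatenate([p.classes for p in parts])
    return DwellSequence(durs, classes, start=parts[0].start).merge_adjacent()


def _crop_dwells(seq: DwellSequence, t_stop: float) -> DwellSequence:
    """Truncate a dwell sequence (relative to its start) at ``t_stop``."""
    ends = np.cumsum(seq.durations)
    keep = np.searchsorted(ends, t_stop, side="left") + 1
    durs = seq.durations[:keep].copy()
    overshoot = ends[keep - 1] - t_stop
    if overshoot > 0:
        durs[-1] -= overshoot
    good = durs > 0
    return DwellSequence(durs[good], seq.classes[:keep][good].copy(),
                        start=seq.start, amplitude=seq.amplitude)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_current(dwells: DwellSequence, acquisition: AcquisitionConfig,
                   seed=None, include_noise: bool = True) -> TraceRecord:
    """Render a dwell sequence as a sampled, filtered, noisy current trace.

    Each sample carries the open-channel current weighted by the fraction
    of its sample interval spent open (area-accurate sample-and-hold), so
    dwells shorter than one sample are attenuated, never dropped.  The
    trace is then Gaussian filtered, optionally resampled, and white
    Gaussian noise is added.  Desensitised dwells sit at the shut
    (baseline) level.
    """
    if len(dwells) == 0:
        raise ValueError("dwell sequence is empty")
    fs = acquisition.sample_rate
    total = dwells.total_duration
    n = max(int(round(total * fs)), 2)

    # cumulative open time as a piecewise-linear function of time
    edges = np.concatenate(([0.0], np.cumsum(dwells.durations)))
    is_open = dwells.classes == CLASS_OPEN
    cum_open = np.concatenate(([0.0], np.cumsum(np.where(is_open, dwells.durations, 0.0))))
    sample_edges = np.arange(n + 1) / fs
    frac = np.diff(np.interp(sample_edges, edges, cum_open)) * fs
    x = acquisition.single_channel_current * frac

    if acquisition.filter_corner is not None:
        x = gaussian_filter_samples(x, fs, acquisition.filter_corner)
    rate = fs
    if acquisition.resample_rate is not None and acquisition.resample_rate < fs:
        factor = fs / acquisition.resample_rate
        if abs(factor - round(factor)) < 1e-9:
            x = x[:: int(round(factor))]
        else:
            t_new = np.arange(int(math.floor(total * acquisition.resample_rate))) \
                / acquisition.resample_rate
            x = np.interp(t_new, np.arange(n) / fs, x)
        rate = acquisition.resample_rate
    if include_noise and acquisition.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, acquisition.noise_sd, x.size)
    return TraceRecord(current=x, sample_rate=rate, start=dwells.start,
                       acquisition=acquisition)


# ---------------------------------------------------------------------------
# cluster recordings
# ---------------------------------------------------------------------------

def simulate_cluster_recording(
    mech: FlipMechanism,
    concentration: float,
    n_clusters: int,
    acquisition: AcquisitionConfig,
    seed,
    min_gap: float = 0.100,
    min_duration: float = 0.100,
    max_tries: int = 10,
) -> tuple[TraceRecord, DwellSequence]:
    """Simulate a cell-attached recording containing qualifying clusters.

    The channel cycles between a long-lived desensitised state and runs of
    activity; the recording is extended until ``n_clusters`` clusters
    satisfy the >=``min_duration`` / >=``min_gap`` rules.  Returns the
    rendered trace and the ground-truth dwell sequence (desensitised
    dwells keep their class so the truth can be segmented identically).

    ``concentration=math.inf`` simulates the saturated three-state core.
    """
    if mech.desens_on <= 0 or mech.desens_off <= 0:
        raise ValueError("cluster recordings need non-zero desensitisation rates")
    if math.isinf(concentration):
        Q = build_saturated_core(mech.E_levels[-1], mech.F_levels[-1],
                                 close_rate=mech.close_rate[-1],
                                 flip_off=mech.flip_off[-1],
                                 desens_on=mech.desens_on,
                                 desens_off=mech.desens_off)
    else:
        Q = build_generator(mech, concentration)

    if n_clusters == 0:
        n = int(round(0.1 * acquisition.sample_rate))
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, acquisition.noise_sd, max(n, 2))
        trace = TraceRecord(current=noise, sample_rate=acquisition.sample_rate,
                            acquisition=acquisition)
        empty = DwellSequence(np.array([0.1]), np.array([CLASS_SHUT], dtype=object))
        return trace, empty

    d_idx = Q.state_classes.index(CLASS_DESENS)
    pi = equilibrium_distribution(Q)
    entry_rate = pi[d_idx] * mech.desens_off  # cluster starts per second
    t_chunk = 2.0 * n_clusters / entry_rate + 5.0 / mech.desens_off

    parts: list[DwellSequence] = []
    for attempt in range(max_tries):
        parts.append(sample_trajectory(Q, t_chunk, seed + 7919 * attempt,
                                       start_state=d_idx))
        combined = _concat_dwells(parts)
        clusters = segment_clusters(combined, min_gap=min_gap,
                                    min_duration=min_duration, keep_censored=False)
        if len(clusters) >= n_clusters:
            break
    else:
        raise RuntimeError(
            f"only {len(clusters)} qualifying clusters after {max_tries} chunks; "
            "desensitisation rates produce too few clusters")

    last = clusters[n_clusters - 1]
    t_cut = min(last.start + last.duration + 1.01 * min_gap,
                combined.total_duration)
    truth = _crop_dwells(combined, t_cut)
    trace = render_current(truth, acquisition, seed=seed + 104729)
    return trace, truth


# ---------------------------------------------------------------------------
# concentration-response studies
# ---------------------------------------------------------------------------

def simulate_crc_study(
    true_imax: float,
    true_ec50: float,
    true_nh: float,
    concentrations,
    n_cells: int,
    cell_cv: float = 0.2,
    noise_cv: float = 0.1,
    seed=None,
    agonist: str = "glycine",
    ph: str = "7.4",
    reference_imax: float | None = None,
) -> CRCStudy:
    """Simulate per-cell dose-response curves around known Hill parameters.

    Cell-level maxima scatter lognormally with coefficient of variation
    ``cell_cv`` (mean preserved); responses carry multiplicative lognormal
    noise of CV ``noise_cv``.  Each cell also gets a same-cell saturating
    glycine reference (``reference_imax`` defaults to ``true_imax``,
    scaled by the same cell factor).
    """
    c = np.asarray(list(concentrations), dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 concentrations spanning the EC50")
    rng = np.random.default_rng(seed)
    ref_imax = true_imax if reference_imax is None else reference_imax

    def lognorm_factor(cv, size=None):
        if cv <= 0:
            return 1.0 if size is None else np.ones(size)
        s = math.sqrt(math.log(1.0 + cv ** 2))
        return np.exp(rng.normal(-0.5 * s * s, s, size))

    cells = []
    for k in range(n_cells):
        cell_factor = float(lognorm_factor(cell_cv))
        clean = true_imax * cell_factor * c ** true_nh / (c ** true_nh + true_ec50 ** true_nh)
        responses = clean * lognorm_factor(noise_cv, c.size)
        reference = float(ref_imax * cell_factor * lognorm_factor(noise_cv))
        cells.append(CRCCell(
            cell_id=f"cell{k:02d}", agonist=agonist, ph=ph,
            concentrations=c.copy(), peak_responses=responses,
            reference_saturating_response=reference))
    truth = {"imax": true_imax, "ec50": true_ec50, "nh": true_nh,
             "cell_cv": cell_cv, "noise_cv": noise_cv}
    return CRCStudy(cells=cells, truth=truth)


# ---------------------------------------------------------------------------
# concentration jumps
# ---------------------------------------------------------------------------

def _concentration_profile(t: np.ndarray, protocol: JumpProtocol) -> np.ndarray:
    """Smooth switch: exponential saturation/decay with tau = t2080/ln 4,
    so the 20-80% transition time is exactly the configured exchange time."""
    tau = protocol.exchange_time_2080 / math.log(4.0)
    t0 = protocol.onset
    t1 = t0 + protocol.pulse_duration
    c = np.zeros_like(t)
    rising = (t >= t0) & (t < t1)
    c[rising] = 1.0 - np.exp(-(t[rising] - t0) / tau)
    c_end = 1.0 - math.exp(-protocol.pulse_duration / tau)
    falling = t >= t1
    c[falling] = c_end * np.exp(-(t[falling] - t1) / tau)
    return protocol.pulse_concentration * c


def simulate_jump_response(
    mech: FlipMechanism,
    protocol: JumpProtocol,
    acquisition: AcquisitionConfig,
    seed=None,
    reuse_tolerance: float = 0.01,
) -> TraceRecord:
    """Deterministic macroscopic response to a fast agonist pulse.

    State occupancies are propagated with piecewise-constant matrix
    exponentials: within each sample interval the concentration is frozen
    at its midpoint value, and a cached propagator is reused while the
    concentration changes by less than ``reuse_tolerance`` (relative).
    Current is n_channels * single-channel current * open occupancy,
    then filtered (and noise added only if the acquisition requests it).
    """
    fs = acquisition.sample_rate
    dt = 1.0 / fs
    n = int(round(protocol.duration * fs))
    t = np.arange(n) * dt
    c_mid = _concentration_profile(t + 0.5 * dt, protocol)

    Q0 = build_generator(mech, 0.0)
    open_mask = Q0.open_states.astype(float)
    p = np.zeros(Q0.n_states)
    p[Q0.state_names.index("R0")] = 1.0  # rested, unliganded

    popen = np.empty(n)
    floor = max(protocol.pulse_concentration, 1.0) * 1e-12
    c_used = None
    propagator = None
    for k in range(n):
        popen[k] = p @ open_mask
        c_k = c_mid[k] if c_mid[k] > floor else 0.0
        if (c_used is None or
                (c_k == 0.0) != (c_used == 0.0) or
                (c_k > 0.0 and abs(c_k - c_used) > reuse_tolerance * c_used)):
            propagator = scipy.linalg.expm(build_generator(mech, c_k).rates * dt)
            c_used = c_k
        p = p @ propagator

    x = protocol.n_channels * acquisition.single_channel_current * popen
    if acquisition.filter_corner is not None:
        x = gaussian_filter_samples(x, fs, acquisition.filter_corner)
    if acquisition.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, acquisition.noise_sd, x.size)
    return TraceRecord(current=x, sample_rate=fs, acquisition=acquisition,
                       labels={"pulse_concentration_m": protocol.pulse_concentration,
                               "pulse_duration_s": protocol.pulse_duration,
                               "onset_s": protocol.onset})


def propagate_constant(Q: GeneratorMatrix, p0: np.ndarray, t: float) -> np.ndarray:
    """Exact occupancy after time ``t`` under a fixed generator."""
    return np.asarray(p0, dtype=float) @ scipy.linalg.expm(Q.rates * t)
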