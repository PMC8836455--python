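# Methods

## The gating model

GlyR activation is modelled as an aggregated continuous-time Markov
chain built on the flip mechanism. With `n_sites = 3` identical binding
sites the state space is

    R0 – R1 – R2 – R3        resting, 0–3 agonists bound
          |    |    |
          F1   F2   F3       flipped (pre-opening) at each liganded level
          |    |    |
          O1   O2   O3       open
                    |
                    D        long-lived desensitised (off the fully
                             liganded resting state; simulation only)

Binding steps carry the statistical factors for identical independent
sites (forward rate (n−i)·k_on·c for step i→i+1, backward (i+1)·k_off).
The graph is a tree, so with desensitisation zeroed detailed balance
holds automatically and the equilibrium open occupancy of the top level
equals the closed form `max Popen = E_eff/(E_eff+1)` with
`E_eff = E·F/(F+1)` (E = open/close, F = flip_on/flip_off of the fully
liganded level). At saturating agonist the chain collapses to the
three-state core R–F–O (`build_saturated_core`), the model used for the
single-channel open-probability computations.

Assumptions worth stating: sites are identical and independent; flipping
is concerted (one flipped state per ligation level); there is a single
aggregate desensitised state; binding among flipped states is omitted
(this keeps the graph a tree — at saturation, where the quantitative
claims live, those transitions are never vacated anyway).

## Parameters

Equilibrium constants are the quantities the analysis constrains;
absolute rates only set dwell-time scales. Defaults:

| parameter | default | units | why |
|---|---|---|---|
| E (fully liganded) | 38 | – | mammalian homomeric reference |
| F (fully liganded) | 8 | – | mammalian homomeric reference |
| close_rate | 7 000 | s⁻¹ | plausible open-dwell scale (~0.14 ms); open_rate = E·close_rate |
| flip_off | 15 000 | s⁻¹ | brief flipped sojourns; flip_on = F·flip_off |
| partial_scale | 0.1 | – | E_i, F_i scaled down 10× per vacant site; only the top level enters the headline results |
| k_on | 5×10⁶ | M⁻¹s⁻¹ | per-site association, typical for small agonists |
| k_off | 2 000 | s⁻¹ | per-site dissociation; sets deactivation scale |
| desens_on / desens_off | 125 / 1.0 | s⁻¹ | ~1 s clusters separated by ~1 s gaps (calibration knobs, not mechanistic claims) |

"Saturating" is defined operationally: the concentration at which
sub-maximally liganded states hold < 0.1 % equilibrium occupancy
(`saturating_concentration`, found by doubling). A uniform loss of
gating efficacy is realised by dividing every level's opening rate
(`with_efficacy_divided`), the simplest kinetic change consistent with
E being the pH-sensitive constant.

## Equilibria and propagation

Stationary distributions are solved from the null space of the
transposed generator (not by detailed-balance chaining), so cycles added
later would not break the solver. A chain is accepted when it has a
unique closed communicating class; strict irreducibility would wrongly
reject the zero-concentration generator, whose unique stationary law
(all mass in R0) is still well defined.

Concentration-jump responses integrate dp/dt = p·Q(c(t)) by piecewise
matrix exponentials on the sample grid, freezing c at each interval
midpoint and reusing a cached propagator while c changes by < 1 % —
unconditionally stable for stiff generators and exact for
piecewise-constant c (verified against the two-state closed form to
better than 1e-6 relative). The agonist switch is an exponential
saturation/decay with τ = t₂₀₋₈₀/ln 4, so the configured 20–80 %
exchange time is exact.

## The synthetic-data generator

It emulates three experiment types and retains ground truth for every
output:

- **Cell-attached cluster recordings.** Trajectories are sampled by the
  embedded-chain (Gillespie) construction; sojourns are aggregated into
  open/shut/desensitised dwells. Rendering is area-accurate
  sample-and-hold (each sample carries the open-time fraction of its
  interval, so sub-sample dwells are attenuated, never dropped),
  followed by a Gaussian filter (σ = 0.1325/f_c, the standard −3 dB
  relation; cascades combine as (Σf_i⁻²)^(−1/2)), optional resampling
  (100 kHz → 33.3 kHz default) and additive white Gaussian noise.
  Desensitised dwells render at the shut level.
- **Dose–response studies.** Per-cell Hill curves with lognormal
  cell-level maxima (CV `cell_cv`, mean preserved) and multiplicative
  lognormal response noise (CV `noise_cv`), plus a same-cell saturating
  reference sharing the cell factor.
- **Concentration jumps.** Deterministic macroscopic currents,
  n_channels · i_single · P(open)(t), noiseless unless requested.

What it does **not** emulate: seal/leak artifacts, capacitive
transients, series-resistance error, baseline drift, multi-channel
patches, or subconductance levels. Passing tests therefore demonstrate
correctness of the analysis chain under idealised recording conditions,
not robustness to every pathology of real patches.

Two calibration notes. First, because inter-cluster gaps are exponential,
a fraction shorter than the 100 ms rule merges adjacent clusters and
drags measured cluster Popen slightly below the equilibrium value; with
the default ~1 s gaps this bias is ≲ 0.5 %, well inside Monte-Carlo
error. Second, the cluster-recovery checks use a slowed copy of the
saturated core (close_rate 70 s⁻¹, flip_off 150 s⁻¹, same E and F) so
that intra-cluster shut dwells (~1 ms mean) exceed ten times the 3 kHz
filter dead time — the regime in which half-amplitude idealization is
expected to be faithful.

## Idealization

Half-amplitude threshold crossing with sub-sample linear interpolation
of crossing times (reduces quantisation bias at 33.3 kHz). When levels
are not supplied they are estimated from a two-component Gaussian
mixture fit to the all-points histogram (dominant mode = baseline, mode
separation = amplitude). A fixed dead time, default 0.3/f_c (≈ the
filter's effective resolution), is imposed retrospectively: unresolved
intervals are concatenated into the preceding resolved dwell, conserving
total time exactly. Clusters split at non-open dwells ≥ 100 ms, must
last ≥ 100 ms, span first to last opening, and are flagged (not
silently kept) when truncated by a record edge; samples beyond 1.5× the
single-channel amplitude raise a double-opening QC flag.

## Hill fits

Per-cell only (pooled fits are display-only by design). Imax and EC50
are log-parameterised so positivity is structural and the optimizer is
stable across two-decade concentration ranges; starts are
deterministic (Imax = largest response, EC50 = concentration nearest
half-max, nH = 1); least squares is unweighted. Flat or monotonically
decreasing data raise a fit error; an EC50 outside tested-range ×
[0.01, 100] is flagged. Irel uses the fitted maximum over the same-cell
observed saturating reference by default (the observed-maximum variant
is available). Group summaries are mean ± SD over cells.

## Jump kinetics

Rise: single exponential over the 20–100 % rising segment, asymptote
constrained to the measured peak by default (a flag frees it); rises
spanning < 2 sample intervals are flagged exchange-limited rather than
fitted. Decay: fitted from the 90 % to the 10 % crossing with offset
fixed at baseline; one and two exponentials are both fitted and the
two-component model is accepted only if it wins an F-test at α = 0.05
with both fractional areas ≥ 5 %; the area-weighted τ = Σ aᵢτᵢ is
reported for biexponential fits. Peak detection skips the first 0.5 ms
after pulse onset. On noisy traces, peaks and amplitude crossings are
located on a lightly smoothed copy (Gaussian, σ = 8 samples) while the
fits themselves use raw samples; noise-free traces are used as-is so
that step-sharp features stay sharp. AUC is the trapezoidal integral of
the baseline-subtracted trace. Solution exchange QC interpolates the
20–80 % rise and 80–20 % decay of an open-tip junction current and
accepts only when both are < 200 µs. Percent-of-control comparisons are
same-patch (paired) by construction.

## Statistics

The randomization test uses the difference of group means, two-tailed:
P is the fraction of label arrangements with |Δ*| ≥ |Δ_obs| (ties count
as extreme, with a small absolute tolerance so exact floating-point
ties are caught). Enumeration is exhaustive and exact whenever the
number of arrangements is within the iteration budget; otherwise
Monte-Carlo resampling is used without adding the observed arrangement
to the count (the two conventions differ by ≤ 1/N). The unpaired t test
is classical Student (pooled variance); Welch is behind a flag.
Degenerate paired data are flagged: identical samples give t = 0,
P = 1; a constant non-zero difference gives an infinite-statistic flag
with P = 0. Multiple comparisons gate significance strictly at
α/m (default 0.05/3).

## Problem sizes and numerics

The shipped checks use 30 clusters of ≥ 1 s for open-probability
recovery (Monte-Carlo SE ≈ 0.003), 8-cell dose–response studies at 10 %
noise for EC50 recovery (100-study ensembles for bias checks), 10,000
permutation resamples, and 0.25 s jump sweeps at 100 kHz — sizes chosen
so each quantity's Monte-Carlo error is well inside the tolerance being
asserted. Known numerical limits: the Popen↔efficacy round trip is
exact only to ~eps·(1+E_eff) in float64 (the 1−p subtraction), and the
exact 10–90 % Gaussian rise time is 0.3396/f_c, about 2.3 % above the
conventional 0.3321/f_c max-slope figure; tests assert the exact
values.

## Units

All internal quantities are SI: seconds, pA, molar, Hz. Report writers
and the CLI convert to the display conventions (ms, nA, µM) only at the
edge.
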