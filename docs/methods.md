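# Methods

`dendrophase` models how the electrotonic structure of a pacemaker neuron's
dendritic arbor shapes its spike-timing dynamics.  The pipeline runs in four
stages, each usable on its own: (1) a quasi-linear cable model translating the
spatial extent of a dendritic input into a somatic phase delay; (2) phase
response curve (PRC) estimation from pulse-barrage spike trains; (3) a
Fokker–Planck model of the population rate transient (PSTH) built from the
PRC's Fourier series; and (4) entrainment analysis of periodic drive through
effective-phase return maps and circular statistics.  A synthetic-data module
generates every input the pipeline consumes, so all fitters are validated by
parameter recovery.

## Cable model

The dendritic arbor is collapsed onto a semi-infinite quasi-linear cable
`u(x, t)` with the somatic end (`x = 0`) clamped at a constant potential; the
current delivered to the soma is proportional (gain `kappa`) to the voltage
gradient at the somatic boundary.  Sinusoidal stimulation of a band
`[r, R]` of cable at angular frequency `omega` injects a somatic current that
is again sinusoidal: `I(t) = kappa [F(r, t) - F(R, t)]` where each band-edge
term

    F(r, t) = exp(-p r / lambda) / (lambda sqrt(p^2 + q^2))
              * cos(omega t - q r / lambda - arctan(q / p))

decays exponentially with the edge's electrotonic distance and lags with a
distance-proportional (`q r / lambda`) plus a fixed (`arctan(q/p)`)
contribution.  The spectral factors are

    p, q = sqrt((sqrt(alpha^2 + beta^2) +/- alpha) / 2),

with `alpha(omega) = 1`, `beta(omega) = omega tau` for a passive cable (the
default everywhere; user-supplied `alpha`, `beta` cover quasi-linearized
active conductances).  They satisfy `p^2 - q^2 = alpha` and `2 p q = beta`
exactly, which the test suite asserts to 1e-12.

The measurable quantity is the lag of the peak of the cross-correlation
function (CCF) between the stimulus and the somatic current.  Two closed-form
limits matter:

* point stimulation at distance `R` (narrow band):
  `Phi_R = (R / lambda) q(omega) mod 2 pi` — unbounded, linear in distance;
* band from the soma to `R`:
  `Phi_0 = arctan(q/p) - arctan[ sin(R q / lambda) / (e^{R p / lambda} - cos(R q / lambda)) ]`
  — monotone in `R` and bounded by `arctan(q/p)`.

`solve_ccf_equation` handles the general band by bracketing the zero of the
CCF derivative on a 720-point grid over one period and bisecting to 1e-10,
keeping the root where the CCF is maximal.  `ccf_peak` extracts the same lag
from sampled traces: the CCF of a trace against a unit cosine reference is
`a cos(omega D) + b sin(omega D)` with `a, b` the projections of the trace on
cosine and sine, so the function evaluates that form at sample-resolution lags
and refines the peak with three-point parabolic interpolation; the stimulus's
own lag is extracted identically and subtracted, making the result invariant
to the stimulus phase origin.

Whole-cell recordings add the phase of the isopotential somatic membrane,
`Phi_S = arctan(2 pi f tau)`.  `fit_electrotonic` fits the two parameters
`tau` (membrane time constant, ms) and `rho = R / lambda` (electrotonic extent
of the stimulated region) to measured total delays
`(Phi_0 + Phi_S) / 2 pi` over 6–16 Hz (the default range; lower frequencies
are noisy in practice), using bounded trust-region least squares
(`tau` in (0, 100] ms, `rho` in (0, 5]).  The (tau, rho) surface is bimodal at
high noise — `rho -> 0` trades off against the large-`rho` plateau of `Phi_0`
— so the optimiser is restarted from a 13-point grid and the lowest-cost
solution kept.  When the physical outer radius of the stimulated region is
known, `lambda = R / rho` is reported (e.g. `rho = 0.05` at a 65 um radius
gives `lambda = 1.3 mm`).

Identifiability note: the band term contributes only ~0.01 cycles to the
total delay at `rho ~ 0.4`, so `rho` is recoverable only when per-frequency
phase errors are well below that.  CCF extraction from protocol-scale traces
(20 kHz, 3.5 s per frequency, SNR 10) delivers ~3e-4-cycle errors and
tau/rho RMSE of ~0.3 % / ~2.5 %; adding phase noise of 0.01 cycles directly
destroys `rho` identification entirely.  The recovery tests therefore work at
trace level.

## PRC estimation

A type-I pacemaker perturbed by a Poisson barrage of brief light pulses
shortens each interspike interval (ISI) according to the phases at which
pulses land.  Each ISI is divided into 50 equal bins (bin width scales with
ISI duration; bin `j` is centred at `(j - 0.5) / 50`), pulse onsets are
counted per bin (a pulse exactly at a spike time opens the next ISI), and the
grand mean count is subtracted.  Ordinary least squares of ISI durations on
the 50 mean-subtracted count columns (plus intercept) yields coefficients
`b_j` = ms of ISI change per extra pulse in bin `j`; these are converted to
phase advance per pulse as `Z(phi_j) = -b_j / T_bar` with `T_bar` the fitted
intercept.  Bins that never receive a pulse are dropped (reported, NaN in the
output).  Raw estimates may dip below zero near phases 0 and 1 when the
unperturbed period jitters; no clipping is applied.

The empirical PRC is summarised by an acute triangle on [0, 1] with peak
phase `theta`, amplitude `A` and offset `C`.  For fixed `theta` the
amplitude/offset solve is linear, so `theta` is profiled on a coarse grid and
refined by bounded scalar minimisation (exact inputs are recovered to 1e-6).
The zero-offset unit triangle has Fourier coefficients (convention
`Z_k = \int_0^1 Z(phi) e^{-2 pi i k phi} d phi`):

    Z_0 = 1/2,   Z_k = (e^{-2 pi i k theta} - 1) / (4 pi^2 theta (1 - theta) k^2).

ChR2 photocurrent kinetics are fit as
`A (e^{-t/tau_rise} - e^{-t/tau_decay})`; with `tau_rise < tau_decay` the
bracket is negative, so `A` is fitted with free sign and the time constants
are relabelled so `tau_rise` always names the faster edge.  The kernel's
single interior extremum at
`t* = tau_r tau_d / (tau_d - tau_r) ln(tau_d / tau_r)` serves as a
closed-form oracle in the tests.

## Population rate model

The PSTH around barrage onset (4-ms bins, pooled spike counts /
(sweeps x bin width)) is modelled by the Fokker–Planck solution for a
population of independent phase oscillators hit by a step of excitation:

    R(t) = F_base + H(t) (F_steady - F_base) / Z_0
           * sum_k Z_k exp(-[sigma^2 k^2 / 2] t - i 2 pi k t / T_0),

truncated at `k = -100..100` (doubling the truncation changes values by
< 0.1 %).  `F_base` and `F_steady` are measured from fixed windows (defaults
[-3 s, 0) and [4 s, 9 s)) rather than co-fitted; `T_0 = 1 / F_base`.  Only
`sigma` (phase diffusion) and `theta` (PRC peak) are estimated, from the
first 50 ms after onset.  The early rise of `R` mirrors the falling limb of
the PRC, so a later PRC peak produces an earlier PSTH peak — the ordering the
tests assert for the parameter sets (`theta` 0.901 vs 0.733).

Units: `sigma` is expressed in s^(-1/2), i.e. mode `k` decays at
`sigma^2 k^2 / 2` per second.  With per-millisecond damping, values of
`sigma` near 5 would erase all transient structure within 0.1 ms and the
model could not produce the observed multi-ten-millisecond rise; per-second
damping puts the k=1 relaxation at ~60 ms, matching the transients the model
is meant to describe.

The `(sigma, theta)` objective is multimodal when the data are weakly damped,
so the fit restarts from a 12-point grid and keeps the lowest cost.  On
synthetic populations at protocol scale (19 cells x 25 sweeps, 7 spikes/s,
weak barrage) the 50-ms window contains ~13 noisy bins and a single
realisation estimates `theta` with SD ~0.08; the end-to-end test therefore
checks the absence of bias (mean over 5 seeds within 0.07 of truth) rather
than single-seed accuracy.  Note the synthetic population dephases much more
slowly than fitted `sigma` values of ~5 imply for real recordings, where
across-cell rate heterogeneity dominates the damping.

## Entrainment

Under periodic drive, every spike is assigned an *effective phase*
`psi = frac(f (t - t_start))` in the stimulus cycle; with the drive written
as `-A cos(2 pi f t)`, its depolarising peak sits at `psi = 0.5`.  A spike at
`psi` is followed one perturbed period `Tp(psi)` later by a spike at

    psi' = psi + Tp(psi) / T  mod 1,

a circle map whose stable fixed points (|slope| < 1) are the locking phases.
`Tp(psi)` comes either from data — (psi, next-ISI) pairs summarised by a
3-mode Fourier series; sessions whose phase coverage leaves a gap larger than
0.25 cycles are refused as locked — or from the pacemaker's PRC by
integrating

    dphi/dt = f0 - A cos(2 pi [f t + psi]) Z(phi)

from `phi = 0` until `phi = 1` (classical RK4, step `T0 / 10^4`, crossing
located by linear interpolation; the phase-change bookkeeping
`Tp = T0 (1 - dphi)` is then an identity).  The model map is built from 256
integrations interpolated by a periodic cubic spline; fixed points are found
by bracketing `Tp(psi)/T = m` (integer winding `m`) on 1024 points and
bisecting to 1e-10, with the slope from a central difference (h = 1e-5).
With the unit triangular PRC, `A = 5`, `f = f0 = 7 Hz`, the map yields a
single stable fixed point at 0.5363 cycles for `theta = 0.9` and 0.5986 for
`theta = 0.75` — locking just after the drive's peak and later for the
earlier-peaked PRC — and an independent event-by-event simulation of the same
oscillator lands on the same phase to < 1e-4 cycles.

Locking strength and phase are read from the mean resultant vector
`(1/N) sum e^{2 pi i psi_j}`.  The significance threshold on its amplitude is
the 95th percentile over 10,000 surrogate series of 100 uniform phases
(~0.173–0.175; Rayleigh approximation `sqrt(-ln 0.05 / n)`), scaling as
`1/sqrt(n)`.  Phase differences between conditions are tested by resampling
reference-condition phases with amplitude-proportional weights and measuring
two-sided shorter-arc displacements of the resampled means; this reading of
"representation by vector size" is one of several possible and is
seed-controlled and calibration-tested (null p-values approximately uniform)
rather than uniquely fixed.

## Synthetic data

The generator reproduces the study conditions end to end: a ~7 spikes/s
pacemaker; barrages of 0.5-ms pulses with exponential inter-pulse intervals
(mean 2.17 ms "proximal", 6 ms "full-field", truncated below at the pulse
width); sweeps of 3 s baseline + 9 s stimulation repeated 25 times; ChR2
kernels with 1.5/5.1 ms rise/decay; 20 kHz sampling; per-cycle Gaussian
period jitter with SD 2 % of the period (enough to produce the negative raw
PRC values near phases 0 and 1 seen empirically); and a per-pulse phase
advance `a_eff = 0.01` at the PRC peak, which under the 2.17-ms barrage
raises the firing rate by ~33 % while staying in the weak-perturbation
regime.  Barrage responses advance the phase impulsively
(`phi += a_eff Z(phi)` per pulse, event-driven and exact between events);
cosine drive is integrated continuously.  Everything is a pure function of
(config, seed).

What the generator does *not* emulate: across-cell rate heterogeneity and
intrinsic channel noise (its populations dephase far more slowly than real
ones — see the population section), conductance-based spike generation, ChR2
desensitisation, and morphological variability.  Passing recovery tests
therefore demonstrate estimator correctness under the stated statistical
model, not robustness to every feature of real recordings.

## Numerical choices and edge cases

* Time is ms internally; driving frequencies are Hz
  (`omega = 2 pi f / 1000` rad/ms); phases are radians unless a name says
  cycles.  File readers accept seconds via a `# units: s` header.
* `Phi_0` at `R = 0` returns its series limit 0 (the printed form is 0/0).
* A zero-width illumination band warns and returns zero current.
* `ccf_peak` requires >= 2 stimulus periods and uses only whole periods;
  flat responses are an error, not a silent zero lag.
* The identity return map (every point fixed) is flagged as degenerate
  rather than enumerated.
* Barrage inter-pulse intervals shorter than the pulse width are resampled.
* Bootstrap helpers take explicit seeds; default replicate count 10,000.

## Problem sizes used in validation

Recovery studies use 300-s barrages (PRC, 20 seeds per peak phase), 12
sweep replicates at 3.5 s per frequency (cable), 50 model-level and 5
protocol-scale population replicates (PSTH), and 12–30 s entrainment
sessions, with the map built from 256 phase-equation integrations.
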