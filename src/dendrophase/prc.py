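"""Phase response curve estimation from pulse-barrage spike trains.

A type-I pacemaker perturbed by a Poisson barrage of brief excitatory pulses
shortens each interspike interval (ISI) according to where in the cycle the
pulses land.  Binning the pulses of every ISI into 50 phase bins and regressing
the ISI durations on the mean-subtracted bin counts recovers the phase response
curve (PRC) at the 50 bin centres.  The empirical PRC of these neurons is well
described by an acute triangle on [0, 1] with peak phase ``theta``, amplitude
``A`` and offset ``C``; the triangle's Fourier series feeds the population-rate
model and the entrainment simulation.  The module also fits the
double-exponential kinetics of channelrhodopsin-2 (ChR2) photocurrents, whose
rise time sets how fast a light pulse is actually felt at the soma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "SpikeTrain",
    "PulseTrain",
    "BinnedPulses",
    "TriangularPRC",
    "Chr2Kinetics",
    "PrcEstimate",
    "bin_pulses",
    "estimate_prc",
    "fit_triangle",
    "triangle_fourier",
    "fit_chr2_kernel",
    "chr2_kernel",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one cell/trial with its recording window."""

    times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.window
        if not (lo < hi):
            raise ValueError(f"window must satisfy start < end, got {self.window}")
        if len(times) and (times[0] < lo or times[-1] > hi):
            raise ValueError("spike times fall outside the recording window")

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def rate_hz(self) -> float:
        lo, hi = self.window
        return 1000.0 * len(self.times) / (hi - lo)

    def restricted(self, lo: float, hi: float) -> "SpikeTrain":
        """Spikes within [lo, hi], with the window narrowed accordingly."""
        m = (self.times >= lo) & (self.times <= hi)
        return SpikeTrain(self.times[m], (lo, hi))


@dataclass(frozen=True)
class PulseTrain:
    """Optogenetic pulse onsets (ms) and common pulse width (ms)."""

    onsets: np.ndarray
    width: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.ndim != 1:
            raise ValueError("pulse onsets must be 1-D")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if not (self.width > 0):
            raise ValueError("pulse width must be positive")
        if len(onsets) > 1 and np.min(np.diff(onsets)) < self.width:
            raise ValueError("inter-pulse interval shorter than pulse width")


@dataclass
class BinnedPulses:
    """Per-ISI pulse counts in 50 (by default) equal phase bins.

    ``counts[a, j]`` is the number of pulse onsets landing in phase bin ``j``
    of ISI ``a``; bin ``j`` is centred at phase ``(j + 0.5) / n_bins``.
    ``delta`` is ``counts`` minus its grand mean over all entries.
    """

    counts: np.ndarray
    isis_ms: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.isis_ms = np.asarray(self.isis_ms, dtype=float)
        if self.counts.ndim != 2 or len(self.isis_ms) != self.counts.shape[0]:
            raise ValueError("counts must be (n_isi, n_bins) matching isis")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def phase_centers(self) -> np.ndarray:
        n = self.n_bins
        return (np.arange(n) + 0.5) / n

    @property
    def delta(self) -> np.ndarray:
        return self.counts - self.counts.mean()


def bin_pulses(spikes: SpikeTrain, pulses: PulseTrain, n_bins: int = 50) -> BinnedPulses:
    """Assign each pulse onset to the phase bin of the ISI it falls in.

    Each ISI ``[t_n, t_{n+1})`` (half-open: a pulse exactly at a spike time
    opens the following ISI) is divided into ``n_bins`` equal bins, so the bin
    width scales with the ISI duration.  Pulses before the first or after the
    last spike are dropped and counted in ``n_dropped``.
    """
    t = spikes.times
    if len(t) < 2:
        raise ValueError("need at least 2 spikes (one ISI) to bin pulses")
    on = pulses.onsets
    isis = np.diff(t)
    # ISI index: pulse in [t_a, t_{a+1})
    idx = np.searchsorted(t, on, side="right") - 1
    keep = (idx >= 0) & (idx < len(isis))
    dropped = int(len(on) - keep.sum())
    idx = idx[keep]
    phase = (on[keep] - t[idx]) / isis[idx]
    j = np.minimum((phase * n_bins).astype(int), n_bins - 1)
    counts = np.zeros((len(isis), n_bins), dtype=int)
    np.add.at(counts, (idx, j), 1)
    return BinnedPulses(counts=counts, isis_ms=isis, n_dropped=dropped)


@dataclass
class PrcEstimate:
    """Raw regression PRC: phase-advance-per-pulse at the bin centres."""

    phases: np.ndarray
    z: np.ndarray
    z_se: np.ndarray
    mean_isi_ms: float
    dropped_bins: list[int] = field(default_factory=list)


def estimate_prc(binned: BinnedPulses) -> PrcEstimate:
    """Multiple-regression PRC estimate from binned pulse counts.

    Ordinary least squares of the ISI durations on the mean-subtracted bin
    counts (plus an intercept).  A regression coefficient ``b_j`` is the ISI
    change (ms) per extra pulse in bin ``j``; it is converted to phase advance
    per pulse via ``Z(phi_j) = -b_j / T_bar`` where ``T_bar`` is the fitted
    intercept (the mean ISI at zero pulse excess), so pulses that shorten the
    ISI give positive Z.  Bins that never receive a pulse are rank-deficient
    columns; they are dropped and reported (their Z is NaN).
    """
    n_isi, n_bins = binned.counts.shape
    if n_isi < 200:
        warnings.warn(
            f"only {n_isi} ISIs for a {n_bins}-coefficient regression; "
            "PRC estimate will be noisy"
        )
    dp = binned.delta
    col_ok = binned.counts.sum(axis=0) > 0
    dropped = [int(j) for j in np.nonzero(~col_ok)[0]]
    X = np.column_stack([np.ones(n_isi), dp[:, col_ok]])
    y = binned.isis_ms
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient even after dropping empty bins"
        )
    resid = y - X @ coef
    dof = max(n_isi - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se_all = np.sqrt(s2 * np.diag(XtX_inv))
    t_bar = float(coef[0])
    z = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    z[col_ok] = -coef[1:] / t_bar
    se[col_ok] = se_all[1:] / abs(t_bar)
    return PrcEstimate(
        phases=binned.phase_centers,
        z=z,
        z_se=se,
        mean_isi_ms=t_bar,
        dropped_bins=dropped,
    )


@dataclass(frozen=True)
class TriangularPRC:
    """Acute-triangle PRC on [0, 1]: peak at phase ``theta``, height ``amp``, offset ``offset``.

    Evaluation is piecewise linear between ``(0, offset)``, ``(theta,
    offset + amp)`` and ``(1, offset)``; the zero-offset unit triangle
    (``amp = 1, offset = 0``) is the shape whose Fourier series enters the
    population-rate and entrainment models.
    """

    theta: float
    amp: float = 1.0
    offset: float = 0.0
    tabulated: PrcEstimate | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")

    def __call__(self, phi: np.ndarray | float) -> np.ndarray | float:
        phi = np.asarray(phi, dtype=float)
        up = phi / self.theta
        down = (1.0 - phi) / (1.0 - self.theta)
        out = self.offset + self.amp * np.where(phi <= self.theta, up, down)
        return out if out.ndim else float(out)

    def unit(self) -> "TriangularPRC":
        """The zero-offset, unit-amplitude triangle with the same peak phase."""
        return TriangularPRC(theta=self.theta)


def _triangle_design(phases: np.ndarray, theta: float, force_zero: bool) -> np.ndarray:
    shape = np.where(phases <= theta, phases / theta, (1 - phases) / (1 - theta))
    if force_zero:
        return shape[:, None]
    return np.column_stack([shape, np.ones_like(phases)])


def fit_triangle(
    z: np.ndarray,
    phases: np.ndarray | None = None,
    force_zero_ends: bool = False,
) -> TriangularPRC:
    """Least-squares acute-triangle fit to tabulated PRC values.

    For each candidate peak phase the amplitude (and offset, unless
    ``force_zero_ends`` pins the curve to (0,0) and (1,0)) is a linear
    least-squares solve, so ``theta`` is found by profiling: a coarse scan
    over (0, 1) followed by bounded scalar refinement of the profiled sum of
    squares.
    """
    z = np.asarray(z, dtype=float)
    if phases is None:
        phases = (np.arange(len(z)) + 0.5) / len(z)
    phases = np.asarray(phases, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("PRC values must be finite")
    if np.ptp(z) == 0:
        raise ValueError("flat PRC values: peak phase is not identifiable")

    def sse(theta: float) -> float:
        X = _triangle_design(phases, theta, force_zero_ends)
        coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
        r = z - X @ coef
        return float(r @ r)

    grid = np.linspace(0.01, 0.99, 197)
    errs = np.array([sse(t) for t in grid])
    k = int(np.argmin(errs))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    theta = float(res.x)
    X = _triangle_design(phases, theta, force_zero_ends)
    coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    amp = float(coef[0])
    offset = 0.0 if force_zero_ends else float(coef[1])
    return TriangularPRC(theta=theta, amp=amp, offset=offset)


def triangle_fourier(prc: TriangularPRC, k: int) -> complex:
    """Fourier coefficient ``Z_hat_k`` of the zero-offset unit triangle at ``prc.theta``.

    Convention ``Z_hat_k = integral_0^1 Z(phi) exp(-2 pi i k phi) dphi``:

    ``Z_hat_0 = 1/2``,
    ``Z_hat_k = (exp(-2 pi i k theta) - 1) / (4 pi^2 theta (1 - theta) k^2)``.

    Coefficients refer to the unit-amplitude triangle; callers scale by the
    fitted amplitude where needed.  ``Z_hat_{-k} = conj(Z_hat_k)``.
    """
    if k == 0:
        return 0.5 + 0.0j
    theta = prc.theta
    num = np.exp(-2j * np.pi * k * theta) - 1.0
    return complex(num / (4 * np.pi**2 * theta * (1 - theta) * k**2))


@dataclass(frozen=True)
class Chr2Kinetics:
    """Double-exponential ChR2 photocurrent kernel ``A (e^{-t/tau_rise} - e^{-t/tau_decay})``.

    ``amp`` keeps the fitted sign (with ``tau_rise < tau_decay`` the bracket is
    negative, so an inward-positive current has negative ``amp``);
    ``polarity`` is +1 when the peak of the kernel is positive.
    """

    amp: float
    tau_rise: float
    tau_decay: float

    def __post_init__(self) -> None:
        if not (self.tau_rise > 0 and self.tau_decay > 0):
            raise ValueError("time constants must be positive")
        if self.tau_rise == self.tau_decay:
            raise ValueError("tau_rise must differ from tau_decay")

    @property
    def polarity(self) -> int:
        return 1 if self(self.peak_time) > 0 else -1

    @property
    def peak_time(self) -> float:
        """Closed-form time of the kernel's single interior extremum (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = self.amp * (np.exp(-t / self.tau_rise) - np.exp(-t / self.tau_decay))
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)


def chr2_kernel(t: np.ndarray, kin: Chr2Kinetics) -> np.ndarray:
    """Evaluate the photocurrent kernel at times ``t`` (ms from pulse onset)."""
    return kin(t)


def fit_chr2_kernel(t_ms: np.ndarray, avg_response: np.ndarray) -> Chr2Kinetics:
    """Fit the double-exponential kernel to a pulse-triggered average current.

    The trace must start at pulse onset and be baseline subtracted.
    Nonlinear least squares with free-signed amplitude; the time constants are
    labelled so ``tau_rise < tau_decay``.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    y = np.asarray(avg_response, dtype=float)
    peak_idx = int(np.argmax(np.abs(y)))
    t_peak = max(t_ms[peak_idx], t_ms[1] if len(t_ms) > 1 else 1.0)
    y_peak = y[peak_idx]

    def model(t, a, tr, td):
        return a * (np.exp(-t / tr) - np.exp(-t / td))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t_ms,
            y,
            p0=[-2.0 * y_peak, 0.5 * t_peak, 2.0 * t_peak],
            bounds=([-np.inf, 1e-3, 1e-3], [np.inf, 1e3, 1e3]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"ChR2 kernel fit did not converge: {exc}") from exc
    a, tr, td = popt
    if tr > td:  # relabel so tau_rise names the faster edge
        tr, td = td, tr
        a = -a
    return Chr2Kinetics(amp=float(a), tau_rise=float(tr), tau_decay=float(td))
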