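"""Extension and relaxation analysis of tethered concatemers.

After flow stops, a concatemer's normalized length follows a single
exponential, L(t)/L0 = (1−a) + a·exp(−t/τ), with amplitude a close to 1 and
a relaxation time τ that scales with initial length as τ = A·L0^ν.
Normalizing time by L0^ν collapses all traces onto a master curve.  Under
flow, the steady-state extension rises linearly with the log of wall shear
stress from an onset stress to saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.special import expit
from scipy.stats import linregress

__all__ = [
    "ExtensionTrace",
    "RelaxationFit",
    "ScalingFit",
    "fit_relaxation",
    "fit_relaxation_ensemble",
    "fit_scaling_law",
    "collapse_master_curve",
    "fit_extension_vs_logshear",
]


@dataclass(frozen=True)
class ExtensionTrace:
    """Per-frame concatemer length around a flow-stop event."""

    times: np.ndarray  # s, from flow stop
    length: np.ndarray  # μm
    initial_length: float  # L0, μm, at 1280 dyn cm⁻² before flow stop
    flow_direction: str = "forward"
    viscosity: float = 58.0  # cP (sucrose buffer)
    concatemer_id: int = -1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.length, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and length must match")
        if self.initial_length <= 0:
            raise ValueError("initial_length must be positive")
        if (y < 0).any():
            raise ValueError("lengths must be >= 0")
        if self.flow_direction not in ("forward", "backward"):
            raise ValueError("flow_direction must be 'forward' or 'backward'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "length", y)

    @property
    def normalized(self) -> np.ndarray:
        return self.length / self.initial_length


@dataclass(frozen=True)
class RelaxationFit:
    tau: float  # s
    amplitude: float  # a, in (0, 1]
    residual_rms: float
    success: bool = True
    message: str = ""


@dataclass(frozen=True)
class ScalingFit:
    exponent: float  # ν
    prefactor: float  # s·μm^−ν
    exponent_ci: tuple  # 95%
    r_value: float = float("nan")


def _relax_model(t, a, tau):
    return (1.0 - a) + a * np.exp(-t / tau)


def fit_relaxation(trace: ExtensionTrace, amplitude: float | None = None) -> RelaxationFit:
    """Fit L(t)/L0 = (1−a) + a·exp(−t/τ) to one post-cessation trace.

    ``amplitude`` pins a (the ensemble-global value); otherwise a is free in
    (0, 1].  Returns ``success=False`` with a message for traces that do not
    decay.
    """
    t = trace.times - trace.times[0]
    y = trace.normalized
    if t.size < 8:
        raise ValueError("need >= 8 post-cessation frames")
    drop = y[: max(2, t.size // 5)].mean() - y[-max(2, t.size // 5):].mean()
    noise = float(np.std(np.diff(y)) / np.sqrt(2.0))
    if drop <= max(2.0 * noise, 0.0):
        return RelaxationFit(float("nan"), float("nan"), float("nan"),
                             success=False, message="trace does not decay")
    tau0 = max(t[-1] / 3.0, float(np.median(np.diff(t))))
    try:
        if amplitude is None:
            popt, _ = curve_fit(_relax_model, t, y, p0=[0.9, tau0],
                                bounds=([1e-6, 1e-9], [1.0, np.inf]), maxfev=20000)
            a, tau = popt
        else:
            popt, _ = curve_fit(lambda tt, tau: _relax_model(tt, amplitude, tau),
                                t, y, p0=[tau0], bounds=([1e-9], [np.inf]), maxfev=20000)
            a, tau = amplitude, popt[0]
    except RuntimeError:
        return RelaxationFit(float("nan"), float("nan"), float("nan"),
                             success=False, message="exponential fit failed")
    rms = float(np.sqrt(np.mean((_relax_model(t, a, tau) - y) ** 2)))
    return RelaxationFit(float(tau), float(a), rms)


def fit_relaxation_ensemble(traces) -> tuple[float, list[RelaxationFit]]:
    """Fit all traces with a single shared amplitude a and per-trace τ.

    Returns ``(a, fits)``.  The shared-a form follows the observation that a
    single global amplitude (≈0.96) describes the whole ensemble.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    prelim = [fit_relaxation(tr) for tr in traces]
    ok = [(tr, f) for tr, f in zip(traces, prelim) if f.success]
    if not ok:
        raise ValueError("no trace shows a fittable decay")
    a0 = float(np.clip(np.median([f.amplitude for _, f in ok]), 0.05, 1.0))
    log_tau0 = np.log([max(f.tau, 1e-6) for _, f in ok])

    def resid(theta):
        a = expit(theta[0])  # keep a in (0, 1)
        out = []
        for (tr, _), lt in zip(ok, theta[1:]):
            t = tr.times - tr.times[0]
            out.append(_relax_model(t, a, np.exp(lt)) - tr.normalized)
        return np.concatenate(out)

    x0 = np.r_[np.log(a0 / (1 - a0 + 1e-9)), log_tau0]
    sol = least_squares(resid, x0, method="lm", max_nfev=50000)
    a = float(expit(sol.x[0]))
    fits = []
    j = 1
    for tr, f in zip(traces, prelim):
        if f.success:
            tau = float(np.exp(sol.x[j]))
            t = tr.times - tr.times[0]
            rms = float(np.sqrt(np.mean((_relax_model(t, a, tau) - tr.normalized) ** 2)))
            fits.append(RelaxationFit(tau, a, rms))
            j += 1
        else:
            fits.append(f)
    return a, fits


def fit_scaling_law(pairs, n_bootstrap: int = 1000, seed: int | None = 0) -> ScalingFit:
    """Power-law fit τ = A·L0^ν by linear regression of log τ on log L0.

    ``pairs`` is a sequence of (L0 in μm, τ in s).  Requires ≥ 5 pairs
    spanning at least a 2-fold range in L0.  The exponent CI is a
    nonparametric bootstrap over pairs.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (L0, tau) tuples")
    arr = arr[np.all(np.isfinite(arr), axis=1) & np.all(arr > 0, axis=1)]
    if arr.shape[0] < 5:
        raise ValueError("need >= 5 finite positive (L0, tau) pairs")
    l0, tau = arr[:, 0], arr[:, 1]
    if l0.max() / l0.min() < 2.0:
        raise ValueError("L0 range must span >= 2-fold for a scaling fit")
    x, y = np.log(l0), np.log(tau)
    reg = linregress(x, y)
    rng = np.random.default_rng(seed)
    slopes = []
    n = x.size
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0:
            continue
        slopes.append(linregress(x[idx], y[idx]).slope)
    lo, hi = np.percentile(slopes, [2.5, 97.5]) if slopes else (float("nan"),) * 2
    return ScalingFit(
        exponent=float(reg.slope),
        prefactor=float(np.exp(reg.intercept)),
        exponent_ci=(float(lo), float(hi)),
        r_value=float(reg.rvalue),
    )


def collapse_master_curve(traces, exponent: float, n_bins: int = 30):
    """Collapse traces onto a master curve by rescaling time with L0^−ν.

    Bins the rescaled time over the window covered by every trace and
    returns ``(bin_centers, mean, sd, dispersion)`` where dispersion is the
    mean across bins of the inter-trace SD of L/L0 — lower is a better
    collapse.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("need >= 2 traces to collapse")
    # times are taken as already measured from flow stop
    rescaled = [(tr.times / tr.initial_length**exponent, tr.normalized)
                for tr in traces]
    lo = max(s[0] for s, _ in rescaled)
    hi = min(s[-1] for s, _ in rescaled)
    if hi <= lo:
        raise ValueError("traces share no overlap window after rescaling")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_trace = np.full((len(rescaled), n_bins), np.nan)
    for i, (s, y) in enumerate(rescaled):
        per_trace[i] = np.interp(centers, s, y)
    mean = per_trace.mean(axis=0)
    sd = per_trace.std(axis=0, ddof=0)
    dispersion = float(sd.mean())
    return centers, mean, sd, dispersion


def fit_extension_vs_logshear(curve, saturation_cut: float = 0.95):
    """Linear fit of relative extension against ln(σ) over the rising region.

    ``curve`` is a sequence of (σ in dyn cm⁻², L/L0).  Points at or beyond
    saturation (L/L0 > ``saturation_cut``) are excluded; the onset stress is
    where the fit extrapolates to L/L0 = 0.  Returns
    ``(slope, stress_intercept)``.
    """
    arr = np.asarray(list(curve), dtype=float)
    arr = arr[(arr[:, 0] > 0) & np.isfinite(arr[:, 1])]
    if arr.shape[0] < 4:
        raise ValueError("need >= 4 stress levels above zero")
    rising = arr[arr[:, 1] <= saturation_cut]
    if rising.shape[0] < 2 or np.ptp(rising[:, 1]) == 0:
        raise ValueError("no rising region: input all compact or all saturated")
    reg = linregress(np.log(rising[:, 0]), rising[:, 1])
    if reg.slope <= 0:
        raise ValueError("extension does not increase with shear stress")
    intercept_stress = float(np.exp(-reg.intercept / reg.slope))
    return float(reg.slope), intercept_stress
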