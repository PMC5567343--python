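"""Pseudo-first-order association kinetics and affinity bookkeeping.

Ligand (GPIbα) is in large excess over binding sites, so the bound density
in a tension bin follows homogeneous 1:1 kinetics,

    n(t) = N_total · (1 − exp(−(k_on[C] + k_off)·t)) · k_on[C]/(k_on[C] + k_off),

with observed rate k_obs = k_on[C] + k_off affine in concentration.  The
global fit shares (k_on, k_off, N_total) across the concentration ladder of
one force bin; K_D = k_off/k_on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.stats import linregress

__all__ = [
    "KineticsParams",
    "AssociationTrace",
    "KineticsFitResult",
    "association_curve",
    "association_at_frame",
    "fit_association",
    "kobs_regression",
    "dissociation_constant",
    "mean_site_spacing",
    "dissociation_distance",
    "flow_cessation_off_rate",
    "OffRateFit",
]


@dataclass(frozen=True)
class KineticsParams:
    """1:1 binding parameters for one tension bin."""

    k_on: float  # M⁻¹ s⁻¹
    k_off: float  # s⁻¹
    n_total: float = float("nan")  # sites μm⁻¹
    ligand_concentration: float = float("nan")  # nM
    frame_interval: float = float("nan")  # s

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")

    @property
    def k_d(self) -> float:
        """K_D = k_off/k_on in nM."""
        return dissociation_constant(self.k_on, self.k_off)

    @property
    def k_obs(self) -> float:
        """Observed relaxation rate k_on[C] + k_off, s⁻¹."""
        return self.k_on * self.ligand_concentration * 1e-9 + self.k_off


@dataclass(frozen=True)
class AssociationTrace:
    """Time-stamped bound-ligand density at one concentration and force bin."""

    times: np.ndarray  # s, strictly increasing
    bound_per_um: np.ndarray
    ligand_concentration: float  # nM
    force_bin: tuple = (float("nan"), float("nan"))  # pN interval
    n_concatemers: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.bound_per_um, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and bound_per_um must match")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "bound_per_um", y)


@dataclass(frozen=True)
class KineticsFitResult:
    params: KineticsParams
    confidence_intervals: dict  # name -> (lo, hi), 95%
    residual_rms: float
    flags: tuple = ()
    n_total_per_concentration: dict | None = None


def association_curve(times, params: KineticsParams):
    """Bound density (sites μm⁻¹) at ``times`` (s) from the 1:1 model."""
    t = np.asarray(times, dtype=float)
    kc = params.k_on * params.ligand_concentration * 1e-9
    kobs = kc + params.k_off
    if kobs == 0:
        out = np.zeros_like(t)
        return out if out.ndim else 0.0
    out = params.n_total * (1.0 - np.exp(-kobs * t)) * kc / kobs
    return out if out.ndim else float(out)


def association_at_frame(i, params: KineticsParams):
    """Bound density at frame index ``i`` (frame interval Δt on params)."""
    if not params.frame_interval > 0:
        raise ValueError("frame_interval must be set and positive")
    return association_curve(np.asarray(i) * params.frame_interval, params)


def kobs_regression(traces):
    """Secondary pathway: per-trace exponential fits + linear regression.

    Fits each trace independently to A·(1−exp(−k_obs·t)) and regresses k_obs
    on [C]; slope = k_on (M⁻¹ s⁻¹), intercept = k_off (s⁻¹).  Serves as an
    independent oracle for the global fit.
    """
    kobs_list, conc_list = [], []
    for tr in traces:
        t, y = tr.times, tr.bound_per_um
        a0 = max(y.max(), 1e-9)
        k0 = 1.0 / max(t[len(t) // 3], t[0])
        popt, _ = curve_fit(
            lambda tt, a, k: a * (1.0 - np.exp(-k * tt)),
            t, y, p0=[a0, k0], bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=20000,
        )
        kobs_list.append(popt[1])
        conc_list.append(tr.ligand_concentration * 1e-9)  # M
    reg = linregress(conc_list, kobs_list)
    return float(reg.slope), float(reg.intercept)


def fit_association(
    traces,
    n_bootstrap: int = 300,
    seed: int | None = 0,
    shared_n_total: bool = True,
):
    """Global fit of (k_on, k_off, N_total) across a concentration ladder.

    All traces must belong to one force bin.  N_total is shared across
    concentrations by default (one plateau parameter, matching the single
    N_total of the kinetic model); ``shared_n_total=False`` fits one plateau
    per concentration as a diagnostic.  95% CIs by residual bootstrap.

    A single-concentration input is fit but flagged
    ``under_identified_single_concentration`` with a warning; data whose rise
    is complete before the first frame are flagged
    ``kobs_unidentifiable_plateau_only``.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    concs = sorted({tr.ligand_concentration for tr in traces})
    conc_index = {c: i for i, c in enumerate(concs)}
    flags = []
    if len(concs) < 2:
        flags.append("under_identified_single_concentration")
        warnings.warn("single ligand concentration: k_off poorly constrained", stacklevel=2)

    t_all = np.concatenate([tr.times for tr in traces])
    y_all = np.concatenate([tr.bound_per_um for tr in traces])
    c_all = np.concatenate(
        [np.full(tr.times.size, tr.ligand_concentration * 1e-9) for tr in traces]
    )  # M
    idx_all = np.concatenate(
        [np.full(tr.times.size, conc_index[tr.ligand_concentration]) for tr in traces]
    )

    try:
        kon0, koff0 = kobs_regression(traces)
        kon0 = max(kon0, 1e3)
        koff0 = max(koff0, 1e-3)
    except Exception:
        kon0, koff0 = 1e7, 1.0
    if not (np.isfinite(kon0) and np.isfinite(koff0)):  # e.g. single concentration
        kon0, koff0 = 1e7, 1.0
    frac0 = kon0 * c_all.max() / (kon0 * c_all.max() + koff0)
    n0 = max(y_all.max() / max(frac0, 1e-6), 1e-6)

    n_amp = 1 if shared_n_total else len(concs)

    def model(theta, t, c, idx):
        kon, koff = theta[0], theta[1]
        kc = kon * c
        kobs = np.maximum(kc + koff, 1e-300)
        ntot = theta[2] if shared_n_total else theta[2 + idx]
        return ntot * (1.0 - np.exp(-kobs * t)) * kc / kobs

    x0 = np.log(np.concatenate([[kon0, koff0], np.full(n_amp, n0)]))

    def resid(logtheta):
        return model(np.exp(logtheta), t_all, c_all, idx_all) - y_all

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    theta = np.exp(sol.x)
    kon, koff = float(theta[0]), float(theta[1])
    ntot = float(np.mean(theta[2:]))
    fit_y = model(theta, t_all, c_all, idx_all)
    resid_y = y_all - fit_y
    rms = float(np.sqrt(np.mean(resid_y**2)))

    # Identifiability: the rise must be resolved by the frame grid.
    dt_min = min(float(np.diff(tr.times).min()) for tr in traces)
    t0_min = min(float(tr.times[0]) for tr in traces)
    kobs_max = kon * c_all.max() + koff
    if kobs_max * max(dt_min, t0_min) > 3.0:
        flags.append("kobs_unidentifiable_plateau_only")

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_bootstrap):
        y_b = fit_y + rng.choice(resid_y, size=resid_y.size, replace=True)

        def resid_b(logtheta):
            return model(np.exp(logtheta), t_all, c_all, idx_all) - y_b

        try:
            sb = least_squares(resid_b, sol.x, method="lm", max_nfev=5000)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        tb = np.exp(sb.x)
        boot.append([tb[0], tb[1], float(np.mean(tb[2:]))])
    cis = {}
    if boot:
        boot_arr = np.asarray(boot)
        for j, name in enumerate(["k_on", "k_off", "n_total"]):
            lo, hi = np.percentile(boot_arr[:, j], [2.5, 97.5])
            cis[name] = (float(lo), float(hi))
        kd_boot = boot_arr[:, 1] / np.maximum(boot_arr[:, 0], 1e-30) * 1e9
        lo, hi = np.percentile(kd_boot, [2.5, 97.5])
        cis["k_d"] = (float(lo), float(hi))

    params = KineticsParams(k_on=kon, k_off=koff, n_total=ntot,
                            ligand_concentration=float(c_all.max() / 1e-9))
    per_conc = None
    if not shared_n_total:
        per_conc = {c: float(theta[2 + i]) for c, i in conc_index.items()}
    return KineticsFitResult(params=params, confidence_intervals=cis,
                             residual_rms=rms, flags=tuple(flags),
                             n_total_per_concentration=per_conc)


def dissociation_constant(k_on: float, k_off: float) -> float:
    """K_D = k_off/k_on, returned in nM."""
    if k_on <= 0:
        raise ValueError("k_on must be positive to define an affinity")
    return k_off / k_on * 1e9


def mean_site_spacing(n_total: float) -> float:
    """Average distance between bound sites, nm, from a per-μm density."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 1000.0 / n_total


def dissociation_distance(
    k_off: float,
    transport_velocity: float,
    dissociated_fraction: float,
) -> float:
    """Downstream distance (mm) within which the given fraction of ligand
    dissociates at transport velocity v (mm s⁻¹): v·(−ln(1−p))/k_off."""
    if not 0 <= dissociated_fraction < 1:
        raise ValueError("dissociated_fraction must be in [0, 1)")
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    return transport_velocity * (-math.log1p(-dissociated_fraction)) / k_off


@dataclass(frozen=True)
class OffRateFit:
    k_off: float  # s⁻¹
    amplitude: float
    baseline: float
    lower_bound_flag: bool
    success: bool
    message: str = ""


def flow_cessation_off_rate(trace: AssociationTrace) -> OffRateFit:
    """Off-rate from the decay of bound signal after flow stop.

    Fits A·exp(−k·t) + B.  When the fitted decay time 1/k is shorter than two
    frame intervals the value is flagged as a lower bound (time-resolution
    limited).  Returns ``success=False`` for non-decaying traces.
    """
    t = trace.times - trace.times[0]
    y = trace.bound_per_um
    if t.size < 5:
        raise ValueError("need >= 5 frames after flow stop")
    head = y[: max(2, t.size // 5)].mean()
    tail = y[-max(2, t.size // 5):].mean()
    drop = head - tail
    # noise from the settled tail only, so a fast decay does not inflate it
    tail_seg = y[-max(4, t.size // 3):]
    noise = float(np.std(np.diff(tail_seg)) / np.sqrt(2.0))
    if drop <= max(2.0 * noise, 0.0) or drop <= 0:
        return OffRateFit(float("nan"), float("nan"), float("nan"),
                          lower_bound_flag=False, success=False,
                          message="trace does not decay")
    dt = float(np.median(np.diff(t)))
    try:
        popt, _ = curve_fit(
            lambda tt, a, k, b: a * np.exp(-k * tt) + b,
            t, y, p0=[drop, 1.0 / max(3 * dt, 1e-6), tail],
            bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        return OffRateFit(float("nan"), float("nan"), float("nan"),
                          lower_bound_flag=False, success=False,
                          message="exponential fit failed")
    a, k, b = popt
    lower_bound = bool(1.0 / k < 2.0 * dt)
    return OffRateFit(float(k), float(a), float(b),
                      lower_bound_flag=lower_bound, success=True)
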