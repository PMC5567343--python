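"""From per-frame intensity profiles to the pipeline's derived quantities.

Profiles are 1-D two-channel intensity traces along the flow axis (tether at
the upstream end).  This module measures contour lengths, converts intensity
to fluorophore/molecule counts via single-fluorophore calibration and degree
of labeling, applies the cohort QC rules, bins bound-ligand density by
monomer tension, calls activation against background, and extracts the
size-dependent activation-threshold law σ50 = b/N_VWF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydrodynamics import FlowCondition, TensionProfile, average_monomer_force, tirf_attenuation
from .twostate import FORCE_BIN_EDGES

__all__ = [
    "IntensityProfile",
    "CalibrationParams",
    "LengthMeasurement",
    "ActivationResult",
    "ThresholdResult",
    "measure_length",
    "intensity_to_count",
    "estimate_single_fluor_intensity",
    "monomer_extension",
    "qc_filter",
    "bin_by_tension",
    "activation_call",
    "threshold_stress",
    "fit_activation_threshold",
]

#: Camera pixel size at the sample, μm (60× objective, 16 μm camera pixels).
DEFAULT_PIXEL_SIZE_UM = 0.27


@dataclass(frozen=True)
class IntensityProfile:
    """Two-channel intensity profile along the flow axis at one frame."""

    positions: np.ndarray  # μm, uniform spacing, ascending
    vwf_channel: np.ndarray  # counts
    ligand_channel: np.ndarray | None = None  # counts
    time: float = 0.0  # s
    shear_stress: float = 0.0  # dyn cm⁻²
    exposure: float = 0.010  # s

    def __post_init__(self) -> None:
        x = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.vwf_channel, dtype=float)
        if x.shape != v.shape:
            raise ValueError("positions and vwf_channel must match")
        dx = np.diff(x)
        if x.size > 1 and not np.allclose(dx, dx[0], rtol=1e-6):
            raise ValueError("positions must be uniformly spaced")
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "vwf_channel", v)
        if self.ligand_channel is not None:
            lig = np.asarray(self.ligand_channel, dtype=float)
            if lig.shape != x.shape:
                raise ValueError("ligand_channel must match positions")
            object.__setattr__(self, "ligand_channel", lig)

    @property
    def pixel_size(self) -> float:
        return float(self.positions[1] - self.positions[0]) if self.positions.size > 1 else DEFAULT_PIXEL_SIZE_UM


@dataclass(frozen=True)
class CalibrationParams:
    """Intensity-to-count calibration for one channel."""

    single_fluor_intensity: float  # counts per fluorophore per exposure
    degree_of_labeling: float  # fluorophores per monomer (VWF) or molecule (GPIbα)
    tirf_penetration_depth: float = 150.0  # nm
    reference_height: float = 4.5  # nm (dye on surface-bound streptavidin)

    def __post_init__(self) -> None:
        if self.single_fluor_intensity < 0:
            raise ValueError("single_fluor_intensity must be >= 0")
        if self.degree_of_labeling <= 0:
            raise ValueError("degree_of_labeling must be positive")


#: Presets matching the labeling stoichiometries of the two channels.
VWF_CALIBRATION_DOL = 0.67
LIGAND_CALIBRATION_DOL = 1.01


@dataclass(frozen=True)
class LengthMeasurement:
    length_um: float
    start_um: float
    end_um: float
    detected: bool
    threshold: float


def _background_stats(values: np.ndarray) -> tuple[float, float]:
    """Robust background mean/SD via median and scaled MAD."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, 1.4826 * mad


def measure_length(
    profile: IntensityProfile,
    channel: str = "vwf",
    background: np.ndarray | None = None,
    flank_fraction: float = 0.15,
) -> LengthMeasurement:
    """End-to-end extent of the largest contiguous above-threshold region.

    Threshold is background mean + 3 background SD (robust median/MAD
    statistics); background defaults to the flanking ``flank_fraction`` of
    pixels at each end of the profile.  The boundary is refined to sub-pixel
    precision by linear interpolation at the threshold crossings.
    """
    y = profile.vwf_channel if channel == "vwf" else profile.ligand_channel
    if y is None:
        raise ValueError(f"profile has no {channel} channel")
    x = profile.positions
    if background is None:
        k = max(int(flank_fraction * y.size), 2)
        background = np.concatenate([y[:k], y[-k:]])
    mu, sd = _background_stats(np.asarray(background, dtype=float))
    thr = mu + 3.0 * sd
    above = y > thr
    if not above.any():
        return LengthMeasurement(0.0, float("nan"), float("nan"), False, thr)
    # largest contiguous run
    padded = np.r_[False, above, False]
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    i = int(np.argmax(ends - starts))
    s, e = int(starts[i]), int(ends[i]) - 1  # inclusive pixel indices
    dx = profile.pixel_size
    # sub-pixel refinement: interpolate the threshold crossing into the
    # flanking pixel, clamped to the boundary pixel's half-width footprint so
    # a single bright pixel measures one pixel width
    shift = dx / 2.0
    if s > 0 and y[s] > y[s - 1]:
        frac = (y[s] - thr) / (y[s] - y[s - 1])
        shift = dx * min(max(frac, 0.0), 0.5)
    start_um = x[s] - shift
    shift = dx / 2.0
    if e < y.size - 1 and y[e] > y[e + 1]:
        frac = (y[e] - thr) / (y[e] - y[e + 1])
        shift = dx * min(max(frac, 0.0), 0.5)
    end_um = x[e] + shift
    length = end_um - start_um
    return LengthMeasurement(float(length), float(start_um), float(end_um), True, thr)


def intensity_to_count(
    total_intensity: float,
    calib: CalibrationParams,
    dye_height: float | None = None,
) -> float:
    """Convert integrated intensity to monomer/molecule count.

    count = I / (single-fluorophore intensity × degree of labeling); when
    ``dye_height`` (nm) is given, the TIRF height attenuation relative to the
    calibration reference is divided out.
    """
    if calib.single_fluor_intensity <= 0:
        raise ValueError("single-fluorophore intensity calibration is zero")
    count = total_intensity / (calib.single_fluor_intensity * calib.degree_of_labeling)
    if dye_height is not None:
        count /= tirf_attenuation(dye_height, calib.reference_height,
                                  calib.tirf_penetration_depth)
    return count


def _binary_segmentation(y: np.ndarray, min_size: int, penalty: float) -> list[int]:
    """Recursive mean-shift change-point detection; returns sorted breakpoints."""

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2)) if seg.size else 0.0

    def split(lo, hi, out):
        n = hi - lo
        if n < 2 * min_size:
            return
        seg = y[lo:hi]
        total = sse(seg)
        best_gain, best_k = 0.0, None
        cum = np.cumsum(seg)
        cum2 = np.cumsum(seg**2)
        for k in range(min_size, n - min_size + 1):
            left = cum2[k - 1] - cum[k - 1] ** 2 / k
            right = (cum2[-1] - cum2[k - 1]) - (cum[-1] - cum[k - 1]) ** 2 / (n - k)
            gain = total - left - right
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is not None and best_gain > penalty:
            out.append(lo + best_k)
            split(lo, lo + best_k, out)
            split(lo + best_k, hi, out)

    out: list[int] = []
    split(0, y.size, out)
    return sorted(out)


def estimate_single_fluor_intensity(
    photobleach_trace: np.ndarray,
    min_segment: int = 3,
) -> float:
    """Single-fluorophore intensity from a stepwise photobleaching trace.

    Segments the trace by binary-segmentation change-point detection (noise
    scale from the MAD of first differences, BIC-style penalty) and returns
    the median downward step between consecutive segment medians.  Segments
    must be flat at the noise scale — a smooth ramp is rejected rather than
    chopped into pseudo-steps.

    Raises ``ValueError`` if the trace is stepless or not stepwise.
    """
    y = np.asarray(photobleach_trace, dtype=float)
    if y.size < 2 * min_segment:
        raise ValueError("photobleach trace too short")
    diffs = np.diff(y)
    sigma = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / math.sqrt(2.0)
    penalty = 2.0 * max(sigma, 1e-12) ** 2 * math.log(y.size)
    bkps = _binary_segmentation(y, min_segment, penalty)
    if not bkps:
        raise ValueError("no photobleaching steps detected")
    bounds = [0, *bkps, y.size]
    segments = [y[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    levels = np.array([np.median(seg) for seg in segments])
    within = np.median([np.median(np.abs(seg - lvl)) for seg, lvl in zip(segments, levels)])
    if within > max(3.0 * sigma, 1e-9):
        raise ValueError("trace is not stepwise (segments are not flat)")
    steps = -np.diff(levels)
    down = steps[steps > 0]
    if down.size == 0:
        raise ValueError("no downward photobleaching steps detected")
    return float(np.median(down))


def monomer_extension(length_um: float, n_monomers: float) -> float:
    """Average extension per monomer, nm."""
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    return 1000.0 * length_um / n_monomers


def qc_filter(
    records: pd.DataFrame,
    cv_threshold: float = 0.10,
    min_extension_nm: float = 20.0,
    reference_stress: float = 1280.0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort quality control for binding analyses.

    ``records`` needs columns ``concatemer_id``, ``shear_dyn_cm2``,
    ``length_um``, ``n_monomers`` with one row per repeat measurement.
    Excludes concatemers whose repeat lengths at matched stress vary by more
    than ``cv_threshold`` (rule ``length_cv``), and those extended less than
    ``min_extension_nm`` per monomer at the reference stress (rule
    ``low_extension``; applies to binding analyses only).  Concatemers with a
    single observation are kept with the reproducibility rule flagged
    unevaluated.

    Returns ``(per-concatemer frame with keep flag and reason codes, counts)``.
    """
    required = {"concatemer_id", "shear_dyn_cm2", "length_um", "n_monomers"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    counts = {"length_cv": 0, "low_extension": 0, "cv_unevaluated": 0, "kept": 0}
    for cid, grp in records.groupby("concatemer_id"):
        reasons = []
        cv_evaluated = False
        for _, sub in grp.groupby("shear_dyn_cm2"):
            if len(sub) >= 2:
                cv_evaluated = True
                mean_len = sub["length_um"].mean()
                if mean_len > 0 and sub["length_um"].std(ddof=0) / mean_len > cv_threshold:
                    reasons.append("length_cv")
                    break
        ref = grp[grp["shear_dyn_cm2"] == reference_stress]
        if len(ref):
            ext = monomer_extension(ref["length_um"].mean(), ref["n_monomers"].iloc[0])
            if ext < min_extension_nm:
                reasons.append("low_extension")
        keep = not reasons
        rows.append({
            "concatemer_id": cid,
            "keep": keep,
            "reasons": ";".join(reasons),
            "cv_evaluated": cv_evaluated,
        })
        if keep:
            counts["kept"] += 1
        for r in reasons:
            counts[r] += 1
        if not cv_evaluated:
            counts["cv_unevaluated"] += 1
    return pd.DataFrame(rows), counts


def bin_by_tension(
    profile: IntensityProfile,
    tension: TensionProfile,
    calib: CalibrationParams,
    n_monomers_along_contour: int | None = None,
    bin_edges: np.ndarray = FORCE_BIN_EDGES,
) -> pd.DataFrame:
    """Bound-ligand density per tension bin along an extended concatemer.

    The tether is taken at the upstream (x-minimum) end of the detected
    contour; each pixel maps to its monomer (by downstream rank along the
    measured length) and thence to the monomer's tension bin (half-open
    [0,8) … [48,56) pN).  Ligand intensity summed per bin is converted to
    molecules via the calibration and divided by the bin's occupied length.

    Returns a frame with columns ``bin_low``, ``bin_high``, ``mean_force``,
    ``ligand_per_um``, ``length_um`` and an ``incomplete`` attribute flag in
    ``DataFrame.attrs`` when the concatemer does not reach all bins.
    """
    if profile.ligand_channel is None:
        raise ValueError("profile has no ligand channel")
    meas = measure_length(profile, channel="vwf")
    if not meas.detected:
        raise ValueError("no concatemer detected in the VWF channel")
    n_mono = n_monomers_along_contour or tension.per_monomer_force.size
    x = profile.positions
    inside = (x >= meas.start_um) & (x <= meas.end_um)
    xi = x[inside] - meas.start_um
    ligand = profile.ligand_channel[inside]
    # downstream rank of the monomer under each pixel
    rank = np.minimum((xi / meas.length_um * n_mono).astype(int), n_mono - 1)
    force = tension.per_monomer_force[rank]
    # tensions beyond the last bin edge fall outside the binned analysis
    in_range = force < bin_edges[-1]
    force, ligand = force[in_range], ligand[in_range]
    bin_idx = np.searchsorted(bin_edges, force, side="right") - 1
    px = profile.pixel_size
    rows = []
    n_bins_expected = 7
    for b in range(bin_edges.size - 1):
        sel = bin_idx == b
        if not sel.any():
            continue
        length = sel.sum() * px
        molecules = intensity_to_count(float(ligand[sel].sum()), calib)
        rows.append({
            "bin_low": float(bin_edges[b]),
            "bin_high": float(bin_edges[b + 1]),
            "mean_force": float(force[sel].mean()),
            "ligand_per_um": molecules / length,
            "length_um": float(length),
        })
    out = pd.DataFrame(rows)
    out.attrs["incomplete"] = len(out) < n_bins_expected
    return out


def activation_call(
    roi_density_per_frame: np.ndarray,
    background_samples: np.ndarray,
    n_consecutive: int = 3,
    n_sd: float = 3.0,
) -> bool:
    """True when the ROI ligand density exceeds background mean + 3 SD in at
    least ``n_consecutive`` consecutive steady-flow frames (strict
    inequality; a signal exactly at threshold is not activation)."""
    bg = np.asarray(background_samples, dtype=float)
    if bg.size == 0:
        raise ValueError("background region is empty")
    roi = np.asarray(roi_density_per_frame, dtype=float)
    thr = bg.mean() + n_sd * bg.std(ddof=0)
    above = roi > thr
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return True
    return False


@dataclass(frozen=True)
class ThresholdResult:
    sigma_t: float  # dyn cm⁻²; nan when never activated
    defined: bool
    inconsistent: bool = False  # activation calls non-monotone in σ


def threshold_stress(calls) -> ThresholdResult:
    """Threshold stress σ_T: the lowest σ of an ascending ramp with a
    positive activation call.

    ``calls`` is a sequence of (σ, activated) pairs in ramp order; a
    non-monotone σ schedule raises.  Non-monotone calls (yes→no→yes) take the
    first positive σ and set the ``inconsistent`` flag.
    """
    calls = list(calls)
    sigmas = np.array([c[0] for c in calls], dtype=float)
    if (np.diff(sigmas) <= 0).any():
        raise ValueError("stress schedule must be strictly ascending")
    flags = [bool(c[1]) for c in calls]
    if not any(flags):
        return ThresholdResult(float("nan"), defined=False)
    first = flags.index(True)
    inconsistent = not all(flags[first:])
    return ThresholdResult(float(sigmas[first]), defined=True, inconsistent=inconsistent)


@dataclass(frozen=True)
class ActivationResult:
    """Size-dependence of the activation threshold."""

    b: float  # dyn cm⁻², hyperbola coefficient of σ50 = b/N_VWF
    per_bin: pd.DataFrame  # size-bin table: n_vwf, sigma50, n, max tension stats
    max_tension_cv: float  # across-size-bin CV of median max tension at threshold
    median_max_tension: float  # pN


def fit_activation_threshold(
    records: pd.DataFrame,
    n_bins: int = 6,
    size_range: tuple = (20, 200),
    min_per_bin: int = 5,
) -> ActivationResult:
    """Fit σ50 = b/N_VWF to per-concatemer activation thresholds.

    ``records`` needs columns ``n_vwf`` and ``sigma_t`` (NaN for concatemers
    that never activated; those are dropped).  Concatemers are grouped into
    log-spaced size bins; per-bin σ50 is the median σ_T; b comes from
    count-weighted least squares of σ50 against 1/N.  The per-concatemer
    maximal tension at threshold, f_mono(σ_T)·N_VWF, and its across-bin
    coefficient of variation quantify the uniformity of the tension
    threshold.
    """
    df = records.dropna(subset=["sigma_t"]).copy()
    edges = np.geomspace(size_range[0], size_range[1], n_bins + 1)
    edges[-1] *= 1.0 + 1e-9  # include the upper bound
    df["size_bin"] = np.clip(np.searchsorted(edges, df["n_vwf"], side="right") - 1,
                             0, n_bins - 1)
    df["max_tension"] = [
        average_monomer_force(FlowCondition(s)) * n
        for s, n in zip(df["sigma_t"], df["n_vwf"])
    ]
    rows = []
    for b_idx, grp in df.groupby("size_bin"):
        if len(grp) < min_per_bin:
            continue
        # σ50 and the bin's representative size come from the same median
        # concatemer (sorted by σ_T), keeping σ50·N exact on pure hyperbolas
        med = grp.sort_values("sigma_t").iloc[(len(grp) - 1) // 2]
        rows.append({
            "size_bin": int(b_idx),
            "n_vwf": float(med["n_vwf"]),
            "sigma50": float(med["sigma_t"]),
            "n": len(grp),
            "median_max_tension": float(grp["max_tension"].median()),
        })
    per_bin = pd.DataFrame(rows)
    if len(per_bin) < 3:
        raise ValueError("need >= 3 size bins with enough concatemers")
    w = per_bin["n"].to_numpy(dtype=float)
    inv_n = 1.0 / per_bin["n_vwf"].to_numpy()
    sigma50 = per_bin["sigma50"].to_numpy()
    b_coef = float(np.sum(w * sigma50 * inv_n) / np.sum(w * inv_n**2))
    mt = per_bin["median_max_tension"].to_numpy()
    cv = float(mt.std(ddof=0) / mt.mean()) if mt.mean() > 0 else float("nan")
    return ActivationResult(
        b=b_coef,
        per_bin=per_bin,
        max_tension_cv=cv,
        median_max_tension=float(np.median(df["max_tension"])),
    )
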