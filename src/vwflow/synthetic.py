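"""Ground-truth-annotated synthetic single-molecule experiments.

Generates cohorts of tethered concatemers with the statistical structure the
analysis assumes — log-uniform sizes of 20–200 monomers, Poisson labeling at
0.67 fluorophores per monomer, log-shear extension with a 15 dyn cm⁻² onset
and saturation at 1280 dyn cm⁻², single-exponential relaxation with
τ = A·L0^ν, per-site two-state binding simulated as an exact telegraph
(Gillespie) process, and TIRF/camera rendering with Poisson photon and
Gaussian read noise — so that every pipeline stage can be tested against
known generating parameters without any experimental download.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hydrodynamics import FlowCondition, average_monomer_force, tension_profile, tirf_attenuation
from .kinetics import AssociationTrace
from .polymer import Concatemer
from .relaxation import ExtensionTrace
from .twostate import ForceBinnedBinding, TwoStateParams, state2_occupancy

__all__ = [
    "SimConfig",
    "preset_150mM",
    "preset_10mM",
    "sample_cohort",
    "simulate_telegraph",
    "simulate_extension",
    "simulate_binding",
    "render_profile",
    "simulate_photobleach",
    "generate_relaxation_dataset",
    "generate_equilibrium_binding_dataset",
    "generate_association_dataset",
    "generate_activation_dataset",
    "generate_extension_curve",
]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic experiment.

    Defaults reproduce the 150 mM NaCl study conditions; the RNG seed is
    mandatory so every dataset is reproducible end to end.
    """

    seed: int
    # cohort
    cohort_size: int = 240
    size_range: tuple = (20, 200)  # monomers, log-uniform
    tether_end_fraction: float = 0.10  # tether within the terminal 10%
    vwf_dol: float = 0.67  # fluorophores per monomer
    ligand_dol: float = 1.01  # fluorophores per ligand molecule
    # two-state binding (150 mM NaCl preset; Table-1b-style parameters)
    delta_G: float = 3.2  # k_BT
    delta_x: float = 0.6  # nm
    k_on2: float = 50e6  # M⁻¹ s⁻¹
    k_off: float = 3.9  # s⁻¹
    temperature: float = 295.0  # K
    concentrations: tuple = (12.5, 25.0, 50.0, 100.0, 200.0)  # nM
    # extension law
    onset_stress: float = 15.0  # dyn cm⁻²
    saturation_stress: float = 1280.0  # dyn cm⁻²
    extension_per_monomer_mean: float = 31.0  # nm at saturation
    extension_per_monomer_sd: float = 12.0  # nm
    extension_per_monomer_min: float = 5.0  # nm (truncation)
    compact_size_um: float = 0.3  # apparent globule size
    # relaxation
    relax_amplitude: float = 0.96  # a
    relax_exponent: float = 0.59  # ν
    relax_prefactor: float = 0.20  # s·μm^−ν
    tau_scatter_sigma_log: float = 0.15  # lognormal scatter of τ
    # frame schedules
    equilibrium_exposure: float = 0.010  # s
    equilibrium_interval: float = 0.300  # s
    kinetics_fps: float = 57.0
    relaxation_fps: float = 20.0
    # activation threshold (pure tension threshold: σ_T = b / N_downstream)
    activation_b: float = 6.9e4  # dyn cm⁻²
    # camera / optics
    pixel_size_um: float = 0.27
    psf_sigma_um: float = 0.15
    single_fluor_vwf: float = 200.0  # counts per fluorophore per exposure
    single_fluor_ligand: float = 200.0
    read_noise_sd: float = 10.0  # counts
    tirf_penetration_depth: float = 150.0  # nm
    vwf_height: float = 10.0  # nm
    reference_height: float = 4.5  # nm
    bleach_rate: float = 0.5  # s⁻¹ (photobleach calibration fixture)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (1 <= self.size_range[0] < self.size_range[1]):
            raise ValueError("size_range must be an increasing pair of counts >= 1")
        for name in ("k_on2", "k_off", "onset_stress", "saturation_stress",
                     "relax_prefactor", "kinetics_fps", "relaxation_fps",
                     "pixel_size_um", "psf_sigma_um", "activation_b",
                     "equilibrium_interval", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.relax_amplitude <= 1:
            raise ValueError("relax_amplitude must be in (0, 1]")

    @property
    def two_state(self) -> TwoStateParams:
        return TwoStateParams(
            delta_G=self.delta_G, delta_x=self.delta_x,
            k_d2=self.k_off / self.k_on2 * 1e9, k_on2=self.k_on2,
            temperature=self.temperature,
        )

    @property
    def activation_tension_pN(self) -> float:
        """Tension threshold implied by the σ50 = b/N coefficient."""
        return average_monomer_force(FlowCondition(self.activation_b))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("size_range", "concentrations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def preset_150mM(seed: int) -> SimConfig:
    """Physiological-ionic-strength preset (the default parameter set)."""
    return SimConfig(seed=seed)


def preset_10mM(seed: int) -> SimConfig:
    """Low-ionic-strength preset: stronger electrostatic steering."""
    return SimConfig(seed=seed, delta_G=2.8, delta_x=0.8,
                     k_on2=538e6, k_off=0.3, activation_b=3.0e4,
                     concentrations=(5.0, 10.0, 20.0, 40.0, 80.0))


# ---------------------------------------------------------------------------
# cohort

def sample_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> list[Concatemer]:
    """Sample a cohort of labeled concatemers.

    Sizes are log-uniform over ``size_range``; the tether attaches at a
    uniformly random monomer within the terminal ``tether_end_fraction`` of
    either end (end-biased wall attachment); labels are Poisson per monomer.
    """
    rng = config.rng() if rng is None else rng
    lo, hi = config.size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), size=config.cohort_size))
    sizes = np.clip(sizes.astype(int), lo, hi)
    cohort = []
    for n in sizes:
        span = max(1, int(math.ceil(config.tether_end_fraction * n)))
        offset = int(rng.integers(0, span))
        tether = offset if rng.random() < 0.5 else n - 1 - offset
        fluors = rng.poisson(config.vwf_dol, size=n)
        cohort.append(Concatemer(int(n), tether, fluors))
    return cohort


# ---------------------------------------------------------------------------
# telegraph (Gillespie) binding simulator

def simulate_telegraph(
    k_on_eff,
    k_off: float,
    frame_times: np.ndarray,
    rng: np.random.Generator,
    initial_state=None,
) -> np.ndarray:
    """Exact two-state telegraph simulation of independent binding sites.

    Each site switches 0→1 with rate ``k_on_eff`` (scalar or per-site array,
    s⁻¹) and 1→0 with ``k_off``.  Event times are drawn exactly (exponential
    waiting times, Gillespie); states are read out on ``frame_times``.
    Returns a boolean array of shape (n_sites, n_frames).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    k_on_eff = np.atleast_1d(np.asarray(k_on_eff, dtype=float))
    n_sites = k_on_eff.size
    t_end = frame_times[-1]
    if initial_state is None:
        state0 = np.zeros(n_sites, dtype=np.int8)
    else:
        state0 = np.atleast_1d(initial_state).astype(np.int8)
    # accumulate state changes per (site, frame-slot)
    delta = np.zeros((n_sites, frame_times.size + 1), dtype=np.int32)
    t_cur = np.zeros(n_sites)
    state = state0.copy()
    active = np.ones(n_sites, dtype=bool)
    # sites with zero on-rate and empty initial state never move
    active &= ~((k_on_eff == 0) & (state0 == 0))
    while active.any():
        idx = np.flatnonzero(active)
        rates = np.where(state[idx] == 1, k_off, k_on_eff[idx])
        movable = rates > 0
        idx = idx[movable]
        if idx.size == 0:
            break
        rates = rates[movable]
        dt = rng.exponential(1.0 / rates)
        t_next = t_cur[idx] + dt
        done = t_next > t_end
        active[idx[done]] = False
        flip = idx[~done]
        t_flip = t_next[~done]
        if flip.size:
            slot = np.searchsorted(frame_times, t_flip, side="left")
            sign = np.where(state[flip] == 1, -1, 1).astype(np.int32)
            np.add.at(delta, (flip, slot), sign)
            state[flip] = 1 - state[flip]
            t_cur[flip] = t_flip
        t_cur[idx[done]] = t_end
    states = state0[:, None] + np.cumsum(delta[:, :-1], axis=1)
    return states.astype(bool)


# ---------------------------------------------------------------------------
# extension / relaxation

def steady_extension(sigma, l_max_um: float, config: SimConfig, compact_size: float | None = None):
    """Steady-state length (μm) under wall shear stress σ (dyn cm⁻²).

    L/L_max rises linearly in ln σ from the onset stress to saturation;
    below the onset the molecule is a compact globule.
    """
    sigma = np.asarray(sigma, dtype=float)
    frac = np.log(np.maximum(sigma, 1e-300) / config.onset_stress) / math.log(
        config.saturation_stress / config.onset_stress
    )
    frac = np.clip(frac, 0.0, 1.0)
    compact = config.compact_size_um if compact_size is None else compact_size
    out = np.maximum(frac * l_max_um, compact)
    out = np.where(sigma <= config.onset_stress, compact, out)
    return out if out.ndim else float(out)


def sample_extension_per_monomer(config: SimConfig, rng: np.random.Generator, size=None):
    """Saturation extension per monomer, nm: truncated normal across the cohort."""
    mu, sd, lo = (config.extension_per_monomer_mean, config.extension_per_monomer_sd,
                  config.extension_per_monomer_min)
    a = (lo - mu) / sd
    u = rng.uniform(norm.cdf(a), 1.0, size=size)
    return mu + sd * norm.ppf(u)


def simulate_extension(
    concatemer: Concatemer,
    schedule,
    config: SimConfig,
    rng: np.random.Generator,
    extension_per_monomer: float | None = None,
) -> tuple[ExtensionTrace | None, dict]:
    """Length trajectory over a shear schedule (list of (σ, duration) pairs).

    Extension is instantaneous (complete within one frame); after a flow stop
    the length relaxes as (1−a) + a·exp(−t/τ) with τ = A·L0^ν times a
    lognormal molecule-to-molecule scatter.  Returns the post-cessation
    :class:`~vwflow.relaxation.ExtensionTrace` (or None if the schedule never
    stops flow) and a ground-truth dict.
    """
    if extension_per_monomer is None:
        extension_per_monomer = float(sample_extension_per_monomer(config, rng))
    l_max = concatemer.n_monomers * extension_per_monomer / 1000.0
    dt = 1.0 / config.relaxation_fps
    times, lengths, sigmas = [], [], []
    t = 0.0
    current_len = config.compact_size_um
    relax_trace = None
    truth = {"l_max_um": l_max, "extension_per_monomer_nm": extension_per_monomer,
             "true_tau_s": float("nan"), "l0_um": float("nan")}
    for sigma, duration in schedule:
        frames = np.arange(0.0, duration, dt)
        if sigma > 0:
            current_len = float(steady_extension(sigma, l_max, config))
            seg = np.full(frames.size, current_len)
        else:
            l0 = current_len
            tau = config.relax_prefactor * l0**config.relax_exponent
            tau *= float(np.exp(rng.normal(0.0, config.tau_scatter_sigma_log)))
            a = config.relax_amplitude
            seg = l0 * ((1.0 - a) + a * np.exp(-frames / tau))
            if relax_trace is None and l0 > config.compact_size_um:
                relax_trace = (frames.copy(), seg.copy(), l0)
                truth["true_tau_s"] = tau
                truth["l0_um"] = l0
            current_len = float(seg[-1]) if seg.size else current_len
        times.append(frames + t)
        lengths.append(seg)
        sigmas.append(np.full(frames.size, sigma))
        t += duration
    truth["times_s"] = np.concatenate(times)
    truth["length_um"] = np.concatenate(lengths)
    truth["sigma"] = np.concatenate(sigmas)
    trace = None
    if relax_trace is not None:
        ft, seg, l0 = relax_trace
        trace = ExtensionTrace(times=ft, length=seg, initial_length=l0,
                               concatemer_id=-1)
    return trace, truth


# ---------------------------------------------------------------------------
# binding

def site_tensions(concatemer: Concatemer, sigma: float) -> np.ndarray:
    """Per-monomer tension (pN), ordered tether → free end then upstream arm."""
    return tension_profile(concatemer, FlowCondition(sigma)).per_monomer_force


def simulate_binding(
    concatemer: Concatemer,
    sigma: float,
    concentration_nM: float,
    frame_times: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    equilibrated: bool = False,
) -> np.ndarray:
    """Per-frame bound state of each A1 site (one site per monomer).

    Each site binds as an independent telegraph process with on-rate
    k_on,2·P₂(f_site)·[C] and off-rate k_off.  Sites on an unextended
    (compact) molecule are shielded and binding-incompetent.  With
    ``equilibrated=True`` the initial state is drawn from the stationary
    occupancy (equilibrium snapshots); otherwise all sites start unbound
    (flow-initiation kinetics).
    """
    forces = site_tensions(concatemer, sigma)
    competent = sigma > config.onset_stress
    occ = state2_occupancy(forces, config.two_state)
    k_on_eff = config.k_on2 * occ * concentration_nM * 1e-9 if competent else np.zeros_like(occ)
    if equilibrated:
        p_stat = k_on_eff / (k_on_eff + config.k_off)
        init = (rng.random(forces.size) < p_stat).astype(np.int8)
    else:
        init = None
    return simulate_telegraph(k_on_eff, config.k_off, frame_times, rng, initial_state=init)


# ---------------------------------------------------------------------------
# rendering

def _render_channel(positions_um, fluor_pos_um, fluor_counts, single_fluor,
                    attenuation, psf_sigma, pixel, rng, read_sd):
    half = pixel / 2.0
    expected = np.zeros_like(positions_um)
    for x0, n in zip(fluor_pos_um, fluor_counts):
        if n == 0:
            continue
        frac = norm.cdf((positions_um + half - x0) / psf_sigma) - norm.cdf(
            (positions_um - half - x0) / psf_sigma)
        expected += n * single_fluor * attenuation * frac
    photons = rng.poisson(expected).astype(float)
    return photons + rng.normal(0.0, read_sd, size=expected.size)


def render_profile(
    concatemer: Concatemer,
    length_um: float,
    bound_sites: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    margin_um: float = 2.0,
    sigma: float = float("nan"),
    time: float = 0.0,
):
    """Render one frame's two-channel intensity profile.

    VWF fluorophores sit at their monomers' positions along the extended
    contour (all at one diffraction-limited spot when compact); the ligand
    channel renders one fluorophore ensemble per bound site.  Gaussian PSF,
    TIRF height attenuation, Poisson photon noise, Gaussian read noise.
    """
    from .trace_analysis import IntensityProfile

    px = config.pixel_size_um
    n_pix = int(round((length_um + 2 * margin_um) / px))
    positions = np.arange(n_pix) * px
    n = concatemer.n_monomers
    compact = length_um <= config.compact_size_um
    if compact:
        mono_pos = np.full(n, margin_um + length_um / 2.0)
    else:
        mono_pos = margin_um + (np.arange(n) + 0.5) / n * length_um
    atten = tirf_attenuation(config.vwf_height, config.reference_height,
                             config.tirf_penetration_depth)
    fluors = (concatemer.fluorophores_per_monomer
              if concatemer.fluorophores_per_monomer is not None
              else np.ones(n))
    vwf = _render_channel(positions, mono_pos, fluors, config.single_fluor_vwf,
                          atten, config.psf_sigma_um, px, rng, config.read_noise_sd)
    bound_sites = np.asarray(bound_sites, dtype=bool)
    lig_counts = np.where(bound_sites, config.ligand_dol, 0.0)
    ligand = _render_channel(positions, mono_pos, lig_counts, config.single_fluor_ligand,
                             atten, config.psf_sigma_um, px, rng, config.read_noise_sd)
    return IntensityProfile(positions=positions, vwf_channel=vwf, ligand_channel=ligand,
                            time=time, shear_stress=sigma,
                            exposure=config.equilibrium_exposure)


def simulate_photobleach(
    n_fluorophores: int,
    config: SimConfig,
    rng: np.random.Generator,
    duration: float | None = None,
    fps: float = 10.0,
) -> np.ndarray:
    """Stepwise photobleaching staircase for single-fluorophore calibration.

    Per-fluorophore exponential bleach times at ``bleach_rate``; intensity is
    (surviving fluorophores)·single_fluor plus Gaussian read noise.  A zero
    bleach rate yields a constant (noisy) trace.
    """
    if n_fluorophores < 1:
        raise ValueError("need at least one fluorophore")
    if duration is None:
        duration = 5.0 / config.bleach_rate if config.bleach_rate > 0 else 10.0
    t = np.arange(0.0, duration, 1.0 / fps)
    if config.bleach_rate > 0:
        bleach_times = rng.exponential(1.0 / config.bleach_rate, size=n_fluorophores)
    else:
        bleach_times = np.full(n_fluorophores, np.inf)
    surviving = (bleach_times[None, :] > t[:, None]).sum(axis=1)
    return surviving * config.single_fluor_vwf + rng.normal(0.0, config.read_noise_sd, t.size)


# ---------------------------------------------------------------------------
# dataset builders (the CSV/JSON products the analysis modules consume)

def generate_relaxation_dataset(
    config: SimConfig,
    n_traces: int = 94,
    duration_s: float = 3.0,
    rng: np.random.Generator | None = None,
):
    """Flow-stop relaxation traces for ``n_traces`` concatemers.

    Returns ``(traces, truth)`` where truth is a frame with ``l0_um`` and
    ``true_tau_s`` per trace.
    """
    rng = config.rng() if rng is None else rng
    cfg = replace(config, cohort_size=n_traces)
    cohort = sample_cohort(cfg, rng)
    schedule = [(config.saturation_stress, 0.5), (0.0, duration_s)]
    traces, rows = [], []
    for i, cm in enumerate(cohort):
        trace, truth = simulate_extension(cm, schedule, config, rng)
        if trace is None:
            continue
        noisy = np.clip(trace.length + rng.normal(0.0, 0.05 * trace.initial_length,
                                                  trace.length.size), 0.0, None)
        traces.append(ExtensionTrace(times=trace.times, length=noisy,
                                     initial_length=trace.initial_length,
                                     concatemer_id=i))
        rows.append({"concatemer_id": i, "l0_um": truth["l0_um"],
                     "true_tau_s": truth["true_tau_s"],
                     "n_monomers": cm.n_monomers})
    return traces, pd.DataFrame(rows)


def generate_extension_curve(
    config: SimConfig,
    sigmas=(20, 40, 80, 160, 320, 640, 1280),
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.03,
):
    """Mean relative extension vs wall shear stress (log-shear law + noise)."""
    rng = config.rng() if rng is None else rng
    sig = np.asarray(sigmas, dtype=float)
    rel = steady_extension(sig, 1.0, config, compact_size=0.0)
    rel = np.clip(rel + rng.normal(0.0, noise_sd, sig.size), 0.0, None)
    return list(zip(sig.tolist(), rel.tolist()))


def generate_equilibrium_binding_dataset(
    config: SimConfig,
    n_concatemers: int = 103,
    concentration_nM: float = 100.0,
    n_frames: int = 5,
    rng: np.random.Generator | None = None,
):
    """Force-binned equilibrium bound densities from long concatemers.

    Uses concatemers long enough to span all seven 8 pN tension bins at
    saturation stress, draws per-site equilibrium occupancy over ``n_frames``
    equilibrium frames, and pools bound counts per tension bin across the
    cohort.  Snapshots are sampled from the equilibrium binding law
    n(f)/N = P₂(f)·[C]/(K_D,2 + [C]) — the conformation-then-binding
    hierarchy of the two-state model; flow-initiation *kinetics* use the
    exact telegraph simulator instead (see docs).  Sites at tensions beyond
    the 56 pN bin ceiling are outside the binned analysis and dropped.
    Returns ``(bins, truth)`` with per-bin
    :class:`~vwflow.twostate.ForceBinnedBinding` and the generating
    parameters.
    """
    rng = config.rng() if rng is None else rng
    sigma = config.saturation_stress
    f_mono = average_monomer_force(FlowCondition(sigma))
    n_min = int(math.ceil(56.0 / f_mono)) + 2  # span all seven bins
    cfg = replace(config, cohort_size=n_concatemers,
                  size_range=(max(n_min, config.size_range[0]),
                              max(config.size_range[1], n_min + 1)))
    cohort = sample_cohort(cfg, rng)
    edges = np.arange(0.0, 64.0, 8.0)
    bound_tot = np.zeros(7)
    length_tot = np.zeros(7)
    force_sum = np.zeros(7)
    site_cnt = np.zeros(7)
    spacing_um = 60.0 / 1000.0  # one site per monomer along the extended contour
    k_d2 = config.k_off / config.k_on2 * 1e9  # nM
    langmuir = concentration_nM / (k_d2 + concentration_nM)
    for cm in cohort:
        forces = site_tensions(cm, sigma)
        keep = forces < edges[-1]
        forces = forces[keep]
        p_occ = langmuir * state2_occupancy(forces, config.two_state)
        states = rng.random((forces.size, n_frames)) < p_occ[:, None]
        mean_bound = states.mean(axis=1)  # per-site occupancy over frames
        bin_idx = np.searchsorted(edges, forces, side="right") - 1
        np.add.at(bound_tot, bin_idx, mean_bound)
        np.add.at(length_tot, bin_idx, spacing_um)
        np.add.at(force_sum, bin_idx, forces)
        np.add.at(site_cnt, bin_idx, 1.0)
    bins = [
        ForceBinnedBinding(
            bin_center_force=float(force_sum[b] / site_cnt[b]),
            bound_per_um=float(bound_tot[b] / length_tot[b]),
            ligand_concentration=concentration_nM,
            n_concatemers=n_concatemers,
        )
        for b in range(7) if site_cnt[b] > 0
    ]
    truth = {
        "delta_G": config.delta_G, "delta_x": config.delta_x,
        "n_total_per_um": 1.0 / spacing_um,
        "n_max_per_um": (1.0 / spacing_um) * concentration_nM
        / (config.k_off / config.k_on2 * 1e9 + concentration_nM),
    }
    return bins, truth


def generate_association_dataset(
    config: SimConfig,
    force_pN: float,
    n_sites: int = 2000,
    duration_s: float = 0.6,
    rng: np.random.Generator | None = None,
):
    """Association traces at the concentration ladder for one tension bin.

    ``n_sites`` independent A1 sites at tension ``force_pN`` are simulated
    from the unbound state at each ladder concentration; the bound count is
    converted to a per-μm density at one site per 60 nm.  Returns
    ``(traces, truth)``.
    """
    rng = config.rng() if rng is None else rng
    frame_times = np.arange(1, int(duration_s * config.kinetics_fps) + 1) / config.kinetics_fps
    occ = state2_occupancy(force_pN, config.two_state)
    spacing_um = 60.0 / 1000.0
    traces = []
    for conc in config.concentrations:
        k_on_eff = config.k_on2 * occ * conc * 1e-9
        states = simulate_telegraph(np.full(n_sites, k_on_eff), config.k_off,
                                    frame_times, rng)
        density = states.sum(axis=0) / (n_sites * spacing_um)
        traces.append(AssociationTrace(times=frame_times, bound_per_um=density,
                                       ligand_concentration=conc,
                                       n_concatemers=n_sites))
    truth = {
        "k_on_apparent": config.k_on2 * occ,
        "k_off": config.k_off,
        "n_total_per_um": 1.0 / spacing_um,
        "force_pN": force_pN,
    }
    return traces, truth


def generate_activation_dataset(
    config: SimConfig,
    sigma_ramp: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
):
    """Per-concatemer activation thresholds over an ascending stress ramp.

    Activation obeys a pure tension threshold by construction: a concatemer
    activates at the first ramp stress where its maximal tension
    f_mono(σ)·N_downstream reaches the threshold tension implied by the
    configured coefficient b (σ_T·N = b).  Returns ``(records, truth)`` with
    records columns ``concatemer_id``, ``n_vwf``, ``n_downstream``,
    ``sigma_t``.
    """
    rng = config.rng() if rng is None else rng
    if sigma_ramp is None:
        sigma_ramp = np.geomspace(20.0, 4000.0, 40)
    cohort = sample_cohort(config, rng)
    f_act = config.activation_tension_pN
    rows = []
    for i, cm in enumerate(cohort):
        calls = []
        for s in sigma_ramp:
            max_tension = average_monomer_force(FlowCondition(float(s))) * cm.n_downstream
            calls.append((float(s), max_tension >= f_act))
        first = next((s for s, c in calls if c), float("nan"))
        rows.append({"concatemer_id": i, "n_vwf": cm.n_monomers,
                     "n_downstream": cm.n_downstream, "sigma_t": first})
    truth = {"b": config.activation_b, "tension_threshold_pN": f_act}
    return pd.DataFrame(rows), truth
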