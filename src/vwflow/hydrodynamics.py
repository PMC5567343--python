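"""Hydrodynamic drag, tension profiles, and collision-rate estimates.

A concatemer tethered to the chamber wall experiences Stokes drag on every
monomer; the drag accumulates along the chain so that tension is maximal at
the tether and zero at the free end.  Because the near-wall flow velocity at
height ``h`` is ``v = γh`` and ``μγ = σ``, the per-monomer drag depends only
on the wall shear stress σ and the monomer geometry — viscosity cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    AVOGADRO,
    CP_TO_PA_S,
    DEFAULT_TEMPERATURE_K,
    DYN_CM2_TO_PA,
    KB_J_PER_K,
)
from .polymer import Concatemer

__all__ = [
    "FlowCondition",
    "DragModel",
    "DUMBBELL",
    "FIVE_SPHERE",
    "TensionProfile",
    "CollisionParams",
    "monomer_drag_force",
    "average_monomer_force",
    "tension_profile",
    "diffusion_limited_rate",
    "advective_collision_rate",
    "tirf_attenuation",
    "constants_table",
]


@dataclass(frozen=True)
class FlowCondition:
    """Flow state in the chamber.

    Parameters
    ----------
    wall_shear_stress : float
        σ in dyn cm⁻².
    viscosity : float
        μ in cP; only enters the stress↔rate conversion and diffusion rates.
    temperature : float
        K.
    transport_velocity : float, optional
        Bulk transport velocity in mm s⁻¹, used for downstream-dissociation
        distance estimates.
    """

    wall_shear_stress: float
    viscosity: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE_K
    transport_velocity: float | None = None

    def __post_init__(self) -> None:
        if self.wall_shear_stress < 0:
            raise ValueError("wall_shear_stress must be >= 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def shear_rate(self) -> float:
        """γ = σ/μ in s⁻¹."""
        return self.wall_shear_stress * DYN_CM2_TO_PA / (self.viscosity * CP_TO_PA_S)


@dataclass(frozen=True)
class DragModel:
    """Sphere-chain idealization of a VWF monomer for Stokes-drag estimates.

    ``dumbbell`` treats the dimer as two 13 nm-radius spheres (one sphere per
    monomer, center height 20 nm); ``five_sphere`` strings five 3 nm-radius
    spheres per monomer at 10 nm center height.
    """

    name: str
    sphere_radius: float  # nm
    sphere_count: int  # drag spheres per monomer
    monomer_center_height: float  # nm above the wall
    monomer_contour_length: float = 60.0  # nm

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0 or self.monomer_center_height <= 0:
            raise ValueError("drag-model geometry must be positive")
        if self.sphere_count < 1:
            raise ValueError("sphere_count must be >= 1")
        if self.monomer_contour_length <= 0:
            raise ValueError("monomer_contour_length must be positive")


DUMBBELL = DragModel("dumbbell", sphere_radius=13.0, sphere_count=1, monomer_center_height=20.0)
FIVE_SPHERE = DragModel("five_sphere", sphere_radius=3.0, sphere_count=5, monomer_center_height=10.0)


@dataclass(frozen=True)
class TensionProfile:
    """Per-monomer tension from tether to free end.

    ``per_monomer_force[i]`` is the tension borne across monomer ``i`` —
    f_mono times the number of monomers strictly downstream of it — so the
    free-end entry is exactly zero.  The tension at the tether point itself,
    which also carries the drag of the tethered monomer, is
    ``tension_at_tether = f_mono × n_downstream``.
    """

    per_monomer_force: np.ndarray  # pN, ordered tether → free end, then upstream arm
    f_mono: float  # pN
    tension_at_tether: float  # pN

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_monomer_force, dtype=float)
        if (arr < 0).any():
            raise ValueError("tension must be non-negative")
        if (np.diff(arr) > 1e-9).any():
            raise ValueError("tension must be non-increasing from tether to free end")
        object.__setattr__(self, "per_monomer_force", arr)

    def force_at_monomer(self, downstream_rank: int) -> float:
        """Tension at the monomer ranked ``downstream_rank`` from the tether."""
        return float(self.per_monomer_force[downstream_rank])


@dataclass(frozen=True)
class CollisionParams:
    """Geometry for Smoluchowski / advective collision-rate estimates.

    ``encounter_radius`` defaults to 2r (equal reactant radii); the relative
    diffusion coefficient D_AG = 2·k_BT/(6πμr) is computed on demand.
    """

    reactant_radius: float = 3.0  # nm
    encounter_radius: float | None = None  # nm; defaults to 2r
    shear_rate: float = 0.0  # s⁻¹
    height: float = 10.0  # nm

    def __post_init__(self) -> None:
        if self.reactant_radius <= 0:
            raise ValueError("reactant_radius must be positive")
        if self.encounter_radius is None:
            object.__setattr__(self, "encounter_radius", 2.0 * self.reactant_radius)
        if self.encounter_radius <= 0 or self.height <= 0:
            raise ValueError("encounter_radius and height must be positive")
        if self.shear_rate < 0:
            raise ValueError("shear_rate must be >= 0")

    def relative_diffusion(self, viscosity_cp: float, temperature: float) -> float:
        """D_AG = 2·k_BT/(6πμr) in m² s⁻¹."""
        mu = viscosity_cp * CP_TO_PA_S
        r = self.reactant_radius * 1e-9
        return 2.0 * KB_J_PER_K * temperature / (6.0 * math.pi * mu * r)


def monomer_drag_force(model: DragModel, flow: FlowCondition) -> float:
    """Stokes drag on one monomer, in pN.

    f = n_spheres · 6π·r·μ·v with v = γh and μγ = σ, hence
    f = n_spheres · 6π·r·σ·h: the result depends only on wall shear stress
    and geometry, not viscosity.
    """
    r = model.sphere_radius * 1e-9  # m
    h = model.monomer_center_height * 1e-9  # m
    sigma = flow.wall_shear_stress * DYN_CM2_TO_PA  # Pa
    force_n = model.sphere_count * 6.0 * math.pi * r * sigma * h
    return force_n * 1e12  # pN


def average_monomer_force(flow: FlowCondition) -> float:
    """Mean per-monomer drag of the dumbbell and five-sphere models, pN.

    Linear in σ; equals 0.5 pN (one decimal) at 1280 dyn cm⁻².
    """
    return 0.5 * (monomer_drag_force(DUMBBELL, flow) + monomer_drag_force(FIVE_SPHERE, flow))


def tension_profile(concatemer: Concatemer, flow: FlowCondition) -> TensionProfile:
    """Tension along a tethered concatemer under flow.

    The downstream (longer) arm bears f_mono per downstream monomer; monomers
    on the short, upstream side of an interior tether trail in the flow with
    no downstream load and are assigned zero tension.  The returned profile is
    ordered tether → free end, with the upstream arm's zeros appended.
    """
    f_mono = average_monomer_force(flow)
    n_down = concatemer.n_downstream
    n_up = concatemer.n_upstream
    downstream = f_mono * np.arange(n_down - 1, -1, -1, dtype=float)
    profile = np.concatenate([downstream, np.zeros(n_up)])
    return TensionProfile(
        per_monomer_force=profile,
        f_mono=f_mono,
        tension_at_tether=f_mono * n_down,
    )


def diffusion_limited_rate(
    params: CollisionParams | None = None,
    flow: FlowCondition | None = None,
) -> float:
    """Smoluchowski diffusion-limited collision rate, M⁻¹ s⁻¹.

    k_D = 4π·R*·D_AG = 8·k_BT/(3μ) for equal reactant radii — independent of
    the radius itself.  Defaults: T = 298 K, μ = 1 cP (aqueous).
    """
    temperature = flow.temperature if flow is not None else 298.0
    viscosity = flow.viscosity if flow is not None else 1.0
    mu = viscosity * CP_TO_PA_S
    rate_m3_per_s = 8.0 * KB_J_PER_K * temperature / (3.0 * mu)
    return rate_m3_per_s * 1e3 * AVOGADRO  # m³/s → L/(mol·s)


def advective_collision_rate(params: CollisionParams) -> float:
    """Collision rate from advective flux through a disk of radius R*, M⁻¹ s⁻¹.

    k_A = π·(R*)²·v with v = γh.
    """
    r_star = params.encounter_radius * 1e-9  # m
    h = params.height * 1e-9  # m
    rate_m3_per_s = math.pi * r_star**2 * params.shear_rate * h
    return rate_m3_per_s * 1e3 * AVOGADRO


def tirf_attenuation(
    dye_height: float,
    reference_height: float = 4.5,
    penetration_depth: float = 150.0,
) -> float:
    """Evanescent-field intensity ratio between a dye at ``dye_height`` and one
    at ``reference_height`` (nm), for the given TIRF penetration depth."""
    if penetration_depth <= 0:
        raise ValueError("penetration_depth must be positive")
    if dye_height < 0 or reference_height < 0:
        raise ValueError("heights must be >= 0")
    return math.exp(-(dye_height - reference_height) / penetration_depth)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def constants_table() -> dict:
    """Closed-form worked quantities at the reference conditions.

    Self-check table for the CLI: per-monomer drag at 1280 dyn cm⁻², the
    diffusion vs advection collision rates at γ = 128,000 s⁻¹, TIRF
    attenuation at 10/20 nm dye height, and the structural Δx arithmetic.
    Every entry is computed through the same module functions the pipeline
    uses; report-level rounding is one decimal (pN) and one significant
    figure (collision rates).
    """
    from .kinetics import dissociation_distance
    from .twostate import structural_delta_x

    flow = FlowCondition(wall_shear_stress=1280.0)
    coll = CollisionParams(reactant_radius=3.0, shear_rate=128000.0, height=10.0)
    k_d = diffusion_limited_rate(None, FlowCondition(1280.0, viscosity=1.0, temperature=298.0))
    k_a = advective_collision_rate(coll)
    return {
        "drag_dumbbell_pN_at_1280": round(monomer_drag_force(DUMBBELL, flow), 1),
        "drag_five_sphere_pN_at_1280": round(monomer_drag_force(FIVE_SPHERE, flow), 1),
        "drag_average_pN_at_1280": round(average_monomer_force(flow), 1),
        "diffusion_limited_rate_M_per_s": _round_sig(k_d, 1),
        "advective_collision_rate_M_per_s": _round_sig(k_a, 1),
        "diffusion_over_advection": round(k_d / k_a),
        "tirf_ratio_h10": round(tirf_attenuation(10.0), 2),
        "tirf_ratio_h20": round(tirf_attenuation(20.0), 2),
        "structural_delta_x_nm": structural_delta_x(1.8, 0.8, 1.2),
        "dissociation_distance_mm_90pct": round(dissociation_distance(23.0, 7.0, 0.90), 2),
    }
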