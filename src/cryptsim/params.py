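"""Parameter containers for crypt simulations.

All lengths are measured in cell radii (1 cell radius = 5 µm), volumes in µm³
and times in hours unless stated otherwise.  The defaults below define the
reference wild-type crypt: a hemispherical niche of radius 4 cell radii joined
to a cylinder of the same radius, an exit boundary at geodesic position
P = 30, Wnt thresholds P1 = 5 / P2 = 12 and Notch contact thresholds
C1 = 3 (Paneth contacts for stem-cell maintenance) / C2 = 1 (goblet contacts
for enterocyte maintenance).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

#: one cell radius in µm; sets the length unit of the whole model
CELL_RADIUS_UM = 5.0

#: reference (post-division) cell volume, µm³: a sphere of radius 5 µm
V0_UM3 = 4.0 / 3.0 * 3.141592653589793 * CELL_RADIUS_UM**3  # ≈ 523.6

HOURS_PER_WEEK = 168.0


@dataclass
class GeometryParams:
    """Fixed basal-membrane surface: hemispherical cap + cylinder."""

    cap_radius: float = 4.0          # cell radii; cylinder radius is the same
    crypt_length: float = 40.0       # max axial extent kept in memory
    exit_position: float = 30.0      # cells with P > exit_position are removed

    def __post_init__(self) -> None:
        if self.cap_radius <= 0:
            raise ValueError("cap_radius must be positive")
        if self.crypt_length <= self.cap_radius:
            raise ValueError("crypt_length must exceed cap_radius")


@dataclass
class MechanicsParams:
    """Overdamped off-lattice mechanics constants."""

    k_rep: float = 2.0               # Hertz repulsion prefactor
    k_adh: float = 0.4               # constant short-range adhesion magnitude
    adhesion_range: float = 0.2      # cell radii beyond touching
    friction: float = 1.0            # normalises the time unit
    bias_up: float = 0.3             # EC/GC active migration force (up-axis)
    bias_up_start: float = 8.0       # active up-migration engages above this P
    bias_down: float = 0.3           # PC active migration force (down-axis)
    dt: float = 0.1                  # mechanics substep, h
    dt_max: float = 0.25             # stability bound on dt
    max_step: float = 0.2            # displacement clamp per substep, cell radii
    contact_factor: float = 1.4      # contact iff d < factor·(r_i+r_j)
    substrate_tolerance: float = 0.1 # cell radii, for substrate-contact test
    pc_anchor_friction: float = 1.0  # friction multiplier for terminal PCs
    pc_anchor_extent: float = 5.0    # ... anchored below this position (1 = off)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > self.dt_max:
            raise ValueError(
                f"dt={self.dt} outside stability range (0, {self.dt_max}]"
            )


@dataclass
class GrowthParams:
    """Linear volume growth and contact inhibition."""

    v0: float = V0_UM3               # post-division volume, µm³
    vp_fraction: float = 0.8         # contact-inhibition threshold Vp = 0.8·V0
    cycle_growth_time: float = 16.0  # h to double volume unconstrained
    cycle_cv: float = 0.1            # lognormal CV of per-cell growth times
    pc_volume_scale: float = 1.5     # target volume of terminal PCs (x V0):
                                     # Paneth cells are large secretory cells
    anoikis_volume_fraction: float = 0.05  # delamination when available < frac·V0
    anoikis_grace: float = 12.0      # h of sustained full compression

    @property
    def vp(self) -> float:
        return self.vp_fraction * self.v0


@dataclass
class FateParams:
    """Positional Wnt thresholds and Notch contact-count thresholds."""

    P1: float = 5.0                  # loss of high Wnt (specification border)
    P2: float = 12.0                 # terminal differentiation border
    C1: int = 3                      # min PC contacts for SC maintenance
    C2: int = 1                      # min GC contacts for EC maintenance
    niche_extent: float = 5.0        # fixed SC-niche region P < niche_extent
    fate_interval: float = 1.0       # h between fate-update ticks
    specification_delay: float = 8.0 # h a ligand deficit must persist before
                                     # secretory specification commits
    max_pc_progenitor_wait: float = 48.0  # h inhibited before terminal w/o division

    def __post_init__(self) -> None:
        if not self.P2 > self.P1 >= 0:
            raise ValueError("need P2 > P1 >= 0")
        if self.C1 < 0 or self.C2 < 0:
            raise ValueError("C1, C2 must be >= 0")


@dataclass
class PanethLifespanParams:
    """Paneth-cell death control.

    ``mean_intrinsic_lifespan`` is expressed in weeks (the unit in which the
    biology is usually quoted); draws are truncated-normal with the given CV.
    ``contact_death_enabled`` switches on programmed death after more than
    ``contact_starvation_threshold`` hours without any stem-cell contact.
    """

    mean_intrinsic_lifespan: float = 4.0   # weeks
    lifespan_cv: float = 0.25
    contact_death_enabled: bool = False
    contact_starvation_threshold: float = 12.0  # h, strict ">"

    def __post_init__(self) -> None:
        if self.mean_intrinsic_lifespan <= 0:
            raise ValueError("mean_intrinsic_lifespan must be > 0")
        if self.contact_starvation_threshold <= 0:
            raise ValueError("contact_starvation_threshold must be > 0")

    @property
    def mean_lifespan_hours(self) -> float:
        return self.mean_intrinsic_lifespan * HOURS_PER_WEEK


@dataclass
class MutationEvent:
    """One mutation event: a selector plus a profile name, at a given time.

    ``time`` is measured from the analysis start (steady state);
    the selector/profile objects live in :mod:`cryptsim.mutation`.
    """

    selector: str = "deepest_SC"
    profile: str = "neutral"
    time: float = 0.0
    count: int = 1
    fraction: Optional[float] = None
    profile_overrides: dict = field(default_factory=dict)


@dataclass
class AnalysisParams:
    censor_horizon: float = 52 * HOURS_PER_WEEK   # h
    conversion_population: str = "SC"             # "SC" or "all"
    stop_at_conversion: bool = True
    snapshot_interval: float = 12.0               # h


@dataclass
class BurnInParams:
    min_hours: float = 336.0        # 2 simulated weeks
    max_hours: float = 1500.0
    drift_tolerance: float = 0.02   # relative drift over a 1-week window
    window: float = 168.0


@dataclass
class SimulationParams:
    """Complete, self-contained configuration of one scenario."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    fate: FateParams = field(default_factory=FateParams)
    paneth: PanethLifespanParams = field(default_factory=PanethLifespanParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    burn_in: BurnInParams = field(default_factory=BurnInParams)
    mutation_events: list = field(default_factory=list)
    replicates: int = 1
    master_seed: int = 0
    label: str = "wild_type"

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        kwargs: dict[str, Any] = {}
        sub = {
            "geometry": GeometryParams,
            "mechanics": MechanicsParams,
            "growth": GrowthParams,
            "fate": FateParams,
            "paneth": PanethLifespanParams,
            "analysis": AnalysisParams,
            "burn_in": BurnInParams,
        }
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                kwargs[key] = sub[key](**val)
            elif key == "mutation_events":
                kwargs[key] = [
                    MutationEvent(**m) if isinstance(m, dict) else m for m in val
                ]
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump(self.to_dict(), buf, sort_keys=False)
        return buf.getvalue()

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationParams":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)
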