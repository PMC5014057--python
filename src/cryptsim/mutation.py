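"""Heritable parameter-override profiles ("mutations") and their selectors.

A mutation is modelled as a named profile of parameter overrides attached to
selected stem cells at a defined time; daughters inherit the profile at
division.  Profiles can override

* ``C1_eff`` / ``C2_eff`` — the Notch contact-count thresholds,
* ``Vp_scale`` — rescales the contact-inhibition threshold volume,
* ``cycle_time_delta`` — additive change of the mean volume-doubling time (h),
* ``pc_migration_bias`` — switch the downward Paneth migration bias on/off,
* ``maintain_outside_niche`` — treat Wnt as high at every position and
  suppress terminal differentiation (niche-independent maintenance).

Two literature-motivated profiles are provided: ``mutant1`` raises the Paneth
contact requirement of stem-cell maintenance (C1 > 3), which biases the
mutant lineage toward Paneth specification; ``mutant2`` additionally confers
niche-independent maintenance, reduced contact-inhibition sensitivity
(Vp* = 0.76 Vp) and Paneth progeny without a migration bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import population as pops
from .params import FateParams

_ALLOWED_KEYS = {
    "C1_eff",
    "C2_eff",
    "Vp_scale",
    "cycle_time_delta",
    "pc_migration_bias",
    "maintain_outside_niche",
}

SELECTOR_MODES = (
    "deepest_SC",
    "random_SC",
    "all_SCs",
    "half_of_SCs",
    "division_associated",
)


@dataclass
class MutationProfile:
    name: str
    overrides: dict = field(default_factory=dict)
    applied_at: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.overrides) - _ALLOWED_KEYS
        if bad:
            raise ValueError(f"unknown override keys: {sorted(bad)}")

    def compose(self, other: "MutationProfile") -> "MutationProfile":
        """Later profile wins on key collisions."""
        merged = {**self.overrides, **other.overrides}
        return MutationProfile(
            name=f"{self.name}+{other.name}",
            overrides=merged,
            applied_at=other.applied_at,
        )


def neutral_profile() -> MutationProfile:
    """Pure clone label: no parameter overrides, dynamics unchanged."""
    return MutationProfile("neutral", {})


def mutant1_profile(C1_value: int = 4) -> MutationProfile:
    """Wnt-activating mutant: raised Paneth-contact requirement (C1 > 3)."""
    if not isinstance(C1_value, (int, np.integer)) or C1_value <= 3:
        raise ValueError("mutant1 requires an integer C1 value > 3")
    return MutationProfile(f"mutant1_C1_{C1_value}", {"C1_eff": int(C1_value)})


def mutant2_profile(C1_value: int = 4) -> MutationProfile:
    """mutant1 plus niche-independent maintenance, lower contact-inhibition
    sensitivity (Vp* = 0.76 Vp) and Paneth progeny without migration bias."""
    prof = mutant1_profile(C1_value)
    return MutationProfile(
        f"mutant2_C1_{C1_value}",
        {
            **prof.overrides,
            "Vp_scale": 0.76,
            "pc_migration_bias": False,
            "maintain_outside_niche": True,
        },
    )


NAMED_PROFILES = {
    "neutral": neutral_profile,
    "mutant1": mutant1_profile,
    "mutant2": mutant2_profile,
}


def make_profile(name: str, overrides: Optional[dict] = None,
                 **kwargs) -> MutationProfile:
    if overrides:
        return MutationProfile(name, dict(overrides))
    if name in NAMED_PROFILES:
        return NAMED_PROFILES[name](**kwargs)
    return MutationProfile(name, {})


# ---------------------------------------------------------------------------


class ProfileTable:
    """Registry of profiles with per-profile effective parameter arrays.

    Profile index 0 is always the wild type derived from :class:`FateParams`.
    """

    def __init__(self, fate: FateParams):
        self.fate = fate
        self.profiles: list[MutationProfile] = [MutationProfile("wild_type", {})]
        self._rebuild()

    def _rebuild(self) -> None:
        n = len(self.profiles)
        self.C1_eff = np.full(n, self.fate.C1, dtype=np.int64)
        self.C2_eff = np.full(n, self.fate.C2, dtype=np.int64)
        self.vp_scale = np.ones(n)
        self.cycle_delta = np.zeros(n)
        self.pc_bias_on = np.ones(n, dtype=bool)
        self.maintain_outside = np.zeros(n, dtype=bool)
        for i, prof in enumerate(self.profiles):
            ov = prof.overrides
            if "C1_eff" in ov:
                self.C1_eff[i] = ov["C1_eff"]
            if "C2_eff" in ov:
                self.C2_eff[i] = ov["C2_eff"]
            if "Vp_scale" in ov:
                self.vp_scale[i] = ov["Vp_scale"]
            if "cycle_time_delta" in ov:
                self.cycle_delta[i] = ov["cycle_time_delta"]
            if "pc_migration_bias" in ov:
                self.pc_bias_on[i] = bool(ov["pc_migration_bias"])
            if "maintain_outside_niche" in ov:
                self.maintain_outside[i] = bool(ov["maintain_outside_niche"])

    def add(self, profile: MutationProfile) -> int:
        self.profiles.append(profile)
        self._rebuild()
        return len(self.profiles) - 1

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]


# ---------------------------------------------------------------------------
# selectors


@dataclass
class MutationSelector:
    mode: str = "deepest_SC"
    count: int = 1
    fraction: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in SELECTOR_MODES:
            raise ValueError(f"unknown selector mode {self.mode!r}")

    def select(self, pop: pops.CellPopulation, P: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Indices of the SCs to mutate (never non-SC cells)."""
        sc_idx = np.flatnonzero(pop.is_sc())
        if len(sc_idx) == 0:
            raise RuntimeError("selector matched no SC")
        if self.mode == "deepest_SC":
            # minimal P; ties broken deterministically by lowest cell id
            Psc = P[sc_idx]
            best = Psc.min()
            cand = sc_idx[Psc <= best + 1e-12]
            return np.array([cand[np.argmin(pop.id[cand])]])
        if self.mode == "all_SCs":
            return sc_idx
        if self.mode == "half_of_SCs":
            # position-stratified halving: SCs sorted by depth are split in
            # consecutive pairs, one member per pair chosen by coin flip, so
            # the two halves start with matched positional quality (an
            # alternating arrangement, not a random cluster assignment)
            order = sc_idx[np.argsort(P[sc_idx], kind="stable")]
            picked = []
            for a in range(0, len(order) - 1, 2):
                picked.append(order[a + int(rng.random() < 0.5)])
            if len(order) % 2:
                if rng.random() < 0.5:
                    picked.append(order[-1])
            return np.asarray(picked, dtype=np.int64)
        if self.mode == "random_SC":
            k = min(self.count, len(sc_idx))
            return rng.choice(sc_idx, size=k, replace=False)
        raise ValueError(
            "division_associated selection operates on the division event "
            "stream; use division_associated_selector()"
        )


def apply_mutation(
    pop: pops.CellPopulation,
    table: ProfileTable,
    selector: MutationSelector,
    profile: MutationProfile,
    P: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Attach *profile* to the selected SCs; returns the mutated cell ids.

    Daughter cells inherit the profile automatically because division copies
    the per-cell profile index.
    """
    idx = selector.select(pop, P, rng)
    if np.any(pop.state[idx] != pops.SC):
        raise RuntimeError("mutation applied to a non-SC cell")
    pidx = table.add(profile)
    pop.profile[idx] = pidx
    # an immediate cycle-time change also affects the cells' current clocks
    delta = table.cycle_delta[pidx]
    if delta:
        pop.growth_time[idx] = np.maximum(pop.growth_time[idx] + delta, 1.0)
    return pop.id[idx].copy()


def division_associated_selector(division_events, rng: np.random.Generator):
    """Pick the mutation carrier from a stream of SC division events.

    The first SC division after the mutation time point carries the mutation;
    one of the two daughters is chosen by fair coin.  Placing mutations this
    way makes their positional distribution equal to the SC division-event
    distribution p(P) by construction.

    *division_events* is an iterable of records with ``daughter1_id`` /
    ``daughter2_id`` fields (or (mother, d1, d2, ...) tuples).
    """
    for ev in division_events:
        if hasattr(ev, "daughter1_id"):
            d1, d2 = ev.daughter1_id, ev.daughter2_id
        else:
            d1, d2 = ev[1], ev[2]
        return d1 if rng.random() < 0.5 else d2
    return None
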