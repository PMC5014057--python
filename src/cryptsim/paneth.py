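"""Paneth-cell lifespan control.

Terminal Paneth cells carry an intrinsic lifespan drawn once at terminal
differentiation (truncated-normal around the configured mean, weeks).  An
optional extrinsic mechanism removes Paneth cells that fail to touch any
stem cell for more than a starvation threshold (default 12 h): unused
niche cells are cleared, which keeps Paneth and stem cells intermingled
even for long intrinsic lifespans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import population as pops
from .mechanics import ContactGraph
from .params import PanethLifespanParams
from .population import CellPopulation

__all__ = [
    "sample_intrinsic_lifespan",
    "update_contact_clock",
    "pc_death_check",
    "paneth_tick",
    "PCDeath",
]


def sample_intrinsic_lifespan(
    params: PanethLifespanParams, rng: np.random.Generator, size=None
):
    """Draw intrinsic lifespans in hours (truncated at zero)."""
    mean = params.mean_lifespan_hours
    sd = params.lifespan_cv * mean
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    n = 1 if size is None else int(size)
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():  # truncation: redraw the negligible negative tail
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return float(out[0]) if size is None else out


def update_contact_clock(clock, has_SC_contact, dt: float):
    """Starvation clock: accumulates without SC contact, resets with it."""
    clock = np.asarray(clock, dtype=float)
    has = np.asarray(has_SC_contact, dtype=bool)
    out = np.where(has, 0.0, clock + dt)
    if out.ndim == 0:
        return float(out)
    return out


def pc_death_check(clock: float, age: float, lifespan: float,
                   params: PanethLifespanParams):
    """Death cause for one terminal Paneth cell, or ``None``.

    Contact-triggered death needs strictly more than the starvation
    threshold; otherwise the intrinsic clock applies.
    """
    if params.contact_death_enabled and clock > params.contact_starvation_threshold:
        return "contact"
    if age > lifespan:
        return "intrinsic"
    return None


@dataclass
class PCDeath:
    time: float
    cell_id: int
    founder_id: int
    P: float
    cause: str  # "contact" | "intrinsic"


def paneth_tick(
    pop: CellPopulation,
    contacts: ContactGraph,
    P: np.ndarray,
    params: PanethLifespanParams,
    dt: float,
    time: float,
) -> list[PCDeath]:
    """Advance starvation clocks and remove dying terminal Paneth cells."""
    term = pop.state == pops.PC_TERM
    if not term.any():
        return []
    pop.pc_age[term] += dt
    # SC contact per Paneth cell
    has_sc = np.zeros(pop.n, dtype=bool)
    if len(contacts.pairs):
        i, j = contacts.pairs[:, 0], contacts.pairs[:, 1]
        sc = pop.is_sc()
        has_sc |= np.bincount(i, weights=sc[j], minlength=pop.n).astype(bool)
        has_sc |= np.bincount(j, weights=sc[i], minlength=pop.n).astype(bool)
    pop.pc_clock[term] = update_contact_clock(
        pop.pc_clock[term], has_sc[term], dt
    )
    contact_death = np.zeros(pop.n, dtype=bool)
    if params.contact_death_enabled:
        contact_death = term & (
            pop.pc_clock > params.contact_starvation_threshold
        )
    intrinsic_death = term & ~contact_death & (pop.pc_age > pop.pc_lifespan)
    dead = contact_death | intrinsic_death
    records = [
        PCDeath(
            time=time,
            cell_id=int(pop.id[idx]),
            founder_id=int(pop.founder[idx]),
            P=float(P[idx]),
            cause="contact" if contact_death[idx] else "intrinsic",
        )
        for idx in np.flatnonzero(dead)
    ]
    if dead.any():
        pop.keep(~dead)
    return records
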