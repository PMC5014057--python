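"""Wnt/Notch lineage fate rules.

Wnt activity is a function of crypt position only: high below ``P1``, low
between ``P1`` and ``P2``, and below the terminal-differentiation threshold
beyond ``P2`` (each threshold position belongs to the lower-Wnt class).
Notch activity is determined by contacts: secretory neighbours (Paneth and
goblet cells) present ligand, and a cell needs at least ``C1`` Paneth
contacts to keep the stem-cell fate (``C2`` goblet contacts for the
enterocyte fate).  All decisions are reversible until terminal
differentiation; Paneth progenitors terminally differentiate after one last
cell cycle following specification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import population as pops
from .mechanics import ContactGraph
from .mutation import ProfileTable
from .params import FateParams
from .population import Cell, CellPopulation

__all__ = [
    "WNT_HIGH",
    "WNT_LOW",
    "WNT_TERMINAL",
    "wnt_class",
    "count_ligand_contacts",
    "update_fate",
    "pc_last_cycle_tracker",
    "fate_tick",
    "FateChange",
]

WNT_HIGH = "high"
WNT_LOW = "low"
WNT_TERMINAL = "terminal_zone"
_WNT_NAMES = (WNT_HIGH, WNT_LOW, WNT_TERMINAL)


def wnt_class(P, fate: FateParams):
    """Wnt signalling class at position *P* (scalar or array).

    ``high`` for P < P1, ``low`` for P1 <= P < P2, ``terminal_zone`` for
    P >= P2.
    """
    P_arr = np.asarray(P, dtype=float)
    code = np.where(P_arr >= fate.P2, 2, np.where(P_arr >= fate.P1, 1, 0))
    if P_arr.ndim == 0:
        return _WNT_NAMES[int(code)]
    return code


def ligand_contact_counts(
    pop: CellPopulation, contacts: ContactGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell numbers of Paneth and goblet contact neighbours.

    Paneth ligand presentation follows terminal differentiation: only
    terminal PCs count toward ``n_PC`` (a cell hours into Paneth
    specification does not yet present ligand, and specifying clusters must
    not stabilise each other).  Goblet counting includes progenitors, whose
    specification is fast relative to transit.
    """
    n_pc = np.zeros(pop.n, dtype=np.int64)
    n_gc = np.zeros(pop.n, dtype=np.int64)
    if len(contacts.pairs):
        i, j = contacts.pairs[:, 0], contacts.pairs[:, 1]
        pc = pop.state == pops.PC_TERM
        gc = pop.is_gc()
        n_pc += np.bincount(i, weights=pc[j], minlength=pop.n).astype(np.int64)
        n_pc += np.bincount(j, weights=pc[i], minlength=pop.n).astype(np.int64)
        n_gc += np.bincount(i, weights=gc[j], minlength=pop.n).astype(np.int64)
        n_gc += np.bincount(j, weights=gc[i], minlength=pop.n).astype(np.int64)
    return n_pc, n_gc


def count_ligand_contacts(
    cell: Cell, contacts: ContactGraph, pop: CellPopulation
) -> tuple[int, int]:
    """(n_PC, n_GC) for one cell; a cell never counts its own state."""
    idx = int(np.flatnonzero(pop.id == cell.id)[0])
    nbrs = contacts.neighbours(idx)
    pc = pop.state == pops.PC_TERM
    gc = pop.is_gc()
    return int(pc[nbrs].sum()), int(gc[nbrs].sum())


# ---------------------------------------------------------------------------
# the decision table


def _decide(state: int, wnt: int, n_pc: int, n_gc: int,
            c1: int, c2: int, maintain: bool) -> tuple[int, str]:
    """New state and trigger for one non-terminal cell.

    ``wnt`` is the coded class (0 high, 1 low, 2 terminal); cells with
    niche-independent maintenance behave as Wnt-high everywhere and never
    terminally differentiate through position (outside the niche the driver
    additionally freezes their fate entirely).
    """
    if maintain:
        wnt = 0
    if state == pops.SC:
        if wnt == 0:
            return (pops.SC, "") if n_pc >= c1 else (pops.PC_PROG, "notch")
        # lost high Wnt: the cell enters the enterocyte branch
        if wnt == 2:
            return pops.EC_TERM, "terminal"
        return (pops.EC_PROG, "wnt") if n_gc >= c2 else (pops.GC_PROG, "wnt")
    if state == pops.EC_PROG:
        if wnt == 0 and n_pc >= c1:
            return pops.SC, "notch"
        if wnt == 2:
            return pops.EC_TERM, "terminal"
        return (pops.EC_PROG, "") if n_gc >= c2 else (pops.GC_PROG, "notch")
    if state == pops.GC_PROG:
        if wnt == 0:
            # back in the high-Wnt niche: Notch level decides SC vs Paneth
            return (pops.SC, "wnt") if n_pc >= c1 else (pops.PC_PROG, "wnt")
        if wnt == 2:
            return pops.GC_TERM, "terminal"
        if n_gc >= c2:
            return pops.EC_PROG, "notch"
        return pops.GC_PROG, ""
    if state == pops.PC_PROG:
        if wnt == 0:
            return (pops.SC, "notch") if n_pc >= c1 else (pops.PC_PROG, "")
        # a Paneth progenitor that loses high Wnt is a low-Wnt/low-Notch
        # cell, i.e. the goblet branch (reversible until terminal)
        if wnt == 2:
            return pops.GC_TERM, "terminal"
        return (pops.EC_PROG, "wnt") if n_gc >= c2 else (pops.GC_PROG, "wnt")
    raise ValueError("update_fate called on a terminal cell")


def decide_vec(state, wnt, n_pc, n_gc, c1, c2, maintain) -> np.ndarray:
    """Vectorised decision table; must agree with :func:`_decide` elementwise.

    Terminal states pass through unchanged.
    """
    S = np.asarray(state)
    w = np.where(np.asarray(maintain, bool), 0, np.asarray(wnt))
    ok_pc = np.asarray(n_pc) >= np.asarray(c1)
    ok_gc = np.asarray(n_gc) >= np.asarray(c2)
    new = S.copy()
    sc = S == pops.SC
    new[sc & (w == 0) & ~ok_pc] = pops.PC_PROG
    new[sc & (w == 2)] = pops.EC_TERM
    new[sc & (w == 1) & ok_gc] = pops.EC_PROG
    new[sc & (w == 1) & ~ok_gc] = pops.GC_PROG
    ec = S == pops.EC_PROG
    to_sc = ec & (w == 0) & ok_pc
    new[to_sc] = pops.SC
    new[ec & ~to_sc & (w == 2)] = pops.EC_TERM
    new[ec & ~to_sc & (w != 2) & ~ok_gc] = pops.GC_PROG
    gc = S == pops.GC_PROG
    new[gc & (w == 0) & ok_pc] = pops.SC
    new[gc & (w == 0) & ~ok_pc] = pops.PC_PROG
    new[gc & (w == 2)] = pops.GC_TERM
    new[gc & (w == 1) & ok_gc] = pops.EC_PROG
    pc = S == pops.PC_PROG
    new[pc & (w == 0) & ok_pc] = pops.SC
    new[pc & (w == 2)] = pops.GC_TERM
    new[pc & (w == 1) & ok_gc] = pops.EC_PROG
    new[pc & (w == 1) & ~ok_gc] = pops.GC_PROG
    return new


def update_fate(
    cell: Cell, n_PC: int, n_GC: int, wnt, fate: FateParams,
    C1_eff: int | None = None, C2_eff: int | None = None,
    maintain_outside_niche: bool = False,
) -> str:
    """Decision-table lookup for a single non-terminal cell (spec surface)."""
    code = _WNT_NAMES.index(wnt) if isinstance(wnt, str) else int(wnt)
    c1 = fate.C1 if C1_eff is None else C1_eff
    c2 = fate.C2 if C2_eff is None else C2_eff
    new, _ = _decide(
        cell.state_code, code, n_PC, n_GC, c1, c2, maintain_outside_niche
    )
    return pops.STATE_NAMES[new]


def pc_last_cycle_tracker(
    state: str, completed_division: bool, inhibited_wait: float,
    max_wait: float = 48.0,
) -> bool:
    """Whether a Paneth progenitor terminally differentiates now.

    True on the first completed division after specification, or once the
    cell has been contact-inhibited for at least *max_wait* hours without
    managing to divide.  Reverting to SC resets the tracker (the wait clock
    is zeroed on any state change).
    """
    if state != "PC_progenitor":
        return False
    return completed_division or inhibited_wait >= max_wait


# ---------------------------------------------------------------------------
# per-tick driver entry point


@dataclass
class FateChange:
    time: float
    cell_id: int
    founder_id: int
    P: float
    old_state: int
    new_state: int
    trigger: str


def fate_tick(
    pop: CellPopulation,
    contacts: ContactGraph,
    P: np.ndarray,
    table: ProfileTable,
    fate: FateParams,
    rng: np.random.Generator,
    time: float,
    paneth_sampler=None,
) -> list[FateChange]:
    """One fate-update sweep.

    Candidate cells (those whose decision-table outcome differs from their
    current state under the pre-tick neighbourhood) are visited in random
    order; each candidate re-reads its neighbours' *current* states before
    committing, so earlier flips inhibit later ones as in an asynchronous
    update.  Paneth progenitors that exhausted the contact-inhibition wait
    convert terminally without dividing.
    """
    if pop.n == 0:
        return []
    n_pc, n_gc = ligand_contact_counts(pop, contacts)
    wnt = wnt_class(P, fate)
    c1 = table.C1_eff[pop.profile]
    c2 = table.C2_eff[pop.profile]
    maintain = table.maintain_outside[pop.profile]
    changes: list[FateChange] = []

    # Paneth progenitors stuck in contact inhibition: terminal without division
    stuck = np.flatnonzero(
        (pop.state == pops.PC_PROG) & (pop.pc_wait >= fate.max_pc_progenitor_wait)
    )
    for idx in stuck:
        changes.append(
            FateChange(time, int(pop.id[idx]), int(pop.founder[idx]),
                       float(P[idx]), pops.PC_PROG, pops.PC_TERM, "last_cycle")
        )
        pop.state[idx] = pops.PC_TERM
        pop.pc_age[idx] = 0.0
        pop.pc_wait[idx] = 0.0
        if paneth_sampler is not None:
            pop.pc_lifespan[idx] = paneth_sampler(rng)

    if not pop.is_proliferative().any():
        return changes
    # vectorised proposal pass to find candidates cheaply
    proposed = decide_vec(pop.state, wnt, n_pc, n_gc, c1, c2, maintain)
    changed = proposed != pop.state
    # niche-independent maintenance: outside the niche these cells keep
    # their current fate altogether (no specification, no differentiation)
    changed &= ~(maintain & (P >= fate.niche_extent))
    # Notch-state hysteresis: contact-driven transitions (specification into
    # and reversal out of the secretory branches) commit only once their
    # trigger has persisted; position-driven Wnt transitions are immediate
    S, Pr = pop.state, proposed
    notch_driven = changed & (
        ((S == pops.SC) & (Pr == pops.PC_PROG))
        | ((S == pops.PC_PROG) & (Pr == pops.SC))
        | ((S == pops.EC_PROG) & (Pr == pops.GC_PROG))
        | ((S == pops.GC_PROG) & (Pr == pops.EC_PROG))
    )
    pop.deficit_clock = np.where(
        notch_driven, pop.deficit_clock + fate.fate_interval, 0.0
    )
    if fate.specification_delay > 0:
        changed &= ~notch_driven | (
            pop.deficit_clock > fate.specification_delay
        )
    cand = np.flatnonzero(changed)
    if len(cand) == 0:
        return changes
    order = rng.permutation(len(cand))
    pc_mask = pop.state == pops.PC_TERM
    gc_mask = pop.is_gc()
    for k in order:
        idx = cand[k]
        nbrs = contacts.neighbours(idx)
        np_c = int(pc_mask[nbrs].sum())
        ng_c = int(gc_mask[nbrs].sum())
        old = int(pop.state[idx])
        new, trig = _decide(
            old, int(wnt[idx]), np_c, ng_c,
            int(c1[idx]), int(c2[idx]), bool(maintain[idx]),
        )
        if new == old:
            continue
        pop.state[idx] = new
        pop.pc_wait[idx] = 0.0
        pop.deficit_clock[idx] = 0.0
        if new == pops.PC_TERM:
            pop.pc_age[idx] = 0.0
            if paneth_sampler is not None:
                pop.pc_lifespan[idx] = paneth_sampler(rng)
        pc_mask[idx] = new == pops.PC_TERM
        gc_mask[idx] = new in pops.GC_STATES
        changes.append(
            FateChange(time, int(pop.id[idx]), int(pop.founder[idx]),
                       float(P[idx]), old, new, trig)
        )
    return changes
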