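"""Off-lattice overdamped cell mechanics on the crypt surface.

Cells are adhesive elastic spheres constrained to the basal membrane.  Pair
interactions combine a Hertz-like repulsion ``k_rep * delta^{3/2}`` for
overlap depth ``delta`` with a constant short-range adhesion of magnitude
``k_adh`` acting over a gap band of width ``adhesion_range``.  Enterocyte and
goblet lineages experience a constant active migration force up the
crypt-villus axis, Paneth lineages down the axis, stem cells none.  Positions
follow first-order (overdamped) dynamics and are re-projected onto the
surface after every substep; per-substep displacements are clamped to
``max_step``.

Crowding is quantified by an available-volume proxy: the cell volume minus
the summed sphere-sphere overlap (lens) volumes with its contact neighbours,
floored at zero.  Growth pauses (contact inhibition) when the available
volume falls below the threshold ``Vp``; sustained full compression marks a
cell for delamination (anoikis) in the driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import population as pops
from .geometry import CryptSurface
from .mutation import ProfileTable
from .params import GrowthParams, MechanicsParams
from .population import Cell, CellPopulation

__all__ = [
    "ContactGraph",
    "detect_contacts",
    "pairwise_force",
    "migration_bias_force",
    "step_positions",
    "local_compression",
    "available_volumes",
    "grow_cells",
    "divide_cell",
    "perform_divisions",
    "apply_anoikis_and_exit",
    "sphere_overlap_volume",
]


# ---------------------------------------------------------------------------
# contacts


@dataclass
class ContactGraph:
    """Symmetric contact graph over one population snapshot.

    ``pairs`` holds index pairs (i < j) into the population arrays;
    ``ids`` the corresponding cell-id pairs.
    """

    pairs: np.ndarray          # (M, 2) int indices
    ids: np.ndarray            # (M, 2) int cell ids
    n: int                     # number of cells

    def __post_init__(self) -> None:
        self._indptr = None
        self._indices = None

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.ids.tolist()}

    def _build_adj(self):
        if self._indptr is None:
            if len(self.pairs):
                src = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
                dst = np.concatenate([self.pairs[:, 1], self.pairs[:, 0]])
                order = np.argsort(src, kind="stable")
                self._indices = dst[order]
                self._indptr = np.searchsorted(
                    src[order], np.arange(self.n + 1)
                )
            else:
                self._indices = np.zeros(0, dtype=np.int64)
                self._indptr = np.zeros(self.n + 1, dtype=np.int64)
        return self._indptr, self._indices

    def neighbours(self, index: int) -> np.ndarray:
        """Neighbour *indices* of cell at *index*."""
        indptr, indices = self._build_adj()
        return indices[indptr[index]:indptr[index + 1]]

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if len(self.pairs):
            np.add.at(deg, self.pairs[:, 0], 1)
            np.add.at(deg, self.pairs[:, 1], 1)
        return deg


def _candidate_pairs(pop: CellPopulation, cutoff: float) -> np.ndarray:
    if pop.n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    tree = cKDTree(pop.pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.astype(np.int64)


def detect_contacts(
    pop: CellPopulation,
    contact_factor: float = 1.1,
    margin: float = 0.0,
) -> ContactGraph:
    """Contact graph: edge iff centre distance < contact_factor*(r_i+r_j).

    ``margin`` widens the criterion (used to build reusable candidate lists
    for the mechanics substeps); the force laws themselves vanish beyond the
    adhesion band, so stale extra candidates are harmless.
    """
    r = pop.radius
    rmax = r.max() if pop.n else 1.0
    cutoff = contact_factor * 2.0 * rmax + margin
    pairs = _candidate_pairs(pop, cutoff)
    if len(pairs):
        d = np.linalg.norm(pop.pos[pairs[:, 0]] - pop.pos[pairs[:, 1]], axis=1)
        keep = d < contact_factor * (r[pairs[:, 0]] + r[pairs[:, 1]]) + margin
        pairs = pairs[keep]
    ids = pop.id[pairs] if len(pairs) else np.zeros((0, 2), dtype=np.int64)
    return ContactGraph(pairs=pairs, ids=ids, n=pop.n)


# ---------------------------------------------------------------------------
# forces


def _deterministic_directions(id_i: np.ndarray, id_j: np.ndarray) -> np.ndarray:
    """Reproducible separation directions for coincident centres."""
    ang = (17.0 * (id_i + id_j) + 0.5) % (2.0 * np.pi)
    return np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)


def _pair_force_magnitudes(
    d: np.ndarray, s: np.ndarray, params: MechanicsParams
) -> np.ndarray:
    """Signed magnitude along the centre line (positive = repulsive)."""
    delta = s - d
    f = np.zeros_like(d)
    overlap = delta > 0
    f[overlap] = params.k_rep * delta[overlap] ** 1.5
    gap = d - s
    adhere = (gap >= 0) & (gap < params.adhesion_range)
    f[adhere] -= params.k_adh
    return f


def pair_forces(
    pop: CellPopulation, pairs: np.ndarray, params: MechanicsParams
) -> np.ndarray:
    """Net pairwise force on every cell, (N, 3)."""
    F = np.zeros((pop.n, 3))
    if len(pairs) == 0:
        return F
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pop.pos[i] - pop.pos[j]
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    degenerate = d < 1e-9
    u = np.empty_like(dvec)
    ok = ~degenerate
    u[ok] = dvec[ok] / d[ok, None]
    if degenerate.any():
        u[degenerate] = _deterministic_directions(
            pop.id[i[degenerate]], pop.id[j[degenerate]]
        )
    r = pop.radius
    f = _pair_force_magnitudes(d, r[i] + r[j], params)
    fv = f[:, None] * u
    for c in range(3):
        F[:, c] += np.bincount(i, weights=fv[:, c], minlength=pop.n)
        F[:, c] -= np.bincount(j, weights=fv[:, c], minlength=pop.n)
    return F


def pairwise_force(
    cell_i: Cell, cell_j: Cell, params: MechanicsParams | None = None
) -> np.ndarray:
    """Force on *cell_i* exerted by *cell_j* (antisymmetric)."""
    params = params or MechanicsParams()
    dvec = np.asarray(cell_i.position, float) - np.asarray(cell_j.position, float)
    d = float(np.linalg.norm(dvec))
    if d < 1e-9:
        u = _deterministic_directions(
            np.array([cell_i.id]), np.array([cell_j.id])
        )[0]
        d = 0.0
    else:
        u = dvec / d
    f = _pair_force_magnitudes(
        np.array([d]), np.array([cell_i.radius + cell_j.radius]), params
    )[0]
    return f * u


def bias_forces(
    pop: CellPopulation,
    surface: CryptSurface,
    params: MechanicsParams,
    table: ProfileTable | None = None,
) -> np.ndarray:
    """Active migration forces: EC/GC up the axis, PC down, SC none."""
    up = surface.meridian_up(pop.pos)
    coef = np.zeros(pop.n)
    state = pop.state
    ec_gc = np.isin(state, (pops.EC_PROG, pops.EC_TERM, pops.GC_PROG, pops.GC_TERM))
    if params.bias_up_start > 0:
        # active up-migration engages above the niche region only
        ec_gc &= surface.axial_position_on_surface(pop.pos) > params.bias_up_start
    coef[ec_gc] = params.bias_up
    # only terminally differentiated PCs migrate down: progenitors are still
    # SC-like until the last cell cycle completes
    pc = pop.state == pops.PC_TERM
    if table is not None:
        pc &= table.pc_bias_on[pop.profile]
    coef[pc] = -params.bias_down
    return coef[:, None] * up


def migration_bias_force(
    cell: Cell,
    surface: CryptSurface,
    params: MechanicsParams | None = None,
    pc_bias_on: bool = True,
) -> np.ndarray:
    """Single-cell migration bias (tangent to the surface)."""
    params = params or MechanicsParams()
    up = surface.meridian_up(np.asarray(cell.position, float))
    code = cell.state_code
    if code in (pops.EC_PROG, pops.EC_TERM, pops.GC_PROG, pops.GC_TERM):
        return params.bias_up * up
    if code == pops.PC_TERM and pc_bias_on:
        return -params.bias_down * up
    return np.zeros(3)


def step_positions(
    pop: CellPopulation,
    contacts: ContactGraph,
    surface: CryptSurface,
    params: MechanicsParams,
    dt: float | None = None,
    table: ProfileTable | None = None,
    bias: np.ndarray | None = None,
    friction: np.ndarray | None = None,
) -> int:
    """One overdamped substep; returns the number of clamped displacements.

    *bias* lets the caller reuse a precomputed migration-bias field across
    substeps of one tick (the bias changes only with states/positions);
    *friction* an optional per-cell friction (terminal Paneth cells anchored
    in the niche move with increased friction).
    """
    dt = params.dt if dt is None else dt
    if not 0 < dt <= params.dt_max:
        raise ValueError(f"dt={dt} outside stability range (0, {params.dt_max}]")
    F = pair_forces(pop, contacts.pairs, params)
    F += bias_forces(pop, surface, params, table) if bias is None else bias
    if friction is None:
        disp = F * (dt / params.friction)
    else:
        disp = F * (dt / friction[:, None])
    norm = np.sqrt(np.einsum("ij,ij->i", disp, disp))
    clamped = norm > params.max_step
    n_clamped = int(clamped.sum())
    if n_clamped:
        disp[clamped] *= (params.max_step / norm[clamped])[:, None]
    pop.pos = surface.project_to_surface(pop.pos + disp)
    return n_clamped


# ---------------------------------------------------------------------------
# compression / growth


def sphere_overlap_volume(r1, r2, d):
    """Lens (intersection) volume of two spheres, vectorised."""
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    d = np.asarray(d, float)
    out = np.zeros(np.broadcast(r1, r2, d).shape)
    r1, r2, d = np.broadcast_arrays(r1, r2, d)
    inside = d <= np.abs(r1 - r2)
    if inside.any():
        rm = np.minimum(r1, r2)
        out[inside] = 4.0 / 3.0 * np.pi * rm[inside] ** 3
    overlap = (~inside) & (d < r1 + r2)
    if overlap.any():
        R, r, dd = r1[overlap], r2[overlap], np.maximum(d[overlap], 1e-12)
        s = R + r - dd
        out[overlap] = (
            np.pi
            * s**2
            * (dd**2 + 2 * dd * r - 3 * r**2 + 2 * dd * R + 6 * r * R - 3 * R**2)
            / (12.0 * dd)
        )
    return out if out.shape else float(out)


def available_volumes(pop: CellPopulation, contacts: ContactGraph) -> np.ndarray:
    """Volume minus summed pairwise overlap with neighbours, floored at 0 (µm³).

    Geometric radii are in cell-radius units; the overlap fraction of the
    unit-sphere volume is applied to the µm³ cell volumes.
    """
    avail = pop.volume.copy()
    if len(contacts.pairs):
        i, j = contacts.pairs[:, 0], contacts.pairs[:, 1]
        d = np.linalg.norm(pop.pos[i] - pop.pos[j], axis=1)
        r = pop.radius
        lens = sphere_overlap_volume(r[i], r[j], d)
        # convert lens volume from (cell radius)^3 to µm³ (1 c.r. = 5 µm)
        lens_um3 = lens * 125.0
        avail -= np.bincount(i, weights=lens_um3, minlength=pop.n)
        avail -= np.bincount(j, weights=lens_um3, minlength=pop.n)
    return np.maximum(avail, 0.0)


def local_compression(cell: Cell, contacts: ContactGraph,
                      pop: CellPopulation) -> float:
    """Available volume (µm³) of one cell given the current contact graph."""
    idx = int(np.flatnonzero(pop.id == cell.id)[0])
    avail = float(pop.volume[idx])
    r = pop.radius
    for j in contacts.neighbours(idx):
        d = float(np.linalg.norm(pop.pos[idx] - pop.pos[j]))
        avail -= float(sphere_overlap_volume(r[idx], r[j], d)) * 125.0
    return max(avail, 0.0)


def grow_cells(
    pop: CellPopulation,
    contacts: ContactGraph,
    dt: float,
    growth: GrowthParams,
    table: ProfileTable | None = None,
) -> None:
    """Linear volume growth with contact inhibition.

    Proliferative cells whose available volume is at least the (profile-
    scaled) threshold ``Vp`` gain ``v0/growth_time`` per hour, capped at
    ``2 v0``; compressed cells pause and are flagged ``inhibited``.  The
    delamination clock accumulates for cells held at (near) zero available
    volume regardless of lineage.
    """
    avail = available_volumes(pop, contacts)
    vp_eff = growth.vp
    if table is not None:
        vp_eff = growth.vp * table.vp_scale[pop.profile]
    prolif = pop.is_proliferative()
    uncompressed = avail >= vp_eff
    can_grow = prolif & uncompressed
    pop.inhibited = prolif & ~uncompressed
    if can_grow.any():
        dv = growth.v0 / pop.growth_time[can_grow] * dt
        pop.volume[can_grow] = np.minimum(
            pop.volume[can_grow] + dv, 2.0 * growth.v0
        )
    # terminal Paneth cells mature into large secretory cells
    if growth.pc_volume_scale > 1.0:
        target = growth.pc_volume_scale * growth.v0
        pc_grow = (
            (pop.state == pops.PC_TERM) & uncompressed & (pop.volume < target)
        )
        if pc_grow.any():
            dv = growth.v0 / pop.growth_time[pc_grow] * dt
            pop.volume[pc_grow] = np.minimum(pop.volume[pc_grow] + dv, target)
    squeezed = avail <= growth.anoikis_volume_fraction * growth.v0
    pop.squeeze_clock = np.where(squeezed, pop.squeeze_clock + dt, 0.0)
    # Paneth progenitors count time spent contact-inhibited
    pcp = pop.state == pops.PC_PROG
    pop.pc_wait = np.where(
        pcp & pop.inhibited, pop.pc_wait + dt, np.where(pcp, pop.pc_wait, 0.0)
    )


# ---------------------------------------------------------------------------
# division


def _sample_growth_time(
    rng: np.random.Generator, mean: float, cv: float, size: int
) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def divide_cell(cell: Cell, rng: np.random.Generator,
                surface: CryptSurface | None = None,
                v0: float | None = None) -> tuple[Cell, Cell]:
    """Split one cell into two daughters of volume ``v0`` each.

    Daughters sit at ±0.5 r along a random tangential direction (random
    in-plane direction if no surface is given) and inherit lineage state,
    founder and profile.  Terminal cells never divide.
    """
    if cell.state_code in pops.TERMINAL:
        raise ValueError("terminal cells do not divide")
    v0 = cell.volume / 2.0 if v0 is None else v0
    pos = np.asarray(cell.position, float)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    if surface is not None:
        e1, e2 = surface.tangent_basis(pos)
        u = np.cos(phi) * e1 + np.sin(phi) * e2
    else:
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
    off = 0.5 * cell.radius * u
    p1, p2 = pos + off, pos - off
    if surface is not None:
        p1 = surface.project_to_surface(p1)
        p2 = surface.project_to_surface(p2)
    mk = lambda p: Cell(
        id=-1,
        position=p,
        volume=v0,
        lineage_state=cell.lineage_state,
        founder_id=cell.founder_id,
        profile=cell.profile,
    )
    return mk(p1), mk(p2)


@dataclass
class DivisionRecord:
    time: float
    mother_id: int
    daughter1_id: int
    daughter2_id: int
    P: float
    mother_state: int
    founder_id: int
    profile: int


def perform_divisions(
    pop: CellPopulation,
    surface: CryptSurface,
    growth: GrowthParams,
    table: ProfileTable,
    rng: np.random.Generator,
    time: float,
    paneth_sampler=None,
) -> list[DivisionRecord]:
    """Divide every proliferative cell that reached ``2 v0``.

    A Paneth progenitor completes its last cycle here: both daughters emerge
    terminally differentiated (the caller passes *paneth_sampler* to assign
    their intrinsic lifespans).
    """
    ready = np.flatnonzero(
        pop.is_proliferative() & (pop.volume >= 2.0 * growth.v0 - 1e-9)
    )
    if len(ready) == 0:
        return []
    records: list[DivisionRecord] = []
    P_ready = surface.axial_position(pop.pos[ready])
    new_pos, new_state, new_founder, new_profile = [], [], [], []
    new_gt, new_lifespan = [], []
    for k, idx in enumerate(ready):
        pos = pop.pos[idx]
        r = float(pop.radius[idx])
        phi = rng.uniform(0.0, 2.0 * np.pi)
        e1, e2 = surface.tangent_basis(pos)
        u = np.cos(phi) * e1 + np.sin(phi) * e2
        off = 0.5 * r * u
        p1 = surface.project_to_surface(pos + off)
        p2 = surface.project_to_surface(pos - off)
        state = int(pop.state[idx])
        prof = int(pop.profile[idx])
        if state == pops.PC_PROG:
            dstate = pops.PC_TERM  # last cell cycle after specification
        else:
            dstate = state
        mean_gt = max(growth.cycle_growth_time + table.cycle_delta[prof], 1.0)
        gts = _sample_growth_time(rng, mean_gt, growth.cycle_cv, 2)
        if dstate == pops.PC_TERM and paneth_sampler is not None:
            ls = [paneth_sampler(rng), paneth_sampler(rng)]
        else:
            ls = [0.0, 0.0]
        for p, gt, lsp in ((p1, gts[0], ls[0]), (p2, gts[1], ls[1])):
            new_pos.append(p)
            new_state.append(dstate)
            new_founder.append(int(pop.founder[idx]))
            new_profile.append(prof)
            new_gt.append(gt)
            new_lifespan.append(lsp)
        records.append(
            DivisionRecord(
                time=time,
                mother_id=int(pop.id[idx]),
                daughter1_id=-1,  # filled below once ids are assigned
                daughter2_id=-1,
                P=float(P_ready[k]),
                mother_state=state,
                founder_id=int(pop.founder[idx]),
                profile=prof,
            )
        )
    keep = np.ones(pop.n, dtype=bool)
    keep[ready] = False
    pop.keep(keep)
    ids = pop.add(
        positions=np.asarray(new_pos),
        states=new_state,
        volumes=growth.v0,
        founders=new_founder,
        profiles=new_profile,
        growth_times=new_gt,
        v0=growth.v0,
    )
    pop.pc_lifespan[-len(ids):] = new_lifespan
    for k, rec in enumerate(records):
        rec.daughter1_id = int(ids[2 * k])
        rec.daughter2_id = int(ids[2 * k + 1])
    return records


# ---------------------------------------------------------------------------
# removal


@dataclass
class RemovalRecord:
    time: float
    event: str
    cell_id: int
    founder_id: int
    P: float
    state: int


def apply_anoikis_and_exit(
    pop: CellPopulation,
    surface: CryptSurface,
    mech: MechanicsParams,
    growth: GrowthParams,
    time: float,
    P: np.ndarray | None = None,
) -> list[RemovalRecord]:
    """Remove cells that left the crypt (P > exit, strict) or lost substrate
    contact — geometrically, or by sustained delamination-grade compression."""
    if pop.n == 0:
        return []
    if P is None:
        P = surface.axial_position(pop.pos)
    dist = surface.surface_distance(pop.pos)
    detached = dist > pop.radius + mech.substrate_tolerance + 1e-12
    squeezed = pop.squeeze_clock > growth.anoikis_grace
    anoikis = detached | squeezed
    exited = P > surface.exit_position
    removed = anoikis | exited
    records = []
    for idx in np.flatnonzero(removed):
        records.append(
            RemovalRecord(
                time=time,
                event="exit" if exited[idx] else "anoikis",
                cell_id=int(pop.id[idx]),
                founder_id=int(pop.founder[idx]),
                P=float(P[idx]),
                state=int(pop.state[idx]),
            )
        )
    if removed.any():
        pop.keep(~removed)
    return records
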