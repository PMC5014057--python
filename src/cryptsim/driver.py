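"""Scenario orchestration: initialization, main loop, replicates, presets.

The per-hour tick executes, in order: candidate-contact refresh, mechanics
substeps (overdamped forces + surface projection), growth with contact
inhibition, divisions, fate updates, Paneth death checks, anoikis/exit
removal, and bookkeeping (event logs, monoclonal-conversion and fixation
tracking).  A replicate starts from a seeded near-steady layout, burns in
until the population drifts less than a tolerance over a one-week window,
then freezes founder labels ("competition start") and runs until monoclonal
conversion, fixation/loss of a mutant label, or the censoring horizon.

Seeding is counter-based: replicate *k* of master seed *s* uses
``np.random.SeedSequence((s, k))`` spawned into independent streams for
initialization, dynamics and mutation selection, so replicate sets are
extensible and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fate as fate_mod
from . import lineage, mechanics, paneth
from . import population as pops
from .geometry import CryptSurface
from .mutation import (
    MutationProfile,
    MutationSelector,
    ProfileTable,
    make_profile,
)
from .params import HOURS_PER_WEEK, MutationEvent, SimulationParams
from .population import CellPopulation

__all__ = [
    "Simulation",
    "ReplicateResult",
    "ExperimentResult",
    "initialize_crypt",
    "run_scenario",
    "replicate_experiment",
    "scenario",
    "SCENARIOS",
]


# ---------------------------------------------------------------------------
# initial layout


def _initial_layout(params: SimulationParams, rng: np.random.Generator) -> CellPopulation:
    """Seed cells on the surface near steady-state density and composition."""
    geo = params.geometry
    R = geo.cap_radius
    spacing = 1.9  # slightly compressed relative to touching distance
    pts: list[np.ndarray] = []
    pts.append(np.array([0.0, 0.0, -R]))  # bottom pole
    # cap rings
    theta = 0.5 * spacing / R
    while theta <= np.pi / 2:
        m = max(1, int(round(2 * np.pi * R * np.sin(theta) / spacing)))
        off = rng.uniform(0, 2 * np.pi)
        for k in range(m):
            phi = off + 2 * np.pi * k / m
            pts.append(
                R * np.array(
                    [np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     -np.cos(theta)]
                )
            )
        theta += spacing / R
    # cylinder rows up to just below the exit boundary
    row_h = spacing * np.sqrt(3) / 2
    z = (theta - np.pi / 2) * R  # continue the meridian spacing smoothly
    m = max(3, int(round(2 * np.pi * R / spacing)))
    row = 0
    while R * np.pi / 2 + z <= geo.exit_position - 1.0:
        off = rng.uniform(0, 2 * np.pi) + (np.pi / m) * (row % 2)
        for k in range(m):
            phi = off + 2 * np.pi * k / m
            pts.append(np.array([R * np.cos(phi), R * np.sin(phi), z]))
        z += row_h
        row += 1
    positions = np.asarray(pts)

    surface = CryptSurface(geo)
    P = surface.axial_position(positions)
    fate = params.fate
    states = np.empty(len(positions), dtype=np.int64)
    u = rng.random(len(positions))
    # seed the cap region with an SC/PC mix near the self-organised balance
    niche = P < max(fate.P1, R * np.pi / 2)
    transit = ~niche & (P < fate.P2)
    upper = P >= fate.P2
    pc_frac = 0.5 if fate.C1 > 0 else 0.0
    gc_frac = 0.15 if fate.C2 > 0 else 0.0
    states[niche] = np.where(u[niche] < pc_frac, pops.PC_TERM, pops.SC)
    states[transit] = np.where(u[transit] < gc_frac, pops.GC_PROG, pops.EC_PROG)
    states[upper] = np.where(u[upper] < gc_frac, pops.GC_TERM, pops.EC_TERM)

    pop = CellPopulation()
    growth = params.growth
    vols = growth.v0 * rng.uniform(1.0, 1.8, len(positions))
    vols[states == pops.PC_TERM] = growth.v0 * rng.uniform(
        1.0, 1.3, int((states == pops.PC_TERM).sum())
    )
    gts = mechanics._sample_growth_time(
        rng, growth.cycle_growth_time, growth.cycle_cv, len(positions)
    )
    pop.add(positions, states, volumes=vols, growth_times=gts, v0=growth.v0)
    pcs = np.flatnonzero(states == pops.PC_TERM)
    if len(pcs):
        ls = paneth.sample_intrinsic_lifespan(params.paneth, rng, size=len(pcs))
        pop.pc_lifespan[pcs] = ls
        pop.pc_age[pcs] = rng.uniform(0.0, 0.8, len(pcs)) * ls
    return pop


# ---------------------------------------------------------------------------
# results


@dataclass
class ReplicateResult:
    label: str
    seed: int
    n_start: int
    sc_start: pd.DataFrame            # id, P, founder at competition start
    start_snapshot: pd.DataFrame
    final_snapshot: pd.DataFrame
    events: pd.DataFrame
    divisions: pd.DataFrame
    summary_series: pd.DataFrame      # sparse time series of composition
    conversion_time: Optional[float]
    winner_founder: Optional[int]
    winner_start_P: Optional[float]
    winner_profile: Optional[int]
    fixation_outcome: Optional[str]   # fixed | lost | censored | None
    fixation_time: Optional[float]
    mutated_ids: list
    profile_names: list
    end_time: float
    pc_death_causes: dict

    # -- lineage-analysis accessors ------------------------------------
    def sc_division_positions(self) -> np.ndarray:
        d = self.divisions
        if len(d) == 0:
            return np.zeros(0)
        return d.loc[d["mother_state"] == "SC", "P"].to_numpy(float)

    def sc_start_positions(self) -> np.ndarray:
        return self.sc_start["P"].to_numpy(float)

    def build_tree(self) -> lineage.PhylogenyTree:
        roots = self.sc_start["id"].tolist()
        d = self.divisions
        sc_divs = d[d["mother_state"] == "SC"]
        recs = list(
            zip(
                sc_divs["mother_id"], sc_divs["daughter1_id"],
                sc_divs["daughter2_id"], sc_divs["time"], sc_divs["P"],
            )
        )
        outcomes = {}
        ev = self.events
        for _, r in ev[ev["event"].isin(["anoikis", "exit"])].iterrows():
            outcomes[int(r["cell_id"])] = (float(r["time"]), r["event"])
        for _, r in ev[ev["event"] == "fate_change"].iterrows():
            if r["lineage_state"] == "SC":  # old state was SC: specified away
                outcomes.setdefault(
                    int(r["cell_id"]), (float(r["time"]), "specified")
                )
        tree = lineage.build_tree(
            roots, recs, start_time=0.0, end_time=self.end_time,
            leaf_outcomes=outcomes,
        )
        return tree


class ExperimentResult:
    """Replicate collection with aggregated competition statistics."""

    def __init__(self, params: SimulationParams, results: list[ReplicateResult]):
        self.params = params
        self.results = results

    def __len__(self) -> int:
        return len(self.results)

    def conversion_times(self) -> np.ndarray:
        return np.array(
            [r.conversion_time for r in self.results if r.conversion_time is not None],
            dtype=float,
        )

    def n_censored(self) -> int:
        return sum(1 for r in self.results if r.conversion_time is None)

    def positional_distributions(self) -> lineage.PositionalDistribution:
        return lineage.positional_distributions(
            [r.sc_start_positions() for r in self.results],
            [r.sc_division_positions() for r in self.results],
            [r.winner_start_P for r in self.results],
        )

    def advantaged_sc_count(self) -> tuple[float, float]:
        dist = self.positional_distributions()
        return lineage.count_advantaged_scs(
            [r.sc_start_positions() for r in self.results], dist
        )

    def fixation_outcomes(self) -> list[str]:
        return [
            r.fixation_outcome for r in self.results if r.fixation_outcome is not None
        ]

    def fixation_statistics(self) -> lineage.FixationStats:
        return lineage.fixation_statistics(self.fixation_outcomes())

    def mean_sc_count(self) -> float:
        return float(np.mean([len(r.sc_start) for r in self.results]))

    # -- persistence ----------------------------------------------------
    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(self.params.to_yaml())
        rows = []
        for r in self.results:
            rows.append(
                {
                    "label": r.label,
                    "seed": r.seed,
                    "n_sc_start": len(r.sc_start),
                    "conversion_time_h": r.conversion_time,
                    "winner_start_P": r.winner_start_P,
                    "fixation_outcome": r.fixation_outcome,
                    "fixation_time_h": r.fixation_time,
                }
            )
        pd.DataFrame(rows).to_csv(out / "replicates.csv", index=False)
        try:
            self.positional_distributions().to_frame().to_csv(
                out / "positional_distributions.csv", index=False
            )
        except ValueError:
            pass
        for i, r in enumerate(self.results):
            r.events.to_csv(out / f"events_rep{i:03d}.csv", index=False)


# ---------------------------------------------------------------------------
# the simulation engine


class Simulation:
    """One crypt, one replicate."""

    def __init__(self, params: SimulationParams, seed: int, replicate: int = 0):
        self.params = params
        self.seed = int(seed)
        ss = np.random.SeedSequence((int(seed), int(replicate)))
        init_ss, dyn_ss, mut_ss = ss.spawn(3)
        self.init_rng = np.random.default_rng(init_ss)
        self.rng = np.random.default_rng(dyn_ss)
        self.mut_rng = np.random.default_rng(mut_ss)
        self.surface = CryptSurface(params.geometry)
        self.table = ProfileTable(params.fate)
        self.pop = _initial_layout(params, self.init_rng)
        self.time = 0.0
        self.analysis_started = False
        self._pending_events: list[MutationEvent] = []
        self._division_assoc_pending: list[MutationEvent] = []
        self.mutated_ids: list[int] = []
        self._reset_logs()
        self._n_substeps = 0
        self._n_clamped = 0
        self._sampler = lambda rng: paneth.sample_intrinsic_lifespan(
            params.paneth, rng
        )
        # competition bookkeeping
        self.conversion_time: Optional[float] = None
        self.winner_founder: Optional[int] = None
        self.fixation_outcome: Optional[str] = None
        self.fixation_time: Optional[float] = None

    # ------------------------------------------------------------------
    def _reset_logs(self) -> None:
        self.division_records: list[mechanics.DivisionRecord] = []
        self.event_rows: list[tuple] = []
        self.summary_rows: list[tuple] = []
        self.pc_death_causes = {"contact": 0, "intrinsic": 0}

    # ------------------------------------------------------------------
    def tick(self, log: bool = True) -> None:
        """Advance one fate interval (default 1 h)."""
        p = self.params
        dt_f = p.fate.fate_interval
        mech = p.mechanics
        n_sub = max(1, int(round(dt_f / mech.dt)))
        # mechanics: candidate pairs refreshed once per tick, reused across
        # substeps (force laws vanish beyond the adhesion band, so the margin
        # makes the stale list safe)
        cand = mechanics.detect_contacts(self.pop, mech.contact_factor, margin=0.5)
        bias = mechanics.bias_forces(self.pop, self.surface, mech, self.table)
        friction = None
        if mech.pc_anchor_friction != 1.0:
            # terminal PCs that reached the niche hold their final position
            anchored = (self.pop.state == pops.PC_TERM) & (
                self.surface.axial_position_on_surface(self.pop.pos)
                < mech.pc_anchor_extent
            )
            friction = np.full(self.pop.n, mech.friction)
            friction[anchored] *= mech.pc_anchor_friction
        for _ in range(n_sub):
            self._n_clamped += mechanics.step_positions(
                self.pop, cand, self.surface, mech, mech.dt, self.table,
                bias=bias, friction=friction,
            )
            self._n_substeps += self.pop.n
        self.time += dt_f
        self.pop.age += dt_f
        t = self.time
        # growth and division
        graph = mechanics.detect_contacts(self.pop, mech.contact_factor)
        mechanics.grow_cells(self.pop, graph, dt_f, p.growth, self.table)
        divs = mechanics.perform_divisions(
            self.pop, self.surface, p.growth, self.table, self.rng, t,
            paneth_sampler=self._sampler,
        )
        if divs:
            if self._division_assoc_pending and self.analysis_started:
                self._apply_division_associated(divs)
            if log:
                self.division_records.extend(divs)
            graph = mechanics.detect_contacts(self.pop, mech.contact_factor)
        P = self.surface.axial_position_on_surface(self.pop.pos)
        # fate updates
        changes = fate_mod.fate_tick(
            self.pop, graph, P, self.table, p.fate, self.rng, t,
            paneth_sampler=self._sampler,
        )
        if log:
            for ch in changes:
                self.event_rows.append(
                    (ch.time, "fate_change", ch.cell_id, ch.founder_id, ch.P,
                     pops.STATE_NAMES[ch.old_state], ch.trigger,
                     pops.STATE_NAMES[ch.new_state])
                )
        # Paneth death checks
        deaths = paneth.paneth_tick(self.pop, graph, P, p.paneth, dt_f, t)
        for d in deaths:
            self.pc_death_causes[d.cause] += 1
            if log:
                self.event_rows.append(
                    (d.time, f"death_{d.cause}", d.cell_id, d.founder_id,
                     d.P, "PC_terminal", d.cause, "")
                )
        # anoikis and crypt exit (P is stale if Paneth deaths removed cells)
        removals = mechanics.apply_anoikis_and_exit(
            self.pop, self.surface, mech, p.growth, t,
            P=None if deaths else P,
        )
        if log:
            for r in removals:
                self.event_rows.append(
                    (r.time, r.event, r.cell_id, r.founder_id, r.P,
                     pops.STATE_NAMES[r.state], "", "")
                )

    # ------------------------------------------------------------------
    def burn_in(self) -> None:
        """Run to steady-state cell turnover (population-size drift below
        tolerance over a one-week window)."""
        b = self.params.burn_in
        sizes: list[tuple[float, int]] = []
        check_every = 12.0
        next_check = 0.0
        window_pts = max(2, int(b.window / check_every))
        while True:
            self.tick(log=False)
            if self.time >= next_check:
                sizes.append((self.time, self.pop.n))
                next_check += check_every
            if self.time >= b.min_hours and len(sizes) >= 2 * window_pts:
                recent = np.mean([s for _, s in sizes[-window_pts:]])
                prev = np.mean(
                    [s for _, s in sizes[-2 * window_pts:-window_pts]]
                )
                if abs(recent - prev) / max(prev, 1.0) < b.drift_tolerance:
                    return
            if self.time > b.max_hours:
                raise RuntimeError(
                    f"no steady state within {b.max_hours} h burn-in: "
                    f"population {self.pop.n}, trace tail {sizes[-5:]}"
                )

    # ------------------------------------------------------------------
    def start_analysis(self) -> None:
        """Freeze founder labels and restart clocks at the competition start."""
        self.time = 0.0
        self.pop.founder = self.pop.id.copy()
        self._reset_logs()
        self._n_substeps = 0
        self._n_clamped = 0
        self.analysis_started = True
        P = self.surface.axial_position(self.pop.pos)
        sc = self.pop.is_sc()
        self.sc_start = pd.DataFrame(
            {
                "id": self.pop.id[sc],
                "P": P[sc],
                "founder": self.pop.founder[sc],
            }
        )
        self.start_snapshot = self.pop.snapshot(
            self.surface, 0.0, self.table.names
        )
        # start positions for every cell: a winning founder may have been a
        # progenitor at competition start (reserve cells that revert to SC)
        self._start_positions = {
            int(i): float(p) for i, p in zip(self.pop.id, P)
        }
        self._pending_events = list(self.params.mutation_events)

    # ------------------------------------------------------------------
    def _apply_mutations_due(self) -> None:
        still = []
        for ev in self._pending_events:
            if self.time >= ev.time:
                profile = make_profile(ev.profile, ev.profile_overrides or None)
                if ev.selector == "division_associated":
                    self._division_assoc_pending.append(ev)
                    continue
                sel = MutationSelector(
                    mode=ev.selector, count=ev.count, fraction=ev.fraction
                )
                P = self.surface.axial_position(self.pop.pos)
                from .mutation import apply_mutation

                ids = apply_mutation(
                    self.pop, self.table, sel, profile, P, self.mut_rng
                )
                self.mutated_ids.extend(int(i) for i in ids)
            else:
                still.append(ev)
        self._pending_events = still

    def _apply_division_associated(self, divs) -> None:
        """Attach pending division-coupled mutations to the next SC division."""
        sc_divs = [d for d in divs if d.mother_state == pops.SC]
        if not sc_divs:
            return
        for ev in list(self._division_assoc_pending):
            d = sc_divs[0]
            child = (
                d.daughter1_id if self.mut_rng.random() < 0.5 else d.daughter2_id
            )
            idx = int(np.flatnonzero(self.pop.id == child)[0])
            profile = make_profile(ev.profile, ev.profile_overrides or None)
            pidx = self.table.add(profile)
            self.pop.profile[idx] = pidx
            self.mutated_ids.append(child)
            # the mutation "originates" at the mother's division position
            self._start_positions[child] = d.P
            self._division_assoc_pending.remove(ev)

    # ------------------------------------------------------------------
    def _check_conversion(self) -> None:
        if self.conversion_time is not None:
            return
        if self.params.analysis.conversion_population == "all":
            founders = self.pop.founder
        else:
            founders = self.pop.founder[self.pop.is_sc()]
        if len(founders) > 0 and (founders == founders[0]).all():
            self.conversion_time = self.time
            self.winner_founder = int(founders[0])

    def _check_fixation(self) -> None:
        if self.fixation_outcome is not None or not self.mutated_ids:
            return
        mut = self.pop.profile != 0
        if not mut.any():
            self.fixation_outcome = "lost"
            self.fixation_time = self.time
            return
        sc = self.pop.is_sc()
        if sc.any() and mut[sc].all():
            self.fixation_outcome = "fixed"
            self.fixation_time = self.time

    # ------------------------------------------------------------------
    def run(self, horizon: Optional[float] = None) -> ReplicateResult:
        """Advance from the competition start until resolution or censoring."""
        p = self.params
        horizon = p.analysis.censor_horizon if horizon is None else horizon
        # clone-fixation tracking applies to single-clone mutation events;
        # population-wide reprogramming (all/half of SCs) is followed through
        # monoclonal conversion instead
        has_mutation = any(
            ev.selector in ("random_SC", "deepest_SC", "division_associated")
            for ev in p.mutation_events
        )
        snap_every = p.analysis.snapshot_interval
        next_snap = 0.0
        if not self.analysis_started:
            self.start_analysis()
        self._apply_mutations_due()
        self._summarize()
        next_snap = snap_every
        while self.time < horizon - 1e-9:
            self.tick(log=True)
            self._apply_mutations_due()
            self._check_conversion()
            if has_mutation:
                self._check_fixation()
            if self.time >= next_snap:
                self._summarize()
                next_snap += snap_every
            if self.pop.n == 0:
                break
            if p.analysis.stop_at_conversion:
                done_conv = self.conversion_time is not None
                done_fix = (not has_mutation) or self.fixation_outcome is not None
                if has_mutation:
                    if self.fixation_outcome is not None:
                        break
                elif done_conv:
                    break
        if self._n_substeps and self._n_clamped / self._n_substeps > 0.01:
            raise RuntimeError(
                "numerical instability: displacement clamp triggered on "
                f"{100 * self._n_clamped / self._n_substeps:.1f}% of substeps"
            )
        if has_mutation and self.fixation_outcome is None:
            self.fixation_outcome = "censored"
        return self._result()

    def _summarize(self) -> None:
        P = self.surface.axial_position(self.pop.pos)
        sc = self.pop.is_sc()
        pc = self.pop.state == pops.PC_TERM
        bottom = P < 2.0
        n_bottom = int(bottom.sum())
        self.summary_rows.append(
            (
                self.time,
                self.pop.n,
                int(sc.sum()),
                int(pc.sum()),
                (pc & bottom).sum() / n_bottom if n_bottom else np.nan,
                len(np.unique(self.pop.founder[sc])) if sc.any() else 0,
            )
        )

    # ------------------------------------------------------------------
    def _result(self) -> ReplicateResult:
        events = pd.DataFrame(
            self.event_rows,
            columns=[
                "time", "event", "cell_id", "founder_id", "P",
                "lineage_state", "trigger", "new_state",
            ],
        )
        divisions = pd.DataFrame(
            [
                (
                    d.time, d.mother_id, d.daughter1_id, d.daughter2_id, d.P,
                    pops.STATE_NAMES[d.mother_state], d.founder_id, d.profile,
                )
                for d in self.division_records
            ],
            columns=[
                "time", "mother_id", "daughter1_id", "daughter2_id", "P",
                "mother_state", "founder_id", "profile",
            ],
        )
        summary = pd.DataFrame(
            self.summary_rows,
            columns=[
                "time", "n_cells", "n_SC", "n_PC",
                "pc_fraction_bottom", "n_founders_SC",
            ],
        )
        winner_P = None
        winner_profile = None
        if self.winner_founder is not None:
            winner_P = self._start_positions.get(self.winner_founder)
            sc = self.pop.is_sc()
            if sc.any():
                winner_profile = int(self.pop.profile[sc][0])
        return ReplicateResult(
            label=self.params.label,
            seed=self.seed,
            n_start=len(self.start_snapshot),
            sc_start=self.sc_start,
            start_snapshot=self.start_snapshot,
            final_snapshot=self.pop.snapshot(
                self.surface, self.time, self.table.names
            ),
            events=events,
            divisions=divisions,
            summary_series=summary,
            conversion_time=self.conversion_time,
            winner_founder=self.winner_founder,
            winner_start_P=winner_P,
            winner_profile=winner_profile,
            fixation_outcome=self.fixation_outcome,
            fixation_time=self.fixation_time,
            mutated_ids=list(self.mutated_ids),
            profile_names=list(self.table.names),
            end_time=self.time,
            pc_death_causes=dict(self.pc_death_causes),
        )


# ---------------------------------------------------------------------------
# public entry points


def initialize_crypt(
    params: SimulationParams, seed: int = 0, replicate: int = 0
) -> Simulation:
    """Burn a crypt in to steady state and freeze founder labels."""
    sim = Simulation(params, seed, replicate)
    sim.burn_in()
    sim.start_analysis()
    return sim


def run_scenario(
    params: SimulationParams, seed: int, replicate: int = 0,
    horizon: Optional[float] = None,
) -> ReplicateResult:
    """One replicate: burn-in, competition run, full logs."""
    sim = initialize_crypt(params, seed, replicate)
    return sim.run(horizon)


def replicate_experiment(
    params: SimulationParams,
    n_reps: Optional[int] = None,
    seed: Optional[int] = None,
    horizon: Optional[float] = None,
) -> ExperimentResult:
    """Run replicates with counter-derived seeds and aggregate them."""
    n_reps = params.replicates if n_reps is None else n_reps
    seed = params.master_seed if seed is None else seed
    results, errors = [], []
    for k in range(n_reps):
        try:
            results.append(run_scenario(params, seed, replicate=k, horizon=horizon))
        except RuntimeError as exc:  # collected, not fatal unless all fail
            errors.append((k, str(exc)))
    if not results:
        raise RuntimeError(f"all {n_reps} replicates failed: {errors}")
    exp = ExperimentResult(params, results)
    exp.errors = errors
    return exp


# ---------------------------------------------------------------------------
# scenario presets


def _base() -> SimulationParams:
    return SimulationParams()


def scenario(name: str, **overrides) -> SimulationParams:
    """Named scenario presets for the experiments this model targets."""
    p = _base()
    if name == "wild_type":
        p.label = "wild_type"
        p.paneth.mean_intrinsic_lifespan = 4.0
        p.paneth.contact_death_enabled = False
    elif name == "pc_lifespan_4wk":
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 4.0
        p.paneth.contact_death_enabled = False
    elif name == "pc_lifespan_8wk":
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = False
    elif name == "pc_contact_control":
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
    elif name == "autonomous_notch":
        p.label = name
        p.fate.C1 = 0
        p.fate.C2 = 0
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
    elif name == "c1_split":
        # steady state at reference C1 = 3, then at competition start half of
        # the SCs require C1 = 4 Paneth contacts and the other half C1 = 2
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
        p.mutation_events = [
            MutationEvent(
                selector="all_SCs", profile="high_C1",
                profile_overrides={"C1_eff": 4}, time=0.0,
            ),
            MutationEvent(
                selector="half_of_SCs", profile="low_C1",
                profile_overrides={"C1_eff": 2}, time=0.0,
            ),
        ]
    elif name == "neutral_label":
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
        p.mutation_events = [
            MutationEvent(selector="random_SC", profile="neutral", time=0.0)
        ]
    elif name in ("mutant1_wild_type", "mutant1_autonomous"):
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
        if name.endswith("autonomous"):
            p.fate.C1 = 0
            p.fate.C2 = 0
            ov = {"C1_eff": 0}
        else:
            ov = {"C1_eff": overrides.pop("C1_value", 4)}
        p.mutation_events = [
            MutationEvent(
                selector="random_SC", profile="mutant1",
                profile_overrides=ov, time=0.0,
            )
        ]
    elif name in ("mutant2_wild_type", "mutant2_autonomous"):
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
        ov = {
            "Vp_scale": 0.76,
            "pc_migration_bias": False,
            "maintain_outside_niche": True,
        }
        if name.endswith("autonomous"):
            p.fate.C1 = 0
            p.fate.C2 = 0
            ov["C1_eff"] = 0
        else:
            ov["C1_eff"] = overrides.pop("C1_value", 4)
        p.mutation_events = [
            MutationEvent(
                selector="random_SC", profile="mutant2",
                profile_overrides=ov, time=0.0,
            )
        ]
    elif name == "division_associated":
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
        p.mutation_events = [
            MutationEvent(
                selector="division_associated", profile="neutral", time=0.0
            )
        ]
    elif name == "cycle_time_delta":
        # positional advantage vs a slower-cycling deepest SC
        p.label = name
        p.paneth.mean_intrinsic_lifespan = 8.0
        p.paneth.contact_death_enabled = True
        p.mutation_events = [
            MutationEvent(
                selector="deepest_SC", profile="slow_cycle",
                profile_overrides={
                    "cycle_time_delta": overrides.pop("delta_h", 3.5)
                },
                time=0.0,
            )
        ]
    elif name == "broad_crypt":
        p.label = name
        p.geometry.cap_radius = overrides.pop("cap_radius", 6.0)
        p.paneth.mean_intrinsic_lifespan = 4.0
    else:
        raise KeyError(f"unknown scenario {name!r}")
    for key, val in overrides.items():
        setattr(p, key, val)
    return p


SCENARIOS = (
    "wild_type",
    "pc_lifespan_4wk",
    "pc_lifespan_8wk",
    "pc_contact_control",
    "autonomous_notch",
    "c1_split",
    "neutral_label",
    "mutant1_wild_type",
    "mutant1_autonomous",
    "mutant2_wild_type",
    "mutant2_autonomous",
    "division_associated",
    "cycle_time_delta",
    "broad_crypt",
)
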