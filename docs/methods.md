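# Model and methods

`cryptsim` is an individual cell-based (off-lattice, cell-centre) model of
the mouse small intestinal crypt, built to study clonal competition among
intestinal stem cells (SCs) and the fixation of mutations under Wnt/Notch
deregulation.  This note documents the model, its assumptions, the default
parameters, and the places where design was genuinely open.

## Geometry

The basal membrane is a fixed surface of revolution: a hemispherical cap of
radius `R = 4` cell radii (1 cell radius = 5 µm) joined smoothly to a
cylinder of the same radius.  Cells are spheres whose centres are
constrained to this surface (projected back after every step) — a
monolayer idealisation.  The axial position `P` of a cell is the geodesic
(meridian-arc) distance from the bottom pole in cell-radius units, so
`P = 1, 2, 3, …` label successive cell rows at the crypt bottom; the cap
equator sits at `P = 2π ≈ 6.3`.  Cells with `P > 30` (strict) leave the
crypt and are removed.  The cap radius is a configuration parameter: with
the default, a crypt carries ≈ 200–230 cells and ≈ 13–18 SCs at steady
state, consistent with mouse small intestinal crypts.

## Cell mechanics

Motion is overdamped: velocity = (sum of forces)/friction, friction
normalising the time unit.  Pair forces combine

* Hertz-like repulsion `k_rep · δ^{3/2}` for overlap depth `δ` (`k_rep = 2`),
* constant adhesion `k_adh = 0.4` over a gap band of 0.2 cell radii
  (full adhesion applies at exact touching; repulsion is zero there).

Active migration: enterocyte (EC) and goblet (GC) lineages experience a
constant up-axis force (0.3) that engages above `P = 8` — below that the
crypt bottom is treated as passively rearranging; Paneth cells (PCs)
experience a constant down-axis force (0.3) toward the crypt bottom; SCs
none.  The integration substep is `dt = 0.1 h` with a hard displacement
clamp of 0.2 cell radii per substep; a run aborts if the clamp triggers on
more than 1% of cell-substeps.  The candidate contact list is refreshed
once per 1 h tick with a 0.5 cell-radius margin; force laws vanish beyond
the adhesion band, so the margin makes the stale list exact in practice.

Two cells are *in contact* when their centre distance is below
`1.4 · (r_i + r_j)`.  The factor is deliberately generous: it counts the
full first coordination shell even in relaxed packing, so a stem cell in a
mixed niche typically holds 4–5 Paneth contacts and the Notch threshold
`C1 = 3` is violated only by genuine neighbourhood changes, not by
sub-cell-radius jitter.

Crowding is measured by an available-volume proxy: a cell's volume minus
the summed sphere–sphere lens volumes with its contact neighbours, floored
at zero.  Growth pauses (contact inhibition) when available volume falls
below `Vp = 0.8 · V0`; the threshold scales with a mutant's `Vp_scale`.
A cell held below `0.35 · V0` of available volume for more than 12 h
delaminates and is removed as anoikis — this is how loss of substrate
contact manifests in a surface-constrained monolayer, and it is the
mechanism that penalises the heavily compressed bottom pole (`P ≈ 0–1`).

Cells grow linearly, doubling their volume in a per-cell growth time drawn
lognormally (mean 16 h, CV 0.1), then split into two daughters of volume
`V0` placed ±0.5 r along a uniformly random tangential direction.
Daughters inherit lineage state, clone (founder) label and mutation
profile.  Terminal Paneth cells do not divide but mature into large
secretory cells: they grow (under the same contact-inhibition rule) to
`1.5 V0`.  Their size matters: bulky Paneth cells crowd stem cells out of
the deepest rows, which shapes f(P), makes specification into the Paneth
lineage costly in the clonal competition, and is what gives a raised
Paneth-contact requirement (C1 = 4) its competitive penalty.

## Fate regulation

Wnt activity is a function of position only: high below `P1 = 5`, low
between `P1` and `P2 = 12`, terminal beyond `P2` (each threshold position
belongs to the lower class).  Notch activity is contact-borne: terminal
Paneth cells present Notch ligand (a cell hours into Paneth specification
does not yet — ligand presentation follows differentiation, and specifying
clusters must not stabilise each other); goblet counting includes
progenitors.  A cell needs `C1 = 3` Paneth contacts to keep the SC fate
and `C2 = 1` goblet contacts to keep the EC fate.

Non-terminal fates are the quadrants of the (Wnt, Notch) plane, and every
pre-terminal decision is reversible:

|            | Notch high            | Notch low            |
|------------|-----------------------|----------------------|
| Wnt high   | SC (`n_PC ≥ C1`)      | PC progenitor        |
| Wnt low    | EC prog. (`n_GC ≥ C2`)| GC progenitor        |

so an SC that loses Paneth contacts specifies into the Paneth lineage, an
EC that loses goblet contacts into the goblet lineage, a Paneth progenitor
that drifts above `P1` joins the goblet branch, and a goblet progenitor
pushed back into the niche rejoins the SC/Paneth branch.  Terminal
differentiation at `P ≥ P2` freezes the current branch (EC or GC).  PC
progenitors terminally differentiate after completing one last cell cycle
(both daughters emerge terminal); one that stays contact-inhibited for
48 h converts without dividing.  Fate updates run every 1 h; candidate
cells are visited in random order and re-read their neighbours' current
states before committing.

**Notch hysteresis (specification delay).**  Contact-driven transitions —
specification into and reversal out of the secretory branches — commit
only once their trigger condition has persisted for more than
`specification_delay = 8 h`; position-driven Wnt transitions are
immediate.  The intracellular Notch state integrates ligand exposure over
hours, while the positional Wnt readout is a modelling idealisation with
no intrinsic timescale.  Without the delay, sub-day contact fluctuations
convert SCs into PCs roughly an order of magnitude faster than Paneth
cells die, driving the niche to either Paneth washout or a Paneth plug
with SC extinction; without the *reversal* side of the hysteresis,
specification costs nothing (a freshly specified progenitor reverts as
soon as the neighbourhood fluctuates back), which erases the competitive
penalty of a raised Paneth-contact requirement.  Eight hours is short
against the cell cycle (16 h) and long against mechanical relaxation
(~1 h).

## Paneth lifespan control

Terminal PCs draw an intrinsic lifespan once, from a truncated normal with
mean `τ^P` (weeks; default 4) and CV 0.25.  With contact control enabled, a
terminal PC that spends more than 12 h (strict) without touching any SC
dies by programmed death, with the cause recorded (`contact` vs
`intrinsic`).  Scenario presets: intrinsic-only 4 wk and 8 wk, and the
contact-controlled setting (8 wk intrinsic + 12 h starvation rule).

*Limitation.*  In this monolayer model the Paneth standing population is
balanced substantially by advection out of the niche (cells swept toward
the villus by the proliferative flux) rather than by the death clock alone,
so measured PC turnover is faster than lifespan-based expectations and the
accumulation of PCs at the bottom under `τ^P = 8 wk` is weaker than a model
with firmly anchored Paneth cells would show.  Parameter regimes that
anchored PCs strongly enough for death-dominated turnover were bistable
(Paneth famine or plug, each ending in SC extinction); we chose the robust
intermingled regime, whose competition statistics are the quantities this
package exists to compute.

## Mutations

A mutation event attaches a named profile of parameter overrides to
selected SCs at a defined time (profiles: `C1_eff`, `C2_eff`, `Vp_scale`,
`cycle_time_delta`, `pc_migration_bias`, `maintain_outside_niche`);
daughters inherit the profile.  Selectors: deepest SC (ties broken by
lowest id), random SC(s), all, half, or division-associated (the next SC
division after the event carries the mutation in one daughter chosen by
fair coin, which by construction places mutations with the division-event
distribution p(P)).  `mutant1` raises the Paneth-contact requirement
(`C1 > 3`); `mutant2` additionally sets `Vp* = 0.76 Vp`, removes the PC
migration bias of its progeny, and is maintained outside the niche (treated
as Wnt-high everywhere, no positional terminal differentiation).

## Competition analysis

At the competition start (after burn-in, or at the mutation time) every
cell's founder label is frozen to its own id.  Monoclonal conversion is the
first instant all *stem cells* share one founder (evaluating over the whole
crypt would be bounded below by the Paneth lifespan; the whole-crypt option
exists as configuration).  From replicate runs we tabulate, in unit
`floor(P)` bins:

* `f(P)` — SC positions at competition start,
* `w(P)` — start positions of winning-clone founders (absent, not zero, if
  no replicate resolves),
* `p(P)` — positions of SC division events,

each normalised to 1, with across-replicate standard deviations.  The
positional advantage is `w(P)/f(P)` (bins with `f = 0` excluded); the
*advantaged SC count* is the mean over replicates of the number of SCs
starting in bins with `w(P) > 0`.  A winning founder may have been a
progenitor at the competition start (reserve cells that revert to SC);
its start position still counts.  Fixation of a labelled/mutant clone
means the mutant profile is carried by every SC; loss means no live cell
carries it; the fixation statistics report fixed/lost/censored counts and
`n · p̂` ("fixations out of n mutations").  For division-associated versus
random mutation placement, the expected fixations out of n placed with
distribution q is `Σ_P q(P) · w(P)/f(P)`, which is identically 1 for
random placement (q = f).

Position bins are unit-wide with assignment by `floor(P)`.  Note that the
discrete cell rows of the packed crypt bottom sit near half-integer
geodesic positions (the pole row spans P ≈ 0–1), so "row k" statements
about the bottom rows correspond to floor bins k−1 and k; the sub-pole
bin 0 holds well under one stem cell per crypt and is resolvable only
with very large replicate counts.

Stem-cell phylogenies are binary forests (edges = SC lifetimes, vertices =
SC mitoses annotated with P and time) built by replaying the division log;
they export as Newick with an annotation table and round-trip through
standard parsers.

## Initialization, burn-in, seeding

A replicate seeds cells on the surface at near-steady density (rings at
1.9 cell-radius spacing), with an SC/PC mix in the cap, EC/GC progenitors
in the transit region and terminal cells above, randomised volumes and
growth phases, then burns in until the week-window mean population size
drifts less than 2% (at least 336 h; error beyond 1500 h).  Each replicate
`k` of master seed `s` uses `SeedSequence((s, k))` spawned into disjoint
streams for initialization, dynamics, and mutation selection, which makes
runs bit-reproducible and replicate sets extensible; a pure-label mutation
leaves the trajectory bitwise unchanged.

## Problem sizes

The statistics in the test-suite and in `scripts/acceptance.py` use
10–60 replicates per scenario with censoring horizons of 10–20 simulated
weeks (a full year for the intermingling-stability check), chosen so the
replicate standard errors are small against the quantities compared while
a complete run stays in the minutes range on one core.

## What the synthetic scenarios do and do not show

All experiments are self-contained simulations; no external data enter.
Passing tests demonstrate the internal consistency of the model and its
agreement with the published summary statistics of the same model class —
not agreement with new biological measurements.  Known deviations: Paneth
turnover is advection-dominated (above); the absolute conversion-time
scale depends on the ledgered mechanics constants and is meaningful mainly
through scenario orderings and ratios.
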