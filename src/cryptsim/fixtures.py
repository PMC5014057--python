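"""Deterministic miniature cell configurations for fast unit testing.

These fixtures build tiny populations with exactly known neighbour
structure so mechanics and fate rules can be exercised in milliseconds
without running full crypts.
"""

from __future__ import annotations

import numpy as np

from . import population as pops
from .geometry import CryptSurface
from .params import CELL_RADIUS_UM, GeometryParams
from .population import CellPopulation

__all__ = ["make_ring_fixture", "make_niche_fixture"]


def _volume_for_radius(r_cell_radii: float) -> float:
    r_um = r_cell_radii * CELL_RADIUS_UM
    return 4.0 / 3.0 * np.pi * r_um**3


def make_ring_fixture(
    n_cells: int, radius: float | None = None,
    surface: CryptSurface | None = None,
) -> tuple[CellPopulation, CryptSurface]:
    """*n* identical cells evenly spaced on the cap-equator circle.

    Cell volumes are chosen so each cell exactly touches its two ring
    neighbours (centre distance = half the chord between adjacent slots);
    with even spacing the net pairwise force on every cell is zero by
    symmetry.
    """
    if n_cells < 3:
        raise ValueError("ring fixture needs n >= 3 cells")
    surface = surface or CryptSurface(GeometryParams())
    R = surface.R if radius is None else float(radius)
    if radius is not None and abs(R - surface.R) > 1e-9:
        surface = CryptSurface(GeometryParams(cap_radius=R, crypt_length=R * 10))
    r_cell = R * np.sin(np.pi / n_cells)
    if 2 * r_cell > 2.0 * R:
        raise ValueError("cells would overlap beyond a diameter")
    ang = 2 * np.pi * np.arange(n_cells) / n_cells
    posn = np.stack(
        [R * np.cos(ang), R * np.sin(ang), np.zeros(n_cells)], axis=1
    )
    pop = CellPopulation()
    pop.add(posn, states=pops.SC, volumes=_volume_for_radius(r_cell))
    return pop, surface


def make_niche_fixture(
    layout: str, surface: CryptSurface | None = None
) -> tuple[CellPopulation, CryptSurface]:
    """Hand-built niche arrangement from a layout string.

    Grammar: ``"CENTRE|NB1,NB2,..."`` where each slot is a lineage-state
    name (``SC``, ``PC``, ``GC``, ``EC`` shorthands map to the terminal
    secretory / progenitor absorptive states) optionally suffixed with
    ``@k`` to assign profile index *k*.  The centre cell sits at the crypt
    bottom pole; neighbours are placed around it at touching distance, so
    the contact graph is exactly the star adjacency for up to five
    neighbours.
    """
    shorthand = {
        "SC": pops.SC,
        "PC": pops.PC_TERM,
        "GC": pops.GC_TERM,
        "EC": pops.EC_PROG,
        **{name: code for code, name in enumerate(pops.STATE_NAMES)},
    }
    surface = surface or CryptSurface(GeometryParams())
    R = surface.R

    def parse(tok: str) -> tuple[int, int]:
        tok = tok.strip()
        prof = 0
        if "@" in tok:
            tok, p = tok.split("@")
            prof = int(p)
        if tok not in shorthand:
            raise ValueError(f"unknown state symbol {tok!r}")
        return shorthand[tok], prof

    if "|" in layout:
        centre_tok, rest = layout.split("|", 1)
        nb_toks = [t for t in rest.split(",") if t.strip()]
    else:
        centre_tok, nb_toks = layout, []
    centre_state, centre_prof = parse(centre_tok)
    r_cell = 1.0  # one cell radius
    # polar angle such that the 3D chord to the pole equals 2 r_cell
    theta = 2 * np.arcsin(r_cell / R)
    positions = [np.array([0.0, 0.0, -R])]
    states, profs = [centre_state], [centre_prof]
    for k, tok in enumerate(nb_toks):
        st, pr = parse(tok)
        phi = 2 * np.pi * k / max(len(nb_toks), 1)
        positions.append(
            R * np.array(
                [np.sin(theta) * np.cos(phi),
                 np.sin(theta) * np.sin(phi),
                 -np.cos(theta)]
            )
        )
        states.append(st)
        profs.append(pr)
    pop = CellPopulation()
    pop.add(
        np.asarray(positions), states=states,
        volumes=_volume_for_radius(r_cell), profiles=profs,
    )
    return pop, surface
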