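"""Cell state containers.

The simulation keeps all per-cell state in a structure-of-arrays
(:class:`CellPopulation`) so that mechanics and fate updates vectorise over
the few hundred cells of a crypt.  A lightweight :class:`Cell` view object
exposes single cells for fixtures, unit tests and the scalar operation APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import CELL_RADIUS_UM, V0_UM3

# --------------------------------------------------------------------------
# lineage states

SC = 0
EC_PROG = 1
GC_PROG = 2
PC_PROG = 3
EC_TERM = 4
GC_TERM = 5
PC_TERM = 6

STATE_NAMES = (
    "SC",
    "EC_progenitor",
    "GC_progenitor",
    "PC_progenitor",
    "EC_terminal",
    "GC_terminal",
    "PC_terminal",
)
STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}

PROLIFERATIVE = frozenset({SC, EC_PROG, GC_PROG, PC_PROG})
TERMINAL = frozenset({EC_TERM, GC_TERM, PC_TERM})
PC_STATES = frozenset({PC_PROG, PC_TERM})
GC_STATES = frozenset({GC_PROG, GC_TERM})

_PC_MASK = np.zeros(7, dtype=bool)
_PC_MASK[[PC_PROG, PC_TERM]] = True
_GC_MASK = np.zeros(7, dtype=bool)
_GC_MASK[[GC_PROG, GC_TERM]] = True
_PROLIF_MASK = np.zeros(7, dtype=bool)
_PROLIF_MASK[[SC, EC_PROG, GC_PROG, PC_PROG]] = True


def radius_from_volume(volume) -> np.ndarray:
    """Sphere-equivalent radius in cell radii from a volume in µm³."""
    return (3.0 * np.asarray(volume) / (4.0 * np.pi)) ** (1.0 / 3.0) / CELL_RADIUS_UM


@dataclass
class Cell:
    """Single-cell view used by fixtures and scalar operations."""

    id: int
    position: np.ndarray
    volume: float = V0_UM3
    lineage_state: str = "SC"
    founder_id: int = -1
    profile: int = 0
    age: float = 0.0

    @property
    def radius(self) -> float:
        return float(radius_from_volume(self.volume))

    @property
    def state_code(self) -> int:
        return STATE_INDEX[self.lineage_state]


_FLOAT_FIELDS = (
    "volume",
    "age",
    "growth_time",      # h to double volume, sampled per cell
    "pc_clock",         # h without SC contact (terminal PCs)
    "pc_age",           # h since PC_terminal conversion
    "pc_lifespan",      # sampled intrinsic lifespan, h
    "squeeze_clock",    # h of sustained full compression
    "pc_wait",          # h a PC progenitor spent contact-inhibited
    "deficit_clock",    # h of sustained ligand-contact deficit
)
_INT_FIELDS = ("id", "state", "founder", "profile")


class CellPopulation:
    """Structure-of-arrays over all live cells of one crypt."""

    def __init__(self) -> None:
        self.pos = np.zeros((0, 3))
        for name in _FLOAT_FIELDS:
            setattr(self, name, np.zeros(0))
        for name in _INT_FIELDS:
            setattr(self, name, np.zeros(0, dtype=np.int64))
        self.inhibited = np.zeros(0, dtype=bool)
        self._next_id = 0

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.id)

    @property
    def n(self) -> int:
        return len(self.id)

    @property
    def radius(self) -> np.ndarray:
        return radius_from_volume(self.volume)

    def fresh_ids(self, count: int) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + count, dtype=np.int64)
        self._next_id += count
        return ids

    # ------------------------------------------------------------------
    def add(
        self,
        positions: np.ndarray,
        states,
        volumes=None,
        founders=None,
        profiles=None,
        growth_times=None,
        ids=None,
        v0: float = V0_UM3,
    ) -> np.ndarray:
        """Append cells; returns their ids."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        m = len(positions)
        states = np.broadcast_to(np.asarray(states, dtype=np.int64), (m,)).copy()
        volumes = (
            np.full(m, v0) if volumes is None
            else np.broadcast_to(np.asarray(volumes, dtype=float), (m,)).copy()
        )
        if ids is None:
            ids = self.fresh_ids(m)
        else:
            ids = np.asarray(ids, dtype=np.int64)
            self._next_id = max(self._next_id, int(ids.max()) + 1)
        founders = (
            ids.copy() if founders is None
            else np.broadcast_to(np.asarray(founders, dtype=np.int64), (m,)).copy()
        )
        profiles = (
            np.zeros(m, dtype=np.int64) if profiles is None
            else np.broadcast_to(np.asarray(profiles, dtype=np.int64), (m,)).copy()
        )
        growth_times = (
            np.full(m, 16.0) if growth_times is None
            else np.broadcast_to(np.asarray(growth_times, dtype=float), (m,)).copy()
        )
        self.pos = np.vstack([self.pos, positions])
        self.id = np.concatenate([self.id, ids])
        self.state = np.concatenate([self.state, states])
        self.founder = np.concatenate([self.founder, founders])
        self.profile = np.concatenate([self.profile, profiles])
        self.volume = np.concatenate([self.volume, volumes])
        self.growth_time = np.concatenate([self.growth_time, growth_times])
        for name in ("age", "pc_clock", "pc_age", "pc_lifespan",
                     "squeeze_clock", "pc_wait", "deficit_clock"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros(m)]))
        self.inhibited = np.concatenate([self.inhibited, np.zeros(m, dtype=bool)])
        return ids

    def keep(self, mask: np.ndarray) -> None:
        """Drop all cells where *mask* is False."""
        self.pos = self.pos[mask]
        for name in _FLOAT_FIELDS + _INT_FIELDS:
            setattr(self, name, getattr(self, name)[mask])
        self.inhibited = self.inhibited[mask]

    # ------------------------------------------------------------------
    # convenience masks
    def is_pc(self) -> np.ndarray:
        return _PC_MASK[self.state]

    def is_gc(self) -> np.ndarray:
        return _GC_MASK[self.state]

    def is_proliferative(self) -> np.ndarray:
        return _PROLIF_MASK[self.state]

    def is_sc(self) -> np.ndarray:
        return self.state == SC

    # ------------------------------------------------------------------
    def cell(self, index: int) -> Cell:
        return Cell(
            id=int(self.id[index]),
            position=self.pos[index].copy(),
            volume=float(self.volume[index]),
            lineage_state=STATE_NAMES[self.state[index]],
            founder_id=int(self.founder[index]),
            profile=int(self.profile[index]),
            age=float(self.age[index]),
        )

    def cells(self):
        return [self.cell(i) for i in range(self.n)]

    # ------------------------------------------------------------------
    def snapshot(self, surface=None, time: float = 0.0,
                 profile_names=None) -> pd.DataFrame:
        """Flat snapshot table (one row per live cell)."""
        P = surface.axial_position(self.pos) if surface is not None else np.nan
        names = [STATE_NAMES[s] for s in self.state]
        prof = (
            [profile_names[p] for p in self.profile]
            if profile_names is not None
            else self.profile
        )
        return pd.DataFrame(
            {
                "time": time,
                "id": self.id,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
                "P": P,
                "volume": self.volume,
                "lineage_state": names,
                "founder_id": self.founder,
                "profile": prof,
            }
        )

    @classmethod
    def from_snapshot(cls, df: pd.DataFrame) -> "CellPopulation":
        pop = cls()
        pop.add(
            positions=df[["x", "y", "z"]].to_numpy(dtype=float),
            states=[STATE_INDEX[s] for s in df["lineage_state"]],
            volumes=df["volume"].to_numpy(dtype=float),
            founders=df["founder_id"].to_numpy(dtype=np.int64),
            ids=df["id"].to_numpy(dtype=np.int64),
        )
        return pop

    def copy(self) -> "CellPopulation":
        new = CellPopulation()
        new.pos = self.pos.copy()
        for name in _FLOAT_FIELDS + _INT_FIELDS:
            setattr(new, name, getattr(self, name).copy())
        new.inhibited = self.inhibited.copy()
        new._next_id = self._next_id
        return new
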