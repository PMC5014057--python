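"""Phylogenies of the stem-cell history and clonal-competition statistics.

Stem-cell divisions define a binary forest: each edge is one stem cell's
lifetime, each internal vertex a mitotic event annotated with the crypt
position P of the dividing cell.  From replicate simulations this module
derives

* monoclonal conversion times (the first instant the tracked population
  descends from a single founder),
* the positional distributions f(P) (stem cells at competition start),
  w(P) (origins of winning clones) and p(P) (stem-cell division events),
* the positional advantage ratio w(P)/f(P) and the number of "advantaged"
  stem cells (those starting in bins with w(P) > 0),
* fixation statistics of labelled/mutant clones,

and exports trees as Newick with a companion annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhylogenyTree",
    "PositionalDistribution",
    "detect_monoclonal_conversion",
    "positional_distributions",
    "advantage_ratio",
    "count_advantaged_scs",
    "fixation_statistics",
    "fixations_per_n_from_distributions",
    "FixationStats",
    "export_newick",
]


# ---------------------------------------------------------------------------
# phylogenetic forest


@dataclass
class _Node:
    cell_id: int
    birth_time: float
    parent: Optional[int] = None
    children: list = field(default_factory=list)
    div_time: Optional[float] = None
    div_P: Optional[float] = None
    end_time: Optional[float] = None
    outcome: str = "alive"  # specified | anoikis | exit | alive | divided


class PhylogenyTree:
    """Division-event forest over the stem-cell history."""

    def __init__(self, root_ids: Sequence[int], start_time: float = 0.0):
        self.start_time = float(start_time)
        self.roots = [int(r) for r in root_ids]
        self.nodes: dict[int, _Node] = {
            int(r): _Node(int(r), start_time) for r in root_ids
        }

    # -- construction --------------------------------------------------
    def record_division(
        self, mother_id: int, daughter_ids: Sequence[int], t: float, P: float
    ) -> None:
        """Close the mother edge at *t* and open two daughter edges."""
        if mother_id not in self.nodes:
            raise KeyError(f"unknown mother {mother_id}")
        node = self.nodes[mother_id]
        if node.children:
            raise ValueError(f"cell {mother_id} divided twice")
        node.div_time = node.end_time = t
        node.div_P = P
        node.outcome = "divided"
        for d in daughter_ids:
            d = int(d)
            self.nodes[d] = _Node(d, t, parent=mother_id)
            node.children.append(d)

    def close_leaf(self, cell_id: int, t: float, outcome: str) -> None:
        node = self.nodes.get(cell_id)
        if node is not None and not node.children:
            node.end_time = t
            node.outcome = outcome

    def finalize(self, end_time: float) -> None:
        for node in self.nodes.values():
            if node.end_time is None:
                node.end_time = end_time
                node.outcome = "alive"

    # -- queries -------------------------------------------------------
    def leaves(self) -> list[int]:
        return [cid for cid, n in self.nodes.items() if not n.children]

    def n_vertices(self) -> int:
        return sum(1 for n in self.nodes.values() if n.children)

    def edge_length(self, cell_id: int) -> float:
        n = self.nodes[cell_id]
        end = n.end_time if n.end_time is not None else self.start_time
        return end - n.birth_time

    def total_edge_length(self) -> float:
        return sum(self.edge_length(c) for c in self.nodes)

    def vertex_positions(self) -> np.ndarray:
        return np.array(
            [n.div_P for n in self.nodes.values() if n.children], dtype=float
        )

    def subtree_ids(self, root: int) -> list[int]:
        out, stack = [], [root]
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self.nodes[c].children)
        return out


def build_tree(
    root_ids: Sequence[int],
    divisions: Iterable,
    start_time: float = 0.0,
    end_time: Optional[float] = None,
    leaf_outcomes: Optional[dict] = None,
) -> PhylogenyTree:
    """Replay division records (mother, d1, d2, t, P) into a forest.

    Only divisions whose mother is reachable from *root_ids* are attached;
    *leaf_outcomes* maps cell id -> (time, outcome) for closed-out cells.
    """
    tree = PhylogenyTree(root_ids, start_time)
    for rec in divisions:
        if hasattr(rec, "mother_id"):
            m, d1, d2, t, P = (
                rec.mother_id, rec.daughter1_id, rec.daughter2_id, rec.time, rec.P
            )
        else:
            m, d1, d2, t, P = rec
        if m in tree.nodes:
            tree.record_division(m, (d1, d2), t, P)
    if leaf_outcomes:
        for cid, (t, outcome) in leaf_outcomes.items():
            tree.close_leaf(cid, t, outcome)
    if end_time is not None:
        tree.finalize(end_time)
    return tree


# ---------------------------------------------------------------------------
# Newick export


def export_newick(tree: PhylogenyTree) -> tuple[str, pd.DataFrame]:
    """Newick string (branch lengths in hours) + per-node annotation table.

    Multiple roots are joined under an artificial zero-length root so the
    output remains a single valid Newick tree.
    """
    rows = []
    for cid, n in tree.nodes.items():
        rows.append(
            {
                "node": f"c{cid}",
                "birth_time": n.birth_time,
                "end_time": n.end_time,
                "division_P": n.div_P,
                "outcome": n.outcome,
            }
        )
    ann = pd.DataFrame(rows)
    if not tree.nodes:
        return ";", ann

    def render(root: int) -> str:
        # iterative post-order to survive deep caterpillar trees
        out: dict[int, str] = {}
        stack = [(root, False)]
        while stack:
            cid, expanded = stack.pop()
            node = tree.nodes[cid]
            if node.children and not expanded:
                stack.append((cid, True))
                for ch in node.children:
                    stack.append((ch, False))
                continue
            length = tree.edge_length(cid)
            if node.children:
                inner = ",".join(out.pop(ch) for ch in node.children)
                out[cid] = f"({inner})c{cid}:{length:g}"
            else:
                out[cid] = f"c{cid}:{length:g}"
        return out[root]

    parts = [render(r) for r in tree.roots]
    if len(parts) == 1:
        return parts[0] + ";", ann
    return "(" + ",".join(parts) + ")root:0;", ann


# ---------------------------------------------------------------------------
# monoclonal conversion


def detect_monoclonal_conversion(founder_series: Iterable) -> Optional[float]:
    """First time at which every tracked cell shares one founder.

    *founder_series* yields ``(time, founders)`` pairs in temporal order,
    where ``founders`` is the array of founder labels of the tracked
    population (stem cells by default).  Returns ``None`` if the series ends
    first or a sample is empty.
    """
    for t, founders in founder_series:
        f = np.asarray(founders)
        if len(f) > 0 and (f == f[0]).all():
            return float(t)
    return None


# ---------------------------------------------------------------------------
# positional distributions


@dataclass
class PositionalDistribution:
    """Binned-by-position probability vectors with replicate statistics.

    Bins are unit-width integer bins assigned by ``floor(P)``.
    """

    bins: np.ndarray
    f: np.ndarray
    p: np.ndarray
    w: Optional[np.ndarray]
    f_sd: np.ndarray
    p_sd: np.ndarray
    w_sd: Optional[np.ndarray]
    n_replicates: int
    n_winners: int

    def to_frame(self) -> pd.DataFrame:
        d = {
            "P_bin": self.bins,
            "f": self.f,
            "f_sd": self.f_sd,
            "p": self.p,
            "p_sd": self.p_sd,
        }
        if self.w is not None:
            d["w"] = self.w
            d["w_sd"] = self.w_sd
        return pd.DataFrame(d)


def _binned(P: np.ndarray, n_bins: int) -> np.ndarray:
    h = np.zeros(n_bins)
    if len(P):
        idx = np.clip(np.floor(P).astype(int), 0, n_bins - 1)
        np.add.at(h, idx, 1.0)
        h /= h.sum()
    return h


def positional_distributions(
    sc_start_P: Sequence[np.ndarray],
    division_P: Sequence[np.ndarray],
    winner_P: Sequence[Optional[float]],
    n_bins: int = 31,
) -> PositionalDistribution:
    """Aggregate f(P), p(P), w(P) over replicates.

    * ``sc_start_P[r]`` — positions of the stem cells of replicate *r* at
      competition start (defines f);
    * ``division_P[r]`` — positions of its stem-cell division events (p);
    * ``winner_P[r]`` — start position of the winning clone's founder, or
      ``None`` for censored replicates (w; absent if no replicate resolved).
    """
    R = len(sc_start_P)
    f_mat = np.stack([_binned(np.asarray(x, float), n_bins) for x in sc_start_P])
    p_mat = np.stack([_binned(np.asarray(x, float), n_bins) for x in division_P])
    winners = [wp for wp in winner_P if wp is not None]
    if winners:
        w_mat = np.stack(
            [_binned(np.array([wp]), n_bins) for wp in winners]
        )
        w, w_sd = w_mat.mean(axis=0), w_mat.std(axis=0, ddof=1 if len(winners) > 1 else 0)
    else:
        w = w_sd = None
    return PositionalDistribution(
        bins=np.arange(n_bins),
        f=f_mat.mean(axis=0),
        f_sd=f_mat.std(axis=0, ddof=1 if R > 1 else 0),
        p=p_mat.mean(axis=0),
        p_sd=p_mat.std(axis=0, ddof=1 if R > 1 else 0),
        w=w,
        w_sd=w_sd,
        n_replicates=R,
        n_winners=len(winners),
    )


def advantage_ratio(dist: PositionalDistribution) -> pd.DataFrame:
    """Per-bin ratio w(P)/f(P) with propagated replicate uncertainty.

    Bins with f = 0 are excluded (the ratio is undefined there).
    """
    if dist.w is None:
        raise ValueError("w(P) is absent: no replicate resolved a winner")
    keep = dist.f > 0
    f, w = dist.f[keep], dist.w[keep]
    ratio = w / f
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            np.where(w > 0, (dist.w_sd[keep] / np.where(w > 0, w, 1.0)) ** 2, 0.0)
            + (dist.f_sd[keep] / f) ** 2
        )
    return pd.DataFrame(
        {
            "P_bin": dist.bins[keep],
            "ratio": ratio,
            "ratio_sd": ratio * rel,
            "f": f,
            "w": w,
        }
    )


def count_advantaged_scs(
    sc_start_P: Sequence[np.ndarray], dist: PositionalDistribution
) -> tuple[float, float]:
    """Mean ± s.d. over replicates of the number of stem cells that start in
    bins from which winning clones originate (w(P) > 0)."""
    if dist.w is None:
        raise ValueError("w(P) is absent: no replicate resolved a winner")
    good_bins = set(dist.bins[dist.w > 0].tolist())
    counts = []
    for P in sc_start_P:
        b = np.floor(np.asarray(P, float)).astype(int)
        counts.append(int(np.isin(b, list(good_bins)).sum()))
    counts = np.asarray(counts, float)
    sd = counts.std(ddof=1) if len(counts) > 1 else 0.0
    return float(counts.mean()), float(sd)


# ---------------------------------------------------------------------------
# fixation statistics


@dataclass
class FixationStats:
    n_total: int
    n_resolved: int
    n_fixed: int
    n_lost: int
    n_censored: int

    @property
    def fixation_probability(self) -> float:
        if self.n_resolved == 0:
            raise ZeroDivisionError("all replicates censored: statistic undefined")
        return self.n_fixed / self.n_resolved

    @property
    def loss_probability(self) -> float:
        return 1.0 - self.fixation_probability

    def fixations_per_n(self, n: int) -> float:
        """Expected fixed mutations out of *n* independent mutations."""
        return n * self.fixation_probability


def fixation_statistics(outcomes: Iterable[str]) -> FixationStats:
    """Tally replicate outcomes (each ``fixed``, ``lost`` or ``censored``)."""
    outcomes = list(outcomes)
    n_fixed = outcomes.count("fixed")
    n_lost = outcomes.count("lost")
    n_cens = outcomes.count("censored")
    unknown = len(outcomes) - n_fixed - n_lost - n_cens
    if unknown:
        raise ValueError("outcomes must be 'fixed', 'lost' or 'censored'")
    return FixationStats(
        n_total=len(outcomes),
        n_resolved=n_fixed + n_lost,
        n_fixed=n_fixed,
        n_lost=n_lost,
        n_censored=n_cens,
    )


def fixations_per_n_from_distributions(
    placement: np.ndarray, w: np.ndarray, f: np.ndarray
) -> float:
    """Expected fixations out of n mutations placed with distribution q(P).

    A clone founded by one of the ``n f(P)`` stem cells in bin P wins with
    probability ``w(P) / (n f(P))``, so out of n mutations placed with q(P)
    the expected number fixed is ``sum_P q(P) w(P)/f(P)`` — equal to 1 for
    random placement (q = f) by construction.
    """
    q = np.asarray(placement, float)
    w = np.asarray(w, float)
    f = np.asarray(f, float)
    keep = f > 0
    return float(np.sum(q[keep] * w[keep] / f[keep]))
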