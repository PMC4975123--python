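"""Exhaustive 2-point depth comparisons and the consensus depth order.

In the 2-point task an observer sees two marked vertices and clicks the one
that appears nearer.  With all V(V-1)/2 unordered pairs judged once, an
optimal consensus depth order is obtained by counting how often each vertex
was called nearer (a Borda/Copeland count on the comparison tournament).
The internal consistency of a session is summarised by a number of merit
defined like Kendall's tau: (concordant - discordant) / all judged pairs.
Judgements contradicting the consensus are the "confusions" that drive the
segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

__all__ = [
    "PairJudgement",
    "JudgementSet",
    "DepthOrder",
    "ConfusionSet",
    "n_pairs",
    "depth_order",
    "merit",
    "discordant_pairs",
    "kendall_tau",
    "DepthOrderModel",
    "DepthOrderResults",
    "read_judgements_csv",
    "write_judgements_csv",
]


@dataclass(frozen=True)
class PairJudgement:
    """One forced-choice response: ``chosen`` (= a or b) looked nearer."""

    a: int
    b: int
    chosen: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"pair must have distinct vertices, got ({self.a},{self.b})")
        if self.chosen not in (self.a, self.b):
            raise ValueError(f"chosen={self.chosen} is neither {self.a} nor {self.b}")


@dataclass
class JudgementSet:
    """All responses of one observer in one session."""

    observer: str
    session: str
    judgements: list[PairJudgement]

    def __len__(self) -> int:
        return len(self.judgements)

    def validate_unique_pairs(self) -> None:
        seen: set[tuple[int, int]] = set()
        for j in self.judgements:
            key = (min(j.a, j.b), max(j.a, j.b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair {key} in session {self.session!r}")
            seen.add(key)

    def is_complete(self, v: int) -> bool:
        """True when every unordered pair of ``v`` vertices was judged exactly once."""
        return len({(min(j.a, j.b), max(j.a, j.b)) for j in self.judgements}) == n_pairs(
            v
        ) == len(self.judgements)


@dataclass
class DepthOrder:
    """Consensus ranking of vertices by depth; rank 0 = nearest, ties allowed."""

    ranks: np.ndarray
    win_counts: np.ndarray
    levels: int = field(default=0)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        self.win_counts = np.asarray(self.win_counts, dtype=np.int64)
        if not self.levels:
            self.levels = int(len(np.unique(self.ranks)))


@dataclass
class ConfusionSet:
    """Unordered vertex pairs whose judgement contradicts the consensus order."""

    pairs: set[tuple[int, int]]

    def __post_init__(self) -> None:
        self.pairs = {(min(a, b), max(a, b)) for a, b in self.pairs}
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pair in confusion set")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return (min(a, b), max(a, b)) in self.pairs


# ----------------------------------------------------------------------
def n_pairs(v: int) -> int:
    """Number of orderless vertex pairs, v(v-1)/2."""
    if v < 2:
        raise ValueError(f"need at least 2 vertices, got {v}")
    return v * (v - 1) // 2


def depth_order(js: JudgementSet, v: int) -> DepthOrder:
    """Consensus depth order by counting how often each vertex was judged nearer.

    Vertices are densely ranked by descending win count (equal counts share a
    rank; the next rank is one more), so ``levels`` equals the number of
    distinct win counts the observer resolved.
    """
    js.validate_unique_pairs()
    wins = np.zeros(v, dtype=np.int64)
    for j in js.judgements:
        if j.a >= v or j.b >= v or j.a < 0 or j.b < 0:
            raise ValueError(f"judgement ({j.a},{j.b}) outside vertex range [0,{v})")
        wins[j.chosen] += 1
    # dense rank of descending counts
    distinct = np.unique(wins)[::-1]
    rank_of = {int(c): r for r, c in enumerate(distinct)}
    ranks = np.array([rank_of[int(c)] for c in wins], dtype=np.int64)
    return DepthOrder(ranks=ranks, win_counts=wins, levels=len(distinct))


def merit(js: JudgementSet, order: DepthOrder) -> float:
    """Consistency of raw judgements with a consensus order, tau-a style.

    merit = (C - D) / N over the N judged pairs, where a judgement is
    concordant (C) when the chosen vertex has the strictly smaller (nearer)
    consensus rank and discordant (D) when it has the strictly larger one.
    Pairs tied in the consensus count in N but in neither C nor D.
    """
    if not js.judgements:
        raise ValueError("empty judgement set")
    ranks = order.ranks
    c = d = 0
    for j in js.judgements:
        ra, rb = ranks[j.a], ranks[j.b]
        if ra == rb:
            continue
        nearer = j.a if ra < rb else j.b
        if j.chosen == nearer:
            c += 1
        else:
            d += 1
    return (c - d) / len(js.judgements)


def discordant_pairs(js: JudgementSet, order: DepthOrder) -> ConfusionSet:
    """Pairs whose judgement strictly contradicts the consensus order."""
    ranks = order.ranks
    pairs: set[tuple[int, int]] = set()
    for j in js.judgements:
        ra, rb = ranks[j.a], ranks[j.b]
        if ra == rb:
            continue
        nearer = j.a if ra < rb else j.b
        if j.chosen != nearer:
            pairs.add((min(j.a, j.b), max(j.a, j.b)))
    return ConfusionSet(pairs=pairs)


def kendall_tau(order1: DepthOrder | np.ndarray, order2: DepthOrder | np.ndarray) -> float:
    """Tie-corrected Kendall tau-b between two rankings of the same vertices."""
    r1 = order1.ranks if isinstance(order1, DepthOrder) else np.asarray(order1)
    r2 = order2.ranks if isinstance(order2, DepthOrder) else np.asarray(order2)
    if len(r1) != len(r2):
        raise ValueError("rankings cover different vertex sets")
    if len(r1) < 2:
        raise ValueError("need at least 2 vertices")
    tau, _ = kendalltau(r1, r2, variant="b")
    return float(tau)


# ----------------------------------------------------------------------
class DepthOrderModel:
    """Reconstructs the consensus depth order of one session.

    Parameters
    ----------
    judgement_set : JudgementSet
        The session's responses.
    n_vertices : int
        Number of vertices of the triangulation the pairs were drawn from.

    Examples
    --------
    >>> js = JudgementSet("obs", "s1", [PairJudgement(0, 1, 0), PairJudgement(0, 2, 0),
    ...                                 PairJudgement(1, 2, 1)])
    >>> res = DepthOrderModel(js, 3).fit()
    >>> res.merit
    1.0
    """

    def __init__(self, judgement_set: JudgementSet, n_vertices: int):
        self.judgement_set = judgement_set
        self.n_vertices = int(n_vertices)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_vertices: int | None = None) -> "DepthOrderModel":
        """Build from a ``observer,session,vertex_a,vertex_b,chosen`` frame (one session)."""
        if df[["observer", "session"]].drop_duplicates().shape[0] != 1:
            raise ValueError("frame contains more than one observer/session")
        js = JudgementSet(
            observer=str(df["observer"].iloc[0]),
            session=str(df["session"].iloc[0]),
            judgements=[
                PairJudgement(int(r.vertex_a), int(r.vertex_b), int(r.chosen))
                for r in df.itertuples()
            ],
        )
        if n_vertices is None:
            n_vertices = int(df[["vertex_a", "vertex_b"]].to_numpy().max()) + 1
        return cls(js, n_vertices)

    def fit(self) -> "DepthOrderResults":
        order = depth_order(self.judgement_set, self.n_vertices)
        m = merit(self.judgement_set, order)
        confusions = discordant_pairs(self.judgement_set, order)
        return DepthOrderResults(self, order, m, confusions)


class DepthOrderResults:
    """Consensus order, its merit, and the discordant (confused) pairs."""

    def __init__(self, model: DepthOrderModel, order: DepthOrder, merit_: float,
                 confusions: ConfusionSet):
        self.model = model
        self.order = order
        self.merit = merit_
        self.confusions = confusions

    @property
    def ranks(self) -> np.ndarray:
        return self.order.ranks

    @property
    def win_counts(self) -> np.ndarray:
        return self.order.win_counts

    @property
    def levels(self) -> int:
        return self.order.levels

    @property
    def n_discordant(self) -> int:
        return len(self.confusions)

    def to_dict(self) -> dict:
        return {
            "observer": self.model.judgement_set.observer,
            "session": self.model.judgement_set.session,
            "n_vertices": self.model.n_vertices,
            "n_judgements": len(self.model.judgement_set),
            "win_counts": self.order.win_counts.tolist(),
            "ranks": self.order.ranks.tolist(),
            "levels": self.levels,
            "merit": self.merit,
            "n_discordant": self.n_discordant,
        }

    def summary(self) -> str:
        js = self.model.judgement_set
        lines = [
            "Consensus depth order (win-count reconstruction)",
            f"  observer/session : {js.observer}/{js.session}",
            f"  vertices         : {self.model.n_vertices}",
            f"  judged pairs     : {len(js)}",
            f"  resolved levels  : {self.levels}",
            f"  number of merit  : {self.merit:.3f}",
            f"  discordant pairs : {self.n_discordant}",
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
def read_judgements_csv(path: str | Path) -> list[JudgementSet]:
    """Read ``observer,session,vertex_a,vertex_b,chosen`` rows into sessions."""
    df = pd.read_csv(path)
    required = {"observer", "session", "vertex_a", "vertex_b", "chosen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"judgement CSV missing columns {sorted(missing)}")
    out = []
    for (obs, sess), grp in df.groupby(["observer", "session"], sort=True):
        out.append(
            JudgementSet(
                observer=str(obs),
                session=str(sess),
                judgements=[
                    PairJudgement(int(r.vertex_a), int(r.vertex_b), int(r.chosen))
                    for r in grp.itertuples()
                ],
            )
        )
    return out


def write_judgements_csv(sets: list[JudgementSet], path: str | Path) -> None:
    rows = [
        {"observer": s.observer, "session": s.session, "vertex_a": j.a,
         "vertex_b": j.b, "chosen": j.chosen}
        for s in sets
        for j in s.judgements
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
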