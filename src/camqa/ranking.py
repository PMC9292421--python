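"""Tolerance-gated tournament ranking and diversity-aware selection.

A pair of scored models is compared on the global (dark) score unless the two
globals agree within a tolerance, in which case the interface pseudo-energy
alone decides — this shifts the emphasis of selection onto the quality of the
inter-chain interface.  A full round-robin of such comparisons yields Copeland
(win-count) rankings that are deterministic and independent of input order.
Diverse top-k selection then greedily clusters models in rank order by
interface CAD similarity and returns the cluster leaders.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

from .errors import EmptyInputError, IncompleteMatrixError, IncompleteScoreError
from .voromqa import ModelScores

__all__ = [
    "RankingConfig",
    "RankedList",
    "compare_pair",
    "tournament_rank",
    "select_diverse",
]


@dataclasses.dataclass
class RankingConfig:
    """Knobs of the selection protocol.

    tolerance: global-score difference below which the interface energy is
        the only decisive factor (score units, default 0.02).
    cluster_threshold: interface CAD similarity at or above which two models
        belong to the same cluster (default 0.65).
    k: number of diverse models to select (default 5).
    """

    tolerance: float = 0.02
    cluster_threshold: float = 0.65
    k: int = 5

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not 0.0 <= self.cluster_threshold <= 1.0:
            raise ValueError("cluster_threshold must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclasses.dataclass
class RankedList:
    """Ordered model ids with win counts, scores and (optional) clusters."""

    order: list[str]
    wins: dict[str, int]
    scores: dict[str, ModelScores]
    clusters: dict[str, int] | None = None


def _check_scored(m: ModelScores) -> None:
    for field in ("global_dark", "interface_energy"):
        v = getattr(m, field, None)
        if v is None:
            raise IncompleteScoreError(f"model {m.model_id} is missing {field}")


def compare_pair(a: ModelScores, b: ModelScores, tol: float) -> ModelScores:
    """Return the winner of a tolerance-gated pairwise comparison.

    Globals differing by more than ``tol``: the higher global wins.
    Otherwise the lower (more favorable) interface energy wins; exact ties
    fall back to the higher global, then the lexicographically smaller id.
    """
    _check_scored(a)
    _check_scored(b)
    if abs(a.global_dark - b.global_dark) > tol:
        return a if a.global_dark > b.global_dark else b
    if a.interface_energy != b.interface_energy:
        return a if a.interface_energy < b.interface_energy else b
    if a.global_dark != b.global_dark:
        return a if a.global_dark > b.global_dark else b
    return a if a.model_id <= b.model_id else b


def tournament_rank(models: Sequence[ModelScores], cfg: RankingConfig) -> RankedList:
    """Round-robin Copeland ranking of scored models.

    Order: descending win count, ties by global score, then interface energy,
    then id — total and independent of the input permutation.
    """
    if len(models) == 0:
        raise EmptyInputError("no models to rank")
    wins = {m.model_id: 0 for m in models}
    if len(wins) != len(models):
        raise ValueError("duplicate model ids")
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            winner = compare_pair(models[i], models[j], cfg.tolerance)
            wins[winner.model_id] += 1
    by_id = {m.model_id: m for m in models}
    order = sorted(
        wins,
        key=lambda mid: (
            -wins[mid],
            -by_id[mid].global_dark,
            by_id[mid].interface_energy,
            mid,
        ),
    )
    return RankedList(order=order, wins=wins, scores=by_id)


def select_diverse(
    ranked: RankedList,
    pairwise_sim: Mapping[frozenset, float] | Callable[[str, str], float],
    cfg: RankingConfig,
) -> list[str]:
    """Greedy leader clustering in rank order; returns the first k leaders.

    A model joins the first existing cluster whose leader it resembles at or
    above ``cluster_threshold`` (interface CAD similarity), otherwise it
    founds a new cluster.  Cluster assignments are recorded on ``ranked``.
    """

    def sim(a: str, b: str) -> float:
        if callable(pairwise_sim):
            return pairwise_sim(a, b)
        try:
            return pairwise_sim[frozenset((a, b))]
        except KeyError as exc:
            raise IncompleteMatrixError(f"missing similarity for ({a}, {b})") from exc

    leaders: list[str] = []
    assignment: dict[str, int] = {}
    for mid in ranked.order:
        placed = False
        for ci, leader in enumerate(leaders):
            if sim(mid, leader) >= cfg.cluster_threshold:
                assignment[mid] = ci
                placed = True
                break
        if not placed:
            assignment[mid] = len(leaders)
            leaders.append(mid)
    ranked.clusters = assignment
    return leaders[: cfg.k]
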