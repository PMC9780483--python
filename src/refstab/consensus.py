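"""Competition ranking per method and geometric-mean-of-ranks consensus.

Each method contributes one score per gene with a known direction (lower
M and lower model-based stability are better; higher correlation with
the index is better).  Scores become competition ranks — ties share the
minimum applicable rank and the next distinct score skips ranks
(1, 1, 3) — and the consensus score of a gene is the geometric mean of
its per-method ranks; genes are ordered by ascending geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

ASCENDING = "ascending_better"
DESCENDING = "descending_better"

#: Conventional score direction per stability method.
METHOD_DIRECTIONS = {
    "genorm": ASCENDING,
    "normfinder": ASCENDING,
    "bestkeeper": DESCENDING,
}


@dataclass
class MethodScores:
    """One method's per-gene scores; ``None``/NaN marks a missing score.

    ``missing_order`` optionally gives ascending sort keys used to order
    the missing-score genes after all scored genes (default: input order).
    """

    name: str
    scores: Mapping[str, float | None]
    direction: str = ASCENDING
    missing_order: Mapping[str, float] | None = None


@dataclass
class ConsensusRanking:
    methods: list[str]
    ranks: pd.DataFrame  # genes x methods, integer competition ranks
    geomeans: pd.Series  # unrounded, for sorting
    final_order: list[str]
    final_ranks: dict[str, int]

    def to_frame(self, scores: Mapping[str, Mapping[str, float | None]] | None = None) -> pd.DataFrame:
        genes = self.final_order
        out = pd.DataFrame({"gene": genes})
        for m in self.methods:
            if scores and m in scores:
                out[f"{m}_score"] = [scores[m].get(g) for g in genes]
            out[f"{m}_rank"] = [int(self.ranks.at[g, m]) for g in genes]
        out["geomean"] = [round(float(self.geomeans[g]), 3) for g in genes]
        out["final_rank"] = [self.final_ranks[g] for g in genes]
        return out


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def competition_ranks(
    scores: Mapping[str, float | None],
    direction: str = ASCENDING,
    missing_order: Mapping[str, float] | None = None,
) -> dict[str, int]:
    """Competition ("1, 1, 3") ranks of ``scores``.

    The best score gets rank 1; tied genes share the lowest applicable
    rank; the next distinct score's rank equals 1 plus the number of
    better-or-tied genes.  Missing scores are ranked after every scored
    gene, ordered by ``missing_order`` (else input order).
    """
    if direction not in (ASCENDING, DESCENDING):
        raise ValidationError(f"unknown direction {direction!r}")
    scored = {g: float(v) for g, v in scores.items() if not _is_missing(v)}
    if not scored:
        raise InsufficientDataError("all scores missing")
    sign = 1.0 if direction == ASCENDING else -1.0
    vals = np.array([sign * v for v in scored.values()])
    ranks = {
        g: int(1 + np.sum(vals < sign * scored[g])) for g in scored
    }
    missing = [g for g in scores if _is_missing(scores[g])]
    if missing_order is not None:
        missing.sort(key=lambda g: missing_order.get(g, math.inf))
    next_rank = len(scored) + 1
    for g in missing:
        ranks[g] = next_rank
        next_rank += 1
    return ranks


def geometric_mean_rank(rank_tuple: Sequence[float]) -> float:
    """Geometric mean of one gene's per-method ranks (unrounded).

    Report to 3 decimals with ``round(value, 3)``; keep the unrounded
    value for sorting.
    """
    ranks = list(rank_tuple)
    if not ranks:
        raise ValidationError("empty rank tuple")
    if any(r < 1 for r in ranks):
        raise ValidationError(f"ranks must be >= 1, got {ranks}")
    return float(np.exp(np.mean(np.log(ranks))))


def aggregate(results: Sequence[MethodScores]) -> ConsensusRanking:
    """Aggregate per-method scores into the final consensus ordering.

    Every method must cover the same gene universe.  Ties on the
    geometric mean are broken by arithmetic mean rank, then input order.
    """
    if not results:
        raise InsufficientDataError("no methods to aggregate")
    universe = list(results[0].scores)
    for ms in results[1:]:
        if set(ms.scores) != set(universe):
            only_a = sorted(set(universe) - set(ms.scores))
            only_b = sorted(set(ms.scores) - set(universe))
            raise ValidationError(
                f"gene universes differ: only in {results[0].name}: {only_a}; "
                f"only in {ms.name}: {only_b}"
            )

    rank_cols = {}
    for ms in results:
        rank_cols[ms.name] = competition_ranks(
            ms.scores, ms.direction, ms.missing_order
        )
    ranks = pd.DataFrame(rank_cols, index=universe)
    geomeans = pd.Series(
        {g: geometric_mean_rank(ranks.loc[g].tolist()) for g in universe}
    )
    input_pos = {g: i for i, g in enumerate(universe)}
    final_order = sorted(
        universe,
        key=lambda g: (geomeans[g], ranks.loc[g].mean(), input_pos[g]),
    )
    final_ranks = {g: i + 1 for i, g in enumerate(final_order)}
    return ConsensusRanking(
        methods=[ms.name for ms in results],
        ranks=ranks,
        geomeans=geomeans,
        final_order=final_order,
        final_ranks=final_ranks,
    )
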