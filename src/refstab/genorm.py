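"""geNorm-style stability analysis.

A gene's M-value is the mean, over all partner genes, of the standard
deviation across samples of the pairwise log2 expression ratio; lower M
means more stable.  The least-stable gene is excluded stepwise until two
genes remain, and V_n/n+1 — the SD of the log2 ratio of normalization
factors built from the n and the n+1 most stable genes — guides how many
reference genes are needed (conventional cut-off 0.15).  Genes whose M
exceeds 1.5 are flagged as unreliable references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cp_io import QuantityMatrix
from .errors import InsufficientDataError, ValidationError

#: M above this is conventionally considered unreliable as a reference.
M_RELIABILITY_THRESHOLD = 1.5

#: V_n/n+1 below this means adding the (n+1)-th gene is unnecessary.
V_THRESHOLD = 0.15


@dataclass
class GenormResult:
    """Outcome of the stepwise geNorm ranking.

    ``m_values`` holds each gene's M at the iteration of its exclusion;
    the final two genes share the final-pair M.  ``ranks`` are competition
    ranks: the final pair are both rank 1 and the next gene rank 3.
    """

    m_values: dict[str, float]
    exclusion_order: list[str]
    full_panel_m: dict[str, float]
    v_series: dict[int, float]
    ranks: dict[str, int]
    stability_order: list[str]
    unreliable: list[str] = field(default_factory=list)
    m_threshold: float = M_RELIABILITY_THRESHOLD
    v_threshold: float = V_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.m_values, key=lambda g: (self.ranks[g], g))
        return pd.DataFrame(
            {
                "gene": genes,
                "m_at_exclusion": [self.m_values[g] for g in genes],
                "full_panel_m": [self.full_panel_m[g] for g in genes],
                "rank": [self.ranks[g] for g in genes],
                "unreliable": [g in self.unreliable for g in genes],
            }
        )

    def v_frame(self) -> pd.DataFrame:
        ns = sorted(self.v_series)
        return pd.DataFrame(
            {
                "n": ns,
                "v_n_nplus1": [self.v_series[n] for n in ns],
                "below_threshold": [self.v_series[n] < self.v_threshold for n in ns],
            }
        )


def _log2q(q: QuantityMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    df = q.log2()
    return df if genes is None else df.loc[list(genes)]


def pairwise_variation(q: QuantityMatrix, gene_j: str, gene_k: str) -> float:
    """SD across samples of log2(Q_j / Q_k); symmetric in its arguments.

    Uses the sample standard deviation (n-1 denominator).
    """
    for g in (gene_j, gene_k):
        if g not in q.q_values.index:
            raise ValidationError(f"unknown gene {g!r}")
    if len(q.samples) < 2:
        raise InsufficientDataError("pairwise variation needs >=2 samples")
    ratios = np.log2(q.q_values.loc[gene_j] / q.q_values.loc[gene_k])
    return float(ratios.std(ddof=1))


def m_value(q: QuantityMatrix, gene: str, gene_set: Sequence[str]) -> float:
    """Mean pairwise variation of ``gene`` against every other set member."""
    gene_set = list(gene_set)
    if gene not in gene_set:
        raise ValidationError(f"gene {gene!r} not in gene_set")
    if len(gene_set) < 2:
        raise InsufficientDataError("M needs a gene set of >=2 genes")
    partners = [g for g in gene_set if g != gene]
    return float(np.mean([pairwise_variation(q, gene, k) for k in partners]))


def _m_values(log2q: pd.DataFrame) -> pd.Series:
    """Vectorized M for every gene in the panel spanned by ``log2q``."""
    arr = log2q.to_numpy()
    n_genes = arr.shape[0]
    # SD of log-ratio for every ordered pair via pairwise differences
    diffs = arr[:, None, :] - arr[None, :, :]  # genes x genes x samples
    sds = diffs.std(axis=2, ddof=1)
    m = (sds.sum(axis=1)) / (n_genes - 1)  # diagonal SD is 0
    return pd.Series(m, index=log2q.index)


def stepwise_ranking(q: QuantityMatrix) -> GenormResult:
    """Iteratively exclude the highest-M gene until two genes remain.

    Ties for the worst M are broken by removing the gene that appears
    later in input order (deterministic).  Records each gene's M at its
    exclusion step; the surviving pair share the final-pair M, which is
    the SD of their log ratio.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise InsufficientDataError("stepwise ranking needs >=3 genes")
    if len(q.samples) < 2:
        raise InsufficientDataError("stepwise ranking needs >=2 samples")

    log2q = _log2q(q)
    full_panel_m = _m_values(log2q).to_dict()

    remaining = list(genes)
    exclusion_order: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    while len(remaining) > 2:
        m = _m_values(log2q.loc[remaining])
        worst_m = m.max()
        # later-in-input-order tie-break
        worst = [g for g in remaining if m[g] == worst_m][-1]
        m_at_exclusion[worst] = float(m[worst])
        exclusion_order.append(worst)
        remaining.remove(worst)

    final_m = _m_values(log2q.loc[remaining])
    for g in remaining:
        m_at_exclusion[g] = float(final_m[g])

    # most-stable-first ordering: final pair (input order), then reverse exclusion
    stability_order = list(remaining) + exclusion_order[::-1]
    ranks = {g: 1 for g in remaining}
    for i, g in enumerate(exclusion_order[::-1]):
        ranks[g] = 3 + i

    v_series = _v_series(log2q, stability_order)
    unreliable = [g for g in genes if m_at_exclusion[g] > M_RELIABILITY_THRESHOLD]
    return GenormResult(
        m_values=m_at_exclusion,
        exclusion_order=exclusion_order,
        full_panel_m=full_panel_m,
        v_series=v_series,
        ranks=ranks,
        stability_order=stability_order,
        unreliable=unreliable,
    )


def normalization_factor(q: QuantityMatrix, gene_subset: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the subset's quantities."""
    subset = list(gene_subset)
    if not subset:
        raise InsufficientDataError("normalization factor needs >=1 gene")
    missing = [g for g in subset if g not in q.q_values.index]
    if missing:
        raise ValidationError(f"unknown genes: {missing}")
    return np.exp2(np.log2(q.q_values.loc[subset]).mean(axis=0))


def _v_series(log2q: pd.DataFrame, stability_order: Sequence[str]) -> dict[int, float]:
    out: dict[int, float] = {}
    for n in range(2, len(stability_order)):
        nf_n = log2q.loc[list(stability_order[:n])].mean(axis=0)
        nf_n1 = log2q.loc[list(stability_order[: n + 1])].mean(axis=0)
        out[n] = float((nf_n - nf_n1).std(ddof=1))
    return out


def pairwise_v(q: QuantityMatrix, ranking: GenormResult | Sequence[str]) -> dict[int, float]:
    """V_n/n+1 = SD across samples of log2(NF_n / NF_{n+1}) for n = 2..G-1.

    ``NF_n`` uses the n most stable genes of ``ranking``.
    """
    order = ranking.stability_order if isinstance(ranking, GenormResult) else list(ranking)
    if len(order) < 3:
        raise InsufficientDataError("pairwise V needs >=3 genes")
    return _v_series(_log2q(q, order), order)
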