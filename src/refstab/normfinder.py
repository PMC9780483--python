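"""Model-based stability analysis (variance decomposition).

Works on y = log2(Q).  Each sample is first centered across genes, which
absorbs sample-specific loading shifts.  With a group structure, each
gene's expression in each group is decomposed into an intragroup variance
(estimated with a small-panel correction for the centering step) and an
intergroup deviation d (the centered group mean minus the gene's grand
mean), which is shrunk toward zero by an empirical-Bayes factor.  The
per-gene stability value is the mean over groups of |shrunken d| plus the
standard error of d-hat; lower is more stable.  A two-gene combination is
scored the same way on the averaged deviations and halved averaged
variances, so opposite-sign group deviations cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .cp_io import QuantityMatrix
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "NormFinderResult",
    "normfinder_stability",
    "ungrouped_stability",
    "pair_stability",
    "best_two_gene_combination",
]


@dataclass
class NormFinderResult:
    """Per-gene stability values and the variance components behind them."""

    stability: pd.Series
    intragroup_var: pd.DataFrame | None
    intergroup_dev: pd.DataFrame | None
    raw_intergroup_dev: pd.DataFrame | None
    best_pair: tuple[str, str] | None
    best_pair_stability: float | None
    grouped: bool
    ranks: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.stability.index, key=lambda g: (self.ranks[g], g))
        df = pd.DataFrame(
            {
                "gene": genes,
                "stability": [self.stability[g] for g in genes],
                "rank": [self.ranks[g] for g in genes],
            }
        )
        if self.grouped and self.intergroup_dev is not None:
            for grp in self.intergroup_dev.columns:
                df[f"d_{grp}"] = [self.intergroup_dev.at[g, grp] for g in genes]
                df[f"sigma2_{grp}"] = [self.intragroup_var.at[g, grp] for g in genes]
        return df


def _competition_ranks(scores: pd.Series) -> dict[str, int]:
    # ascending-better competition ranks (ties share the minimum rank)
    vals = scores.to_numpy()
    return {
        g: int(1 + np.sum(vals < scores[g]))
        for g in scores.index
    }


def _centered_log2(q: QuantityMatrix) -> pd.DataFrame:
    y = q.log2()
    return y.sub(y.mean(axis=0), axis=1)


def _group_columns(q: QuantityMatrix, groups: Mapping[str, str]) -> dict[str, list[str]]:
    missing = [s for s in q.samples if s not in groups]
    if missing:
        raise ValidationError(f"samples without group label: {missing}")
    cols: dict[str, list[str]] = {}
    for s in q.samples:
        cols.setdefault(groups[s], []).append(s)
    return cols


def _corrected_intragroup_var(resid: pd.DataFrame, n: int) -> pd.Series:
    """Unbiased per-gene variance from two-way-centered residuals.

    Centering each sample across G genes biases the naive estimator:
    E[svar_i] = sigma_i^2 (G-2)/G + sigma_bar^2 / G.  Inverting gives the
    correction below; negative estimates are clamped to zero.
    """
    G = resid.shape[0]
    if G < 3:
        raise InsufficientDataError("variance correction needs >=3 genes")
    svar = (resid**2).sum(axis=1) / (n - 1)
    corrected = (svar - svar.mean() / (G - 1)) * G / (G - 2)
    return corrected.clip(lower=0.0)


def ungrouped_stability(q: QuantityMatrix) -> NormFinderResult:
    """Single-group stability: the corrected SD of centered residuals."""
    if len(q.genes) < 3:
        raise InsufficientDataError("need >=3 genes")
    if len(q.samples) < 3:
        raise InsufficientDataError("need >=3 samples")
    y = _centered_log2(q)
    resid = y.sub(y.mean(axis=1), axis=0)
    var = _corrected_intragroup_var(resid, len(q.samples))
    stability = np.sqrt(var)
    return NormFinderResult(
        stability=stability,
        intragroup_var=None,
        intergroup_dev=None,
        raw_intergroup_dev=None,
        best_pair=None,
        best_pair_stability=None,
        grouped=False,
        ranks=_competition_ranks(stability),
    )


def _decompose(
    q: QuantityMatrix, groups: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Return (sigma2, d_raw, d_shrunk, n_per_group), genes x groups."""
    if len(q.genes) < 3:
        raise InsufficientDataError("need >=3 genes")
    cols = _group_columns(q, groups)
    if len(cols) < 2:
        raise InsufficientDataError(
            "grouped analysis needs >=2 groups; use ungrouped_stability"
        )
    for grp, ss in cols.items():
        if len(ss) < 2:
            raise InsufficientDataError(f"group {grp!r} has <2 samples")

    y = _centered_log2(q)
    grand = y.mean(axis=1)
    group_names = list(cols)
    n_g = pd.Series({g: len(cols[g]) for g in group_names}, dtype=float)

    sigma2 = pd.DataFrame(index=y.index, columns=group_names, dtype=float)
    d_raw = pd.DataFrame(index=y.index, columns=group_names, dtype=float)
    for grp in group_names:
        sub = y[cols[grp]]
        group_mean = sub.mean(axis=1)
        resid = sub.sub(group_mean, axis=0)
        sigma2[grp] = _corrected_intragroup_var(resid, len(cols[grp]))
        d_raw[grp] = group_mean - grand

    G, K = d_raw.shape
    gamma2 = float((d_raw**2).to_numpy().sum() / ((G - 1) * (K - 1)))
    sampling_var = sigma2.div(n_g, axis=1)
    shrink = gamma2 / (gamma2 + sampling_var) if gamma2 > 0 else 0.0 * sampling_var
    d_shrunk = d_raw * shrink
    return sigma2, d_raw, d_shrunk, n_g


def normfinder_stability(
    q: QuantityMatrix, groups: Mapping[str, str] | None = None
) -> NormFinderResult:
    """Grouped stability values; falls back to ungrouped for one group."""
    if groups is None:
        groups = q.groups
    if groups is None or len(set(groups.get(s) for s in q.samples)) < 2:
        return ungrouped_stability(q)

    sigma2, d_raw, d_shrunk, n_g = _decompose(q, groups)
    se = np.sqrt(sigma2.div(n_g, axis=1))
    stability = (d_shrunk.abs() + se).mean(axis=1)

    pair, pair_stab = _best_pair(sigma2, d_shrunk, n_g)
    return NormFinderResult(
        stability=stability,
        intragroup_var=sigma2,
        intergroup_dev=d_shrunk,
        raw_intergroup_dev=d_raw,
        best_pair=pair,
        best_pair_stability=pair_stab,
        grouped=True,
        ranks=_competition_ranks(stability),
    )


def _pair_stability(
    sigma2: pd.DataFrame, d_shrunk: pd.DataFrame, n_g: pd.Series, a: str, b: str
) -> float:
    d_pair = (d_shrunk.loc[a] + d_shrunk.loc[b]) / 2.0
    var_pair = (sigma2.loc[a] + sigma2.loc[b]) / 2.0 / 2.0  # average, then /2 genes
    se_pair = np.sqrt(var_pair / n_g)
    return float((d_pair.abs() + se_pair).mean())


def _best_pair(
    sigma2: pd.DataFrame, d_shrunk: pd.DataFrame, n_g: pd.Series
) -> tuple[tuple[str, str], float]:
    best, best_val = None, np.inf
    for a, b in combinations(sigma2.index, 2):
        val = _pair_stability(sigma2, d_shrunk, n_g, a, b)
        if val < best_val:
            best, best_val = (a, b), val
    return best, best_val


def pair_stability(
    q: QuantityMatrix, groups: Mapping[str, str], gene_a: str, gene_b: str
) -> float:
    """Combined stability of one candidate pair (lower is better)."""
    sigma2, _, d_shrunk, n_g = _decompose(q, groups)
    return _pair_stability(sigma2, d_shrunk, n_g, gene_a, gene_b)


def best_two_gene_combination(
    q: QuantityMatrix, groups: Mapping[str, str] | None = None
) -> tuple[tuple[str, str], float]:
    """Exhaustive search for the pair minimizing combined stability."""
    if groups is None:
        groups = q.groups
    if groups is None or len(set(groups.get(s) for s in q.samples)) < 2:
        raise InsufficientDataError("two-gene combination requires >=2 groups")
    sigma2, _, d_shrunk, n_g = _decompose(q, groups)
    return _best_pair(sigma2, d_shrunk, n_g)
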