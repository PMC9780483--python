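"""BestKeeper-style analysis on raw Cp values.

Unlike the other two algorithms this one operates on the Cp scale, not on
relative quantities: genes are described by their Cp dispersion (SD > 1
cycle flags a gene as unreliable), an index is built as the per-sample
geometric mean of the retained genes' Cp, and analyzed genes are ranked
by descending Pearson correlation with that index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cp_io import CpMatrix
from .errors import ConfigurationError, InsufficientDataError, ValidationError

#: Genes with Cp standard deviation above this are flagged unreliable.
SD_THRESHOLD = 1.0

#: Compatibility cap on analyzable genes (the classic tool's limit).
DEFAULT_MAX_GENES = 10


@dataclass
class BestKeeperResult:
    descriptives: pd.DataFrame
    sd_flagged: list[str]
    pre_excluded: list[str]
    index: pd.Series
    correlations: pd.DataFrame  # columns r, p; NaN for excluded genes
    ranks: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.descriptives.index, key=lambda g: (self.ranks[g], g))
        d = self.descriptives
        return pd.DataFrame(
            {
                "gene": genes,
                "n": [d.at[g, "n"] for g in genes],
                "geo_mean_cp": [d.at[g, "geo_mean_cp"] for g in genes],
                "ar_mean_cp": [d.at[g, "ar_mean_cp"] for g in genes],
                "min_cp": [d.at[g, "min_cp"] for g in genes],
                "max_cp": [d.at[g, "max_cp"] for g in genes],
                "sd_cp": [d.at[g, "sd_cp"] for g in genes],
                "cv_pct": [d.at[g, "cv_pct"] for g in genes],
                "sd_flag": [g in self.sd_flagged for g in genes],
                "r": [self.correlations["r"].get(g, np.nan) for g in genes],
                "p": [self.correlations["p"].get(g, np.nan) for g in genes],
                "rank": [self.ranks[g] for g in genes],
            }
        )


def descriptive_stats(cp: CpMatrix) -> pd.DataFrame:
    """Per-gene Cp descriptives: means, extremes, SD (n-1) and CV%."""
    if cp.n_samples < 2:
        raise InsufficientDataError("descriptive stats need >=2 samples")
    v = cp.values
    ar_mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "n": v.shape[1],
            "geo_mean_cp": np.exp(np.log(v).mean(axis=1)),
            "ar_mean_cp": ar_mean,
            "min_cp": v.min(axis=1),
            "max_cp": v.max(axis=1),
            "sd_cp": sd,
            "cv_pct": 100.0 * sd / ar_mean,
        }
    )


def bestkeeper_index(cp: CpMatrix, retained_genes: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the retained genes' Cp values."""
    retained = list(retained_genes)
    if len(retained) < 2:
        raise InsufficientDataError("index needs >=2 retained genes")
    missing = [g for g in retained if g not in cp.values.index]
    if missing:
        raise ValidationError(f"unknown genes: {missing}")
    return np.exp(np.log(cp.values.loc[retained]).mean(axis=0))


def correlate_with_index(cp: CpMatrix, index: pd.Series) -> pd.DataFrame:
    """Pearson r (and two-sided p, n-2 df) of each gene's Cp vs the index.

    Zero-variance genes get NaN r with a diagnostic column.
    """
    if cp.n_samples < 3:
        raise InsufficientDataError("correlation needs >=3 samples")
    idx = index.loc[cp.samples].to_numpy(dtype=float)
    rows = {}
    for g in cp.genes:
        x = cp.values.loc[g].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(idx) == 0:
            rows[g] = (np.nan, np.nan, "zero variance")
            continue
        r, p = stats.pearsonr(x, idx)
        rows[g] = (float(r), float(p), "")
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["r", "p", "note"]
    ).loc[cp.genes]


def run_bestkeeper(
    cp: CpMatrix,
    max_genes: int = DEFAULT_MAX_GENES,
    pre_exclude: Sequence[str] | None = None,
    exclusion_rank_scores: dict[str, float] | None = None,
) -> BestKeeperResult:
    """Full pipeline: descriptives -> SD flag -> index -> correlation -> rank.

    Genes in ``pre_exclude`` are removed before analysis (required when the
    panel exceeds ``max_genes``); they are ranked after all analyzed genes,
    ordered by ``exclusion_rank_scores`` (e.g. their M-values from the
    pairwise analysis) when given, else by input order.  SD-flagged genes
    stay out of the index but still receive an r value.
    """
    pre_excluded = list(pre_exclude or [])
    missing = [g for g in pre_excluded if g not in cp.values.index]
    if missing:
        raise ValidationError(f"pre-excluded genes not in panel: {missing}")
    analyzed_genes = [g for g in cp.genes if g not in pre_excluded]
    if len(analyzed_genes) > max_genes:
        raise ConfigurationError(
            f"{len(analyzed_genes)} genes exceed the {max_genes}-gene limit; "
            "supply a pre-exclusion list or raise max_genes"
        )

    descriptives = descriptive_stats(cp)
    analyzed = cp.subset_genes(analyzed_genes)
    sd_flagged = [
        g for g in analyzed_genes if descriptives.at[g, "sd_cp"] > SD_THRESHOLD
    ]
    retained = [g for g in analyzed_genes if g not in sd_flagged]
    if len(retained) < 2:
        raise InsufficientDataError(
            "fewer than 2 genes pass the SD threshold; no index can be built"
        )
    index = bestkeeper_index(cp, retained)
    correlations = correlate_with_index(analyzed, index)

    # descending-r competition ranks over analyzed genes with a valid r
    scored = correlations["r"].dropna()
    ranks: dict[str, int] = {
        g: int(1 + np.sum(scored.to_numpy() > scored[g])) for g in scored.index
    }
    next_rank = len(scored) + 1
    unscored = [g for g in analyzed_genes if g not in scored.index] + pre_excluded
    if exclusion_rank_scores is not None:
        unscored.sort(key=lambda g: exclusion_rank_scores.get(g, np.inf))
    for g in unscored:
        ranks[g] = next_rank
        next_rank += 1
    return BestKeeperResult(
        descriptives=descriptives,
        sd_flagged=sd_flagged,
        pre_excluded=pre_excluded,
        index=index,
        correlations=correlations,
        ranks=ranks,
    )
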