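"""Cp data model, delimited-text I/O, replicate handling, and the
Cp -> relative-quantity / amplification-efficiency computations.

Quantification-cycle (Cp/Cq) tables come in two layouts:

* ``wide`` — first column gene identifiers, remaining columns one per
  sample; one Cp per cell.
* ``long`` — columns ``sample, gene, replicate, cp``; one well per row.

All downstream stability algorithms consume :class:`CpMatrix` (raw
cycles) or :class:`QuantityMatrix` (relative quantities
``Q = E**-dCp`` against a per-gene calibrator).
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    FitError,
    FormatError,
    InsufficientDataError,
    MissingDataError,
    ParameterError,
    ValidationError,
)

#: Open interval of plausible quantification cycles.
CP_BOUNDS = (0.0, 45.0)

#: Admissible amplification efficiencies (fold increase per cycle).
EFFICIENCY_BOUNDS = (1.0, 2.2)


def _check_cp_value(value: float, gene: str, sample: str) -> float:
    try:
        cp = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"non-numeric Cp {value!r} for gene {gene!r}, sample {sample!r}"
        ) from None
    if not math.isfinite(cp) or not (CP_BOUNDS[0] < cp < CP_BOUNDS[1]):
        raise ValidationError(
            f"Cp {cp!r} for gene {gene!r}, sample {sample!r} outside "
            f"open interval {CP_BOUNDS}"
        )
    return cp


@dataclass
class CpMatrix:
    """Genes x samples quantification-cycle values.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    replicate_map
        Optional mapping ``sample -> (biological sample, replicate index)``
        describing technical-replicate structure of the columns.
    groups
        Optional mapping ``sample -> group label`` (e.g. cell line).
    """

    values: pd.DataFrame
    replicate_map: dict[str, tuple[str, int]] | None = None
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        arr = df.to_numpy(dtype=float)
        bad = ~np.isfinite(arr) | (arr <= CP_BOUNDS[0]) | (arr >= CP_BOUNDS[1])
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"Cp {df.iat[g, s]!r} for gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r} outside open interval {CP_BOUNDS}"
            )
        self.values = df.astype(float)
        if self.groups is not None:
            missing = [s for s in df.columns if s not in self.groups]
            if missing:
                raise ValidationError(f"samples without group label: {missing}")
        if self.replicate_map is not None:
            missing = [s for s in df.columns if s not in self.replicate_map]
            if missing:
                raise ValidationError(f"samples without replicate entry: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def group_of(self, sample: str) -> str:
        if self.groups is None:
            raise MissingDataError("CpMatrix has no group mapping")
        return self.groups[sample]

    def subset_genes(self, genes: Sequence[str]) -> "CpMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"unknown genes: {missing}")
        return CpMatrix(
            self.values.loc[list(genes)],
            replicate_map=dict(self.replicate_map) if self.replicate_map else None,
            groups=dict(self.groups) if self.groups else None,
        )


@dataclass
class QuantityMatrix:
    """Relative quantities ``Q`` per gene x sample (dimensionless).

    ``Q[g, s] = E_g ** -(Cp[g, s] - calibrator_g)``; with the per-gene
    minimum calibrator every gene's maximum Q equals 1.
    """

    q_values: pd.DataFrame
    calibrator: pd.Series
    efficiencies: pd.Series
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        arr = self.q_values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError("relative quantities must be finite and > 0")

    @property
    def genes(self) -> list[str]:
        return list(self.q_values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q_values.columns)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.q_values)


@dataclass
class EfficiencyEstimate:
    """Standard-curve fit of Cp against log10(relative concentration)."""

    gene: str
    slope: float
    efficiency: float
    r_squared: float
    n_points: int
    intercept: float = 0.0
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading / writing


def _open(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def _sep_for(source, sep: str | None) -> str:
    if sep is not None:
        return sep
    name = getattr(source, "name", source if isinstance(source, (str, os.PathLike)) else "")
    return "," if str(name).lower().endswith(".csv") else "\t"


def read_cp_table(
    source,
    layout: str = "wide",
    sep: str | None = None,
    groups: Mapping[str, str] | None = None,
) -> CpMatrix:
    """Read a delimited Cp table into a :class:`CpMatrix`.

    ``layout='wide'``: first column gene names, remaining columns samples.
    ``layout='long'``: columns ``sample, gene, replicate, cp``; the
    replicate structure is preserved in ``replicate_map`` (well columns are
    named ``<sample>.<replicate>``).

    Gene and sample ordering is preserved from the input.
    """
    sep = _sep_for(source, sep)
    handle, close = _open(source)
    try:
        if layout == "wide":
            # round_trip parsing keeps write->read bit-identical
            df = pd.read_csv(handle, sep=sep, dtype={0: str},
                             float_precision="round_trip")
        elif layout == "long":
            df = pd.read_csv(handle, sep=sep, float_precision="round_trip")
        else:
            raise FormatError(f"unknown layout {layout!r}")
    finally:
        if close:
            handle.close()

    if layout == "wide":
        df = df.set_index(df.columns[0])
        df.index.name = "gene"
        if df.index.has_duplicates:
            raise FormatError(
                f"duplicate gene identifiers: "
                f"{df.index[df.index.duplicated()].unique().tolist()}"
            )
        for gene in df.index:
            for sample in df.columns:
                _check_cp_value(df.at[gene, sample], gene, sample)
        cp = CpMatrix(df.astype(float), groups=dict(groups) if groups else None)
        return cp

    required = ["sample", "gene", "replicate", "cp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"long layout requires columns {required}; missing {missing}")
    key = df[["sample", "gene", "replicate"]].astype(str)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise FormatError(f"duplicate (sample, gene, replicate) triple: {dup}")

    genes = list(dict.fromkeys(df["gene"].astype(str)))
    wells: list[str] = []
    replicate_map: dict[str, tuple[str, int]] = {}
    for sample, rep in dict.fromkeys(
        zip(df["sample"].astype(str), df["replicate"])
    ):
        well = f"{sample}.{rep}"
        if well in replicate_map:
            raise FormatError(f"duplicate well {well!r}")
        wells.append(well)
        replicate_map[well] = (sample, int(rep))

    wide = pd.DataFrame(np.nan, index=genes, columns=wells)
    for row in df.itertuples(index=False):
        sample, gene = str(row.sample), str(row.gene)
        well = f"{sample}.{row.replicate}"
        wide.at[gene, well] = _check_cp_value(row.cp, gene, sample)
    if wide.isna().any().any():
        gene = wide.index[wide.isna().any(axis=1)][0]
        raise MissingDataError(f"gene {gene!r} missing Cp for some wells")
    wide.index.name = "gene"
    well_groups = None
    if groups:
        well_groups = {w: groups[bs] for w, (bs, _) in replicate_map.items()}
    return CpMatrix(wide, replicate_map=replicate_map, groups=well_groups)


def write_cp_table(cp: CpMatrix, path, layout: str = "wide", sep: str | None = None) -> None:
    """Write a CpMatrix back to delimited text (round-trips bit-identically)."""
    sep = _sep_for(path, sep)
    if layout == "wide":
        df = cp.values.copy()
        df.index.name = "gene"
        df.to_csv(path, sep=sep)
    elif layout == "long":
        rep = cp.replicate_map or {s: (s, 1) for s in cp.samples}
        rows = [
            {"sample": rep[s][0], "gene": g, "replicate": rep[s][1], "cp": cp.values.at[g, s]}
            for s in cp.samples
            for g in cp.genes
        ]
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    else:
        raise FormatError(f"unknown layout {layout!r}")


def read_group_map(source, sep: str | None = None) -> dict[str, str]:
    """Read a two-column (sample, group) mapping."""
    sep = _sep_for(source, sep)
    df = pd.read_csv(source, sep=sep)
    if df.shape[1] < 2:
        raise FormatError("group mapping needs two columns (sample, group)")
    samples = df.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        raise FormatError(
            f"duplicate samples in group map: {samples[samples.duplicated()].tolist()}"
        )
    return dict(zip(samples, df.iloc[:, 1].astype(str)))


def read_efficiency_table(source, sep: str | None = None) -> dict[str, float]:
    """Read a two-column (gene, efficiency) table."""
    sep = _sep_for(source, sep)
    df = pd.read_csv(source, sep=sep)
    if df.shape[1] < 2:
        raise FormatError("efficiency table needs two columns (gene, efficiency)")
    genes = df.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        raise FormatError("duplicate genes in efficiency table")
    effs = {g: float(e) for g, e in zip(genes, df.iloc[:, 1])}
    for g, e in effs.items():
        _check_efficiency(e, g)
    return effs


# ---------------------------------------------------------------------------
# replicate collapsing and the quantity transform


def collapse_replicates(cp: CpMatrix, method: str = "mean") -> CpMatrix:
    """Average technical replicates to one Cp per gene x biological sample.

    Averaging Cp arithmetically equals taking the geometric mean of the
    corresponding quantities, the conventional qPCR aggregation.
    """
    if cp.replicate_map is None:
        raise MissingDataError("CpMatrix has no replicate_map to collapse")
    if method != "mean":
        raise ParameterError(f"unsupported collapse method {method!r}")

    bio_order: list[str] = list(
        dict.fromkeys(cp.replicate_map[s][0] for s in cp.samples)
    )
    cols = {}
    for bio in bio_order:
        wells = [s for s in cp.samples if cp.replicate_map[s][0] == bio]
        if not wells:
            raise MissingDataError(f"biological sample {bio!r} has zero replicates")
        cols[bio] = cp.values[wells].mean(axis=1)
    collapsed = pd.DataFrame(cols)[bio_order]
    collapsed.index.name = "gene"
    groups = None
    if cp.groups is not None:
        groups = {}
        for s in cp.samples:
            bio = cp.replicate_map[s][0]
            label = cp.groups[s]
            if groups.setdefault(bio, label) != label:
                raise ValidationError(
                    f"replicates of biological sample {bio!r} disagree on group"
                )
    return CpMatrix(collapsed, replicate_map=None, groups=groups)


def _check_efficiency(e: float, gene: str) -> float:
    e = float(e)
    if not math.isfinite(e) or not (EFFICIENCY_BOUNDS[0] < e <= EFFICIENCY_BOUNDS[1]):
        raise ParameterError(
            f"amplification efficiency {e!r} for gene {gene!r} outside "
            f"({EFFICIENCY_BOUNDS[0]}, {EFFICIENCY_BOUNDS[1]}]"
        )
    return e


def to_relative_quantities(
    cp: CpMatrix,
    efficiencies: float | Mapping[str, float] = 2.0,
    calibrator: str = "per_gene_min",
) -> QuantityMatrix:
    """Transform Cp values to relative quantities ``Q = E**-dCp``.

    ``dCp`` is taken against the per-gene minimum Cp across samples, so
    every Q lies in (0, 1] and each gene's maximum Q is exactly 1.  The
    default efficiency is perfect doubling (E = 2) for every gene; a
    per-gene mapping may be supplied instead.
    """
    if calibrator != "per_gene_min":
        raise ParameterError(f"unknown calibrator {calibrator!r}")
    if isinstance(efficiencies, Mapping):
        missing = [g for g in cp.genes if g not in efficiencies]
        if missing:
            raise ParameterError(f"genes without efficiency: {missing}")
        eff = pd.Series({g: _check_efficiency(efficiencies[g], g) for g in cp.genes})
    else:
        e = _check_efficiency(float(efficiencies), "<all>")
        eff = pd.Series(e, index=cp.genes, dtype=float)
    eff = eff.loc[cp.genes]

    cal = cp.values.min(axis=1)
    dcp = cp.values.sub(cal, axis=0)
    q = pd.DataFrame(
        np.power(eff.to_numpy()[:, None], -dcp.to_numpy()),
        index=cp.values.index,
        columns=cp.values.columns,
    )
    return QuantityMatrix(
        q_values=q,
        calibrator=cal,
        efficiencies=eff,
        groups=dict(cp.groups) if cp.groups else None,
    )


# ---------------------------------------------------------------------------
# standard-curve efficiency


def estimate_efficiency(
    dilutions: Sequence[tuple[float, float]],
    gene: str = "",
) -> EfficiencyEstimate:
    """Fit a dilution standard curve and derive amplification efficiency.

    ``dilutions`` are ``(relative concentration, Cp)`` pairs.  Ordinary
    least squares of Cp on log10(concentration) yields the slope; the
    efficiency is ``10**(-1/slope)``.  Callers enforcing a calibration
    quality gate should check ``r_squared`` (conventionally > 0.99).
    """
    pts = [(float(c), float(cp)) for c, cp in dilutions]
    if len(pts) < 3:
        raise FitError(f"need >=3 dilution points, got {len(pts)}")
    conc = np.array([c for c, _ in pts])
    cps = np.array([cp for _, cp in pts])
    if np.any(conc <= 0):
        raise FitError("relative concentrations must be > 0")
    x = np.log10(conc)
    if len(np.unique(x)) < 3:
        raise FitError("need >=3 distinct concentrations")
    if np.ptp(x) == 0:
        raise FitError("zero variance in concentration")

    fit = stats.linregress(x, cps)
    slope = float(fit.slope)
    warnings = []
    if np.ptp(x) < 2:
        warnings.append("dilution series spans < 2 orders of magnitude")
    if slope >= 0:
        warnings.append(f"non-negative slope {slope:.4g}: not a valid dilution series")
        efficiency = float("nan")
    else:
        efficiency = float(10.0 ** (-1.0 / slope))
    return EfficiencyEstimate(
        gene=gene,
        slope=slope,
        efficiency=efficiency,
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(pts),
        intercept=float(fit.intercept),
        warnings=warnings,
    )
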