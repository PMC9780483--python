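"""Seeded generator of grouped Cp matrices with known stability ground truth.

The generative model mirrors the decomposition the stability algorithms
assume: Cp is a per-gene baseline, plus a per-gene-x-group offset, plus a
per-sample loading shift shared by all genes of that sample, plus
per-gene stability noise, plus independent technical-replicate jitter —
all noise normal on the Cp scale (log-normal quantities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cp_io import CpMatrix
from .errors import ConfigurationError

PANEL_12 = [
    "G01", "G02", "G03", "G04", "G05", "G06",
    "G07", "G08", "G09", "G10", "G11", "G12",
]


@dataclass
class SyntheticTruth:
    """Generator parameters defining which genes are stable by construction."""

    genes: list[str]
    baselines: dict[str, float]  # cycles
    noise_sd: dict[str, float]  # per-gene stability noise, cycles
    group_offsets: dict[str, dict[str, float]]  # gene -> group -> cycles
    loading_sd: float  # per-sample shared shift, cycles
    replicate_sd: float  # technical jitter, cycles
    groups: list[str] = field(default_factory=lambda: ["g1", "g2", "g3", "g4"])
    samples_per_group: int = 6
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError("duplicate gene names")
        for g in self.genes:
            b = self.baselines.get(g)
            if b is None or not (5.0 < b < 40.0):
                raise ConfigurationError(f"baseline for {g!r} must be in (5, 40)")
            if self.noise_sd.get(g, -1.0) < 0:
                raise ConfigurationError(f"noise SD for {g!r} must be >= 0")
        if self.loading_sd < 0 or self.replicate_sd < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.samples_per_group < 1 or self.replicates < 1:
            raise ConfigurationError("need >=1 sample per group and >=1 replicate")

    def offset(self, gene: str, group: str) -> float:
        return self.group_offsets.get(gene, {}).get(group, 0.0)

    @property
    def most_stable_gene(self) -> str:
        """The designed winner: uniquely minimal noise SD and no offsets."""
        min_sd = min(self.noise_sd[g] for g in self.genes)
        winners = [
            g
            for g in self.genes
            if self.noise_sd[g] == min_sd
            and all(self.offset(g, grp) == 0.0 for grp in self.groups)
        ]
        if len(winners) != 1:
            raise ConfigurationError(
                f"designed most-stable gene is not unique: {winners}"
            )
        return winners[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "baselines": self.baselines,
                "noise_sd": self.noise_sd,
                "group_offsets": self.group_offsets,
                "loading_sd": self.loading_sd,
                "replicate_sd": self.replicate_sd,
                "groups": self.groups,
                "samples_per_group": self.samples_per_group,
                "replicates": self.replicates,
                "seed": self.seed,
            },
            indent=2,
        )


def simulate_cp(truth: SyntheticTruth) -> tuple[CpMatrix, SyntheticTruth]:
    """Draw one grouped Cp matrix; bit-reproducible for a given seed.

    Cp[g, well(s, r)] = baseline_g + offset_{g, group(s)} + loading_s
                        + noise_{g, s} + jitter_{g, s, r}
    """
    rng = np.random.default_rng(truth.seed)
    genes = truth.genes
    wells: list[str] = []
    groups_map: dict[str, str] = {}
    replicate_map: dict[str, tuple[str, int]] = {}
    bio_samples: list[tuple[str, str]] = []  # (bio sample, group)
    for grp in truth.groups:
        for i in range(1, truth.samples_per_group + 1):
            bio = f"{grp}_s{i}"
            bio_samples.append((bio, grp))
            for r in range(1, truth.replicates + 1):
                well = f"{bio}_r{r}" if truth.replicates > 1 else bio
                wells.append(well)
                groups_map[well] = grp
                replicate_map[well] = (bio, r)

    n_bio = len(bio_samples)
    loading = rng.normal(0.0, truth.loading_sd, size=n_bio)
    noise = rng.normal(
        0.0,
        np.array([truth.noise_sd[g] for g in genes])[:, None],
        size=(len(genes), n_bio),
    )
    jitter = rng.normal(
        0.0, truth.replicate_sd, size=(len(genes), n_bio, truth.replicates)
    )

    values = np.empty((len(genes), len(wells)))
    col = 0
    for b, (bio, grp) in enumerate(bio_samples):
        base = (
            np.array([truth.baselines[g] + truth.offset(g, grp) for g in genes])
            + loading[b]
            + noise[:, b]
        )
        for r in range(truth.replicates):
            values[:, col] = base + jitter[:, b, r]
            col += 1

    df = pd.DataFrame(values, index=genes, columns=wells)
    df.index.name = "gene"
    cp = CpMatrix(
        df,
        replicate_map=replicate_map if truth.replicates > 1 else None,
        groups=groups_map,
    )
    return cp, truth


def _flat(genes, value) -> dict[str, float]:
    return {g: float(value) for g in genes}


def default_presets(seed: int = 0) -> dict[str, SyntheticTruth]:
    """Named generator configurations.

    * ``clean`` — one designed stable gene (noise 0.05) among noisy
      (0.5) companions, no group effects.
    * ``grouped-bias`` — like clean, but one gene carries a 2-cycle
      offset in a single group.
    * ``paper-like`` — 12-gene panel whose baselines span ~15.7-30.7
      cycles with moderate, heterogeneous noise.
    """
    genes = PANEL_12
    baselines = {g: float(b) for g, b in zip(genes, np.linspace(16.0, 31.0, 12))}

    # loading SD kept moderate so total per-gene Cp dispersion stays below
    # the Cp-scale SD > 1 reliability flag for typical draws
    clean_noise = _flat(genes, 0.5)
    clean_noise["G01"] = 0.05
    clean = SyntheticTruth(
        genes=list(genes),
        baselines=dict(baselines),
        noise_sd=clean_noise,
        group_offsets={},
        loading_sd=0.5,
        replicate_sd=0.1,
        seed=seed,
    )

    biased = SyntheticTruth(
        genes=list(genes),
        baselines=dict(baselines),
        noise_sd=dict(clean_noise),
        group_offsets={"G07": {"g2": 2.0}},
        loading_sd=0.5,
        replicate_sd=0.1,
        seed=seed,
    )

    # 12-gene panel emulating the observed Cp spread: ribosomal RNA lowest
    # (~15.7 cycles), a low-abundance enzyme highest (~30.7 cycles)
    paper_genes = [
        "18S", "GAPDH", "ACTB", "B2M", "PPIA", "RPL-29",
        "TBP", "HPRT-1", "PUM1", "ALAS1", "GUSB", "PBGD",
    ]
    paper_baselines = {
        "18S": 15.7, "GAPDH": 18.2, "ACTB": 18.9, "B2M": 20.1,
        "PPIA": 20.8, "RPL-29": 21.6, "TBP": 25.4, "HPRT-1": 26.2,
        "PUM1": 26.9, "ALAS1": 27.8, "GUSB": 28.9, "PBGD": 30.7,
    }
    rng = np.random.default_rng(seed)
    paper_noise = {
        g: float(sd) for g, sd in zip(paper_genes, rng.uniform(0.1, 0.6, 12))
    }
    stable = min(paper_noise, key=paper_noise.get)
    paper_noise[stable] = 0.05  # ensure a unique designed winner
    paper_like = SyntheticTruth(
        genes=list(paper_genes),
        baselines=paper_baselines,
        noise_sd=paper_noise,
        group_offsets={},
        loading_sd=0.5,
        replicate_sd=0.1,
        groups=["HOS", "Saos-2", "MG-63", "U2OS"],
        seed=seed,
    )
    return {"clean": clean, "grouped-bias": biased, "paper-like": paper_like}
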