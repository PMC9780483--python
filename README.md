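# refstab

Reference-gene stability analysis for RT-qPCR quantification-cycle (Cp/Cq)
data. Given a genes × samples Cp table, refstab runs the three classic
candidate-reference-gene stability algorithms and aggregates their
rankings into a consensus ordering:

* **Pairwise-variation ranking** (geNorm-style): per-gene M-values
  (mean SD of pairwise log2 expression ratios), stepwise exclusion of
  the least stable gene, normalization factors, and the V_n/n+1 series
  for choosing how many reference genes to use (0.15 cut-off; M > 1.5
  flags an unreliable gene).
* **Model-based variance decomposition** (NormFinder-style): per-gene
  intragroup variances with a small-panel correction, shrunken
  intergroup deviations, per-gene stability values, and the best
  two-gene combination. Falls back to an ungrouped analysis when no
  group structure is available.
* **Cp-scale dispersion/correlation analysis** (BestKeeper-style):
  per-gene descriptive statistics on raw Cp, the SD > 1 cycle
  reliability flag, a per-sample geometric-mean index, and ranking by
  Pearson correlation with the index (10-gene compatibility cap,
  overridable).
* **Consensus**: per-method competition ranks (ties share the minimum
  rank: 1, 1, 3) aggregated by the geometric mean of each gene's rank
  numbers; lower geometric mean = more stably expressed.

Supporting pieces: the Cp → relative-quantity transform
(`Q = E^-ΔCp` against the per-gene minimum Cp), standard-curve
amplification-efficiency estimation (`E = 10^(-1/slope)`), technical
replicate collapsing, and a seeded synthetic-data generator with known
stability ground truth.

## CLI

```sh
# generate a synthetic grouped Cp table with a truth sidecar
refstab simulate --preset clean --seed 1 --out sim/

# full workflow: all three methods + consensus report bundle
refstab run --cp-table sim/cp.tsv --layout long --groups sim/groups.tsv \
            --out results/

# single stages
refstab genorm --cp-table sim/cp.tsv --layout long --out results-genorm/
refstab consensus --scores scores.json --out consensus.tsv
```

`refstab run` accepts a YAML config (`--config run.yaml`) whose keys
mirror the flags; flags override the file. The report bundle contains
per-method TSVs, a consensus TSV (per-method scores, ranks, geometric
means, final ranking), a JSON manifest, and a plain-text summary naming
the most stable gene and the best two-gene combination. The manifest is
written last, so its absence marks an incomplete run.

Input formats: wide tables (first column gene, one column per sample) or
long tables (`sample, gene, replicate, cp`); TSV/CSV autodetected by
extension. Group mappings and per-gene efficiencies are two-column TSVs.
Cp values must lie in (0, 45); technical replicates are averaged on the
Cp scale before the quantity transform.

## Library use

```python
from refstab import (
    read_cp_table, collapse_replicates, to_relative_quantities,
    stepwise_ranking, normfinder_stability, run_bestkeeper,
    MethodScores, aggregate,
)

cp = collapse_replicates(read_cp_table("cp.tsv", layout="long"))
q = to_relative_quantities(cp)            # E = 2 by default
gn = stepwise_ranking(q)                  # M-values, V series
nf = normfinder_stability(q, cp.groups)   # stability values, best pair
bk = run_bestkeeper(cp, max_genes=12)     # SD flags, index, r
ranking = aggregate([
    MethodScores("genorm", gn.m_values),
    MethodScores("normfinder", nf.stability.to_dict()),
    MethodScores("bestkeeper", bk.correlations["r"].to_dict(),
                 "descending_better", missing_order=gn.m_values),
])
print(ranking.final_order)
```
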