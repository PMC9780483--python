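"""Independent brute-force reference implementations used as test arbiters.

Everything here is deliberately written with plain-Python loops on nested
dicts/lists — no pandas, no shared code with the package under test —
and recomputes each quantity from its definition at every step.
"""

import math
from itertools import combinations


def sample_sd(xs):
    n = len(xs)
    m = sum(xs) / n
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))


def mean(xs):
    return sum(xs) / len(xs)


# --- geNorm ---------------------------------------------------------------


def pairwise_sd(q_j, q_k):
    """SD of log2(Q_j / Q_k) across samples."""
    return sample_sd([math.log2(a / b) for a, b in zip(q_j, q_k)])


def m_value(qmat, gene, gene_set):
    """qmat: dict gene -> list of quantities (same sample order)."""
    partners = [g for g in gene_set if g != gene]
    return mean([pairwise_sd(qmat[gene], qmat[g]) for g in partners])


def stepwise(qmat, gene_order):
    """Full stepwise exclusion; ties broken by later input position."""
    remaining = list(gene_order)
    exclusion, m_at_exclusion = [], {}
    while len(remaining) > 2:
        ms = {g: m_value(qmat, g, remaining) for g in remaining}
        worst_m = max(ms.values())
        worst = [g for g in remaining if ms[g] == worst_m][-1]
        exclusion.append(worst)
        m_at_exclusion[worst] = ms[worst]
        remaining.remove(worst)
    final = pairwise_sd(qmat[remaining[0]], qmat[remaining[1]])
    for g in remaining:
        m_at_exclusion[g] = final
    return exclusion, m_at_exclusion, remaining


def norm_factor(qmat, subset, n_samples):
    """Per-sample geometric mean of the subset's quantities."""
    out = []
    for s in range(n_samples):
        prod = 1.0
        for g in subset:
            prod *= qmat[g][s]
        out.append(prod ** (1.0 / len(subset)))
    return out


def v_series(qmat, order, n_samples):
    out = {}
    for n in range(2, len(order)):
        nf_n = norm_factor(qmat, order[:n], n_samples)
        nf_n1 = norm_factor(qmat, order[: n + 1], n_samples)
        out[n] = sample_sd([math.log2(a / b) for a, b in zip(nf_n, nf_n1)])
    return out


# --- NormFinder -----------------------------------------------------------


def _center_samples(y):
    """y: dict gene -> dict sample -> value; subtract per-sample gene mean."""
    genes = list(y)
    samples = list(next(iter(y.values())))
    centered = {g: {} for g in genes}
    for s in samples:
        m = mean([y[g][s] for g in genes])
        for g in genes:
            centered[g][s] = y[g][s] - m
    return centered


def _corrected_var(svar, gene):
    G = len(svar)
    return max(0.0, (svar[gene] - mean(list(svar.values())) / (G - 1)) * G / (G - 2))


def normfinder_grouped(y, groups):
    """Grouped stability from log2 quantities.

    y: dict gene -> dict sample -> log2 quantity; groups: sample -> group.
    Returns (stability, sigma2, d_raw, d_shrunk) keyed by gene / (gene, group).
    """
    yc = _center_samples(y)
    genes = list(y)
    samples = list(next(iter(y.values())))
    group_names = list(dict.fromkeys(groups[s] for s in samples))
    cols = {grp: [s for s in samples if groups[s] == grp] for grp in group_names}

    grand = {g: mean([yc[g][s] for s in samples]) for g in genes}
    sigma2, d_raw = {}, {}
    for grp in group_names:
        n_g = len(cols[grp])
        gm = {g: mean([yc[g][s] for s in cols[grp]]) for g in genes}
        svar = {
            g: sum((yc[g][s] - gm[g]) ** 2 for s in cols[grp]) / (n_g - 1)
            for g in genes
        }
        for g in genes:
            sigma2[(g, grp)] = _corrected_var(svar, g)
            d_raw[(g, grp)] = gm[g] - grand[g]

    G, K = len(genes), len(group_names)
    gamma2 = sum(d * d for d in d_raw.values()) / ((G - 1) * (K - 1))
    d_shrunk, stability = {}, {}
    for g in genes:
        parts = []
        for grp in group_names:
            n_g = len(cols[grp])
            samp_var = sigma2[(g, grp)] / n_g
            shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else 0.0
            d_shrunk[(g, grp)] = d_raw[(g, grp)] * shrink
            parts.append(abs(d_shrunk[(g, grp)]) + math.sqrt(samp_var))
        stability[g] = mean(parts)
    return stability, sigma2, d_raw, d_shrunk


def normfinder_ungrouped(y):
    """Single-group stability: corrected SD of two-way-centered residuals."""
    yc = _center_samples(y)
    genes = list(y)
    samples = list(next(iter(y.values())))
    n = len(samples)
    gm = {g: mean([yc[g][s] for s in samples]) for g in genes}
    svar = {
        g: sum((yc[g][s] - gm[g]) ** 2 for s in samples) / (n - 1) for g in genes
    }
    return {g: math.sqrt(_corrected_var(svar, g)) for g in genes}


def best_pair(y, groups):
    """Exhaustive pair search on the same scale as single-gene stability."""
    _, sigma2, _, d_shrunk = normfinder_grouped(y, groups)
    genes = list(y)
    samples = list(next(iter(y.values())))
    group_names = list(dict.fromkeys(groups[s] for s in samples))
    n_per = {grp: sum(1 for s in samples if groups[s] == grp) for grp in group_names}
    best, best_val = None, float("inf")
    for a, b in combinations(genes, 2):
        parts = []
        for grp in group_names:
            d_pair = (d_shrunk[(a, grp)] + d_shrunk[(b, grp)]) / 2.0
            var_pair = (sigma2[(a, grp)] + sigma2[(b, grp)]) / 4.0
            parts.append(abs(d_pair) + math.sqrt(var_pair / n_per[grp]))
        val = mean(parts)
        if val < best_val:
            best, best_val = (a, b), val
    return best, best_val


# --- BestKeeper / misc ----------------------------------------------------


def pearson(xs, ys):
    n = len(xs)
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(
        sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)
    )
    return num / den


def geometric_mean(xs):
    prod = 1.0
    for x in xs:
        prod *= x
    return prod ** (1.0 / len(xs))
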