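"""Gene stratification: threshold estimation and distance-based clustering.

Two complementary procedures group dystonia genes by their pallidal dynamics:

1. *Thresholding.* Per-gene fractions of neurons expressing a phenomenon
   (bursting, tonicity, irregularity, oscillations) are compared with
   one-sided Fisher exact tests over all ordered gene pairs (BH/FDR
   corrected); genes merge into ordered groups, and the boundary between
   adjacent groups is located by incrementally raising the low boundary
   gene's count until the one-sided test loses significance.

2. *Distance.* Per-feature histograms (shared bins) are compared between
   genes with the Jensen-Shannon distance (base-2 logs, so each feature's
   distance lies in [0, 1]); per-feature matrices are summed into a
   cumulative matrix which is clustered with UPGMA into an ultrametric
   dendrogram, serializable as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .stats import benjamini_hochberg

#: feature sets per neural phenomenon used for cumulative JS distances
PHENOMENON_FEATURES: dict[str, list[str]] = {
    "regularity": ["firing_regularity", "cv", "local_variation", "isi_skewness", "asymmetry_index"],
    "discharge": ["firing_rate", "isi_mean_ms", "isi_std_ms", "isi_corr_coefficient"],
    "bursts": ["burst_index", "burst_duration_s", "burst_frequency_hz", "interburst_duration_s",
               "burst_count", "burst_avg_spike_count", "burst_spike_proportion_pct", "firing_regularity"],
    "oscillations": ["delta_freq_hz", "theta_freq_hz", "alpha_freq_hz", "beta_freq_hz", "gamma_freq_hz"],
    "pauses": ["pause_index", "pause_ratio", "pause_duration_s", "pause_frequency_hz",
               "pause_count", "pause_spike_proportion_pct", "pause_time_proportion_pct"],
}


# ---------------------------------------------------------------------------
# fractions and Fisher-based grouping
# ---------------------------------------------------------------------------

def phenomenon_fractions(table: pd.DataFrame, flag: str) -> pd.DataFrame:
    """Per-gene counts and fraction of neurons expressing ``flag``.

    Returns a frame indexed by gene with integer columns ``k`` (expressing)
    and ``n`` (total) and ``fraction = k/n``; genes with n=0 are excluded.
    """
    g = table.groupby("gene")[flag].agg(k="sum", n="count")
    g = g[g["n"] > 0].astype({"k": int, "n": int})
    g["fraction"] = g["k"] / g["n"]
    return g.sort_values("fraction")


def fisher_one_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided Fisher exact p for H1: fraction 1 < fraction 2."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="less")[1])


@dataclass
class GroupPartition:
    """Ordered groups of genes (low -> high fraction) from pairwise Fisher tests."""

    groups: list[list[str]]
    pair_p: pd.DataFrame  # columns low, high, p_raw, p_fdr
    non_transitive: bool = False


def fisher_group_partition(fractions: pd.DataFrame, alpha: float = 0.05) -> GroupPartition:
    """Partition genes into fraction-ordered groups.

    All ordered pairs (lower-fraction gene vs higher) are tested one-sided;
    BH/FDR correction is applied across the pairs. Genes are then scanned in
    ascending fraction order and a new group starts when a gene is
    FDR-significantly above *every* member of the current group (greedy,
    deterministic). A significance pattern that contradicts the ordering is
    flagged ``non_transitive`` and resolved greedily.
    """
    genes = list(fractions.index)  # already sorted ascending by fraction
    pairs = []
    for a, b in combinations(genes, 2):  # a has the lower fraction
        p = fisher_one_sided(int(fractions.loc[a, "k"]), int(fractions.loc[a, "n"]),
                             int(fractions.loc[b, "k"]), int(fractions.loc[b, "n"]))
        pairs.append({"low": a, "high": b, "p_raw": p})
    pair_df = pd.DataFrame(pairs)
    if not pair_df.empty:
        pair_df["p_fdr"] = benjamini_hochberg(pair_df["p_raw"].to_numpy())
    sig = {(r.low, r.high): r.p_fdr <= alpha for r in pair_df.itertuples()}

    groups: list[list[str]] = [[genes[0]]] if genes else []
    for gene in genes[1:]:
        if all(sig.get((m, gene), False) for m in groups[-1]):
            groups.append([gene])
        else:
            groups[-1].append(gene)

    # non-transitivity: a significant pair ending up inside one group
    non_transitive = any(
        sig.get((a, b), False)
        for grp in groups
        for a, b in combinations(grp, 2)
    )
    return GroupPartition(groups=groups, pair_p=pair_df, non_transitive=non_transitive)


@dataclass
class ThresholdEstimate:
    """Boundary threshold between a low and a high boundary gene."""

    low_gene: str
    high_gene: str
    threshold_pct: float
    p_trace: list[tuple[float, float]] = field(default_factory=list)  # (fraction, p)
    note: str = "threshold = first non-significant fraction; uncorrected p within the trace"


def estimate_boundary_threshold(
    low: tuple[int, int],
    high: tuple[int, int],
    alpha: float = 0.05,
    low_gene: str = "low",
    high_gene: str = "high",
) -> ThresholdEstimate:
    """Incremental one-sided Fisher scan locating the fraction threshold.

    Starting from the low boundary gene's observed count, k_low is raised by 1
    per step (n_low fixed) and the one-sided Fisher test against the high
    boundary gene repeated until significance is lost; the threshold is the
    fraction (in percent) at that first non-significant step. If the initial
    pair is already non-significant the threshold equals the low fraction.
    """
    (k_lo, n_lo), (k_hi, n_hi) = low, high
    if k_lo / n_lo >= k_hi / n_hi:
        return ThresholdEstimate(low_gene, high_gene, 100.0 * k_lo / n_lo,
                                 [(100.0 * k_lo / n_lo, 1.0)], note="low fraction >= high fraction")
    trace = []
    for k in range(k_lo, n_lo + 1):
        p = fisher_one_sided(k, n_lo, k_hi, n_hi)
        frac = 100.0 * k / n_lo
        trace.append((frac, p))
        if p > alpha:
            if k == k_lo:
                return ThresholdEstimate(low_gene, high_gene, frac, trace,
                                         note="initial pair non-significant")
            return ThresholdEstimate(low_gene, high_gene, frac, trace)
    return ThresholdEstimate(low_gene, high_gene, 100.0, trace, note="significant up to n_low")


def boundary_threshold_from_partition(
    fractions: pd.DataFrame, partition: GroupPartition, alpha: float = 0.05,
    boundary: int = -1,
) -> ThresholdEstimate | None:
    """Threshold between two adjacent groups of a partition: low boundary =
    highest-fraction gene of the lower group, high boundary = lowest-fraction
    gene of the upper group. ``boundary=-1`` (default) takes the boundary
    below the top group — the headline threshold separating the
    phenomenon-rich block from the remaining genes."""
    if len(partition.groups) < 2:
        return None
    upper = partition.groups[boundary]
    lower = partition.groups[boundary - 1]
    low_gene = max(lower, key=lambda g: fractions.loc[g, "fraction"])
    high_gene = min(upper, key=lambda g: fractions.loc[g, "fraction"])
    return estimate_boundary_threshold(
        (int(fractions.loc[low_gene, "k"]), int(fractions.loc[low_gene, "n"])),
        (int(fractions.loc[high_gene, "k"]), int(fractions.loc[high_gene, "n"])),
        alpha, low_gene=low_gene, high_gene=high_gene,
    )


# ---------------------------------------------------------------------------
# Jensen-Shannon cumulative distances
# ---------------------------------------------------------------------------

def js_distance_hist(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon distance (base-2) between two histograms; in [0, 1]."""
    return float(jensenshannon(p, q, base=2))


def js_cumulative_distance(
    table: pd.DataFrame,
    features: list[str],
    n_bins: int = 30,
    min_n: int = 5,
) -> pd.DataFrame:
    """Cumulative Jensen-Shannon distance matrix over a feature set.

    Per feature: all defined values are pooled, 30 equal-width bins span the
    pooled 1st-99th percentile range (shared across genes), per-gene counts
    are normalized and compared pairwise with the base-2 JS distance; the
    cumulative matrix is the elementwise sum over the features. Genes with
    fewer than ``min_n`` defined neurons for a feature are excluded from that
    feature's contribution.
    """
    genes = sorted(table["gene"].unique())
    total = pd.DataFrame(0.0, index=genes, columns=genes)
    for feat in features:
        sub = table[["gene", feat]].dropna()
        counts = sub.groupby("gene")[feat].count()
        ok = [g for g in genes if counts.get(g, 0) >= min_n]
        if len(ok) < 2:
            continue
        pooled = sub[sub["gene"].isin(ok)][feat].to_numpy(dtype=float)
        lo, hi = np.percentile(pooled, [1, 99])
        if hi <= lo:
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        hists = {}
        for g in ok:
            v = np.clip(sub.loc[sub["gene"] == g, feat].to_numpy(dtype=float), lo, hi)
            h, _ = np.histogram(v, bins=edges)
            hists[g] = h / h.sum()
        for a, b in combinations(ok, 2):
            d = js_distance_hist(hists[a], hists[b])
            total.loc[a, b] += d
            total.loc[b, a] += d
    return total


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge sequence. Heights are ultrametric node heights (half the
    between-cluster average distance at each merge)."""

    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]  # (left leaves, right leaves, height)
    newick: str


def upgma(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering of a distance matrix.

    Ties in the minimum between-cluster distance are broken by lexicographic
    order of the smallest member labels. Merge heights (half the average
    pairwise distance) are non-decreasing, yielding an ultrametric tree.
    """
    labels = list(matrix.index)
    D = matrix.to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    # clusters: id -> (leaf set, size, newick string, height)
    clusters: dict[int, tuple[frozenset, int, str, float]] = {
        i: (frozenset([lab]), 1, lab, 0.0) for i, lab in enumerate(labels)
    }
    # average distances between cluster ids
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i, j in combinations(range(len(labels)), 2)
    }
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        def sortkey(pair):
            i, j = pair
            return (dist[pair], min(clusters[i][0]), min(clusters[j][0]))

        i, j = min(dist, key=sortkey)
        d = dist[(i, j)]
        height = d / 2.0
        si, sj = clusters[i], clusters[j]
        bl_i, bl_j = height - si[3], height - sj[3]
        newick = f"({si[2]}:{bl_i:.6g},{sj[2]}:{bl_j:.6g})"
        merged = (si[0] | sj[0], si[1] + sj[1], newick, height)
        merges.append((si[0], sj[0], height))
        # update average distances to the merged cluster
        del clusters[i], clusters[j]
        new_dist = {}
        for (a, b), v in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = v
        for k in clusters:
            di = dist[(min(i, k), max(i, k))]
            dj = dist[(min(j, k), max(j, k))]
            nk = clusters[k][1]
            new_dist[(min(k, next_id), max(k, next_id))] = (si[1] * di + sj[1] * dj) / (si[1] + sj[1])
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    root = next(iter(clusters.values()))
    return Dendrogram(labels=labels, merges=merges, newick=root[2] + ";")


def cut_dendrogram(dend: Dendrogram, n_groups: int) -> list[set[str]]:
    """Leaf partition obtained by undoing the last ``n_groups - 1`` merges."""
    groups = [set(ls | rs) for ls, rs, _ in dend.merges[-1:]]  # root
    groups = [set(dend.labels)]
    for ls, rs, _ in reversed(dend.merges):
        if len(groups) >= n_groups:
            break
        target = next(g for g in groups if (ls | rs) <= g)
        groups.remove(target)
        groups.extend([set(ls), set(rs)])
    return groups
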