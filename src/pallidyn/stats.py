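"""Nonparametric cohort statistics across genes.

Continuous features: Kruskal-Wallis omnibus with Mann-Whitney U post hocs;
binary phenomenon flags: chi-square omnibus and pairwise Fisher exact tests.
p values are corrected with Holm-Bonferroni (within the stated family) or
Benjamini-Hochberg, and effect sizes (Cohen's d, Cramer's v, odds ratio) are
attached only where the corrected p reaches 0.05, with conventional magnitude
labels (d: 0.2/0.5/0.8; v: 0.1/0.25/0.5 for the 9-group table's df).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class ComparisonResult:
    feature: str
    contrast: str
    test: str
    statistic: float
    p_raw: float
    p_corrected: float
    correction: str
    effect_size: float | None = None
    effect_kind: str | None = None
    magnitude: str | None = None


def holm(pvals: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p values."""
    return multipletests(pvals, method="holm")[1]


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjusted p values."""
    return multipletests(pvals, method="fdr_bh")[1]


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD."""
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2))
    return float((np.mean(x) - np.mean(y)) / sp) if sp > 0 else 0.0


def d_magnitude(d: float) -> str:
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cramers_v(table: np.ndarray) -> float:
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if n > 0 and k > 0 else np.nan


def v_magnitude(v: float) -> str:
    if v >= 0.5:
        return "very large"
    if v >= 0.25:
        return "large"
    if v >= 0.1:
        return "medium"
    return "small"


def _groups(table: pd.DataFrame, feature: str) -> dict[str, np.ndarray]:
    """Defined (non-NaN) values per gene, listwise per feature."""
    out = {}
    for gene, sub in table.groupby("gene"):
        v = sub[feature].dropna().to_numpy(dtype=float)
        if v.size >= 2:
            out[gene] = v
    return out


def omnibus_continuous(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Kruskal-Wallis across genes for each feature, Holm-corrected over the
    feature family; Cohen's d between the two extreme-median genes when the
    corrected p reaches significance."""
    rows = []
    for feat in features:
        g = _groups(table, feat)
        if len(g) < 2:
            continue
        vals = list(g.values())
        if all(np.all(v == vals[0][0]) for v in vals):  # fully tied
            rows.append((feat, g, np.nan, 1.0))
            continue
        h, p = stats.kruskal(*vals)
        rows.append((feat, g, float(h), float(p)))
    if not rows:
        return pd.DataFrame()
    p_corr = holm(np.array([r[3] for r in rows]))
    results = []
    for (feat, g, h, p), pc in zip(rows, p_corr):
        res = ComparisonResult(feat, "all genes", "kruskal-wallis", h, p, float(pc), "holm")
        if pc <= ALPHA:
            med = {k: np.median(v) for k, v in g.items()}
            lo, hi = min(med, key=med.get), max(med, key=med.get)
            d = cohens_d(g[hi], g[lo])
            res.effect_size, res.effect_kind, res.magnitude = d, "cohens_d", d_magnitude(d)
        results.append(res.__dict__)
    return pd.DataFrame(results)


def pairwise_posthoc(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for every gene pair, Holm-corrected across the
    pairs of this feature; Cohen's d attached when significant."""
    g = _groups(table, feature)
    pairs = list(combinations(sorted(g), 2))
    raw = []
    for a, b in pairs:
        u, p = stats.mannwhitneyu(g[a], g[b], alternative="two-sided")
        raw.append((a, b, float(u), float(p)))
    if not raw:
        return pd.DataFrame()
    p_corr = holm(np.array([r[3] for r in raw]))
    out = []
    for (a, b, u, p), pc in zip(raw, p_corr):
        res = ComparisonResult(feature, f"{a} vs {b}", "mann-whitney", u, p, float(pc), "holm")
        if pc <= ALPHA:
            d = cohens_d(g[a], g[b])
            res.effect_size, res.effect_kind, res.magnitude = d, "cohens_d", d_magnitude(d)
        out.append(res.__dict__)
    return pd.DataFrame(out)


def binary_tests(table: pd.DataFrame, flag: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus chi-square (genes x flag) with Cramer's v, plus pairwise 2x2
    Fisher exact tests (two-sided) with odds ratios, Holm-corrected."""
    counts = table.groupby("gene")[flag].agg(["sum", "count"])
    counts = counts[counts["count"] > 0]
    cont = np.column_stack([counts["sum"], counts["count"] - counts["sum"]]).astype(int)

    omni_rows = []
    if cont.shape[0] >= 2 and np.all(cont.sum(axis=0) > 0):
        chi2, p, _, _ = stats.chi2_contingency(cont, correction=False)
        res = ComparisonResult(flag, "all genes", "chi-square", float(chi2), float(p), float(p), "none")
        if p <= ALPHA:
            v = cramers_v(cont)
            res.effect_size, res.effect_kind, res.magnitude = v, "cramers_v", v_magnitude(v)
        omni_rows.append(res.__dict__)
    omni = pd.DataFrame(omni_rows)

    genes = list(counts.index)
    pairs = list(combinations(genes, 2))
    raw = []
    for a, b in pairs:
        t = np.array([[counts.loc[a, "sum"], counts.loc[a, "count"] - counts.loc[a, "sum"]],
                      [counts.loc[b, "sum"], counts.loc[b, "count"] - counts.loc[b, "sum"]]], dtype=int)
        orr, p = stats.fisher_exact(t, alternative="two-sided")
        raw.append((a, b, float(orr), float(p)))
    pair_out = []
    if raw:
        p_corr = holm(np.array([r[3] for r in raw]))
        for (a, b, orr, p), pc in zip(raw, p_corr):
            res = ComparisonResult(flag, f"{a} vs {b}", "fisher-exact", orr, p, float(pc), "holm")
            if pc <= ALPHA:
                res.effect_size, res.effect_kind = orr, "odds_ratio"
            pair_out.append(res.__dict__)
    return omni, pd.DataFrame(pair_out)


def ovr_tests(table: pd.DataFrame, features: list[str], flags: list[str]) -> pd.DataFrame:
    """One-vs-rest contrasts: each gene against the pooled remainder.

    Mann-Whitney U for continuous features, Fisher exact for binary flags;
    Holm correction within each gene's family of tests.
    """
    genes = sorted(table["gene"].unique())
    out = []
    for gene in genes:
        mask = table["gene"] == gene
        fam: list[ComparisonResult] = []
        for feat in features:
            x = table.loc[mask, feat].dropna().to_numpy(dtype=float)
            y = table.loc[~mask, feat].dropna().to_numpy(dtype=float)
            if x.size < 2 or y.size < 2:
                continue
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            fam.append(ComparisonResult(feat, f"{gene} vs rest", "mann-whitney", float(u), float(p), np.nan, "holm"))
        for flag in flags:
            x = table.loc[mask, flag].astype(bool)
            y = table.loc[~mask, flag].astype(bool)
            t = np.array([[x.sum(), (~x).sum()], [y.sum(), (~y).sum()]], dtype=int)
            orr, p = stats.fisher_exact(t, alternative="two-sided")
            fam.append(ComparisonResult(flag, f"{gene} vs rest", "fisher-exact", float(orr), float(p), np.nan, "holm"))
        if not fam:
            continue
        p_corr = holm(np.array([r.p_raw for r in fam]))
        for r, pc in zip(fam, p_corr):
            r.p_corrected = float(pc)
            out.append(r.__dict__)
    return pd.DataFrame(out)
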