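"""Patient-level clinical analyses: DBS outcome contrasts and correlations.

The central clinical quantity is the percent change of the BFMDRS-M motor
score from the preoperative assessment to a follow-up horizon (negative =
improvement). Patient groups defined by the gene stratification (tonic-gene
vs bursting-gene profiles) are contrasted with a one-sided exact
Mann-Whitney U test (H1: the tonic-gene group improves less), and clinical
variables are related to patient-mean neural metrics with Spearman
correlations whose significance is assessed by a permutation test with
BH/FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import benjamini_hochberg, holm
from .types import ClinicalRecord

#: genes whose pallidal activity is tonicity-dominated (stratification outcome)
TONIC_GENES = frozenset({"AOPEP", "THAP1", "PANK2"})


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre; negative values are improvement."""
    if pre <= 0:
        raise ValueError("preoperative score must be positive")
    return 100.0 * (post - pre) / pre


@dataclass
class OutcomeContrast:
    median_pct_change_a: float   # tonic-gene group
    median_pct_change_b: float   # remaining genes
    n_a: int
    n_b: int
    p_one_sided: float
    method: str
    horizon_years: int


def outcome_table(records: list[ClinicalRecord], horizon_years: int = 1) -> pd.DataFrame:
    """Per-patient percent change at a follow-up horizon (missing excluded)."""
    rows = []
    for r in records:
        post = r.followup(horizon_years)
        if post is None:
            continue
        rows.append({"patient_id": r.patient_id, "gene": r.gene,
                     "pct_change": percent_change(r.bfmdrs_pre, post)})
    return pd.DataFrame(rows)


def group_outcome_compare(
    records: list[ClinicalRecord],
    tonic_genes: frozenset[str] = TONIC_GENES,
    horizon_years: int = 1,
    method: str = "exact",
) -> OutcomeContrast:
    """Contrast DBS response between tonic-gene patients and the remainder.

    Group medians of the percent change plus a one-sided Mann-Whitney U p
    (H1: the tonic-gene group's percent change is greater, i.e. it improves
    less). The exact null distribution is used by default (both groups are
    well under n=30); ``method='asymptotic'`` switches to the normal
    approximation with midranks for ties.
    """
    tab = outcome_table(records, horizon_years)
    a = tab.loc[tab["gene"].isin(tonic_genes), "pct_change"].to_numpy()
    b = tab.loc[~tab["gene"].isin(tonic_genes), "pct_change"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both patient groups must be non-empty")
    p = float(stats.mannwhitneyu(a, b, alternative="greater", method=method).pvalue)
    return OutcomeContrast(
        median_pct_change_a=float(np.median(a)),
        median_pct_change_b=float(np.median(b)),
        n_a=int(a.size), n_b=int(b.size),
        p_one_sided=p, method=method, horizon_years=horizon_years,
    )


def patient_summaries(feature_table: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Mean of each neural metric over every patient's neurons, plus the
    per-patient fractions of tonic/irregular/bursting and oscillatory units."""
    agg = feature_table.groupby("patient_id").agg(
        {m: "mean" for m in metrics} | {"gene": "first"}
    )
    for flag in ("is_tonic", "is_irregular", "is_bursting", "osc_any"):
        if flag in feature_table.columns:
            agg[f"frac_{flag.removeprefix('is_')}"] = feature_table.groupby("patient_id")[flag].mean()
    return agg.reset_index()


def spearman_permutation(
    summaries: pd.DataFrame,
    clinical_vars: list[str],
    neural_metrics: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman rho for every (clinical variable, neural metric) pair with a
    label-permutation p value, BH/FDR-corrected across the whole table.

    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1); pairs with fewer than
    5 complete patients or a constant column are undefined (NaN).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cv in clinical_vars:
        for nm in neural_metrics:
            sub = summaries[[cv, nm]].dropna()
            x, y = sub[cv].to_numpy(dtype=float), sub[nm].to_numpy(dtype=float)
            if len(sub) < 5 or np.all(x == x[0]) or np.all(y == y[0]):
                rows.append({"clinical": cv, "metric": nm, "rho": np.nan, "p_perm": np.nan})
                continue
            rho = float(stats.spearmanr(x, y).statistic)
            count = 0
            for _ in range(n_perm):
                r = float(stats.spearmanr(rng.permutation(x), y).statistic)
                if abs(r) >= abs(rho):
                    count += 1
            rows.append({"clinical": cv, "metric": nm, "rho": rho,
                         "p_perm": (1 + count) / (n_perm + 1)})
    out = pd.DataFrame(rows)
    mask = out["p_perm"].notna()
    out["p_fdr"] = np.nan
    if mask.any():
        out.loc[mask, "p_fdr"] = benjamini_hochberg(out.loc[mask, "p_perm"].to_numpy())
    return out


def group_variable_compare(
    summaries: pd.DataFrame,
    group_col: str = "group",
    variables: tuple[str, ...] = ("onset_age", "disease_duration", "bfmdrs_pre"),
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for onset age, disease duration and
    preoperative BFMDRS between two patient groups, Holm-corrected."""
    groups = sorted(summaries[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    rows = []
    for var in variables:
        a = summaries.loc[summaries[group_col] == groups[0], var].dropna().to_numpy(dtype=float)
        b = summaries.loc[summaries[group_col] == groups[1], var].dropna().to_numpy(dtype=float)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"variable": var, "statistic": float(u), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm(out["p_raw"].to_numpy())
    return out
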