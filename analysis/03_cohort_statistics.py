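#!/usr/bin/env python
"""Nonparametric comparisons of neural features across dystonia genes:
Kruskal-Wallis omnibus (Holm-corrected family), Mann-Whitney pairwise post
hocs per feature, chi-square / Fisher tests on the binary phenomenon flags,
and one-vs-rest contrasts. Writes tidy tables under results/stats/.
"""

from pathlib import Path

import pandas as pd

from pallidyn.features import METRICS
from pallidyn.stats import binary_tests, omnibus_continuous, ovr_tests, pairwise_posthoc

OUT = Path(__file__).resolve().parents[1] / "results"
FLAGS = ["is_tonic", "is_irregular", "is_bursting", "osc_any"]


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    out = OUT / "stats"
    out.mkdir(exist_ok=True)

    omni = omnibus_continuous(table, METRICS)
    omni.to_csv(out / "omnibus_continuous.csv", index=False)
    sig = omni[omni["p_corrected"] <= 0.05]
    print(f"omnibus: {len(sig)}/{len(omni)} features differ across genes (Holm p <= 0.05)")
    medium = sig[sig["magnitude"].isin(["medium", "large"])]
    print(f"  of these, {len(medium)} with at least medium effect size (Cohen's d >= 0.5)")

    pairs = pd.concat([pairwise_posthoc(table, f) for f in METRICS], ignore_index=True)
    pairs.to_csv(out / "pairwise_posthoc.csv", index=False)
    per_pair = pairs.assign(sig=pairs["p_corrected"] <= 0.05).groupby("contrast")["sig"].sum()
    top = per_pair.sort_values(ascending=False).head(3)
    print("gene pairs with the most significantly different features:")
    for contrast, k in top.items():
        print(f"  {contrast}: {int(k)} features")

    binary_rows, pair_rows = [], []
    for flag in FLAGS:
        omni_b, pairs_b = binary_tests(table, flag)
        binary_rows.append(omni_b)
        pair_rows.append(pairs_b)
    pd.concat(binary_rows, ignore_index=True).to_csv(out / "binary_omnibus.csv", index=False)
    pd.concat(pair_rows, ignore_index=True).to_csv(out / "binary_pairwise.csv", index=False)

    ovr = ovr_tests(table, METRICS, FLAGS)
    ovr.to_csv(out / "ovr_tests.csv", index=False)
    burst_feats = [f for f in METRICS if f.startswith("burst")]
    n_burst_sig = int(((ovr["feature"].isin(burst_feats)) & (ovr["p_corrected"] <= 0.05)).sum())
    print(f"one-vs-rest: {n_burst_sig} significant burst-related contrasts across genes")


if __name__ == "__main__":
    main()
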