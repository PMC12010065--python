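#!/usr/bin/env python
"""Stratify the dystonia genes two ways: (1) fraction thresholding — one-sided
Fisher tests on the per-gene fractions of bursting/tonic/irregular/oscillatory
neurons, group partition and boundary thresholds; (2) cumulative
Jensen-Shannon distances over phenomenon feature sets, clustered with UPGMA
into Newick dendrograms. Writes results/stratification/.
"""

from pathlib import Path

import pandas as pd

from pallidyn import stratify as strat

OUT = Path(__file__).resolve().parents[1] / "results"
PHENOMENA = {"bursting": "is_bursting", "tonicity": "is_tonic",
             "irregularity": "is_irregular", "oscillations": "osc_any"}


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    out = OUT / "stratification"
    out.mkdir(exist_ok=True)

    rows = []
    for name, flag in PHENOMENA.items():
        if flag not in table.columns or table[flag].sum() == 0:
            continue
        fr = strat.phenomenon_fractions(table, flag)
        part = strat.fisher_group_partition(fr)
        thr = strat.boundary_threshold_from_partition(fr, part)
        fr.to_csv(out / f"fractions_{name}.csv")
        part.pair_p.to_csv(out / f"fisher_pairs_{name}.csv", index=False)
        groups = " | ".join(",".join(g) for g in part.groups)
        print(f"{name}: groups (low->high fraction): {groups}")
        if thr is not None:
            print(f"  boundary threshold {thr.threshold_pct:.1f}% "
                  f"({thr.low_gene} vs {thr.high_gene})")
            rows.append({"phenomenon": name, "threshold_pct": thr.threshold_pct,
                         "low_gene": thr.low_gene, "high_gene": thr.high_gene})
    pd.DataFrame(rows).to_csv(out / "thresholds.csv", index=False)

    for name, feats in strat.PHENOMENON_FEATURES.items():
        have = [f for f in feats if f in table.columns]
        D = strat.js_cumulative_distance(table, have)
        if (D.to_numpy() == 0).all():
            continue
        dend = strat.upgma(D)
        D.to_csv(out / f"js_distance_{name}.csv")
        (out / f"dendrogram_{name}.nwk").write_text(dend.newick + "\n")
        two = [sorted(g) for g in strat.cut_dendrogram(dend, 2)]
        print(f"JS/UPGMA [{name}]: 2-group cut -> {two}")


if __name__ == "__main__":
    main()
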