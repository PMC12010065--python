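#!/usr/bin/env python
"""PCA of the neuron feature table (undefined cells encoded as explicit
absence) and pairwise Calinski-Harabasz separability of the gene populations
on the first two principal components. Writes scores, loadings, explained
variance and the CH matrix under results/pca/.
"""

from pathlib import Path

import pandas as pd

from pallidyn.embedding import ch_matrix, pca_embed

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    out = OUT / "pca"
    out.mkdir(exist_ok=True)

    emb, high = pca_embed(table)
    emb.scores.to_csv(out / "scores.csv", index=False)
    emb.loadings.to_csv(out / "loadings.csv")
    emb.correlation_loadings.to_csv(out / "correlation_loadings.csv")
    pd.DataFrame({"pc": [f"PC{i+1}" for i in range(len(emb.explained_variance_ratio))],
                  "explained_pct": 100 * emb.explained_variance_ratio}).to_csv(
        out / "explained_variance.csv", index=False)

    evr = 100 * emb.explained_variance_ratio
    print(f"PC1 explains {evr[0]:.2f}% and PC2 {evr[1]:.2f}% of total variance "
          f"(first five: {evr[:5].sum():.1f}%)")
    print(f"high-loading features (|corr loading| >= 0.5 on PC1/PC2): {len(high)}")

    ch = ch_matrix(emb)
    ch.to_csv(out / "ch_separability.csv")
    pairs = ch.where(~ch.isna()).stack().sort_values(ascending=False)
    print("most separable gene pairs (CH on PC1-PC2):")
    seen = set()
    shown = 0
    for (a, b), v in pairs.items():
        if frozenset((a, b)) in seen:
            continue
        seen.add(frozenset((a, b)))
        print(f"  {a}-{b}: {v:.1f}")
        shown += 1
        if shown == 3:
            break


if __name__ == "__main__":
    main()
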