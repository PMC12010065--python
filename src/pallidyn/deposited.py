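"""End-to-end reproduction pipeline for the deposited cohort recordings.

The study's processed spike data are archived at doi:10.5281/zenodo.13269430
as anonymized tabular text. This module runs the full analysis — feature
extraction, discharge classification, threshold stratification, PCA — on a
local copy of that deposit and reports the headline quantities (stratification
thresholds for burstiness/tonicity/oscillations, PC1/PC2 explained variance,
per-gene oscillatory fractions, and the PLA2G6-THAP1 significant-feature
count). It never downloads anything itself; pass the path to the unpacked
deposit. Because several per-metric definitions are documented stand-ins for
the original extraction code, agreement with the published values is expected
to be approximate unless the deposit contains the authors' own feature table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import features, io, stratify
from .embedding import pca_embed
from .stats import pairwise_posthoc


def reproduce_deposited_analysis(deposit_path: str | Path,
                                 columns: dict[str, str] | None = None,
                                 cfg: features.FeatureConfig | None = None) -> dict:
    """Run the pipeline on a local copy of the deposited spike tables.

    ``deposit_path`` may be a single CSV or a directory of CSVs in the spike
    table schema (use ``columns`` to map the deposit's column names). Returns
    a dict of headline quantities keyed like the published values.
    """
    deposit_path = Path(deposit_path)
    if not deposit_path.exists():
        raise FileNotFoundError(
            f"deposited data not found at {deposit_path}; download and unpack "
            "doi:10.5281/zenodo.13269430 first"
        )
    paths = sorted(deposit_path.glob("*.csv")) if deposit_path.is_dir() else [deposit_path]
    trains = [t for p in paths for t in io.read_spike_table(p, columns)]
    if not trains:
        raise ValueError("no spike trains found in the deposit")

    cfg = cfg or features.FeatureConfig()
    table = features.featurize_cohort(trains, cfg)

    out: dict[str, float] = {"n_neurons": float(len(table))}

    for flag, key in (("is_bursting", "bursting_threshold_pct"),
                      ("is_tonic", "tonicity_threshold_pct"),
                      ("osc_any", "oscillation_threshold_pct")):
        frac = stratify.phenomenon_fractions(table, flag)
        part = stratify.fisher_group_partition(frac)
        thr = stratify.boundary_threshold_from_partition(frac, part)
        out[key] = thr.threshold_pct if thr is not None else float("nan")

    emb, _ = pca_embed(table)
    out["pc1_explained_pct"] = 100.0 * float(emb.explained_variance_ratio[0])
    out["pc2_explained_pct"] = 100.0 * float(emb.explained_variance_ratio[1])

    for gene in ("GNAL", "PLA2G6"):
        sub = table[table["gene"] == gene]
        if len(sub):
            out[f"{gene}_oscillatory_pct"] = 100.0 * float(sub["osc_any"].mean())

    n_sig = 0
    n_tested = 0
    for feat in features.METRICS:
        ph = pairwise_posthoc(table, feat)
        if ph.empty:
            continue
        row = ph[ph["contrast"].isin(["PLA2G6 vs THAP1", "THAP1 vs PLA2G6"])]
        if len(row):
            n_tested += 1
            n_sig += int(row["p_corrected"].iloc[0] <= 0.05)
    out["pla2g6_thap1_significant_features"] = float(n_sig)
    out["pla2g6_thap1_tested_features"] = float(n_tested)
    return out
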