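#!/usr/bin/env python
"""Featurize the simulated cohort: firing statistics, burst and pause metrics,
per-band oscillation flags, and the tonic/irregular/bursting discharge label
for every neuron. Reads results/spikes.csv, writes results/features.csv.

Oscillation testing (100 ISI-shuffle surrogates per neuron) dominates the
runtime; disable with --no-oscillations for quick iterations.
"""

import argparse
from pathlib import Path

from pallidyn import io
from pallidyn.features import FeatureConfig, featurize_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--spikes", type=Path, default=OUT / "spikes.csv")
    ap.add_argument("--no-oscillations", action="store_true")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    trains = io.read_spike_table(args.spikes)
    cfg = FeatureConfig(compute_oscillations=not args.no_oscillations, seed=args.seed)
    table = featurize_cohort(trains, cfg)
    table.to_csv(OUT / "features.csv", index=False)

    counts = table["discharge"].value_counts().to_dict()
    print(f"featurized {len(table)} neurons -> {OUT / 'features.csv'}")
    print("discharge labels:", counts)
    if not args.no_oscillations:
        print(f"oscillatory (any band): {table['osc_any'].mean():.1%}")


if __name__ == "__main__":
    main()
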