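#!/usr/bin/env python
"""Reproduce the headline quantities from the study's deposited cohort
recordings (doi:10.5281/zenodo.13269430). The deposit must be downloaded and
unpacked locally first (it is anonymized tabular text); pass its path, plus a
column mapping if the deposit's column names differ from the canonical
unit_id/patient_id/gene/time_s schema.

Usage: python analysis/08_deposited_data.py data/deposited_zenodo_13269430
"""

import argparse
import json
from pathlib import Path

from pallidyn.deposited import reproduce_deposited_analysis

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("deposit", type=Path)
    ap.add_argument("--column-map", type=Path, default=None,
                    help="JSON file mapping canonical column names to the deposit's")
    args = ap.parse_args()

    columns = json.loads(args.column_map.read_text()) if args.column_map else None
    out = reproduce_deposited_analysis(args.deposit, columns)
    OUT.mkdir(exist_ok=True)
    (OUT / "deposited_reproduction.json").write_text(json.dumps(out, indent=2) + "\n")
    for k, v in out.items():
        print(f"{k}: {v:.2f}")


if __name__ == "__main__":
    main()
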