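"""Tabular I/O for spike tables and packaged clinical / gene-profile fixtures.

Spike tables are plain CSV with a header, one row per spike, UTF-8, '.' decimal,
times in seconds with at least 0.1 ms precision. The default schema has columns
``unit_id, patient_id, gene, time_s`` and an optional per-unit ``duration_s``;
deposits with other column names are handled through a column-mapping dict.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ClinicalRecord, GeneProfile, SpikeTrain, GENES

logger = logging.getLogger("pallidyn")

DEFAULT_COLUMNS = {
    "unit_id": "unit_id",
    "patient_id": "patient_id",
    "gene": "gene",
    "time_s": "time_s",
    "duration_s": "duration_s",
}

#: decimal precision of spike times on write (0.1 ms)
TIME_DECIMALS = 4


def read_spike_table(path: str | Path, columns: dict[str, str] | None = None) -> list[SpikeTrain]:
    """Read a spike table into one :class:`SpikeTrain` per unit.

    ``columns`` maps the canonical names (``unit_id``, ``patient_id``, ``gene``,
    ``time_s``, optional ``duration_s``) to the file's actual column names.
    Times are sorted per unit; exact duplicate timestamps within a unit are
    dropped with a warning. When no duration column is present the duration is
    inferred as max(time) + mean ISI and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("spike table %s is empty", path)
        return []
    required = ["unit_id", "patient_id", "gene", "time_s"]
    missing = [colmap[c] for c in required if colmap[c] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[colmap["time_s"]].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed spike time at line {line}")

    has_duration = colmap["duration_s"] in df.columns
    trains: list[SpikeTrain] = []
    for unit_id, sub in df.groupby(colmap["unit_id"], sort=True):
        times = np.sort(sub[colmap["time_s"]].to_numpy(dtype=float))
        uniq = np.unique(times)
        if uniq.size < times.size:
            logger.warning("unit %s: %d duplicate timestamps dropped", unit_id, times.size - uniq.size)
            times = uniq
        if has_duration and not sub[colmap["duration_s"]].isna().all():
            duration = float(sub[colmap["duration_s"]].dropna().iloc[0])
        else:
            mean_isi = float(np.mean(np.diff(times))) if times.size > 1 else 1.0
            duration = float(times[-1]) + mean_isi if times.size else 1.0
            logger.warning("unit %s: no stated duration, inferred %.4f s", unit_id, duration)
        trains.append(
            SpikeTrain(
                unit_id=str(unit_id),
                patient_id=str(sub[colmap["patient_id"]].iloc[0]),
                gene=str(sub[colmap["gene"]].iloc[0]),
                times=times,
                duration=duration,
            )
        )
    return trains


def write_spike_table(trains: list[SpikeTrain], path: str | Path) -> None:
    """Write spike trains in the canonical CSV schema (times rounded to 0.1 ms)."""
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "patient_id": tr.patient_id,
                    "gene": tr.gene,
                    "time_s": round(float(t), TIME_DECIMALS),
                    "duration_s": tr.duration,
                }
            )
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS)).to_csv(path, index=False)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("pallidyn").joinpath("data", name)))


def load_clinical_fixture() -> list[ClinicalRecord]:
    """The packaged 31-patient clinical table (BFMDRS-M pre and 1/3/5-year post-DBS)."""
    df = pd.read_csv(_fixture_path("clinical_bfmdrs.csv"))
    if len(df) != 31:
        raise ValueError(f"clinical fixture corrupted: expected 31 records, found {len(df)}")
    records = []
    for _, r in df.iterrows():
        def opt(v):
            return None if pd.isna(v) or str(v).strip().lower() in ("", "na") else float(v)

        records.append(
            ClinicalRecord(
                patient_id=str(r.patient_id),
                gene=str(r.gene),
                sex=str(r.sex),
                onset_age=float(r.onset_age),
                surgery_age=float(r.surgery_age),
                bfmdrs_pre=float(r.bfmdrs_pre),
                bfmdrs_fu1=opt(r.bfmdrs_fu1),
                bfmdrs_fu3=opt(r.bfmdrs_fu3),
                bfmdrs_fu5=opt(r.bfmdrs_fu5),
            )
        )
    genes = {rec.gene for rec in records}
    if not genes <= set(GENES):
        raise ValueError(f"clinical fixture contains unknown genes: {genes - set(GENES)}")
    return records


def clinical_frame(records: list[ClinicalRecord] | None = None) -> pd.DataFrame:
    """Clinical records as a tidy DataFrame (one row per patient)."""
    if records is None:
        records = load_clinical_fixture()
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "gene": [r.gene for r in records],
            "sex": [r.sex for r in records],
            "onset_age": [r.onset_age for r in records],
            "surgery_age": [r.surgery_age for r in records],
            "disease_duration": [r.disease_duration for r in records],
            "bfmdrs_pre": [r.bfmdrs_pre for r in records],
            "bfmdrs_fu1": [r.bfmdrs_fu1 for r in records],
            "bfmdrs_fu3": [r.bfmdrs_fu3 for r in records],
            "bfmdrs_fu5": [r.bfmdrs_fu5 for r in records],
        }
    )


def load_gene_profiles() -> dict[str, GeneProfile]:
    """Per-gene neural signatures: 28 continuous metrics (mean, SD) per gene,
    plus synthetic calibration fractions of discharge regimes."""
    prof = pd.read_csv(_fixture_path("gene_profiles.csv"))
    frac = pd.read_csv(_fixture_path("gene_fractions_synthetic.csv"), comment="#")
    frac = frac.set_index("gene")
    profiles: dict[str, GeneProfile] = {}
    for gene in GENES:
        metrics = {
            row["metric"]: (float(row[f"{gene}_mean"]), float(row[f"{gene}_sd"]))
            for _, row in prof.iterrows()
        }
        f = frac.loc[gene]
        profiles[gene] = GeneProfile(
            gene=gene,
            metrics=metrics,
            frac_tonic=float(f.frac_tonic),
            frac_irregular=float(f.frac_irregular),
            frac_bursting=float(f.frac_bursting),
            frac_oscillatory=float(f.frac_oscillatory),
        )
    return profiles
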