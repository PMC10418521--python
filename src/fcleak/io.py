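"""Delimited-text I/O for cohorts, timeseries, FC tables and reports.

All tabular outputs are CSV (timeseries are one CSV per scan); each file
carries a leading ``# config_hash=...`` comment so any stage can be
rerun from intermediates and traced to the config that produced it.
Readers skip ``#`` comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import RoiTimeseries, validate_cohort

MANIFEST_NAME = "manifest.csv"


def _write_csv(df: pd.DataFrame, path: Path, run_hash: Optional[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if run_hash:
            fh.write(f"# config_hash={run_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_cohort(
    scans: Sequence[RoiTimeseries],
    cohort: pd.DataFrame,
    outdir,
    run_hash: Optional[str] = None,
) -> Path:
    """Write one timeseries CSV per scan plus the cohort manifest.

    Manifest columns: subject_id, scan_id, path (relative), tr_seconds,
    phenotype_cont, phenotype_bin.  Timeseries files have one ROI per
    column (header ROI0..ROI{P-1}), one TR per row.
    """
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    validate_cohort(cohort)
    rows = []
    pheno = cohort.set_index(["subject_id", "scan_id"])
    for ts in scans:
        fname = f"{ts.subject_id}_{ts.scan_id}.csv"
        cols = [f"ROI{j}" for j in range(ts.n_rois)]
        _write_csv(pd.DataFrame(ts.values, columns=cols), ts_dir / fname, run_hash)
        rec = pheno.loc[(ts.subject_id, ts.scan_id)]
        rows.append(
            {
                "subject_id": ts.subject_id,
                "scan_id": ts.scan_id,
                "path": f"timeseries/{fname}",
                "tr_seconds": ts.tr_seconds,
                "phenotype_cont": float(rec["phenotype_cont"]),
                "phenotype_bin": int(rec["phenotype_bin"]),
            }
        )
    manifest = pd.DataFrame(rows)
    _write_csv(manifest, outdir / MANIFEST_NAME, run_hash)
    return outdir / MANIFEST_NAME


def read_cohort(manifest_path):
    """Read a manifest written by :func:`write_cohort`.

    Returns (list of RoiTimeseries, cohort table).
    """
    manifest_path = Path(manifest_path)
    manifest = read_csv(manifest_path)
    root = manifest_path.parent
    scans = []
    for _, row in manifest.iterrows():
        values = read_csv(root / row["path"]).to_numpy(dtype=float)
        scans.append(
            RoiTimeseries(
                subject_id=str(row["subject_id"]),
                scan_id=str(row["scan_id"]),
                values=values,
                tr_seconds=float(row["tr_seconds"]),
            )
        )
    cohort = manifest[
        ["subject_id", "scan_id", "phenotype_cont", "phenotype_bin"]
    ].copy()
    cohort["subject_id"] = cohort["subject_id"].astype(str)
    cohort["scan_id"] = cohort["scan_id"].astype(str)
    return scans, validate_cohort(cohort)


def write_fc_table(fc_table: pd.DataFrame, path, run_hash: Optional[str] = None) -> Path:
    path = Path(path)
    _write_csv(fc_table, path, run_hash)
    return path


def read_fc_table(path) -> pd.DataFrame:
    df = read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    df["scan_id"] = df["scan_id"].astype(str)
    df["window_index"] = df["window_index"].astype(int)
    return df


def write_cohort_table(cohort: pd.DataFrame, path, run_hash: Optional[str] = None) -> Path:
    path = Path(path)
    _write_csv(validate_cohort(cohort), path, run_hash)
    return path


def read_cohort_table(path) -> pd.DataFrame:
    df = read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    df["scan_id"] = df["scan_id"].astype(str)
    return validate_cohort(df)


def write_similarity(sim, path, run_hash: Optional[str] = None) -> Path:
    """Similarity matrix as CSV with unit labels on both axes."""
    path = Path(path)
    df = sim.to_frame().reset_index().rename(columns={"index": "unit"})
    _write_csv(df, path, run_hash)
    return path


def write_json(payload: dict, path, run_hash: Optional[str] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if run_hash:
        payload = {"config_hash": run_hash, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
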