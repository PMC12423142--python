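"""Reading and writing the package's file formats.

Long-format CSVs, comma-separated with a header row, UTF-8:

* ``timeseries.csv`` — participant_id, day, rt_seconds (one row per
  participant-day);
* ``participants.csv`` — participant_id, age_std, sex_male, edu_std,
  race_black, eth_hispanic, mci (a blank mci cell marks a missing /
  held-out outcome);
* report artifacts — a Table-1-style ``summary.csv`` (coefficient block,
  then group-level block) and a ``metrics.json`` with AUC and bootstrap CI
  per model variant.

Every run writes a ``manifest.json`` recording the seed, configuration
hash, package version and timestamp so results can be re-run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Dataset,
    ManifestCovariates,
    OutcomeRecord,
    Participant,
    SubjectTimeSeries,
)

logger = logging.getLogger(__name__)

__all__ = ["load_dataset", "write_dataset", "write_report", "write_manifest"]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_std",
    "sex_male",
    "edu_std",
    "race_black",
    "eth_hispanic",
    "mci",
]


def write_dataset(data: Dataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write timeseries.csv and participants.csv for a dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_rows = []
    for p in data:
        for t, v in zip(p.series.times, p.series.values):
            ts_rows.append(
                {"participant_id": p.participant_id, "day": t, "rt_seconds": repr(float(v))}
            )
    ts_path = out_dir / "timeseries.csv"
    pd.DataFrame(ts_rows).to_csv(ts_path, index=False)
    part_rows = []
    for p in data:
        c = p.covariates
        part_rows.append(
            {
                "participant_id": p.participant_id,
                "age_std": repr(float(c.age_std)),
                "sex_male": c.sex_male,
                "edu_std": repr(float(c.edu_std)),
                "race_black": c.race_black,
                "eth_hispanic": c.eth_hispanic,
                "mci": "" if p.outcome.mci is None else p.outcome.mci,
            }
        )
    part_path = out_dir / "participants.csv"
    pd.DataFrame(part_rows, columns=PARTICIPANT_COLUMNS).to_csv(part_path, index=False)
    return ts_path, part_path


def load_dataset(timeseries_path: str | Path, participants_path: str | Path) -> Dataset:
    """Load and validate a dataset from the two CSVs.

    Participant ids must match exactly across the files; non-numeric
    response times are reported with their row number; blank ``mci`` cells
    become missing outcomes.
    """
    ts = pd.read_csv(
        timeseries_path, dtype={"participant_id": str}, float_precision="round_trip"
    )
    parts = pd.read_csv(
        participants_path, dtype={"participant_id": str}, float_precision="round_trip"
    )
    for col in ("participant_id", "day", "rt_seconds"):
        if col not in ts.columns:
            raise ValueError(f"timeseries file missing column {col!r}")
    for col in PARTICIPANT_COLUMNS:
        if col not in parts.columns:
            raise ValueError(f"participants file missing column {col!r}")

    rt = pd.to_numeric(ts["rt_seconds"], errors="coerce")
    bad = ts.index[rt.isna() & ts["rt_seconds"].notna()]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"non-numeric rt_seconds at file row(s) {[int(i) + 2 for i in bad[:10]]}")
    if rt.isna().any():
        raise ValueError("missing rt_seconds values")
    ts = ts.assign(rt_seconds=rt)

    ts_ids = set(ts["participant_id"])
    part_ids = set(parts["participant_id"])
    only_ts = sorted(ts_ids - part_ids)
    only_part = sorted(part_ids - ts_ids)
    if only_ts or only_part:
        raise ValueError(
            "participant ids do not match across files: "
            f"only in timeseries {only_ts[:10]}, only in participants {only_part[:10]}"
        )

    grouped = {pid: g.sort_values("day") for pid, g in ts.groupby("participant_id")}
    participants = []
    n_missing = 0
    for row in parts.itertuples(index=False):
        g = grouped[row.participant_id]
        series = SubjectTimeSeries(
            row.participant_id,
            g["day"].to_numpy(dtype=float),
            g["rt_seconds"].to_numpy(dtype=float),
        )
        cov = ManifestCovariates(
            age_std=float(row.age_std),
            sex_male=int(row.sex_male),
            edu_std=float(row.edu_std),
            race_black=int(row.race_black),
            eth_hispanic=int(row.eth_hispanic),
        )
        mci_raw = row.mci
        if mci_raw is None or (isinstance(mci_raw, float) and np.isnan(mci_raw)) or mci_raw == "":
            outcome = OutcomeRecord(None)
            n_missing += 1
        else:
            outcome = OutcomeRecord(int(mci_raw))
        participants.append(Participant(series, cov, outcome))
    data = Dataset(participants)
    observed = [p.outcome.mci for p in data if p.outcome.observed]
    logger.info(
        "loaded %d participants (%d rows); %d missing outcomes; prevalence %.3f",
        len(data),
        len(ts),
        n_missing,
        float(np.mean(observed)) if observed else float("nan"),
    )
    return data


def write_report(summary: pd.DataFrame, metrics: dict | None, out_dir: str | Path) -> None:
    """Write the Table-1-style summary CSV (4+ decimal places) and, when
    cross-validation metrics are given, a metrics.json.

    Output is deterministic: identical inputs reproduce identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out_dir / "summary.csv", float_format="%.6f")
    if metrics is not None:
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Record seed, a config hash and versions alongside run outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "poppred_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
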