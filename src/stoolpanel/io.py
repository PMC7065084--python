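"""Readers and writers for the pipeline's tabular formats.

All files are tab-separated UTF-8 with a mandatory header row. Missing assay
values are written as ``NA``; both ``NA`` and the empty string are accepted on
read. Counts must parse as non-negative integers — intensity-style fractional
values are rejected because the beta-binomial model consumes counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .types import (
    ARM_STATUS,
    CAE_ARMS,
    AnalysisConfig,
    ArmCallProfile,
    CountMatrix,
    FormatError,
    SampleTable,
)

logger = logging.getLogger("stoolpanel")

_NA = ["NA", ""]


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a proteins x samples spectral-count TSV.

    First column holds the protein-group id; remaining columns are samples.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: count matrix needs an id column plus >=1 sample")
    protein_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy()
    if pd.isna(values).any():
        i, j = np.argwhere(pd.isna(values))[0]
        raise FormatError(
            f"{path}: missing count at protein {protein_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    # CountMatrix validates integrality/non-negativity and names the cell.
    return CountMatrix(protein_ids, sample_ids, values)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(
        path, sep="\t", header=0, dtype=str, na_values=_NA, keep_default_na=False
    )
    for col in SampleTable.REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: sample table missing column {col!r}")
        if df[col].isna().any():
            raise FormatError(f"{path}: column {col!r} has missing entries")
    return SampleTable(df)


def write_sample_table(t: SampleTable, path: str | Path) -> None:
    t.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_arm_calls(path: str | Path) -> list[ArmCallProfile]:
    """Read long-format arm calls (adenoma_id, patient_id, arm, status).

    Arms absent for an adenoma default to ``neutral`` (a warning is logged);
    conflicting duplicate (adenoma, arm) rows are an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in ("adenoma_id", "patient_id", "arm", "status"):
        if col not in df.columns:
            raise FormatError(f"{path}: arm-call table missing column {col!r}")
    bad = set(df["status"]) - set(ARM_STATUS)
    if bad:
        raise FormatError(f"{path}: invalid status {sorted(bad)}")
    profiles: list[ArmCallProfile] = []
    for (adenoma_id, patient_id), grp in df.groupby(
        ["adenoma_id", "patient_id"], sort=False
    ):
        calls: dict[str, str] = {}
        for _, row in grp.iterrows():
            arm, status = row["arm"], row["status"]
            if arm in calls:
                if calls[arm] != status:
                    raise FormatError(
                        f"{path}: conflicting calls for adenoma {adenoma_id!r} "
                        f"arm {arm!r}: {calls[arm]!r} vs {status!r}"
                    )
                continue
            calls[arm] = status
        missing = [a for a in CAE_ARMS if a not in calls]
        if missing:
            logger.warning(
                "adenoma %s: arms %s absent from %s, defaulting to neutral",
                adenoma_id, missing, path,
            )
            for a in missing:
                calls[a] = "neutral"
        profiles.append(ArmCallProfile(str(adenoma_id), str(patient_id), calls))
    return profiles


def write_arm_calls(profiles: Iterable[ArmCallProfile], path: str | Path) -> None:
    rows = [
        {"adenoma_id": p.adenoma_id, "patient_id": p.patient_id, "arm": arm,
         "status": status}
        for p in profiles
        for arm, status in p.calls.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
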