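"""Progression-risk classification of colorectal adenomas from arm-level
DNA copy-number events.

Seven arm-level events are associated with adenoma-to-carcinoma progression
(cancer-associated events, CAEs): gains of 8q, 13q and 20q, and losses of 8p,
15q, 17p and 18q. An adenoma carrying two or more CAEs is classified as high
risk of progressing to cancer; a patient is high risk if at least one of
their adenomas is.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import CAE_ARMS, CAE_DIRECTIONS, ArmCallProfile, FormatError

#: Universe of the seven cancer-associated events.
CAE_UNIVERSE = frozenset(f"{d}_{arm}" for arm, d in CAE_DIRECTIONS.items())

HIGH_RISK_MIN_CAES = 2


@dataclass(frozen=True)
class CaeSet:
    """The cancer-associated events present in one adenoma."""

    events: frozenset[str]

    def __post_init__(self) -> None:
        extra = self.events - CAE_UNIVERSE
        if extra:
            raise ValueError(f"unknown CAEs: {sorted(extra)}")

    @property
    def count(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class RiskLabel:
    adenoma_id: str
    risk: str  # "low" | "high"
    cae_count: int

    def __post_init__(self) -> None:
        if self.risk != ("high" if self.cae_count >= HIGH_RISK_MIN_CAES else "low"):
            raise ValueError("risk label inconsistent with CAE count")


def call_cae(profile: ArmCallProfile) -> CaeSet:
    """Extract the CAEs from an arm-call profile.

    An arm contributes only if its status matches the CAE direction (gain for
    8q/13q/20q, loss for 8p/15q/17p/18q); all other arms are ignored.
    """
    events = set()
    for arm in CAE_ARMS:
        direction = CAE_DIRECTIONS[arm]
        if profile.calls[arm] == direction:
            events.add(f"{direction}_{arm}")
    return CaeSet(frozenset(events))


def classify_adenoma(cae: CaeSet, adenoma_id: str = "") -> RiskLabel:
    """High risk iff the adenoma carries two or more CAEs."""
    risk = "high" if cae.count >= HIGH_RISK_MIN_CAES else "low"
    return RiskLabel(adenoma_id, risk, cae.count)


def classify_profiles(profiles: Iterable[ArmCallProfile]) -> list[RiskLabel]:
    return [classify_adenoma(call_cae(p), p.adenoma_id) for p in profiles]


def classify_patient(labels: Sequence[RiskLabel]) -> str:
    """Patient-level risk: high iff any adenoma is high risk."""
    if not labels:
        raise ValueError("patient has no adenomas; risk undefined")
    return "high" if any(l.risk == "high" for l in labels) else "low"


def patient_risk(profiles: Iterable[ArmCallProfile]) -> dict[str, str]:
    """Map patient_id -> low/high over all their adenomas."""
    by_patient: dict[str, list[RiskLabel]] = defaultdict(list)
    for p in profiles:
        by_patient[p.patient_id].append(classify_adenoma(call_cae(p), p.adenoma_id))
    return {pid: classify_patient(labels) for pid, labels in by_patient.items()}


def summarize_risk(
    labels: Sequence[RiskLabel], morphology: Mapping[str, str]
) -> pd.DataFrame:
    """Frequency of high-risk adenomas, overall and by morphology.

    ``morphology`` maps adenoma_id -> advanced/non_advanced. Returns one row
    per stratum with numerator, denominator and percentage.
    """
    missing = [l.adenoma_id for l in labels if l.adenoma_id not in morphology]
    if missing:
        raise ValueError(f"adenomas without morphology tag: {missing[:5]}")
    rows = []
    strata = {
        "all": labels,
        "advanced": [l for l in labels if morphology[l.adenoma_id] == "advanced"],
        "non_advanced": [
            l for l in labels if morphology[l.adenoma_id] == "non_advanced"
        ],
    }
    for name, grp in strata.items():
        n_high = sum(1 for l in grp if l.risk == "high")
        n = len(grp)
        rows.append(
            {
                "stratum": name,
                "n_high_risk": n_high,
                "n_total": n,
                "pct_high_risk": 100.0 * n_high / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


# --- convenience adapter: arm calls from pre-segmented log2-ratio tables ---

def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like segment table (adenoma_id, patient_id, chrom, start,
    end, log2_ratio; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=0)
    needed = {"adenoma_id", "patient_id", "chrom", "start", "end", "log2_ratio"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: segment table missing columns {sorted(missing)}")
    return df


def read_arm_table(path: str | Path) -> pd.DataFrame:
    """Read arm coordinate boundaries (chrom, arm, start, end)."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = {"chrom", "arm", "start", "end"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: arm table missing columns {sorted(missing)}")
    return df


def arm_calls_from_segments(
    segments: pd.DataFrame,
    arm_table: pd.DataFrame,
    adenoma_id: str,
    patient_id: str,
    gain_thr: float = 0.2,
    loss_thr: float = -0.2,
) -> ArmCallProfile:
    """Call arm status from log2-ratio segments by length-weighted mean.

    An arm is called ``gain`` when the length-weighted mean log2 ratio of the
    segments overlapping it is >= ``gain_thr``, ``loss`` when <= ``loss_thr``,
    else ``neutral``. Arms with no overlapping segment are neutral. The
    thresholds are conventions of this adapter, not calibrated values.
    """
    if not gain_thr > 0 > loss_thr:
        raise ValueError("need gain_thr > 0 > loss_thr")
    segs = segments.sort_values(["chrom", "start"])
    for chrom, grp in segs.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (ends <= starts).any():
            raise FormatError(f"empty or inverted segment on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"overlapping segments on chromosome {chrom}")
    calls: dict[str, str] = {}
    for _, arm in arm_table.iterrows():
        on_chrom = segs[segs["chrom"] == arm["chrom"]]
        ov_start = np.maximum(on_chrom["start"].to_numpy(), arm["start"])
        ov_end = np.minimum(on_chrom["end"].to_numpy(), arm["end"])
        weights = np.clip(ov_end - ov_start, 0, None).astype(float)
        if weights.sum() == 0:
            calls[arm["arm"]] = "neutral"
            continue
        mean = float(
            np.average(on_chrom["log2_ratio"].to_numpy(), weights=weights)
        )
        if mean >= gain_thr:
            calls[arm["arm"]] = "gain"
        elif mean <= loss_thr:
            calls[arm["arm"]] = "loss"
        else:
            calls[arm["arm"]] = "neutral"
    for a in CAE_ARMS:
        calls.setdefault(a, "neutral")
    return ArmCallProfile(adenoma_id, patient_id, calls)
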