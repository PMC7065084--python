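"""Shared domain types for the stool-proteomics panel pipeline.

The pipeline moves three tabular objects around: a spectral-count matrix
(protein groups x stool samples), a per-sample clinical table, and per-adenoma
chromosome-arm copy-number call profiles. Each type validates its own
invariants on construction so downstream stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DIAGNOSIS_LEVELS = ("control", "low_risk_adenoma", "high_risk_adenoma", "crc")
MORPHOLOGY_LEVELS = ("advanced", "non_advanced", "not_applicable")

#: The seven chromosome arms whose copy-number status enters the progression
#: risk rule (gains of 8q/13q/20q, losses of 8p/15q/17p/18q).
CAE_ARMS = ("8p", "8q", "13q", "15q", "17p", "18q", "20q")
ARM_STATUS = ("gain", "neutral", "loss")

#: Direction each arm must change in to count as a cancer-associated event.
CAE_DIRECTIONS: Mapping[str, str] = {
    "8q": "gain",
    "13q": "gain",
    "20q": "gain",
    "8p": "loss",
    "15q": "loss",
    "17p": "loss",
    "18q": "loss",
}


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Protein-group x sample spectral-count matrix.

    Counts are non-negative integers (number of MS/MS spectra assigned to a
    protein group in a sample). Per-sample totals are always recomputed from
    the matrix, never trusted from file.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_proteins, n_samples)
    _totals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.protein_ids, "protein id")
        _check_unique(self.sample_ids, "sample id")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac = counts % 1
            bad = np.argwhere((frac != 0) | ~np.isfinite(counts))
            if bad.size:
                i, j = bad[0]
                raise FormatError(
                    f"non-integral count {counts[i, j]!r} at protein "
                    f"{self.protein_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count {counts[i, j]} at protein "
                f"{self.protein_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        self._totals = None

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def totals(self) -> np.ndarray:
        """Per-sample column sums (cached)."""
        if self._totals is None:
            self._totals = self.counts.sum(axis=0)
        return self._totals

    def protein_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def subset_samples(self, index: Sequence[int]) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            self.protein_ids,
            [self.sample_ids[j] for j in index],
            self.counts[:, index],
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.protein_index(p) for p in protein_ids]
        return CountMatrix(list(protein_ids), self.sample_ids, self.counts[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.protein_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample clinical annotation.

    ``fit_value`` (FIT hemoglobin concentration) and ``hp_value`` (haptoglobin
    immunoassay concentration) are optional assay columns; missing entries are
    kept as NaN and are never imputed.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "diagnosis_class", "morphology")
    OPTIONAL = ("fit_value", "hp_value")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample table missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        _check_unique(list(df["sample_id"]), "sample id")
        bad = set(df["diagnosis_class"]) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise FormatError(
                f"unknown diagnosis_class {sorted(bad)}; allowed: {list(DIAGNOSIS_LEVELS)}"
            )
        bad = set(df["morphology"]) - set(MORPHOLOGY_LEVELS)
        if bad:
            raise FormatError(
                f"unknown morphology {sorted(bad)}; allowed: {list(MORPHOLOGY_LEVELS)}"
            )
        non_adenoma = df["diagnosis_class"].isin(["control", "crc"])
        wrong = non_adenoma != (df["morphology"] == "not_applicable")
        if wrong.any():
            sid = df.loc[wrong, "sample_id"].iloc[0]
            raise FormatError(
                f"sample {sid!r}: morphology must be not_applicable exactly for "
                "control/crc samples"
            )
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def diagnosis(self) -> np.ndarray:
        return self.data["diagnosis_class"].to_numpy()

    def class_counts(self) -> dict[str, int]:
        vc = self.data["diagnosis_class"].value_counts()
        return {lvl: int(vc.get(lvl, 0)) for lvl in DIAGNOSIS_LEVELS}

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.data.loc[np.asarray(mask)].reset_index(drop=True))

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Reorder rows to match ``sample_ids`` (all must be present)."""
        df = self.data.set_index("sample_id", drop=False)
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise FormatError(f"samples absent from sample table: {missing[:5]}")
        return SampleTable(df.loc[list(sample_ids)].reset_index(drop=True))


@dataclass(frozen=True)
class ArmCallProfile:
    """Arm-level copy-number status of one adenoma over the seven CAE arms."""

    adenoma_id: str
    patient_id: str
    calls: Mapping[str, str]

    def __post_init__(self) -> None:
        calls = dict(self.calls)
        missing = [a for a in CAE_ARMS if a not in calls]
        if missing:
            raise FormatError(
                f"adenoma {self.adenoma_id!r}: missing arms {missing}"
            )
        for arm, status in calls.items():
            if status not in ARM_STATUS:
                raise FormatError(
                    f"adenoma {self.adenoma_id!r}, arm {arm!r}: invalid status "
                    f"{status!r}; allowed: {list(ARM_STATUS)}"
                )
        object.__setattr__(self, "calls", calls)


@dataclass
class AnalysisConfig:
    """Run-level constants for the discovery pipeline.

    Thresholds follow the two candidate-selection regimes: the loose regime
    (log2 fold-change > 0, raw p <= 0.1) used for the high-risk-adenoma
    analysis and the strict regime (log2 fold-change >= 2, adjusted p <= 0.05)
    used for the combined high-risk + CRC analysis.
    """

    seed: int = 0
    fc_loose: float = 0.0
    p_loose: float = 0.1
    fc_strict: float = 2.0
    p_strict: float = 0.05
    adjust_method: str = "bh"
    panel_sizes: tuple[int, ...] = (2, 3, 4)
    specificity_target: float = 0.95
    n_boot: int = 2000
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    comparator_protein: str = "HBA1"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.specificity_target < 1:
            raise ValueError("specificity_target must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        for name in ("p_loose", "p_strict"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        self.panel_sizes = tuple(int(k) for k in self.panel_sizes)

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=int(seed))
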