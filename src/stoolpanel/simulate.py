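"""Synthetic stool-proteomics cohorts with known ground truth.

The generator emulates the statistical structure the discovery analysis
assumes: zero-heavy, overdispersed spectral counts over ~790 protein groups
for a case/control cohort (controls, low-risk adenomas, molecularly high-risk
adenomas, CRC), arm-level copy-number profiles whose two-or-more-CAE rule
yields ~16% high-risk adenomas, and FIT/haptoglobin assay values driven by a
shared latent bleeding intensity so the hemoglobin-family correlations arise
by construction.

Counts are drawn from the same beta-binomial law the test assumes
(parameterized by proportion pi and overdispersion phi, Beta(alpha, beta)
with alpha = pi(1-phi)/phi), so parameter-recovery tests are meaningful.
Case effects multiply the affected proteins' proportions by 2^log2fc, after
which each sample's proportions are renormalized; structural zeros are
injected on top at a configured rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cna import call_cae, classify_adenoma
from .types import (
    CAE_ARMS,
    CAE_DIRECTIONS,
    ArmCallProfile,
    CountMatrix,
    SampleTable,
)
from .cna import RiskLabel

#: Proteins with a designated biological role in the generator.
HEMOGLOBIN_PROTEINS = ("HBA1", "HBB")
HAPTOGLOBIN_PROTEIN = "HP"


def cae_event_probability(target_high_risk: float = 0.158, n_arms: int = 7) -> float:
    """Per-arm event probability p with P(Binomial(n_arms, p) >= 2) = target."""
    if not 0 < target_high_risk < 1:
        raise ValueError("target fraction must be in (0, 1)")

    def tail(p: float) -> float:
        return 1.0 - (1 - p) ** n_arms - n_arms * p * (1 - p) ** (n_arms - 1)

    return float(optimize.brentq(lambda p: tail(p) - target_high_risk, 1e-9, 1 - 1e-9))


@dataclass
class CohortDesign:
    """Study conditions for one synthetic cohort.

    Defaults mirror the discovery series: 129 controls, 56 low-risk adenoma,
    15 high-risk adenoma and 79 CRC individuals over 790 protein groups.
    Dispersion and zero-inflation rates are free parameters of the generator
    (the source data report none).
    """

    n_controls: int = 129
    n_low_risk: int = 56
    n_high_risk: int = 15
    n_crc: int = 79
    n_proteins: int = 790
    n_differential_hr: int = 20
    n_differential_crc: int = 60  # total CRC-elevated; superset of the HR set
    effect_log2fc: Sequence[float] | None = None  # drawn U(1.0, 2.5) when None
    base_pi: np.ndarray | None = None  # drawn heavy-tailed when None
    phi: float = 0.005
    library_size_log_mean: float = float(np.log(20000))
    library_size_log_sigma: float = 0.35
    zero_inflation: float = 0.05
    bleeding_log_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 0.0,
            "low_risk_adenoma": 0.3,
            "high_risk_adenoma": 0.8,
            "crc": 2.0,
        }
    )
    bleeding_log_sd: float = 0.8
    hp_bleed_weight: float = 0.7
    hp_tissue_log2: Mapping[str, float] = field(
        default_factory=lambda: {"high_risk_adenoma": 1.0, "crc": 1.3}
    )
    #: differential proteins are drawn from proteins whose baseline
    #: proportion lies inside this quantile band: candidate biomarkers must
    #: be detectable, but a dominant protein would distort every other
    #: proportion through the within-sample renormalization
    differential_abundance_band: tuple[float, float] = (0.5, 0.95)
    mean_extra_adenomas: float = 0.34  # adenomas per patient = 1 + Poisson(this)
    cae_event_prob: float | None = None  # calibrated to 15.8% when None
    p_advanced_given_high: float = 0.80
    p_advanced_given_low: float = 0.26
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_low_risk", "n_high_risk", "n_crc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phi < 0 or self.phi >= 1:
            raise ValueError("phi must be in [0, 1)")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.base_pi is not None:
            base = np.asarray(self.base_pi, dtype=float)
            if np.any(base < 0) or base.sum() > 1.0 + 1e-12:
                raise ValueError("base_pi must be >= 0 with sum <= 1")
        if self.n_differential_crc < self.n_differential_hr:
            raise ValueError("n_differential_crc must be >= n_differential_hr")
        if self.n_differential_crc + 3 > self.n_proteins:
            raise ValueError("too many differential proteins for n_proteins")

    @property
    def n_samples(self) -> int:
        return self.n_controls + self.n_low_risk + self.n_high_risk + self.n_crc


@dataclass
class GroundTruth:
    protein_ids: list[str]
    elevated_in_high_risk: np.ndarray  # bool per protein
    elevated_in_crc: np.ndarray
    true_log2fc: np.ndarray
    bleeding: np.ndarray  # per-sample latent log bleeding intensity
    arm_profiles: list[ArmCallProfile]
    adenoma_risk: list[RiskLabel]
    adenoma_morphology: dict[str, str]


def _protein_ids(n: int) -> list[str]:
    ids = [*HEMOGLOBIN_PROTEINS, HAPTOGLOBIN_PROTEIN]
    ids += [f"PG{i:04d}" for i in range(4, n + 1)]
    return ids


def _draw_profile(rng: np.random.Generator, probs: np.ndarray) -> dict[str, str]:
    calls = {}
    for arm, p in zip(CAE_ARMS, probs):
        if rng.random() < p:
            calls[arm] = CAE_DIRECTIONS[arm]
        else:
            calls[arm] = "neutral"
    return calls


def generate_arm_profiles(
    n_adenomas: int,
    event_probs: float | Mapping[str, float] | None = None,
    seed: int = 0,
    adenoma_ids: Sequence[str] | None = None,
    patient_ids: Sequence[str] | None = None,
) -> tuple[list[ArmCallProfile], list[RiskLabel]]:
    """Independent Bernoulli CAE draws per arm; labels from the >=2 rule.

    ``event_probs`` is a scalar, a per-arm mapping, or None (calibrated so the
    high-risk fraction is 15.8%). Event direction is fixed by the CAE
    definition; a non-event arm is neutral.
    """
    if event_probs is None:
        event_probs = cae_event_probability()
    if isinstance(event_probs, Mapping):
        probs = np.array([event_probs[a] for a in CAE_ARMS], dtype=float)
    else:
        probs = np.full(len(CAE_ARMS), float(event_probs))
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("event probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if adenoma_ids is None:
        adenoma_ids = [f"A{i:04d}" for i in range(1, n_adenomas + 1)]
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(1, n_adenomas + 1)]
    profiles, labels = [], []
    for aid, pid in zip(adenoma_ids, patient_ids):
        prof = ArmCallProfile(aid, pid, _draw_profile(rng, probs))
        profiles.append(prof)
        labels.append(classify_adenoma(call_cae(prof), aid))
    return profiles, labels


def _conditional_profile(
    rng: np.random.Generator, probs: np.ndarray, want_high: bool
) -> dict[str, str]:
    """Rejection-sample an arm profile with the requested risk label."""
    for _ in range(100000):
        calls = _draw_profile(rng, probs)
        n_cae = sum(
            1 for arm in CAE_ARMS if calls[arm] == CAE_DIRECTIONS[arm]
        )
        if (n_cae >= 2) == want_high:
            return calls
    raise RuntimeError("rejection sampling failed; event probabilities degenerate")


def generate_cohort(
    design: CohortDesign,
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Generate a full synthetic cohort. Deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    P, S = design.n_proteins, design.n_samples
    ids = _protein_ids(P)

    # baseline proportions: heavy-tailed so a few proteins dominate totals
    if design.base_pi is not None:
        base_pi = np.asarray(design.base_pi, dtype=float).copy()
        base_pi = base_pi / max(base_pi.sum(), 1e-300)
    else:
        w = rng.lognormal(mean=0.0, sigma=2.0, size=P)
        w[:3] = np.quantile(w, 0.90)  # hemoglobin-family proteins are abundant
        base_pi = w / w.sum()

    # truth flags: HP is elevated in high-risk and CRC; the remaining
    # differential proteins are drawn from the generic pool
    elev_hr = np.zeros(P, dtype=bool)
    elev_crc = np.zeros(P, dtype=bool)
    true_fc = np.zeros(P)
    if design.n_differential_crc > 0:
        pool = np.arange(3, P)
        lo, hi = np.quantile(base_pi[pool], design.differential_abundance_band)
        pool = pool[(base_pi[pool] >= lo) & (base_pi[pool] <= hi)]
        chosen = rng.choice(pool, size=design.n_differential_crc - 1, replace=False)
        crc_idx = np.r_[2, chosen]  # HP is always part of the elevated set
        hr_idx = crc_idx[: design.n_differential_hr]
        elev_hr[hr_idx] = True
        elev_crc[crc_idx] = True
        if design.effect_log2fc is not None:
            eff = np.asarray(design.effect_log2fc, dtype=float)
            if eff.shape != (design.n_differential_crc,):
                raise ValueError(
                    "effect_log2fc must have one entry per CRC-elevated protein"
                )
        else:
            eff = rng.uniform(1.0, 2.5, size=design.n_differential_crc)
        true_fc[crc_idx] = eff

    # samples and classes
    classes = (
        ["control"] * design.n_controls
        + ["low_risk_adenoma"] * design.n_low_risk
        + ["high_risk_adenoma"] * design.n_high_risk
        + ["crc"] * design.n_crc
    )
    sample_ids = [f"S{i:04d}" for i in range(1, S + 1)]
    patient_ids = [f"P{i:04d}" for i in range(1, S + 1)]

    # latent bleeding intensity (log scale)
    mu = np.array([design.bleeding_log_mean[c] for c in classes])
    bleeding = mu + design.bleeding_log_sd * rng.standard_normal(S)

    # per-sample proportions
    is_hr = np.array([c == "high_risk_adenoma" for c in classes])
    is_crc = np.array([c == "crc" for c in classes])
    pi = np.tile(base_pi[:, None], (1, S))
    pi[np.ix_(elev_hr, is_hr)] *= 2.0 ** true_fc[elev_hr][:, None]
    pi[np.ix_(elev_crc, is_crc)] *= 2.0 ** true_fc[elev_crc][:, None]
    hb = np.exp(bleeding)
    pi[0:2, :] *= hb[None, :]
    pi[2, :] *= np.exp(design.hp_bleed_weight * bleeding)
    pi /= pi.sum(axis=0, keepdims=True)

    totals = rng.lognormal(
        design.library_size_log_mean, design.library_size_log_sigma, size=S
    )
    totals = np.maximum(totals.astype(np.int64), 200)

    phi = design.phi
    if phi < 1e-12:
        counts = rng.binomial(totals[None, :], pi)
    else:
        a = pi * (1 - phi) / phi
        b = (1 - pi) * (1 - phi) / phi
        p_draw = rng.beta(a, b)
        counts = rng.binomial(totals[None, :], p_draw)
    if design.zero_inflation > 0:
        counts[rng.random(counts.shape) < design.zero_inflation] = 0

    # adenomas and arm profiles, consistent with the designed patient classes
    event_p = (
        design.cae_event_prob
        if design.cae_event_prob is not None
        else cae_event_probability()
    )
    probs = np.full(len(CAE_ARMS), event_p)
    profiles: list[ArmCallProfile] = []
    adenoma_risk: list[RiskLabel] = []
    morphology: dict[str, str] = {}
    sample_morph: list[str] = []
    a_counter = 0
    for sid, pid, cls in zip(sample_ids, patient_ids, classes):
        if cls not in ("low_risk_adenoma", "high_risk_adenoma"):
            sample_morph.append("not_applicable")
            continue
        n_aden = 1 + rng.poisson(design.mean_extra_adenomas)
        patient_advanced = False
        for a in range(n_aden):
            a_counter += 1
            aid = f"A{a_counter:04d}"
            if cls == "low_risk_adenoma":
                calls = _conditional_profile(rng, probs, want_high=False)
            elif a == 0:
                calls = _conditional_profile(rng, probs, want_high=True)
            else:
                calls = _draw_profile(rng, probs)
            prof = ArmCallProfile(aid, pid, calls)
            label = classify_adenoma(call_cae(prof), aid)
            profiles.append(prof)
            adenoma_risk.append(label)
            p_adv = (
                design.p_advanced_given_high
                if label.risk == "high"
                else design.p_advanced_given_low
            )
            adv = rng.random() < p_adv
            morphology[aid] = "advanced" if adv else "non_advanced"
            patient_advanced = patient_advanced or adv
        sample_morph.append("advanced" if patient_advanced else "non_advanced")

    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": patient_ids,
                "diagnosis_class": classes,
                "morphology": sample_morph,
                "fit_value": np.nan,
                "hp_value": np.nan,
            }
        )
    )
    matrix = CountMatrix(ids, sample_ids, counts)
    truth = GroundTruth(
        ids, elev_hr, elev_crc, true_fc, bleeding, profiles, adenoma_risk, morphology
    )
    return matrix, table, truth


@dataclass
class AssayNoise:
    """Noise model for the FIT and haptoglobin immunoassay values.

    Both assays are monotone (exponential) functions of the latent bleeding
    intensity plus independent log-scale Gaussian noise; haptoglobin gains an
    additional tissue-derived component in high-risk adenoma and CRC samples.
    """

    fit_sigma: float = 0.8
    hp_sigma: float = 0.6
    hp_bleed_weight: float = 0.7
    hp_tissue_log2: Mapping[str, float] = field(
        default_factory=lambda: {"high_risk_adenoma": 1.0, "crc": 1.3}
    )
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.fit_sigma < 0 or self.hp_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @classmethod
    def for_target_rho(
        cls, rho: float, bleeding_sd: float = 0.8, hp_bleed_weight: float = 0.7
    ) -> "AssayNoise":
        """Calibrate the FIT noise so Spearman(FIT, Hp) hits ``rho``.

        Uses the Gaussian-copula relation rho_s = (6/pi) asin(r/2): all noise
        is placed on FIT, no tissue component, so the FIT/Hp log-scale
        Pearson correlation r determines the Spearman correlation.
        """
        if not 0 < rho < 1:
            raise ValueError("target rho must be in (0, 1)")
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        sigma = bleeding_sd * np.sqrt(1.0 / r**2 - 1.0)
        return cls(
            fit_sigma=float(sigma),
            hp_sigma=0.0,
            hp_bleed_weight=hp_bleed_weight,
            hp_tissue_log2={},
        )


def generate_assay_values(
    sample_table: SampleTable,
    truth: GroundTruth,
    noise: AssayNoise = AssayNoise(),
    seed: int = 0,
) -> SampleTable:
    """Fill fit_value and hp_value from the latent bleeding intensity."""
    rng = np.random.default_rng(seed)
    b = np.asarray(truth.bleeding, dtype=float)
    n = len(sample_table)
    if b.shape != (n,):
        raise ValueError("bleeding intensity must align with the sample table")
    fit = np.exp(b + noise.fit_sigma * rng.standard_normal(n))
    tissue = np.array(
        [
            np.log(2.0) * noise.hp_tissue_log2.get(c, 0.0)
            for c in sample_table.diagnosis
        ]
    )
    hp = np.exp(
        noise.hp_bleed_weight * b + tissue + noise.hp_sigma * rng.standard_normal(n)
    )
    if noise.missing_rate > 0:
        fit[rng.random(n) < noise.missing_rate] = np.nan
        hp[rng.random(n) < noise.missing_rate] = np.nan
    df = sample_table.data.copy()
    df["fit_value"] = fit
    df["hp_value"] = hp
    return SampleTable(df)
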