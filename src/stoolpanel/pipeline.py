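"""End-to-end discovery and validation runs.

``run_discovery`` chains the full analysis: arm-level risk classification,
case-definition labelling (high-risk adenomas only; high-risk + CRC),
beta-binomial differential abundance under the matching threshold regime,
lasso panel construction for the configured sizes, leave-one-out
cross-validated ROC evaluation against the hemoglobin comparator with
stratified bootstrap comparison, and application of the panel cutoff to the
held-out low-risk adenomas. Everything is deterministic given the config
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import cna, diffabund, evaluate, lasso
from .types import AnalysisConfig, ArmCallProfile, CountMatrix, SampleTable
from .validation import group_fold_change, spearman_corr

logger = logging.getLogger("stoolpanel")

SCHEMA_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def comparator_scores(m: CountMatrix, protein: str) -> np.ndarray:
    """Per-sample comparator score: log2(normalized count + 1) of one protein."""
    norm = diffabund.normalize_counts(m)
    return np.log2(norm[m.protein_index(protein)] + 1.0)


def relabel_from_arm_calls(
    samples: SampleTable, profiles: Sequence[ArmCallProfile]
) -> SampleTable:
    """Assign low/high-risk adenoma classes from patient-level CNA risk."""
    risk = cna.patient_risk(profiles)
    df = samples.data.copy()
    adenoma = df["diagnosis_class"].isin(["low_risk_adenoma", "high_risk_adenoma"])
    missing = sorted(set(df.loc[adenoma, "patient_id"]) - set(risk))
    if missing:
        raise ValueError(f"adenoma patients without arm calls: {missing[:5]}")
    df.loc[adenoma, "diagnosis_class"] = [
        "high_risk_adenoma" if risk[p] == "high" else "low_risk_adenoma"
        for p in df.loc[adenoma, "patient_id"]
    ]
    return SampleTable(df)


def _case_definition(samples: SampleTable, include_crc: bool) -> np.ndarray | None:
    """Mask selecting the analysis samples; parallel case mask returned too."""
    diag = samples.diagnosis
    cases = ["high_risk_adenoma"] + (["crc"] if include_crc else [])
    keep = np.isin(diag, ["control"] + cases)
    case = np.isin(diag, cases)
    return keep, case


def _evaluate_panel(
    m_cc: CountMatrix,
    y: np.ndarray,
    candidates: list[str],
    k: int,
    comparator: np.ndarray,
    config: AnalysisConfig,
    seed: int,
    m_low: CountMatrix | None,
) -> dict:
    path_spec = lasso.PathSpec(config.n_lambda, config.lambda_min_ratio)
    cv = evaluate.loocv_predict(m_cc, y, candidates, k, path_spec)
    rep = evaluate.sensitivity_at_specificity(cv.prob, y, config.specificity_target)
    comp_rep = evaluate.sensitivity_at_specificity(
        comparator, y, config.specificity_target
    )
    boot = evaluate.compare_pauc_bootstrap(
        cv.prob, comparator, y, config.n_boot, seed, config.specificity_target
    )
    out = {
        "k": k,
        "cv_status_counts": {
            s: cv.fold_status.count(s) for s in sorted(set(cv.fold_status))
        },
        "selection_frequency": {
            p: f for p, f in sorted(
                cv.selection_frequency.items(), key=lambda kv: -kv[1]
            ) if f > 0
        },
        "pauc_raw": rep.pauc_raw,
        "pauc_std": rep.pauc_std,
        "sens_at_spec": rep.sens_at_spec,
        "sens_ci": rep.ci,
        "confusion": rep.confusion,
        "threshold": rep.threshold,
        "comparator_pauc_std": comp_rep.pauc_std,
        "comparator_sens_at_spec": comp_rep.sens_at_spec,
        "comparator_sens_ci": comp_rep.ci,
        "comparator_confusion": comp_rep.confusion,
        "bootstrap_vs_comparator": {
            "delta_pauc_std": boot.delta,
            "d_stat": boot.d_stat,
            "p_value": boot.p_value,
            "n_boot": boot.n_boot,
        },
        "note": (
            "candidate list computed once on the full dataset and held fixed "
            "inside LOOCV; cross-validated performance is optimistic to that "
            "extent"
        ),
    }
    # held-out low-risk adenomas: full-data panel model, cutoff at the
    # specificity target on the case/control scores of that same model
    if m_low is not None and m_low.n_samples > 0:
        X_full, tf = lasso.build_features(m_cc, candidates)
        panel = lasso.select_panel(X_full, y, k, path_spec, tf.feature_names)
        if panel.status == "constructed":
            scores_cc = lasso.predict_prob(panel.model, X_full)
            full_rep = evaluate.sensitivity_at_specificity(
                scores_cc, y, config.specificity_target
            )
            held = evaluate.apply_to_held_out(
                full_rep.threshold, lasso.predict_prob(panel.model, tf.apply(m_low))
            )
            out["held_out_low_risk"] = {
                "n_positive": held.n_positive,
                "n_total": held.n_total,
                "fraction": held.fraction,
                "ci": held.ci,
            }
    return out


def run_discovery(
    config: AnalysisConfig,
    m: CountMatrix,
    samples: SampleTable,
    arm_profiles: Sequence[ArmCallProfile] | None = None,
    adenoma_morphology: Mapping[str, str] | None = None,
) -> dict:
    """Run the discovery analysis; returns the JSON-serializable run report."""
    samples = samples.aligned_to(m.sample_ids)
    report: dict = {"schema_version": SCHEMA_VERSION, "config": asdict(config)}

    # 1. molecular risk classification
    if arm_profiles is not None:
        labels = cna.classify_profiles(arm_profiles)
        if adenoma_morphology is None:
            morph_by_patient = dict(
                zip(samples.data["patient_id"], samples.data["morphology"])
            )
            adenoma_morphology = {
                p.adenoma_id: morph_by_patient.get(p.patient_id, "non_advanced")
                for p in arm_profiles
            }
        report["risk_summary"] = cna.summarize_risk(
            labels, adenoma_morphology
        ).to_dict(orient="records")
        samples = relabel_from_arm_calls(samples, arm_profiles)
    report["class_counts"] = samples.class_counts()

    rng = np.random.SeedSequence(config.seed)
    boot_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2)]

    analyses = {
        "high_risk": {"include_crc": False, "strict": False},
        "high_risk_plus_crc": {"include_crc": True, "strict": True},
    }
    candidate_lists: dict[str, list[str]] = {}
    for name, spec_ in analyses.items():
        keep, case = _case_definition(samples, spec_["include_crc"])
        m_cc = m.subset_samples(np.flatnonzero(keep))
        y = case[keep].astype(int)
        de = diffabund.de_table(m_cc, y.astype(bool), config.adjust_method)
        if spec_["strict"]:
            cands = diffabund.select_candidates(
                de, config.fc_strict, config.p_strict, use_adjusted=True, strict_fc=True
            )
        else:
            cands = diffabund.select_candidates(
                de, config.fc_loose, config.p_loose, use_adjusted=False, strict_fc=False
            )
        candidate_lists[name] = cands
        low_mask = samples.diagnosis == "low_risk_adenoma"
        m_low = m.subset_samples(np.flatnonzero(low_mask))
        comparator = comparator_scores(m_cc, config.comparator_protein)
        panels = {}
        seed = boot_seeds[0 if name == "high_risk" else 1]
        for k in config.panel_sizes:
            if not cands or k > len(cands):
                panels[str(k)] = {"status": "not_constructible",
                                  "reason": "too few candidates"}
                continue
            X, tf = lasso.build_features(m_cc, cands)
            presult = lasso.select_panel(
                X, y, k,
                lasso.PathSpec(config.n_lambda, config.lambda_min_ratio),
                tf.feature_names,
            )
            entry = {"status": presult.status,
                     "size_sequence": sorted(set(presult.size_sequence))}
            if presult.status == "constructed":
                entry["selected"] = presult.model.selected
                entry.update(
                    _evaluate_panel(
                        m_cc, y, cands, k, comparator, config, seed, m_low
                    )
                )
            panels[str(k)] = entry
        report[name] = {
            "n_candidates": len(cands),
            "candidates": cands,
            "de_table_rows": len(de),
            "panels": panels,
        }

    a, b = set(candidate_lists["high_risk"]), set(candidate_lists["high_risk_plus_crc"])
    overlap = sorted(a & b)
    if a and b:
        report["candidate_overlap"] = {
            "k": len(overlap),
            "proteins": overlap,
            "p_hypergeom": diffabund.hypergeom_overlap(
                len(overlap), len(a), len(b), m.n_proteins
            ),
        }
    return _jsonable(report)


def run_validation(config: AnalysisConfig, samples: SampleTable) -> dict:
    """Immunoassay validation: Hp group comparisons and FIT correlations."""
    df = samples.data
    if df["hp_value"].isna().all():
        raise ValueError("hp_value column is entirely missing")
    diag = samples.diagnosis
    ctrl = df.loc[diag == "control", "hp_value"].to_numpy()
    if np.isfinite(ctrl).sum() == 0:
        raise ValueError("no control samples with Hp values: no comparison group")
    out: dict = {"schema_version": SCHEMA_VERSION, "groups": {}}
    for cls in ("low_risk_adenoma", "high_risk_adenoma", "crc"):
        vals = df.loc[diag == cls, "hp_value"].to_numpy()
        vals = vals[np.isfinite(vals)]
        ctrl_ok = ctrl[np.isfinite(ctrl)]
        if len(vals) == 0:
            continue
        g = group_fold_change(
            np.r_[vals, ctrl_ok], np.r_[np.ones(len(vals)), np.zeros(len(ctrl_ok))]
        )
        out["groups"][cls] = {
            "fold_change": g.fold_change,
            "fold_change_median": g.fold_change_median,
            "p_value": g.p_value,
            "n_case": g.n_case,
            "n_control": g.n_control,
            "method": g.method,
        }
    fit = df["fit_value"].to_numpy()
    hp = df["hp_value"].to_numpy()
    if np.sum(np.isfinite(fit) & np.isfinite(hp)) >= 3:
        c = spearman_corr(fit, hp)
        out["spearman_hp_vs_fit"] = {
            "rho": c.rho, "p_value": c.p_value, "n_used": c.n_used
        }
    return _jsonable(out)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
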