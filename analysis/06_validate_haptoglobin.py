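"""Haptoglobin validation statistics on the simulated assay values.

Compares haptoglobin concentrations between each case class and controls
(fold-change of group means, Wilcoxon rank-sum p), and correlates the
haptoglobin and hemoglobin mass-spectrometry abundances with the FIT values
(Spearman, missing values excluded pairwise). Writes
results/validation.json.
"""

import json
from pathlib import Path

import numpy as np

from stoolpanel import diffabund, io
from stoolpanel.pipeline import run_validation
from stoolpanel.types import AnalysisConfig
from stoolpanel.validation import spearman_corr

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    m = io.read_count_matrix(DATA / "counts.tsv")
    samples = io.read_sample_table(DATA / "samples.tsv").aligned_to(m.sample_ids)

    report = run_validation(AnalysisConfig(), samples)
    for cls, g in report["groups"].items():
        print(
            f"Hp {cls} vs control: fold-change {g['fold_change']:.1f} "
            f"(medians {g['fold_change_median']:.1f}), p = {g['p_value']:.2g} "
            f"({g['method']}, n = {g['n_case']}/{g['n_control']})"
        )

    norm = diffabund.normalize_counts(m)
    fit = samples.data["fit_value"].to_numpy()
    report["spearman_vs_fit_counts"] = {}
    for protein in ("HBA1", "HBB", "HP"):
        counts = norm[m.protein_index(protein)]
        r = spearman_corr(counts, fit)
        report["spearman_vs_fit_counts"][protein] = {
            "rho": r.rho, "p_value": r.p_value, "n_used": r.n_used
        }
        print(f"Spearman {protein} counts vs FIT: rho = {r.rho:.2f} "
              f"(p = {r.p_value:.2g}, n = {r.n_used})")

    with open(ROOT / "results" / "validation.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
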