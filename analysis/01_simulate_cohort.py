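"""Generate the synthetic discovery cohort used by the downstream analyses.

Draws a cohort at the study design conditions (129 controls, 56 low-risk
adenoma, 15 high-risk adenoma and 79 CRC individuals over 790 protein
groups), attaches FIT and haptoglobin assay values driven by the latent
bleeding intensity, and writes counts.tsv / samples.tsv / arm_calls.tsv /
truth.json under results/data/.
"""

import json
from pathlib import Path

from stoolpanel import io
from stoolpanel.simulate import (
    AssayNoise,
    CohortDesign,
    generate_assay_values,
    generate_cohort,
)

SEED = 20240101
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = CohortDesign(seed=SEED)
    matrix, samples, truth = generate_cohort(design)
    samples = generate_assay_values(samples, truth, AssayNoise(), seed=SEED + 1)

    io.write_count_matrix(matrix, OUT / "counts.tsv")
    io.write_sample_table(samples, OUT / "samples.tsv")
    io.write_arm_calls(truth.arm_profiles, OUT / "arm_calls.tsv")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": SEED,
                "elevated_in_high_risk": [
                    p for p, f in zip(truth.protein_ids, truth.elevated_in_high_risk) if f
                ],
                "elevated_in_crc": [
                    p for p, f in zip(truth.protein_ids, truth.elevated_in_crc) if f
                ],
                "adenoma_risk": {l.adenoma_id: l.risk for l in truth.adenoma_risk},
                "adenoma_morphology": truth.adenoma_morphology,
            },
            fh,
            indent=2,
        )
    print(f"cohort: {matrix.n_proteins} proteins x {matrix.n_samples} samples")
    print(f"classes: {samples.class_counts()}")
    print(f"adenomas with arm calls: {len(truth.arm_profiles)}")
    print(f"wrote {OUT}/counts.tsv, samples.tsv, arm_calls.tsv, truth.json")


if __name__ == "__main__":
    main()
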