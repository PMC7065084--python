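"""Lasso-logistic biomarker panels of two, three and four proteins.

For each case definition, fits the L1-regularized logistic path over the
candidate proteins and walks it from sparse to dense looking for panels of
exactly 2, 3 and 4 proteins. Correlated candidates can enter or leave the
active set together, in which case a size is skipped and that panel is
reported as not constructible. Writes results/panels.json.
"""

import json
from pathlib import Path

import numpy as np

from stoolpanel import io, lasso

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    m = io.read_count_matrix(DATA / "counts.tsv")
    samples = io.read_sample_table(DATA / "samples.tsv").aligned_to(m.sample_ids)

    out = {}
    for name, case_classes in (
        ("high_risk", ["high_risk_adenoma"]),
        ("high_risk_plus_crc", ["high_risk_adenoma", "crc"]),
    ):
        cands = (ROOT / "results" / f"candidates_{name}.txt").read_text().split()
        keep = np.isin(samples.diagnosis, ["control"] + case_classes)
        sub = m.subset_samples(np.flatnonzero(keep))
        y = np.isin(samples.diagnosis[keep], case_classes).astype(int)
        X, tf = lasso.build_features(sub, cands)
        out[name] = {}
        print(f"{name} ({len(cands)} candidates):")
        for k in (2, 3, 4):
            if k > len(cands):
                print(f"  k={k}: too few candidates")
                continue
            res = lasso.select_panel(X, y, k, feature_names=tf.feature_names)
            if res.status == "constructed":
                out[name][k] = {"status": res.status, "selected": res.model.selected}
                print(f"  k={k}: {', '.join(res.model.selected)}")
            else:
                out[name][k] = {
                    "status": res.status,
                    "size_sequence": sorted(set(res.size_sequence)),
                }
                print(
                    f"  k={k}: not constructible (sizes seen on path: "
                    f"{sorted(set(res.size_sequence))})"
                )
    with open(ROOT / "results" / "panels.json", "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    main()
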