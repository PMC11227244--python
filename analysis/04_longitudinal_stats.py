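#!/usr/bin/env python
"""Longitudinal phageome statistics from the completed pipeline run.

Collects the phageome partition (donor-shared / baseline-conserved /
novel), the week-6-anchored variability comparison, vOTU stability
categories, alpha-diversity contrasts and lifestyle totals into
results/, with a short narrative of what was significant.
"""

import shutil
from pathlib import Path

import pandas as pd

from phagefmt import io as pio

ROOT = Path(__file__).resolve().parents[1]

TABLES = {
    "partition.tsv": "partition_by_origin.tsv",
    "stats/variability_tests.tsv": "variability_tests.tsv",
    "stats/stability_table.tsv": "stability_categories.tsv",
    "stats/alpha_tests.tsv": "alpha_diversity_tests.tsv",
    "stats/lifestyle_tests.tsv": "lifestyle_tests.tsv",
}


def main() -> None:
    run = ROOT / "scratch" / "run"
    if not run.exists():
        raise SystemExit("run analysis/02_run_pipeline.py first")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for src, dst in TABLES.items():
        if (run / src).exists():
            shutil.copy(run / src, results / dst)

    part = pio.read_tsv(run / "partition.tsv")
    for col in part.columns:
        if col.startswith(("p_", "n_")):
            part[col] = part[col].astype(float)
    meta = pio.read_tsv(ROOT / "scratch" / "cohort" / "metadata.tsv")
    arm = dict(zip(meta["subject_id"], meta["treatment"]))
    part["arm"] = part["subject"].map(arm)
    post = part[part["timepoint"] != "baseline"]
    shares = post.groupby("arm")[["p_shared_with_donors", "p_novel"]].mean()
    print("mean post-treatment vOTU origin proportions by arm:")
    print(shares.to_string(float_format="%.3f"))

    for name, label in (("stats/alpha_tests.tsv", "alpha diversity"),
                        ("stats/lifestyle_tests.tsv", "lifestyle totals"),
                        ("stats/variability_tests.tsv", "variability")):
        path = run / name
        if not path.exists():
            continue
        tests = pd.read_csv(path, sep="\t")
        sig = tests[tests["q"] <= 0.05]
        print(f"\n{label}: {len(sig)} of {len(tests)} contrasts with q <= 0.05")
        if not sig.empty:
            print(sig.to_string(index=False))


if __name__ == "__main__":
    main()
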