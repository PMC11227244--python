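#!/usr/bin/env python
"""Parameter-recovery benchmarks of the pipeline against ground truth.

Runs the fast validation studies (ANI-vs-Hamming agreement, clone
threshold operating characteristics, CPM conservation, engraftment
recall/precision on the default cohort) and writes
results/recovery_benchmarks.tsv. The replicate-based studies
(diversity-efficacy correlation, type-I control, temperate recovery)
are exercised by scripts/acceptance.py and the test suite.
"""

from pathlib import Path

import pandas as pd

from phagefmt import benchmarks as B

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    rows = []
    ani = B.ani_oracle_agreement(SEED)
    rows.append(("ani_max_abs_error_pct", ani["max_abs_error_pct"], ani["n"]))
    clone = B.clone_threshold_rates(SEED)
    rows.append(("clone_sensitivity", clone["sensitivity"], clone["n"]))
    rows.append(("clone_specificity", clone["specificity"], clone["n"]))
    cpm = B.cpm_conservation(SEED)
    rows.append(("cpm_max_rel_deviation", cpm["max_rel_deviation"], cpm["n"]))
    rec = B.default_recovery(SEED)
    rows.append(("engraftment_recall", rec["recall"], rec["n_true_transfers"]))
    rows.append(("engraftment_precision", rec["precision"], rec["n_true_transfers"]))
    rows.append(("placebo_events", rec["placebo_events"], rec["n_true_transfers"]))

    df = pd.DataFrame(rows, columns=["metric", "value", "n"])
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    df.to_csv(results / "recovery_benchmarks.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
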