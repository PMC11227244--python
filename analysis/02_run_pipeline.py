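#!/usr/bin/env python
"""Run the full phageome pipeline on the simulated cohort.

Screens contigs with the viral decision rules, clusters UViGs into
vOTUs (ANI >= 95% / AF >= 85%), detects clone pairs (ANI >= 99.4%),
quantifies vOTU abundance via the gene catalog (RPK -> CPM -> median ->
sum), calls engraftment events, and computes the longitudinal
statistics. Expects scratch/cohort/ from 01_simulate_cohort.py; the
full run lands in scratch/run/ and the headline summary in
results/pipeline_summary.tsv.
"""

import logging
import shutil
from pathlib import Path

from phagefmt.pipeline import RunConfig, run_all

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    cohort_dir = ROOT / "scratch" / "cohort"
    if not cohort_dir.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cfg = RunConfig(seed=SEED, simulate=False, input_dir=str(cohort_dir))
    result = run_all(cfg, ROOT / "scratch" / "run")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    shutil.copy(result.run_dir / "summary.tsv", results / "pipeline_summary.tsv")
    print("\nfunnel:", result.funnel)
    print(f"events: {len(result.events)}; summary -> results/pipeline_summary.tsv")


if __name__ == "__main__":
    main()
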