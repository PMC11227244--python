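#!/usr/bin/env python
"""Donor engraftment efficacy and its relation to phageome diversity.

From the completed pipeline run (scratch/run/): per-donor engraftment
efficacy with the chi-squared homogeneity test, and the Pearson
correlation between each donor's Shannon diversity (from the vOTU
abundance profiles) and their efficacy. Writes
results/efficacy_by_donor.tsv.
"""

from pathlib import Path

from phagefmt import io as pio
from phagefmt.stats import pearson_test, shannon

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    run = ROOT / "scratch" / "run"
    if not run.exists():
        raise SystemExit("run analysis/02_run_pipeline.py first")
    efficacy = pio.read_tsv(run / "efficacy.tsv")
    efficacy["efficacy"] = efficacy["efficacy"].astype(float)
    for col in ("n_votus_donor", "n_engrafted"):
        efficacy[col] = efficacy[col].astype(int)
    abund = pio.read_matrix(run / "votu_abundance.tsv")
    metadata = pio.read_metadata(ROOT / "scratch" / "cohort" / "metadata.tsv")
    donor_samples = {m.subject_id: m.sample_id for m in metadata
                     if m.role.value == "donor"}
    efficacy["shannon"] = [
        shannon(abund[donor_samples[d]].to_numpy()) for d in efficacy["donor_id"]
    ]
    r, p = pearson_test(efficacy["shannon"], efficacy["efficacy"])

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pio.write_tsv(efficacy, results / "efficacy_by_donor.tsv")
    print(efficacy.to_string(index=False))
    print(f"\ndiversity-efficacy Pearson r = {r:.3f} (two-sided p = {p:.4f})")
    overall = efficacy["n_engrafted"].sum() / efficacy["n_votus_donor"].sum()
    print(f"pooled per-donor efficacy = {overall:.3f}")


if __name__ == "__main__":
    main()
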