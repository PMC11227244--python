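# phagefmt

Gut phageome analysis for fecal microbiota transplantation (FMT) trials:
from annotated viral contigs and gene-level read counts to viral OTUs,
clone-level donor engraftment events, per-donor engraftment efficacy,
phageome origin partitions, and longitudinal diversity/stability
statistics — together with a ground-truthed synthetic cohort generator so
the whole pipeline is testable without access to raw sequencing data.

It is written for microbiome researchers who track *which donor phages
establish in which recipients* in a sex-matched, multi-donor,
placebo-controlled FMT design with stool sampling at baseline and weeks
6, 12 and 26.

## The model in brief

* **UViGs → vOTUs.** Uncultivated virus genomes (assembled viral contigs)
  are screened with decision rules on their annotations (viral/host/hallmark
  gene counts, classifier score; false positives at host genes > 4 or
  host-to-viral ratio > 0.386) and clustered into viral operational
  taxonomic units at ANI ≥ 95% over an alignment fraction ≥ 85% of the
  shorter sequence, computed by a fragment-mapping ANI estimator. The
  longest member represents each vOTU; only vOTUs whose representative has
  completeness ≥ 90% enter the analyses.
* **Clones → engraftment.** Two same-vOTU UViGs at ANI ≥ 99.4% / AF ≥ 0.85
  are clones of one phage lineage. A donor phage is *engrafted* when a clone
  is found in a sex-matched recipient from week 6 onward but not at that
  recipient's baseline. Donor efficacy = engrafted / identified vOTUs per
  donor (vOTUs carried by several donors count for each).
* **Abundance.** Gene counts → RPK (per-kilobase) → CPM (per-sample sums of
  10⁶) → UViG abundance as the median CPM over its catalog genes → vOTU
  abundance as the member sum.
* **Ecology.** Shannon diversity H = −Σ p ln p, Bray–Curtis dissimilarity
  Σ|a−b|/Σ(a+b), Wilcoxon rank-sum, Pearson χ² with standardized-residual
  post hoc, Pearson correlation, and linear mixed models
  (treatment × timepoint, random intercept per subject) with
  Benjamini–Hochberg FDR within declared families.

See `docs/methods.md` for the full specification of rules, parameters and
the synthetic generator.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library; big intermediates go to `scratch/`, tables to
`results/`):

```bash
python analysis/01_simulate_cohort.py   # synthetic trial + ground truth
python analysis/02_run_pipeline.py      # screen -> cluster -> quantify -> engraft -> stats
python analysis/03_engraftment.py       # efficacy per donor vs donor diversity
python analysis/04_longitudinal_stats.py
python analysis/05_recovery_benchmarks.py
```

`03_engraftment.py` prints, for the default seed-1 cohort (8 donors,
20 FMT + 20 placebo recipients):

```
donor_id  n_votus_donor  n_engrafted  efficacy  shannon
    DF01             44           31  0.704545 3.007290
    DF02             39           27  0.692308 2.079728
    DF03             39           25  0.641026 2.900957
    DF04             53           43  0.811321 2.994768
    DM01             44           34  0.772727 3.109964
    DM02             42           16  0.380952 2.359397
    DM03             36           27  0.750000 2.770257
    DM04             46           32  0.695652 2.462141

diversity-efficacy Pearson r = 0.503 (two-sided p = 0.2041)
pooled per-donor efficacy = 0.685
```

Each row is one donor: how many vOTUs were identified in their stool, how
many of those engrafted in at least one sex-matched FMT recipient, the
resulting efficacy, and the donor's Shannon diversity estimated from the
quantified vOTU profiles. The least diverse male donor (DM02, H = 2.36)
has by far the lowest efficacy (0.38) — the diversity–engraftment relation
the pipeline is built to measure. All 390 called events in this cohort are
true simulated transfers, and the placebo arm yields zero events
(`05_recovery_benchmarks.py`).

The same stages are available as a CLI (`phagefmt simulate|screen|cluster|
quantify|engraft|stats|run-all|report`); `phagefmt run-all --seed 1 --out
DIR` reproduces the whole run from one YAML-configurable entry point.

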