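# Methods

`phagefmt` analyzes the gut phageome of a sex-stratified, multi-donor,
placebo-controlled fecal microbiota transplantation (FMT) trial from
assembled viral contigs and gene-level read counts. This note documents the
models, decision rules, parameters and numerical choices, and what the
synthetic cohort generator does and does not emulate.

## Pipeline model

### Viral screening

Inputs are per-contig annotations produced upstream by viral-classification
and quality-estimation tools (consumed here as data). A contig is a putative
uncultivated virus genome (UViG) if any of:

* ≥ 1 predicted viral gene,
* zero predicted host genes,
* classifier score ≥ 0.95,
* ≥ 3 viral hallmark genes.

Included contigs are removed as false positives when host-gene evidence
dominates: host genes > 4, or host-to-viral gene ratio (HVR) > 0.386. All
comparators follow the printed rule exactly (strict `>` for the
false-positive cuts, inclusive `≥` elsewhere), so `host_genes == 4` and
`HVR == 0.386` are kept while `score == 0.95` and `completeness == 90` pass.
HVR with zero viral genes is defined as +∞ (flagged) when host genes exist
and 0 when both counts are zero; the inclusion rule makes the first case
unreachable in practice, but the definition keeps the operator total. The
completeness ≥ 90% ("high-quality draft") filter is applied at the
vOTU-representative level by default, with a per-UViG flag also available.

### ANI/AF and clustering

Pairwise similarity is a fragment-mapping average nucleotide identity (ANI)
estimator: the shorter sequence is tiled into non-overlapping 1000 bp
fragments; each fragment is aligned at its best location on the longer
sequence (edlib infix alignment, edit distance); fragments with identity
≥ 80% are *mapped*. ANI is the mean identity over mapped fragments. The
alignment fraction AF is mapped fragments / tiled full fragments — the
trailing partial fragment is excluded from numerator and denominator alike,
so identical sequences score AF = 1.0 regardless of length modulo 1000.
Unmapped pairs report ANI = 0 and AF = 0 (not missing), so thresholds
evaluate false. Edit distance can undercut Hamming distance when indels
substitute for clustered mismatches; on substitution-only pairs at ≤ 5%
divergence the measured discrepancy stays below 0.05 percentage points
(tests assert ≤ 0.5).

vOTUs (viral operational taxonomic units, a species-rank proxy) are built by
greedy centroid clustering at ANI ≥ 95% / AF ≥ 0.85 of the shorter sequence:
records sorted longest-first, each joining the first qualifying centroid
(best-hit assignment available by flag), else founding a new cluster — hence
the representative is always the longest member. Clone pairs — same-lineage
evidence for donor tracking — are within-vOTU pairs at ANI ≥ 99.4% /
AF ≥ 0.85; the clone relation is kept symmetric but not forced transitive.
A 16-mer sketch index prunes centroid comparisons: unrelated sequences share
essentially no 16-mers, while at 20% divergence (the mutation model's cap) a
10 kb pair still shares hundreds, so pruned pairs are exactly those whose
fragments could not reach the 80% mapping floor. An adapter for precomputed
external ANI tables supports parity runs against a reference implementation.

### Abundance

Genes (ORF coordinates are inputs) are dereplicated into a non-redundant
catalog at 95% identity over 85% of the shorter gene, with the fragment
length shortened to 300 bp. Per-centroid counts are length-normalized to
reads per kilobase (RPK), depth-normalized per sample, and scaled to copies
per million (CPM; per-sample sums are exactly 10⁶ for non-empty samples).
A UViG's abundance is the *median* CPM over its catalog genes — zero-count
genes included by default, since excluding them would make presence/absence
circular (configurable). A gene cluster shared between UViGs is attributed
to every UViG contributing a member (configurable to centroid-owner-only).
vOTU abundance is the per-sample sum over member UViGs; a vOTU is
*identified* in a sample iff its value is strictly positive.

### Engraftment

A donor phage is engrafted when a clone of it appears in a sex-matched
recipient at week 6 or later and no donor clone of that vOTU was present in
that recipient's baseline sample. Events are keyed per (vOTU, recipient);
cross-sex clone pairs are excluded with a warning (capsules were
administered male-to-male and female-to-female). Placebo recipients are
processed identically; their event count is a specificity control.
Attribution assigns every donor in which the vOTU was identified
(membership-based presence); multi-carrier events are tagged "multiple" and
count toward each carrier's efficacy numerator. Donor engraftment efficacy
is engrafted / identified vOTUs per donor, compared across donors by
Pearson's χ² with standardized-residual post hoc (BH-FDR across cells).

Each recipient-timepoint phageome is partitioned by vOTU origin:
*shared with donors* (clone-level evidence against sex-matched donors by
default; vOTU-level by flag), else *conserved from baseline*, else *novel*.
A donor-carried vOTU present at the recipient's baseline is labeled
donor-shared in the partition but is not an engraftment event.

### Statistics

Alpha diversity is Shannon's H = −Σ p ln p (natural log, the ecology-package
convention); beta diversity is Bray–Curtis, Σ|a−b| / Σ(a+b). Group
comparisons: Wilcoxon rank-sum (exact p for tie-free samples ≤ 25, else
normal approximation with continuity correction); Pearson correlation with
the t-distribution p (n − 2 df); Pearson χ² without continuity correction.
Longitudinal contrasts come from a linear mixed model
`value ~ treatment × timepoint` with a random intercept per subject (REML),
reporting the treatment effect at each post-baseline timepoint via Wald
contrasts; a singular mixed fit falls back to fixed-effects OLS with a
logged warning. The default response for alpha diversity and lifestyle
totals is the per-subject change from baseline ("raw" available), since the
trial's question is about post-treatment *variation*. Benjamini–Hochberg FDR
is applied within the family each analysis declares: within sex across
lifestyle × timepoint for lifestyle totals, within sex for alpha-diversity
contrasts, across the sex × timepoint Wilcoxon family for variability, and
collectively across donors × timepoints for the donor-convergence models.

## Synthetic cohort generator

The generator emulates the trial design so every downstream stage is
testable against ground truth. Defaults (one choice, stated here, used by
the tests and the reproduction script):

| parameter | default | meaning |
|---|---|---|
| donors | 4 per sex | richness Uniform(30, 60) lineages each |
| recipients | 10 FMT + 10 placebo per sex | baseline + weeks 6/12/26 |
| genome length | 5–12 kb | uniform-random nucleotides |
| genes | 300–1500 bp | non-overlapping, tiling ≥ 70% of the genome |
| clone divergence | 0.002 subs/site | transferred clones (identity ≈ 99.8%) |
| distractor divergence | 0.03 | same-vOTU non-clones seeded at baseline |
| transfer link | logit p = −2.0 + 1.0·(H − 3.1) | per (donor phage, recipient) |
| recipient richness | 25 | incl. 5 donor-relative distractors |
| persistence | 0.85 (conserved), 0.9 (engrafted) | per post timepoint |
| novel lineages | Poisson(9) FMT / Poisson(7) placebo | per post timepoint |
| lifestyle | 30% temperate, 20% unknown | temperate ×2 post-FMT by default |
| abundance noise | lognormal σ = 1.2 | per lineage and sample |
| counts | NB, α = 0.5, depth 2×10⁵ | mean ∝ abundance × gene length × depth |
| background | 12 lineages/subject, 3 kb, weight ×9 | completeness 20–80% |

Notes on the less obvious choices:

* **Transfer link.** The per-phage transfer probability is logistic in the
  donor's Shannon diversity. A bare `logistic(slope · H)` saturates for
  realistic H ≈ 3–4, so the link is centered and given an intercept; the
  defaults give per-recipient transfer probabilities around 0.1 and
  donor-level efficacies in the 0.4–0.8 range — the scale of the source
  trial (63% of donor vOTUs engrafted; ~3.5 events per engrafted vOTU).
  Any monotone link expresses the intended positive diversity–efficacy
  relation.
* **Background lineages.** Real gut phageome assemblies are dominated by
  low/medium-quality genomes (93.2% of vOTUs in the source trial) that are
  excluded from the high-quality analyses but still absorb sequencing
  depth. The generator's background pool reproduces this: high-quality
  lineages carry only ~25% of each sample's CPM, so lifestyle totals over
  HQ vOTUs are not compositionally closed and a temperate increase does not
  mechanically force an equal-and-opposite virulent decrease.
* **Mutation model.** Substitution-only (no indels, no gene gain/loss), so
  exact Hamming identity is an oracle for ANI on clone/distractor pairs.
  Annotation fields are drawn per observation so every simulated genome
  passes the screen; junk contigs that fail inclusion or trip the
  false-positive rule are added to exercise the funnel.
* **Temperate induction.** The post-FMT fold multiplies the abundance of
  every temperate lineage in FMT recipients after baseline. The magnitude
  is a free parameter (the trial reports direction and significance, not an
  effect size); recovery checks use fold = 3 and sign/significance only.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: read-level errors and assembly artifacts (counts
are drawn at the gene level), indel and recombination divergence between
clones (real ANI estimates degrade faster), strain-level gene content
variation, multiple donation rounds per donor (a single pooled donation is
generated; the metadata model carries `donation_round` so either policy is
expressible), and ecological interactions between lineages (abundances are
independent lognormals).

## Validation studies and problem sizes

The reproduction script and the test suite re-derive every headline check
at these scales (chosen as a balance of statistical resolution and a
single-CPU runtime of a few minutes):

* **Arithmetic on printed counts**: overall efficacy 282/451 (62.5%, printed
  as 63%) and the high-quality vOTU fraction 1761/25,805 (6.8%).
* **Screen truth table**: exhaustive 640-point grid over the rule clauses
  including every boundary, against an independent restatement.
* **ANI oracle / clone thresholds**: 200 pairs of 10 kb each.
* **Engraftment recovery**: one default cohort (8 donors, 40 recipients,
  168 samples, ~8000 UViGs); recall, precision, and placebo events
  measured against the transfer truth.
* **Diversity–efficacy correlation**: 20 replicate cohorts at reduced scale
  (richness 10–40, 3 recipients per arm per sex, 4–8 kb genomes) with the
  full sequence pipeline; donor Shannon diversity estimated from quantified
  donor profiles. A slope-0 arm checks the false-positive rate.
* **Type-I control and temperate recovery**: 200 (resp. 20) abundance-level
  replicates (12 recipients per arm per sex, transfers disabled so the arms
  differ only where a parameter says they do) exercising the mixed-model
  and Wilcoxon layers on ground-truth vOTU abundance tables. With transfers
  active a virulent-abundance difference between arms is a *true* effect
  (FMT recipients genuinely gain donor phages), so the no-transfer
  configuration is the correct null for false-positive accounting; the
  transfer path is validated separately by the sequence-level studies.

## Known limitations

* The fragment estimator's AF convention (full fragments only) differs
  slightly from alignment-length conventions of external tools; for
  sequences just above 1 kb the AF granularity is coarse. The external
  ANI-table adapter exists for parity checks.
* Greedy first-hit clustering is order-dependent by design (longest-first,
  deterministic); the upstream study's custom clustering script is
  unspecified, so first-hit vs best-hit is exposed as a flag.
* The clone ANI cutoff (99.4%) and the HVR cutoff (0.386) are taken as
  given from the source study; the procedures that derived them are out of
  scope.
* Mixed models on small arms can be singular; the OLS fallback preserves
  the contrast definition but not the within-subject correlation.
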