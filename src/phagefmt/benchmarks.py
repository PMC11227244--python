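"""Recovery and calibration studies of the pipeline on synthetic cohorts.

Each function runs the pipeline (or one of its layers) on generator
output and measures how well the known ground truth is recovered:
engraftment recall/precision, clone-threshold sensitivity/specificity,
ANI agreement with the exact Hamming oracle, the donor
diversity-efficacy correlation, type-I error of the statistical layer
under a no-effect configuration, and power to detect the post-FMT
temperate-abundance increase. These studies back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ani import compute_ani_af, hamming_identity_pct, SimilarityProvider
from .catalog import (
    AbundanceMatrix,
    Unit,
    aggregate_counts_to_catalog,
    build_gene_catalog,
    catalog_gene_to_uvigs,
    counts_to_cpm,
    extract_gene_sequences,
    uvig_abundance,
    votu_abundance,
)
from .cluster import CLONE_AF, CLONE_ANI_PCT, cluster_votus, detect_clones, membership_table
from .engraftment import (
    attribute_donors,
    detect_engraftment_events,
    donor_efficacy,
    donor_presence_table,
)
from .model import Role, Treatment
from .screen import retained_records
from .simulate import (
    SimConfig,
    build_plan,
    mutate_clone,
    random_sequence,
    simulate_cohort,
    simulate_gene_counts,
)
from .stats import (
    alpha_diversity_contrasts,
    lifestyle_totals,
    pearson_test,
    shannon,
    variability_from_wk6,
)


def _child_seed(seed: int, *tag: int) -> int:
    return int(np.random.SeedSequence((seed, *tag)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# ANI oracle agreement & clone threshold behavior

def ani_oracle_agreement(
    seed: int, n_pairs: int = 200, length: int = 10_000,
    max_divergence: float = 0.05,
) -> dict:
    """Max |fragment-ANI - Hamming identity| over substitution-only pairs
    spanning divergence 0..max_divergence."""
    rng = np.random.default_rng(_child_seed(seed, 4))
    errors = []
    for i in range(n_pairs):
        div = max_divergence * i / (n_pairs - 1)
        parent = random_sequence(rng, length)
        child, _ = mutate_clone(rng, parent, div)
        sim = compute_ani_af(parent, child)
        errors.append(abs(sim.ani_pct - hamming_identity_pct(parent, child)))
    return {"max_abs_error_pct": float(max(errors)),
            "mean_abs_error_pct": float(np.mean(errors)), "n": n_pairs}


def clone_threshold_rates(
    seed: int, n_pairs: int = 200, length: int = 10_000,
    clone_divergence: float = 0.002, nonclone_divergence: float = 0.03,
) -> dict:
    """Sensitivity of the clone rule on true-clone pairs and specificity
    on same-vOTU non-clone pairs."""
    rng = np.random.default_rng(_child_seed(seed, 5))
    def is_clone(a: str, b: str) -> bool:
        sim = compute_ani_af(a, b)
        return sim.ani_pct >= CLONE_ANI_PCT and sim.af_smaller >= CLONE_AF

    hits = misses = 0
    for _ in range(n_pairs):
        parent = random_sequence(rng, length)
        child, _ = mutate_clone(rng, parent, clone_divergence)
        if is_clone(parent, child):
            hits += 1
        distractor, _ = mutate_clone(rng, parent, nonclone_divergence)
        if is_clone(parent, distractor):
            misses += 1
    return {"sensitivity": hits / n_pairs,
            "specificity": 1.0 - misses / n_pairs, "n": n_pairs}


# ---------------------------------------------------------------------------
# engraftment recovery (full sequence pipeline)

@dataclass
class StudyResult:
    recall: float
    precision: float
    n_true_transfers: int
    n_called_fmt: int
    n_placebo_events: int
    efficacy: pd.DataFrame           # donor_id, n_votus, n_engrafted, efficacy
    donor_shannon_est: dict[str, float]


def engraftment_study(config: SimConfig, estimate_donor_diversity: bool = False) -> StudyResult:
    """Run simulate -> screen -> cluster -> clones -> events and score
    the calls against the generator's transfer truth.

    Recall/precision are on (lineage, recipient) pairs for FMT
    recipients; placebo events are counted separately (expected zero).
    With ``estimate_donor_diversity`` the donor samples are additionally
    quantified (gene catalog -> CPM -> vOTU profiles) to obtain the
    pipeline's Shannon estimate per donor.
    """
    cohort = simulate_cohort(config)
    truth = cohort.truth
    retained = retained_records(cohort.uvigs)
    provider = SimilarityProvider({u.uvig_id: u.sequence for u in retained})
    clusters = cluster_votus(retained, provider)
    by_id = {u.uvig_id: u for u in retained}
    hq = [c for c in clusters if by_id[c.representative].completeness_pct >= 90.0]
    clones = detect_clones(hq, provider)
    membership = membership_table(hq)
    events = detect_engraftment_events(clones, retained, cohort.metadata, membership)
    presence = donor_presence_table(membership, retained, cohort.metadata)
    for e in events:
        attribute_donors(e, presence)
    efficacy, _ = donor_efficacy(events, presence, cohort.metadata)

    lineage_of_votu: dict[str, str] = {}
    for c in hq:
        for m in c.members:
            lin = truth.lineage_of_uvig.get(m)
            if lin is not None:
                lineage_of_votu.setdefault(c.votu_id, lin)
    treatment = {m.subject_id: m.treatment for m in cohort.metadata}
    called_fmt = {
        (lineage_of_votu.get(e.votu_id), e.recipient_subject)
        for e in events if treatment[e.recipient_subject] is Treatment.FMT
    }
    n_placebo = sum(1 for e in events if treatment[e.recipient_subject] is Treatment.placebo)
    true_pairs = truth.transferred_pairs()
    n_tp = len(called_fmt & true_pairs)
    recall = n_tp / len(true_pairs) if true_pairs else float("nan")
    precision = n_tp / len(called_fmt) if called_fmt else float("nan")

    donor_h: dict[str, float] = {}
    if estimate_donor_diversity:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
        counts = simulate_gene_counts(rng, truth, cohort.metadata, cohort.genes, config)
        donor_samples = [m for m in cohort.metadata if m.role is Role.donor]
        donor_sample_ids = [m.sample_id for m in donor_samples]
        donor_uvigs = {u.uvig_id for u in retained if u.sample_id in set(donor_sample_ids)}
        genes = [g for g in cohort.genes if g.uvig_id in donor_uvigs]
        gene_seqs = extract_gene_sequences(genes, {u.uvig_id: u.sequence for u in retained})
        catalog = build_gene_catalog(genes, gene_seqs)
        counts_d = counts.loc[
            counts.index.intersection([g.gene_id for g in genes]), donor_sample_ids
        ]
        centroid_counts, lengths = aggregate_counts_to_catalog(counts_d, catalog)
        cpm = counts_to_cpm(centroid_counts, lengths)
        uvig_ab = uvig_abundance(cpm, catalog_gene_to_uvigs(catalog, genes))
        donor_hq = [c for c in hq if c.members & donor_uvigs]
        votu_ab = votu_abundance(uvig_ab, donor_hq)
        for m in donor_samples:
            donor_h[m.subject_id] = shannon(votu_ab.data[m.sample_id].to_numpy())

    eff_df = pd.DataFrame(
        [{"donor_id": d.donor_id, "n_votus_donor": d.n_votus_donor,
          "n_engrafted": d.n_engrafted, "efficacy": d.efficacy} for d in efficacy]
    )
    return StudyResult(recall, precision, len(true_pairs), len(called_fmt),
                       n_placebo, eff_df, donor_h)


def default_recovery(seed: int) -> dict:
    """Engraftment recall/precision of the default cohort (8 donors,
    20 FMT + 20 placebo recipients, 4 timepoints)."""
    res = engraftment_study(dataclasses.replace(SimConfig(), seed=_child_seed(seed, 7)))
    return {"recall": res.recall, "precision": res.precision,
            "placebo_events": res.n_placebo_events,
            "n_true_transfers": res.n_true_transfers}


#: scaled-down cohort for replicate studies (see docs/methods.md)
REPLICATE_SIM = SimConfig(
    n_donors_per_sex=4,
    donor_richness_range=(10, 40),
    recipient_richness=12,
    n_fmt=3,
    n_placebo=3,
    genome_length_range=(4000, 8000),
    n_distractors=3,
    novel_rate_fmt=4.0,
    novel_rate_placebo=3.0,
    background_per_subject=6,
    n_junk_contigs=0,
    engraft_prob_intercept=-1.5,
    diversity_center=2.5,
)


def diversity_efficacy_recovery(
    seed: int, n_reps: int = 20, slope: float = 1.0,
) -> dict:
    """Donor diversity-efficacy Pearson correlation over replicate
    cohorts: fraction of replicates with r > 0 and with one-sided
    p < 0.05 (under slope 0 the latter is the false-positive rate)."""
    pos = sig = 0
    for rep in range(n_reps):
        cfg = dataclasses.replace(
            REPLICATE_SIM, seed=_child_seed(seed, 8, rep),
            engraft_prob_slope=slope,
        )
        res = engraftment_study(cfg, estimate_donor_diversity=True)
        eff = res.efficacy.dropna(subset=["efficacy"])
        h = [res.donor_shannon_est[d] for d in eff["donor_id"]]
        e = eff["efficacy"].astype(float).to_numpy()
        if np.std(h) == 0 or np.std(e) == 0:
            continue
        r, p_two = pearson_test(h, e)
        p_one = p_two / 2 if r > 0 else 1 - p_two / 2
        if r > 0:
            pos += 1
        if p_one < 0.05:
            sig += 1
    return {"frac_r_positive": pos / n_reps, "frac_significant": sig / n_reps,
            "n": n_reps}


# ---------------------------------------------------------------------------
# statistics layer: type-I control and temperate recovery

#: abundance-level replicate cohort with transfers disabled, so the two
#: arms differ only where a parameter says they do
NULL_SIM = SimConfig(
    n_donors_per_sex=4,
    donor_richness_range=(15, 30),
    recipient_richness=25,
    n_fmt=12,
    n_placebo=12,
    n_distractors=3,
    novel_rate_fmt=5.0,
    novel_rate_placebo=5.0,
    background_per_subject=8,
    n_junk_contigs=0,
    engraft_prob_slope=0.0,
    engraft_prob_intercept=-20.0,   # no transfers
    temperate_postfmt_fold=1.0,
)


def _truth_hq_abundance(plan) -> AbundanceMatrix:
    """Ground-truth vOTU abundance restricted to high-quality lineages
    (the analysis substrate the pipeline would produce)."""
    truth = plan.truth
    hq = [lid for lid in truth.abundance.index
          if truth.kind_of_lineage[lid] != "background"]
    return AbundanceMatrix(truth.abundance.loc[hq], Unit.CPM_derived)


def stats_null_rates(seed: int, n_reps: int = 200) -> dict:
    """Type-I error of the mixed-model alpha-diversity contrasts and of
    the Wilcoxon variability comparisons under the generator's null."""
    lmm_sig = lmm_total = wil_sig = wil_total = 0
    for rep in range(n_reps):
        cfg = dataclasses.replace(NULL_SIM, seed=_child_seed(seed, 9, rep))
        plan = build_plan(cfg)
        abund = _truth_hq_abundance(plan)
        _, alpha_tests = alpha_diversity_contrasts(abund, plan.metadata)
        if not alpha_tests.empty:
            lmm_sig += int((alpha_tests["q"] <= 0.05).sum())
            lmm_total += len(alpha_tests)
        _, var_tests = variability_from_wk6(abund, plan.metadata)
        if not var_tests.empty:
            wil_sig += int((var_tests["q"] <= 0.05).sum())
            wil_total += len(var_tests)
    return {
        "lmm_rate": lmm_sig / lmm_total if lmm_total else float("nan"),
        "wilcoxon_rate": wil_sig / wil_total if wil_total else float("nan"),
        "n": n_reps,
    }


def temperate_recovery(seed: int, n_reps: int = 20, fold: float = 3.0) -> dict:
    """Power to detect the post-FMT temperate-abundance increase.

    Per replicate: does any temperate contrast reach q <= 0.05 at a post
    timepoint? Also reports the per-contrast significant rate for
    virulent phages (expected near-nominal: the fold applies to
    temperate lineages only)."""
    hit = 0
    vir_sig = vir_total = 0
    for rep in range(n_reps):
        cfg = dataclasses.replace(NULL_SIM, seed=_child_seed(seed, 10, rep),
                                  temperate_postfmt_fold=fold)
        plan = build_plan(cfg)
        abund = _truth_hq_abundance(plan)
        lifestyles = {lid: plan.truth.lifestyle_of_lineage[lid] for lid in abund.data.index}
        _, tests = lifestyle_totals(abund, lifestyles, plan.metadata)
        if tests.empty:
            continue
        temp = tests[tests["lifestyle"] == "temperate"]
        vir = tests[tests["lifestyle"] == "virulent"]
        if (temp["q"] <= 0.05).any():
            hit += 1
        vir_sig += int((vir["q"] <= 0.05).sum())
        vir_total += len(vir)
    return {
        "temperate_power": hit / n_reps,
        "virulent_rate": vir_sig / vir_total if vir_total else float("nan"),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# arithmetic on the trial's printed counts

#: unique donor vOTUs engrafted / identified across all donors, and the
#: vOTU completeness funnel, as printed in the source trial
PRINTED_ENGRAFTED, PRINTED_DONOR_VOTUS = 282, 451
PRINTED_HQ_VOTUS, PRINTED_TOTAL_VOTUS = 1761, 25_805


def overall_efficacy_pct() -> float:
    from .model import DonorEfficacy

    d = DonorEfficacy("all", PRINTED_DONOR_VOTUS, PRINTED_ENGRAFTED)
    return 100.0 * d.efficacy


def hq_votu_fraction_pct() -> float:
    return 100.0 * PRINTED_HQ_VOTUS / PRINTED_TOTAL_VOTUS


# ---------------------------------------------------------------------------
# screening rule truth table

def screen_rule_agreement() -> dict:
    """Exhaustively compare the implemented screen against a direct
    restatement of the inclusion/false-positive rules over a grid of
    annotation values including every boundary."""
    from .model import UViGRecord
    from .screen import classify_putative_viral, flag_false_positive

    n = agree = 0
    for viral in (0, 1, 2, 3, 500):
        for host in (0, 1, 2, 4, 5, 7, 193, 194):
            for score in (0.1, 0.94, 0.95, 0.99):
                for hallmark in (0, 2, 3, 5):
                    rec = UViGRecord(
                        uvig_id="t", sample_id="s", sequence="A" * 100,
                        length_bp=100, viral_genes=viral, host_genes=host,
                        hallmark_genes=hallmark, screen_score=score,
                        completeness_pct=50.0,
                    )
                    include_expect = (viral >= 1 or host == 0
                                      or score >= 0.95 or hallmark >= 3)
                    if viral == 0:
                        hvr_expect = math.inf if host > 0 else 0.0
                    else:
                        hvr_expect = host / viral
                    fp_expect = host > 4 or hvr_expect > 0.386
                    inc, _ = classify_putative_viral(rec)
                    fp, hvr = flag_false_positive(rec)
                    n += 1
                    if inc == include_expect and fp == fp_expect and hvr == hvr_expect:
                        agree += 1
    return {"agreement": agree / n, "n": n}


# ---------------------------------------------------------------------------
# CPM conservation

def cpm_conservation(seed: int, n_genes: int = 200, n_samples: int = 30) -> dict:
    """Max relative deviation of per-sample CPM sums from 1e6 on random
    count tables (samples with all-zero counts excluded)."""
    rng = np.random.default_rng(_child_seed(seed, 6))
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(n_genes, n_samples)).astype(float),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    counts.iloc[:, 0] = 0.0   # an all-zero sample must stay all-zero
    lengths = {f"g{i}": int(rng.integers(300, 1500)) for i in range(n_genes)}
    cpm = counts_to_cpm(counts, lengths)
    sums = cpm.data.sum(axis=0)
    nonzero = sums[counts.sum(axis=0) > 0]
    max_rel = float((nonzero - 1e6).abs().max() / 1e6)
    zero_ok = bool((cpm.data.loc[:, counts.sum(axis=0) == 0] == 0).all().all())
    return {"max_rel_deviation": max_rel, "zero_columns_preserved": zero_ok,
            "n": int(len(nonzero))}
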