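"""Synthetic cohort generator: construction contracts, determinism,
mutation model, truth invariants, count model."""

import dataclasses

import numpy as np
import pytest

from phagefmt.ani import hamming_identity_pct
from phagefmt.model import Treatment
from phagefmt.screen import classify_putative_viral, flag_false_positive
from phagefmt.simulate import (
    SimConfig,
    build_plan,
    mutate_clone,
    simulate_cohort,
    simulate_gene_counts,
    simulate_genome,
    write_cohort,
)


class TestSimulateGenome:
    def test_construction_contract(self, rng):
        rec, genes = simulate_genome(rng, 5000, uvig_id="g")
        assert rec.length_bp == len(rec.sequence) == 5000
        assert len(genes) >= 3
        # genes non-overlapping and within bounds
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert spans[-1][1] <= 5000
        # tiling >= 70% of the genome
        covered = sum(e - s for s, e in spans)
        assert covered >= 0.7 * 5000
        # passes the viral screen
        assert classify_putative_viral(rec)[0]
        assert not flag_false_positive(rec)[0]

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(rng, 800)

    def test_seed_determinism(self):
        a, _ = simulate_genome(np.random.default_rng(3), 4000)
        b, _ = simulate_genome(np.random.default_rng(3), 4000)
        assert a.sequence == b.sequence


class TestMutateClone:
    def test_zero_divergence_identity(self, rng):
        parent = "ACGT" * 1000
        child, n = mutate_clone(rng, parent, 0.0)
        assert child == parent and n == 0

    def test_realized_rate_and_identity(self, rng):
        from phagefmt.simulate import random_sequence

        parent = random_sequence(rng, 10_000)
        child, n = mutate_clone(rng, parent, 0.002)
        assert 5 <= n <= 45   # ~Binomial(10000, 0.002)
        assert hamming_identity_pct(parent, child) == pytest.approx(
            100 * (1 - n / 10_000)
        )

    def test_nonclone_divergence_below_threshold(self, rng):
        from phagefmt.simulate import random_sequence

        parent = random_sequence(rng, 10_000)
        child, _ = mutate_clone(rng, parent, 0.03)
        assert hamming_identity_pct(parent, child) < 99.4

    def test_out_of_range_divergence(self, rng):
        with pytest.raises(ValueError):
            mutate_clone(rng, "ACGT" * 300, 0.3)


class TestCohortTruth:
    def test_no_placebo_transfers(self, small_cohort):
        placebo = {
            m.subject_id for m in small_cohort.metadata
            if m.treatment is Treatment.placebo
        }
        assert not any(t.recipient_id in placebo for t in small_cohort.truth.transfers)

    def test_transferred_lineages_exist_in_donor_samples(self, small_cohort):
        donor_pool = set().union(*small_cohort.truth.donor_lineages.values())
        for t in small_cohort.truth.transfers:
            assert t.lineage_id in small_cohort.truth.donor_lineages[t.donor_id]
            assert t.lineage_id in donor_pool

    def test_clone_pairs_identity_above_threshold(self, small_cohort):
        seqs = dict(small_cohort.sequences)
        checked = 0
        for a, b, div in small_cohort.truth.clone_pairs:
            if div > 0.01:   # distractor pairs recorded at 0.03
                continue
            ident = hamming_identity_pct(seqs[a], seqs[b])
            assert ident > 99.4
            checked += 1
        assert checked > 0

    def test_byte_identical_outputs_under_fixed_seed(self, small_config, tmp_path):
        for d in ("run1", "run2"):
            write_cohort(simulate_cohort(small_config), tmp_path / d)
        for name in ("genomes.fasta", "annotations.tsv", "metadata.tsv",
                     "genes.tsv", "truth/transfers.tsv"):
            assert (tmp_path / "run1" / name).read_bytes() == \
                   (tmp_path / "run2" / name).read_bytes()

    def test_null_slope_equalizes_transfer_rates(self):
        cfg = dataclasses.replace(
            SimConfig(), seed=5, engraft_prob_slope=0.0, n_fmt=4, n_placebo=0,
            donor_richness_range=(10, 40),
        )
        plan = build_plan(cfg)
        # per-phage transfer rate should not depend on donor richness
        rates = {}
        n_recipients_per_sex = cfg.n_fmt
        for donor, pool in plan.truth.donor_lineages.items():
            n_tx = sum(1 for t in plan.truth.transfers if t.donor_id == donor)
            rates[donor] = n_tx / (len(pool) * n_recipients_per_sex)
        r = np.array(list(rates.values()))
        assert r.std() < 0.2   # no systematic diversity-driven spread


class TestGeneCounts:
    def test_absent_lineage_genes_are_zero(self, small_cohort, small_config, rng):
        counts = simulate_gene_counts(
            rng, small_cohort.truth, small_cohort.metadata,
            small_cohort.genes, small_config,
        )
        truth = small_cohort.truth
        # a gene only receives reads in the sample its UViG came from
        uvig_sample = {u.uvig_id: u.sample_id for u in small_cohort.uvigs}
        sub = counts.sample(n=min(200, len(counts)), random_state=1)
        for gene_id, row in sub.iterrows():
            own = uvig_sample[gene_id.rsplit(":", 1)[0]]
            assert row.drop(own).sum() == 0

    def test_expected_count_scales_with_gene_length(self):
        """Doubling gene length doubles the expected count at fixed
        abundance (mean over repeated draws within 5%)."""
        import pandas as pd

        from phagefmt.model import GeneRecord, Role, SampleRecord, Sex, Timepoint, Treatment
        from phagefmt.simulate import SimTruth

        truth = SimTruth()
        truth.lineage_of_uvig = {"s1|c0": "L0"}
        truth.abundance = pd.DataFrame({"s1": [1e6]}, index=["L0"])
        meta = [SampleRecord("s1", "D1", Role.donor, Treatment.none,
                             Sex.female, Timepoint.donation, 1)]
        genes = [GeneRecord("s1|c0:g0", "s1|c0", 0, 400, 400),
                 GeneRecord("s1|c0:g1", "s1|c0", 400, 1200, 800)]
        cfg = SimConfig(mean_depth=10_000, count_dispersion=0.1)
        totals = np.zeros(2)
        n_draws = 400
        master = np.random.default_rng(42)
        for _ in range(n_draws):
            counts = simulate_gene_counts(master, truth, meta, genes, cfg)
            totals += counts["s1"].to_numpy()
        ratio = totals[1] / totals[0]
        assert ratio == pytest.approx(2.0, rel=0.05)
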