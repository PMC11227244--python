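"""Gene catalog and CPM abundance aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phagefmt.catalog import (
    AbundanceMatrix,
    Unit,
    aggregate_counts_to_catalog,
    build_gene_catalog,
    catalog_gene_to_uvigs,
    counts_to_cpm,
    uvig_abundance,
    votu_abundance,
)
from phagefmt.model import GeneRecord, VOTUCluster
from phagefmt.simulate import mutate_clone, random_sequence


def gene(gene_id, uvig_id, length):
    return GeneRecord(gene_id, uvig_id, 0, length, length)


class TestGeneCatalog:
    def test_identical_genes_share_cluster(self, rng):
        seq = random_sequence(rng, 900)
        genes = [gene("a:g0", "a", 900), gene("b:g0", "b", 900)]
        catalog = build_gene_catalog(genes, {"a:g0": seq, "b:g0": seq})
        (cluster,) = catalog
        assert cluster.members == {"a:g0", "b:g0"}

    def test_divergent_genes_separate(self, rng):
        seq = random_sequence(rng, 900)
        far, _ = mutate_clone(rng, seq, 0.10)   # ~90% identity < 95% cut
        genes = [gene("a:g0", "a", 900), gene("b:g0", "b", 900)]
        catalog = build_gene_catalog(genes, {"a:g0": seq, "b:g0": far})
        assert len(catalog) == 2

    def test_partition_property(self, rng):
        base = random_sequence(rng, 600)
        seqs = {f"u{i}:g0": mutate_clone(rng, base, 0.002)[0] for i in range(4)}
        genes = [gene(g, g.split(":")[0], 600) for g in seqs]
        catalog = build_gene_catalog(genes, seqs)
        members = [m for c in catalog for m in c.members]
        assert sorted(members) == sorted(seqs)


class TestCpm:
    def test_sole_gene_takes_the_million(self):
        counts = pd.DataFrame({"s1": [100.0]}, index=["g"])
        cpm = counts_to_cpm(counts, {"g": 2000})
        assert cpm.unit is Unit.CPM
        assert cpm.data.loc["g", "s1"] == pytest.approx(1e6)

    def test_equal_rpk_splits_evenly(self):
        counts = pd.DataFrame({"s1": [100.0, 50.0]}, index=["a", "b"])
        cpm = counts_to_cpm(counts, {"a": 2000, "b": 1000})   # RPK 50 each
        assert cpm.data["s1"].tolist() == pytest.approx([5e5, 5e5])

    def test_missing_length_names_gene(self):
        counts = pd.DataFrame({"s1": [1.0]}, index=["mystery"])
        with pytest.raises(KeyError, match="mystery"):
            counts_to_cpm(counts, {})

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_per_sample_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(6, 4)).astype(float),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(4)],
        )
        lengths = {f"g{i}": int(rng.integers(300, 1500)) for i in range(6)}
        cpm = counts_to_cpm(counts, lengths)
        sums = cpm.data.sum(axis=0)
        for s in counts.columns:
            if counts[s].sum() > 0:
                assert sums[s] == pytest.approx(1e6, rel=1e-9)
            else:
                assert sums[s] == 0.0


class TestAggregation:
    def cpm_matrix(self, values, genes):
        return AbundanceMatrix(
            pd.DataFrame({"s1": values}, index=genes), Unit.CPM
        )

    @pytest.mark.parametrize(
        "values, expected",
        [([10.0, 20.0, 30.0], 20.0),   # odd median
         ([0.0, 0.0, 50.0], 0.0),      # zeros included by default
         ([10.0, 20.0], 15.0)],        # even-count median
    )
    def test_uvig_median(self, values, expected):
        genes = [f"g{i}" for i in range(len(values))]
        cpm = self.cpm_matrix(values, genes)
        ab = uvig_abundance(cpm, {g: {"u1"} for g in genes})
        assert ab.data.loc["u1", "s1"] == pytest.approx(expected)
        assert ab.unit is Unit.CPM_derived

    def test_median_zero_policy_flag(self):
        cpm = self.cpm_matrix([0.0, 0.0, 50.0], ["g0", "g1", "g2"])
        ab = uvig_abundance(cpm, {g: {"u1"} for g in ["g0", "g1", "g2"]},
                            include_zeros=False)
        assert ab.data.loc["u1", "s1"] == pytest.approx(50.0)

    def test_median_permutation_invariant(self, rng):
        vals = list(rng.uniform(0, 100, size=7))
        genes = [f"g{i}" for i in range(7)]
        a = uvig_abundance(self.cpm_matrix(vals, genes), {g: {"u"} for g in genes})
        shuffled = list(np.random.default_rng(1).permutation(vals))
        b = uvig_abundance(self.cpm_matrix(shuffled, genes), {g: {"u"} for g in genes})
        assert a.data.loc["u", "s1"] == pytest.approx(b.data.loc["u", "s1"])

    def test_votu_sum_and_monotonicity(self):
        uvig_ab = AbundanceMatrix(
            pd.DataFrame({"s1": [5.0, 7.0, 2.0]}, index=["u1", "u2", "u3"]),
            Unit.CPM_derived,
        )
        one = votu_abundance(uvig_ab, [VOTUCluster("v1", "u1", {"u1", "u2"})])
        assert one.data.loc["v1", "s1"] == pytest.approx(12.0)
        grown = votu_abundance(uvig_ab, [VOTUCluster("v1", "u1", {"u1", "u2", "u3"})])
        assert grown.data.loc["v1", "s1"] >= one.data.loc["v1", "s1"]
        single = votu_abundance(uvig_ab, [VOTUCluster("v2", "u3", {"u3"})])
        assert single.data.loc["v2", "s1"] == pytest.approx(2.0)

    def test_catalog_counts_aggregate_and_attribution(self, rng):
        seq = random_sequence(rng, 600)
        genes = [gene("a:g0", "a", 600), gene("b:g0", "b", 600)]
        catalog = build_gene_catalog(genes, {"a:g0": seq, "b:g0": seq})
        counts = pd.DataFrame({"s1": [4.0, 6.0]}, index=["a:g0", "b:g0"])
        agg, lengths = aggregate_counts_to_catalog(counts, catalog)
        centroid = catalog[0].centroid_gene
        assert agg.loc[centroid, "s1"] == pytest.approx(10.0)
        assert lengths[centroid] == 600
        g2u = catalog_gene_to_uvigs(catalog, genes)
        assert g2u[centroid] == {"a", "b"}   # shared cluster -> both UViGs
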