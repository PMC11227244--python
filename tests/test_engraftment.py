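"""Engraftment calling on hand-built scenarios: event definition,
baseline disqualification, donor attribution, efficacy arithmetic,
phageome partition."""

import numpy as np
import pandas as pd
import pytest

from phagefmt.catalog import AbundanceMatrix, Unit
from phagefmt.engraftment import (
    attribute_donors,
    detect_engraftment_events,
    donor_efficacy,
    donor_presence_table,
    donor_share_by_votu,
    partition_phageome,
)
from phagefmt.model import (
    ClonePair,
    DonorEfficacy,
    EngraftmentEvent,
    Role,
    SampleRecord,
    Sex,
    Timepoint,
    Treatment,
    UViGRecord,
)


def sample(sid, subject, role, treatment, sex, tp, round_=None):
    return SampleRecord(sid, subject, Role(role), Treatment(treatment),
                        Sex(sex), Timepoint(tp), round_)


def uvig(uvig_id, sample_id):
    return UViGRecord(uvig_id=uvig_id, sample_id=sample_id, sequence="A" * 100,
                      length_bp=100, viral_genes=1, host_genes=0,
                      hallmark_genes=0, screen_score=0.9, completeness_pct=95.0)


def clone(a, b):
    return ClonePair(a, b, 99.9, 1.0)


@pytest.fixture()
def scenario():
    """One female donor; one female FMT recipient, one male FMT
    recipient, one female placebo recipient."""
    metadata = [
        sample("D1_don1", "D1", "donor", "none", "female", "donation", 1),
        sample("D2_don1", "D2", "donor", "none", "female", "donation", 1),
    ]
    uvigs = [uvig("d1_v1", "D1_don1"), uvig("d1_v2", "D1_don1"),
             uvig("d2_v1", "D2_don1")]
    for subj, treat, sex in (("R1", "FMT", "female"), ("R2", "FMT", "male"),
                             ("P1", "placebo", "female")):
        for tp in ("baseline", "wk6", "wk12", "wk26"):
            sid = f"{subj}_{tp}"
            metadata.append(sample(sid, subj, "recipient", treat, sex, tp))
            uvigs.append(uvig(f"{subj}_{tp}_x", sid))
    membership = {u.uvig_id: "votuA" for u in uvigs}
    return metadata, uvigs, membership


class TestEventDefinition:
    def test_post_detection_without_baseline_is_event(self, scenario):
        metadata, uvigs, membership = scenario
        clones = [clone("d1_v1", "R1_wk6_x"), clone("d1_v1", "R1_wk12_x")]
        (event,) = detect_engraftment_events(clones, uvigs, metadata, membership)
        assert event.recipient_subject == "R1"
        assert event.first_detection is Timepoint.wk6
        assert event.donors == {"D1"}

    def test_baseline_clone_disqualifies(self, scenario):
        metadata, uvigs, membership = scenario
        clones = [clone("d1_v1", "R1_baseline_x"), clone("d1_v1", "R1_wk12_x")]
        assert detect_engraftment_events(clones, uvigs, metadata, membership) == []

    def test_cross_sex_pair_excluded_with_warning(self, scenario, caplog):
        metadata, uvigs, membership = scenario
        clones = [clone("d1_v1", "R2_wk6_x")]   # female donor, male recipient
        with caplog.at_level("WARNING", logger="phagefmt"):
            events = detect_engraftment_events(clones, uvigs, metadata, membership)
        assert events == []
        assert any("spans sexes" in r.message for r in caplog.records)

    def test_placebo_recipients_processed(self, scenario):
        metadata, uvigs, membership = scenario
        clones = [clone("d1_v1", "P1_wk26_x")]
        (event,) = detect_engraftment_events(clones, uvigs, metadata, membership)
        assert event.recipient_subject == "P1"
        assert event.first_detection is Timepoint.wk26


class TestAttribution:
    def test_single_carrier(self, scenario):
        metadata, uvigs, _ = scenario
        membership = {"d1_v1": "votuA"}
        presence = donor_presence_table(membership, uvigs, metadata)
        event = EngraftmentEvent("votuA", "R1", {"D1"}, Timepoint.wk6)
        assert attribute_donors(event, presence) == {"D1"}
        assert not event.multiple_donors

    def test_multi_donor_tagged_multiple(self, scenario):
        metadata, uvigs, membership = scenario
        presence = donor_presence_table(membership, uvigs, metadata)
        event = EngraftmentEvent("votuA", "R1", {"D1"}, Timepoint.wk6)
        assert attribute_donors(event, presence) == {"D1", "D2"}
        assert event.multiple_donors

    def test_empty_donor_set_is_internal_error(self):
        event = EngraftmentEvent("ghost", "R1", set(), Timepoint.wk6)
        with pytest.raises(RuntimeError):
            attribute_donors(event, {})


class TestEfficacy:
    def test_proportion_arithmetic(self):
        d = DonorEfficacy("D", 100, 63)
        assert d.efficacy == pytest.approx(0.63)
        assert DonorEfficacy("D", 10, 0).efficacy == 0.0
        assert DonorEfficacy("D", 0, 0).efficacy is None

    def test_chisq_matches_hand_formula(self):
        """2x2 engrafted/not table (8,2 vs 2,8): chi2 = sum (O-E)^2/E = 7.2."""
        presence = {f"v{i}": {"D1"} for i in range(10)}
        presence.update({f"w{i}": {"D2"} for i in range(10)})
        events = [EngraftmentEvent(f"v{i}", "R1", {"D1"}, Timepoint.wk6) for i in range(8)]
        events += [EngraftmentEvent(f"w{i}", "R1", {"D2"}, Timepoint.wk6) for i in range(2)]
        eff, test = donor_efficacy(events, presence)
        by_id = {e.donor_id: e for e in eff}
        assert by_id["D1"].n_engrafted == 8 and by_id["D2"].n_engrafted == 2
        assert test.statistic == pytest.approx(7.2)

    def test_multi_donor_counts_toward_each_carrier(self):
        presence = {"v0": {"D1", "D2"}}
        events = [EngraftmentEvent("v0", "R1", {"D1", "D2"}, Timepoint.wk6)]
        eff, _ = donor_efficacy(events, presence)
        assert all(e.n_engrafted == 1 for e in eff)


class TestPartition:
    def test_three_way_labels(self):
        metadata = [
            sample(f"R1_{tp}", "R1", "recipient", "FMT", "female", tp)
            for tp in ("baseline", "wk6", "wk12", "wk26")
        ]
        # votuS: donor-shared; votuB: baseline-conserved; votuN: novel at wk12
        mat = pd.DataFrame(
            {
                "R1_baseline": [0.0, 5.0, 0.0],
                "R1_wk6": [3.0, 5.0, 0.0],
                "R1_wk12": [3.0, 0.0, 2.0],
                "R1_wk26": [0.0, 5.0, 2.0],
            },
            index=["votuS", "votuB", "votuN"],
        )
        abund = AbundanceMatrix(mat, Unit.CPM_derived)
        part = partition_phageome(abund, {"R1": {"votuS"}}, metadata)
        row = part.set_index("timepoint")
        assert row.loc["wk6", "n_shared_with_donors"] == 1
        assert row.loc["wk6", "n_conserved_from_baseline"] == 1
        assert row.loc["wk12", "n_novel"] == 1
        assert row.loc["wk26", "n_conserved_from_baseline"] == 1  # votuB again
        assert row.loc["baseline", "n_novel"] == 0
        props = part[["p_shared_with_donors", "p_conserved_from_baseline", "p_novel"]]
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_missing_baseline_raises(self):
        metadata = [sample("R1_wk6", "R1", "recipient", "FMT", "female", "wk6")]
        mat = pd.DataFrame({"R1_wk6": [1.0]}, index=["v"])
        with pytest.raises(ValueError, match="baseline"):
            partition_phageome(AbundanceMatrix(mat, Unit.CPM_derived), {}, metadata)

    def test_votu_level_share_uses_sex_matching(self, scenario):
        metadata, uvigs, membership = scenario
        presence = donor_presence_table(membership, uvigs, metadata)
        share = donor_share_by_votu(presence, metadata)
        assert share["R1"] == {"votuA"}   # female recipient, female donors
        assert share["R2"] == set()       # male recipient, no male donors


class TestCohortRecovery:
    def test_events_match_simulated_transfers(self, small_cohort):
        """End-to-end on the small cohort: every called FMT event is a
        true transfer and every transfer is called; placebo clean."""
        from phagefmt.ani import SimilarityProvider
        from phagefmt.cluster import cluster_votus, detect_clones, membership_table
        from phagefmt.screen import retained_records

        retained = retained_records(small_cohort.uvigs)
        provider = SimilarityProvider({u.uvig_id: u.sequence for u in retained})
        clusters = cluster_votus(retained, provider)
        by_id = {u.uvig_id: u for u in retained}
        hq = [c for c in clusters if by_id[c.representative].completeness_pct >= 90]
        clones = detect_clones(hq, provider)
        membership = membership_table(hq)
        events = detect_engraftment_events(clones, retained, small_cohort.metadata,
                                           membership)
        truth = small_cohort.truth
        lineage_of_votu = {}
        for c in hq:
            for m in c.members:
                lin = truth.lineage_of_uvig.get(m)
                if lin:
                    lineage_of_votu.setdefault(c.votu_id, lin)
        treat = {m.subject_id: m.treatment for m in small_cohort.metadata}
        called = {
            (lineage_of_votu[e.votu_id], e.recipient_subject)
            for e in events if treat[e.recipient_subject] is Treatment.FMT
        }
        assert called == truth.transferred_pairs()
        assert not any(treat[e.recipient_subject] is Treatment.placebo for e in events)
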