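"""Engraftment calling, donor attribution, efficacy, and phageome partition.

A donor phage is engrafted when a clone of it (same vOTU, ANI >= 99.4% /
AF >= 0.85) is identified in a recipient at a post-treatment timepoint
(week 6 onward) and no donor clone of that vOTU was present in the
recipient at baseline. Events are keyed per (vOTU, recipient); the paper-
scale "999 events" unit. Donor attribution assigns every donor in which
the vOTU was identified; more than one carrier means the true source is
ambiguous and the event is tagged "multiple", counting toward each
carrier's efficacy numerator.

Placebo recipients are processed identically — their (expected zero)
event count is a specificity control for the pipeline, not a biological
claim.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import pandas as pd

from .catalog import AbundanceMatrix
from .model import (
    ClonePair,
    DonorEfficacy,
    EngraftmentEvent,
    Role,
    SampleRecord,
    Timepoint,
    Treatment,
    UViGRecord,
)
from .stats import chisq_with_posthoc

logger = logging.getLogger("phagefmt")


def _sample_index(metadata: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {m.sample_id: m for m in metadata}


def donor_presence_table(
    membership: dict[str, str],
    uvigs: Sequence[UViGRecord],
    metadata: Sequence[SampleRecord],
) -> dict[str, set[str]]:
    """vOTU -> set of donor subjects in which the vOTU was identified
    (has a member UViG assembled from a donor sample)."""
    samples = _sample_index(metadata)
    presence: dict[str, set[str]] = defaultdict(set)
    for u in uvigs:
        meta = samples.get(u.sample_id)
        if meta is None or meta.role is not Role.donor:
            continue
        votu = membership.get(u.uvig_id)
        if votu is not None:
            presence[votu].add(meta.subject_id)
    return dict(presence)


def detect_engraftment_events(
    clones: Sequence[ClonePair],
    uvigs: Sequence[UViGRecord],
    metadata: Sequence[SampleRecord],
    membership: dict[str, str],
) -> list[EngraftmentEvent]:
    """Call engraftment events from donor-recipient clone pairs.

    Only sex-matched donor-recipient pairs qualify (capsules were
    administered male-to-male / female-to-female); cross-sex clone pairs
    are excluded with a warning. A clone detected in the recipient's
    baseline sample disqualifies the (vOTU, recipient) pair entirely.
    """
    samples = _sample_index(metadata)
    uvig_meta = {u.uvig_id: samples[u.sample_id] for u in uvigs if u.sample_id in samples}

    detections: dict[tuple[str, str], list[tuple[Timepoint, str, tuple[str, str]]]] = defaultdict(list)
    baseline_blocked: set[tuple[str, str]] = set()

    for pair in clones:
        ma, mb = uvig_meta.get(pair.uvig_a), uvig_meta.get(pair.uvig_b)
        if ma is None or mb is None:
            continue
        if ma.role is mb.role:
            continue
        donor_uvig, donor_meta = (pair.uvig_a, ma) if ma.role is Role.donor else (pair.uvig_b, mb)
        recip_uvig, recip_meta = (pair.uvig_b, mb) if ma.role is Role.donor else (pair.uvig_a, ma)
        if donor_meta.sex is not recip_meta.sex:
            logger.warning(
                "clone pair %s/%s spans sexes (%s donor, %s recipient); excluded",
                pair.uvig_a, pair.uvig_b, donor_meta.sex.value, recip_meta.sex.value,
            )
            continue
        votu = membership.get(donor_uvig)
        key = (votu, recip_meta.subject_id)
        if recip_meta.timepoint is Timepoint.baseline:
            baseline_blocked.add(key)
        else:
            detections[key].append(
                (recip_meta.timepoint, donor_meta.subject_id, (donor_uvig, recip_uvig))
            )

    events: list[EngraftmentEvent] = []
    for (votu, recipient), hits in sorted(detections.items()):
        if (votu, recipient) in baseline_blocked:
            continue
        first = min((tp for tp, _, _ in hits), key=lambda t: t.order)
        donors = {d for _, d, _ in hits}
        evidence = sorted({pair for _, _, pair in hits})
        events.append(EngraftmentEvent(votu, recipient, donors, first, evidence))
    n_fmt = sum(
        1 for e in events
        if _subject_treatment(metadata, e.recipient_subject) is Treatment.FMT
    )
    logger.info(
        "detect_engraftment_events: %d events (%d in FMT recipients, %d placebo)",
        len(events), n_fmt, len(events) - n_fmt,
    )
    return events


def _subject_treatment(metadata: Sequence[SampleRecord], subject: str) -> Treatment:
    for m in metadata:
        if m.subject_id == subject:
            return m.treatment
    raise KeyError(subject)


def attribute_donors(
    event: EngraftmentEvent, donor_presence: dict[str, set[str]]
) -> set[str]:
    """All donors in which the event's vOTU was identified; the event is
    tagged "multiple" (via ``multiple_donors``) when ambiguous."""
    donors = set(donor_presence.get(event.votu_id, set())) | set(event.donors)
    if not donors:
        raise RuntimeError(
            f"event {event.votu_id}/{event.recipient_subject} has no carrying donor"
        )
    event.donors = donors
    return donors


def donor_efficacy(
    events: Sequence[EngraftmentEvent],
    donor_presence: dict[str, set[str]],
    metadata: Sequence[SampleRecord] | None = None,
) -> tuple[list[DonorEfficacy], "pd.DataFrame | None"]:
    """Per-donor engraftment efficacy plus a chi-squared homogeneity test.

    Efficacy = engrafted vOTUs / vOTUs identified in the donor; a vOTU
    carried by several donors counts toward each carrier. Events in
    placebo recipients are excluded from the numerator. Returns the
    per-donor table and the chi-squared/post hoc results (None when the
    test is degenerate).
    """
    votus_of_donor: dict[str, set[str]] = defaultdict(set)
    for votu, donors in donor_presence.items():
        for d in donors:
            votus_of_donor[d].add(votu)
    engrafted_of_donor: dict[str, set[str]] = defaultdict(set)
    for e in events:
        if metadata is not None and _subject_treatment(metadata, e.recipient_subject) is not Treatment.FMT:
            continue
        for d in e.donors:
            engrafted_of_donor[d].add(e.votu_id)
    out = [
        DonorEfficacy(d, len(votus_of_donor[d]), len(engrafted_of_donor[d] & votus_of_donor[d]))
        for d in sorted(votus_of_donor)
    ]
    table = pd.DataFrame(
        {
            "engrafted": [e.n_engrafted for e in out],
            "not_engrafted": [e.n_votus_donor - e.n_engrafted for e in out],
        },
        index=[e.donor_id for e in out],
    )
    test = None
    if len(out) >= 2 and table.to_numpy().sum() > 0:
        try:
            test = chisq_with_posthoc(table)
        except ValueError:
            logger.warning("donor_efficacy: degenerate contingency table, test skipped")
    return out, test


def partition_phageome(
    abund: AbundanceMatrix,
    donor_share: dict[str, set[str]],
    metadata: Sequence[SampleRecord],
) -> pd.DataFrame:
    """Classify each recipient-timepoint vOTU by origin.

    Categories: ``shared_with_donors`` when a sex-matched donor carries
    the vOTU (per the supplied ``donor_share`` evidence — clone-level by
    default, see :func:`donor_share_by_clone`); else
    ``conserved_from_baseline`` when identified in the subject's baseline
    sample; else ``novel``. Baseline samples have no novel class by
    definition. Returns one row per (subject, timepoint) with counts and
    proportions.
    """
    mat = abund.data
    samples = [m for m in metadata if m.role is Role.recipient and m.sample_id in mat.columns]
    by_subject: dict[str, dict[Timepoint, str]] = defaultdict(dict)
    for m in samples:
        by_subject[m.subject_id][m.timepoint] = m.sample_id
    rows = []
    for subject in sorted(by_subject):
        tps = by_subject[subject]
        if Timepoint.baseline not in tps:
            raise ValueError(f"subject {subject}: missing baseline sample")
        base_col = mat[tps[Timepoint.baseline]]
        baseline_votus = set(base_col.index[base_col > 0])
        shared = donor_share.get(subject, set())
        for tp, sid in sorted(tps.items(), key=lambda kv: kv[0].order):
            col = mat[sid]
            identified = set(col.index[col > 0])
            n_shared = len(identified & shared)
            if tp is Timepoint.baseline:
                n_conserved = len(identified) - n_shared
                n_novel = 0
            else:
                n_conserved = len((identified - shared) & baseline_votus)
                n_novel = len(identified - shared - baseline_votus)
            total = n_shared + n_conserved + n_novel
            rows.append(
                {
                    "subject": subject,
                    "timepoint": tp.value,
                    "n_shared_with_donors": n_shared,
                    "n_conserved_from_baseline": n_conserved,
                    "n_novel": n_novel,
                    "p_shared_with_donors": n_shared / total if total else 0.0,
                    "p_conserved_from_baseline": n_conserved / total if total else 0.0,
                    "p_novel": n_novel / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def donor_share_by_clone(
    clones: Sequence[ClonePair],
    uvigs: Sequence[UViGRecord],
    metadata: Sequence[SampleRecord],
    membership: dict[str, str],
) -> dict[str, set[str]]:
    """subject -> vOTUs with clone-level evidence of sex-matched donor
    carriage (the default donor-share notion for the partition)."""
    samples = _sample_index(metadata)
    uvig_meta = {u.uvig_id: samples[u.sample_id] for u in uvigs if u.sample_id in samples}
    share: dict[str, set[str]] = defaultdict(set)
    for pair in clones:
        ma, mb = uvig_meta.get(pair.uvig_a), uvig_meta.get(pair.uvig_b)
        if ma is None or mb is None or ma.role is mb.role:
            continue
        donor_meta, recip_meta = (ma, mb) if ma.role is Role.donor else (mb, ma)
        if donor_meta.sex is not recip_meta.sex:
            continue
        votu = membership.get(pair.uvig_a)
        if votu is not None:
            share[recip_meta.subject_id].add(votu)
    return dict(share)


def donor_share_by_votu(
    donor_presence: dict[str, set[str]],
    metadata: Sequence[SampleRecord],
) -> dict[str, set[str]]:
    """subject -> vOTUs identified in any sex-matched donor (the looser,
    vOTU-level donor-share notion; available by flag)."""
    donor_sex = {m.subject_id: m.sex for m in metadata if m.role is Role.donor}
    votus_by_sex: dict[str, set[str]] = defaultdict(set)
    for votu, donors in donor_presence.items():
        for d in donors:
            votus_by_sex[donor_sex[d].value].add(votu)
    out = {}
    for m in metadata:
        if m.role is Role.recipient:
            out[m.subject_id] = votus_by_sex.get(m.sex.value, set())
    return out
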