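"""Viral-contig screening decision rules.

A contig is a putative virus if it carries at least one predicted viral
gene, or has no host genes, or scores >= 0.95 with the viral classifier,
or carries three or more viral hallmark genes. Included contigs are then
flagged as false positives when host-gene evidence dominates: more than 4
host genes, or a host-to-viral gene ratio (HVR) above 0.386. Finally only
high-quality draft genomes (completeness >= 90%) enter downstream analyses.

All comparators are exactly as stated: ">" is strict, ">=" inclusive, so
host_genes == 4 and HVR == 0.386 are *not* flagged, and score == 0.95 and
completeness == 90 *are* kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import ScreenDecision, UViGRecord

logger = logging.getLogger("phagefmt")


@dataclass(frozen=True)
class ScreenThresholds:
    min_viral_genes: int = 1
    min_score: float = 0.95
    min_hallmark: int = 3
    max_host_genes: int = 4       # flagged when strictly greater
    max_hvr: float = 0.386        # flagged when strictly greater
    min_completeness: float = 90.0


DEFAULT_THRESHOLDS = ScreenThresholds()


def classify_putative_viral(
    r: UViGRecord, thresholds: ScreenThresholds = DEFAULT_THRESHOLDS
) -> tuple[bool, list[str]]:
    """Inclusion rule; returns (included, satisfied clause tags)."""
    reasons = []
    if r.viral_genes >= thresholds.min_viral_genes:
        reasons.append("viral_gene")
    if r.host_genes == 0:
        reasons.append("no_host_genes")
    if r.screen_score >= thresholds.min_score:
        reasons.append("score")
    if r.hallmark_genes >= thresholds.min_hallmark:
        reasons.append("hallmark")
    return bool(reasons), reasons


def hvr_of(r: UViGRecord) -> float:
    """Host-to-viral gene ratio.

    Defined as +inf when viral_genes == 0 but host genes exist (always
    flagged), and 0 when both counts are 0.
    """
    if r.viral_genes == 0:
        return math.inf if r.host_genes > 0 else 0.0
    return r.host_genes / r.viral_genes


def flag_false_positive(
    r: UViGRecord, thresholds: ScreenThresholds = DEFAULT_THRESHOLDS
) -> tuple[bool, float]:
    """False-positive rule for contigs that passed inclusion."""
    hvr = hvr_of(r)
    flagged = r.host_genes > thresholds.max_host_genes or hvr > thresholds.max_hvr
    return flagged, hvr


def filter_high_quality(
    records: Sequence[UViGRecord], thresholds: ScreenThresholds = DEFAULT_THRESHOLDS
) -> list[UViGRecord]:
    """Retain high-quality draft genomes (completeness >= 90), order preserved."""
    return [r for r in records if r.completeness_pct >= thresholds.min_completeness]


def screen_records(
    records: Iterable[UViGRecord], thresholds: ScreenThresholds = DEFAULT_THRESHOLDS
) -> list[ScreenDecision]:
    """Run the composed screen on every record.

    ``high_quality`` here is the UViG-level completeness flag; the paper-
    default application of the completeness filter is at the vOTU-
    representative level downstream (see :mod:`phagefmt.pipeline`).
    """
    decisions = []
    n_excluded = n_fp = n_kept = 0
    for r in records:
        included, reasons = classify_putative_viral(r, thresholds)
        if not included:
            decisions.append(
                ScreenDecision(r.uvig_id, False, False, False, hvr_of(r), ["no_inclusion_clause"])
            )
            n_excluded += 1
            continue
        fp, hvr = flag_false_positive(r, thresholds)
        if fp:
            tags = reasons + (
                ["fp_host_genes"] if r.host_genes > thresholds.max_host_genes else []
            ) + (["fp_hvr"] if hvr > thresholds.max_hvr else [])
            decisions.append(ScreenDecision(r.uvig_id, True, True, False, hvr, tags))
            n_fp += 1
            continue
        hq = r.completeness_pct >= thresholds.min_completeness
        decisions.append(ScreenDecision(r.uvig_id, True, False, hq, hvr, reasons))
        n_kept += 1
    total = n_excluded + n_fp + n_kept
    logger.info(
        "screen: %d contigs -> %d excluded, %d false positives, %d retained",
        total, n_excluded, n_fp, n_kept,
    )
    return decisions


def retained_records(
    records: Sequence[UViGRecord], thresholds: ScreenThresholds = DEFAULT_THRESHOLDS
) -> list[UViGRecord]:
    """Records surviving inclusion and false-positive removal (all
    completeness levels; the HQ filter applies at vOTU level)."""
    out = []
    for r in records:
        included, _ = classify_putative_viral(r, thresholds)
        if included and not flag_false_positive(r, thresholds)[0]:
            out.append(r)
    return out
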