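"""Greedy centroid clustering of UViGs into vOTUs and clone detection.

vOTUs follow the MIUViG species-rank convention: ANI >= 95% over alignment
fraction >= 85% of the shorter sequence. Records are processed longest
first; each joins the first existing centroid meeting both thresholds
(first-hit assignment, configurable to best-hit), else founds a new
cluster, so the longest member is always the representative.

Clones — same-lineage pairs used for donor-to-recipient tracking — are
within-vOTU pairs at the stricter ANI >= 99.4% / AF >= 0.85. The clone
relation is symmetric but deliberately not forced transitive.
"""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Sequence

from .ani import SketchIndex
from .model import ClonePair, PairwiseSimilarity, UViGRecord, VOTUCluster

logger = logging.getLogger("phagefmt")

VOTU_ANI_PCT = 95.0
VOTU_AF = 0.85
CLONE_ANI_PCT = 99.4
CLONE_AF = 0.85

SimilarityFn = Callable[[str, str], PairwiseSimilarity]


def cluster_votus(
    records: Sequence[UViGRecord],
    sims: SimilarityFn,
    min_ani_pct: float = VOTU_ANI_PCT,
    min_af: float = VOTU_AF,
    assignment: str = "first",
    prefilter: bool = True,
) -> list[VOTUCluster]:
    """Cluster UViGs into vOTUs by greedy centroid assignment.

    ``assignment`` is "first" (join the first qualifying centroid in
    length order) or "best" (highest-ANI qualifying centroid). With
    ``prefilter`` a k-mer sketch index skips centroids that cannot reach
    the mapping identity floor.
    """
    if not records:
        raise ValueError("cluster_votus: no records")
    if assignment not in ("first", "best"):
        raise ValueError(f"unknown assignment policy {assignment!r}")
    ordered = sorted(records, key=lambda r: (-r.length_bp, r.uvig_id))
    clusters: list[VOTUCluster] = []
    centroid_of: dict[str, VOTUCluster] = {}
    index = SketchIndex() if prefilter else None
    for rec in ordered:
        if index is not None:
            candidate_ids = index.candidates(rec.sequence)
            # preserve founding (length) order for first-hit semantics
            candidates = sorted(
                (centroid_of[c] for c in candidate_ids), key=lambda c: c.votu_id
            )
        else:
            candidates = clusters
        chosen: VOTUCluster | None = None
        best_ani = -1.0
        for cluster in candidates:
            sim = sims(cluster.representative, rec.uvig_id)
            if sim.ani_pct >= min_ani_pct and sim.af_smaller >= min_af:
                if assignment == "first":
                    chosen = cluster
                    break
                if sim.ani_pct > best_ani:
                    best_ani = sim.ani_pct
                    chosen = cluster
        if chosen is None:
            chosen = VOTUCluster(
                votu_id=f"vOTU{len(clusters):05d}",
                representative=rec.uvig_id,
                members={rec.uvig_id},
            )
            clusters.append(chosen)
            centroid_of[rec.uvig_id] = chosen
            if index is not None:
                index.add(rec.uvig_id, rec.sequence)
        else:
            chosen.members.add(rec.uvig_id)
    logger.info("cluster_votus: %d UViGs -> %d vOTUs", len(records), len(clusters))
    return clusters


def detect_clones(
    clusters: Sequence[VOTUCluster],
    sims: SimilarityFn,
    min_ani_pct: float = CLONE_ANI_PCT,
    min_af: float = CLONE_AF,
) -> list[ClonePair]:
    """Emit within-vOTU pairs meeting the clone thresholds."""
    pairs: list[ClonePair] = []
    for cluster in clusters:
        for a, b in itertools.combinations(sorted(cluster.members), 2):
            sim = sims(a, b)
            if sim.ani_pct >= min_ani_pct and sim.af_smaller >= min_af:
                pairs.append(ClonePair(a, b, sim.ani_pct, sim.af_smaller))
    logger.info("detect_clones: %d clone pairs", len(pairs))
    return pairs


def membership_table(clusters: Sequence[VOTUCluster]) -> dict[str, str]:
    """uvig_id -> votu_id map (clusters partition the input)."""
    out: dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            out[m] = c.votu_id
    return out
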