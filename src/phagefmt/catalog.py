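"""Non-redundant gene catalog and CPM abundance profiles.

Reads are counted per gene; genes are dereplicated into a catalog at 95%
identity over 85% of the shorter gene. Counts are length-normalized to
RPK (reads per kilobase of gene), depth-normalized within each sample and
scaled to copies per million (CPM), then aggregated: a UViG's abundance
in a sample is the *median* CPM over its catalog genes (zero-count genes
included, configurable), and a vOTU's abundance is the sum over its
member UViGs. A vOTU is "identified" in a sample iff its value > 0.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ani import SimilarityProvider, SketchIndex
from .model import GeneRecord, VOTUCluster

logger = logging.getLogger("phagefmt")

GENE_MIN_IDENTITY_PCT = 95.0
GENE_MIN_AF = 0.85
GENE_FRAGMENT_LEN = 300


class Unit(str, enum.Enum):
    count = "count"
    RPK = "RPK"
    CPM = "CPM"
    CPM_derived = "CPM-derived"


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance table with an explicit unit."""

    data: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")


@dataclass
class GeneCluster:
    centroid_gene: str
    centroid_length: int
    members: set[str] = field(default_factory=set)


def extract_gene_sequences(
    genes: Sequence[GeneRecord], uvig_sequences: dict[str, str]
) -> dict[str, str]:
    out = {}
    for g in genes:
        seq = uvig_sequences.get(g.uvig_id)
        if seq is None:
            raise KeyError(f"no sequence for parent UViG {g.uvig_id!r} of gene {g.gene_id}")
        out[g.gene_id] = seq[g.start : g.end]
    return out


def build_gene_catalog(
    genes: Sequence[GeneRecord],
    gene_sequences: dict[str, str],
    min_identity_pct: float = GENE_MIN_IDENTITY_PCT,
    min_af: float = GENE_MIN_AF,
) -> list[GeneCluster]:
    """Greedy length-descending clustering of genes at 95%/85%.

    Same kernel as vOTU clustering with the fragment length shortened to
    min(gene length, 300) so short genes still tile at least one fragment.
    """
    ordered = sorted(genes, key=lambda g: (-g.length_bp, g.gene_id))
    provider = SimilarityProvider(gene_sequences, fragment_len=GENE_FRAGMENT_LEN)
    index = SketchIndex(stride=4, min_hits=3)
    clusters: list[GeneCluster] = []
    cluster_of_centroid: dict[str, GeneCluster] = {}
    for g in ordered:
        seq = gene_sequences[g.gene_id]
        chosen = None
        for cid in sorted(index.candidates(seq),
                          key=lambda c: cluster_of_centroid[c].centroid_gene):
            cluster = cluster_of_centroid[cid]
            sim = provider(cluster.centroid_gene, g.gene_id)
            if sim.ani_pct >= min_identity_pct and sim.af_smaller >= min_af:
                chosen = cluster
                break
        if chosen is None:
            chosen = GeneCluster(g.gene_id, g.length_bp, {g.gene_id})
            clusters.append(chosen)
            cluster_of_centroid[g.gene_id] = chosen
            index.add(g.gene_id, seq)
        else:
            chosen.members.add(g.gene_id)
    logger.info("build_gene_catalog: %d genes -> %d clusters", len(genes), len(clusters))
    return clusters


def aggregate_counts_to_catalog(
    counts: pd.DataFrame, catalog: Sequence[GeneCluster]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sum per-gene counts into per-catalog-centroid counts; returns the
    centroid x sample matrix and centroid lengths."""
    centroid_of = {m: c.centroid_gene for c in catalog for m in c.members}
    present = counts.index.map(centroid_of.get)
    grouped = counts.groupby(present.to_numpy()).sum()
    grouped.index.name = "gene_id"
    lengths = {c.centroid_gene: c.centroid_length for c in catalog}
    # centroids with no counted member appear as all-zero rows
    missing = [c.centroid_gene for c in catalog if c.centroid_gene not in grouped.index]
    if missing:
        zeros = pd.DataFrame(0.0, index=missing, columns=grouped.columns)
        grouped = pd.concat([grouped, zeros]).sort_index()
    return grouped, lengths


def counts_to_cpm(
    counts: AbundanceMatrix | pd.DataFrame, lengths: dict[str, int]
) -> AbundanceMatrix:
    """count -> RPK -> CPM. RPK = count/(length/1000); CPM rescales each
    sample's RPK column to sum to 1e6 (all-zero columns stay zero)."""
    mat = counts.data if isinstance(counts, AbundanceMatrix) else counts
    missing = [g for g in mat.index if g not in lengths]
    if missing:
        raise KeyError(f"missing gene lengths for {missing[:5]}{'...' if len(missing) > 5 else ''}")
    len_kb = pd.Series({g: lengths[g] / 1000.0 for g in mat.index})
    if (len_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = mat.div(len_kb, axis=0)
    colsum = rpk.sum(axis=0)
    cpm = rpk.div(colsum.where(colsum > 0, 1.0), axis=1) * 1e6
    return AbundanceMatrix(cpm, Unit.CPM)


def uvig_abundance(
    cpm: AbundanceMatrix,
    gene_to_uvigs: dict[str, set[str]],
    include_zeros: bool = True,
) -> AbundanceMatrix:
    """Median gene CPM per UViG per sample.

    ``gene_to_uvigs`` maps each catalog centroid to every UViG that
    contributed a member gene (a shared gene cluster's CPM is attributed
    to each contributor). With ``include_zeros`` (default) zero-count
    genes enter the median; otherwise the median is over nonzero genes
    only and all-zero UViGs get 0.
    """
    rows: dict[str, list[str]] = {}
    for gene, uvigs in gene_to_uvigs.items():
        for u in uvigs:
            rows.setdefault(u, []).append(gene)
    mat = cpm.data
    values = np.zeros((len(rows), mat.shape[1]))
    uvig_ids = sorted(rows)
    for i, u in enumerate(uvig_ids):
        sub = mat.loc[rows[u]].to_numpy()
        if include_zeros:
            values[i] = np.median(sub, axis=0)
        else:
            masked = np.where(sub > 0, sub, np.nan)
            with np.errstate(all="ignore"):
                med = np.nanmedian(masked, axis=0)
            values[i] = np.nan_to_num(med)
    out = pd.DataFrame(values, index=uvig_ids, columns=mat.columns)
    return AbundanceMatrix(out, Unit.CPM_derived)


def votu_abundance(
    uvig_abund: AbundanceMatrix, clusters: Sequence[VOTUCluster]
) -> AbundanceMatrix:
    """Per-sample sum of member-UViG abundances per vOTU."""
    mat = uvig_abund.data
    votu_ids = []
    rows = []
    for c in clusters:
        members = [m for m in c.members if m in mat.index]
        votu_ids.append(c.votu_id)
        if members:
            rows.append(mat.loc[members].sum(axis=0))
        else:
            logger.warning("votu_abundance: vOTU %s has no quantified members", c.votu_id)
            rows.append(pd.Series(0.0, index=mat.columns))
    out = pd.DataFrame(rows, index=votu_ids)
    out.index.name = "votu_id"
    return AbundanceMatrix(out, Unit.CPM_derived)


def catalog_gene_to_uvigs(
    catalog: Sequence[GeneCluster], genes: Sequence[GeneRecord]
) -> dict[str, set[str]]:
    parent = {g.gene_id: g.uvig_id for g in genes}
    return {
        c.centroid_gene: {parent[m] for m in c.members}
        for c in catalog
    }
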