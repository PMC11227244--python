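"""End-to-end orchestration: simulate -> screen -> cluster -> quantify ->
engraft -> stats, with a single YAML config as the source of truth.

Every stage logs input/output record counts so the screening funnel
(contigs -> putative viral -> post-FP -> HQ vOTUs) is auditable, and the
effective configuration is serialized into the run directory for
provenance. Stage outputs are plain TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .ani import SimilarityProvider
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
from .cluster import cluster_votus, detect_clones, membership_table
from .engraftment import (
    attribute_donors,
    detect_engraftment_events,
    donor_efficacy,
    donor_presence_table,
    donor_share_by_clone,
    donor_share_by_votu,
    partition_phageome,
)
from .model import Treatment, UViGRecord
from .screen import ScreenThresholds, retained_records, screen_records
from .simulate import SimConfig, simulate_cohort, simulate_gene_counts, write_cohort
from .stats import (
    alpha_diversity_contrasts,
    convergence_to_donors,
    lifestyle_totals,
    variability_from_wk6,
    votu_stability,
)

logger = logging.getLogger("phagefmt")


@dataclass
class RunConfig:
    """All thresholds and toggles of a pipeline run."""

    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    # clustering thresholds
    votu_ani_pct: float = 95.0
    votu_af: float = 0.85
    clone_ani_pct: float = 99.4
    clone_af: float = 0.85
    fragment_len: int = 1000
    min_frag_identity: float = 80.0
    assignment: str = "first"          # centroid assignment: first | best
    # screening thresholds
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    # quantification toggles
    median_include_zeros: bool = True
    attribute_shared_genes: bool = True    # shared gene clusters to all contributors
    # partition donor-share evidence: clone | votu
    donor_share_level: str = "clone"
    # statistics
    lmm_response: str = "change"           # change | raw
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        })
        screen = ScreenThresholds(**raw.pop("screen", {}))
        return cls(sim=sim, screen=screen, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["sim"] = {k: list(v) if isinstance(v, tuple) else v
                      for k, v in dataclasses.asdict(self.sim).items()}
        raw["screen"] = dataclasses.asdict(self.screen)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class RunResult:
    run_dir: Path
    uvigs: list[UViGRecord]
    metadata: list
    clusters: list
    hq_clusters: list
    clones: list
    votu_abund: AbundanceMatrix
    events: list
    efficacy: list
    partition: pd.DataFrame
    funnel: dict[str, int]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def run_all(config: RunConfig, run_dir: str | Path) -> RunResult:
    """Execute every stage; outputs land under ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        cohort = simulate_cohort(sim_cfg)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
        counts = simulate_gene_counts(rng, cohort.truth, cohort.metadata,
                                      cohort.genes, sim_cfg)
        inputs = run_dir / "inputs"
        write_cohort(cohort, inputs, counts=counts)
        sequences, uvigs, metadata, genes = (
            cohort.sequences, cohort.uvigs, cohort.metadata, cohort.genes)
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when simulate=False")
        inputs = Path(config.input_dir)
        for name in ("genomes.fasta", "annotations.tsv", "metadata.tsv",
                     "genes.tsv", "gene_counts.tsv"):
            _require(inputs / name)
        sequences = pio.read_fasta(inputs / "genomes.fasta")
        uvigs = pio.read_annotations(inputs / "annotations.tsv", sequences)
        metadata = pio.read_metadata(inputs / "metadata.tsv")
        genes = pio.read_genes(inputs / "genes.tsv",
                               {u.uvig_id: u.length_bp for u in uvigs})
        counts = pio.read_gene_counts(inputs / "gene_counts.tsv")

    funnel = {"contigs": len(uvigs)}

    # ---- screen ----------------------------------------------------------
    decisions = screen_records(uvigs, config.screen)
    pio.write_tsv(
        pd.DataFrame(
            [{"uvig_id": d.uvig_id, "included": d.included,
              "false_positive": d.false_positive, "high_quality": d.high_quality,
              "hvr": d.hvr, "reasons": ",".join(d.reasons)} for d in decisions]
        ),
        run_dir / "screen_decisions.tsv",
    )
    retained = retained_records(uvigs, config.screen)
    funnel["putative_viral"] = sum(1 for d in decisions if d.included)
    funnel["post_false_positive"] = len(retained)

    # ---- cluster ---------------------------------------------------------
    seq_of = {u.uvig_id: u.sequence for u in retained}
    provider = SimilarityProvider(seq_of, fragment_len=config.fragment_len,
                                  min_frag_identity=config.min_frag_identity)
    clusters = cluster_votus(retained, provider, config.votu_ani_pct,
                             config.votu_af, assignment=config.assignment)
    by_id = {u.uvig_id: u for u in retained}
    hq_clusters = [c for c in clusters
                   if by_id[c.representative].completeness_pct
                   >= config.screen.min_completeness]
    funnel["votus"] = len(clusters)
    funnel["hq_votus"] = len(hq_clusters)
    logger.info("funnel: %s", funnel)
    pio.write_tsv(
        pd.DataFrame(
            [{"votu_id": c.votu_id, "representative": c.representative, "member": m}
             for c in clusters for m in sorted(c.members)]
        ),
        run_dir / "votus.tsv",
    )
    clones = detect_clones(hq_clusters, provider, config.clone_ani_pct, config.clone_af)
    pio.write_tsv(
        pd.DataFrame(
            [{"uvig_a": c.uvig_a, "uvig_b": c.uvig_b, "ani_pct": c.ani_pct,
              "af_smaller": c.af_smaller} for c in clones]
        ),
        run_dir / "clones.tsv",
    )

    # ---- quantify --------------------------------------------------------
    retained_ids = set(seq_of)
    q_genes = [g for g in genes if g.uvig_id in retained_ids]
    gene_seqs = extract_gene_sequences(q_genes, seq_of)
    catalog = build_gene_catalog(q_genes, gene_seqs)
    counts_q = counts.loc[counts.index.intersection([g.gene_id for g in q_genes])]
    centroid_counts, lengths = aggregate_counts_to_catalog(counts_q, catalog)
    cpm = counts_to_cpm(centroid_counts, lengths)
    if config.attribute_shared_genes:
        gene_to_uvigs = catalog_gene_to_uvigs(catalog, q_genes)
    else:
        parent = {g.gene_id: g.uvig_id for g in q_genes}
        gene_to_uvigs = {c.centroid_gene: {parent[c.centroid_gene]} for c in catalog}
    uvig_abund = uvig_abundance(cpm, gene_to_uvigs,
                                include_zeros=config.median_include_zeros)
    votu_abund = votu_abundance(uvig_abund, clusters)
    hq_ids = [c.votu_id for c in hq_clusters]
    hq_abund = AbundanceMatrix(votu_abund.data.loc[hq_ids], Unit.CPM_derived)
    pio.write_matrix(votu_abund.data, run_dir / "votu_abundance.tsv")

    # ---- engraftment -----------------------------------------------------
    membership = membership_table(hq_clusters)
    presence = donor_presence_table(membership, retained, metadata)
    events = detect_engraftment_events(clones, retained, metadata, membership)
    for e in events:
        attribute_donors(e, presence)
    efficacy, efficacy_test = donor_efficacy(events, presence, metadata)
    pio.write_tsv(
        pd.DataFrame(
            [{"votu_id": e.votu_id, "recipient": e.recipient_subject,
              "donors": ",".join(sorted(e.donors)),
              "multiple": e.multiple_donors,
              "first_detection": e.first_detection.value} for e in events]
        ),
        run_dir / "events.tsv",
    )
    pio.write_tsv(
        pd.DataFrame(
            [{"donor_id": d.donor_id, "n_votus_donor": d.n_votus_donor,
              "n_engrafted": d.n_engrafted,
              "efficacy": d.efficacy} for d in efficacy]
        ),
        run_dir / "efficacy.tsv",
    )
    if config.donor_share_level == "clone":
        share = donor_share_by_clone(clones, retained, metadata, membership)
    else:
        share = donor_share_by_votu(presence, metadata)
    partition = partition_phageome(hq_abund, share, metadata)
    pio.write_tsv(partition, run_dir / "partition.tsv")

    # ---- stats -----------------------------------------------------------
    stats_dir = run_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    bc, var_tests = variability_from_wk6(hq_abund, metadata)
    pio.write_tsv(bc, stats_dir / "variability_bc.tsv")
    if not var_tests.empty:
        pio.write_tsv(var_tests, stats_dir / "variability_tests.tsv")
    stab_tab, stab_tests = votu_stability(hq_abund, metadata)
    pio.write_tsv(stab_tab.reset_index(names="treatment"), stats_dir / "stability_table.tsv")
    for sex, res in stab_tests.items():
        pio.write_tsv(res.residuals, stats_dir / f"stability_posthoc_{sex}.tsv")
    lifestyle_of_votu = {
        c.votu_id: by_id[c.representative].lifestyle for c in hq_clusters
    }
    totals, life_tests = lifestyle_totals(hq_abund, lifestyle_of_votu, metadata,
                                          response=config.lmm_response)
    pio.write_tsv(totals, stats_dir / "lifestyle_totals.tsv")
    if not life_tests.empty:
        pio.write_tsv(life_tests, stats_dir / "lifestyle_tests.tsv")
    alpha, alpha_tests = alpha_diversity_contrasts(hq_abund, metadata,
                                                   response=config.lmm_response)
    pio.write_tsv(alpha, stats_dir / "alpha_diversity.tsv")
    if not alpha_tests.empty:
        pio.write_tsv(alpha_tests, stats_dir / "alpha_tests.tsv")
    conv_bc, conv_tests = convergence_to_donors(hq_abund, metadata)
    pio.write_tsv(conv_bc, stats_dir / "convergence_bc.tsv")
    if not conv_tests.empty:
        pio.write_tsv(conv_tests, stats_dir / "convergence_tests.tsv")

    # ---- summary ---------------------------------------------------------
    n_unique_engrafted = len({e.votu_id for e in events
                              if _is_fmt(metadata, e.recipient_subject)})
    n_donor_votus = len(presence)
    summary_rows = [
        {"metric": k, "value": v} for k, v in funnel.items()
    ] + [
        {"metric": "engraftment_events_fmt",
         "value": sum(1 for e in events if _is_fmt(metadata, e.recipient_subject))},
        {"metric": "engraftment_events_placebo",
         "value": sum(1 for e in events if not _is_fmt(metadata, e.recipient_subject))},
        {"metric": "unique_engrafted_votus", "value": n_unique_engrafted},
        {"metric": "donor_votus_total", "value": n_donor_votus},
        {"metric": "overall_efficacy",
         "value": n_unique_engrafted / n_donor_votus if n_donor_votus else float("nan")},
    ]
    for d in efficacy:
        summary_rows.append({"metric": f"efficacy_{d.donor_id}",
                             "value": d.efficacy if d.efficacy is not None else "NA"})
    if efficacy_test is not None:
        summary_rows.append({"metric": "efficacy_chisq_p", "value": efficacy_test.p})
    pio.write_tsv(pd.DataFrame(summary_rows), run_dir / "summary.tsv")

    return RunResult(run_dir, uvigs, metadata, clusters, hq_clusters, clones,
                     votu_abund, events, efficacy, partition, funnel)


def _is_fmt(metadata, subject: str) -> bool:
    for m in metadata:
        if m.subject_id == subject:
            return m.treatment is Treatment.FMT
    raise KeyError(subject)


# ---------------------------------------------------------------------------
# report

REPORT_TABLES = (
    "efficacy_per_donor.tsv",
    "donor_convergence.tsv",
    "partition_proportions.tsv",
    "stability_categories.tsv",
    "lifestyle_totals.tsv",
)


def report(run_dir: str | Path, plots: bool = True) -> list[Path]:
    """Assemble figure-panel tables (and PNG plots) from a completed run.

    Raises FileNotFoundError listing missing stage outputs when the run
    is incomplete.
    """
    run_dir = Path(run_dir)
    needed = ["efficacy.tsv", "partition.tsv", "stats/lifestyle_totals.tsv",
              "stats/stability_table.tsv"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing outputs: {missing}")
    out_dir = run_dir / "report"
    out_dir.mkdir(exist_ok=True)
    written: list[Path] = []

    efficacy = pio.read_tsv(run_dir / "efficacy.tsv")
    pio.write_tsv(efficacy, out_dir / REPORT_TABLES[0])

    conv_path = run_dir / "stats" / "convergence_bc.tsv"
    if conv_path.exists():
        conv = pio.read_tsv(conv_path)
    else:
        conv = pd.DataFrame(columns=["donor", "subject", "timepoint", "value"])
    if conv.empty:
        conv = pd.DataFrame(
            [{"note": "no donor-convergence data (no donors or recipients in run)"}]
        )
    pio.write_tsv(conv, out_dir / REPORT_TABLES[1])

    partition = pio.read_tsv(run_dir / "partition.tsv")
    pio.write_tsv(partition, out_dir / REPORT_TABLES[2])
    stab = pio.read_tsv(run_dir / "stats" / "stability_table.tsv")
    pio.write_tsv(stab, out_dir / REPORT_TABLES[3])
    life = pio.read_tsv(run_dir / "stats" / "lifestyle_totals.tsv")
    pio.write_tsv(life, out_dir / REPORT_TABLES[4])
    written = [out_dir / t for t in REPORT_TABLES]

    if plots:
        _plots(out_dir, efficacy, partition, life)
    return written


def _plots(out_dir: Path, efficacy: pd.DataFrame, partition: pd.DataFrame,
           life: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    eff = efficacy.dropna(subset=["efficacy"])
    ax.bar(eff["donor_id"], eff["efficacy"].astype(float))
    ax.set_ylabel("engraftment efficacy")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out_dir / "efficacy_per_donor.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3))
    props = partition.groupby("timepoint")[
        ["p_shared_with_donors", "p_conserved_from_baseline", "p_novel"]
    ].mean()
    props.plot(kind="bar", stacked=True, ax=ax, legend=True)
    ax.set_ylabel("mean proportion of vOTUs")
    fig.tight_layout()
    fig.savefig(out_dir / "partition_proportions.png", dpi=120)
    plt.close(fig)
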