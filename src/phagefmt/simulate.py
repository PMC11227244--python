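"""Synthetic FMT-cohort generator with ground truth.

Emulates a sex-stratified, multi-donor FMT trial of the gut phageome:
donors of differing phageome richness donate once; sex-matched FMT and
placebo recipients are sampled at baseline and 6, 12, 26 weeks. Donor
phages transfer clonally into FMT recipients only, from week 6 onward,
with per-phage transfer probability a logistic function of the donor's
phageome Shannon diversity. Recipient baselines contain near-threshold
"distractor" relatives of donor phages (non-clones in the same vOTU),
novel lineages appear at single later timepoints, and a pool of
low-completeness "background" lineages absorbs most of the sequencing
depth (so analyses restricted to high-quality vOTUs are not
compositionally closed, as in real gut phageome data where most vOTUs
fail the completeness filter).

The mutation model is substitution-only, so Hamming identity is an exact
oracle for ANI on clone/distractor pairs. Every stochastic choice flows
from one seeded generator: a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .model import (
    GeneRecord,
    Lifestyle,
    Role,
    SampleRecord,
    Sex,
    Timepoint,
    Treatment,
    UViGRecord,
    POST_TIMEPOINTS,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults are the package's study conditions: 8 donors (4 per sex),
    10 FMT + 10 placebo recipients per sex, 4 recipient timepoints.
    """

    seed: int = 0
    n_donors_per_sex: int = 4
    donor_richness_range: tuple[int, int] = (30, 60)
    recipient_richness: int = 25
    n_fmt: int = 10                    # per sex
    n_placebo: int = 10                # per sex
    genome_length_range: tuple[int, int] = (5000, 12000)
    clone_divergence: float = 0.002    # substitutions/site for transfers
    distractor_divergence: float = 0.03
    engraft_prob_slope: float = 1.0
    engraft_prob_intercept: float = -2.0
    diversity_center: float = 3.1      # Shannon at which intercept applies
    temperate_fraction: float = 0.3
    unknown_lifestyle_fraction: float = 0.2
    temperate_postfmt_fold: float = 2.0
    count_dispersion: float = 0.5      # NB alpha: var = mu + alpha mu^2
    mean_depth: int = 200_000          # reads per sample
    abund_sigma: float = 1.2           # lognormal sd of lineage weights
    n_distractors: int = 5             # per recipient baseline
    novel_rate_fmt: float = 9.0        # Poisson mean per post timepoint
    novel_rate_placebo: float = 7.0
    conserved_persistence: float = 0.85
    engraft_persistence: float = 0.9
    n_shared_lineages_per_sex: int = 2  # lineages seeded into two donors
    background_per_subject: int = 12
    background_genome_length: int = 3000
    background_weight_mult: float = 9.0
    n_junk_contigs: int = 30

    def validate(self) -> None:
        for name in (
            "clone_divergence",
            "distractor_divergence",
            "temperate_fraction",
            "unknown_lifestyle_fraction",
            "conserved_persistence",
            "engraft_persistence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("donor_richness_range", "genome_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.temperate_postfmt_fold < 1.0:
            raise ValueError("temperate_postfmt_fold must be >= 1")
        if self.temperate_fraction + self.unknown_lifestyle_fraction > 1.0:
            raise ValueError("lifestyle fractions exceed 1")
        if self.n_distractors > self.recipient_richness:
            raise ValueError("n_distractors exceeds recipient_richness")


@dataclass(frozen=True)
class Transfer:
    donor_id: str
    lineage_id: str
    recipient_id: str
    transfer_time: Timepoint


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    clone_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    transfers: list[Transfer] = field(default_factory=list)
    lineage_of_uvig: dict[str, str] = field(default_factory=dict)
    lifestyle_of_lineage: dict[str, Lifestyle] = field(default_factory=dict)
    kind_of_lineage: dict[str, str] = field(default_factory=dict)
    donor_lineages: dict[str, set[str]] = field(default_factory=dict)
    donor_shannon: dict[str, float] = field(default_factory=dict)
    #: lineage x sample relative abundance on the CPM scale (all lineages).
    abundance: pd.DataFrame | None = None

    def transferred_pairs(self) -> set[tuple[str, str]]:
        return {(t.lineage_id, t.recipient_id) for t in self.transfers}


@dataclass
class Cohort:
    sequences: list[tuple[str, str]]
    uvigs: list[UViGRecord]
    genes: list[GeneRecord]
    metadata: list[SampleRecord]
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# sequence-level primitives

def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_clone(
    rng: np.random.Generator, parent: str, divergence: float
) -> tuple[str, int]:
    """Apply uniform point substitutions at the per-site rate ``divergence``.

    Returns the mutated sequence and the realized substitution count
    (length is preserved; every substitution changes the base).
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError(f"divergence must be in [0, 0.2], got {divergence}")
    arr = np.frombuffer(parent.encode(), dtype=np.uint8).copy()
    sites = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in sites:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode(), len(sites)


def simulate_genome(
    rng: np.random.Generator,
    length: int,
    uvig_id: str = "uvig",
    sample_id: str = "sample",
    lifestyle: Lifestyle = Lifestyle.unknown,
    completeness_range: tuple[float, float] = (90.0, 100.0),
) -> tuple[UViGRecord, list[GeneRecord]]:
    """Draw one genome with non-overlapping genes tiling >= 70% of it and
    annotation fields that pass the viral screen."""
    if length < 1000:
        raise ValueError(f"genome length {length} too short to tile genes (need >= 1000)")
    sequence = random_sequence(rng, length)
    genes: list[GeneRecord] = []
    pos = int(rng.integers(0, 60))
    i = 0
    while pos + 300 <= length:
        gene_len = int(rng.integers(300, min(1501, length - pos + 1)))
        genes.append(
            GeneRecord(
                gene_id=f"{uvig_id}:g{i}",
                uvig_id=uvig_id,
                start=pos,
                end=pos + gene_len,
                length_bp=gene_len,
            )
        )
        pos += gene_len + int(rng.integers(10, 80))
        i += 1
    n_genes = len(genes)
    viral_genes = int(rng.integers(max(1, n_genes // 2), n_genes + 1))
    host_cap = min(4, int(0.386 * viral_genes))
    host_genes = int(rng.integers(0, host_cap + 1))
    record = UViGRecord(
        uvig_id=uvig_id,
        sample_id=sample_id,
        sequence=sequence,
        length_bp=length,
        viral_genes=viral_genes,
        host_genes=host_genes,
        hallmark_genes=int(rng.integers(0, 4)),
        screen_score=float(rng.uniform(0.5, 1.0)),
        completeness_pct=float(rng.uniform(*completeness_range)),
        lifestyle=lifestyle,
    )
    return record, genes


# ---------------------------------------------------------------------------
# cohort plan (abundance level)

@dataclass
class _Lineage:
    lineage_id: str
    kind: str                  # donor | own | novel | background
    lifestyle: Lifestyle
    length: int
    completeness_range: tuple[float, float]


@dataclass
class _Entry:
    lineage_id: str
    relation: str              # founder | clone | distractor
    divergence: float
    weight: float
    copy_key: str              # realization cache key (per subject)


@dataclass
class CohortPlan:
    """Lineage presence and abundance weights per sample, before any
    sequence realization. Sufficient for abundance-level statistics."""

    config: SimConfig
    metadata: list[SampleRecord]
    lineages: dict[str, _Lineage]
    entries: dict[str, list[_Entry]]       # sample_id -> entries
    truth: SimTruth


def _shannon(weights: np.ndarray) -> float:
    p = weights / weights.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def build_plan(config: SimConfig) -> CohortPlan:
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    lineages: dict[str, _Lineage] = {}
    entries: dict[str, list[_Entry]] = {}
    metadata: list[SampleRecord] = []

    def new_lineage(kind: str, prefix: str, length: int,
                    completeness: tuple[float, float]) -> _Lineage:
        lid = f"{prefix}{len(lineages):05d}"
        u = rng.random()
        if kind == "background" or u < config.unknown_lifestyle_fraction:
            style = Lifestyle.unknown
        elif u < config.unknown_lifestyle_fraction + config.temperate_fraction:
            style = Lifestyle.temperate
        else:
            style = Lifestyle.virulent
        lin = _Lineage(lid, kind, style, length, completeness)
        lineages[lid] = lin
        truth.lifestyle_of_lineage[lid] = style
        truth.kind_of_lineage[lid] = kind
        return lin

    def weight() -> float:
        return float(rng.lognormal(0.0, config.abund_sigma))

    glen = lambda: int(rng.integers(config.genome_length_range[0],
                                    config.genome_length_range[1] + 1))

    # --- donors -----------------------------------------------------------
    donors_by_sex: dict[Sex, list[str]] = {Sex.female: [], Sex.male: []}
    donor_pool: dict[str, list[str]] = {}
    for sex, tag in ((Sex.female, "DF"), (Sex.male, "DM")):
        for d in range(config.n_donors_per_sex):
            subj = f"{tag}{d + 1:02d}"
            donors_by_sex[sex].append(subj)
            richness = int(rng.integers(config.donor_richness_range[0],
                                        config.donor_richness_range[1] + 1))
            pool = [new_lineage("donor", "L", glen(), (90.0, 100.0)).lineage_id
                    for _ in range(richness)]
            donor_pool[subj] = pool
            truth.donor_lineages[subj] = set(pool)
    # seed shared lineages into a second same-sex donor
    for sex in (Sex.female, Sex.male):
        ds = donors_by_sex[sex]
        if len(ds) < 2:
            continue
        for s in range(config.n_shared_lineages_per_sex):
            src, dst = ds[s % len(ds)], ds[(s + 1) % len(ds)]
            shared = donor_pool[src][int(rng.integers(0, len(donor_pool[src])))]
            if shared not in donor_pool[dst]:
                donor_pool[dst].append(shared)
                truth.donor_lineages[dst].add(shared)

    for sex in (Sex.female, Sex.male):
        for subj in donors_by_sex[sex]:
            sample_id = f"{subj}_don1"
            metadata.append(SampleRecord(sample_id, subj, Role.donor,
                                         Treatment.none, sex, Timepoint.donation, 1))
            sample_entries = [
                _Entry(lid, "founder" if subj == _owner(lid, donor_pool, donors_by_sex) else "clone",
                       0.0 if subj == _owner(lid, donor_pool, donors_by_sex) else config.clone_divergence,
                       weight(), f"{subj}|{lid}")
                for lid in donor_pool[subj]
            ]
            for k in range(config.background_per_subject):
                lin = new_lineage("background", "B", config.background_genome_length, (20.0, 80.0))
                sample_entries.append(_Entry(lin.lineage_id, "founder", 0.0,
                                             weight() * config.background_weight_mult,
                                             f"{subj}|{lin.lineage_id}"))
            entries[sample_id] = sample_entries
            analyzed_w = np.array([e.weight for e in sample_entries
                                   if lineages[e.lineage_id].kind == "donor"])
            truth.donor_shannon[subj] = _shannon(analyzed_w)

    # --- recipients -------------------------------------------------------
    def transfer_prob(donor: str) -> float:
        h = truth.donor_shannon[donor]
        logit = config.engraft_prob_intercept + config.engraft_prob_slope * (
            h - config.diversity_center
        )
        return 1.0 / (1.0 + math.exp(-logit))

    arms = [(Treatment.FMT, "R", config.n_fmt), (Treatment.placebo, "P", config.n_placebo)]
    for sex, stag in ((Sex.female, "F"), (Sex.male, "M")):
        sex_pool = sorted({lid for d in donors_by_sex[sex] for lid in donor_pool[d]})
        for treatment, ttag, n in arms:
            for r in range(n):
                subj = f"{ttag}{stag}{r + 1:02d}"
                # persistent community: own lineages + donor-relative distractors
                own = [new_lineage("own", "L", glen(), (90.0, 100.0)).lineage_id
                       for _ in range(config.recipient_richness - config.n_distractors)]
                n_dist = min(config.n_distractors, len(sex_pool))
                dist = [sex_pool[i] for i in
                        rng.choice(len(sex_pool), size=n_dist, replace=False)]
                subj_bg = [new_lineage("background", "B",
                                       config.background_genome_length, (20.0, 80.0)).lineage_id
                           for _ in range(config.background_per_subject)]
                # transfers (FMT only), decided per sex-matched donor phage
                transferred: list[str] = []
                if treatment is Treatment.FMT:
                    got: set[str] = set()
                    for donor in donors_by_sex[sex]:
                        q = transfer_prob(donor)
                        for lid in donor_pool[donor]:
                            if rng.random() < q:
                                truth.transfers.append(
                                    Transfer(donor, lid, subj, Timepoint.wk6))
                                if lid not in got:
                                    got.add(lid)
                                    transferred.append(lid)
                novel_rate = (config.novel_rate_fmt if treatment is Treatment.FMT
                              else config.novel_rate_placebo)
                for tp in (Timepoint.baseline,) + POST_TIMEPOINTS:
                    sample_id = f"{subj}_{tp.value}"
                    metadata.append(SampleRecord(sample_id, subj, Role.recipient,
                                                 treatment, sex, tp, None))
                    se: list[_Entry] = []
                    post = tp is not Timepoint.baseline
                    # temperate induction post-FMT: applied to every
                    # temperate lineage in FMT recipients after baseline
                    def lineage_weight(lid: str) -> float:
                        w = weight()
                        if (post and treatment is Treatment.FMT
                                and truth.lifestyle_of_lineage[lid] is Lifestyle.temperate):
                            w *= config.temperate_postfmt_fold
                        return w

                    for lid in own:
                        if post and rng.random() >= config.conserved_persistence:
                            continue
                        se.append(_Entry(lid, "founder", 0.0, lineage_weight(lid),
                                         f"{subj}|{lid}"))
                    for lid in dist:
                        if post and rng.random() >= config.conserved_persistence:
                            continue
                        se.append(_Entry(lid, "distractor", config.distractor_divergence,
                                         lineage_weight(lid), f"{subj}|dist|{lid}"))
                    if post:
                        keep = (tp is Timepoint.wk6)
                        for lid in transferred:
                            if keep or rng.random() < config.engraft_persistence:
                                se.append(_Entry(lid, "clone", config.clone_divergence,
                                                 lineage_weight(lid), f"{subj}|tx|{lid}"))
                        for _ in range(rng.poisson(novel_rate)):
                            lin = new_lineage("novel", "L", glen(), (90.0, 100.0))
                            se.append(_Entry(lin.lineage_id, "founder", 0.0,
                                             lineage_weight(lin.lineage_id),
                                             f"{subj}|{lin.lineage_id}"))
                    for lid in subj_bg:
                        se.append(_Entry(lid, "founder", 0.0,
                                         weight() * config.background_weight_mult,
                                         f"{subj}|{lid}"))
                    entries[sample_id] = se

    # --- truth abundance table (CPM scale over all lineages) -------------
    sample_ids = [m.sample_id for m in metadata]
    abund = pd.DataFrame(0.0, index=sorted(lineages), columns=sample_ids)
    for sid in sample_ids:
        for e in entries[sid]:
            abund.loc[e.lineage_id, sid] += e.weight
    colsum = abund.sum(axis=0)
    abund = abund.div(colsum.where(colsum > 0, 1.0), axis=1) * 1e6
    truth.abundance = abund

    return CohortPlan(config, metadata, lineages, entries, truth)


def _owner(lid: str, donor_pool: dict[str, list[str]], donors_by_sex) -> str:
    # first donor (in construction order) carrying the lineage
    for sex in (Sex.female, Sex.male):
        for d in donors_by_sex[sex]:
            if lid in donor_pool[d]:
                return d
    raise KeyError(lid)


# ---------------------------------------------------------------------------
# sequence realization

def realize_cohort(plan: CohortPlan) -> Cohort:
    """Realize the plan into genomes, per-sample UViGs, genes and truth
    clone pairs. Deterministic given the plan's config seed."""
    config = plan.config
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    truth = plan.truth
    founders: dict[str, tuple[UViGRecord, list[GeneRecord]]] = {}
    for lid, lin in plan.lineages.items():
        founders[lid] = simulate_genome(
            rng, lin.length, uvig_id=f"ref|{lid}", sample_id="",
            lifestyle=lin.lifestyle, completeness_range=lin.completeness_range,
        )

    copy_seq: dict[str, tuple[str, float]] = {}   # copy_key -> (sequence, realized divergence)
    sequences: list[tuple[str, str]] = []
    uvigs: list[UViGRecord] = []
    genes: list[GeneRecord] = []
    first_uvig_of_copy: dict[str, str] = {}
    founder_uvig_of_lineage: dict[str, str] = {}

    for sample in plan.metadata:
        sid = sample.sample_id
        for i, e in enumerate(plan.entries[sid]):
            ref, _ = founders[e.lineage_id]
            if e.copy_key in copy_seq:
                seq, realized = copy_seq[e.copy_key]
            elif e.relation == "founder":
                seq, realized = ref.sequence, 0.0
                copy_seq[e.copy_key] = (seq, realized)
            else:
                mutated, n_subs = mutate_clone(rng, ref.sequence, e.divergence)
                seq, realized = mutated, n_subs / len(ref.sequence)
                copy_seq[e.copy_key] = (seq, realized)
            uvig_id = f"{sid}|c{i:03d}"
            # annotation fields drawn per observation (assemblies differ)
            lin = plan.lineages[e.lineage_id]
            obs, obs_genes = simulate_genome(
                rng, len(seq), uvig_id=uvig_id, sample_id=sid,
                lifestyle=lin.lifestyle, completeness_range=lin.completeness_range,
            )
            obs = replace(obs, sequence=seq)
            sequences.append((uvig_id, seq))
            uvigs.append(obs)
            genes.extend(obs_genes)
            truth.lineage_of_uvig[uvig_id] = e.lineage_id
            if e.relation == "founder" and e.lineage_id not in founder_uvig_of_lineage:
                founder_uvig_of_lineage[e.lineage_id] = uvig_id
            if e.relation != "founder" and e.copy_key not in first_uvig_of_copy:
                anchor = founder_uvig_of_lineage.get(e.lineage_id)
                if anchor is not None:
                    truth.clone_pairs.append((anchor, uvig_id, realized))
            first_uvig_of_copy.setdefault(e.copy_key, uvig_id)

    # junk (non-viral / false-positive) contigs to exercise the screen
    junk_samples = [m.sample_id for m in plan.metadata]
    for j in range(config.n_junk_contigs):
        sid = junk_samples[j % len(junk_samples)]
        length = int(rng.integers(2000, 4001))
        seq = random_sequence(rng, length)
        uvig_id = f"{sid}|junk{j:03d}"
        if j % 2 == 0:   # fails every inclusion clause
            fields = dict(viral_genes=0, host_genes=int(rng.integers(1, 9)),
                          hallmark_genes=int(rng.integers(0, 3)),
                          screen_score=float(rng.uniform(0.0, 0.94)))
        else:            # included but a clear false positive
            fields = dict(viral_genes=1, host_genes=int(rng.integers(5, 12)),
                          hallmark_genes=0, screen_score=float(rng.uniform(0.0, 0.94)))
        uvigs.append(UViGRecord(uvig_id=uvig_id, sample_id=sid, sequence=seq,
                                length_bp=length, completeness_pct=float(rng.uniform(0, 50)),
                                lifestyle=Lifestyle.unknown, **fields))
        sequences.append((uvig_id, seq))

    return Cohort(sequences, uvigs, genes, plan.metadata, truth, config)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Full generator: plan the community, then realize sequences."""
    return realize_cohort(build_plan(config))


# ---------------------------------------------------------------------------
# gene-level counts

def simulate_gene_counts(
    rng: np.random.Generator,
    truth: SimTruth,
    metadata: list[SampleRecord],
    genes: list[GeneRecord],
    config: SimConfig,
) -> pd.DataFrame:
    """Overdispersed gene-level read counts (gene x sample).

    A gene's expected count in its own sample is proportional to its
    lineage's relative abundance there, its length, and the sample depth
    (reads spread uniformly along the genome); noise is negative binomial
    with dispersion alpha (var = mu + alpha mu^2). Genes of lineages
    absent from a sample get count 0, and genes only receive reads in the
    sample their UViG was assembled from (cross-sample signal arises
    downstream through the gene catalog).
    """
    if truth.abundance is None:
        raise ValueError("truth has no abundance table")
    sample_ids = [m.sample_id for m in metadata]
    gene_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "uvig_id": [g.uvig_id for g in genes],
            "length_bp": [g.length_bp for g in genes],
        }
    )
    gene_df["sample_id"] = [g.uvig_id.split("|")[0] for g in genes]
    gene_df["lineage"] = gene_df["uvig_id"].map(truth.lineage_of_uvig)
    gene_df = gene_df[gene_df["sample_id"].isin(sample_ids)]
    uvig_len = gene_df.groupby("uvig_id")["length_bp"].transform("sum")
    rel = np.array(
        [
            truth.abundance.at[lineage, sid] / 1e6 if lineage in truth.abundance.index else 0.0
            for lineage, sid in zip(gene_df["lineage"], gene_df["sample_id"])
        ]
    )
    mu = config.mean_depth * rel * gene_df["length_bp"].to_numpy() / uvig_len.to_numpy()
    counts = _nbinom(rng, mu, config.count_dispersion)
    mat = pd.DataFrame(0.0, index=gene_df["gene_id"], columns=sample_ids)
    col_idx = pd.Index(sample_ids).get_indexer(gene_df["sample_id"])
    vals = mat.to_numpy()
    vals[np.arange(len(gene_df)), col_idx] = counts
    out = pd.DataFrame(vals, index=gene_df["gene_id"], columns=sample_ids)
    out.index.name = "gene_id"
    out.columns.name = "sample_id"
    return out


def _nbinom(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2); Poisson when alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu).astype(float)
    n = 1.0 / alpha
    p = n / (n + np.where(mu > 0, mu, 1.0))
    draws = rng.negative_binomial(n, p).astype(float)
    draws[mu <= 0] = 0.0
    return draws


# ---------------------------------------------------------------------------
# on-disk emission

def write_cohort(cohort: Cohort, outdir: str | Path,
                 counts: pd.DataFrame | None = None) -> None:
    """Emit genomes.fasta, annotations.tsv, metadata.tsv, genes.tsv,
    gene_counts.tsv (optional) and truth/*.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_fasta(cohort.sequences, outdir / "genomes.fasta")
    pio.write_annotations(cohort.uvigs, outdir / "annotations.tsv")
    pio.write_metadata(cohort.metadata, outdir / "metadata.tsv")
    pio.write_genes(cohort.genes, outdir / "genes.tsv")
    if counts is not None:
        pio.write_gene_counts(counts, outdir / "gene_counts.tsv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = cohort.truth
    pio.write_tsv(
        pd.DataFrame(t.clone_pairs, columns=["uvig_a", "uvig_b", "true_divergence"]),
        truth_dir / "clone_pairs.tsv",
    )
    pio.write_tsv(
        pd.DataFrame(
            [(x.donor_id, x.lineage_id, x.recipient_id, x.transfer_time.value) for x in t.transfers],
            columns=["donor_id", "lineage_id", "recipient_id", "transfer_time"],
        ),
        truth_dir / "transfers.tsv",
    )
    pio.write_tsv(
        pd.DataFrame(
            [
                (u, lid, t.lifestyle_of_lineage[lid].value, t.kind_of_lineage[lid])
                for u, lid in t.lineage_of_uvig.items()
            ],
            columns=["uvig_id", "lineage_id", "lifestyle", "kind"],
        ),
        truth_dir / "lineages.tsv",
    )
    if t.abundance is not None:
        pio.write_matrix(t.abundance, truth_dir / "abundance.tsv")
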