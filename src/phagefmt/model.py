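"""Shared domain types for the phageome pipeline.

The pipeline's unit of sequence is the UViG (uncultivated virus genome): a
putative viral contig assembled from a single stool metagenome. UViGs are
clustered into vOTUs (viral operational taxonomic units, a species-rank
proxy) at ANI >= 95% over >= 85% alignment fraction of the shorter sequence,
and pairs within a vOTU at ANI >= 99.4% are treated as clones of the same
phage lineage for donor-to-recipient tracking.

Coordinates are 0-based, half-open everywhere inside the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Role(str, enum.Enum):
    donor = "donor"
    recipient = "recipient"


class Treatment(str, enum.Enum):
    FMT = "FMT"
    placebo = "placebo"
    none = "none"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Timepoint(str, enum.Enum):
    """Sampling timepoints; recipient timepoints are totally ordered."""

    baseline = "baseline"
    wk6 = "wk6"
    wk12 = "wk12"
    wk26 = "wk26"
    donation = "donation"

    @property
    def order(self) -> int:
        return _TIMEPOINT_ORDER[self]


_TIMEPOINT_ORDER = {
    Timepoint.baseline: 0,
    Timepoint.wk6: 1,
    Timepoint.wk12: 2,
    Timepoint.wk26: 3,
    Timepoint.donation: -1,
}

#: Recipient timepoints in temporal order.
RECIPIENT_TIMEPOINTS = (Timepoint.baseline, Timepoint.wk6, Timepoint.wk12, Timepoint.wk26)
#: Timepoints at which an engraftment event may first be detected.
POST_TIMEPOINTS = (Timepoint.wk6, Timepoint.wk12, Timepoint.wk26)


class Lifestyle(str, enum.Enum):
    temperate = "temperate"
    virulent = "virulent"
    unknown = "unknown"


class ValidationError(ValueError):
    """Raised when an input row violates a domain-type invariant."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    subject_id: str
    role: Role
    treatment: Treatment
    sex: Sex
    timepoint: Timepoint
    donation_round: int | None = None

    def __post_init__(self) -> None:
        if self.role is Role.donor:
            if self.treatment is not Treatment.none:
                raise ValidationError(
                    f"donor sample {self.sample_id}: treatment must be 'none', got {self.treatment.value}"
                )
            if self.timepoint is not Timepoint.donation:
                raise ValidationError(
                    f"donor sample {self.sample_id}: timepoint must be 'donation', got {self.timepoint.value}"
                )
        else:
            if self.timepoint is Timepoint.donation:
                raise ValidationError(
                    f"recipient sample {self.sample_id}: timepoint 'donation' is donor-only"
                )
            if self.treatment is Treatment.none:
                raise ValidationError(
                    f"recipient sample {self.sample_id}: treatment must be FMT or placebo"
                )


@dataclass(frozen=True)
class UViGRecord:
    """One uncultivated virus genome with the annotation fields the
    screening rules consume.

    ``screen_score`` holds the viral-classifier score in [0, 1];
    ``completeness_pct`` the estimated genome completeness in [0, 100].
    """

    uvig_id: str
    sample_id: str
    sequence: str
    length_bp: int
    viral_genes: int
    host_genes: int
    hallmark_genes: int
    screen_score: float
    completeness_pct: float
    lifestyle: Lifestyle = Lifestyle.unknown
    predicted_host: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp != len(self.sequence):
            raise ValidationError(
                f"{self.uvig_id}: length_bp {self.length_bp} != sequence length {len(self.sequence)}"
            )
        for name in ("viral_genes", "host_genes", "hallmark_genes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.uvig_id}: {name} must be >= 0")
        if not 0.0 <= self.screen_score <= 1.0:
            raise ValidationError(f"{self.uvig_id}: screen_score must be in [0,1]")
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValidationError(
                f"{self.uvig_id}: completeness_pct {self.completeness_pct} outside [0,100]"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A predicted ORF on a UViG, 0-based half-open coordinates."""

    gene_id: str
    uvig_id: str
    start: int
    end: int
    length_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"{self.gene_id}: need 0 <= start < end")
        if self.length_bp != self.end - self.start:
            raise ValidationError(
                f"{self.gene_id}: length_bp {self.length_bp} != end - start"
            )


@dataclass(frozen=True)
class PairwiseSimilarity:
    """Fragment-ANI estimate for an unordered UViG pair.

    ``af_smaller`` is the alignment fraction relative to the shorter
    sequence (mapped full fragments / tiled full fragments).
    """

    uvig_a: str
    uvig_b: str
    ani_pct: float
    af_smaller: float


@dataclass
class VOTUCluster:
    votu_id: str
    representative: str
    members: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ClonePair:
    """Two same-vOTU UViGs at ANI >= 99.4% / AF >= 0.85 — one phage lineage."""

    uvig_a: str
    uvig_b: str
    ani_pct: float
    af_smaller: float


@dataclass
class ScreenDecision:
    uvig_id: str
    included: bool
    false_positive: bool
    high_quality: bool
    hvr: float
    reasons: list[str] = field(default_factory=list)


@dataclass
class EngraftmentEvent:
    """A donor phage clone detected in a recipient post-treatment only.

    One event per (vOTU, recipient); ``first_detection`` is the earliest
    post-treatment timepoint with clone-level evidence, and ``donors`` the
    set of sex-matched donors carrying a clone of the vOTU ("multiple" tag
    when attribution is ambiguous).
    """

    votu_id: str
    recipient_subject: str
    donors: set[str]
    first_detection: Timepoint
    evidence: list[tuple[str, str]] = field(default_factory=list)

    @property
    def multiple_donors(self) -> bool:
        return len(self.donors) > 1


@dataclass
class DonorEfficacy:
    donor_id: str
    n_votus_donor: int
    n_engrafted: int

    @property
    def efficacy(self) -> float | None:
        if self.n_votus_donor == 0:
            return None
        return self.n_engrafted / self.n_votus_donor
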