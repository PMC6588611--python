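"""Shared domain model: enums and record types used across the pipeline.

All coordinates follow VCF convention (1-based, inclusive).  Allele
fractions are stored as fractions in [0, 1]; percentages are produced
only at report time.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Consequence(str, enum.Enum):
    FRAMESHIFT = "FRAMESHIFT"
    NONSENSE = "NONSENSE"
    MISSENSE = "MISSENSE"
    SPLICE_SITE = "SPLICE_SITE"
    START_LOSS = "START_LOSS"
    SYNONYMOUS = "SYNONYMOUS"
    INTRONIC = "INTRONIC"
    OTHER_NONCODING = "OTHER_NONCODING"


#: Consequence classes treated as loss-of-function for classification.
LOF_CONSEQUENCES = frozenset(
    {Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.START_LOSS}
)


class Pathway(str, enum.Enum):
    HR = "HR"
    FANCONI = "FANCONI"
    CHECKPOINT = "CHECKPOINT"
    NER = "NER"
    MMR = "MMR"
    OTHER = "OTHER"


#: Pathways counted toward the homologous-recombination super-group.
#: Fanconi anemia genes are a labeled sub-group of HR in all
#: HR-fraction summaries.
HR_SUPERGROUP = frozenset({Pathway.HR, Pathway.FANCONI})


class Inheritance(str, enum.Enum):
    DOMINANT = "DOMINANT"
    RECESSIVE = "RECESSIVE"


class ActionableClass(str, enum.Enum):
    PARPI = "PARPI"
    IMMUNOTHERAPY = "IMMUNOTHERAPY"
    NONE = "NONE"


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM = "HOM"


class Phase(str, enum.Enum):
    """Phase of a somatic variant relative to the germline allele."""

    CIS = "CIS"
    TRANS = "TRANS"
    UNKNOWN = "UNKNOWN"


class PairPhase(str, enum.Enum):
    """Pairwise phase between two somatic variants."""

    SAME_ALLELE = "SAME_ALLELE"
    OPPOSITE_ALLELES = "OPPOSITE_ALLELES"
    UNKNOWN = "UNKNOWN"


class ACMGClass(enum.IntEnum):
    """Five-tier pathogenicity scale."""

    BENIGN = 1
    LIKELY_BENIGN = 2
    VUS = 3
    LIKELY_PATHOGENIC = 4
    PATHOGENIC = 5


#: Classes considered reportable downstream.
REPORTABLE_CLASSES = frozenset({ACMGClass.LIKELY_PATHOGENIC, ACMGClass.PATHOGENIC})


class HitCategory(str, enum.Enum):
    LOH = "LOH"
    SOMATIC_SECOND_HIT = "SOMATIC_SECOND_HIT"
    REVERSION = "REVERSION"
    BIALLELIC_SOMATIC = "BIALLELIC_SOMATIC"
    NONE = "NONE"


class HRDStatus(str, enum.Enum):
    DEFICIENT = "DEFICIENT"
    NORMAL = "NORMAL"


class ParpiStatus(str, enum.Enum):
    SENSITIVE = "SENSITIVE"
    INSENSITIVE = "INSENSITIVE"


class Association(str, enum.Enum):
    ESTABLISHED = "ESTABLISHED"
    EMERGING = "EMERGING"
    NONE = "NONE"


class ClinicalGroup(str, enum.Enum):
    GROUP1 = "GROUP1"
    GROUP2 = "GROUP2"
    GROUP3 = "GROUP3"


@dataclass(frozen=True)
class GeneRecord:
    """One gene-panel entry."""

    symbol: str
    pathway: Pathway
    inheritance: Inheritance = Inheritance.DOMINANT
    acmg_return: bool = False
    actionable_class: ActionableClass = ActionableClass.NONE


@dataclass
class GenePanel:
    """A validated collection of :class:`GeneRecord`, keyed by symbol."""

    genes: dict[str, GeneRecord]

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self.genes[symbol]

    def __iter__(self):
        return iter(self.genes.values())


@dataclass
class VariantCall:
    """One germline variant call for one patient.

    ``pop_af`` is the maximum allele frequency across the population
    databases consulted by the caller; pre-aggregation across databases
    is the caller's responsibility.  A missing value is treated as 0
    (absent from all databases).
    """

    patient_id: str
    gene: str
    chrom: str = "."
    pos: int = 0
    ref: str = "."
    alt: str = "."
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.OTHER_NONCODING
    splice_offset: int = 0
    call_quality: Optional[float] = None
    depth: Optional[int] = None
    vaf: Optional[float] = None
    pop_af: float = 0.0
    known_pathogenic_common: bool = False
    indel_net_length: int = 0
    zygosity: Zygosity = Zygosity.HET
    previously_identified: Optional[bool] = None

    def key(self) -> tuple:
        return (self.patient_id, self.gene, self.chrom, self.pos,
                self.ref, self.alt, self.hgvs_c)


@dataclass
class ClassifiedVariant:
    """A variant call plus its 5-class verdict and the evidence trail."""

    variant: VariantCall
    acmg_class: ACMGClass
    evidence_tags: frozenset[str] = frozenset()
    curated_assertion: Optional[ACMGClass] = None

    @property
    def reportable(self) -> bool:
        return self.acmg_class in REPORTABLE_CLASSES


@dataclass
class PatientRecord:
    patient_id: str
    cancer_type: str
    family_history: bool = False


@dataclass
class PatientGenotype:
    """All classified variants of one patient.

    ``gene_phase`` gives, where known, the relative phase of the variant
    pair within a gene (meaningful for genes carrying two variants).
    """

    patient_id: str
    variants: list[ClassifiedVariant] = field(default_factory=list)
    gene_phase: dict[str, Phase] = field(default_factory=dict)

    def by_gene(self) -> dict[str, list[ClassifiedVariant]]:
        out: dict[str, list[ClassifiedVariant]] = {}
        for cv in self.variants:
            out.setdefault(cv.variant.gene, []).append(cv)
        return out


@dataclass
class SomaticVariant:
    """A somatic variant observed in the tumor of a germline carrier."""

    gene: str
    hgvs_c: str = ""
    consequence: Consequence = Consequence.OTHER_NONCODING
    splice_offset: int = 0
    indel_net_length: int = 0
    phase_vs_germline: Phase = Phase.UNKNOWN
    pair_phase: PairPhase = PairPhase.UNKNOWN
    curated_pathogenic: bool = False


@dataclass
class TumorObservation:
    """Tumor-side view of one germline variant."""

    patient_id: str
    gene: str
    hgvs_c: str = ""
    tumor_vaf: Optional[float] = None
    tumor_depth: Optional[int] = None
    somatic_hits: list[SomaticVariant] = field(default_factory=list)


@dataclass
class SecondHitResult:
    """Outcome of second-hit analysis for one germline variant."""

    patient_id: str
    gene: str
    hgvs_c: str
    category: HitCategory
    loh: Optional[bool] = None
    biallelic_somatic: bool = False
    evidence: dict = field(default_factory=dict)


@dataclass
class HRDCall:
    """Per-sample expression-signature call."""

    sample_id: str
    hrd_status: HRDStatus
    parpi_status: ParpiStatus
    hrd_confidence: float = 1.0
    parpi_confidence: float = 1.0
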