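"""Clinical-significance grouping, treatment suggestion, return-of-results
recommendation, and cohort summary tabulation.

Group 1: the gene is established for the patient's cancer type
(reduced-penetrance alleles included).  Group 2: emerging association,
or tumor evidence (LOH / somatic second hit) without an established
association, or the gene's pathway is flagged over-represented for that
cancer type.  Group 3: everything else.

Treatment suggestions follow a fixed rule table: PARPi for class-4/5
BRCA1/BRCA2 carriers, immunotherapy for class-4/5 carriers in the four
mismatch-repair genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_core import pct, round_half_away
from .models import (
    ACMGClass,
    ActionableClass,
    Association,
    ClassifiedVariant,
    ClinicalGroup,
    Consequence,
    GenePanel,
    HitCategory,
    PatientGenotype,
    PatientRecord,
    Pathway,
    SecondHitResult,
)

PARPI_GENES = frozenset({"BRCA1", "BRCA2"})
MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})


@dataclass
class GenotypePhenotypeTable:
    """Gene-to-cancer-type association knowledge plus penetrance flags.

    ``associations`` maps (gene, cancer_type) to an association level;
    missing rows mean NONE.  ``moderate_risk_alleles`` holds (gene,
    hgvs_p) pairs whose reduced risk blocks return of results.
    ``overrepresented`` flags (pathway, cancer_type) pairs configured as
    over-represented in the cohort (a judgment call, not auto-detected).
    """

    associations: dict[tuple[str, str], Association] = field(default_factory=dict)
    moderate_risk_alleles: set[tuple[str, str]] = field(default_factory=set)
    overrepresented: set[tuple[Pathway, str]] = field(default_factory=set)

    def association(self, gene: str, cancer_type: str) -> Association:
        return self.associations.get((gene, cancer_type), Association.NONE)


def default_gpt() -> GenotypePhenotypeTable:
    """A small default association table covering well-established pairs;
    user configuration is expected for anything beyond these examples."""
    est = {}
    for gene in ("BRCA1", "BRCA2"):
        for ctype in ("Breast cancer", "Ovarian cancer",
                      "Pancreatic cancer", "Prostate cancer"):
            est[(gene, ctype)] = Association.ESTABLISHED
    for gene in MMR_GENES:
        for ctype in ("Colorectal cancer", "Endometrial cancer"):
            est[(gene, ctype)] = Association.ESTABLISHED
    for ctype in ("Melanoma", "Malignant Mesothelioma"):
        est[("BAP1", ctype)] = Association.ESTABLISHED
    est[("CHEK2", "Breast cancer")] = Association.ESTABLISHED
    est[("APC", "Colorectal cancer")] = Association.ESTABLISHED
    emerging = {
        ("FANCM", "Breast cancer"), ("WRN", "Pancreatic cancer"),
        ("NBN", "NSCLC"), ("BLM", "Colorectal cancer"),
        ("ATM", "Colorectal cancer"), ("FANCM", "Colorectal cancer"),
    }
    for key in emerging:
        est[key] = Association.EMERGING
    return GenotypePhenotypeTable(
        associations=est,
        moderate_risk_alleles={("BRCA1", "p.Arg1699Gln")},
        overrepresented={(Pathway.FANCONI, "Malignant Mesothelioma")},
    )


@dataclass
class ClinicalAssessment:
    variant: ClassifiedVariant
    group: ClinicalGroup
    treatment_suggestion: ActionableClass
    return_recommended: bool
    rationale: frozenset[str] = frozenset()


def assign_clinical_group(
    v: ClassifiedVariant,
    cancer_type: str,
    tumor_evidence: Optional[SecondHitResult],
    gpt: GenotypePhenotypeTable,
    panel: GenePanel | None = None,
) -> ClinicalGroup:
    """Assign a reportable variant to clinical-significance group 1-3."""
    gene = v.variant.gene
    assoc = gpt.association(gene, cancer_type)
    if assoc is Association.ESTABLISHED:
        return ClinicalGroup.GROUP1
    if assoc is Association.EMERGING:
        return ClinicalGroup.GROUP2
    if tumor_evidence is not None and tumor_evidence.category in (
            HitCategory.LOH, HitCategory.SOMATIC_SECOND_HIT):
        return ClinicalGroup.GROUP2
    if panel is not None and gene in panel:
        if (panel[gene].pathway, cancer_type) in gpt.overrepresented:
            return ClinicalGroup.GROUP2
    return ClinicalGroup.GROUP3


def suggest_treatment(
    variants: Iterable[ClassifiedVariant],
    panel: GenePanel | None = None,
) -> set[ActionableClass]:
    """Treatment suggestions for one patient, de-duplicated.

    PARPi only for BRCA1/BRCA2 class-4/5 carriers; immunotherapy only
    for MLH1/MSH2/MSH6/PMS2 class-4/5 carriers.
    """
    out: set[ActionableClass] = set()
    for cv in variants:
        if not cv.reportable:
            continue
        gene = cv.variant.gene
        if gene in PARPI_GENES:
            out.add(ActionableClass.PARPI)
        elif gene in MMR_GENES:
            out.add(ActionableClass.IMMUNOTHERAPY)
    return out


def recommend_return(
    v: ClassifiedVariant,
    panel: GenePanel,
    gpt: GenotypePhenotypeTable,
    family_history: bool,
    group: Optional[ClinicalGroup] = None,
) -> tuple[bool, frozenset[str]]:
    """Return-of-results recommendation with rationale tags.

    Moderate-risk alleles are never returned, even in genes on the
    return list.  Otherwise genes flagged for return qualify, and
    group-1/2 variants qualify when family history is present.
    """
    gene = v.variant.gene
    if (gene, v.variant.hgvs_p) in gpt.moderate_risk_alleles:
        return False, frozenset({"moderate_risk_allele"})
    if gene in panel and panel[gene].acmg_return:
        return True, frozenset({"return_list_gene"})
    if family_history and group in (ClinicalGroup.GROUP1, ClinicalGroup.GROUP2):
        return True, frozenset({"family_history_group12"})
    return False, frozenset({"no_rule_fired"})


def assess(
    genotypes: Sequence[PatientGenotype],
    patients: Sequence[PatientRecord],
    second_hits: Sequence[SecondHitResult],
    panel: GenePanel,
    gpt: GenotypePhenotypeTable | None = None,
) -> list[tuple[str, ClinicalAssessment]]:
    """Full clinical assessment of every reportable variant."""
    gpt = gpt or default_gpt()
    by_patient = {p.patient_id: p for p in patients}
    hits = {(r.patient_id, r.gene, r.hgvs_c): r for r in second_hits}
    out: list[tuple[str, ClinicalAssessment]] = []
    for gt in genotypes:
        patient = by_patient.get(gt.patient_id)
        if patient is None:
            continue
        suggestions = suggest_treatment(gt.variants, panel)
        for cv in gt.variants:
            if not cv.reportable:
                continue
            ev = hits.get((gt.patient_id, cv.variant.gene, cv.variant.hgvs_c))
            group = assign_clinical_group(
                cv, patient.cancer_type, ev, gpt, panel)
            gene = cv.variant.gene
            if gene in PARPI_GENES:
                suggestion = ActionableClass.PARPI
            elif gene in MMR_GENES:
                suggestion = ActionableClass.IMMUNOTHERAPY
            else:
                suggestion = ActionableClass.NONE
            returned, rationale = recommend_return(
                cv, panel, gpt, patient.family_history, group)
            out.append((gt.patient_id, ClinicalAssessment(
                variant=cv, group=group,
                treatment_suggestion=suggestion,
                return_recommended=returned, rationale=rationale)))
    return out


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Deterministic cohort tabulation.

    ``per_type`` maps cancer type -> (patients, carriers).  Counts are
    stored raw; every percentage is derived at report time with the
    round-half-away convention.
    """

    n_patients: int
    n_carriers: int
    per_type: dict[str, tuple[int, int]]
    per_gene: dict[str, int]
    per_consequence: dict[Consequence, int]
    per_pathway: dict[Pathway, int]
    multi_variant_counts: dict[int, int]
    excluded_recessive_het: int
    panel_size: int
    n_brca_variants: int = 0
    n_brca_not_previously_identified: int = 0
    n_actionable_patients: int = 0

    @property
    def total_variants(self) -> int:
        return sum(self.per_consequence.values())

    @property
    def genes_with_variants(self) -> int:
        return sum(1 for n in self.per_gene.values() if n > 0)

    @property
    def carrier_fraction_pct(self) -> Optional[float]:
        return pct(self.n_carriers, self.n_patients, 1)

    @property
    def gene_panel_hit_pct(self) -> Optional[float]:
        return pct(self.genes_with_variants, self.panel_size)

    @property
    def actionable_pct(self) -> Optional[float]:
        return pct(self.n_actionable_patients, self.n_patients)

    @property
    def brca_novel_pct(self) -> Optional[float]:
        return pct(self.n_brca_not_previously_identified, self.n_brca_variants)

    def consequence_pct(self, csq: Consequence) -> Optional[float]:
        return pct(self.per_consequence.get(csq, 0), self.total_variants)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_carriers": self.n_carriers,
            "carrier_fraction_pct": self.carrier_fraction_pct,
            "total_variants": self.total_variants,
            "genes_with_variants": self.genes_with_variants,
            "panel_size": self.panel_size,
            "gene_panel_hit_pct": self.gene_panel_hit_pct,
            "multi_variant_counts": {str(k): v for k, v in
                                     sorted(self.multi_variant_counts.items())},
            "excluded_recessive_het": self.excluded_recessive_het,
            "n_brca_variants": self.n_brca_variants,
            "n_brca_not_previously_identified":
                self.n_brca_not_previously_identified,
            "brca_novel_pct": self.brca_novel_pct,
            "n_actionable_patients": self.n_actionable_patients,
            "actionable_pct": self.actionable_pct,
        }


def build_summary(
    patients: Sequence[PatientRecord],
    reportable: Sequence[ClassifiedVariant],
    panel: GenePanel,
    excluded_recessive_het: int = 0,
) -> CohortSummary:
    """Tabulate the cohort from patient records and reportable variants.

    Carriers, per-gene/consequence/pathway counts, the multi-variant
    histogram, BRCA1/2 novelty and actionability are all computed from
    the data; nothing is taken from configuration.
    """
    from .pathway_burden import pathway_distribution

    reportable = [cv for cv in reportable if cv.reportable]
    per_patient: dict[str, list[ClassifiedVariant]] = {}
    for cv in reportable:
        per_patient.setdefault(cv.variant.patient_id, []).append(cv)

    carriers = set(per_patient)
    per_type: dict[str, tuple[int, int]] = {}
    for p in patients:
        n, k = per_type.get(p.cancer_type, (0, 0))
        per_type[p.cancer_type] = (n + 1, k + (1 if p.patient_id in carriers else 0))

    per_gene: dict[str, int] = {}
    per_consequence: dict[Consequence, int] = {}
    for cv in reportable:
        per_gene[cv.variant.gene] = per_gene.get(cv.variant.gene, 0) + 1
        per_consequence[cv.variant.consequence] = \
            per_consequence.get(cv.variant.consequence, 0) + 1

    dist = pathway_distribution(reportable, panel)

    multi: dict[int, int] = {}
    for cvs in per_patient.values():
        multi[len(cvs)] = multi.get(len(cvs), 0) + 1

    brca = [cv for cv in reportable if cv.variant.gene in PARPI_GENES]
    brca_novel = sum(1 for cv in brca
                     if cv.variant.previously_identified is False)

    actionable = {pid for pid, cvs in per_patient.items()
                  if suggest_treatment(cvs, panel)}

    return CohortSummary(
        n_patients=len(patients),
        n_carriers=len(carriers),
        per_type=per_type,
        per_gene=per_gene,
        per_consequence=per_consequence,
        per_pathway=dict(dist.counts),
        multi_variant_counts=multi,
        excluded_recessive_het=excluded_recessive_het,
        panel_size=panel.size,
        n_brca_variants=len(brca),
        n_brca_not_previously_identified=brca_novel,
        n_actionable_patients=len(actionable),
    )


def write_assessments(assessments: Sequence[tuple[str, ClinicalAssessment]],
                      path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tgene\thgvs_c\tacmg_class\tgroup"
                 "\ttreatment_suggestion\treturn_recommended\trationale\n")
        for pid, a in assessments:
            v = a.variant.variant
            fh.write(f"{pid}\t{v.gene}\t{v.hgvs_c}\t{int(a.variant.acmg_class)}"
                     f"\t{a.group.value}\t{a.treatment_suggestion.value}"
                     f"\t{'true' if a.return_recommended else 'false'}"
                     f"\t{';'.join(sorted(a.rationale))}\n")
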