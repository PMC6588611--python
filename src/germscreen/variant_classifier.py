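"""Deterministic five-class pathogenicity engine and inheritance handling.

The engine is a deliberate simplification of expert manual curation:

* a curated assertion, when supplied, overrides everything;
* loss-of-function consequences (frameshift, nonsense, start loss, and
  splice-site within +/-2 bp) in a panel gene are PATHOGENIC when the
  variant is absent from population databases (pop_af == 0) and
  LIKELY_PATHOGENIC otherwise;
* missense without curation is VUS.

The pop_af-based 4-vs-5 split for LoF variants is a documented stand-in;
expert grading should be injected through the curation channel.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from .errors import OffPanelError
from .germline_filter import DEFAULT_THRESHOLDS, FilterThresholds
from .models import (
    ACMGClass,
    ClassifiedVariant,
    Consequence,
    GenePanel,
    Inheritance,
    LOF_CONSEQUENCES,
    PatientGenotype,
    Phase,
    VariantCall,
    Zygosity,
)

logger = logging.getLogger(__name__)

#: Curation override table: (gene, hgvs_c) -> asserted class.
CurationTable = Mapping[tuple[str, str], ACMGClass]


def is_lof(v: VariantCall, thresholds: FilterThresholds = DEFAULT_THRESHOLDS) -> bool:
    if v.consequence in LOF_CONSEQUENCES:
        return True
    return (v.consequence is Consequence.SPLICE_SITE
            and v.splice_offset != 0
            and abs(v.splice_offset) <= thresholds.max_splice_offset)


def classify_variant(
    v: VariantCall,
    panel: GenePanel,
    curation: CurationTable | None = None,
    curated_assertion: Optional[ACMGClass] = None,
) -> ClassifiedVariant:
    """Classify one filtered variant.

    ``curated_assertion`` (or a ``curation`` table entry keyed by
    (gene, hgvs_c)) takes precedence over the rule table.
    """
    if v.gene not in panel:
        raise OffPanelError(f"off_panel: {v.gene}")
    assertion = curated_assertion
    if assertion is None and curation is not None:
        assertion = curation.get((v.gene, v.hgvs_c))
    if assertion is not None:
        assertion = ACMGClass(assertion)
        return ClassifiedVariant(
            variant=v, acmg_class=assertion,
            evidence_tags=frozenset({"curated_override"}),
            curated_assertion=assertion)
    if is_lof(v):
        if v.pop_af == 0:
            return ClassifiedVariant(v, ACMGClass.PATHOGENIC,
                                     frozenset({"lof_absent_from_databases"}))
        return ClassifiedVariant(v, ACMGClass.LIKELY_PATHOGENIC,
                                 frozenset({"lof_rare"}))
    return ClassifiedVariant(v, ACMGClass.VUS, frozenset({"default_vus"}))


def classify_all(
    calls: Iterable[VariantCall],
    panel: GenePanel,
    curation: CurationTable | None = None,
) -> list[ClassifiedVariant]:
    return [classify_variant(v, panel, curation=curation) for v in calls]


def select_reportable(classified: Iterable[ClassifiedVariant]) -> list[ClassifiedVariant]:
    """Keep classes 4 and 5 only (idempotent)."""
    return [cv for cv in classified if cv.reportable]


def group_genotypes(
    classified: Iterable[ClassifiedVariant],
    gene_phase: Mapping[tuple[str, str], Phase] | None = None,
) -> list[PatientGenotype]:
    """Group classified variants into per-patient genotypes.

    ``gene_phase`` optionally supplies the relative phase of same-gene
    variant pairs, keyed by (patient_id, gene).
    """
    by_patient: dict[str, PatientGenotype] = {}
    for cv in classified:
        pid = cv.variant.patient_id
        gt = by_patient.setdefault(pid, PatientGenotype(patient_id=pid))
        gt.variants.append(cv)
    if gene_phase:
        for (pid, gene), phase in gene_phase.items():
            if pid in by_patient:
                by_patient[pid].gene_phase[gene] = Phase(phase)
    return [by_patient[pid] for pid in sorted(by_patient)]


def apply_inheritance_filter(
    genotypes: Iterable[PatientGenotype],
    panel: GenePanel,
) -> tuple[list[PatientGenotype], list[tuple[str, ClassifiedVariant]]]:
    """Exclude heterozygous singletons in recessive genes.

    In a RECESSIVE gene a patient's variants count toward carrier status
    only when homozygous, or when the gene carries two or more
    reportable variants whose relative phase is TRANS or UNKNOWN
    (potential compound heterozygote; UNKNOWN is treated inclusively).
    Diverted variants are returned separately so they can be reported as
    recessive-het findings.
    """
    kept: list[PatientGenotype] = []
    excluded: list[tuple[str, ClassifiedVariant]] = []
    for gt in genotypes:
        surviving: list[ClassifiedVariant] = []
        for gene, cvs in gt.by_gene().items():
            if gene in panel and panel[gene].inheritance is Inheritance.RECESSIVE:
                reportable = [cv for cv in cvs if cv.reportable]
                hom = [cv for cv in reportable
                       if cv.variant.zygosity is Zygosity.HOM]
                phase = gt.gene_phase.get(gene, Phase.UNKNOWN)
                compound = (len(reportable) >= 2
                            and phase in (Phase.TRANS, Phase.UNKNOWN))
                if hom or compound:
                    surviving.extend(cvs)
                else:
                    excluded.extend((gt.patient_id, cv) for cv in reportable)
                    # non-reportable variants in the gene stay with the patient
                    surviving.extend(cv for cv in cvs if not cv.reportable)
            else:
                surviving.extend(cvs)
        kept.append(PatientGenotype(patient_id=gt.patient_id,
                                    variants=surviving,
                                    gene_phase=dict(gt.gene_phase)))
    return kept, excluded


def count_carriers(genotypes: Iterable[PatientGenotype]) -> set[str]:
    """Patients with at least one reportable variant (each counted once)."""
    return {gt.patient_id for gt in genotypes
            if any(cv.reportable for cv in gt.variants)}
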