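"""LOH calling, somatic second hits, phase analysis and reversion detection.

LOH is called on the raw tumor VAF with a strict cutoff: tumor VAF above
0.65 indicates loss of the wild-type allele.  No purity correction is
applied before thresholding; dilution by normal tissue therefore biases
LOH calls toward under-detection, and sensitivity increases with purity.

A somatic indel in cis with a germline frameshift whose combined net
length is a multiple of three restores the reading frame and is reported
as a REVERSION rather than a second hit.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .models import (
    ClassifiedVariant,
    Consequence,
    GenePanel,
    HitCategory,
    HR_SUPERGROUP,
    LOF_CONSEQUENCES,
    PairPhase,
    Pathway,
    Phase,
    SecondHitResult,
    SomaticVariant,
    TumorObservation,
    VariantCall,
)

#: Strict blood-side heterozygosity bound and tumor-side LOH cutoff.
HET_VAF_BOUND = 0.65
LOH_CUTOFF = 0.65


def check_blood_heterozygosity(vaf_blood: float, bound: float = HET_VAF_BOUND) -> bool:
    """True iff the blood VAF is consistent with a heterozygous call (< 0.65)."""
    return vaf_blood < bound


def call_loh(obs: TumorObservation, cutoff: float = LOH_CUTOFF) -> Optional[bool]:
    """True iff tumor VAF > cutoff (strict); None when no tumor VAF exists."""
    if obs.tumor_vaf is None:
        return None
    return obs.tumor_vaf > cutoff


def detect_reversion(germline: VariantCall, somatic: SomaticVariant) -> bool:
    """Frame-restoring cis somatic indel for a germline frameshift.

    Phase UNKNOWN is conservative: it never supports a reversion call.
    """
    if germline.gene != somatic.gene:
        return False
    if germline.consequence is not Consequence.FRAMESHIFT:
        return False
    if somatic.phase_vs_germline is not Phase.CIS:
        return False
    return (germline.indel_net_length + somatic.indel_net_length) % 3 == 0


def _somatic_reportable(s: SomaticVariant, max_splice_offset: int = 2) -> bool:
    # mirrors the germline reportable-consequence notion: LoF plus
    # curated missense
    if s.consequence in LOF_CONSEQUENCES:
        return True
    if (s.consequence is Consequence.SPLICE_SITE and s.splice_offset != 0
            and abs(s.splice_offset) <= max_splice_offset):
        return True
    return s.consequence is Consequence.MISSENSE and s.curated_pathogenic


def detect_second_hit(
    germline: ClassifiedVariant,
    obs: TumorObservation,
    loh_cutoff: float = LOH_CUTOFF,
) -> SecondHitResult:
    """Classify the tumor-side evidence for one germline variant.

    Precedence: (1) cis frame-restoring somatic indel -> REVERSION;
    (2) reportable somatic variant with phase TRANS or UNKNOWN ->
    SOMATIC_SECOND_HIT; (3) tumor VAF above the cutoff -> LOH;
    (4) a somatic pair on opposite alleles -> BIALLELIC_SOMATIC (also
    recorded as a flag whenever present); (5) NONE.
    """
    v = germline.variant
    loh = call_loh(obs, cutoff=loh_cutoff)
    biallelic = any(s.pair_phase is PairPhase.OPPOSITE_ALLELES
                    for s in obs.somatic_hits)
    evidence: dict = {}

    reversions = [s for s in obs.somatic_hits if detect_reversion(v, s)]
    if reversions:
        evidence["somatic"] = reversions[0].hgvs_c
        evidence["net_length"] = v.indel_net_length + reversions[0].indel_net_length
        return SecondHitResult(v.patient_id, v.gene, v.hgvs_c,
                               HitCategory.REVERSION, loh=loh,
                               biallelic_somatic=biallelic, evidence=evidence)

    hits = [s for s in obs.somatic_hits
            if _somatic_reportable(s)
            and s.phase_vs_germline in (Phase.TRANS, Phase.UNKNOWN)]
    if hits:
        evidence["somatic"] = hits[0].hgvs_c
        evidence["phase"] = hits[0].phase_vs_germline.value
        return SecondHitResult(v.patient_id, v.gene, v.hgvs_c,
                               HitCategory.SOMATIC_SECOND_HIT, loh=loh,
                               biallelic_somatic=biallelic, evidence=evidence)

    if loh:
        evidence["tumor_vaf"] = obs.tumor_vaf
        return SecondHitResult(v.patient_id, v.gene, v.hgvs_c,
                               HitCategory.LOH, loh=loh,
                               biallelic_somatic=biallelic, evidence=evidence)

    if biallelic:
        return SecondHitResult(v.patient_id, v.gene, v.hgvs_c,
                               HitCategory.BIALLELIC_SOMATIC, loh=loh,
                               biallelic_somatic=True, evidence=evidence)

    if obs.tumor_vaf is None:
        evidence["reason"] = "no_tumor"
    return SecondHitResult(v.patient_id, v.gene, v.hgvs_c,
                           HitCategory.NONE, loh=loh,
                           biallelic_somatic=False, evidence=evidence)


def analyze_tumor(
    classified: Sequence[ClassifiedVariant],
    observations: Sequence[TumorObservation],
    loh_cutoff: float = LOH_CUTOFF,
) -> list[SecondHitResult]:
    """Run second-hit analysis for every germline variant with a matching
    tumor observation (matched by patient, gene and hgvs_c; a variant
    without an observation yields a no-tumor NONE result)."""
    index = {(o.patient_id, o.gene, o.hgvs_c): o for o in observations}
    results = []
    for cv in classified:
        v = cv.variant
        obs = index.get((v.patient_id, v.gene, v.hgvs_c))
        if obs is None:
            obs = TumorObservation(patient_id=v.patient_id, gene=v.gene,
                                   hgvs_c=v.hgvs_c, tumor_vaf=None)
        results.append(detect_second_hit(cv, obs, loh_cutoff=loh_cutoff))
    return results


def loh_fraction(
    results: Iterable[SecondHitResult],
    panel: GenePanel | None = None,
    pathway: Pathway | None = None,
    hr_supergroup: bool = False,
) -> Optional[float]:
    """Fraction of evaluable germline variants showing LOH.

    Evaluable means a tumor VAF was available.  ``pathway`` restricts
    both numerator and denominator to genes of that pathway;
    ``hr_supergroup`` restricts to the HR super-group (HR plus Fanconi).
    Returns None for an empty evaluable set.
    """
    subset = []
    for r in results:
        if r.loh is None:
            continue
        if pathway is not None or hr_supergroup:
            if panel is None or r.gene not in panel:
                continue
            pw = panel[r.gene].pathway
            if hr_supergroup:
                if pw not in HR_SUPERGROUP:
                    continue
            elif pw is not pathway:
                continue
        subset.append(r)
    if not subset:
        return None
    return sum(1 for r in subset if r.loh) / len(subset)


def write_second_hits(results: Sequence[SecondHitResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tgene\thgvs_c\tcategory\tloh\tbiallelic_somatic\tevidence\n")
        for r in results:
            loh = "NA" if r.loh is None else ("true" if r.loh else "false")
            ev = ";".join(f"{k}={v}" for k, v in sorted(r.evidence.items()))
            fh.write(f"{r.patient_id}\t{r.gene}\t{r.hgvs_c}\t{r.category.value}"
                     f"\t{loh}\t{'true' if r.biallelic_somatic else 'false'}\t{ev}\n")
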