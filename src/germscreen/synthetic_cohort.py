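"""Synthetic cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes, so every stage is testable without access to patient data:

* heterozygous germline blood VAFs drawn binomially around 0.5 and
  rejection-sampled into the open interval (0.20, 0.65) — real cohorts
  show all blood VAFs below 0.65 and the filter keeps VAF > 0.20, so
  planted pathogenic variants are guaranteed to survive both bounds;
* decoy variants that each violate exactly one named filter stage;
* tumor VAFs shifted under loss of heterozygosity with a per-patient
  purity scalar: expected VAF = purity + (1 - purity) / 2 under loss of
  the wild-type allele, 0.5 otherwise;
* cis frame-restoring somatic indels (reversions) and trans/unknown
  somatic second hits;
* a two-group expression structure over signature genes.

The noise model is binomial read sampling only; there is no base-error
substitution noise, because the tests need labeled filter violations
rather than realism.  All randomness derives from a single integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import (
    Consequence,
    HRDStatus,
    PatientRecord,
    Phase,
    SomaticVariant,
    TumorObservation,
    VariantCall,
    Zygosity,
)

#: Cancer-type weights mirroring the cohort composition of the study
#: population (per-type patient counts over 636).
DEFAULT_CANCER_TYPE_WEIGHTS = {
    "Colorectal cancer": 141, "Breast cancer": 85, "Bile duct cancer": 47,
    "Pancreatic cancer": 43, "NSCLC": 33, "Prostate cancer": 26,
    "Ovarian cancer": 23, "Urothelial cancer": 20, "Gastric cancer": 20,
    "Cervical cancer": 18, "Others": 17, "CUP": 16, "Sarcoma": 14,
    "Head and neck cancer": 14, "Neuroendocrine cancer": 13,
    "Malignant Mesothelioma": 12, "Melanoma": 12, "Esophageal cancer": 11,
    "SCLC": 11, "Hepatocellular cancer": 10, "Adrenocortical cancer": 8,
    "Endometrial cancer": 8, "Thymoma": 8, "Renal cell carcinoma": 6,
    "Adenoid cystic carcinoma": 5, "Myoepithelial carcinoma": 4,
    "Glioblastoma": 4, "Anogenital cancer": 3, "Germ cell cancer": 2,
    "Vulvovaginal cancer": 2,
}

#: Per-gene planting weights, proportional to the most frequently hit
#: genes; arbitrary beyond the top ten.  Dominant-inheritance genes only,
#: so that planted carriers always survive the inheritance filter.
DEFAULT_GENE_WEIGHTS = {
    "BRCA2": 15, "CHEK2": 15, "BRCA1": 7, "ATM": 6, "BAP1": 5, "FANCM": 5,
    "FANCA": 4, "CHEK1": 4, "NBN": 4, "BLM": 4, "WRN": 2, "ATR": 2,
    "PALB2": 2, "RAD51C": 2, "XPC": 1, "TP53": 1, "MSH6": 1, "ERCC2": 1,
}

_CONSEQUENCE_WEIGHTS = [
    (Consequence.FRAMESHIFT, 0.44),
    (Consequence.NONSENSE, 0.36),
    (Consequence.SPLICE_SITE, 0.15),
    (Consequence.START_LOSS, 0.05),
]

DECOY_KINDS = ("quality", "depth", "population", "consequence", "vaf")

#: Cascade stage at which each decoy kind is rejected (low call quality
#: and low depth are both caught by the combined QC stage).
DECOY_STAGE = {
    "quality": "quality",
    "depth": "quality",
    "population": "population",
    "consequence": "consequence",
    "vaf": "vaf",
}


@dataclass
class SimulationConfig:
    n_patients: int = 636
    cancer_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CANCER_TYPE_WEIGHTS))
    carrier_fraction: float = 0.178
    per_gene_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS))
    mean_depth: int = 50
    qual_noise_fraction: float = 0.0
    common_benign_rate: float = 1.0
    tumor_purity_range: tuple[float, float] = (0.4, 0.9)
    loh_fraction: float = 0.27
    second_hit_fraction: float = 0.05
    reversion_fraction: float = 0.02
    recessive_het_rate: float = 0.0
    expression_effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cancer_type_weights.values())
        if total <= 0:
            raise ValidationError("cancer_type_weights must have positive mass")
        self.cancer_type_weights = {
            k: v / total for k, v in self.cancer_type_weights.items()}
        if abs(sum(self.cancer_type_weights.values()) - 1.0) > 1e-9:
            raise ValidationError("cancer_type_weights do not normalize")
        for name in ("carrier_fraction", "loh_fraction", "second_hit_fraction",
                     "reversion_fraction", "recessive_het_rate",
                     "qual_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.tumor_purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("tumor_purity_range must be within [0, 1]")
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")


@dataclass
class TruthRow:
    """One planted pathogenic variant and its tumor-side ground truth."""

    patient_id: str
    gene: str
    hgvs_c: str
    consequence: Consequence
    loh: bool
    second_hit: bool
    reversion: bool
    purity: float


@dataclass
class DecoyRow:
    patient_id: str
    gene: str
    hgvs_c: str
    planted_stage: str


@dataclass
class TruthTable:
    carriers: set[str] = field(default_factory=set)
    pathogenic: list[TruthRow] = field(default_factory=list)
    decoys: list[DecoyRow] = field(default_factory=list)
    recessive_het: list[str] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("patient_id\tgene\thgvs_c\tconsequence\tloh"
                     "\tsecond_hit\treversion\tpurity\n")
            for r in self.pathogenic:
                fh.write(f"{r.patient_id}\t{r.gene}\t{r.hgvs_c}"
                         f"\t{r.consequence.value}"
                         f"\t{'true' if r.loh else 'false'}"
                         f"\t{'true' if r.second_hit else 'false'}"
                         f"\t{'true' if r.reversion else 'false'}"
                         f"\t{r.purity:g}\n")


def _draw_het_vaf(rng: np.random.Generator, depth: int) -> float:
    """Binomial blood VAF rejection-sampled into (0.20, 0.65)."""
    while True:
        alt = rng.binomial(depth, 0.5)
        vaf = alt / depth
        if 0.20 < vaf < 0.65:
            return vaf


def _make_decoy(rng: np.random.Generator, patient_id: str, gene: str,
                index: int, kind: str, mean_depth: int) -> VariantCall:
    # each decoy fails exactly its planted stage and passes every other
    v = VariantCall(
        patient_id=patient_id, gene=gene,
        chrom="1", pos=1_000_000 + index, ref="A", alt="T",
        hgvs_c=f"c.{index + 1}A>T",
        consequence=Consequence.MISSENSE,
        call_quality=60.0, depth=mean_depth, vaf=0.5, pop_af=0.0,
    )
    if kind == "quality":
        v.call_quality = float(rng.integers(0, 20))
    elif kind == "depth":
        v.depth = int(rng.integers(0, 10))
    elif kind == "population":
        v.pop_af = float(rng.uniform(0.011, 0.2))
    elif kind == "consequence":
        v.consequence = Consequence.SYNONYMOUS
    elif kind == "vaf":
        v.vaf = float(rng.uniform(0.01, 0.20))
    else:
        raise ValueError(f"unknown decoy kind {kind}")
    return v


def simulate_cohort(config: SimulationConfig) -> tuple[
        list[PatientRecord], list[VariantCall],
        list[TumorObservation], TruthTable]:
    """Generate (patients, germline calls, tumor observations, truth).

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    types = sorted(config.cancer_type_weights)
    type_p = np.array([config.cancer_type_weights[t] for t in types])
    genes = sorted(config.per_gene_weights)
    gene_w = np.array([config.per_gene_weights[g] for g in genes], float)
    gene_p = gene_w / gene_w.sum() if gene_w.sum() > 0 else None
    csq_values = [c for c, _ in _CONSEQUENCE_WEIGHTS]
    csq_p = np.array([w for _, w in _CONSEQUENCE_WEIGHTS])
    csq_p = csq_p / csq_p.sum()

    patients: list[PatientRecord] = []
    calls: list[VariantCall] = []
    tumor: list[TumorObservation] = []
    truth = TruthTable()

    lo, hi = config.tumor_purity_range
    for i in range(config.n_patients):
        pid = f"SIM{i:05d}"
        ctype = types[rng.choice(len(types), p=type_p)]
        patients.append(PatientRecord(patient_id=pid, cancer_type=ctype))

        if gene_p is not None and rng.random() < config.carrier_fraction:
            gene = genes[rng.choice(len(genes), p=gene_p)]
            csq = csq_values[rng.choice(len(csq_values), p=csq_p)]
            depth = max(int(rng.poisson(config.mean_depth)), 10)
            vaf = _draw_het_vaf(rng, depth)
            pos = int(rng.integers(1, 10_000_000))
            indel = -2 if csq is Consequence.FRAMESHIFT else 0
            offset = int(rng.choice([-2, -1, 1, 2])) \
                if csq is Consequence.SPLICE_SITE else 0
            hgvs = f"c.{pos}del" if indel else f"c.{pos}G>A"
            calls.append(VariantCall(
                patient_id=pid, gene=gene, chrom="2", pos=pos,
                ref="GA" if indel else "G", alt="G" if indel else "A",
                hgvs_c=hgvs, consequence=csq, splice_offset=offset,
                call_quality=60.0, depth=depth, vaf=vaf, pop_af=0.0,
                indel_net_length=indel, zygosity=Zygosity.HET,
            ))
            truth.carriers.add(pid)

            purity = float(rng.uniform(lo, hi))
            loh = bool(rng.random() < config.loh_fraction)
            tumor_depth = max(int(rng.poisson(config.mean_depth)), 1)
            p_alt = purity + (1 - purity) * 0.5 if loh else 0.5
            tumor_vaf = rng.binomial(tumor_depth, p_alt) / tumor_depth

            somatic: list[SomaticVariant] = []
            reversion = (csq is Consequence.FRAMESHIFT
                         and rng.random() < config.reversion_fraction)
            second_hit = (not reversion
                          and rng.random() < config.second_hit_fraction)
            if reversion:
                net = -(indel % 3)  # makes (indel + net) % 3 == 0
                somatic.append(SomaticVariant(
                    gene=gene, hgvs_c=f"c.{pos - 5}del",
                    consequence=Consequence.FRAMESHIFT,
                    indel_net_length=net, phase_vs_germline=Phase.CIS))
            if second_hit:
                phase = Phase.TRANS if rng.random() < 0.5 else Phase.UNKNOWN
                somatic.append(SomaticVariant(
                    gene=gene, hgvs_c=f"c.{pos + 5}G>T",
                    consequence=Consequence.NONSENSE,
                    phase_vs_germline=phase))
            tumor.append(TumorObservation(
                patient_id=pid, gene=gene, hgvs_c=hgvs,
                tumor_vaf=tumor_vaf, tumor_depth=tumor_depth,
                somatic_hits=somatic))
            truth.pathogenic.append(TruthRow(
                patient_id=pid, gene=gene, hgvs_c=hgvs, consequence=csq,
                loh=loh, second_hit=second_hit, reversion=reversion,
                purity=purity))

        if rng.random() < config.recessive_het_rate:
            depth = max(int(rng.poisson(config.mean_depth)), 10)
            calls.append(VariantCall(
                patient_id=pid, gene="MUTYH", chrom="1", pos=45_331_556,
                ref="C", alt="T", hgvs_c="c.1187G>A",
                consequence=Consequence.MISSENSE,
                call_quality=60.0, depth=depth,
                vaf=_draw_het_vaf(rng, depth), pop_af=0.005,
                known_pathogenic_common=True, zygosity=Zygosity.HET,
            ))
            truth.recessive_het.append(pid)

        n_decoys = int(rng.poisson(config.common_benign_rate))
        for d in range(n_decoys):
            kind = DECOY_KINDS[rng.integers(0, len(DECOY_KINDS))]
            gene = genes[rng.integers(0, len(genes))] if genes else "TP53"
            decoy = _make_decoy(rng, pid, gene, i * 100 + d, kind,
                                config.mean_depth)
            calls.append(decoy)
            truth.decoys.append(DecoyRow(
                patient_id=pid, gene=gene, hgvs_c=decoy.hgvs_c,
                planted_stage=kind))

    return patients, calls, tumor, truth


def simulate_tumor_vafs(
    truth: TruthTable,
    purity: float,
    depth: int,
    seed: int,
) -> list[TumorObservation]:
    """Re-draw tumor VAFs for every planted variant at a fixed purity.

    Expected VAF is purity + (1 - purity)/2 when LOH (loss of the
    wild-type allele) was planted, 0.5 otherwise; read counts are
    binomial at ``depth``.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValidationError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for row in truth.pathogenic:
        p_alt = purity + (1 - purity) * 0.5 if row.loh else 0.5
        vaf = rng.binomial(depth, p_alt) / depth if depth > 0 else 0.0
        out.append(TumorObservation(
            patient_id=row.patient_id, gene=row.gene, hgvs_c=row.hgvs_c,
            tumor_vaf=vaf, tumor_depth=depth))
    return out


def simulate_expression(
    n_hrd: int,
    n_normal: int,
    signature_genes: Sequence[str],
    effect_size: float,
    seed: int,
    n_noise_genes: Optional[int] = None,
    sample_prefix: str = "S",
):
    """Two-group expression matrix with hidden labels.

    Signature genes are shifted down by ``effect_size`` standard
    deviations in the deficient group; all other genes are exchangeable
    standard-normal noise.  Returns (matrix: genes x samples DataFrame,
    labels: sample -> HRDStatus).
    """
    if effect_size < 0:
        raise ValidationError("effect_size must be >= 0")
    if n_hrd < 1 or n_normal < 1:
        raise ValidationError("both group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    sig = list(signature_genes)
    if n_noise_genes is None:
        n_noise_genes = max(50, 3 * len(sig))
    noise_genes = [f"NOISE{i:04d}" for i in range(n_noise_genes)]
    genes = sig + noise_genes
    n = n_hrd + n_normal
    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]
    values = rng.normal(0.0, 1.0, size=(len(genes), n))
    values[:len(sig), :n_hrd] -= effect_size
    df = pd.DataFrame(values, index=genes, columns=samples)
    labels = {s: (HRDStatus.DEFICIENT if i < n_hrd else HRDStatus.NORMAL)
              for i, s in enumerate(samples)}
    return df, labels
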