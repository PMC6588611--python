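"""Reference-cohort fixture.

Builds a fully specified 636-patient cohort from the packaged per-type
count table plus the published aggregate counts (121 reportable
variants with consequence composition 51/42/18/9/1, 42 genes hit,
22 BRCA1/2 variants of which 10 not previously identified, 12 carriers
of the recurrent CHEK2 c.1100del allele, 21 PARPi-eligible and 4
immunotherapy-eligible patients, 16 recessive-gene heterozygotes).

The printed per-type carrier counts sum to 109 against a printed total
of 113; the 4 unallocated carriers are assigned to breast (+2), bile
duct (+1) and pancreatic (+1) cancer, whose per-type fractions are not
individually reported.  Everything downstream is computed from the
constructed records, never hard-coded.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .models import (
    ACMGClass,
    ClassifiedVariant,
    Consequence,
    GenePanel,
    PatientRecord,
    VariantCall,
    Zygosity,
)
from .variant_classifier import classify_variant

#: Extra carriers added on top of the printed per-type counts.
CARRIER_REDISTRIBUTION = {
    "Breast cancer": 2,
    "Bile duct cancer": 1,
    "Pancreatic cancer": 1,
}

#: Variants per gene (sums to 121 over 42 genes).
GENE_VARIANT_COUNTS = {
    "BRCA2": 15, "CHEK2": 15, "BRCA1": 7,
    "ATM": 6, "BAP1": 5, "FANCM": 5,
    "FANCA": 4, "CHEK1": 4, "NBN": 4, "BLM": 4,
    # two-variant genes
    "WRN": 2, "ERCC2": 2, "ATR": 2, "RAD51C": 2, "FANCC": 2, "FANCD2": 2,
    "XPC": 2, "ERCC3": 2, "RAD51D": 2, "PALB2": 2, "BRIP1": 2, "BARD1": 2,
    "TP53": 2, "PTEN": 2, "CDH1": 2, "STK11": 2, "SDHB": 2, "VHL": 2,
    "RECQL4": 2, "XPA": 2,
    # one-variant genes
    "MLH1": 1, "MSH2": 1, "MSH6": 1, "PMS2": 1,
    "POLE": 1, "POLD1": 1, "SEC23B": 1, "SMAD9": 1, "FAN1": 1, "DDB2": 1,
    "CDKN2A": 1, "ERCC5": 1,
}

#: Genes whose single variant is a curated pathogenic missense.
MISSENSE_GENES = ("MLH1", "POLE", "POLD1", "SEC23B", "SMAD9",
                  "FAN1", "DDB2", "CDKN2A", "ERCC5")

N_CHEK2_RECURRENT = 12     # carriers of the recurrent c.1100del allele
N_BRCA_NOT_PREVIOUS = 10   # of the 22 BRCA1/2 variants
N_RECESSIVE_HET = 16       # MUTYH/NTHL1 heterozygotes, reported separately


def read_cohort_counts() -> list[tuple[str, int, int]]:
    """(cancer_type, patients, printed carriers) from the packaged table."""
    rows = []
    ref = resources.files("germscreen").joinpath("data/cohort_counts.tsv")
    with resources.as_file(ref) as path, open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    for ln in lines[1:]:
        ctype, n, k = ln.split("\t")
        rows.append((ctype, int(n), int(k)))
    return rows


@dataclass
class ReferenceCohort:
    patients: list[PatientRecord]
    classified: list[ClassifiedVariant]


def _variant_spec_list() -> list[dict]:
    """The 121 variant specs (gene, consequence, annotations), ordered."""
    specs: list[dict] = []
    for gene, n in GENE_VARIANT_COUNTS.items():
        for j in range(n):
            specs.append({"gene": gene, "index": j})

    # fixed consequences first: recurrent CHEK2 frameshift allele,
    # curated missense singletons, one start loss
    n_ms = n_sl = 0
    for s in specs:
        gene, j = s["gene"], s["index"]
        if gene == "CHEK2" and j < N_CHEK2_RECURRENT:
            s["consequence"] = Consequence.FRAMESHIFT
            s["hgvs_c"] = "c.1100del"
            s["hgvs_p"] = "p.Thr367Metfs*15"
            s["pop_af"] = 0.002
            s["known_pathogenic_common"] = True
            s["indel_net_length"] = -1
        elif gene in MISSENSE_GENES and j == 0:
            s["consequence"] = Consequence.MISSENSE
            s["curated"] = ACMGClass.PATHOGENIC
            if gene == "MLH1":
                s["hgvs_p"] = "p.Pro648Ser"
            n_ms += 1
        elif gene == "XPA" and j == 0:
            s["consequence"] = Consequence.START_LOSS
            n_sl += 1
    assert n_ms == 9 and n_sl == 1

    # fill the rest: frameshift to 51 total, nonsense to 42, splice to 18
    remaining = [s for s in specs if "consequence" not in s]
    n_fs = 51 - N_CHEK2_RECURRENT
    n_ns = 42
    n_sp = 18
    assert n_fs + n_ns + n_sp == len(remaining)
    for i, s in enumerate(remaining):
        if i < n_fs:
            s["consequence"] = Consequence.FRAMESHIFT
            s["indel_net_length"] = -2
        elif i < n_fs + n_ns:
            s["consequence"] = Consequence.NONSENSE
        else:
            s["consequence"] = Consequence.SPLICE_SITE
            s["splice_offset"] = -1 if i % 2 else 2
    return specs


def _order_for_assignment(specs: list[dict]) -> list[dict]:
    """Order variant specs so that slot assignment yields the published
    patient-level structure (21 distinct BRCA1/2 patients, 25 actionable
    patients, one recurrent allele per patient)."""
    by_gene: dict[str, list[dict]] = {}
    for s in specs:
        by_gene.setdefault(s["gene"], []).append(s)

    def take(gene: str) -> dict:
        return by_gene[gene].pop(0)

    ordered: list[dict] = []
    # two triple-variant patients: one of them carries two BRCA variants
    ordered += [take("BRCA2"), take("BRCA1"), take("ATM")]
    ordered += [take("FANCA"), take("BLM"), take("NBN")]
    # four double-variant patients
    ordered += [take("BAP1"), take("FANCM")]
    ordered += [take("CHEK1"), take("ATM")]
    ordered += [take("WRN"), take("ERCC2")]
    ordered += [take("ATR"), take("RAD51C")]
    # single-variant patients: remaining BRCA first (distinct patients),
    # then everything else in stable gene order
    ordered += [take("BRCA2") for _ in range(len(by_gene["BRCA2"]))]
    ordered += [take("BRCA1") for _ in range(len(by_gene["BRCA1"]))]
    for gene in GENE_VARIANT_COUNTS:
        ordered += by_gene[gene]
        by_gene[gene] = []
    assert len(ordered) == len(specs)
    return ordered


def reference_cohort(panel: GenePanel) -> ReferenceCohort:
    """Construct the full reference cohort against ``panel``."""
    counts = read_cohort_counts()

    patients: list[PatientRecord] = []
    carrier_ids: list[str] = []
    for t, (ctype, n, k) in enumerate(counts):
        k += CARRIER_REDISTRIBUTION.get(ctype, 0)
        assert k <= n
        for i in range(n):
            pid = f"P{t:02d}_{i:03d}"
            patients.append(PatientRecord(patient_id=pid, cancer_type=ctype))
            if i < k:
                carrier_ids.append(pid)
    assert len(patients) == sum(n for _, n, _ in counts)

    # variant slots per carrier: two patients with 3 variants, four with 2
    slots: list[str] = []
    per_carrier = [3, 3, 2, 2, 2, 2] + [1] * (len(carrier_ids) - 6)
    for pid, m in zip(carrier_ids, per_carrier):
        slots += [pid] * m

    specs = _order_for_assignment(_variant_spec_list())
    assert len(specs) == len(slots)

    brca_count = 0
    classified: list[ClassifiedVariant] = []
    for i, (pid, s) in enumerate(zip(slots, specs)):
        gene = s["gene"]
        prev: bool | None = None
        if gene in ("BRCA1", "BRCA2"):
            # first N_BRCA_NOT_PREVIOUS BRCA variants are newly identified
            prev = brca_count >= N_BRCA_NOT_PREVIOUS
            brca_count += 1
        call = VariantCall(
            patient_id=pid,
            gene=gene,
            chrom="1",
            pos=100_000 + i,
            ref="G",
            alt="A",
            hgvs_c=s.get("hgvs_c", f"c.{100 + i}G>A"),
            hgvs_p=s.get("hgvs_p", ""),
            consequence=s["consequence"],
            splice_offset=s.get("splice_offset", 0),
            call_quality=60.0,
            depth=50,
            vaf=0.48,
            pop_af=s.get("pop_af", 0.0),
            known_pathogenic_common=s.get("known_pathogenic_common", False),
            indel_net_length=s.get("indel_net_length", 0),
            zygosity=Zygosity.HET,
            previously_identified=prev,
        )
        classified.append(classify_variant(
            call, panel, curated_assertion=s.get("curated")))
    assert all(cv.reportable for cv in classified)
    return ReferenceCohort(patients=patients, classified=classified)
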