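"""Reading and writing of the formats the pipeline touches.

Formats
-------
* Gene panel: TSV (columns ``symbol, pathway, inheritance, acmg_return,
  actionable_class``; ``#`` comment lines allowed) or JSON (list of
  objects with the same keys).  A packaged default panel of 168 genes is
  available via :func:`default_panel`; it is a reconstruction and fully
  user-replaceable.
* Variant calls: TSV with a documented header (see ``VARIANT_COLUMNS``)
  or a minimal VCF 4.x subset (CHROM, POS, ID, REF, ALT, QUAL, FORMAT
  DP/AD; INFO is ignored).  VCF positions are kept 1-based as read.
* Cohort summary: a set of deterministic TSV tables plus a JSON report.

Percentages in written tables use round-half-away-from-zero at the
printed precision (:func:`round_half_away`).
"""
from __future__ import annotations

import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, ParseError, ValidationError
from .models import (
    ActionableClass,
    Consequence,
    GenePanel,
    GeneRecord,
    Inheritance,
    Pathway,
    VariantCall,
    Zygosity,
)

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["symbol", "pathway", "inheritance", "acmg_return", "actionable_class"]

VARIANT_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p",
    "consequence", "splice_offset", "call_quality", "depth", "vaf", "pop_af",
    "known_pathogenic_common", "indel_net_length", "zygosity",
    "previously_identified",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (113/636 -> 17.8)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 0) -> Optional[float]:
    """Percentage with the pipeline's rounding convention; None if empty."""
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def _parse_bool(s: str) -> bool:
    v = str(s).strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"cannot parse boolean value {s!r}")


def _build_panel(rows: Iterable[dict]) -> GenePanel:
    genes: dict[str, GeneRecord] = {}
    for row in rows:
        rec = GeneRecord(
            symbol=row["symbol"],
            pathway=Pathway(row["pathway"]),
            inheritance=Inheritance(row.get("inheritance", "DOMINANT")),
            acmg_return=row.get("acmg_return", False)
            if isinstance(row.get("acmg_return"), bool)
            else _parse_bool(row.get("acmg_return", "false")),
            actionable_class=ActionableClass(row.get("actionable_class", "NONE")),
        )
        if rec.symbol in genes:
            raise ValidationError(f"duplicate gene symbol in panel: {rec.symbol}")
        genes[rec.symbol] = rec
    if not genes:
        logger.warning("gene panel is empty")
    return GenePanel(genes=genes)


def read_panel(path: str | Path, format: str | None = None) -> GenePanel:
    """Read a gene panel from TSV or JSON.

    ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    fmt = (format or ("JSON" if path.suffix.lower() == ".json" else "TSV")).upper()
    if fmt == "JSON":
        with open(path) as fh:
            data = json.load(fh)
        for row in data:
            for col in ("symbol", "pathway"):
                if col not in row:
                    raise ConfigurationError(f"panel JSON missing required key {col!r}")
        return _build_panel(data)
    if fmt != "TSV":
        raise ConfigurationError(f"unknown panel format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        logger.warning("gene panel file %s has no rows", path)
        return GenePanel(genes={})
    header = lines[0].split("\t")
    for col in ("symbol", "pathway"):
        if col not in header:
            raise ConfigurationError(f"panel file missing required column {col!r}")
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        rows.append(dict(zip(header, fields)))
    return _build_panel(rows)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for rec in panel:
            fh.write("\t".join([
                rec.symbol, rec.pathway.value, rec.inheritance.value,
                "true" if rec.acmg_return else "false",
                rec.actionable_class.value,
            ]) + "\n")


def default_panel() -> GenePanel:
    """The packaged 168-gene default panel (reconstructed, replaceable)."""
    with resources.as_file(
        resources.files("germscreen").joinpath("data/default_panel.tsv")
    ) as p:
        return read_panel(p, format="TSV")


# ---------------------------------------------------------------------------
# variant calls
# ---------------------------------------------------------------------------

def _opt_float(s: str) -> Optional[float]:
    return None if s in {"", ".", "NA", "None"} else float(s)


def _opt_int(s: str) -> Optional[int]:
    return None if s in {"", ".", "NA", "None"} else int(s)


def _opt_bool(s: str) -> Optional[bool]:
    return None if s in {"", ".", "NA", "None"} else _parse_bool(s)


def read_variant_calls(path: str | Path, format: str | None = None) -> list[VariantCall]:
    """Read variant calls from TSV or minimal VCF.

    TSV rows carry the full :class:`VariantCall` field set.  VCF records
    carry coordinates, QUAL, DP and AD only; VAF is computed as
    alt depth / total depth.  Records without depth information are
    skipped with a warning.  One call is emitted per alternate allele.
    """
    path = Path(path)
    fmt = (format or ("VCF" if path.suffix.lower() == ".vcf" else "TSV")).upper()
    if fmt == "VCF":
        return _read_vcf(path)
    if fmt != "TSV":
        raise ConfigurationError(f"unknown variant format {format!r}")
    calls: list[VariantCall] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return calls
    header = lines[0].split("\t")
    missing = [c for c in ("patient_id", "gene", "consequence") if c not in header]
    if missing:
        raise ConfigurationError(f"variant TSV missing required columns: {missing}")
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(fields)}", line=lineno)
        row = dict(zip(header, fields))
        try:
            calls.append(VariantCall(
                patient_id=row["patient_id"],
                gene=row["gene"],
                chrom=row.get("chrom", "."),
                pos=int(row.get("pos", 0) or 0),
                ref=row.get("ref", "."),
                alt=row.get("alt", "."),
                hgvs_c=row.get("hgvs_c", ""),
                hgvs_p=row.get("hgvs_p", ""),
                consequence=Consequence(row["consequence"]),
                splice_offset=int(row.get("splice_offset", 0) or 0),
                call_quality=_opt_float(row.get("call_quality", "")),
                depth=_opt_int(row.get("depth", "")),
                vaf=_opt_float(row.get("vaf", "")),
                pop_af=float(row.get("pop_af", 0) or 0.0),
                known_pathogenic_common=_parse_bool(
                    row.get("known_pathogenic_common", "false")),
                indel_net_length=int(row.get("indel_net_length", 0) or 0),
                zygosity=Zygosity(row.get("zygosity", "HET") or "HET"),
                previously_identified=_opt_bool(
                    row.get("previously_identified", "")),
            ))
        except (ValueError, KeyError) as exc:
            raise ParseError(str(exc), line=lineno) from exc
    return calls


def _read_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    skipped = 0
    vcf = VCF(str(path))
    sample_id = vcf.samples[0] if vcf.samples else "sample"
    for i, rec in enumerate(vcf):
        try:
            ad = rec.format("AD")
        except Exception:
            ad = None
        dp = None
        try:
            dpf = rec.format("DP")
            if dpf is not None:
                dp = int(dpf[0][0])
        except Exception:
            dp = None
        if ad is None and dp is None:
            skipped += 1
            logger.warning("record %d (%s:%d): no depth information, skipped",
                           i + 1, rec.CHROM, rec.POS)
            continue
        depths = [int(x) for x in ad[0]] if ad is not None else None
        total = dp if dp is not None else sum(d for d in depths if d >= 0)
        for ai, alt in enumerate(rec.ALT):
            vaf = None
            if depths is not None and total and len(depths) > ai + 1:
                vaf = depths[ai + 1] / total
            calls.append(VariantCall(
                patient_id=sample_id,
                gene="",
                chrom=rec.CHROM,
                pos=rec.POS,  # cyvcf2 POS is 1-based
                ref=rec.REF,
                alt=alt,
                call_quality=rec.QUAL,
                depth=total,
                vaf=vaf,
            ))
    if skipped:
        logger.warning("%d VCF records skipped for missing depth", skipped)
    return calls


def write_variant_calls(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as TSV (lossless round-trip with :func:`read_variant_calls`)."""

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if hasattr(v, "value"):
            return v.value
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join(fmt(getattr(c, col)) for col in VARIANT_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def write_report_tables(summary, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort summary as deterministic TSV tables.

    Row order: per-type rows in descending patient count (ties broken by
    name), followed by a ``total`` row; per-gene and per-consequence
    tables in descending count then name.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out_dir / "per_cancer_type.tsv"
    with open(p, "w") as fh:
        fh.write("cancer_type\tpatients\tcarriers\tcarrier_pct\n")
        rows = sorted(summary.per_type.items(), key=lambda kv: (-kv[1][0], kv[0]))
        for ctype, (n, k) in rows:
            fh.write(f"{ctype}\t{n}\t{k}\t{_fmt_pct(pct(k, n))}\n")
        fh.write(f"total\t{summary.n_patients}\t{summary.n_carriers}"
                 f"\t{_fmt_pct(pct(summary.n_carriers, summary.n_patients, 1))}\n")
    paths["per_cancer_type"] = p

    p = out_dir / "per_gene.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tvariants\n")
        for gene, n in sorted(summary.per_gene.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{gene}\t{n}\n")
    paths["per_gene"] = p

    p = out_dir / "per_consequence.tsv"
    with open(p, "w") as fh:
        fh.write("consequence\tvariants\tpct\n")
        total = sum(summary.per_consequence.values())
        for csq, n in sorted(summary.per_consequence.items(),
                             key=lambda kv: (-kv[1], kv[0].value)):
            fh.write(f"{csq.value}\t{n}\t{_fmt_pct(pct(n, total))}\n")
    paths["per_consequence"] = p

    p = out_dir / "per_pathway.tsv"
    with open(p, "w") as fh:
        fh.write("pathway\tvariants\tpct\n")
        total = sum(summary.per_pathway.values())
        for pw, n in sorted(summary.per_pathway.items(),
                            key=lambda kv: (-kv[1], kv[0].value)):
            fh.write(f"{pw.value}\t{n}\t{_fmt_pct(pct(n, total))}\n")
    paths["per_pathway"] = p

    p = out_dir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary_json"] = p
    return paths


def _fmt_pct(v: Optional[float]) -> str:
    return "NA" if v is None else f"{v:g}"


def read_report_tables(out_dir: str | Path):
    """Reconstruct a :class:`~germscreen.clinical_report.CohortSummary`
    from tables written by :func:`write_report_tables`."""
    from .clinical_report import CohortSummary

    out_dir = Path(out_dir)
    with open(out_dir / "summary.json") as fh:
        data = json.load(fh)
    per_type = {}
    with open(out_dir / "per_cancer_type.tsv") as fh:
        next(fh)
        for ln in fh:
            ctype, n, k, _ = ln.rstrip("\n").split("\t")
            if ctype == "total":
                continue
            per_type[ctype] = (int(n), int(k))
    per_gene = {}
    with open(out_dir / "per_gene.tsv") as fh:
        next(fh)
        for ln in fh:
            gene, n = ln.rstrip("\n").split("\t")
            per_gene[gene] = int(n)
    per_consequence = {}
    with open(out_dir / "per_consequence.tsv") as fh:
        next(fh)
        for ln in fh:
            csq, n, _ = ln.rstrip("\n").split("\t")
            per_consequence[Consequence(csq)] = int(n)
    per_pathway = {}
    with open(out_dir / "per_pathway.tsv") as fh:
        next(fh)
        for ln in fh:
            pw, n, _ = ln.rstrip("\n").split("\t")
            per_pathway[Pathway(pw)] = int(n)
    return CohortSummary(
        n_patients=data["n_patients"],
        n_carriers=data["n_carriers"],
        per_type=per_type,
        per_gene=per_gene,
        per_consequence=per_consequence,
        per_pathway=per_pathway,
        multi_variant_counts={int(k): v for k, v in
                              data["multi_variant_counts"].items()},
        excluded_recessive_het=data["excluded_recessive_het"],
        panel_size=data["panel_size"],
        n_brca_variants=data["n_brca_variants"],
        n_brca_not_previously_identified=data["n_brca_not_previously_identified"],
        n_actionable_patients=data["n_actionable_patients"],
    )
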