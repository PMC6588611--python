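"""Pathway assignment and burden/frequency tabulations.

Distributions are variant-level: each reportable variant counts once
under its own gene's pathway (the denominator is the variant count, not
the carrier count).  Fanconi anemia genes keep their FANCONI label but
count toward the homologous-recombination super-group fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import OffPanelError
from .io_core import round_half_away
from .models import (
    ClassifiedVariant,
    GenePanel,
    HR_SUPERGROUP,
    PatientRecord,
    Pathway,
)


def assign_pathway(gene: str, panel: GenePanel) -> Pathway:
    """The panel's pathway label for ``gene`` (FANCONI stays FANCONI)."""
    if gene not in panel:
        raise OffPanelError(f"off_panel: {gene}")
    return panel[gene].pathway


def in_hr_supergroup(gene: str, panel: GenePanel) -> bool:
    return assign_pathway(gene, panel) in HR_SUPERGROUP


@dataclass
class PathwayDistribution:
    counts: dict[Pathway, int] = field(default_factory=dict)
    total: int = 0

    @property
    def fractions(self) -> Optional[dict[Pathway, float]]:
        if self.total == 0:
            return None
        return {pw: n / self.total for pw, n in self.counts.items()}

    @property
    def hr_supergroup_fraction(self) -> Optional[float]:
        """HR + Fanconi share of all variants."""
        if self.total == 0:
            return None
        n = sum(self.counts.get(pw, 0) for pw in HR_SUPERGROUP)
        return n / self.total


def pathway_distribution(
    variants: Iterable[ClassifiedVariant],
    panel: GenePanel,
) -> PathwayDistribution:
    """Partition reportable variants by their gene's pathway."""
    counts: dict[Pathway, int] = {}
    total = 0
    for cv in variants:
        pw = assign_pathway(cv.variant.gene, panel)
        counts[pw] = counts.get(pw, 0) + 1
        total += 1
    return PathwayDistribution(counts=counts, total=total)


@dataclass
class TypeFrequencyRow:
    cancer_type: str
    patients: int
    carriers: int
    fraction: float
    included_in_figure: bool  # strictly more than 10 patients


def cancer_type_frequency(
    patients: Sequence[PatientRecord],
    carriers: Iterable[str],
    min_patients_exclusive: int = 10,
) -> list[TypeFrequencyRow]:
    """Per-cancer-type carrier fractions, ranked descending.

    Every type appears in the table; ``included_in_figure`` flags types
    with strictly more than ``min_patients_exclusive`` patients (the
    figure-view restriction).
    """
    carrier_set = set(carriers)
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for p in patients:
        totals[p.cancer_type] = totals.get(p.cancer_type, 0) + 1
        if p.patient_id in carrier_set:
            hits[p.cancer_type] = hits.get(p.cancer_type, 0) + 1
    rows = [
        TypeFrequencyRow(
            cancer_type=ctype,
            patients=n,
            carriers=hits.get(ctype, 0),
            fraction=hits.get(ctype, 0) / n,
            included_in_figure=n > min_patients_exclusive,
        )
        for ctype, n in totals.items()
    ]
    rows.sort(key=lambda r: (-r.fraction, r.cancer_type))
    return rows


def write_type_frequency(rows: Sequence[TypeFrequencyRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("cancer_type\tpatients\tcarriers\tcarrier_pct\tincluded_in_figure\n")
        for r in rows:
            fh.write(f"{r.cancer_type}\t{r.patients}\t{r.carriers}"
                     f"\t{round_half_away(100 * r.fraction):g}"
                     f"\t{'true' if r.included_in_figure else 'false'}\n")
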