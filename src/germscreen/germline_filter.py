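"""Four-stage germline variant filter cascade.

Stages, in pipeline order:

1. ``quality``     — keep call_quality >= 20 and depth >= 10
2. ``population``  — keep pop_af <= 0.01, or known pathogenic common variants
3. ``consequence`` — keep coding non-synonymous and splice-site (+/-2 bp)
4. ``vaf``         — keep sample VAF > 0.20 (strict)

Rejection on the QC stage is OR-style: failing either quality or depth
rejects the call.  The four predicates are independent, so the final
kept set does not depend on stage order.  All thresholds can be
overridden through :class:`FilterThresholds`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .models import Consequence, VariantCall

STAGE_NAMES = ("quality", "population", "consequence", "vaf")

#: Consequences kept by the consequence filter (SPLICE_SITE additionally
#: requires |splice_offset| <= 2).
KEPT_CONSEQUENCES = frozenset({
    Consequence.FRAMESHIFT,
    Consequence.NONSENSE,
    Consequence.MISSENSE,
    Consequence.START_LOSS,
    Consequence.SPLICE_SITE,
})


@dataclass(frozen=True)
class FilterThresholds:
    min_quality: float = 20.0
    min_depth: int = 10
    max_pop_af: float = 0.01
    min_vaf: float = 0.20
    max_splice_offset: int = 2


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass
class FilterTrace:
    """Per-stage bookkeeping of the cascade."""

    stage_names: list[str] = field(default_factory=list)
    counts_in: dict[str, int] = field(default_factory=dict)
    counts_out: dict[str, int] = field(default_factory=dict)
    rejections: dict[tuple, str] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stage_names.append(stage)
        self.counts_in[stage] = n_in
        self.counts_out[stage] = n_out

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "in": self.counts_in[s], "out": self.counts_out[s]}
            for s in self.stage_names
        ]


# --- stage predicates -------------------------------------------------------

def passes_quality(v: VariantCall, t: FilterThresholds = DEFAULT_THRESHOLDS) -> bool:
    if v.call_quality is None or v.depth is None:
        return False
    return v.call_quality >= t.min_quality and v.depth >= t.min_depth


def passes_population(v: VariantCall, t: FilterThresholds = DEFAULT_THRESHOLDS) -> bool:
    # missing pop_af means absent from all databases -> 0.0
    pop_af = v.pop_af if v.pop_af is not None else 0.0
    return pop_af <= t.max_pop_af or v.known_pathogenic_common


def passes_consequence(v: VariantCall, t: FilterThresholds = DEFAULT_THRESHOLDS) -> bool:
    if v.consequence not in KEPT_CONSEQUENCES:
        return False
    if v.consequence is Consequence.SPLICE_SITE:
        return v.splice_offset != 0 and abs(v.splice_offset) <= t.max_splice_offset
    return True


def passes_vaf(v: VariantCall, t: FilterThresholds = DEFAULT_THRESHOLDS) -> bool:
    return v.vaf is not None and v.vaf > t.min_vaf


_PREDICATES: dict[str, Callable[[VariantCall, FilterThresholds], bool]] = {
    "quality": passes_quality,
    "population": passes_population,
    "consequence": passes_consequence,
    "vaf": passes_vaf,
}


def _reason(stage: str, v: VariantCall) -> str:
    if stage == "quality" and (v.call_quality is None or v.depth is None):
        return "missing_qc"
    return stage


def _apply_stage(
    stage: str,
    calls: Sequence[VariantCall],
    thresholds: FilterThresholds,
    trace: FilterTrace,
) -> list[VariantCall]:
    pred = _PREDICATES[stage]
    kept = []
    for v in calls:
        if pred(v, thresholds):
            kept.append(v)
        else:
            trace.rejections[v.key()] = _reason(stage, v)
    trace.record(stage, len(calls), len(kept))
    return kept


def _single(stage: str, calls, thresholds, trace):
    trace = trace if trace is not None else FilterTrace()
    kept = _apply_stage(stage, list(calls), thresholds or DEFAULT_THRESHOLDS, trace)
    return kept, trace


def filter_quality(calls, thresholds: FilterThresholds | None = None,
                   trace: FilterTrace | None = None):
    return _single("quality", calls, thresholds, trace)


def filter_population(calls, thresholds: FilterThresholds | None = None,
                      trace: FilterTrace | None = None):
    return _single("population", calls, thresholds, trace)


def filter_consequence(calls, thresholds: FilterThresholds | None = None,
                       trace: FilterTrace | None = None):
    return _single("consequence", calls, thresholds, trace)


def filter_vaf(calls, thresholds: FilterThresholds | None = None,
               trace: FilterTrace | None = None):
    return _single("vaf", calls, thresholds, trace)


def run_cascade(
    calls: Sequence[VariantCall],
    thresholds: FilterThresholds | None = None,
    order: Sequence[str] = STAGE_NAMES,
) -> tuple[list[VariantCall], FilterTrace]:
    """Apply the four filters in ``order`` and return (kept, trace).

    The kept set is invariant under permutations of ``order`` because
    every stage tests an independent predicate.
    """
    if sorted(order) != sorted(STAGE_NAMES):
        raise ValueError(f"order must be a permutation of {STAGE_NAMES}, got {order}")
    thresholds = thresholds or DEFAULT_THRESHOLDS
    trace = FilterTrace()
    kept = list(calls)
    for stage in order:
        kept = _apply_stage(stage, kept, thresholds, trace)
    return kept, trace


def write_trace(trace: FilterTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tin\tout\n")
        for row in trace.to_rows():
            fh.write(f"{row['stage']}\t{row['in']}\t{row['out']}\n")
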