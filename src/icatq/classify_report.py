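"""Cell-type classification, the dilution ceiling, and summary tables.

A protein's aggregated log2 heterocyst/filament ratio is compared
symmetrically against the calibrated cutoff (default log2(1.6) = 0.678)
to call it higher in heterocysts, higher in filaments (i.e. vegetative
cells) or evenly distributed. Because the filament sample itself
contains heterocysts at frequency f, the observable ratio of even a
strictly heterocyst-exclusive protein is capped at 1/f — the dilution
ceiling — and the same mixture algebra inverts to estimate the
vegetative-cell abundance from the filament and heterocyst measurements.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .quantify import ProteinRatio
from .simulate import MixtureModelParams

__all__ = [
    "ClassificationThreshold",
    "Call",
    "CellTypeCall",
    "CategorySummary",
    "classify",
    "theoretical_ceiling",
    "deconvolve_vegetative",
    "category_summary",
    "summary_to_frame",
    "unknown_function_candidates",
]

DEFAULT_CUTOFF_LOG2 = math.log2(1.6)

# Sub-function labels that count as "unknown function"
UNKNOWN_SUBFUNCTIONS = {"unassigned", "hypothetical", "conserved hypothetical"}


@dataclass(frozen=True)
class ClassificationThreshold:
    cutoff_log2: float = DEFAULT_CUTOFF_LOG2

    def __post_init__(self) -> None:
        if self.cutoff_log2 <= 0:
            raise ValueError("cutoff must be positive")


class Call(str, enum.Enum):
    HET_HIGHER = "HET_HIGHER"
    EQUAL = "EQUAL"
    FIL_HIGHER = "FIL_HIGHER"


# ordering of calls on the FIL < EQUAL < HET scale, used by the
# comparative module
CALL_ORDER = {Call.FIL_HIGHER: 0, Call.EQUAL: 1, Call.HET_HIGHER: 2}


@dataclass(frozen=True)
class CellTypeCall:
    locus_tag: str
    log2_ratio: float
    call: Call


@dataclass(frozen=True)
class CategorySummary:
    """Count breakdown of calls within one functional category."""

    category: str
    total: int
    n_het: int
    pct_het: int
    n_equal: int
    pct_equal: int
    n_fil: int
    pct_fil: int


def classify(
    ratios: Sequence[ProteinRatio],
    threshold: ClassificationThreshold = ClassificationThreshold(),
) -> list[CellTypeCall]:
    """Three-way cell-type call for each quantified protein.

    Boundary values (|log2 ratio| exactly at the cutoff) are called
    EQUAL: only ratios strictly beyond the threshold count as
    differential.
    """
    c = threshold.cutoff_log2
    calls = []
    for r in ratios:
        if r.log2_ratio > c:
            call = Call.HET_HIGHER
        elif r.log2_ratio < -c:
            call = Call.FIL_HIGHER
        else:
            call = Call.EQUAL
        calls.append(CellTypeCall(r.locus_tag, r.log2_ratio, call))
    return calls


def theoretical_ceiling(params: MixtureModelParams) -> float:
    """Maximum observable Het/Fil fold ratio, 1/f, for a heterocyst-exclusive protein."""
    return 1.0 / params.het_frequency_f


def deconvolve_vegetative(
    filament: float, heterocyst: float, params: MixtureModelParams
) -> tuple[float, bool]:
    """Invert F = f*H + (1-f)*V for the vegetative-cell abundance V.

    Returns ``(V, flagged)``; a negative algebraic solution means the
    measurements are inconsistent with the mixture model (e.g. noise on
    a heterocyst-exclusive protein) and is clipped to zero with the flag
    set.
    """
    if filament < 0 or heterocyst < 0:
        raise ValueError("abundances must be non-negative")
    f = params.het_frequency_f
    v = (filament - f * heterocyst) / (1.0 - f)
    if v < 0:
        return 0.0, True
    return v, False


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _summarise(category: str, calls: Sequence[CellTypeCall]) -> CategorySummary:
    total = len(calls)
    n_het = sum(1 for c in calls if c.call is Call.HET_HIGHER)
    n_equal = sum(1 for c in calls if c.call is Call.EQUAL)
    n_fil = sum(1 for c in calls if c.call is Call.FIL_HIGHER)
    pct = lambda n: _round_half_away(100.0 * n / total) if total else 0
    return CategorySummary(category, total, n_het, pct(n_het), n_equal, pct(n_equal), n_fil, pct(n_fil))


def category_summary(
    calls: Sequence[CellTypeCall],
    annotations: pd.DataFrame | None = None,
) -> list[CategorySummary]:
    """Functional-category breakdown of cell-type calls.

    One row per function class, one per (class, sub-function), plus a
    Total row; proteins without an annotation fall into class NA.
    Percentages are rounded half-away-from-zero to integers; the counts
    are the ground truth and always conserve.
    """
    def lookup(tag: str) -> tuple[str, str]:
        if annotations is not None and tag in annotations.index:
            row = annotations.loc[tag]
            cls = row.get("function_class") or "NA"
            sub = row.get("sub_function") or ""
            return str(cls), str(sub)
        return "NA", ""

    by_class: dict[str, list[CellTypeCall]] = {}
    by_sub: dict[tuple[str, str], list[CellTypeCall]] = {}
    for c in calls:
        cls, sub = lookup(c.locus_tag)
        by_class.setdefault(cls, []).append(c)
        if sub:
            by_sub.setdefault((cls, sub), []).append(c)

    out = [_summarise(cls, group) for cls, group in sorted(by_class.items())]
    out += [
        _summarise(f"{cls}/{sub}", group)
        for (cls, sub), group in sorted(by_sub.items())
    ]
    out.append(_summarise("Total", list(calls)))
    return out


def summary_to_frame(summaries: Sequence[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def unknown_function_candidates(
    calls: Sequence[CellTypeCall],
    ratios: Sequence[ProteinRatio],
    annotations: pd.DataFrame | None = None,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Heterocyst-enriched proteins of unknown function, ranked by ratio.

    Selects proteins annotated to unassigned/hypothetical sub-functions
    (or lacking annotation entirely) whose log2 ratio strictly exceeds
    log2(min_fold), sorted descending, with the replicate variability
    carried along.
    """
    cutoff = math.log2(min_fold)
    var = {r.locus_tag: r.variability_pct for r in ratios}

    def is_unknown(tag: str) -> bool:
        if annotations is None or tag not in annotations.index:
            return True
        sub = str(annotations.loc[tag].get("sub_function") or "").lower()
        cls = str(annotations.loc[tag].get("function_class") or "NA")
        return cls == "NA" or sub in UNKNOWN_SUBFUNCTIONS

    rows = [
        {
            "locus_tag": c.locus_tag,
            "log2_ratio": c.log2_ratio,
            "variability_pct": var.get(c.locus_tag, float("nan")),
        }
        for c in calls
        if c.log2_ratio > cutoff and is_unknown(c.locus_tag)
    ]
    df = pd.DataFrame(rows, columns=["locus_tag", "log2_ratio", "variability_pct"])
    return df.sort_values("log2_ratio", ascending=False, ignore_index=True)
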