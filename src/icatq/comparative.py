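"""Cross-dataset concordance of cell-type calls and transcript levels.

Two comparisons are supported: (i) the same protein's cell-type call in
newly formed versus steady-state heterocysts, collapsed to a four-way
concordance class (higher in heterocysts in both, lower in both, higher
only in the young dataset, higher only in the steady-state dataset);
and (ii) protein-level differential abundance against filament-level
transcript regulation, including the fraction of each transcript
cluster whose members show heterocyst-enriched protein levels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .classify_report import CALL_ORDER, Call, CellTypeCall, DEFAULT_CUTOFF_LOG2

__all__ = [
    "ConcordanceClass",
    "TranscriptRecord",
    "concordance",
    "concordance_summary",
    "transcript_protein_concordance",
]


class ConcordanceClass(str, enum.Enum):
    BOTH_HET = "BOTH_HET"            # higher in heterocysts in both datasets
    BOTH_FIL = "BOTH_FIL"            # lower in heterocysts in both datasets
    YOUNG_HET_ONLY = "YOUNG_HET_ONLY"    # relatively higher in newly formed heterocysts
    STEADY_HET_ONLY = "STEADY_HET_ONLY"  # relatively higher in steady-state heterocysts
    OTHER = "OTHER"                  # equal in both


@dataclass(frozen=True)
class TranscriptRecord:
    """Filament-level transcript fold change with the source study's own call."""

    locus_tag: str
    transcript_log2_fc: float
    differential: bool
    cluster: int | None = None


def concordance(call_young: CellTypeCall, call_steady: CellTypeCall) -> ConcordanceClass:
    """Collapse a pair of three-way calls onto the four concordance classes.

    Agreeing extreme calls map to BOTH_HET / BOTH_FIL; the (EQUAL, EQUAL)
    cell maps to OTHER. Any other combination is assigned to whichever
    dataset sits strictly higher on the ordered FIL < EQUAL < HET scale,
    so e.g. (EQUAL, HET_HIGHER) and (FIL_HIGHER, EQUAL) both indicate a
    relatively higher abundance in steady-state heterocysts.
    """
    if call_young.locus_tag != call_steady.locus_tag:
        raise ValueError(
            f"locus tag mismatch: {call_young.locus_tag} vs {call_steady.locus_tag}"
        )
    a, b = call_young.call, call_steady.call
    if a is Call.HET_HIGHER and b is Call.HET_HIGHER:
        return ConcordanceClass.BOTH_HET
    if a is Call.FIL_HIGHER and b is Call.FIL_HIGHER:
        return ConcordanceClass.BOTH_FIL
    if CALL_ORDER[a] > CALL_ORDER[b]:
        return ConcordanceClass.YOUNG_HET_ONLY
    if CALL_ORDER[a] < CALL_ORDER[b]:
        return ConcordanceClass.STEADY_HET_ONLY
    return ConcordanceClass.OTHER


def concordance_summary(
    calls_young: Sequence[CellTypeCall], calls_steady: Sequence[CellTypeCall]
) -> tuple[dict[ConcordanceClass, int], int, pd.DataFrame]:
    """Inner-join the two call sets and count concordance classes.

    Returns (counts per class, overlap size, per-protein table); the
    class counts always sum to the overlap size.
    """
    young = {c.locus_tag: c for c in calls_young}
    steady = {c.locus_tag: c for c in calls_steady}
    shared = sorted(set(young) & set(steady))
    counts = {cls: 0 for cls in ConcordanceClass}
    rows = []
    for tag in shared:
        cls = concordance(young[tag], steady[tag])
        counts[cls] += 1
        rows.append(
            {
                "locus_tag": tag,
                "log2_young": young[tag].log2_ratio,
                "log2_steady": steady[tag].log2_ratio,
                "call_young": young[tag].call.value,
                "call_steady": steady[tag].call.value,
                "concordance": cls.value,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["locus_tag", "log2_young", "log2_steady", "call_young", "call_steady", "concordance"],
    )
    return counts, len(shared), table


def transcript_protein_concordance(
    calls: Sequence[CellTypeCall],
    transcripts: Sequence[TranscriptRecord],
    cutoff_log2: float = DEFAULT_CUTOFF_LOG2,
) -> dict:
    """Protein-vs-transcript differential cross-tabulation.

    Joins protein calls with transcript records on locus tag and reports
    the fraction differential at each level — transcripts at the source
    dataset's own call, proteins at |log2 ratio| > cutoff — plus, per
    transcript cluster, the fraction of members with heterocyst-enriched
    protein calls.
    """
    call_by_tag = {c.locus_tag: c for c in calls}
    joined = [(t, call_by_tag[t.locus_tag]) for t in transcripts if t.locus_tag in call_by_tag]
    n = len(joined)
    result: dict = {
        "n_overlap": n,
        "n_transcript_differential": 0,
        "n_protein_differential": 0,
        "frac_transcript_differential": float("nan"),
        "frac_protein_differential": float("nan"),
        "cluster_het_fraction": {},
    }
    if n == 0:
        return result
    n_t = sum(1 for t, _ in joined if t.differential)
    n_p = sum(1 for _, c in joined if abs(c.log2_ratio) > cutoff_log2)
    result["n_transcript_differential"] = n_t
    result["n_protein_differential"] = n_p
    result["frac_transcript_differential"] = n_t / n
    result["frac_protein_differential"] = n_p / n
    by_cluster: dict[int, list[CellTypeCall]] = {}
    for t, c in joined:
        if t.cluster is not None:
            by_cluster.setdefault(t.cluster, []).append(c)
    result["cluster_het_fraction"] = {
        k: sum(1 for c in grp if c.call is Call.HET_HIGHER) / len(grp)
        for k, grp in sorted(by_cluster.items())
    }
    return result
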