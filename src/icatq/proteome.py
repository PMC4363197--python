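"""Proteome metadata: FASTA input, Cys content, molecular weight and pI.

A Cys-selective labeling strategy can only ever see the subset of a
proteome that contains at least one cysteine, so the first question for
any such experiment is what fraction of the theoretical proteome is
reachable at all, and how identification coverage varies with the number
of cysteines per protein. This module reads proteomes, attaches optional
functional annotation, and computes those coverage summaries together
with the classical Mw/pI scatter of theoretical versus identified
proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._constants import (
    AMINO_ACIDS,
    AVG_RESIDUE_MASS,
    MONO_RESIDUE_MASS,
    PKA_ACIDIC,
    PKA_BASIC,
    PKA_CTERM,
    PKA_NTERM,
    WATER_AVG,
    WATER_MONO,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "ProteomeSummary",
    "read_fasta",
    "read_annotations",
    "cys_coverage",
    "mol_weight",
    "net_charge",
    "isoelectric_point",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry keyed by its locus tag (e.g. ``Npun_F5511``)."""

    locus_tag: str
    sequence: str
    function_class: str | None = None
    sub_function: str | None = None
    localization: str | None = None

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.locus_tag}: empty sequence")


@dataclass
class ProteomeSummary:
    """Cys-count coverage bins plus the Mw/pI cloud of a proteome."""

    n_proteins: int
    frac_with_cys: float
    # cys count -> (n_total, n_identified, pct_identified)
    cys_bins: dict[int, tuple[int, int, float]]
    mw_pi_points: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n_cys": k, "n_total": t, "n_identified": i, "pct_identified": p}
            for k, (t, i, p) in sorted(self.cys_bins.items())
        ]
        return pd.DataFrame(rows, columns=["n_cys", "n_total", "n_identified", "pct_identified"])


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the locus tag.
    Sequences are uppercased and trailing/embedded ``*`` stop characters
    stripped. Entries containing ambiguous ``X`` residues are excluded
    with a warning (their masses would be guesses); any other
    non-amino-acid character is an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        tag = entry.id
        if tag in seen:
            raise ValueError(f"duplicate locus_tag in {path}: {tag}")
        seen.add(tag)
        seq = str(entry.seq).upper().replace("*", "")
        if "X" in seq:
            logger.warning("excluding %s: contains ambiguous residue X", tag)
            continue
        for pos, ch in enumerate(seq):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"{tag}: non-amino-acid character {ch!r} at position {pos}"
                )
        records.append(ProteinRecord(locus_tag=tag, sequence=seq))
    if not records and not seen:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a TSV annotation table (locus_tag, function_class, sub_function, localization)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "locus_tag" not in df.columns:
        raise ValueError("annotation table must have a locus_tag column")
    return df.set_index("locus_tag")


def annotate(records: Sequence[ProteinRecord], annotations: pd.DataFrame) -> list[ProteinRecord]:
    """Return new records with function class/sub-function attached where known."""
    out = []
    for r in records:
        if r.locus_tag in annotations.index:
            row = annotations.loc[r.locus_tag]
            out.append(
                ProteinRecord(
                    r.locus_tag,
                    r.sequence,
                    function_class=row.get("function_class"),
                    sub_function=row.get("sub_function"),
                    localization=row.get("localization"),
                )
            )
        else:
            out.append(r)
    return out


def cys_coverage(
    proteome: Sequence[ProteinRecord],
    identified: Iterable[str],
    with_mw_pi: bool = True,
) -> ProteomeSummary:
    """Coverage of the identified set across Cys-count bins.

    For each exact cysteine count the summary reports how many proteins
    the theoretical proteome holds and what percentage of them was
    identified. Sparsely populated high-Cys bins are reported as-is.
    """
    identified = set(identified)
    tags = {r.locus_tag for r in proteome}
    missing = identified - tags
    if missing:
        raise ValueError(f"identified tags absent from proteome: {sorted(missing)[:5]}")
    n = len(proteome)
    bins: dict[int, tuple[int, int, float]] = {}
    by_cys: dict[int, list[ProteinRecord]] = {}
    for r in proteome:
        by_cys.setdefault(r.n_cys, []).append(r)
    for k, group in by_cys.items():
        n_id = sum(1 for r in group if r.locus_tag in identified)
        bins[k] = (len(group), n_id, 100.0 * n_id / len(group))
    frac = sum(1 for r in proteome if r.n_cys >= 1) / n if n else 0.0
    points = (
        [
            (mol_weight(r.sequence, "average"), isoelectric_point(r.sequence))
            for r in proteome
        ]
        if with_mw_pi
        else []
    )
    return ProteomeSummary(n, frac, bins, points)


def mol_weight(sequence: str, mode: str = "average") -> float:
    """Molecular weight of a peptide/protein in Da.

    Sum of residue masses from the embedded table plus one water; ``mode``
    selects the average or monoisotopic table.
    """
    if mode == "average":
        table, water = AVG_RESIDUE_MASS, WATER_AVG
    elif mode == "monoisotopic":
        table, water = MONO_RESIDUE_MASS, WATER_MONO
    else:
        raise ValueError(f"unknown mode {mode!r}")
    try:
        return sum(table[aa] for aa in sequence) + water
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from None


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a sequence at a given pH."""
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    neg = 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for aa in sequence:
        if aa in PKA_BASIC:
            pos += 1.0 / (1.0 + 10.0 ** (ph - PKA_BASIC[aa]))
        elif aa in PKA_ACIDIC:
            neg += 1.0 / (1.0 + 10.0 ** (PKA_ACIDIC[aa] - ph))
    return pos - neg

def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """Isoelectric point by bisection on the net-charge curve.

    The terminal groups guarantee a zero crossing in (0, 14); charge is
    monotone decreasing in pH, so plain bisection converges.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
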