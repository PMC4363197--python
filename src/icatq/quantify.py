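"""Two-channel ICAT quantification: peak tables to protein log2 ratios.

The cleavable ICAT reagents derivatise cysteine thiols with either a
light (+227.127 Da) or heavy (+236.157 Da) tag, so the two channels of a
labeled peptide differ by 9.030 Da per cysteine. After avidin enrichment
only Cys-containing tryptic peptides remain; pairing light and heavy
precursor observations of the same charge state and dividing their ion
areas yields peptide-level ratios, which are rolled up to a per-protein
log2 light/heavy (here: heterocyst/filament) ratio across biological
replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._constants import ICAT_HEAVY_MASS, ICAT_LIGHT_MASS
from .proteome import mol_weight

logger = logging.getLogger(__name__)

__all__ = [
    "IcatTag",
    "PairMatchConfig",
    "PeptidePair",
    "ProteinRatio",
    "digest_trypsin",
    "enrich_cys",
    "labeled_mass",
    "match_pairs",
    "protein_rollup",
    "rollup_to_frame",
]


@dataclass(frozen=True)
class IcatTag:
    """Mass added per labeled cysteine by each ICAT channel."""

    light_mass: float = ICAT_LIGHT_MASS
    heavy_mass: float = ICAT_HEAVY_MASS

    @property
    def delta_per_cys(self) -> float:
        return self.heavy_mass - self.light_mass

    def __post_init__(self) -> None:
        if self.light_mass <= 0 or self.heavy_mass <= 0:
            raise ValueError("tag masses must be positive")
        if self.heavy_mass <= self.light_mass:
            raise ValueError("heavy tag must be heavier than light tag")


@dataclass(frozen=True)
class PairMatchConfig:
    mass_tolerance_ppm: float = 10.0
    require_same_charge: bool = True

    def __post_init__(self) -> None:
        if self.mass_tolerance_ppm <= 0:
            raise ValueError("mass tolerance must be positive")


@dataclass(frozen=True)
class PeptidePair:
    """A matched light/heavy precursor pair of the same charge state."""

    locus_tag: str
    peptide: str
    charge: int
    light_area: float
    heavy_area: float
    replicate: int

    @property
    def ratio_light_over_heavy(self) -> float:
        return self.light_area / self.heavy_area

    def __post_init__(self) -> None:
        if self.light_area <= 0 or self.heavy_area <= 0:
            raise ValueError("both channel areas must be positive")


@dataclass
class ProteinRatio:
    """Aggregated log2 light/heavy ratio of one protein across replicates."""

    locus_tag: str
    per_replicate_log2: list[float]
    log2_ratio: float
    variability_pct: float
    n_peptide_pairs: int


def digest_trypsin(sequence: str, max_missed_cleavages: int = 0) -> list[str]:
    """In-silico tryptic digest: cleave after K/R unless followed by P.

    Returns every peptide with 0..max_missed_cleavages missed cleavage
    sites, in N-to-C order (fully cleaved peptides first for each start).
    The 0-missed peptides concatenate back to the input sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    # indices after which cleavage occurs
    sites = [
        i + 1
        for i, aa in enumerate(sequence[:-1])
        if aa in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + sites + [len(sequence)]
    fragments = [sequence[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: list[str] = []
    for start in range(len(fragments)):
        for missed in range(max_missed_cleavages + 1):
            end = start + missed + 1
            if end > len(fragments):
                break
            peptides.append("".join(fragments[start:end]))
    return peptides


def enrich_cys(peptides: Iterable[str]) -> list[str]:
    """Avidin-enrichment model: only Cys-containing peptides survive."""
    return [p for p in peptides if "C" in p]


def labeled_mass(
    peptide: str, channel: str, tag: IcatTag = IcatTag(), mode: str = "monoisotopic"
) -> float:
    """Mass of an ICAT-labeled peptide: base mass + n_cys x channel tag mass."""
    n_cys = peptide.count("C")
    if n_cys == 0:
        raise ValueError(f"peptide {peptide!r} has no cysteine; cannot be ICAT-labeled")
    if channel == "light":
        tag_mass = tag.light_mass
    elif channel == "heavy":
        tag_mass = tag.heavy_mass
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return mol_weight(peptide, mode) + n_cys * tag_mass


def _peak_masses(peaks: pd.DataFrame, tag: IcatTag) -> np.ndarray:
    """Labeled masses for every peak row, preferring an explicit mass column."""
    cache: dict[tuple[str, str], float] = {}

    def compute(peptide: str, channel: str) -> float:
        key = (peptide, channel)
        if key not in cache:
            cache[key] = labeled_mass(peptide, channel, tag)
        return cache[key]

    masses = np.array(
        [compute(str(p), str(c)) for p, c in zip(peaks["peptide"], peaks["channel"])]
    )
    if "mass" in peaks.columns:
        explicit = peaks["mass"].to_numpy(dtype=float)
        masses = np.where(np.isnan(explicit), masses, explicit)
    return masses


def match_pairs(
    peaks: pd.DataFrame,
    tag: IcatTag = IcatTag(),
    config: PairMatchConfig = PairMatchConfig(),
) -> list[PeptidePair]:
    """Match light and heavy peaks into peptide pairs.

    Peaks pair iff they carry the same protein identification, share
    replicate (and sample, if present), share charge state when
    required, and their mass difference lies within the ppm tolerance of
    ``n_cys x delta_per_cys``. Each peak is used at most once; among
    candidate partners the nearest-mass match wins, remaining ties
    broken by larger summed area. Non-labelable peaks (no Cys) are
    dropped up front.
    """
    peaks = peaks.copy()
    peaks = peaks[peaks["peptide"].astype(str).str.contains("C")].reset_index(drop=True)
    if peaks.empty:
        return []
    peaks["_mass"] = _peak_masses(peaks, tag)
    group_cols = ["locus_tag", "replicate"]
    if "sample" in peaks.columns:
        group_cols.append("sample")
    if config.require_same_charge:
        group_cols.append("charge")

    pairs: list[PeptidePair] = []
    for _, grp in peaks.groupby(group_cols, sort=True):
        light = grp[grp["channel"] == "light"].sort_values("_mass")
        heavy = grp[grp["channel"] == "heavy"].sort_values("_mass")
        if light.empty or heavy.empty:
            continue
        h_mass = heavy["_mass"].to_numpy()
        h_area = heavy["area"].to_numpy()
        h_index = heavy.index.to_numpy()
        used = np.zeros(len(heavy), dtype=bool)
        for _, lrow in light.iterrows():
            n_cys = str(lrow["peptide"]).count("C")
            expected = lrow["_mass"] + n_cys * tag.delta_per_cys
            tol = expected * config.mass_tolerance_ppm * 1e-6
            lo = np.searchsorted(h_mass, expected - tol, side="left")
            hi = np.searchsorted(h_mass, expected + tol, side="right")
            cand = [i for i in range(lo, hi) if not used[i]]
            if not cand:
                continue
            if len(cand) > 1:
                cand.sort(key=lambda i: (abs(h_mass[i] - expected), -(lrow["area"] + h_area[i])))
                logger.debug(
                    "ambiguous pair match for %s/%s: %d candidates, nearest-mass wins",
                    lrow["locus_tag"], lrow["peptide"], len(cand),
                )
            best = cand[0]
            used[best] = True
            pairs.append(
                PeptidePair(
                    locus_tag=str(lrow["locus_tag"]),
                    peptide=str(lrow["peptide"]),
                    charge=int(lrow["charge"]),
                    light_area=float(lrow["area"]),
                    heavy_area=float(h_area[best]),
                    replicate=int(lrow["replicate"]),
                )
            )
    return pairs


def protein_rollup(
    pairs: Sequence[PeptidePair], min_replicates: int = 2
) -> tuple[list[ProteinRatio], int]:
    """Roll peptide pairs up to protein-level log2 ratios.

    Per replicate the protein ratio is the median of its peptide-pair
    ratios (robust to single outlier pairs); the aggregated log2 ratio is
    the mean of per-replicate log2 values, i.e. the geometric mean of the
    fold changes. Variability is the percent spread of the linear-scale
    replicate ratios: |r1-r2|/mean x 100 for two replicates, percent CV
    for more. Proteins missing any required replicate are dropped;
    returns (ratios, n_dropped).
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    by_protein: dict[str, dict[int, list[float]]] = {}
    npairs: dict[str, int] = {}
    for p in pairs:
        by_protein.setdefault(p.locus_tag, {}).setdefault(p.replicate, []).append(
            p.ratio_light_over_heavy
        )
        npairs[p.locus_tag] = npairs.get(p.locus_tag, 0) + 1
    out: list[ProteinRatio] = []
    dropped = 0
    for tag_, reps in sorted(by_protein.items()):
        if len(reps) < min_replicates:
            dropped += 1
            logger.debug("dropping %s: present in %d/%d replicates", tag_, len(reps), min_replicates)
            continue
        rep_ratios = [median(v) for _, v in sorted(reps.items())]
        rep_log2 = [math.log2(r) for r in rep_ratios]
        m = float(np.mean(rep_ratios))
        if len(rep_ratios) == 2:
            var_pct = 100.0 * abs(rep_ratios[0] - rep_ratios[1]) / abs(m)
        elif len(rep_ratios) > 2:
            var_pct = 100.0 * float(np.std(rep_ratios, ddof=1)) / abs(m)
        else:
            var_pct = 0.0
        out.append(
            ProteinRatio(
                locus_tag=tag_,
                per_replicate_log2=rep_log2,
                log2_ratio=float(np.mean(rep_log2)),
                variability_pct=var_pct,
                n_peptide_pairs=npairs[tag_],
            )
        )
    return out, dropped


def rollup_to_frame(ratios: Sequence[ProteinRatio]) -> pd.DataFrame:
    """Protein ratio table with one per-replicate log2 column each."""
    nrep = max((len(r.per_replicate_log2) for r in ratios), default=0)
    rows = []
    for r in ratios:
        row = {
            "locus_tag": r.locus_tag,
            "log2_ratio": r.log2_ratio,
            "variability_pct": r.variability_pct,
            "n_peptide_pairs": r.n_peptide_pairs,
        }
        for i in range(nrep):
            row[f"log2_rep{i + 1}"] = (
                r.per_replicate_log2[i] if i < len(r.per_replicate_log2) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
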