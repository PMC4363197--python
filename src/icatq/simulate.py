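"""Synthetic two-cell-type ICAT experiments.

Heterocyst-forming cyanobacteria cannot be measured one cell at a time
by shotgun proteomics; the accessible samples are an enriched heterocyst
fraction and the whole N2-fixing filament, a mixture in which
heterocysts occur at a low frequency f (about 7.5% of cells). For a
protein with per-cell abundance H in heterocysts and V in vegetative
cells the filament fraction therefore carries

    F = f*H + (1 - f)*V

so a heterocyst-exclusive protein (V = 0) can never show a
heterocyst/filament ratio above 1/f — about 13.3-fold at f = 0.075.

This module generates complete in-silico experiments around that model:
a random proteome, ground-truth cell-type abundance classes, labeled
peak tables with multiplicative lognormal noise, detection-limit
censoring and biological replicates, and known-ratio self-mixtures
(1:5, 1:1, 5:1) for accuracy calibration. The light channel is always
the heterocyst (numerator) and the heavy channel the filament
(denominator), matching the labeling convention used throughout the
package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import AA_BACKGROUND_FREQ, AMINO_ACIDS
from .proteome import ProteinRecord
from .quantify import digest_trypsin

__all__ = [
    "MixtureModelParams",
    "TruthClass",
    "GroundTruthProtein",
    "NoiseModel",
    "MixtureDesign",
    "DEFAULT_MIXTURE_DESIGNS",
    "simulate_proteome",
    "assign_ground_truth",
    "filament_abundance",
    "generate_peak_tables",
    "generate_calibration_mixture",
]

PEAK_COLUMNS = ["locus_tag", "peptide", "charge", "channel", "area", "replicate", "sample"]


@dataclass(frozen=True)
class MixtureModelParams:
    """Heterocyst frequency f of the two-cell-type dilution model."""

    het_frequency_f: float = 0.075

    def __post_init__(self) -> None:
        if not 0.0 < self.het_frequency_f < 1.0:
            raise ValueError("heterocyst frequency must lie in (0, 1)")


class TruthClass(str, enum.Enum):
    HET_EXCLUSIVE = "HET_EXCLUSIVE"
    HET_ENRICHED = "HET_ENRICHED"
    EQUAL = "EQUAL"
    FIL_ENRICHED = "FIL_ENRICHED"
    VEG_EXCLUSIVE = "VEG_EXCLUSIVE"


@dataclass(frozen=True)
class GroundTruthProtein:
    """Per-cell-type true abundance of one protein, in arbitrary copy units."""

    locus_tag: str
    abundance_het: float
    abundance_veg: float
    truth_class: TruthClass

    def __post_init__(self) -> None:
        if self.abundance_het < 0 or self.abundance_veg < 0:
            raise ValueError("abundances must be non-negative")
        if self.truth_class is TruthClass.HET_EXCLUSIVE and self.abundance_veg != 0:
            raise ValueError("HET_EXCLUSIVE requires abundance_veg = 0")
        if self.truth_class is TruthClass.VEG_EXCLUSIVE and self.abundance_het != 0:
            raise ValueError("VEG_EXCLUSIVE requires abundance_het = 0")
        if self.truth_class is TruthClass.EQUAL and self.abundance_het != self.abundance_veg:
            raise ValueError("EQUAL requires abundance_het = abundance_veg")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise on precursor areas with hard censoring.

    ``lognormal_sigma`` is the standard deviation of the natural-log area
    noise; the default 0.11 gives a protein-ratio CV at 1:1 mixing of
    roughly 16%, a realistic spread for replicated ICAT measurements.
    Peaks whose noisy area falls below ``detection_limit`` are censored.
    """

    lognormal_sigma: float = 0.11
    detection_limit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lognormal_sigma < 0 or self.detection_limit < 0:
            raise ValueError("sigma and detection limit must be non-negative")


@dataclass(frozen=True)
class MixtureDesign:
    """A known-ratio self-mixture (light:heavy) used for calibration."""

    name: str
    expected_light_to_heavy: float
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.expected_light_to_heavy <= 0:
            raise ValueError("expected ratio must be positive")


DEFAULT_MIXTURE_DESIGNS = (
    MixtureDesign("1to5", 0.2),
    MixtureDesign("1to1", 1.0),
    MixtureDesign("5to1", 5.0),
)


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (80, 450),
    cys_prob: float = 0.0138,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random proteome with i.i.d. residues and a controlled Cys frequency.

    Cysteine appears with probability ``cys_prob`` (the default mirrors a
    typical low bacterial Cys content of just over 1%); the remaining
    probability mass is spread over the other 19 residues according to a
    fixed background composition.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= cys_prob <= 1.0:
        raise ValueError("cys_prob must lie in [0, 1]")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    probs = np.array([AA_BACKGROUND_FREQ[a] if a != "C" else 0.0 for a in aas])
    probs = probs / probs.sum() * (1.0 - cys_prob)
    probs[list(aas).index("C")] = cys_prob
    width = max(len(str(n_proteins)), 4)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length, p=probs))
        records.append(ProteinRecord(f"SYN_{i:0{width}d}", seq))
    return records


def assign_ground_truth(
    proteome: Sequence[ProteinRecord],
    class_mix: Mapping[TruthClass | str, float],
    fold_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
) -> list[GroundTruthProtein]:
    """Assign cell-type abundance classes and true abundances.

    ``class_mix`` maps truth classes to fractions summing to one.
    Enriched proteins draw their fold change log-uniformly from
    ``fold_range`` (heterocyst-enriched: het/veg in the range;
    filament-enriched: the reciprocal). Base abundances are log-uniform
    over two decades so peak areas span a realistic dynamic range.
    """
    mix = {TruthClass(k): float(v) for k, v in class_mix.items()}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    lo, hi = fold_range
    if lo < 1.0 or hi < lo:
        raise ValueError(f"invalid fold range {fold_range}")
    rng = np.random.default_rng(seed)
    classes = list(mix.keys())
    weights = np.array([mix[c] for c in classes])
    out = []
    for rec in proteome:
        cls = classes[int(rng.choice(len(classes), p=weights))]
        base = float(10.0 ** rng.uniform(4.0, 6.0))
        fold = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if cls is TruthClass.EQUAL:
            het, veg = base, base
        elif cls is TruthClass.HET_EXCLUSIVE:
            het, veg = base, 0.0
        elif cls is TruthClass.VEG_EXCLUSIVE:
            het, veg = 0.0, base
        elif cls is TruthClass.HET_ENRICHED:
            het, veg = base * fold, base
        else:  # FIL_ENRICHED
            het, veg = base, base * fold
        out.append(GroundTruthProtein(rec.locus_tag, het, veg, cls))
    return out


def filament_abundance(gt: GroundTruthProtein, params: MixtureModelParams) -> float:
    """Whole-filament concentration F = f*H + (1-f)*V."""
    f = params.het_frequency_f
    return f * gt.abundance_het + (1.0 - f) * gt.abundance_veg


def _peptide_charge(peptide: str) -> int:
    """Deterministic nominal charge state: 2+, or 3+ for basic-residue-rich peptides."""
    return 3 if (peptide.count("K") + peptide.count("R") + peptide.count("H")) >= 3 else 2


def _emit_rows(
    channel_abundance: Mapping[str, dict[str, float]],
    peptides_by_protein: Mapping[str, list[str]],
    noise: NoiseModel,
    n_replicates: int,
    sample: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Shared peak-table emitter.

    Each peptide carries a per-peptide ionization factor shared between
    channels and replicates (it cancels in ratios, as in the real
    measurement); each peak then gets independent lognormal noise and is
    censored below the detection limit.
    """
    rows = []
    for tag, peptides in peptides_by_protein.items():
        abund = channel_abundance[tag]
        for pep in peptides:
            ion = float(10.0 ** rng.uniform(-1.0, 1.0))
            charge = _peptide_charge(pep)
            for rep in range(1, n_replicates + 1):
                for channel in ("light", "heavy"):
                    mu = abund[channel] * ion
                    if mu <= 0:
                        continue
                    area = mu * float(np.exp(rng.normal(0.0, noise.lognormal_sigma)))
                    if area < noise.detection_limit:
                        continue
                    rows.append((tag, pep, charge, channel, area, rep, sample))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def generate_peak_tables(
    ground_truth: Sequence[GroundTruthProtein],
    proteome: Sequence[ProteinRecord],
    params: MixtureModelParams = MixtureModelParams(),
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 2,
    sample: str = "het_vs_fil",
) -> pd.DataFrame:
    """Labeled peak table for the heterocyst-vs-filament experiment.

    Light channel areas follow the heterocyst abundance H, heavy channel
    areas the whole-filament mixture F = f*H + (1-f)*V. Only Cys-bearing
    tryptic peptides are emitted (Cys-free proteins are invisible to the
    ICAT workflow and contribute no rows).
    """
    rng = np.random.default_rng(noise.seed)
    seqs = {r.locus_tag: r.sequence for r in proteome}
    peptides_by_protein = {
        gt.locus_tag: list(
            dict.fromkeys(p for p in digest_trypsin(seqs[gt.locus_tag]) if "C" in p)
        )
        for gt in ground_truth
        if gt.locus_tag in seqs
    }
    channel_abundance = {
        gt.locus_tag: {
            "light": gt.abundance_het,
            "heavy": filament_abundance(gt, params),
        }
        for gt in ground_truth
    }
    return _emit_rows(channel_abundance, peptides_by_protein, noise, n_replicates, sample, rng)


def generate_calibration_mixture(
    design: MixtureDesign,
    ground_truth: Sequence[GroundTruthProtein],
    proteome: Sequence[ProteinRecord],
    params: MixtureModelParams = MixtureModelParams(),
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Known-ratio self-mixture peak table.

    Both channels derive from the same underlying whole-filament protein
    abundances; the light channel is scaled by the designed
    light:heavy ratio before noise, so the true ratio of every protein
    equals ``design.expected_light_to_heavy``.
    """
    rng = np.random.default_rng(noise.seed + 1)
    seqs = {r.locus_tag: r.sequence for r in proteome}
    peptides_by_protein = {
        gt.locus_tag: list(
            dict.fromkeys(p for p in digest_trypsin(seqs[gt.locus_tag]) if "C" in p)
        )
        for gt in ground_truth
        if gt.locus_tag in seqs
    }
    channel_abundance = {}
    for gt in ground_truth:
        base = filament_abundance(gt, params)
        channel_abundance[gt.locus_tag] = {
            "light": design.expected_light_to_heavy * base,
            "heavy": base,
        }
    return _emit_rows(
        channel_abundance, peptides_by_protein, noise, design.n_replicates,
        f"mix_{design.name}", rng,
    )
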