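"""Known-mixture accuracy statistics and empirical fold-change threshold.

Mixing the same labeled peptide pool with itself at designed light:heavy
ratios (1:5, 1:1, 5:1) turns quantification accuracy into a measurable:
every protein's true ratio is known, so the spread of recovered protein
ratios around the design value summarises the method's precision. The
1:1 self-mixture doubles as an empirical null: its 5th-percentile
protein ratio is the fold change below which only 5% of truly-unchanged
proteins fall, and its reciprocal is the smallest down-regulation
distinguishable from noise at that error rate. The analyst's cutoff
(default 1.6-fold, log2 0.678) is chosen at or above this implied fold
and applied symmetrically on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureStats",
    "ThresholdDerivation",
    "mixture_stats",
    "derive_threshold",
    "calibration_report",
    "report_to_text",
]

# Row order of the calibration report table
_REPORT_ROWS = [
    "Expected", "Average", "Median", "Stdev",
    "95th percentile", "5th percentile",
    "Variance", "Variance %", "Number of proteins analyzed",
]


@dataclass(frozen=True)
class MixtureStats:
    """Summary of recovered protein ratios for one known-ratio mixture."""

    expected: float
    average: float
    median: float
    stdev: float
    variance: float
    p95: float
    p5: float
    variance_pct: float
    n_proteins: int


@dataclass(frozen=True)
class ThresholdDerivation:
    """Empirical-null threshold derived from the 1:1 mixture ratios."""

    null_p5: float
    implied_fold: float
    chosen_cutoff_fold: float
    cutoff_log2: float
    alpha: float

    @property
    def conservative(self) -> bool:
        """True when the chosen cutoff is at least as strict as the implied fold."""
        return self.chosen_cutoff_fold >= self.implied_fold


def mixture_stats(protein_ratios: Sequence[float], expected: float) -> MixtureStats:
    """Accuracy summary of one mixture's protein-level ratios.

    Percentiles use linear interpolation (type-7); variance is the sample
    variance (ddof=1) and variance_pct = 100*variance/average.
    """
    ratios = np.asarray(protein_ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 protein ratios")
    if expected <= 0:
        raise ValueError("expected ratio must be positive")
    avg = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    return MixtureStats(
        expected=expected,
        average=avg,
        median=float(np.median(ratios)),
        stdev=sd,
        variance=sd**2,
        p95=float(np.percentile(ratios, 95)),
        p5=float(np.percentile(ratios, 5)),
        variance_pct=100.0 * sd**2 / avg,
        n_proteins=int(ratios.size),
    )


def derive_threshold(
    null_ratios: Sequence[float],
    alpha: float = 0.05,
    chosen_cutoff_fold: float = 1.6,
) -> ThresholdDerivation:
    """Empirical fold-change threshold from 1:1 null ratios.

    The alpha-quantile of the null ratio distribution bounds the false
    positive rate per tail: a protein called down at a fold stricter than
    1/null_p5 would be flagged in at most alpha of truly-unchanged
    proteins. The chosen analyst cutoff is recorded alongside, never
    silently substituted for the implied value.
    """
    ratios = np.asarray(null_ratios, dtype=float)
    if ratios.size < 20:
        raise ValueError("need >= 20 null ratios for a stable 5th percentile")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if chosen_cutoff_fold < 1.0:
        raise ValueError("cutoff fold must be >= 1")
    p = float(np.quantile(ratios, alpha))
    return ThresholdDerivation(
        null_p5=p,
        implied_fold=1.0 / p,
        chosen_cutoff_fold=chosen_cutoff_fold,
        cutoff_log2=math.log2(chosen_cutoff_fold),
        alpha=alpha,
    )


def calibration_report(stats: Mapping[str, MixtureStats]) -> pd.DataFrame:
    """Accuracy table: one column per mixture, rows in the canonical order."""
    if not stats:
        raise ValueError("need at least one mixture")
    cols = {}
    for name, s in stats.items():
        cols[name] = [
            s.expected, s.average, s.median, s.stdev, s.p95, s.p5,
            s.variance, s.variance_pct, s.n_proteins,
        ]
    return pd.DataFrame(cols, index=_REPORT_ROWS)


def report_to_text(report: pd.DataFrame, digits: int = 3) -> str:
    """Human-readable rendering with identical values to the TSV."""
    def fmt(row: str, v: float) -> str:
        if row == "Number of proteins analyzed":
            return str(int(v))
        return f"{v:.{digits}g}"

    out = pd.DataFrame(
        {col: [fmt(row, report.loc[row, col]) for row in report.index]
         for col in report.columns},
        index=report.index,
    )
    return out.to_string()
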