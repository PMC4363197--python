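"""End-to-end pipeline: simulate -> quantify -> calibrate -> classify -> compare.

Each stage writes its TSV output plus a log of dropped records, and a
MANIFEST file lists every output with a SHA-256 content hash so that a
rerun with the same configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import icatq.calibration as calib
import icatq.comparative as comp
import icatq.quantify as qt
import icatq.simulate as sim
from .classify_report import (
    Call,
    ClassificationThreshold,
    category_summary,
    classify,
    summary_to_frame,
    unknown_function_candidates,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_CLASS_MIX = {
    sim.TruthClass.HET_EXCLUSIVE: 0.05,
    sim.TruthClass.HET_ENRICHED: 0.20,
    sim.TruthClass.EQUAL: 0.40,
    sim.TruthClass.FIL_ENRICHED: 0.30,
    sim.TruthClass.VEG_EXCLUSIVE: 0.05,
}


@dataclass
class RunConfig:
    """Configuration for one full synthetic-experiment run."""

    seed: int = 0
    het_frequency_f: float = 0.075
    lognormal_sigma: float = 0.11
    detection_limit: float = 0.0
    n_proteins: int = 300
    n_replicates: int = 2
    alpha: float = 0.05
    cutoff_fold: float = 1.6
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    fold_range: tuple[float, float] = (2.0, 8.0)
    out_dir: Path = Path("icatq_run")

    def __post_init__(self) -> None:
        if not 0.0 < self.het_frequency_f < 1.0:
            raise ValueError("het_frequency_f must lie in (0, 1)")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.cutoff_fold < 1.0:
            raise ValueError("cutoff_fold must be >= 1")

    @classmethod
    def from_file(cls_, path: str | Path) -> "RunConfig":
        """Read a flat key=value config file; unknown keys are an error."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in {"seed", "n_proteins", "n_replicates"}:
                kwargs[key] = int(value)
            elif key in {"het_frequency_f", "lognormal_sigma", "detection_limit",
                         "alpha", "cutoff_fold"}:
                kwargs[key] = float(value)
            elif key == "out_dir":
                kwargs[key] = Path(value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls_(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data and write all outputs.

    Returns a result dictionary with the calibration report, threshold
    derivation, calls, summaries and concordance counts; raises on the
    first stage error (partial outputs remain on disk).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = sim.MixtureModelParams(config.het_frequency_f)
    noise = sim.NoiseModel(config.lognormal_sigma, config.detection_limit, seed=config.seed)

    # --- simulate
    proteome = sim.simulate_proteome(config.n_proteins, seed=config.seed)
    truth = sim.assign_ground_truth(
        proteome, config.class_mix, config.fold_range, seed=config.seed + 1
    )
    peaks = sim.generate_peak_tables(
        truth, proteome, params, noise, n_replicates=config.n_replicates
    )
    _write_tsv(peaks, out / "peaks_het_vs_fil.tsv")
    truth_df = pd.DataFrame(
        [
            {"locus_tag": t.locus_tag, "abundance_het": t.abundance_het,
             "abundance_veg": t.abundance_veg, "truth_class": t.truth_class.value}
            for t in truth
        ]
    )
    _write_tsv(truth_df, out / "ground_truth.tsv")

    mixture_peaks = {}
    for i, design in enumerate(sim.DEFAULT_MIXTURE_DESIGNS):
        mix_noise = sim.NoiseModel(
            config.lognormal_sigma, config.detection_limit, seed=config.seed + 10 + i
        )
        mixture_peaks[design.name] = (design, sim.generate_calibration_mixture(
            design, truth, proteome, params, mix_noise
        ))
        _write_tsv(mixture_peaks[design.name][1], out / f"peaks_mix_{design.name}.tsv")

    # --- quantify
    pairs = qt.match_pairs(peaks)
    ratios, n_dropped = qt.protein_rollup(pairs, min_replicates=config.n_replicates)
    ratio_frame = qt.rollup_to_frame(ratios)
    _write_tsv(ratio_frame, out / "protein_ratios.tsv")
    logger.info("quantified %d proteins (%d dropped by replicate filter)", len(ratios), n_dropped)

    # --- calibrate
    stats = {}
    null_ratios: list[float] = []
    for name, (design, mix_pk) in mixture_peaks.items():
        mix_pairs = qt.match_pairs(mix_pk)
        mix_ratios, _ = qt.protein_rollup(mix_pairs, min_replicates=config.n_replicates)
        linear = [2.0 ** r.log2_ratio for r in mix_ratios]
        stats[name] = calib.mixture_stats(linear, design.expected_light_to_heavy)
        if design.expected_light_to_heavy == 1.0:
            null_ratios = linear
    report = calib.calibration_report(stats)
    report.to_csv(out / "calibration.tsv", sep="\t")
    threshold = calib.derive_threshold(
        null_ratios, alpha=config.alpha, chosen_cutoff_fold=config.cutoff_fold
    )
    (out / "threshold.json").write_text(json.dumps(threshold.__dict__, indent=2) + "\n")

    # --- classify
    thr = ClassificationThreshold(math.log2(config.cutoff_fold))
    calls = classify(ratios, thr)
    calls_df = pd.DataFrame(
        [{"locus_tag": c.locus_tag, "log2_ratio": c.log2_ratio, "call": c.call.value}
         for c in calls]
    )
    _write_tsv(calls_df, out / "calls.tsv")
    summaries = category_summary(calls, annotations=None)
    _write_tsv(summary_to_frame(summaries), out / "category_summary.tsv")
    candidates = unknown_function_candidates(calls, ratios, annotations=None)
    _write_tsv(candidates, out / "candidates.tsv")

    # --- compare: a second, independently seeded run stands in for the
    # steady-state dataset so the concordance stage is exercised end-to-end
    noise2 = sim.NoiseModel(config.lognormal_sigma, config.detection_limit, seed=config.seed + 100)
    peaks2 = sim.generate_peak_tables(
        truth, proteome, params, noise2, n_replicates=config.n_replicates
    )
    ratios2, _ = qt.protein_rollup(qt.match_pairs(peaks2), min_replicates=config.n_replicates)
    calls2 = classify(ratios2, thr)
    counts, overlap, conc_table = comp.concordance_summary(calls, calls2)
    _write_tsv(conc_table, out / "concordance.tsv")
    conc_summary = {c.value: n for c, n in counts.items()}
    conc_summary["overlap"] = overlap
    (out / "concordance_summary.json").write_text(json.dumps(conc_summary, indent=2) + "\n")

    # --- manifest
    manifest_lines = []
    for path in sorted(out.iterdir()):
        if path.name == "MANIFEST":
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest_lines.append(f"{digest}  {path.name}")
    (out / "MANIFEST").write_text("\n".join(manifest_lines) + "\n")

    return {
        "proteome": proteome,
        "truth": truth,
        "ratios": ratios,
        "calibration": report,
        "threshold": threshold,
        "calls": calls,
        "summaries": summaries,
        "concordance_counts": counts,
        "overlap": overlap,
        "n_dropped": n_dropped,
    }
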