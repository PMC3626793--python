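"""End-to-end orchestration: quantify -> normalize -> filter (-> SRM).

`run_pipeline` drives the discovery workflow over one control pair and N
experimental pairs: peptide evidence is aggregated into protein H/L
ratios, median-log normalized, scored for outlier significance, the
control-pair variability model is fitted, and the candidate cascade is
applied.  Optionally, an SRM peak-area table is then normalized and
quantified.  Every stage writes its table to the output directory and the
run finishes with a machine-readable JSON report (stage counts,
exclusion-reason histogram, thresholds, seed), so identical configuration
and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as aq_io
from .candidates import (
    PairDesign,
    build_initial_candidates,
    filter_consistent,
    fit_control_variability,
    select_high_probability,
    stage_counts,
)
from .errors import ConfigurationError, DesignError
from .silac import aggregate_evidence, normalize_ratios, significance_a, significance_b
from .simulate import (
    CONTROL_PAIR_ID,
    SilacSimConfig,
    SrmSimConfig,
    experimental_pair_id,
    simulate_silac_experiment,
    simulate_srm_experiment,
)
from .srm_quant import normalize_housekeeping, normalize_replicates, protein_ratio

__all__ = ["PipelineConfig", "run_pipeline", "quantify_pair", "default_pair_designs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Either ``evidence_paths`` (pair id -> evidence table path) or
    ``silac_sim`` (simulate the evidence in-run) must be given.  Threshold
    defaults follow the analysis design: 2-sigma outlier interval,
    0.5-sigma "no clear change" interval, alpha 0.05 on the significance
    scores, minimum 3 peptide ratio counts for quantification, razor_min 3
    for the sign-conflict filter, intensity bins of 300 proteins for
    Significance B, Huber tuning constant 1.345 for SRM replicate
    alignment.
    """

    pair_designs: Sequence[PairDesign] = ()
    evidence_paths: Mapping[str, str] | None = None
    silac_sim: SilacSimConfig | None = None
    srm_areas_path: str | None = None
    srm_sim: SrmSimConfig | None = None
    sigma_mult: float = 2.0
    half_sigma_mult: float = 0.5
    alpha: float = 0.05
    min_ratio_count: int = 3
    razor_min: int = 3
    min_razor_peptides: int = 2
    bin_size: int = 300
    huber_c: float = 1.345
    seed: int = 0
    output_dir: str = "amnioquant_run"

    def validate(self) -> None:
        for name in ("sigma_mult", "half_sigma_mult", "alpha", "huber_c"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("min_ratio_count", "razor_min", "min_razor_peptides", "bin_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.evidence_paths is None and self.silac_sim is None:
            raise ConfigurationError("either evidence_paths or silac_sim is required")
        if self.silac_sim is not None:
            self.silac_sim.validate()
        if self.srm_sim is not None:
            self.srm_sim.validate()
        designs = list(self.pair_designs)
        if not designs:
            raise ConfigurationError("pair_designs must not be empty")
        n_exp = sum(1 for d in designs if d.pair_type == "experimental")
        n_ctl = sum(1 for d in designs if d.pair_type == "control")
        if n_ctl != 1:
            raise DesignError(f"exactly one control pair required, got {n_ctl}")
        if n_exp == 0:
            raise DesignError("at least one experimental pair required")
        if self.evidence_paths is not None:
            missing = [d.pair_id for d in designs if d.pair_id not in self.evidence_paths]
            if missing:
                raise ConfigurationError(f"evidence_paths missing pairs: {missing}")


def default_pair_designs(n_experimental: int = 3) -> list[PairDesign]:
    """One control pair plus ``n_experimental`` experimental pairs."""
    designs = [PairDesign(CONTROL_PAIR_ID, "control", "CN", 16.0)]
    for i in range(1, n_experimental + 1):
        designs.append(
            PairDesign(experimental_pair_id(i), "experimental", "T21", 15.0 + i)
        )
    return designs


def quantify_pair(
    evidence: pd.DataFrame,
    min_ratio_count: int = 3,
    bin_size: int = 300,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify one pair: aggregate, normalize, score significance.

    Returns the protein-group table (significance columns filled) and the
    evidence table augmented with ``log2_ratio_normalized`` per peptide row
    (raw log2 ratio minus the pair's normalization shift), which the final
    candidate rules consume.
    """
    proteins = aggregate_evidence(evidence, min_ratio_count=min_ratio_count)
    proteins = normalize_ratios(proteins)
    proteins = significance_a(proteins)
    proteins = significance_b(proteins, bin_size=bin_size)

    shift = proteins.attrs["normalization_log2_shift"]
    augmented = evidence.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_log2 = np.log2(augmented["ratio_hl"].to_numpy(float))
    augmented["log2_ratio_normalized"] = raw_log2 - shift
    return proteins, augmented


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured workflow and return the run report."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    designs = list(config.pair_designs)
    control_id = next(d.pair_id for d in designs if d.pair_type == "control")
    experimental_ids = [d.pair_id for d in designs if d.pair_type == "experimental"]

    # --- inputs -----------------------------------------------------------
    if config.silac_sim is not None:
        sim_config = dataclasses.replace(config.silac_sim, seed=config.seed)
        evidence, truth = simulate_silac_experiment(sim_config)
        truth.to_csv(out_dir / "silac_truth.tsv", sep="\t", index=False)
        missing = [pid for pid in (control_id, *experimental_ids) if pid not in evidence]
        if missing:
            raise DesignError(f"simulation produced no evidence for pairs {missing}")
    else:
        evidence = {
            pid: aq_io.read_evidence(config.evidence_paths[pid])
            for pid in (control_id, *experimental_ids)
        }

    # --- silac quantification --------------------------------------------
    pair_tables: dict[str, pd.DataFrame] = {}
    pair_evidence: dict[str, pd.DataFrame] = {}
    for pid in (control_id, *experimental_ids):
        proteins, augmented = quantify_pair(
            evidence[pid],
            min_ratio_count=config.min_ratio_count,
            bin_size=config.bin_size,
        )
        pair_tables[pid] = proteins
        pair_evidence[pid] = augmented
        aq_io.write_protein_groups(proteins, out_dir / f"protein_groups_{pid}.tsv")

    # --- candidate cascade -------------------------------------------------
    model = fit_control_variability(
        pair_tables[control_id],
        sigma_mult=config.sigma_mult,
        half_sigma_mult=config.half_sigma_mult,
    )
    candidates = build_initial_candidates(pair_tables, designs, model, alpha=config.alpha)
    candidates = filter_consistent(candidates, razor_min=config.razor_min)
    candidates = select_high_probability(
        candidates, model, pair_evidence, min_razor_peptides=config.min_razor_peptides
    )
    candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)

    counts = stage_counts(candidates)
    reason_histogram: dict[str, int] = {}
    for reasons in candidates.get("exclusion_reasons", pd.Series(dtype=str)).fillna(""):
        for reason in str(reasons).split(";"):
            if reason:
                reason_histogram[reason] = reason_histogram.get(reason, 0) + 1

    high = candidates[candidates["stage"] == "high_probability"] if len(candidates) else candidates
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "sigma_mult": config.sigma_mult,
            "half_sigma_mult": config.half_sigma_mult,
            "alpha": config.alpha,
            "min_ratio_count": config.min_ratio_count,
            "razor_min": config.razor_min,
            "min_razor_peptides": config.min_razor_peptides,
            "bin_size": config.bin_size,
            "huber_c": config.huber_c,
        },
        "control_model": model.to_dict(),
        "pairs": {
            pid: {
                "n_proteins": int(len(pair_tables[pid])),
                "n_quantified": int(
                    np.isfinite(pair_tables[pid]["ratio_hl_raw"].to_numpy(float)).sum()
                ),
            }
            for pid in (control_id, *experimental_ids)
        },
        "candidates": {
            "pooled_outliers": counts["pooled"],
            "initial": counts["initial"],
            "consistency_filtered": counts["consistency_filtered"],
            "high_probability": counts["high_probability"],
            "exclusion_reasons": reason_histogram,
            "n_increased": int((high["direction"] == "increased").sum()) if len(high) else 0,
            "n_decreased": int((high["direction"] == "decreased").sum()) if len(high) else 0,
        },
        "metadata": {
            "significance_thresholds": "applied per pair",
            "outlier_interval": "control-pair interval applied verbatim to experimental pairs",
            "manual_curation": "replaced by deterministic consistency rules",
        },
    }

    # --- optional SRM stage -------------------------------------------------
    srm_table = None
    if config.srm_sim is not None:
        srm_sim = dataclasses.replace(config.srm_sim, seed=config.seed)
        srm_table, _srm_truth = simulate_srm_experiment(srm_sim)
        aq_io.write_srm_areas(srm_table, out_dir / "srm_areas.csv")
    elif config.srm_areas_path is not None:
        srm_table = aq_io.read_srm_areas(config.srm_areas_path)

    if srm_table is not None:
        normalized, _models = normalize_replicates(srm_table, tuning_constant=config.huber_c)
        housekeeping = sorted(
            set(srm_table.loc[srm_table["protein_id"] == "HOUSEKEEPING", "peptide"])
        )
        if housekeeping:
            normalized = normalize_housekeeping(normalized, housekeeping)
        t21_samples = sorted(normalized.loc[normalized["group"] == "T21", "sample_id"].unique())
        cn_samples = sorted(normalized.loc[normalized["group"] == "CN", "sample_id"].unique())
        results = []
        proteins = sorted(
            set(normalized["protein_id"]) - {"HOUSEKEEPING"}
        )
        for t21_s, cn_s in zip(t21_samples, cn_samples):
            t21_df = normalized[normalized["sample_id"] == t21_s]
            cn_df = normalized[normalized["sample_id"] == cn_s]
            for protein in proteins:
                res = protein_ratio(t21_df, cn_df, protein)
                results.append(
                    {
                        "protein_id": res.protein_id,
                        "t21_sample": res.t21_sample,
                        "cn_sample": res.cn_sample,
                        "ratio_t21_cn": res.ratio_t21_cn,
                        "mean_cv_percent": res.mean_cv_percent,
                        "p_value": res.p_value,
                    }
                )
        srm_results = pd.DataFrame(results)
        srm_results.to_csv(out_dir / "srm_results.tsv", sep="\t", index=False)
        report["srm"] = {
            "n_samples": int(normalized["sample_id"].nunique()),
            "n_proteins": len(proteins),
            "n_comparisons": int(len(srm_results)),
        }

    with open(out_dir / "run_report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    logger.info("run complete: %s", out_dir / "run_report.json")
    return report
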