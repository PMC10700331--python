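"""End-to-end pipeline: simulate -> genotype -> assemble -> associate -> WoE -> ROC.

Stages are individually toggleable; each writes its tabular artifact
(CSV/FASTA/JSON) under the configured output directory and contributes to a
single consolidated JSON report. Identical configuration and seed produce a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import association as assoc
from . import cohort as cohort_mod
from . import rflp
from . import simulate as sim
from .datasets import (
    PUBLISHED_ALLELE_FREQUENCIES,
    load_study_counts,
)
from .exceptions import ConfigurationError
from .model import KetosisAssociation

logger = logging.getLogger("ketogene.pipeline")

_STAGES = ("simulate", "genotype", "assemble", "associate", "woe", "roc")


@dataclass
class PipelineConfig:
    """Stage toggles, stage parameters and IO paths for one pipeline run."""

    stages: tuple[str, ...] = _STAGES
    out_dir: str = "ketogene_out"
    input_csv: str | None = None  # None => the simulate stage must be enabled
    use_study_counts: bool = False  # analyze the packaged counts table instead
    seed: int = 0
    n_animals: int = 979
    bhb_threshold: float = cohort_mod.DEFAULT_BHB_THRESHOLD
    woe_max_gap: float = 30.0
    zero_cell_policy: str = "continuity"
    roc_mode: str = "probability"
    roc_positive: str = "resistant"
    alpha: float = 0.05
    simulation: dict = field(default_factory=dict)  # extra SimulationConfig fields

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        needs_data = {"assemble", "associate", "woe", "roc"} & set(self.stages)
        if (
            needs_data
            and "simulate" not in self.stages
            and self.input_csv is None
            and not self.use_study_counts
        ):
            raise ConfigurationError(
                "analysis stages need an input: enable 'simulate', give "
                "input_csv, or set use_study_counts"
            )
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigurationError(f"input_csv does not exist: {self.input_csv}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the report dict.

    Partial artifacts are retained when a stage fails; the raised error
    names the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "bhb_threshold": config.bhb_threshold,
            "woe_max_gap": config.woe_max_gap,
            "zero_cell_policy": config.zero_cell_policy,
            "roc_mode": config.roc_mode,
            "roc_positive": config.roc_positive,
            "alpha": config.alpha,
        },
        "warnings": [],
    }
    if not config.stages:
        report["warnings"].append("no stages enabled; empty report")
        _write_report(report, out)
        return report

    stage = "setup"
    records = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            cfg = sim.SimulationConfig(
                n_animals=config.n_animals, seed=config.seed, **config.simulation
            )
            cohort = sim.simulate_cohort(cfg)
            records = cohort.records
            cohort.to_csv(out / "cohort.csv")
            report["simulate"] = {
                "n_animals": cfg.n_animals,
                "allele_freq_C": cfg.allele_freq_C,
                "penetrance": dict(cfg.penetrance),
                "n_contaminated": int(records["contaminated"].sum()),
            }
            logger.info("simulated %d records (seed %d)", cfg.n_animals, config.seed)
        elif config.input_csv is not None:
            records = cohort_mod.load_cohort_csv(config.input_csv)

        if "genotype" in config.stages:
            stage = "genotype"
            ref = sim.synthesize_reference(config.seed)
            ref.write_fasta(out / "reference_alleles.fasta")
            ladders = {}
            for allele in ("C", "T"):
                amplicon = rflp.extract_amplicon(ref.template(allele), ref.primers)
                ladders[allele] = rflp.digest(amplicon, ref.enzyme, allele_label=allele)
            call_het = rflp.call_genotype(
                sorted(set(ladders["C"].distinct_bands) | set(ladders["T"].distinct_bands)),
                ladders["C"],
                ladders["T"],
            )
            report["genotype"] = {
                "enzyme": ref.enzyme.name,
                "amplicon_length": ladders["C"].total_length,
                "ladder_C": list(ladders["C"].fragments),
                "ladder_T": list(ladders["T"].fragments),
                "heterozygote_call_check": call_het.genotype,
            }
            logger.info("in-silico assay check: het pattern calls %s", call_het.genotype)

        analysis_input = None
        if config.use_study_counts:
            model = KetosisAssociation.from_counts(load_study_counts())
        elif records is not None:
            stage = "assemble"
            if "assemble" in config.stages:
                dataset, n_removed = cohort_mod.assemble(records, config.bhb_threshold)
                dataset.to_csv(out / "dataset.csv", index=False)
                cohort_mod.descriptives_by_lactation(records).to_csv(
                    out / "descriptives.csv", index=False
                )
                report["assemble"] = {
                    "n_input": len(records),
                    "n_removed": n_removed,
                    "n_analyzable": len(dataset),
                }
                model = KetosisAssociation(dataset)
                model.n_removed = n_removed
            else:
                model = KetosisAssociation.from_cohort(records, config.bhb_threshold)
        else:
            model = None

        if {"associate", "woe", "roc"} & set(config.stages):
            stage = "associate"
            if model is None:
                raise ConfigurationError("no analysis input available")
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                results = model.fit(
                    max_gap=config.woe_max_gap,
                    zero_cell_policy=config.zero_cell_policy,
                    roc_mode=config.roc_mode,
                    positive=config.roc_positive,
                    alpha=config.alpha,
                )
            report["warnings"] += [str(w.message) for w in caught]
            report["analysis"] = results.to_report_dict()
            report["warnings"] += results.consistency_warnings(
                PUBLISHED_ALLELE_FREQUENCIES if config.use_study_counts else None
            )
            results.table.to_dataframe().to_csv(out / "contingency_table.csv")
            results.woe_merged.to_dataframe().to_csv(out / "woe.csv", index=False)
            results.roc.to_dataframe().to_csv(out / "roc.csv", index=False)
            (out / "summary.txt").write_text(results.summary() + "\n")
    except Exception as exc:
        _write_report(report, out)
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
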