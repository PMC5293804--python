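"""End-to-end orchestration: simulate -> extract -> QC -> inference -> report.

``run_pipeline`` writes a complete, reproducible report bundle: the dataset
CSV, the per-trial parameter TSV, the exclusion report, the inference TSVs and
a run manifest (config + seed + software version). Identical manifests yield
byte-identical outputs. On a stage failure the partial outputs are kept next
to a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError, ReachGraspError
from .kinematics import SegmentationConfig, process_dataset
from .qc import filter_participants
from .stats import (
    PARAMETERS,
    anova_table,
    bayes_table,
    condition_means,
    jzs_bf_anova,
    planned_ttests,
    rm_anova,
    summarize_means,
    ttest_table,
)
from .synthgen import GeneratorConfig, preset, simulate_experiment
from .trajio import write_dataset, write_params_table, write_tsv


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    The segmentation variant must match the sampling-rate convention
    (displacement rule at 60 Hz, velocity rule at 200 Hz); a mismatch is
    allowed but recorded as a warning in the manifest.
    """

    generator: GeneratorConfig
    segmentation: SegmentationConfig | None = None
    seed: int = 0
    min_valid_fraction: float = 0.5
    ttest_alpha: float = 0.05
    ttest_correction: str = "bonferroni"
    bf_mc_samples: int = 20000
    anova_parameters: tuple[str, ...] = ("pct_t_vpeak", "t_vpeak_ms", "reach_time_ms")

    def __post_init__(self) -> None:
        if self.segmentation is None:
            self.segmentation = SegmentationConfig(
                variant=self.generator.segmentation_variant()
            )
        self.segmentation.validate_rate(self.generator.sampling_rate_hz)

    def variant_warning(self) -> str | None:
        expected = self.generator.segmentation_variant()
        if self.segmentation.variant != expected:
            return (
                f"segmentation variant {self.segmentation.variant!r} does not match "
                f"the {self.generator.sampling_rate_hz:g} Hz convention ({expected!r})"
            )
        return None


def _manifest(config: RunConfig) -> dict:
    gen = dataclasses.asdict(config.generator)
    gen["condition_means"] = {
        "_".join(cell): dataclasses.asdict(cm)
        for cell, cm in config.generator.condition_means.items()
    }
    manifest = {
        "software": {"name": "reachgrasp", "version": __version__},
        "seed": config.seed,
        "generator": gen,
        "segmentation": dataclasses.asdict(config.segmentation),
        "min_valid_fraction": config.min_valid_fraction,
        "ttest": {"alpha": config.ttest_alpha, "correction": config.ttest_correction},
        "bf_mc_samples": config.bf_mc_samples,
        "anova_parameters": list(config.anova_parameters),
    }
    warning = config.variant_warning()
    if warning:
        manifest["warnings"] = [warning]
    return manifest


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages and write the report bundle into ``outdir``.

    Returns a dict with the in-memory results (params table, means, inference
    tables). Stage errors propagate with the stage name; partial outputs stay
    on disk next to a FAILED marker.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        manifest = _manifest(config)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

        stage = "simulate"
        dataset = simulate_experiment(config.generator, seed=config.seed)
        write_dataset(dataset, out / "dataset.csv")

        stage = "extract"
        params = process_dataset(dataset, config.segmentation)
        write_params_table(params, out / "trial_params.tsv")

        stage = "qc"
        filtered, report = filter_participants(params, config.min_valid_fraction)
        write_tsv(report, out / "exclusions.tsv")

        stage = "analyze"
        means, dropped = condition_means(filtered)
        if not dropped.empty:
            write_tsv(dropped, out / "dropped_subjects.tsv")
        write_tsv(means, out / "subject_means.tsv")
        anova_rows, ttest_rows, bf_rows = [], [], []
        for param in config.anova_parameters:
            if param not in means.columns or means[param].isna().any():
                continue
            for res in rm_anova(means, param):
                anova_rows.append((param, res))
            for res in planned_ttests(means, param, alpha=config.ttest_alpha,
                                      correction=config.ttest_correction):
                ttest_rows.append((param, res))
            bf_rows.append(
                (param, jzs_bf_anova(means, param,
                                     n_mc_samples=config.bf_mc_samples,
                                     seed=config.seed))
            )

        stage = "report"
        write_tsv(summarize_means(means), out / "means.tsv")
        anova = pd.concat(
            [anova_table([r]).assign(parameter=p) for p, r in anova_rows],
            ignore_index=True,
        ) if anova_rows else anova_table([])
        ttests = pd.concat(
            [ttest_table([r]).assign(parameter=p) for p, r in ttest_rows],
            ignore_index=True,
        ) if ttest_rows else ttest_table([])
        bayes = pd.concat(
            [bayes_table([r]).assign(parameter=p) for p, r in bf_rows],
            ignore_index=True,
        ) if bf_rows else bayes_table([])
        write_tsv(anova, out / "anova.tsv")
        write_tsv(ttests, out / "ttests.tsv")
        write_tsv(bayes, out / "bayes.tsv")
    except ReachGraspError as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n", encoding="utf-8")
        raise ReachGraspError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "params": params,
        "exclusions": report,
        "means": means,
        "anova": anova,
        "ttests": ttests,
        "bayes": bayes,
    }
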