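"""Run configuration, deterministic seeding, and the end-to-end driver.

A single integer seed drives every stochastic stage.  Child seeds are
spawned with numpy's ``SeedSequence(seed, spawn_key=(stage,))`` where the
stage indices are fixed (documented in :data:`STAGES`), so adding or
skipping stages never shifts another stage's stream.  Every run writes its
fully-resolved configuration as YAML next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as xmeta
from . import flux, generate, stats
from .pathway import build_default_model

logger = logging.getLogger(__name__)

#: Fixed spawn-key index per stochastic stage.
STAGES = {"concentrations": 0, "herbivory": 1, "expression": 2,
          "bootstrap": 3}

FLOAT_FORMAT = "%.12g"


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage child seed from the single run seed."""
    return np.random.SeedSequence(seed, spawn_key=(STAGES[stage],))


@dataclass
class RunConfig:
    """Fully-resolved settings for one in-silico replication run."""

    seed: int = 0
    out_dir: str = "gsflux-run"
    model_params: dict = field(default_factory=dict)
    n_wt_per_condition: int = 8
    n_het_per_condition: int = 15
    lines: tuple = generate.LINES
    sigma_log: float = generate.DEFAULT_SIGMA_LOG
    ratios: dict = field(default_factory=lambda: dict(generate.DEFAULT_RATIOS))
    n_boot: int = 1000
    ci_level: float = 0.95
    estimator: str = "log_ratio"
    pooling: str = "pooled_wt"
    herbivory_beta: float = 1.2
    herbivory_baseline: float = 12.0
    herbivory_sigma: float = 0.4
    herbivory_flat_sd: float = 0.1
    skip: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["lines"] = list(self.lines)
        data["skip"] = list(self.skip)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def write_csv(df: pd.DataFrame, path) -> None:
    """Locale-independent CSV writer used for every data artifact."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_plants(path) -> pd.DataFrame:
    """Read a wide plant table, accepting the long format transparently."""
    df = pd.read_csv(path)
    if "compound" in df.columns and "concentration" in df.columns:
        df = generate.to_wide(df)
    return df


def read_ratios(path) -> dict[str, float]:
    """Read per-line HET/WT expression ratios (columns line,r)."""
    df = pd.read_csv(path)
    return dict(zip(df["line"].astype(str), df["r"].astype(float)))


def run_all(config: RunConfig) -> Path:
    """Execute the full in-silico replication and write all artifacts.

    Stages: simulate -> MANOVA -> pooling -> proportional-change tables ->
    control-coefficient table -> herbivory ANOVA -> expression meta.
    Deterministic given ``config.seed``; any stage failure aborts with the
    stage name while earlier artifacts remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "setup"
    try:
        stage = "simulate"
        model = build_default_model(config.model_params or None)
        design = generate.generate_design(
            lines=config.lines,
            n_wt_per_condition=config.n_wt_per_condition,
            n_het_per_condition=config.n_het_per_condition)
        write_csv(design, out / "design.csv")
        plants = generate.simulate_concentrations(
            design, model=model, ratios=config.ratios,
            sigma_log=config.sigma_log,
            seed=stage_seed(config.seed, "concentrations"))
        write_csv(plants, out / "plants.csv")
        write_csv(generate.to_long(plants), out / "plants_long.csv")

        stage = "manova"
        per_line = stats.manova_by_line(plants, pooling=config.pooling)
        tab1 = []
        for line, res in per_line.items():
            t = stats.manova_table(res)
            t.insert(0, "line", line)
            tab1.append(t)
        write_csv(pd.concat(tab1, ignore_index=True), out / "table1.csv")

        stage = "pooling"
        directives = {ln: stats.pooling_policy(res)
                      for ln, res in per_line.items()}
        with open(out / "pooling.json", "w") as fh:
            json.dump(directives, fh, indent=2, sort_keys=True)

        stage = "heatmap-tables"
        geno = stats.genotype_change_table(plants, pooling=config.pooling)
        trt = stats.treatment_change_table(plants)
        geno.insert(0, "contrast", "genotype")
        trt.insert(0, "contrast", "treatment")
        trt.insert(1, "line", "pooled")
        write_csv(pd.concat([geno, trt], ignore_index=True),
                  out / "fig2_fig3.csv")

        stage = "estimate"
        table2 = flux.estimate_table(
            plants, config.ratios, estimator=config.estimator,
            pooling=config.pooling, n_boot=config.n_boot,
            level=config.ci_level,
            seed=stage_seed(config.seed, "bootstrap"))
        write_csv(table2, out / "table2.csv")
        flux.table_to_wide(table2).to_csv(out / "table2_display.csv")

        if "herbivory" not in config.skip:
            stage = "herbivory"
            herb = generate.simulate_herbivory(
                plants, beta=config.herbivory_beta,
                baseline=config.herbivory_baseline,
                sigma=config.herbivory_sigma,
                flat_sd=config.herbivory_flat_sd,
                seed=stage_seed(config.seed, "herbivory"))
            write_csv(herb, out / "herbivory.csv")
            write_csv(stats.anova_table(stats.herbivory_anova(herb)),
                      out / "herbivory_anova.csv")

        if "meta" not in config.skip:
            stage = "meta"
            expr = generate.generate_expression_fixtures(
                seed=stage_seed(config.seed, "expression"))
            write_csv(expr, out / "expression.csv")
            write_csv(xmeta.meta_table(expr), out / "fig5.csv")
    except Exception as exc:
        raise RuntimeError(f"run-all failed during stage {stage!r}: {exc}"
                           ) from exc
    logger.info("run-all artifacts written to %s", out)
    return out
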