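"""Median-based meta-analysis of treatment effects on gene expression.

Per gene and experiment, the statistic is the proportional change in
median expression, (treated − control)/control; negative values mean the
treatment lowered expression.  Per-gene changes are then averaged across
the available experiments with a standard error, never imputed: a gene
absent from an experiment simply contributes fewer values, and a gene with
no experiments at all is omitted (with a warning).  Medians are taken as
inputs — each experiment supplies one summary per arm — so the module is
deliberately agnostic about the underlying platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneResponse:
    """Cross-experiment summary of one gene's expression response."""

    gene: str
    changes: list[float] = field(default_factory=list)
    mean_change: float = math.nan
    se: float | None = None
    n_experiments: int = 0


def proportional_expression_change(treated_median: float,
                                   control_median: float) -> float:
    """(treated − control) / control on per-arm median expression."""
    if control_median <= 0:
        raise ValueError(f"control median {control_median} must be positive")
    return (treated_median - control_median) / control_median


def per_experiment_changes(expression: pd.DataFrame) -> pd.DataFrame:
    """Long treated/control median table -> one change per experiment x gene.

    Expects columns ``experiment``, ``gene``, ``arm`` (treated/control) and
    ``median``.  Gene-experiment pairs missing either arm are dropped.
    """
    wide = expression.pivot_table(index=["experiment", "gene"],
                                  columns="arm", values="median",
                                  aggfunc="first").reset_index()
    wide = wide.dropna(subset=["treated", "control"])
    wide["change"] = [
        proportional_expression_change(t, c)
        for t, c in zip(wide["treated"], wide["control"])]
    return wide[["experiment", "gene", "change"]]


def aggregate_across_experiments(changes: dict[str, float] | pd.Series,
                                 gene: str = "") -> GeneResponse:
    """Average one gene's per-experiment changes; SE over experiments.

    With a single experiment the standard error is undefined and reported
    as ``None``.
    """
    if isinstance(changes, pd.Series):
        changes = changes.to_dict()
    vals = [float(v) for v in changes.values() if np.isfinite(v)]
    if not vals:
        logger.warning("gene %s: no experiments with data; omitted", gene)
        return GeneResponse(gene=gene)
    se = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
          if len(vals) > 1 else None)
    return GeneResponse(gene=gene, changes=vals,
                        mean_change=float(np.mean(vals)), se=se,
                        n_experiments=len(vals))


def meta_table(expression: pd.DataFrame,
               genes: list[str] | None = None) -> pd.DataFrame:
    """Full meta-analysis: per-gene mean proportional change and SE.

    ``genes`` restricts and orders the output; by default every gene seen
    in the input is reported, alphabetically.
    """
    per_exp = per_experiment_changes(expression)
    if genes is None:
        genes = sorted(per_exp["gene"].unique())
    rows = []
    for gene in genes:
        sub = per_exp[per_exp["gene"] == gene]
        resp = aggregate_across_experiments(
            dict(zip(sub["experiment"], sub["change"])), gene=gene)
        if resp.n_experiments == 0:
            continue
        rows.append({"gene": gene, "mean_change": resp.mean_change,
                     "se": np.nan if resp.se is None else resp.se,
                     "n_experiments": resp.n_experiments})
    return pd.DataFrame(rows)
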