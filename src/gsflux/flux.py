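"""Flux control coefficient estimation from heterozygous knockdowns.

A heterozygous T-DNA insertion reduces one enzyme's expression by a known
relative ratio r (HET/WT).  The response of each steady-state glucosinolate
pool C gives a finite-change estimate of that enzyme's control coefficient,

    lambda = d ln C / d ln E  ~=  ln(G_HET / G_WT) / ln(r)

with G the per-genotype geometric mean concentration (concentrations are
log-transformed throughout, so geometric means are the natural summary).
The alternative fractional (deviation-index) form
[(G_WT - G_HET)/G_WT] / (1 - r) is available; both converge to the
infinitesimal MCA coefficient as r -> 1.  Uncertainty comes from a
percentile bootstrap over plants, resampled with replacement within each
genotype arm, with r held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generate import LINES, LINE_ENZYME
from .pathway import COMPOUND_NAMES, EnzymeId

ESTIMATORS = ("log_ratio", "fractional")


@dataclass(frozen=True)
class ExpressionRatio:
    """HET/WT relative expression of one enzyme's gene."""

    enzyme: EnzymeId
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"expression ratio r={self.r} must be positive")


@dataclass
class ControlCoefficientEstimate:
    """One Table-2-style cell: enzyme x compound with bootstrap CI."""

    enzyme: str
    compound: str
    lam: float
    ci_low: float
    ci_high: float
    n_boot: int
    estimator: str
    ratio: float          # geometric-mean concentration ratio HET/WT
    ratio_ci: tuple[float, float]
    n_het: int
    n_wt: int

    def format(self) -> str:
        """Render as in a published coefficient table, e.g. ``1.118 (1.006−1.247)``."""
        return f"{self.lam:.3f} ({self.ci_low:.3f}−{self.ci_high:.3f})"


def _check_positive(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{what}: empty sample")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{what}: concentrations must be positive and finite")
    return arr


def genotype_summary(values, scale: str = "geometric") -> float:
    """Summary mean of one genotype arm's concentrations.

    Geometric by default, matching the log transform applied to all
    concentration analyses.
    """
    arr = _check_positive(values, "genotype_summary")
    if scale == "geometric":
        return float(np.exp(np.mean(np.log(arr))))
    if scale == "arithmetic":
        return float(np.mean(arr))
    raise ValueError(f"unknown scale {scale!r}")


def _lambda_from_means(g_het: float, g_wt: float, r: float,
                       estimator: str) -> float:
    if estimator == "log_ratio":
        return float(np.log(g_het / g_wt) / np.log(r))
    if estimator == "fractional":
        return float(((g_wt - g_het) / g_wt) / (1.0 - r))
    raise ValueError(f"unknown estimator {estimator!r}")


def estimate_lambda(het, wt, r: float | ExpressionRatio,
                    estimator: str = "log_ratio") -> float:
    """Point estimate of the control coefficient from two genotype arms."""
    rv = r.r if isinstance(r, ExpressionRatio) else float(r)
    if rv == 1.0:
        raise ValueError("zero enzyme perturbation: r = 1 leaves lambda "
                         "undefined")
    if rv <= 0:
        raise ValueError(f"expression ratio r={rv} must be positive")
    g_het = genotype_summary(het)
    g_wt = genotype_summary(wt)
    return _lambda_from_means(g_het, g_wt, rv, estimator)


def bootstrap_lambdas(het, wt, r: float, estimator: str = "log_ratio",
                      n_boot: int = 1000,
                      seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """The full vector of bootstrap replicate estimates.

    Plants are resampled with replacement within each genotype arm
    independently; r is held fixed.  Vectorised on the log scale, so a
    1000-replicate bootstrap is a pair of matrix row-means.
    """
    het = _check_positive(het, "HET sample")
    wt = _check_positive(wt, "WT sample")
    if het.size < 2 or wt.size < 2:
        raise ValueError("bootstrap needs >= 2 plants per genotype arm")
    if r == 1.0:
        raise ValueError("zero enzyme perturbation: r = 1")
    rng = np.random.default_rng(seed)
    lh = np.log(het)
    lw = np.log(wt)
    ih = rng.integers(0, het.size, size=(n_boot, het.size))
    iw = rng.integers(0, wt.size, size=(n_boot, wt.size))
    mh = lh[ih].mean(axis=1)
    mw = lw[iw].mean(axis=1)
    if estimator == "log_ratio":
        return (mh - mw) / np.log(r)
    if estimator == "fractional":
        g_h = np.exp(mh)
        g_w = np.exp(mw)
        return ((g_w - g_h) / g_w) / (1.0 - r)
    raise ValueError(f"unknown estimator {estimator!r}")


def percentile_interval(samples: np.ndarray,
                        level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval with linear interpolation."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def bootstrap_ci(het, wt, r: float, estimator: str = "log_ratio",
                 n_boot: int = 1000, level: float = 0.95,
                 seed: int | np.random.SeedSequence = 0,
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI for the control coefficient.

    Defaults follow the study design: 1000 resamples, 95% level.
    Degenerate inputs (both arms constant) yield a zero-width interval at
    the point estimate.
    """
    lams = bootstrap_lambdas(het, wt, r, estimator=estimator, n_boot=n_boot,
                             seed=seed)
    return percentile_interval(lams, level=level)


def estimate_cell(het, wt, r: float, estimator: str = "log_ratio",
                  n_boot: int = 1000, level: float = 0.95,
                  seed: int | np.random.SeedSequence = 0,
                  enzyme: str = "", compound: str = "",
                  ) -> ControlCoefficientEstimate:
    """Point estimate plus bootstrap CIs on both the lambda and ratio scales."""
    lam = estimate_lambda(het, wt, r, estimator=estimator)
    lams = bootstrap_lambdas(het, wt, r, estimator=estimator, n_boot=n_boot,
                             seed=seed)
    lo, hi = percentile_interval(lams, level=level)
    g_ratio = genotype_summary(het) / genotype_summary(wt)
    if estimator == "log_ratio":
        ratios = np.exp(lams * np.log(r))
    else:
        ratios = 1.0 - lams * (1.0 - r)
    r_lo, r_hi = percentile_interval(ratios, level=level)
    return ControlCoefficientEstimate(
        enzyme=enzyme, compound=compound, lam=lam, ci_low=lo, ci_high=hi,
        n_boot=n_boot, estimator=estimator, ratio=float(g_ratio),
        ratio_ci=(min(r_lo, r_hi), max(r_lo, r_hi)),
        n_het=len(np.asarray(het)), n_wt=len(np.asarray(wt)))


def estimate_table(plants: pd.DataFrame, ratios: dict[str, float],
                   estimator: str = "log_ratio", pooling: str = "pooled_wt",
                   n_boot: int = 1000, level: float = 0.95,
                   seed: int | np.random.SeedSequence = 0,
                   stratify_env: bool = False) -> pd.DataFrame:
    """The full 3-enzyme x 7-compound control-coefficient table.

    For each insertion line the HET arm is that line's HET plants; the WT
    arm is either every WT plant from all lines (``pooled_wt``, the
    default, as lines share a wild-type genotype) or only the same line's
    WT plants (``per_line``).  Environments are pooled before estimation
    unless ``stratify_env`` resamples within condition strata.

    Returns a tidy DataFrame with one row per enzyme x compound and a
    ``display`` column rendering "lambda (lo−hi)".  Cells whose
    genotype arm is missing are emitted with NaNs and ``ok=False``.
    """
    if pooling not in ("pooled_wt", "per_line"):
        raise ValueError(f"unknown pooling {pooling!r}")
    seed_seq = (seed if isinstance(seed, np.random.SeedSequence)
                else np.random.SeedSequence(seed))
    lines = [ln for ln in LINES if ln in set(plants["line"])]
    cells = []
    children = iter(seed_seq.spawn(len(lines) * len(COMPOUND_NAMES)))
    for line in lines:
        enzyme = LINE_ENZYME[line].value
        r = ratios[line]
        het_df = plants[(plants["line"] == line)
                        & (plants["genotype"] == "HET")]
        wt_df = (plants[plants["genotype"] == "WT"] if pooling == "pooled_wt"
                 else plants[(plants["line"] == line)
                             & (plants["genotype"] == "WT")])
        for compound in COMPOUND_NAMES:
            child = next(children)
            if het_df.empty or wt_df.empty:
                cells.append({"enzyme": enzyme, "compound": compound,
                              "lambda": np.nan, "ci_low": np.nan,
                              "ci_high": np.nan, "ratio": np.nan,
                              "ratio_ci_low": np.nan, "ratio_ci_high": np.nan,
                              "n_het": len(het_df), "n_wt": len(wt_df),
                              "n_boot": n_boot, "estimator": estimator,
                              "r": r, "display": "NA", "ok": False})
                continue
            if stratify_env:
                lams = _stratified_lambdas(het_df, wt_df, compound, r,
                                           estimator, n_boot, child)
                lam = estimate_lambda(het_df[compound], wt_df[compound], r,
                                      estimator)
                lo, hi = percentile_interval(lams, level)
                est = estimate_cell(het_df[compound], wt_df[compound], r,
                                    estimator, n_boot, level, child,
                                    enzyme, compound)
                est.lam, est.ci_low, est.ci_high = lam, lo, hi
            else:
                est = estimate_cell(het_df[compound], wt_df[compound], r,
                                    estimator, n_boot, level, child,
                                    enzyme, compound)
            cells.append({"enzyme": enzyme, "compound": compound,
                          "lambda": est.lam, "ci_low": est.ci_low,
                          "ci_high": est.ci_high, "ratio": est.ratio,
                          "ratio_ci_low": est.ratio_ci[0],
                          "ratio_ci_high": est.ratio_ci[1],
                          "n_het": est.n_het, "n_wt": est.n_wt,
                          "n_boot": n_boot, "estimator": estimator, "r": r,
                          "display": est.format(), "ok": True})
    return pd.DataFrame(cells)


def _stratified_lambdas(het_df: pd.DataFrame, wt_df: pd.DataFrame,
                        compound: str, r: float, estimator: str,
                        n_boot: int, seed) -> np.ndarray:
    """Bootstrap resampling within environment strata (optional mode)."""
    from .generate import ENV_FACTORS

    rng = np.random.default_rng(seed)
    lams = np.zeros(n_boot)
    groups_h = [g[compound].to_numpy()
                for _, g in het_df.groupby(list(ENV_FACTORS))]
    groups_w = [g[compound].to_numpy()
                for _, g in wt_df.groupby(list(ENV_FACTORS))]
    for b in range(n_boot):
        h = np.concatenate([rng.choice(g, size=g.size, replace=True)
                            for g in groups_h])
        w = np.concatenate([rng.choice(g, size=g.size, replace=True)
                            for g in groups_w])
        lams[b] = _lambda_from_means(
            float(np.exp(np.mean(np.log(h)))),
            float(np.exp(np.mean(np.log(w)))), r, estimator)
    return lams


def table_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy estimate table -> display matrix (compound rows, enzyme columns)."""
    wide = table.pivot(index="compound", columns="enzyme", values="display")
    wide = wide.reindex(index=list(COMPOUND_NAMES))
    wide.columns.name = None
    return wide
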