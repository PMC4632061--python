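"""Inferential battery for the factorial knockdown experiment.

The multivariate response is the vector of seven log glucosinolate
concentrations.  The full model per insertion line is

    Y = genotype + W + C + S + J + genotype x E + E x E

with genotype (WT vs HET) and the four binary treatments as fixed effects,
the four genotype-by-environment interactions, and all six pairwise
environment interactions.  Each term is tested with Wilk's Lambda
(det(E) / det(H + E)) and Rao's F approximation, Type III style with
sum-to-zero coding.  Significant multivariate terms are followed by
per-compound univariate tests at alpha = 0.05 and proportional-change
summaries (T_C − U_C)/U_C on back-transformed geometric means.  Leaf-area
herbivory records are analysed with a two-way fixed-effects ANOVA
LR = genotype + flat + genotype x flat.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pathway import COMPOUND_NAMES

ENV_TERMS = ("W", "C", "S", "J")

#: Term structure of the full model, in reporting order.
FULL_MODEL_TERMS: tuple[tuple[str, ...], ...] = (
    ("genotype",), ("W",), ("C",), ("S",), ("J",),
    ("genotype", "W"), ("genotype", "C"), ("genotype", "S"),
    ("genotype", "J"),
    ("W", "C"), ("W", "S"), ("W", "J"), ("C", "S"), ("C", "J"), ("S", "J"),
)


@dataclass
class ManovaTermResult:
    """Wilk's Lambda test of one model term."""

    term: str
    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p_value: float

    @property
    def significance(self) -> str:
        p = self.p_value
        return "***" if p < 1e-3 else "**" if p < 1e-2 else \
            "*" if p < 0.05 else ""


@dataclass
class TreatmentContrast:
    """Univariate follow-up for one compound under one contrast."""

    compound: str
    treatment: str
    t_c: float          # geometric mean, treated / HET arm
    u_c: float          # geometric mean, untreated / WT arm
    prop_change: float  # (T_C - U_C) / U_C
    p_value: float
    significant: bool


@dataclass
class AnovaResult:
    """One row of a univariate ANOVA table."""

    term: str
    ss: float
    df: float
    f_stat: float
    p_value: float


# ---------------------------------------------------------------------------
# design-matrix machinery (sum-to-zero coding)

def _effect_columns(data: pd.DataFrame, factor: str) -> tuple[np.ndarray, int]:
    """Sum-to-zero (deviation) coding for one factor; returns (cols, df)."""
    vals = data[factor]
    levels = sorted(pd.unique(vals.astype(str)))
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    cols = np.zeros((len(data), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(vals.astype(str) == lev, 1.0, 0.0)
    cols[np.asarray(vals.astype(str) == levels[-1]), :] = -1.0
    return cols, k - 1


def build_design_matrix(data: pd.DataFrame,
                        terms=FULL_MODEL_TERMS,
                        ) -> tuple[np.ndarray, dict[str, slice]]:
    """Full-rank design matrix with intercept and sum-to-zero terms.

    Interaction columns are element-wise products of the parent factors'
    effect columns.  Returns the matrix and a map term-label -> column
    slice.
    """
    n = len(data)
    main_cols: dict[str, np.ndarray] = {}
    for term in terms:
        for f in term:
            if f not in main_cols:
                main_cols[f], _ = _effect_columns(data, f)
    blocks = [np.ones((n, 1))]
    spans: dict[str, slice] = {}
    start = 1
    for term in terms:
        parts = [main_cols[f] for f in term]
        cols = parts[0]
        for p in parts[1:]:
            cols = np.einsum("ni,nj->nij", cols, p).reshape(n, -1)
        label = " × ".join(term)
        blocks.append(cols)
        spans[label] = slice(start, start + cols.shape[1])
        start += cols.shape[1]
    X = np.hstack(blocks)
    return X, spans


def _rao_f(lam: float, p: int, q: int, v: float
           ) -> tuple[float, float, float]:
    """Rao's F approximation for Wilk's Lambda.

    Exact when min(p, q) <= 2.  ``p`` responses, ``q`` hypothesis df,
    ``v`` error df.
    """
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    w = v - (p - q + 1.0) / 2.0
    df1 = p * q
    df2 = w * t - (p * q) / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    return f, df1, df2


def manova_fit(data: pd.DataFrame, responses=COMPOUND_NAMES,
               terms=FULL_MODEL_TERMS, log_transform: bool = True,
               ) -> list[ManovaTermResult]:
    """Fit the multivariate linear model and test every term with Wilk's Lambda.

    ``data`` holds the factor columns and the response columns;
    concentrations are natural-log transformed unless ``log_transform`` is
    off.  For each term the hypothesis cross-product matrix is the Type III
    quadratic form H = (L B)' [L (X'X)^{-1} L']^{-1} (L B) and the shared
    error matrix E is the residual cross-product; Lambda = det(E)/det(H+E)
    with Rao's F and its standard degrees of freedom.
    """
    Y = data.loc[:, list(responses)].to_numpy(dtype=float)
    if log_transform:
        if np.any(Y <= 0):
            raise ValueError("log transform requires positive responses")
        Y = np.log(Y)
    X, spans = build_design_matrix(data, terms)
    n, k = X.shape
    p = Y.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        aliased = ", ".join(spans)
        raise ValueError(f"rank-deficient design (rank {rank} < {k} "
                         f"columns); terms: {aliased}")
    v = n - k
    if v <= p:
        raise ValueError(f"too few observations: error df {v} must exceed "
                         f"the {p} responses")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    E = resid.T @ resid
    det_e = np.linalg.det(E)
    results = []
    for label, span in spans.items():
        LB = B[span, :]                       # (q, p)
        M = XtX_inv[span, span]               # (q, q)
        H = LB.T @ np.linalg.solve(M, LB)
        lam = det_e / np.linalg.det(H + E)
        lam = float(min(max(lam, np.finfo(float).tiny), 1.0))
        q = span.stop - span.start
        f, df1, df2 = _rao_f(lam, p, q, v)
        pval = float(sps.f.sf(f, df1, df2)) if df2 > 0 else np.nan
        results.append(ManovaTermResult(term=label, wilks_lambda=lam,
                                        f_stat=float(f), df1=df1, df2=df2,
                                        p_value=pval))
    return results


def manova_table(results: list[ManovaTermResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": r.term, "wilks_lambda": r.wilks_lambda, "F": r.f_stat,
          "df1": r.df1, "df2": r.df2, "p_value": r.p_value,
          "sig": r.significance} for r in results])


# ---------------------------------------------------------------------------
# univariate follow-ups and proportional change

def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def proportional_change(t_c: float, u_c: float) -> float:
    """(T_C − U_C) / U_C for treated vs untreated mean concentrations."""
    if u_c <= 0:
        raise ValueError("untreated mean must be positive")
    return (t_c - u_c) / u_c


def univariate_followups(data: pd.DataFrame, term: str, alpha: float = 0.05,
                         terms=FULL_MODEL_TERMS, responses=COMPOUND_NAMES,
                         ) -> list[TreatmentContrast]:
    """Per-compound follow-up tests for one significant MANOVA term.

    Caller gatekeeping mirrors the study's protocol: follow-ups are only
    meaningful for terms whose multivariate test was significant.  For each
    compound the univariate version of the same linear model is fitted on
    log concentration and the term tested (Type III F); the reported means
    are back-transformed geometric means of the raw arms (treated = flag
    on, or HET), pooled over everything else.
    """
    if term == "genotype":
        treated = data["genotype"] == "HET"
    elif term in ENV_TERMS:
        treated = data[term] == 1
    else:
        raise ValueError(f"unknown follow-up term {term!r}")
    if treated.all() or (~treated).all():
        raise ValueError(f"term {term!r}: one stratum is empty")
    X, spans = build_design_matrix(data, terms)
    span = spans[term]
    XtX_inv = np.linalg.inv(X.T @ X)
    out = []
    for compound in responses:
        y = np.log(data[compound].to_numpy(dtype=float))
        b = XtX_inv @ (X.T @ y)
        resid = y - X @ b
        v = len(y) - X.shape[1]
        sse = float(resid @ resid)
        lb = b[span]
        ssh = float(lb @ np.linalg.solve(XtX_inv[span, span], lb))
        q = span.stop - span.start
        if sse <= 0:  # degenerate: response fully explained
            f = np.inf if ssh > 1e-12 else np.nan
        else:
            f = (ssh / q) / (sse / v)
        pval = float(sps.f.sf(f, q, v)) if np.isfinite(f) else \
            (0.0 if f == np.inf else np.nan)
        t_c = _geomean(data.loc[treated, compound].to_numpy())
        u_c = _geomean(data.loc[~treated, compound].to_numpy())
        out.append(TreatmentContrast(
            compound=compound, treatment=term, t_c=t_c, u_c=u_c,
            prop_change=proportional_change(t_c, u_c), p_value=pval,
            significant=pval < alpha))
    return out


def contrasts_table(contrasts: list[TreatmentContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"compound": c.compound, "treatment": c.treatment, "T_C": c.t_c,
          "U_C": c.u_c, "prop_change": c.prop_change, "p_value": c.p_value,
          "significant": c.significant} for c in contrasts])


def pooling_policy(results: list[ManovaTermResult],
                   alpha: float = 0.05) -> dict[str, bool]:
    """Pooling directives from the genotype-by-environment interactions.

    Both pooling moves (WT+HET pooled when testing environment effects;
    environments pooled when testing the genotype effect) are licensed
    exactly when none of the four genotype x E interactions is significant.
    """
    gxe = [r for r in results
           if r.term.startswith("genotype × ")]
    if not gxe:
        raise ValueError("no genotype × environment interactions in the "
                         "fitted model; fit the full model first")
    all_ns = all(r.p_value >= alpha for r in gxe)
    return {"pool_genotypes_for_env_effects": all_ns,
            "pool_environments_for_genotype_effects": all_ns}


# ---------------------------------------------------------------------------
# herbivory two-way ANOVA

def herbivory_anova(records: pd.DataFrame) -> list[AnovaResult]:
    """Two-way fixed-effects ANOVA of leaf area removed.

    Model LR = genotype + flat + genotype x flat, Type III sums of squares
    with sum-to-zero contrasts; genotype is tested against the residual.
    The block factor is fitted as fixed even though it is a nuisance
    (randomised-flat) effect — a two-way ANOVA table is what the assay
    protocol reports.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col, lo in (("genotype", 2), ("flat", 2)):
        if records[col].nunique() < lo:
            raise ValueError(f"need >= {lo} levels of {col}")
    counts = records.groupby(["genotype", "flat"]).size()
    n_cells = records["genotype"].nunique() * records["flat"].nunique()
    if len(counts) < n_cells:
        raise ValueError("empty genotype x flat cell; cannot fit the "
                         "interaction")
    fit = smf.ols("LR ~ C(genotype, Sum) * C(flat, Sum)", data=records).fit()
    tab = sm.stats.anova_lm(fit, typ=3)
    rename = {"C(genotype, Sum)": "genotype", "C(flat, Sum)": "flat",
              "C(genotype, Sum):C(flat, Sum)": "genotype × flat",
              "Residual": "residual"}
    out = []
    for idx, row in tab.iterrows():
        if idx == "Intercept":
            continue
        out.append(AnovaResult(term=rename.get(idx, idx),
                               ss=float(row["sum_sq"]), df=float(row["df"]),
                               f_stat=float(row["F"]),
                               p_value=float(row["PR(>F)"])))
    return out


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": r.term, "ss": r.ss, "df": r.df, "F": r.f_stat,
          "p_value": r.p_value} for r in results])


# ---------------------------------------------------------------------------
# study-level drivers

def manova_by_line(plants: pd.DataFrame, pooling: str = "pooled_wt",
                   ) -> dict[str, list[ManovaTermResult]]:
    """Fit the full MANOVA once per insertion line.

    With ``pooled_wt`` each line's HET arm is contrasted against the WT
    plants of all lines (the lines share a wild-type genotype); with
    ``per_line`` only the same line's WT plants are used.
    """
    out = {}
    for line in sorted(plants["line"].unique()):
        het = plants[(plants["line"] == line) & (plants["genotype"] == "HET")]
        wt = (plants[plants["genotype"] == "WT"] if pooling == "pooled_wt"
              else plants[(plants["line"] == line)
                          & (plants["genotype"] == "WT")])
        out[line] = manova_fit(pd.concat([het, wt], ignore_index=True))
    return out


def genotype_change_table(plants: pd.DataFrame,
                          pooling: str = "pooled_wt") -> pd.DataFrame:
    """HET-vs-WT proportional change per line x compound (heat-map numbers).

    Environments are pooled, per the no-interaction pooling policy.
    """
    frames = []
    for line in sorted(plants["line"].unique()):
        het = plants[(plants["line"] == line) & (plants["genotype"] == "HET")]
        wt = (plants[plants["genotype"] == "WT"] if pooling == "pooled_wt"
              else plants[(plants["line"] == line)
                          & (plants["genotype"] == "WT")])
        sub = pd.concat([het, wt], ignore_index=True)
        tab = contrasts_table(univariate_followups(sub, "genotype"))
        tab.insert(0, "line", line)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def treatment_change_table(plants: pd.DataFrame) -> pd.DataFrame:
    """Treated-vs-control proportional change per treatment x compound.

    Genotypes are pooled within treatment, per the pooling policy.
    """
    frames = []
    for trt in ENV_TERMS:
        tab = contrasts_table(univariate_followups(plants, trt))
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
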