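"""Synthetic-data generator emulating the factorial knockdown experiment.

The design it reproduces: three T-DNA insertion lines (*Cyp79f1*,
*Cyp83a1*, *Sur1*), each grown as a wild-type (WT) vs heterozygous-knockdown
(HET) contrast under all 2^4 combinations of four binary environmental
treatments — reduced water (W), mechanical leaf crushing (C), reduced soil
nutrients (S) and methyl-jasmonate application (J) — with 8 WT and 15 HET
replicates per condition, i.e. 16 x 23 = 368 plants per line.

Measured concentrations are drawn lognormally around the kinetic model's
genotype x environment steady-state product pools.  Two companion fixtures
are generated the same way: herbivory leaf-area-removed records (leaf
consumption decreasing in short-chain aliphatic glucosinolate content) and
three replicate microarray-style expression experiments with treated/control
medians for the MeJA meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway import (COMPOUND_NAMES, MET_ENTRY, TRP, EnzymeId, PathwayModel,
                      apply_knockdown, build_default_model, steady_state)

LINES: tuple[str, str, str] = ("Cyp79f1", "Cyp83a1", "Sur1")

#: Gene knocked down in each insertion line.
LINE_ENZYME: dict[str, EnzymeId] = {
    "Cyp79f1": EnzymeId.CYP79F1,
    "Cyp83a1": EnzymeId.CYP83A1,
    "Sur1": EnzymeId.SUR1,
}

ENV_FACTORS: tuple[str, str, str, str] = ("W", "C", "S", "J")

PLANT_COLUMNS = ["line", "genotype", "W", "C", "S", "J", "flat"]

#: Default HET/WT relative expression for a single null allele.
DEFAULT_RATIOS: dict[str, float] = {ln: 0.5 for ln in LINES}

DEFAULT_SIGMA_LOG = 0.35  # lognormal measurement noise, log-scale SD
DEFAULT_N_FLATS = 4


@dataclass
class EnvironmentEffects:
    """Multiplicative parameter modifiers per environmental treatment.

    ``enzymes`` maps treatment -> {EnzymeId: factor}; ``influx`` maps
    treatment -> {"met"|"trp": factor}.  Factors multiply when treatments
    combine.  The magnitudes are repo-frozen model choices tuned only to
    reproduce qualitative response directions (notably the MeJA pattern:
    every glucosinolate enzyme induced except CYP81F2, which is repressed,
    with a stronger boost of the indolic precursor supply); they carry no
    measured authority.
    """

    enzymes: dict[str, dict[EnzymeId, float]] = field(default_factory=dict)
    influx: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trt, mods in self.enzymes.items():
            for enz, f in mods.items():
                if f <= 0:
                    raise ValueError(f"{trt}: factor for {enz.value} must "
                                     "be positive")
        for trt, mods in self.influx.items():
            for key, f in mods.items():
                if f <= 0:
                    raise ValueError(f"{trt}: influx factor {key} must be "
                                     "positive")

    @classmethod
    def identity(cls) -> "EnvironmentEffects":
        return cls()

    def apply(self, model: PathwayModel, env: dict[str, int]) -> PathwayModel:
        """Apply the modifiers of every active treatment in ``env``."""
        m = model.copy()
        for trt in ENV_FACTORS:
            if not env.get(trt, 0):
                continue
            for enz, f in self.enzymes.get(trt, {}).items():
                m.enzyme_levels[enz] *= f
            inf = self.influx.get(trt, {})
            if "met" in inf:
                m.influx[MET_ENTRY] *= inf["met"]
            if "trp" in inf:
                m.influx[TRP] *= inf["trp"]
        return m


def default_environment_effects() -> EnvironmentEffects:
    """Frozen default treatment modifiers.

    J (MeJA) induces every pathway enzyme 1.5x except CYP81F2 (0.4x) and
    boosts precursor supply, the indolic side more strongly; C (crushing)
    acts like a milder jasmonate response without the CYP81F2 repression;
    W (low water) and S (low nutrients) mainly curtail precursor supply,
    S hitting the sulfur-hungry aliphatic side hardest.
    """
    up = {e: 1.5 for e in EnzymeId if e is not EnzymeId.DEG}
    up[EnzymeId.CYP81F2] = 0.4
    crush = {e: 1.2 for e in EnzymeId if e is not EnzymeId.DEG}
    return EnvironmentEffects(
        enzymes={"J": up, "C": crush},
        influx={
            "J": {"met": 1.3, "trp": 1.8},
            "C": {"met": 1.15, "trp": 1.3},
            "W": {"met": 0.85, "trp": 0.9},
            "S": {"met": 0.7, "trp": 0.85},
        },
    )


def generate_design(lines=LINES, n_wt_per_condition: int = 8,
                    n_het_per_condition: int = 15,
                    n_flats: int = DEFAULT_N_FLATS,
                    factors=ENV_FACTORS) -> pd.DataFrame:
    """Full factorial plant skeleton table.

    One row per plant with columns line, genotype, the binary treatment
    flags, and a round-robin flat (block) label.  At the default replicate
    counts each line contributes 16 x (8 + 15) = 368 rows.
    """
    lines = tuple(lines)
    if not lines:
        raise ValueError("at least one insertion line is required")
    if n_wt_per_condition < 1 or n_het_per_condition < 1:
        raise ValueError("replicate counts must be >= 1")
    rows = []
    # round-robin per genotype so flats are never confounded with genotype
    flat_counter = {"WT": 0, "HET": 0}
    n_cond = 2 ** len(factors)
    for line in lines:
        for cond in range(n_cond):
            env = {f: (cond >> i) & 1 for i, f in enumerate(factors)}
            for genotype, n in (("WT", n_wt_per_condition),
                                ("HET", n_het_per_condition)):
                for _ in range(n):
                    k = flat_counter[genotype] % n_flats
                    rows.append({"line": line, "genotype": genotype,
                                 **{f: env.get(f, 0) for f in ENV_FACTORS},
                                 "flat": f"flat{k + 1}"})
                    flat_counter[genotype] += 1
    return pd.DataFrame(rows, columns=PLANT_COLUMNS)


def _condition_model(base: PathwayModel, effects: EnvironmentEffects,
                     env: dict[str, int], genotype: str, line: str,
                     ratios: dict[str, float]) -> PathwayModel:
    m = effects.apply(base, env)
    if genotype == "HET":
        m = apply_knockdown(m, LINE_ENZYME[line], ratios[line])
    return m


def simulate_concentrations(design: pd.DataFrame,
                            model: PathwayModel | None = None,
                            effects: EnvironmentEffects | None = None,
                            ratios: dict[str, float] | None = None,
                            sigma_log: float = DEFAULT_SIGMA_LOG,
                            seed: int | np.random.SeedSequence = 0,
                            ) -> pd.DataFrame:
    """Fill a design skeleton with noisy glucosinolate concentrations.

    Steady-state product pools of the condition-specific model (environment
    modifiers applied; the line's knockdown ratio applied for HET plants)
    serve as lognormal medians; each compound is drawn independently with
    log-scale SD ``sigma_log``.  Rows whose model fails to reach steady
    state are dropped with a recorded count (``df.attrs['n_dropped']``).
    Deterministic given ``seed``.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    model = build_default_model() if model is None else model
    effects = default_environment_effects() if effects is None else effects
    ratios = dict(DEFAULT_RATIOS) if ratios is None else dict(ratios)
    rng = np.random.default_rng(seed)

    # each distinct (env, genotype-line) cell needs one steady-state solve
    cache: dict[tuple, np.ndarray | None] = {}
    n_dropped = 0
    medians = np.empty((len(design), len(COMPOUND_NAMES)))
    keep = np.ones(len(design), dtype=bool)
    for i, row in enumerate(design.itertuples(index=False)):
        env = {f: int(getattr(row, f)) for f in ENV_FACTORS}
        key = (tuple(env.values()), row.genotype,
               row.line if row.genotype == "HET" else "WT")
        if key not in cache:
            m = _condition_model(model, effects, env, row.genotype,
                                 row.line, ratios)
            ss = steady_state(m)
            cache[key] = ss.compound_vector() if ss.converged else None
        med = cache[key]
        if med is None:
            keep[i] = False
            n_dropped += 1
        else:
            medians[i] = med

    noise = rng.normal(0.0, sigma_log, size=medians.shape) if sigma_log > 0 \
        else np.zeros_like(medians)
    conc = medians * np.exp(noise)
    out = design.reset_index(drop=True).copy()
    for j, c in enumerate(COMPOUND_NAMES):
        out[c] = conc[:, j]
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def to_long(plants: pd.DataFrame) -> pd.DataFrame:
    """Wide plant table -> long (one row per plant x compound).

    A ``plant`` id column (row number) is added so replicate plants with
    identical factor levels stay distinguishable.
    """
    wide = plants.reset_index(drop=True)
    wide = wide.assign(plant=np.arange(len(wide)))
    return wide.melt(id_vars=["plant"] + PLANT_COLUMNS,
                     value_vars=list(COMPOUND_NAMES),
                     var_name="compound", value_name="concentration")


def to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_long` (row order by plant id)."""
    wide = long.pivot_table(index=["plant"] + PLANT_COLUMNS,
                            columns="compound", values="concentration",
                            sort=False).reset_index().drop(columns="plant")
    wide.columns.name = None
    return wide[PLANT_COLUMNS + list(COMPOUND_NAMES)].sort_index()


def simulate_herbivory(plants: pd.DataFrame, beta: float = 1.2,
                       baseline: float = 12.0, sigma: float = 0.4,
                       flat_sd: float = 0.1,
                       seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Leaf area removed by a generalist caterpillar in a choice-free assay.

    Only the *Cyp79f1* line is assayed.  The percent leaf area removed
    after 3 h decreases exponentially in the plant's short-chain aliphatic
    glucosinolate content (3MSOP + 4MSOB):

        LR = baseline * exp(-beta * (c_3MSOP + c_4MSOB))
                      * exp(flat_effect + noise)

    so knockdown plants, carrying less deterrent, lose more leaf area.
    Flat effects are multiplicative block effects with log-SD ``flat_sd``;
    residual noise has log-SD ``sigma``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rec = plants[plants["line"] == "Cyp79f1"]
    if rec.empty:
        raise ValueError("no Cyp79f1 plants in input")
    rng = np.random.default_rng(seed)
    flats = sorted(rec["flat"].unique())
    flat_eff = dict(zip(flats, rng.normal(0.0, flat_sd, len(flats))))
    short = rec["3MSOP"].to_numpy() + rec["4MSOB"].to_numpy()
    log_lr = (np.log(baseline) - beta * short
              + rec["flat"].map(flat_eff).to_numpy()
              + rng.normal(0.0, sigma, len(rec)))
    return pd.DataFrame({
        "genotype": rec["genotype"].to_numpy(),
        "flat": rec["flat"].to_numpy(),
        "LR": np.maximum(np.exp(log_lr), 0.0),
    })


#: Gene panel for the expression meta-analysis fixtures (every catalytic
#: step of the model; the turnover pseudo-step is not a gene).
EXPRESSION_GENES: tuple[str, ...] = tuple(
    e.value for e in EnzymeId if e is not EnzymeId.DEG)

#: Synthetic stand-ins for the three public MeJA microarray experiments.
EXPERIMENT_IDS: tuple[str, ...] = ("synthetic-meja-exp1", "synthetic-meja-exp2",
                                   "synthetic-meja-exp3")


def default_expression_profile() -> dict[str, float]:
    """True treated/control fold change per gene: all induced except CYP81F2."""
    prof = {g: 1.5 for g in EXPRESSION_GENES}
    prof["CYP81F2"] = 0.4
    return prof


def generate_expression_fixtures(n_experiments: int = 3,
                                 profile: dict[str, float] | None = None,
                                 sigma_log: float = 0.15,
                                 seed: int | np.random.SeedSequence = 0,
                                 ) -> pd.DataFrame:
    """Synthetic treated/control median-expression experiments.

    One row per experiment x gene x arm with a ``median`` column.  Control
    medians are drawn lognormally around 100 expression units; treated
    medians around control x the gene's true fold change from ``profile``.
    The experiments emulate independent public microarray studies, so each
    gets independent noise.
    """
    profile = default_expression_profile() if profile is None else profile
    rng = np.random.default_rng(seed)
    ids = (list(EXPERIMENT_IDS[:n_experiments])
           if n_experiments <= len(EXPERIMENT_IDS)
           else [f"synthetic-meja-exp{i + 1}" for i in range(n_experiments)])
    rows = []
    for exp in ids:
        for gene, fold in profile.items():
            base = 100.0 * np.exp(rng.normal(0.0, 0.3))
            ctrl = base * np.exp(rng.normal(0.0, sigma_log))
            trt = base * fold * np.exp(rng.normal(0.0, sigma_log))
            rows.append({"experiment": exp, "gene": gene, "arm": "control",
                         "median": ctrl})
            rows.append({"experiment": exp, "gene": gene, "arm": "treated",
                         "median": trt})
    return pd.DataFrame(rows)
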