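"""Kinetic model of the branched glucosinolate biosynthesis network.

The model covers the two glucosinolate branches of *Arabidopsis thaliana*
rosette leaves: aliphatic glucosinolates built from chain-elongated
methionine, and indolic glucosinolates built from tryptophan.  Both branches
converge on the shared C-S lyase SUR1, modelled as a saturable step with
competitive substrate interaction, which is what lets a perturbation on one
branch propagate to the other.  Every other reaction is first order in its
substrate and proportional to its enzyme level; products accumulate against
a first-order non-enzymatic turnover (the ``DEG`` pseudo-step), so a
steady-state product concentration is a direct read-out of branch flux.

Concentration and time units are arbitrary: the biology fixes only relative
statements (sign patterns, flux shares), never absolute pool sizes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


class CompoundId(str, enum.Enum):
    """The seven measured glucosinolate products.

    The first four are aliphatic (methylsulfinyl-alkyl, increasing chain
    length); the last three are the indolic parent I3M and its 4-hydroxy and
    1-methoxy modifications.
    """

    MSOP3 = "3MSOP"
    MSOB4 = "4MSOB"
    MSOP5 = "5MSOP"
    MSOH6 = "6MSOH"
    I3M = "I3M"
    OHI3M4 = "4OHI3M"
    MOI3M1 = "1MOI3M"

    @property
    def aliphatic(self) -> bool:
        return self in (CompoundId.MSOP3, CompoundId.MSOB4,
                        CompoundId.MSOP5, CompoundId.MSOH6)

    @property
    def indolic(self) -> bool:
        return not self.aliphatic


#: Compounds in conventional (short-to-long aliphatic, then indolic) order.
COMPOUNDS: tuple[CompoundId, ...] = tuple(CompoundId)

COMPOUND_NAMES: tuple[str, ...] = tuple(c.value for c in COMPOUNDS)


class EnzymeId(str, enum.Enum):
    """Catalytic and pseudo-catalytic steps of the network.

    ``ELONG`` lumps the chain-elongation cycle (MAM pathway), ``LATE_ALI`` /
    ``LATE_IND`` lump the post-SUR1 glucosylation/sulfation steps
    (UGT74B1 + sulfotransferases), and ``DEG`` is the non-enzymatic turnover
    pseudo-step.  CYP79F1, CYP83A1 and SUR1 are the three steps manipulable
    by heterozygous knockdown.
    """

    CYP79F1 = "CYP79F1"
    CYP79F2 = "CYP79F2"
    CYP83A1 = "CYP83A1"
    SUR1 = "SUR1"
    LATE_ALI = "LATE_ALI"
    CYP79B = "CYP79B"
    CYP83B1 = "CYP83B1"
    LATE_IND = "LATE_IND"
    CYP81F2 = "CYP81F2"
    MOD1M = "MOD1M"
    ELONG = "ELONG"
    DEG = "DEG"


MANIPULABLE_ENZYMES: frozenset[EnzymeId] = frozenset(
    {EnzymeId.CYP79F1, EnzymeId.CYP83A1, EnzymeId.SUR1}
)

#: Influx pseudo-steps, addressable in perturbation/summation machinery.
INFLUX_MET = "influx:met"
INFLUX_TRP = "influx:trp"
INFLUX_STEPS: tuple[str, str] = (INFLUX_MET, INFLUX_TRP)


@dataclass(frozen=True)
class Reaction:
    """A single irreversible conversion ``substrate -> product``.

    ``kinetics`` is ``linear`` (rate = k * E * S), ``michaelis_menten``
    (rate = k * E * S / (Km + S)) or ``competitive_mm`` (saturable with all
    members of ``group`` competing for the same enzyme:
    rate_i = k * E * (S_i/Km_i) / (1 + sum_j S_j/Km_j)).
    ``product=None`` marks pure degradation.  Every rate is degree-1 in the
    enzyme level.
    """

    id: str
    substrate: str
    product: str | None
    enzyme: EnzymeId
    k: float
    kinetics: str = "linear"
    km: float = 1.0
    group: str | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"reaction {self.id}: rate constant k={self.k} "
                             "must be positive")
        if self.kinetics not in ("linear", "michaelis_menten",
                                 "competitive_mm"):
            raise ValueError(f"reaction {self.id}: unknown kinetics "
                             f"{self.kinetics!r}")
        if self.kinetics != "linear" and self.km <= 0:
            raise ValueError(f"reaction {self.id}: Km={self.km} must be "
                             "positive")


@dataclass
class PathwayModel:
    """Network topology plus enzyme levels and influx rates.

    ``enzyme_levels`` are dimensionless activities (wild type = 1.0);
    ``influx`` holds the constant source rates for the methionine-derived
    (aliphatic) and tryptophan-derived (indolic) entry pools.
    """

    species: list[str]
    reactions: list[Reaction]
    enzyme_levels: dict[EnzymeId, float]
    influx: dict[str, float]  # species -> constant rate
    products: tuple[str, ...] = COMPOUND_NAMES

    def __post_init__(self) -> None:
        for enz, lev in self.enzyme_levels.items():
            if lev < 0:
                raise ValueError(f"enzyme level {enz.value}={lev} must be "
                                 "nonnegative")
        for sp, v in self.influx.items():
            if v <= 0:
                raise ValueError(f"influx into {sp}: rate {v} must be "
                                 "positive")
        self._index = {s: i for i, s in enumerate(self.species)}

    # -- construction helpers -------------------------------------------

    def copy(self) -> "PathwayModel":
        return PathwayModel(
            species=list(self.species),
            reactions=list(self.reactions),
            enzyme_levels=dict(self.enzyme_levels),
            influx=dict(self.influx),
            products=self.products,
        )

    def with_enzyme_levels(self, levels: dict[EnzymeId, float]) -> "PathwayModel":
        m = self.copy()
        m.enzyme_levels.update(levels)
        for enz, lev in levels.items():
            if lev < 0:
                raise ValueError(f"enzyme level {enz.value}={lev} must be "
                                 "nonnegative")
        return m

    def scaled(self, step: "EnzymeId | str", factor: float) -> "PathwayModel":
        """Multiply one step's level by ``factor``.

        ``step`` is an :class:`EnzymeId` or one of the influx pseudo-step
        labels ``influx:met`` / ``influx:trp``.
        """
        m = self.copy()
        if isinstance(step, EnzymeId):
            m.enzyme_levels[step] = self.enzyme_levels[step] * factor
        elif isinstance(step, str) and step.startswith("influx:"):
            name = step[len("influx:"):]
            key = {"met": MET_ENTRY, "trp": TRP}.get(name, name)
            if key not in self.influx:
                raise KeyError(f"no influx into {key!r}")
            m.influx[key] = self.influx[key] * factor
        else:
            raise KeyError(f"unknown step {step!r}")
        return m

    @property
    def influx_steps(self) -> tuple[str, ...]:
        """Pseudo-step labels for this model's influxes."""
        return tuple(f"influx:{sp}" for sp in self.influx)

    @property
    def all_linear(self) -> bool:
        return all(r.kinetics == "linear" for r in self.reactions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- dynamics -------------------------------------------------------

    def _rates(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction rates at state ``x`` (clipped at 0)."""
        xs = np.maximum(x, 0.0)
        rates = np.empty(len(self.reactions))
        # competitive groups share a saturation denominator
        denoms: dict[str, float] = {}
        for r in self.reactions:
            if r.kinetics == "competitive_mm" and r.group not in denoms:
                denoms[r.group] = 1.0 + sum(
                    xs[self._index[q.substrate]] / q.km
                    for q in self.reactions
                    if q.kinetics == "competitive_mm" and q.group == r.group
                )
        for i, r in enumerate(self.reactions):
            e = self.enzyme_levels[r.enzyme]
            s = xs[self._index[r.substrate]]
            if r.kinetics == "linear":
                rates[i] = r.k * e * s
            elif r.kinetics == "michaelis_menten":
                rates[i] = r.k * e * s / (r.km + s)
            else:
                rates[i] = r.k * e * (s / r.km) / denoms[r.group]
        return rates

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Net production rate of every species."""
        dx = np.zeros(self.n_species)
        for sp, v in self.influx.items():
            dx[self._index[sp]] += v
        rates = self._rates(x)
        for r, v in zip(self.reactions, rates):
            dx[self._index[r.substrate]] -= v
            if r.product is not None:
                dx[self._index[r.product]] += v
        return dx

    def _linear_system(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, b) with steady state solving A x + b = 0.

        Only valid when every reaction is linear.
        """
        n = self.n_species
        A = np.zeros((n, n))
        b = np.zeros(n)
        for sp, v in self.influx.items():
            b[self._index[sp]] += v
        for r in self.reactions:
            c = r.k * self.enzyme_levels[r.enzyme]
            i = self._index[r.substrate]
            A[i, i] -= c
            if r.product is not None:
                A[self._index[r.product], i] += c
        return A, b


# Species labels.  Ln are elongation pools (n rounds set aliphatic chain
# length), An aldoximes (post CYP79F1/F2), Bn aci-nitro intermediates (post
# CYP83A1, the SUR1 substrates), Cn post-SUR1 thiohydroximates handed to the
# lumped late steps.  The indolic branch mirrors this with IAOX/IB/IC.
MET_ENTRY = "L2"
TRP = "TRP"
_CHAIN = (2, 3, 4, 5)
_ALI_PRODUCT = {2: "3MSOP", 3: "4MSOB", 4: "5MSOP", 5: "6MSOH"}

#: Default rate constants, calibrated once so that wild-type steady-state
#: product pools are of comparable magnitude across the seven compounds and
#: the qualitative knockdown/treatment sign patterns hold.  Frozen; no claim
#: of matching any measured absolute concentration.
DEFAULT_PARAMS: dict[str, float] = {
    "influx_met": 1.5,
    "influx_trp": 0.6,
    "k_elong": 1.0,
    "k_cyp79f1": 0.35,
    "k_cyp79f2": 1.2,
    "k_cyp83a1": 2.0,
    "k_sur1": 1.5,
    "km_sur1": 0.4,
    "k_late_ali": 2.0,
    "k_cyp79b": 1.0,
    "k_cyp83b1": 2.0,
    "k_late_ind": 2.0,
    "k_cyp81f2": 0.5,
    "k_mod1m": 0.5,
    "k_deg": 0.3,
    "k_leak": 0.3,
}


def build_default_model(config: dict[str, float] | None = None,
                        sur1_kinetics: str = "competitive_mm") -> PathwayModel:
    """Build the canonical branched glucosinolate network.

    Aliphatic side: elongation chain L2→L3→L4→L5 (ELONG); per chain length
    an entry step (CYP79F1 on all pools, CYP79F2 on the long-chain pools L4
    and L5 only), then CYP83A1, then the shared SUR1 step, then the lumped
    late steps, yielding 3MSOP/4MSOB/5MSOP/6MSOH from L2/L3/L4/L5.  Indolic
    side: TRP→CYP79B→CYP83B1→SUR1→LATE_IND→I3M, with I3M→4OHI3M (CYP81F2)
    and I3M→1MOI3M (MOD1M) as parallel modifications.  All seven products
    turn over first-order via DEG; internal intermediates carry a smaller
    first-order background turnover, also charged to DEG, without which the
    entry steps could carry no flux control at steady state.

    Parameters
    ----------
    config
        Optional overrides for :data:`DEFAULT_PARAMS` keys and/or enzyme
        levels given as ``level_<ENZYME>`` (e.g. ``level_CYP79F1``).
    sur1_kinetics
        ``"competitive_mm"`` (default) or ``"linear"``; the linear variant
        makes the whole model exactly solvable and is used for solver
        validation.
    """
    p = dict(DEFAULT_PARAMS)
    levels = {e: 1.0 for e in EnzymeId}
    if config:
        for key, val in config.items():
            if key.startswith("level_"):
                enz = EnzymeId(key[len("level_"):])
                if val < 0:
                    raise ValueError(f"{key}={val} must be nonnegative")
                levels[enz] = float(val)
            elif key in p:
                if val <= 0:
                    raise ValueError(f"{key}={val} must be positive")
                p[key] = float(val)
            else:
                raise KeyError(f"unknown parameter {key!r}")
    if sur1_kinetics not in ("competitive_mm", "linear"):
        raise ValueError(f"sur1_kinetics={sur1_kinetics!r}")

    species: list[str] = []
    rxns: list[Reaction] = []

    def sur1_rxn(rid: str, sub: str, prod: str) -> Reaction:
        if sur1_kinetics == "linear":
            return Reaction(rid, sub, prod, EnzymeId.SUR1,
                            k=p["k_sur1"] / p["km_sur1"])
        return Reaction(rid, sub, prod, EnzymeId.SUR1, k=p["k_sur1"],
                        kinetics="competitive_mm", km=p["km_sur1"],
                        group="sur1")

    # aliphatic branch
    for n in _CHAIN:
        species += [f"L{n}", f"A{n}", f"B{n}", f"C{n}"]
    for n in _CHAIN[:-1]:
        rxns.append(Reaction(f"elong_{n}", f"L{n}", f"L{n + 1}",
                             EnzymeId.ELONG, k=p["k_elong"]))
    for n in _CHAIN:
        rxns.append(Reaction(f"cyp79f1_{n}", f"L{n}", f"A{n}",
                             EnzymeId.CYP79F1, k=p["k_cyp79f1"]))
    for n in (4, 5):  # long-chain substrate preference
        rxns.append(Reaction(f"cyp79f2_{n}", f"L{n}", f"A{n}",
                             EnzymeId.CYP79F2, k=p["k_cyp79f2"]))
    for n in _CHAIN:
        rxns.append(Reaction(f"cyp83a1_{n}", f"A{n}", f"B{n}",
                             EnzymeId.CYP83A1, k=p["k_cyp83a1"]))
        rxns.append(sur1_rxn(f"sur1_{n}", f"B{n}", f"C{n}"))
        rxns.append(Reaction(f"late_ali_{n}", f"C{n}", _ALI_PRODUCT[n],
                             EnzymeId.LATE_ALI, k=p["k_late_ali"]))

    # indolic branch
    species += [TRP, "IAOX", "IB", "IC"]
    rxns.append(Reaction("cyp79b", TRP, "IAOX", EnzymeId.CYP79B,
                         k=p["k_cyp79b"]))
    rxns.append(Reaction("cyp83b1", "IAOX", "IB", EnzymeId.CYP83B1,
                         k=p["k_cyp83b1"]))
    rxns.append(sur1_rxn("sur1_ind", "IB", "IC"))
    rxns.append(Reaction("late_ind", "IC", "I3M", EnzymeId.LATE_IND,
                         k=p["k_late_ind"]))
    rxns.append(Reaction("cyp81f2", "I3M", "4OHI3M", EnzymeId.CYP81F2,
                         k=p["k_cyp81f2"]))
    rxns.append(Reaction("mod1m", "I3M", "1MOI3M", EnzymeId.MOD1M,
                         k=p["k_mod1m"]))

    intermediates = list(species)
    species += list(COMPOUND_NAMES)

    for c in COMPOUND_NAMES:
        rxns.append(Reaction(f"deg_{c}", c, None, EnzymeId.DEG, k=p["k_deg"]))
    for sp in intermediates:
        rxns.append(Reaction(f"leak_{sp}", sp, None, EnzymeId.DEG,
                             k=p["k_leak"]))

    return PathwayModel(
        species=species,
        reactions=rxns,
        enzyme_levels=levels,
        influx={MET_ENTRY: p["influx_met"], TRP: p["influx_trp"]},
    )


@dataclass
class SteadyState:
    """Steady-state concentrations and per-reaction fluxes."""

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    converged: bool
    residual: float

    def product_concentrations(self) -> dict[str, float]:
        return {c: self.concentrations[c] for c in COMPOUND_NAMES}

    def compound_vector(self) -> np.ndarray:
        return np.array([self.concentrations[c] for c in COMPOUND_NAMES])


def _residual(model: PathwayModel, x: np.ndarray, floor: float) -> float:
    dx = model.rhs(x)
    scale = max(float(np.max(x, initial=0.0)), floor)
    return float(np.max(np.abs(dx)) / scale)


def steady_state(model: PathwayModel, tol: float = 1e-9,
                 t_max: float = 1e6, floor: float = 1e-12) -> SteadyState:
    """Solve for the steady state of ``model``.

    When every reaction is linear the stationary linear system is solved
    directly.  Otherwise the ODEs are integrated from empty pools, with a
    Newton polish, until the relative rate norm
    ``max|dX/dt| / max(max X, floor)`` drops below ``tol``.  Non-convergence
    within ``t_max`` is flagged on the result rather than raised, so callers
    can decide.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")

    if model.all_linear:
        A, b = model._linear_system()
        x = np.linalg.solve(A, -b)
        res = _residual(model, x, floor)
        return _pack(model, x, converged=res <= max(tol, 1e-12), residual=res)

    x = np.zeros(model.n_species)
    t = 50.0
    res = math.inf
    while t <= t_max:
        sol = solve_ivp(lambda _, y: model.rhs(y), (0.0, t), x,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        x = np.maximum(sol.y[:, -1], 0.0)
        # Newton polish from the integrated state
        try:
            r = root(model.rhs, x, method="hybr", tol=1e-13)
            if r.success and np.all(r.x > -1e-9):
                cand = np.maximum(r.x, 0.0)
                if _residual(model, cand, floor) < _residual(model, x, floor):
                    x = cand
        except Exception:
            pass
        res = _residual(model, x, floor)
        if res < tol:
            return _pack(model, x, converged=True, residual=res)
        t *= 4.0
    return _pack(model, x, converged=False, residual=res)


def _pack(model: PathwayModel, x: np.ndarray, converged: bool,
          residual: float) -> SteadyState:
    rates = model._rates(x)
    return SteadyState(
        concentrations={s: float(v) for s, v in zip(model.species, x)},
        fluxes={r.id: float(v) for r, v in zip(model.reactions, rates)},
        converged=converged,
        residual=residual,
    )


def apply_knockdown(model: PathwayModel, enzyme: EnzymeId,
                    r: float) -> PathwayModel:
    """Return a copy with ``enzyme``'s level multiplied by expression ratio ``r``.

    ``r`` is the heterozygote/wild-type relative expression, 0 < r <= 1.
    """
    if not 0 < r <= 1:
        raise ValueError(f"expression ratio r={r} must be in (0, 1]")
    if enzyme not in MANIPULABLE_ENZYMES:
        raise ValueError(f"{enzyme.value} is not one of the manipulable "
                         f"enzymes {sorted(e.value for e in MANIPULABLE_ENZYMES)}")
    return model.with_enzyme_levels(
        {enzyme: model.enzyme_levels[enzyme] * r})


def write_steady_state_csv(ss: SteadyState, path) -> None:
    """Write species concentrations as a two-column CSV."""
    import pandas as pd

    pd.DataFrame(
        {"species": list(ss.concentrations),
         "value": list(ss.concentrations.values())}
    ).to_csv(path, index=False, float_format="%.12g")
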