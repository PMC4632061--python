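"""Ground-truth control coefficients from the kinetic model.

Metabolic control analysis defines the control coefficient of step *i* over
a steady-state quantity *X* as the log-log sensitivity
``C_i = d ln X / d ln E_i``.  Here it is computed by central finite
differences on the kinetic model, providing an estimator-independent oracle,
together with the two classical summation theorems used as internal
consistency checks: flux control coefficients over the complete step set
(enzymes, the elongation and turnover pseudo-steps, and the two influxes)
sum to 1, concentration control coefficients sum to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .pathway import (COMPOUND_NAMES, INFLUX_STEPS, EnzymeId, PathwayModel,
                      steady_state)

#: Every degree-1 step of the default network, pseudo-steps included.
ALL_STEPS: tuple = tuple(EnzymeId) + INFLUX_STEPS


@dataclass(frozen=True)
class ControlCoefficient:
    """Log-log sensitivity of one steady-state target to one step."""

    step: str
    target: str
    value: float


def _target_value(model: PathwayModel, target: str, tol: float) -> float:
    ss = steady_state(model, tol=tol)
    if not ss.converged:
        raise RuntimeError(f"steady state did not converge (residual "
                           f"{ss.residual:.3g}) while evaluating {target!r}")
    if target in ss.concentrations:
        return ss.concentrations[target]
    if target in ss.fluxes:
        return ss.fluxes[target]
    raise KeyError(f"unknown target {target!r}: not a species or reaction id")


def true_control_coefficient(model: PathwayModel, step, target: str,
                             delta: float = 0.01,
                             tol: float = 1e-11) -> ControlCoefficient:
    """Central-difference control coefficient of ``step`` over ``target``.

    ``step`` is an :class:`EnzymeId` or an influx pseudo-step label;
    ``target`` a species (concentration control) or reaction id (flux
    control).  The step level is perturbed multiplicatively by ``e^±delta``
    and the symmetric difference of log targets taken, which is accurate to
    O(delta^2).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    step_label = step.value if isinstance(step, EnzymeId) else str(step)
    up = _target_value(model.scaled(step, math.exp(delta)), target, tol)
    dn = _target_value(model.scaled(step, math.exp(-delta)), target, tol)
    if up <= 0 or dn <= 0:
        raise RuntimeError(f"nonpositive steady-state {target!r} under "
                           f"perturbation of {step_label}")
    value = (math.log(up) - math.log(dn)) / (2.0 * delta)
    return ControlCoefficient(step=step_label, target=target, value=value)


def summation_check(model: PathwayModel, target: str,
                    delta: float = 0.01) -> float:
    """Sum of control coefficients of every step over ``target``.

    For a flux target the flux summation theorem predicts 1; for a
    concentration target (with influx and degradation pseudo-steps
    included, as they are here) the concentration summation theorem
    predicts 0.
    """
    steps = tuple(EnzymeId) + model.influx_steps
    return float(sum(
        true_control_coefficient(model, step, target, delta=delta).value
        for step in steps))


def control_matrix(model: PathwayModel,
                   steps=(EnzymeId.CYP79F1, EnzymeId.CYP83A1, EnzymeId.SUR1),
                   targets: tuple[str, ...] = COMPOUND_NAMES,
                   delta: float = 0.01) -> pd.DataFrame:
    """Matrix of true concentration-control coefficients.

    Rows are targets (default: the seven glucosinolate products), columns
    the requested steps (default: the three manipulable enzymes).
    """
    data = {
        (s.value if isinstance(s, EnzymeId) else str(s)): [
            true_control_coefficient(model, s, t, delta=delta).value
            for t in targets]
        for s in steps
    }
    return pd.DataFrame(data, index=list(targets))
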