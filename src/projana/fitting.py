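"""Demographic parameter fitting by LSS minimisation.

Free parameters of a demography template are fitted by cyclic coordinate
descent: for each parameter in declared order, a bounded one-dimensional
Brent search minimises the total LSS between simulated and observed
projection curves; cycles repeat until a full pass improves the total LSS by
less than ``tol`` or ``max_cycles`` is reached.

The objective is stochastic (it runs the coalescent simulator), so every
evaluation within one fit reuses the same random seed — common random
numbers — which turns the objective into a deterministic, if slightly
jagged, function of the parameters and lets a line search make sense of it.
By default the simulator runs in expectation mode (mutation placement
integrated out analytically per genealogy), which removes one layer of Monte
Carlo noise at no cost in bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .coalescent import simulate_projection
from .demography import DemographicModel
from .projection import ProjectionCurve, lss

__all__ = ["FreeParameter", "FitConfig", "FitResult", "fit_parameters"]


@dataclass(frozen=True)
class FreeParameter:
    """One fitted parameter: its name in ``named_parameters``, box bounds and
    an optional log-scale transform for the line search."""

    name: str
    lower: float
    upper: float
    transform: str = "linear"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if self.transform not in ("linear", "log"):
            raise ValueError(f"{self.name}: transform must be 'linear' or 'log'")
        if self.transform == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log transform requires positive bounds")

    def to_internal(self, value: float) -> float:
        return math.log(value) if self.transform == "log" else value

    def from_internal(self, value: float) -> float:
        return math.exp(value) if self.transform == "log" else value


@dataclass
class FitConfig:
    sites: int = 100_000
    tol: float = 1e-3
    max_cycles: int = 10
    expected: bool = True
    xatol_frac: float = 5e-3  # Brent absolute x tolerance as a fraction of the range
    weights: Sequence[float] | None = None  # per observed curve


@dataclass
class FitResult:
    values: dict
    lss: float
    evaluations: int
    trace: list = field(default_factory=list)


def fit_parameters(
    template: Union[DemographicModel, Sequence[DemographicModel]],
    free: Sequence[FreeParameter],
    observed: Union[ProjectionCurve, Sequence[ProjectionCurve]],
    sites: int | None = None,
    seed: int = 0,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit ``free`` parameters of ``template`` to ``observed`` curves.

    ``template`` and ``observed`` may be single objects or parallel
    sequences (one template per observed curve, all sharing the same
    ``named_parameters``); the objective is the weighted sum of per-curve
    LSS scores.  The returned LSS always equals a fresh objective
    evaluation at the returned values (common random numbers make the
    objective deterministic), and it never exceeds the objective at the
    starting values.
    """
    config = config or FitConfig()
    if sites is not None:
        config.sites = int(sites)

    templates = [template] if isinstance(template, DemographicModel) else list(template)
    curves = [observed] if isinstance(observed, ProjectionCurve) else list(observed)
    if len(templates) == 1 and len(curves) > 1:
        templates = templates * len(curves)
    if len(templates) != len(curves):
        raise ValueError(
            f"{len(templates)} templates cannot be matched to {len(curves)} observed curves"
        )
    weights = list(config.weights) if config.weights else [1.0] * len(curves)
    if len(weights) != len(curves):
        raise ValueError("weights must match the number of observed curves")

    for p in free:
        for tpl in templates:
            if p.name not in tpl.named_parameters:
                raise KeyError(
                    f"free parameter {p.name!r} not declared in the template's "
                    f"named_parameters ({sorted(tpl.named_parameters)})"
                )

    eval_seed = int(np.random.SeedSequence(int(seed)).generate_state(1)[0] % (2**31))
    n_eval = 0
    trace: list = []

    def objective(values: dict) -> float:
        nonlocal n_eval
        total = 0.0
        for tpl, obs, w in zip(templates, curves, weights):
            bound = tpl.bind(values)
            sim = simulate_projection(
                bound, config.sites, eval_seed, expected=config.expected
            )
            total += w * lss(sim, obs)
        if not np.isfinite(total):
            raise ValueError(f"non-finite objective at parameter values {values}")
        n_eval += 1
        trace.append((dict(values), total))
        return total

    values = {
        p.name: float(np.clip(templates[0].named_parameters[p.name], p.lower, p.upper))
        for p in free
    }
    best = objective(values)

    for _cycle in range(config.max_cycles if free else 0):
        cycle_start = best
        for p in free:
            lo, hi = p.to_internal(p.lower), p.to_internal(p.upper)

            def line(u, _p=p):
                trial = dict(values)
                trial[_p.name] = _p.from_internal(u)
                return objective(trial)

            res = minimize_scalar(
                line,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": (hi - lo) * config.xatol_frac},
            )
            # Brent never lands exactly on a bound; check both explicitly so a
            # true value at a bound is returned as the bound
            candidates = [(float(res.fun), float(res.x)), (line(lo), lo), (line(hi), hi)]
            fun, x = min(candidates)
            if fun < best:
                values[p.name] = p.from_internal(x)
                best = fun
        if cycle_start - best < config.tol:
            break

    return FitResult(values=values, lss=best, evaluations=n_eval, trace=trace)
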