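"""Local refinement of a GA result with the size-change dynamics frozen.

Wraps the scipy optimizers offered by AFS inference tools — Powell (the
default, reported as the most effective), Nelder-Mead, BFGS and L-BFGS-B —
over the numeric parameters of a model.  Positive parameters (sizes,
durations, split fractions) are optimized in log space; migration rates in
linear space with a lower bound of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .model import (
    Bounds,
    DemographicModel,
    decode,
    encode,
    epoch_dynamics,
    vector_spec,
)

__all__ = ["LocalSearchConfig", "local_optimize"]

_METHODS = ("Powell", "Nelder-Mead", "BFGS", "L-BFGS-B")


@dataclass(frozen=True)
class LocalSearchConfig:
    """``restarts`` re-launches the optimizer from its own result until the
    log-likelihood gain drops below ``improvement_tol`` (direction-set
    methods like Powell profit from the reset of their search directions)."""

    method: str = "Powell"
    max_evaluations: int = 5000
    bounds: Bounds = field(default_factory=Bounds)
    log_domain: bool = True
    restarts: int = 5
    improvement_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.restarts < 1 or self.improvement_tol <= 0:
            raise ValueError("restarts must be >= 1 and improvement_tol positive")


def _transforms(spec, bounds: Bounds, log_domain: bool):
    """Per-slot forward/backward transforms and transformed box bounds."""
    fwd, bwd, boxes = [], [], []
    for slot in spec:
        lo, hi = bounds.of_kind(slot.kind)
        if log_domain and slot.kind in ("size", "time", "fraction"):
            fwd.append(math.log)
            bwd.append(math.exp)
            boxes.append((math.log(lo), math.log(hi)))
        else:
            fwd.append(lambda v: v)
            bwd.append(lambda v: v)
            boxes.append((lo, hi))
    return fwd, bwd, boxes


def local_optimize(
    start: DemographicModel,
    fitness: Callable[[DemographicModel], float],
    config: LocalSearchConfig | None = None,
) -> DemographicModel:
    """Refine ``start`` by local search; never returns a worse model.

    The dynamics of population size change are fixed to those of ``start``
    (they are categorical and excluded from the optimized vector, whose
    dimension therefore follows the final parameter count).  Failed fitness
    evaluations count as ``-inf`` rather than aborting the search.
    """
    config = config or LocalSearchConfig()
    best = start
    best_ll = fitness(start)
    for _ in range(config.restarts):
        refined = _single_pass(best, fitness, config)
        ll = fitness(refined)
        if ll > best_ll:
            gain = ll - best_ll
            best, best_ll = refined, ll
            if gain < config.improvement_tol:
                break
        else:
            break
    return best


def _single_pass(
    start: DemographicModel,
    fitness: Callable[[DemographicModel], float],
    config: LocalSearchConfig,
) -> DemographicModel:
    spec = vector_spec(start.structure, include_dynamics=False)
    dynamics = epoch_dynamics(start)
    structure = start.structure
    x0_nat = encode(start, include_dynamics=False)
    if x0_nat.size == 0:  # parameter-free model (simplest 1-population history)
        return start
    fwd, bwd, boxes = _transforms(spec, config.bounds, config.log_domain)
    lo = np.array([b[0] for b in boxes])
    hi = np.array([b[1] for b in boxes])
    x0 = np.clip([f(v) for f, v in zip(fwd, np.clip(x0_nat, 1e-300, None) if config.log_domain else x0_nat)], lo, hi)

    start_ll = fitness(start)

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        nat = np.array([b(v) for b, v in zip(bwd, x)])
        try:
            model = decode(nat, structure, dynamics=dynamics)
            ll = fitness(model)
        except (ValueError, FloatingPointError):
            return np.inf
        return np.inf if not np.isfinite(ll) else -ll

    # Powell and Nelder-Mead run unconstrained on the transformed scale with
    # clipping inside the objective: scipy's bounded direction-set line
    # search degenerates on very wide (log-scale) boxes and can terminate at
    # a worse point than it started from
    kwargs: dict = {"method": config.method}
    if config.method == "L-BFGS-B":
        kwargs["bounds"] = optimize.Bounds(lo, hi)
    options: dict = {}
    if config.method == "Powell":
        options["maxfev"] = config.max_evaluations
    elif config.method == "Nelder-Mead":
        options["maxfev"] = config.max_evaluations
    else:
        options["maxiter"] = config.max_evaluations
        kwargs["jac"] = None  # numerical finite differences
    res = optimize.minimize(objective, x0, options=options, **kwargs)

    xbest = np.clip(res.x, lo, hi)
    nat = np.array([b(v) for b, v in zip(bwd, xbest)])
    try:
        refined = decode(nat, structure, dynamics=dynamics)
        refined_ll = fitness(refined)
    except (ValueError, FloatingPointError):
        return start
    return refined if refined_ll > start_ll else start
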