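"""Conversion between genetic (coalescent-scaled) and physical units.

The engine works in genetic units: sizes relative to the ancestral size
``N_A``, times in units of ``2 N_A`` generations and migration rates scaled
by ``2 N_A``.  The overall mutation influx constant ``theta_0 = 4 mu L``
(``mu``: per-site per-generation mutation rate, ``L``: effective sequence
length) links the profiled likelihood scale ``theta-hat = 4 mu L N_A`` to an
absolute ancestral size, from which every other quantity follows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import DemographicModel, Split

__all__ = [
    "theta0",
    "ancestral_size",
    "to_physical_units",
    "scale_factor_from_size",
    "split_time_generations",
]


def theta0(mu: float, L: float) -> float:
    """Expected new mutations per individual per generation, ``4 mu L``."""
    if mu <= 0 or L <= 0:
        raise ValueError("mu and L must be positive")
    return 4.0 * mu * L


def ancestral_size(theta_hat: float, mu: float, L: float) -> float:
    """Ancestral effective size ``N_A = theta-hat / (4 mu L)``."""
    if theta_hat <= 0:
        raise ValueError("theta_hat must be positive")
    return theta_hat / theta0(mu, L)


def to_physical_units(
    model: DemographicModel,
    theta_hat: float,
    mu: float,
    L: float,
    T_g: float,
) -> pd.DataFrame:
    """Tabulate the model in physical units.

    One row per event, most ancient first: population sizes ``N = nu N_A``
    in individuals, epoch lengths in generations (``t = 2 N_A tau``) and in
    years (``t T_g``), per-generation migration rates ``m = M / (2 N_A)``.
    """
    if T_g <= 0:
        raise ValueError("generation time must be positive")
    n_a = ancestral_size(theta_hat, mu, L)
    rows: list[dict] = []
    rows.append(
        {
            "event": "ancestral",
            "N_A": n_a,
            "sizes_individuals": (n_a,),
            "duration_generations": np.inf,
            "duration_years": np.inf,
        }
    )
    for ev in model.events:
        if isinstance(ev, Split):
            rows.append({"event": "split", "fraction": ev.fraction})
            continue
        gens = 2.0 * n_a * ev.duration
        row = {
            "event": "epoch",
            "sizes_individuals": tuple(s * n_a for s in ev.end_sizes),
            "dynamics": tuple(d.value for d in ev.dynamics),
            "duration_generations": gens,
            "duration_years": gens * T_g,
        }
        if ev.num_pops > 1:
            row["migration_per_generation"] = tuple(
                tuple(m / (2.0 * n_a) for m in r) for r in ev.migration
            )
        rows.append(row)
    return pd.DataFrame(rows)


def scale_factor_from_size(reference_size: float, mean_relative_size: float) -> float:
    """Absolute-size anchor ``x`` with ``x * mean_relative_size = reference_size``.

    Used when no mutation-rate calibration exists but an independent census
    or effective-size estimate of one (or an average of) population(s) is
    available: ``x`` then plays the role of ``N_A``.
    """
    if reference_size <= 0 or mean_relative_size <= 0:
        raise ValueError("sizes must be positive")
    return reference_size / mean_relative_size


def split_time_generations(tau_split: float, x: float) -> float:
    """Age of a split in generations, ``t = 2 x tau`` for anchor ``x``."""
    if x <= 0:
        raise ValueError("scale anchor must be positive")
    return 2.0 * x * tau_split
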