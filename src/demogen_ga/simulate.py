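"""Synthetic observed spectra for the three simulated inference scenarios.

Each scenario fixes a true demographic model with sudden size dynamics, a
sample of 20 chromosomes per population and a mutation scale ``theta0``
large enough (default 1000) that the spectrum is informative about every
free parameter.  Observed data are produced either as the engine's expected
spectrum itself or as independent Poisson draws around it — the exact
statistical model under which the composite likelihood is correctly
specified.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .engine import EngineConfig, expected_afs
from .model import DemographicModel, Dynamics, Epoch, Split
from .spectrum import FrequencySpectrum

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "make_scenario",
    "simulate_observed_afs",
    "make_bootstrap_regions",
]

SCENARIO_NAMES = ("bottleneck_1pop", "split_mig_2pop", "secondary_contact_3pop")

_SUD = Dynamics.SUDDEN


@dataclass(frozen=True)
class Scenario:
    """A named true model with its sampling design.

    ``free_params`` maps canonical parameter labels (see
    :func:`demogen_ga.model.vector_spec` with dynamics excluded) to the true
    values of the scenario's identifiable parameters.  Constrained /
    unidentifiable positions (e.g. the split fraction under sudden dynamics,
    or sizes shared between epochs) are not listed, which is why the counts
    are 4, 5 and 8 for the three scenarios.
    """

    name: str
    model: DemographicModel
    sample_sizes: tuple[int, ...]
    theta0: float
    free_params: dict[str, float]

    def engine_config(self, **overrides) -> EngineConfig:
        kwargs = {"sample_sizes": self.sample_sizes, "theta0": self.theta0}
        kwargs.update(overrides)
        return EngineConfig(**kwargs)


def make_scenario(name: str, theta0: float = 1000.0) -> Scenario:
    """Build one of the three named scenarios (20 chromosomes per population).

    * ``bottleneck_1pop`` — crash to a tenth of the ancestral size followed
      by recovery; 4 parameters.
    * ``split_mig_2pop`` — ancestral division with asymmetric migration
      between the daughters; 5 parameters.
    * ``secondary_contact_3pop`` — two splits, an isolation interval, then
      symmetric migration among all three populations; 8 parameters.
    """
    if name == "bottleneck_1pop":
        model = DemographicModel(
            (3,),
            [
                Epoch(0.2, (0.1,), (_SUD,)),
                Epoch(0.1, (1.0,), (_SUD,)),
            ],
        )
        free = {"e1_nu1": 0.1, "e1_T": 0.2, "e2_nu1": 1.0, "e2_T": 0.1}
        return Scenario(name, model, (20,), theta0, free)
    if name == "split_mig_2pop":
        model = DemographicModel(
            (1, 1),
            [
                Split(0.5),
                Epoch(0.5, (1.5, 0.5), (_SUD, _SUD), ((0.0, 1.0), (0.5, 0.0))),
            ],
        )
        free = {
            "e1_nu1": 1.5,
            "e1_nu2": 0.5,
            "e1_m12": 1.0,
            "e1_m21": 0.5,
            "e1_T": 0.5,
        }
        return Scenario(name, model, (20, 20), theta0, free)
    if name == "secondary_contact_3pop":
        m = 1.0
        sym = ((0.0, m, m), (m, 0.0, m), (m, m, 0.0))
        model = DemographicModel(
            (1, 1, 2),
            [
                Split(0.5),
                Epoch(0.3, (1.2, 0.8), (_SUD, _SUD)),  # isolation, 2 populations
                Split(0.5),
                Epoch(0.15, (1.2, 0.6, 0.9), (_SUD,) * 3),  # isolation, 3 populations
                Epoch(0.1, (1.2, 0.6, 0.9), (_SUD,) * 3, sym),  # secondary contact
            ],
        )
        free = {
            "e1_nu1": 1.2,
            "e1_nu2": 0.8,
            "e1_T": 0.3,
            "e2_nu2": 0.6,
            "e2_nu3": 0.9,
            "e2_T": 0.15,
            "e3_m12": m,
            "e3_T": 0.1,
        }
        return Scenario(name, model, (20, 20, 20), theta0, free)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def simulate_observed_afs(
    model: DemographicModel,
    config: EngineConfig,
    seed: int,
    mode: str = "poisson",
) -> FrequencySpectrum:
    """Observed spectrum for a model: the expected AFS or Poisson draws.

    ``mode="expected"`` returns the engine spectrum unchanged;
    ``mode="poisson"`` draws each unmasked entry independently from a
    Poisson law with that mean, reproducibly for a given seed.
    """
    expected = expected_afs(model, config)
    if mode == "expected":
        return expected
    if mode != "poisson":
        raise ValueError("mode must be 'expected' or 'poisson'")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.counts).astype(float)
    counts[expected.mask] = 0.0
    return FrequencySpectrum(
        counts, expected.mask.copy(), expected.folded, expected.population_labels
    )


def make_bootstrap_regions(
    model: DemographicModel,
    config: EngineConfig,
    n_regions: int,
    seed: int,
) -> list[FrequencySpectrum]:
    """Independent region spectra, each Poisson with scale ``theta0 / n_regions``.

    Emulates unlinked genomic blocks: the region spectra are independent and
    sum, in expectation, to the full spectrum — the setting in which block
    bootstrapping is valid and the composite likelihood is well specified.
    """
    if n_regions < 2:
        raise ValueError("need at least two regions")
    region_cfg = EngineConfig(
        sample_sizes=config.sample_sizes,
        theta0=config.theta0 / n_regions,
        bins_factor=config.bins_factor,
        time_step=config.time_step,
        max_substeps=config.max_substeps,
        engine_id=config.engine_id,
    )
    expected = expected_afs(model, region_cfg)
    rng = np.random.default_rng(seed)
    regions = []
    for _ in range(n_regions):
        counts = rng.poisson(expected.counts).astype(float)
        counts[expected.mask] = 0.0
        regions.append(
            FrequencySpectrum(counts, expected.mask.copy(), expected.folded)
        )
    return regions
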