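"""Full inference orchestration: GA, local search and structure increases.

Each independent run starts at the initial structure, alternates global GA
search with local refinement, and — while the current structure is below
the final one — increases the model's complexity by one interval split and
restarts the GA from the expanded best model.  Runs are aggregated into a
single report with AIC (and CLAIC when region spectra are available), an
overfitting check and, when unit constants are supplied, a physical-unit
table of the best model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import EngineConfig, model_loglikelihood
from .ga import GAConfig, run_ga
from .local_search import LocalSearchConfig, local_optimize
from .model import (
    DemographicModel,
    increase_structure,
    model_to_text,
    param_count_final,
)
from .selection import SelectionReport, claic
from .spectrum import FrequencySpectrum
from .units import to_physical_units

__all__ = ["RunConfig", "InferenceResult", "run_inference"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one inference needs besides the data."""

    initial_structure: tuple[int, ...]
    final_structure: tuple[int, ...]
    ga: GAConfig = field(default_factory=GAConfig)
    local_search: LocalSearchConfig = field(default_factory=LocalSearchConfig)
    engine: EngineConfig | None = None
    mu: float | None = None
    L: float | None = None
    T_g: float | None = None
    num_runs: int = 10
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ini, fin = tuple(self.initial_structure), tuple(self.final_structure)
        object.__setattr__(self, "initial_structure", ini)
        object.__setattr__(self, "final_structure", fin)
        if len(ini) != len(fin):
            raise ValueError("initial and final structures must have equal length")
        if any(i > f for i, f in zip(ini, fin)):
            raise ValueError("initial structure must be <= final structure componentwise")
        if self.num_runs < 1:
            raise ValueError("need at least one run")


@dataclass
class RunRecord:
    """Per-run trace: the best model and log-likelihood at each structure."""

    run_index: int
    per_structure: dict[tuple[int, ...], tuple[DemographicModel, float]]


@dataclass
class InferenceResult:
    report: SelectionReport
    best_models: dict[tuple[int, ...], tuple[DemographicModel, float]]
    runs: list[RunRecord]
    physical_units: object | None = None

    @property
    def best_model(self) -> DemographicModel:
        structure, _ = max(
            self.best_models.items(), key=lambda item: item[1][1]
        )
        return self.best_models[structure][0]


def run_inference(
    data: FrequencySpectrum,
    config: RunConfig,
    regions: Sequence[FrequencySpectrum] | None = None,
) -> InferenceResult:
    """Infer demographic models for ``data`` under ``config``.

    Per run: GA at the current structure, local refinement with dynamics
    fixed, then (while below the final structure) a complexity increase and
    another GA round.  A failing run is recorded and skipped; the remaining
    runs are aggregated.  Reported ``k`` uses the dynamics-fixed parameter
    count of each structure.
    """
    engine = config.engine or EngineConfig(sample_sizes=data.sample_sizes)
    if engine.sample_sizes != data.sample_sizes:
        raise ValueError(
            f"engine sample sizes {engine.sample_sizes} != data {data.sample_sizes}"
        )

    def fitness(model: DemographicModel) -> float:
        try:
            ll, _ = model_loglikelihood(model, data, engine)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return -np.inf
        return ll

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    runs: list[RunRecord] = []
    for r in range(config.num_runs):
        rng = np.random.default_rng([config.seed, r])
        record = RunRecord(run_index=r, per_structure={})
        try:
            structure = config.initial_structure
            initial_models: list[DemographicModel] = []
            while True:
                best, history = run_ga(
                    fitness, structure, config.ga, rng, initial_models or None
                )
                refined = local_optimize(best.model, fitness, config.local_search)
                ll = fitness(refined)
                record.per_structure[structure] = (refined, ll)
                if out_dir:
                    stem = f"run{r}_structure{'-'.join(map(str, structure))}"
                    (out_dir / f"{stem}.model.txt").write_text(model_to_text(refined))
                    _write_history(out_dir / f"{stem}.log", history)
                if structure == config.final_structure:
                    break
                expanded = increase_structure(refined, config.final_structure, rng)
                structure = expanded.structure
                initial_models = [expanded]
        except Exception as exc:  # noqa: BLE001 — isolate run failures
            warnings.warn(f"run {r} aborted: {exc}")
        if record.per_structure:
            runs.append(record)
    if not runs:
        raise RuntimeError("every inference run failed")

    # aggregate the best model per structure across runs
    best_models: dict[tuple[int, ...], tuple[DemographicModel, float]] = {}
    for record in runs:
        for structure, (model, ll) in record.per_structure.items():
            if structure not in best_models or ll > best_models[structure][1]:
                best_models[structure] = (model, ll)

    names, ks, logLs = [], [], []
    claics: list[float] | None = [] if regions else None
    P = len(config.final_structure)
    for structure, (model, ll) in sorted(best_models.items()):
        names.append("structure " + str(structure))
        ks.append(param_count_final(structure, P))
        logLs.append(ll)
        if regions:
            claics.append(
                claic(model, data, regions, engine, seed=config.seed)["claic"]
            )
    report = SelectionReport.from_fits(names, ks, logLs, claics)

    physical = None
    if config.mu and config.L and config.T_g:
        best_structure = max(best_models, key=lambda s: best_models[s][1])
        model, _ = best_models[best_structure]
        _, theta_hat = model_loglikelihood(model, data, engine)
        physical = to_physical_units(model, theta_hat, config.mu, config.L, config.T_g)

    result = InferenceResult(
        report=report, best_models=best_models, runs=runs, physical_units=physical
    )
    if out_dir:
        report.to_tsv(out_dir / "report.tsv")
    return result


def _write_history(path: Path, history) -> None:
    lines = ["iteration\tbest_ll\tmean_ll\trate\tstrength"]
    for i, (b, m, r, s) in enumerate(
        zip(history.best_ll, history.mean_ll, history.rate, history.strength)
    ):
        lines.append(f"{i}\t{b:.6f}\t{m:.6f}\t{r:.6f}\t{s:.6f}")
    path.write_text("\n".join(lines) + "\n")
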