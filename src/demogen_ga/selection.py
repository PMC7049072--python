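"""Model comparison: AIC, composite-likelihood AIC, Akaike weights, bootstrap CIs.

For a composite (pseudo-)likelihood the usual AIC penalty ``k`` is replaced
by the Godambe trace ``tr(J H^-1)``, where ``H`` is the expected negative
Hessian of the composite log-likelihood and ``J`` the variability matrix of
its score, here estimated by block bootstrapping over unlinked regions.
Derivatives are taken in log-parameter space (all model parameters are
positive) by central finite differences with a relative step ``epsilon``;
the result should always be checked across a sweep of ``epsilon`` values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import EngineConfig, model_loglikelihood
from .model import DemographicModel, decode, encode, epoch_dynamics
from .spectrum import FrequencySpectrum, bootstrap_resample

__all__ = [
    "aic",
    "claic",
    "akaike_weights",
    "bootstrap_cis",
    "overfit_check",
    "SelectionReport",
    "OverfitWarning",
]


class OverfitWarning(UserWarning):
    """Best-likelihood and best-information-criterion models disagree."""


def aic(k: int, logL: float) -> float:
    """Akaike information criterion ``2 k - 2 logL`` (smaller is better)."""
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return 2.0 * k - 2.0 * logL


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Relative support ``w_i = exp(-D_i / 2) / sum_j exp(-D_j / 2)`` with
    ``D_i = AIC_i - min(AIC)``."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("need a non-empty sequence of finite AIC values")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def overfit_check(best_by_ll: object, best_by_ic: object) -> str | None:
    """Warn iff the best-likelihood and best-criterion models differ.

    Returns the warning message (also emitted as :class:`OverfitWarning`),
    or ``None`` when the two coincide.
    """
    if best_by_ll is None or best_by_ic is None:
        raise ValueError("both model identities are required")
    if best_by_ll == best_by_ic:
        return None
    msg = (
        f"possible overfitting: best likelihood model {best_by_ll!r} differs "
        f"from best information-criterion model {best_by_ic!r}"
    )
    warnings.warn(msg, OverfitWarning, stacklevel=2)
    return msg


# ---------------------------------------------------------------------------
# CLAIC via numerical Godambe adjustment
# ---------------------------------------------------------------------------

def _loglik_in_logspace(
    model: DemographicModel, config: EngineConfig
) -> tuple[Callable[[np.ndarray], Callable[[FrequencySpectrum], float]], np.ndarray]:
    """Return an evaluator ``f(z)(data) -> logL`` over log numeric parameters.

    ``z`` stacks the logs of the model's numeric parameters followed by the
    log of the mutation scale theta; the scale is *not* profiled inside the
    derivative computations, so the differentiated dimension is exactly the
    free-parameter dimension of the reported model.
    """
    dynamics = epoch_dynamics(model)
    structure = model.structure
    x0 = encode(model, include_dynamics=False)
    if np.any(x0 <= 0):
        # zero migration rates cannot be log-stepped; nudge to a tiny floor
        x0 = np.maximum(x0, 1e-8)

    def make(z: np.ndarray) -> Callable[[FrequencySpectrum], float]:
        nat = np.exp(z[:-1])
        theta = float(np.exp(z[-1]))
        m = decode(nat, structure, dynamics=dynamics)

        def ll(data: FrequencySpectrum) -> float:
            cfg = EngineConfig(
                sample_sizes=config.sample_sizes,
                theta0=theta,
                bins_factor=config.bins_factor,
                time_step=config.time_step,
                max_substeps=config.max_substeps,
                engine_id=config.engine_id,
            )
            value, _ = model_loglikelihood(m, data, cfg, profile_scale=False)
            return value

        return ll

    return make, np.log(x0)


def claic(
    model: DemographicModel,
    data: FrequencySpectrum,
    regions: Sequence[FrequencySpectrum],
    config: EngineConfig,
    epsilon: float = 1e-4,
    n_boot: int | None = None,
    seed: int = 0,
) -> dict:
    """Composite-likelihood AIC ``2 tr(J H^-1) - 2 logL`` at the fitted model.

    ``H`` is the negative central-difference Hessian of the full-data
    composite log-likelihood at the optimum; ``J`` is the covariance of the
    score over block-bootstrap resamples of the region spectra.  Returns a
    dict with the score, the trace, ``logL``, the ``epsilon`` used and the
    condition number of ``H``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(regions) < 2:
        raise ValueError("need at least two bootstrap regions")
    from .spectrum import optimal_scale
    from .engine import expected_afs
    from .spectrum import fold as fold_fs

    # anchor theta at its profiled optimum for the full data
    m_unit = expected_afs(model, EngineConfig(
        sample_sizes=config.sample_sizes, theta0=1.0,
        bins_factor=config.bins_factor, time_step=config.time_step,
        max_substeps=config.max_substeps, engine_id=config.engine_id))
    if data.folded:
        m_unit = fold_fs(m_unit)
    theta_hat = optimal_scale(m_unit, data)

    make, z_params = _loglik_in_logspace(model, config)
    z0 = np.concatenate([z_params, [np.log(theta_hat)]])
    p = z0.size

    def ll_full(z: np.ndarray) -> float:
        return make(z)(data)

    logL = ll_full(z0)

    # central-difference Hessian of the full-data log-likelihood
    H = np.empty((p, p))
    e = np.eye(p) * epsilon
    f0 = logL
    for i in range(p):
        for j in range(i, p):
            if i == j:
                fpp = ll_full(z0 + e[i])
                fmm = ll_full(z0 - e[i])
                H[i, i] = (fpp - 2.0 * f0 + fmm) / epsilon**2
            else:
                fpp = ll_full(z0 + e[i] + e[j])
                fpm = ll_full(z0 + e[i] - e[j])
                fmp = ll_full(z0 - e[i] + e[j])
                fmm = ll_full(z0 - e[i] - e[j])
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * epsilon**2)
    H = -H  # negative Hessian

    # score covariance over bootstrap resamples
    n_boot = n_boot or max(2 * len(regions), 50)
    rng = np.random.default_rng(seed)
    grads = np.empty((n_boot, p))
    for b in range(n_boot):
        boot = bootstrap_resample(regions, rng)
        g = np.empty(p)
        for i in range(p):
            g[i] = (make(z0 + e[i])(boot) - make(z0 - e[i])(boot)) / (2.0 * epsilon)
        grads[b] = g
    J = np.cov(grads, rowvar=False)

    cond = float(np.linalg.cond(H))
    try:
        trace = float(np.trace(np.linalg.solve(H, J)))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"Hessian is singular (condition number {cond:.3g}); "
            "try a different epsilon or more bootstrap regions"
        ) from None
    return {
        "claic": 2.0 * trace - 2.0 * logL,
        "trace": trace,
        "logL": logL,
        "epsilon": epsilon,
        "hessian_condition": cond,
        "n_params": p,
    }


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bootstrap_cis(
    fit_procedure: Callable[[FrequencySpectrum], np.ndarray],
    regions: Sequence[FrequencySpectrum],
    n_boot: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-space bootstrap intervals ``exp(mean(log t*) +/- sd(log t*))``.

    ``fit_procedure`` maps a resampled spectrum to the vector of fitted
    (strictly positive) parameters — in the reference protocol a single
    local optimization launched from the reported optimum.  Bootstrap fits
    that fail are dropped with a warning while they stay below 10% of
    ``n_boot``; more failures abort.
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap replicates")
    rng = np.random.default_rng(seed)
    fits: list[np.ndarray] = []
    failures = 0
    for _ in range(n_boot):
        boot = bootstrap_resample(regions, rng)
        try:
            params = np.asarray(fit_procedure(boot), dtype=float)
            if np.any(params <= 0) or not np.all(np.isfinite(params)):
                raise ValueError("non-positive or non-finite fitted parameter")
            fits.append(params)
        except Exception as exc:  # noqa: BLE001 — any fit failure is recorded
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap fits failed")
    if failures:
        warnings.warn(f"{failures}/{n_boot} bootstrap fits failed and were excluded")
    arr = np.log(np.vstack(fits))
    mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=0)
    return pd.DataFrame(
        {
            "estimate": np.exp(mean),
            "low": np.exp(mean - sd),
            "high": np.exp(mean + sd),
        }
    )


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Tabular comparison of fitted models.

    ``table`` has one row per model: k, logL, AIC, optional CLAIC, delta-AIC
    and Akaike weight; ``overfit_warning`` holds the message when the
    best-likelihood and best-criterion models disagree.
    """

    table: pd.DataFrame
    overfit_warning: str | None = None
    cis: dict[str, pd.DataFrame] = field(default_factory=dict)

    @classmethod
    def from_fits(
        cls,
        names: Sequence[str],
        ks: Sequence[int],
        logLs: Sequence[float],
        claics: Sequence[float] | None = None,
    ) -> "SelectionReport":
        aics = [aic(k, ll) for k, ll in zip(ks, logLs)]
        table = pd.DataFrame(
            {"model": list(names), "k": list(ks), "logL": list(logLs), "AIC": aics}
        )
        criterion = "AIC"
        if claics is not None:
            table["CLAIC"] = list(claics)
            criterion = "CLAIC"
        table["delta_AIC"] = table["AIC"] - table["AIC"].min()
        table["akaike_weight"] = akaike_weights(table["AIC"].to_numpy())
        best_ll = table.loc[table["logL"].idxmax(), "model"]
        best_ic = table.loc[table[criterion].idxmin(), "model"]
        warning = overfit_check(best_ll, best_ic) if len(table) > 1 else None
        return cls(table=table, overfit_warning=warning)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
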