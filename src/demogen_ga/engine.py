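"""Deterministic expected-AFS engine, Monte-Carlo coalescent oracle and plugins.

The builtin engine computes the expected allele frequency spectrum of a
:class:`~demogen_ga.model.DemographicModel` by integrating the master
equation of a continuous-time Moran model on per-population allele-count
states.  Each population ``i`` is represented by ``K_i`` virtual gene
copies; the expected number of segregating sites in joint count state
``(k_1, ..., k_P)`` evolves linearly under

* drift: ``k -> k +/- 1`` at rate ``k (K - k) / (2 nu)`` (the exact Moran
  rates whose genealogy is the Kingman coalescent with pair rate ``1/nu``),
* migration: a slot of population ``i`` copies a random slot of ``j`` at
  scaled rate ``M_ij`` per slot,
* mutation influx: new variants enter population ``i`` at count 1 at rate
  ``theta K_i / 2``, calibrated so the drift-mutation equilibrium sample
  spectrum is exactly ``theta nu / d``.

Population splits redistribute the parent's count hypergeometrically over
the daughters' slots (``K_parent = K_a + K_b``), which keeps both daughter
marginals exactly equal to the parent spectrum, and the final population
states are hypergeometrically down-sampled to the requested sample sizes.
Because subsampling commutes with the coalescent, drift is handled exactly
for any ``K_i >= n_i``; migration carries an ``O(M/K)`` finite-K
correction, hence the default of two bins per sampled chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply, splu
from scipy.stats import hypergeom

from .model import DemographicModel, Dynamics, Epoch, Split
from .spectrum import FrequencySpectrum, fold, optimal_scale, poisson_loglik

__all__ = [
    "EngineConfig",
    "expected_afs",
    "expected_afs_mc",
    "register_plugin",
    "model_loglikelihood",
]


@dataclass(frozen=True)
class EngineConfig:
    """Constants of the fitness function: sample sizes, scale and controls.

    ``bins_factor`` sets the Moran resolution ``K_i = bins_factor * n_i``
    (three-population spectra with ``n_i > 10`` fall back to ``K_i = n_i``
    to keep the joint state space desk-scale).  ``time_step`` is the target
    substep length (in ``2 N_A`` generations) for epochs with non-sudden
    dynamics, whose coefficients are frozen at substep midpoints.
    """

    sample_sizes: tuple[int, ...]
    theta0: float = 1.0
    bins_factor: int = 2
    time_step: float = 0.1
    max_substeps: int = 50
    engine_id: str = "builtin"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if not 1 <= len(self.sample_sizes) <= 3:
            raise ValueError("1 to 3 populations supported")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if self.bins_factor < 1 or self.time_step <= 0 or self.max_substeps < 1:
            raise ValueError("invalid integration controls")

    @property
    def num_populations(self) -> int:
        return len(self.sample_sizes)

    def bins(self) -> tuple[int, ...]:
        P = self.num_populations
        if P == 3 and any(n > 10 for n in self.sample_sizes):
            return self.sample_sizes
        return tuple(self.bins_factor * n for n in self.sample_sizes)


# ---------------------------------------------------------------------------
# sparse generator pieces, cached per joint bin shape
# ---------------------------------------------------------------------------

_GEN_CACHE: dict[tuple[int, ...], dict] = {}


def _transition_matrix(shape: tuple[int, ...], axis: int, rate_up, rate_down) -> sp.csr_matrix:
    """Transposed-generator contribution for +-1 moves along one axis."""
    size = int(np.prod(shape))
    idx = np.arange(size).reshape(shape)
    up = np.asarray(rate_up, dtype=float)
    down = np.asarray(rate_down, dtype=float)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    sl_from_up = tuple(slice(0, -1) if a == axis else slice(None) for a in range(len(shape)))
    sl_from_dn = tuple(slice(1, None) if a == axis else slice(None) for a in range(len(shape)))
    src_up = idx[sl_from_up].ravel()
    r_up = up[sl_from_up].ravel()
    rows.append(src_up + int(np.prod(shape[axis + 1 :])))  # dest = src with k_axis + 1
    cols.append(src_up)
    vals.append(r_up)
    src_dn = idx[sl_from_dn].ravel()
    r_dn = down[sl_from_dn].ravel()
    rows.append(src_dn - int(np.prod(shape[axis + 1 :])))
    cols.append(src_dn)
    vals.append(r_dn)
    # diagonal outflow
    rows.append(src_up)
    cols.append(src_up)
    vals.append(-r_up)
    rows.append(src_dn)
    cols.append(src_dn)
    vals.append(-r_dn)
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(size, size),
    )
    return mat.tocsr()


def _generator_pieces(bins: tuple[int, ...]) -> dict:
    """Cacheable sparse pieces: per-pop drift, per-ordered-pair migration, source."""
    key = tuple(bins)
    if key in _GEN_CACHE:
        return _GEN_CACHE[key]
    shape = tuple(K + 1 for K in bins)
    P = len(bins)
    grids = np.indices(shape)
    drift = []
    for i, K in enumerate(bins):
        k = grids[i]
        rate = k * (K - k)  # multiplied by 1/(2 nu_i) at use time
        drift.append(_transition_matrix(shape, i, rate, rate))
    migration = {}
    for i in range(P):
        for j in range(P):
            if i == j:
                continue
            xj = grids[j] / bins[j]
            up = (bins[i] - grids[i]) * xj
            down = grids[i] * (1.0 - xj)
            migration[(i, j)] = _transition_matrix(shape, i, up, down)
    source = np.zeros(shape)
    for i, K in enumerate(bins):
        state = tuple(1 if a == i else 0 for a in range(P))
        source[state] = K / 2.0
    piece = {"drift": drift, "migration": migration, "source": source.ravel(), "shape": shape}
    _GEN_CACHE[key] = piece
    return piece


def _assemble_generator(bins: tuple[int, ...], nus: Sequence[float], M: np.ndarray) -> tuple:
    pieces = _generator_pieces(bins)
    Q = None
    for i, nu in enumerate(nus):
        term = pieces["drift"][i] * (1.0 / (2.0 * nu))
        Q = term if Q is None else Q + term
    for (i, j), mat in pieces["migration"].items():
        if M[i, j] != 0.0:
            Q = Q + mat * float(M[i, j])
    return Q.tocsc(), pieces["source"]


def _propagate(phi: np.ndarray, Q: sp.spmatrix, source: np.ndarray, h: float) -> np.ndarray:
    """Advance ``phi' = Q phi + source`` by time ``h``.

    Near-exact Krylov/Taylor exponential action for moderate stiffness;
    Crank-Nicolson with a capped number of implicit steps otherwise (stiff
    transients of extreme models decay within the first steps, so the slow
    modes that shape the spectrum stay accurate).
    """
    size = phi.size
    stiffness = float(np.abs(Q.diagonal()).max()) * h if size else 0.0
    if stiffness <= 50.0:
        aug = sp.bmat(
            [[Q * h, sp.csc_matrix((source * h).reshape(-1, 1))], [None, sp.csc_matrix((1, 1))]],
            format="csc",
        )
        v = np.concatenate([phi, [1.0]])
        return expm_multiply(aug, v)[:-1]
    n_steps = min(int(math.ceil(stiffness / 10.0)), 200)
    a = h / (2.0 * n_steps)
    eye = sp.identity(size, format="csc")
    lu = splu((eye - a * Q).tocsc())
    right = (eye + a * Q).tocsr()
    step_source = (h / n_steps) * source
    out = phi
    for _ in range(n_steps):
        out = lu.solve(right @ out + step_source)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# splits and sampling
# ---------------------------------------------------------------------------

_HYP_CACHE: dict[tuple[int, int], np.ndarray] = {}
_SPLIT_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _hypergeom_matrix(K: int, n: int) -> np.ndarray:
    """``D[k, d] = P(d derived in a subsample of n | k derived among K)``."""
    key = (K, n)
    if key not in _HYP_CACHE:
        k = np.arange(K + 1)[:, None]
        d = np.arange(n + 1)[None, :]
        with np.errstate(invalid="ignore"):
            D = hypergeom.pmf(d, K, k, n)
        _HYP_CACHE[key] = np.nan_to_num(D)
    return _HYP_CACHE[key]


def _split_tensor(k_a: int, k_b: int) -> np.ndarray:
    """``R[k, ka, kb]``: hypergeometric assignment of ``k`` derived copies
    among the parent's ``k_a + k_b`` slots to the two daughters."""
    key = (k_a, k_b)
    if key not in _SPLIT_CACHE:
        K_p = k_a + k_b
        D = _hypergeom_matrix(K_p, k_a)  # (K_p+1, k_a+1)
        R = np.zeros((K_p + 1, k_a + 1, k_b + 1))
        k = np.arange(K_p + 1)
        for ka in range(k_a + 1):
            kb = k - ka
            ok = (kb >= 0) & (kb <= k_b)
            R[k[ok], ka, kb[ok]] = D[k[ok], ka]
        _SPLIT_CACHE[key] = R
    return _SPLIT_CACHE[key]


def _apply_split(phi: np.ndarray, bins: list[int], k_a: int, k_b: int) -> np.ndarray:
    """Replace the last axis (the dividing population) by two daughter axes."""
    K_p = bins[-1]
    if k_a + k_b != K_p:
        raise ValueError("daughter bins must sum to the parent's bins")
    R = _split_tensor(k_a, k_b)
    out = np.tensordot(phi, R, axes=([phi.ndim - 1], [0]))
    bins[-1:] = [k_a, k_b]
    return out


def _downsample(phi: np.ndarray, bins: Sequence[int], ns: Sequence[int]) -> np.ndarray:
    out = phi
    for axis, (K, n) in enumerate(zip(bins, ns)):
        D = _hypergeom_matrix(K, n)
        out = np.moveaxis(np.tensordot(out, D, axes=([axis], [0])), -1, axis)
    return out


def _phase_bins(final_bins: tuple[int, ...]) -> list[list[int]]:
    """Per-phase bin lists; the last population of an early phase aggregates
    the slots of all populations it will eventually split into."""
    P = len(final_bins)
    phases = [list(final_bins)]
    for p in range(P - 1, 0, -1):
        prev = phases[0]
        phases.insert(0, prev[: p - 1] + [prev[p - 1] + prev[p]])
    return phases


# ---------------------------------------------------------------------------
# builtin engine
# ---------------------------------------------------------------------------

def _builtin_expected_afs(model: DemographicModel, config: EngineConfig) -> FrequencySpectrum:
    P = model.num_populations
    if P != config.num_populations:
        raise ValueError(
            f"model has {P} populations but engine config expects {config.num_populations}"
        )
    final_bins = config.bins()
    phases = _phase_bins(final_bins)
    bins = list(phases[0])

    # ancestral drift-mutation equilibrium (theta = 1): phi(k) = 1/k
    K0 = bins[0]
    phi = np.zeros(K0 + 1)
    phi[1:K0] = 1.0 / np.arange(1, K0)

    start_sizes = model.start_sizes()
    phase = 1
    for ev, start in zip(model.events, start_sizes):
        if isinstance(ev, Split):
            phase += 1
            k_a, k_b = phases[phase - 1][-2], phases[phase - 1][-1]
            phi = _apply_split(phi.reshape([K + 1 for K in bins]), bins, k_a, k_b).ravel()
            continue
        phi = _integrate_epoch(phi, tuple(bins), ev, start, config)
    spectrum = _downsample(
        phi.reshape([K + 1 for K in bins]), bins, config.sample_sizes
    )
    spectrum = np.maximum(spectrum, 0.0) * config.theta0
    return FrequencySpectrum(spectrum, folded=False)


def _integrate_epoch(
    phi: np.ndarray,
    bins: tuple[int, ...],
    epoch: Epoch,
    start_sizes: tuple[float, ...],
    config: EngineConfig,
) -> np.ndarray:
    all_sudden = all(d is Dynamics.SUDDEN for d in epoch.dynamics)
    if all_sudden:
        n_sub = 1
    else:
        n_sub = int(np.clip(math.ceil(epoch.duration / config.time_step), 2, config.max_substeps))
    h = epoch.duration / n_sub
    M = epoch.migration_array() if epoch.num_pops > 1 else np.zeros((1, 1))
    for step in range(n_sub):
        frac_mid = (step + 0.5) / n_sub
        nus = [
            d.size_at(s0, s1, frac_mid)
            for d, s0, s1 in zip(epoch.dynamics, start_sizes, epoch.end_sizes)
        ]
        Q, source = _assemble_generator(bins, nus, M)
        phi = _propagate(phi, Q, source, h)
    return phi


# ---------------------------------------------------------------------------
# plugin registry
# ---------------------------------------------------------------------------

EngineFunc = Callable[[DemographicModel, EngineConfig], FrequencySpectrum]

_ENGINES: dict[str, EngineFunc] = {}


def register_plugin(name: str, func: EngineFunc) -> None:
    """Register an expected-AFS backend under ``name``.

    The callable must be a pure function of ``(model, config)`` returning a
    dense spectrum of shape ``(n_1 + 1, ..., n_P + 1)``; its output is
    validated before use.
    """
    if not callable(func):
        raise TypeError("plugin must be callable")
    _ENGINES[name] = func


register_plugin("builtin", _builtin_expected_afs)


def expected_afs(model: DemographicModel, config: EngineConfig) -> FrequencySpectrum:
    """Expected AFS ``M`` for a model under the configured backend."""
    try:
        func = _ENGINES[config.engine_id]
    except KeyError:
        raise ValueError(
            f"unknown engine {config.engine_id!r}; registered: {sorted(_ENGINES)}"
        ) from None
    out = func(model, config)
    expected_shape = tuple(n + 1 for n in config.sample_sizes)
    if not isinstance(out, FrequencySpectrum):
        out = FrequencySpectrum(np.asarray(out, dtype=float), folded=False)
    if out.counts.shape != expected_shape:
        raise ValueError(
            f"engine {config.engine_id!r} violated its contract: expected shape "
            f"{expected_shape}, got {out.counts.shape}"
        )
    if np.any(out.counts < 0):
        raise ValueError(f"engine {config.engine_id!r} returned negative expected counts")
    return out


# ---------------------------------------------------------------------------
# fitness helper
# ---------------------------------------------------------------------------

def model_loglikelihood(
    model: DemographicModel,
    data: FrequencySpectrum,
    config: EngineConfig,
    profile_scale: bool = True,
) -> tuple[float, float]:
    """Composite log-likelihood of the data, with the overall mutation scale
    profiled out (``theta-hat = sum S / sum M``) unless disabled.

    Returns ``(loglik, theta_hat)``; with ``profile_scale=False`` the scale
    is ``config.theta0`` as-is and ``theta_hat = theta0``.
    """
    m = expected_afs(model, config)
    if data.folded:
        m = fold(m)
    if profile_scale:
        theta = optimal_scale(m, data)
        return poisson_loglik(m.scaled(theta), data), theta * config.theta0
    return poisson_loglik(m, data), config.theta0


# ---------------------------------------------------------------------------
# Monte-Carlo coalescent oracle (msprime)
# ---------------------------------------------------------------------------

def _msprime_demography(model: DemographicModel, substeps_linear: int = 20):
    """Translate a model into an msprime Demography in engine units.

    Haploid populations with ``initial_size = nu`` give a pairwise
    coalescence rate ``1/nu`` per unit of ``2 N_A`` generations, so scaled
    times and migration rates carry over unchanged.  Linear size change is
    approximated by piecewise-constant substeps.
    """
    import msprime

    P = model.num_populations
    names_by_phase = {
        1: ["anc"],
        2: ["p0", "p1" if P == 2 else "p12"],
        3: ["p0", "p1", "p2"],
    }
    final_names = names_by_phase[P]

    demography = msprime.Demography()
    all_names = ["anc"]
    if P >= 2:
        all_names += ["p0", "p1" if P == 2 else "p12"]
    if P == 3:
        all_names += ["p1", "p2"]
    for name in all_names:
        demography.add_population(name=name, initial_size=1.0)

    total_T = sum(ev.duration for ev in model.epochs())

    # forward walk collecting per-segment (constant-coefficient) pieces
    segments = []  # (t_fwd_start, t_fwd_end, names, sizes_start, sizes_end, dynamics, M)
    t = 0.0
    phase = 1
    split_times = []  # (t_fwd, derived names, ancestral name)
    start_sizes = model.start_sizes()
    for ev, start in zip(model.events, start_sizes):
        if isinstance(ev, Split):
            phase += 1
            parent = names_by_phase[phase - 1][-1]
            daughters = names_by_phase[phase][-2:]
            split_times.append((t, daughters, parent))
            continue
        names = names_by_phase[phase]
        n_sub = substeps_linear if any(d is Dynamics.LINEAR for d in ev.dynamics) else 1
        for k in range(n_sub):
            f0, f1 = k / n_sub, (k + 1) / n_sub
            sizes0 = [
                d.size_at(s0, s1, f0) if d is not Dynamics.SUDDEN else s1
                for d, s0, s1 in zip(ev.dynamics, start, ev.end_sizes)
            ]
            sizes1 = [
                d.size_at(s0, s1, f1)
                for d, s0, s1 in zip(ev.dynamics, start, ev.end_sizes)
            ]
            dyn = [
                Dynamics.EXPONENTIAL if d is Dynamics.EXPONENTIAL else Dynamics.SUDDEN
                for d in ev.dynamics
            ]
            segments.append(
                (
                    t + f0 * ev.duration,
                    t + f1 * ev.duration,
                    names,
                    sizes0,
                    sizes1,
                    dyn,
                    ev.migration_array(),
                )
            )
        t += ev.duration

    # emit msprime events backwards in time
    for t0, t1, names, sizes0, sizes1, dyn, M in segments:
        b = total_T - t1  # backward time of the segment's recent edge
        for i, name in enumerate(names):
            if dyn[i] is Dynamics.EXPONENTIAL:
                growth = math.log(sizes1[i] / sizes0[i]) / (t1 - t0)
            else:
                growth = 0.0
            if b == 0.0:
                demography[name].initial_size = sizes1[i]
                demography[name].growth_rate = growth
            else:
                demography.add_population_parameters_change(
                    time=b, population=name, initial_size=sizes1[i], growth_rate=growth
                )
        for i in range(len(names)):
            for j in range(len(names)):
                if i == j:
                    continue
                if b == 0.0:
                    demography.set_migration_rate(names[i], names[j], float(M[i, j]))
                else:
                    demography.add_migration_rate_change(
                        time=b, rate=float(M[i, j]), source=names[i], dest=names[j]
                    )
    for t_fwd, daughters, parent in split_times:
        demography.add_population_split(
            time=total_T - t_fwd, derived=list(daughters), ancestral=parent
        )
    # the ancestral population sits at equilibrium size 1 beyond the oldest epoch
    demography.add_population_parameters_change(
        time=total_T, population="anc", initial_size=1.0, growth_rate=0.0
    )
    demography.sort_events()
    return demography, final_names


def expected_afs_mc(
    model: DemographicModel,
    config: EngineConfig,
    n_replicates: int,
    seed: int,
) -> tuple[FrequencySpectrum, np.ndarray]:
    """Monte-Carlo estimate of the expected AFS from msprime genealogies.

    Averages branch-mode frequency spectra over independent coalescent
    replicates and scales by ``theta0 / 2`` (the mutation rate per unit of
    ``2 N_A`` generations under the infinite-sites model).  Returns the
    estimated spectrum and the per-entry standard error.
    """
    import msprime

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    demography, final_names = _msprime_demography(model)
    samples = {
        name: n for name, n in zip(final_names, config.sample_sizes)
    }
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        sequence_length=1,
        discrete_genome=False,
        num_replicates=n_replicates,
        random_seed=seed,
    )
    shape = tuple(n + 1 for n in config.sample_sizes)
    acc = np.zeros(shape)
    acc2 = np.zeros(shape)
    for ts in reps:
        pops = {p.metadata.get("name"): p.id for p in ts.populations()}
        sample_sets = [ts.samples(population=pops[name]) for name in final_names]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sample_sets, mode="branch", polarised=True, span_normalise=True
        )
        acc += afs
        acc2 += afs**2
    mean = acc / n_replicates
    var = np.maximum(acc2 / n_replicates - mean**2, 0.0)
    se = np.sqrt(var / n_replicates) * (config.theta0 / 2.0)
    fs = FrequencySpectrum(mean * (config.theta0 / 2.0), folded=False)
    return fs, se
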