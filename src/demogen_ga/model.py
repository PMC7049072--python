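"""Structured demographic models: epochs, splits, dynamics and their flat encoding.

A demographic history for ``P <= 3`` populations is a chronological sequence
of *time intervals* (epochs) and *splits* under a *structure*
``(s_1, ..., s_P)`` giving the number of intervals before the first split,
between splits, and after the last split.  All sizes are relative to the
ancestral size ``N_A``, times are in units of ``2 N_A`` generations and
migration rates are scaled by ``2 N_A``.  The first interval is special: the
ancestral population sits at its drift-mutation equilibrium with relative
size 1 and sudden dynamics, so it contributes no free parameters; the
ancestral size itself is recovered from the profiled likelihood scale
(:func:`demogen_ga.spectrum.optimal_scale`), never optimized directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Dynamics",
    "Epoch",
    "Split",
    "Structure",
    "DemographicModel",
    "Bounds",
    "ParamSlot",
    "param_count_ga",
    "param_count_final",
    "vector_spec",
    "encode",
    "decode",
    "increase_structure",
    "random_model",
    "model_to_text",
    "model_from_text",
]


class Dynamics(str, enum.Enum):
    """Functional form of population-size change within an epoch."""

    SUDDEN = "sudden"
    LINEAR = "linear"
    EXPONENTIAL = "exponential"

    def size_at(self, start: float, end: float, frac: float) -> float:
        """Size at fraction ``frac`` of the epoch (0 = start, 1 = end).

        sudden: nu(t) = end throughout; linear: straight line between the
        sizes; exponential: geometric interpolation.
        """
        if self is Dynamics.SUDDEN:
            return end
        if self is Dynamics.LINEAR:
            return start + (end - start) * frac
        return start * (end / start) ** frac


_DYN_CODE = {Dynamics.SUDDEN: 0.0, Dynamics.LINEAR: 1.0, Dynamics.EXPONENTIAL: 2.0}
_CODE_DYN = {v: k for k, v in _DYN_CODE.items()}

Structure = tuple  # alias; a structure is a tuple of positive ints, one per phase


@dataclass(frozen=True)
class Epoch:
    """One time interval.

    ``end_sizes`` are the per-population sizes at the end of the interval;
    start sizes are implicit (the previous interval's end, or the sizes set
    by the preceding split).  ``migration[i, j]`` is the scaled rate at which
    population ``i`` receives migrants from ``j`` (zero diagonal); ``None``
    for single-population intervals.
    """

    duration: float
    end_sizes: tuple[float, ...]
    dynamics: tuple[Dynamics, ...]
    migration: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        p = len(self.end_sizes)
        if len(self.dynamics) != p:
            raise ValueError("one dynamics value per population required")
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if any(s <= 0 for s in self.end_sizes):
            raise ValueError("population sizes must be positive")
        if p == 1:
            if self.migration is not None:
                raise ValueError("single-population epoch cannot carry migration")
        else:
            if self.migration is None:
                object.__setattr__(self, "migration", tuple(tuple(0.0 for _ in range(p)) for _ in range(p)))
            m = np.asarray(self.migration, dtype=float)
            if m.shape != (p, p):
                raise ValueError(f"migration matrix must be {p}x{p}")
            if np.any(m < 0) or np.any(np.diag(m) != 0):
                raise ValueError("migration rates must be >= 0 with zero diagonal")
            object.__setattr__(self, "migration", tuple(tuple(row) for row in m))

    @property
    def num_pops(self) -> int:
        return len(self.end_sizes)

    def migration_array(self) -> np.ndarray:
        p = self.num_pops
        return np.zeros((1, 1)) if p == 1 else np.asarray(self.migration, dtype=float)


@dataclass(frozen=True)
class Split:
    """Division of the most recently formed population.

    ``fraction`` is the share of the parent that forms the first daughter
    (which keeps the parent's index); the remainder forms the new, last
    population.
    """

    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")


Event = Epoch | Split


def _expected_event_layout(structure: Sequence[int]) -> list[tuple[str, int]]:
    """Event kinds/pop-counts implied by a structure, excluding the implicit
    first (ancestral equilibrium) interval."""
    P = len(structure)
    layout: list[tuple[str, int]] = []
    for phase, s in enumerate(structure, start=1):
        n_epochs = s - 1 if phase == 1 else s
        if phase > 1:
            layout.append(("split", phase - 1))
        layout.extend(("epoch", phase) for _ in range(n_epochs))
    return layout


def _validate_structure(structure: Sequence[int], P: int | None = None) -> tuple[int, ...]:
    structure = tuple(int(s) for s in structure)
    if not 1 <= len(structure) <= 3:
        raise ValueError("structure length (number of populations) must be 1, 2 or 3")
    if any(s < 1 for s in structure):
        raise ValueError("structure entries must be >= 1")
    if P is not None and len(structure) != P:
        raise ValueError(f"structure length {len(structure)} != number of populations {P}")
    return structure


@dataclass
class DemographicModel:
    """Ordered epochs and splits under a structure.

    ``events`` excludes the implicit ancestral-equilibrium first interval
    (relative size 1, sudden dynamics, effectively infinite duration), which
    every model begins with.
    """

    structure: tuple[int, ...]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.structure = _validate_structure(self.structure)
        layout = _expected_event_layout(self.structure)
        if len(self.events) != len(layout):
            raise ValueError(
                f"structure {self.structure} implies {len(layout)} events, got {len(self.events)}"
            )
        for ev, (kind, p) in zip(self.events, layout):
            if kind == "split" and not isinstance(ev, Split):
                raise ValueError("event sequence inconsistent with structure: expected a split")
            if kind == "epoch":
                if not isinstance(ev, Epoch):
                    raise ValueError("event sequence inconsistent with structure: expected an epoch")
                if ev.num_pops != p:
                    raise ValueError(
                        f"epoch has {ev.num_pops} populations where structure implies {p}"
                    )

    @property
    def num_populations(self) -> int:
        return len(self.structure)

    def start_sizes(self) -> list[tuple[float, ...]]:
        """Per-event start sizes obtained by walking the history.

        For a :class:`Split` entry the returned tuple holds the sizes *after*
        the split (the daughters' start sizes for the following epoch).
        """
        sizes: tuple[float, ...] = (1.0,)
        out: list[tuple[float, ...]] = []
        for ev in self.events:
            if isinstance(ev, Epoch):
                out.append(sizes)
                sizes = ev.end_sizes
            else:
                j = len(sizes) - 1  # the last formed population divides
                parent = sizes[j]
                sizes = sizes[:j] + (ev.fraction * parent, (1.0 - ev.fraction) * parent)
                out.append(sizes)
        return out

    def epochs(self) -> list[Epoch]:
        return [ev for ev in self.events if isinstance(ev, Epoch)]

    def splits(self) -> list[Split]:
        return [ev for ev in self.events if isinstance(ev, Split)]

    def copy(self) -> "DemographicModel":
        return DemographicModel(self.structure, list(self.events))


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def param_count_ga(structure: Sequence[int], P: int) -> int:
    """Parameter count during the GA phase (dynamics are free).

    ``(P - 1)`` split fractions plus per-phase interval terms
    ``3 (s_1 - 1)``, ``7 s_2``, ``13 s_3``.
    """
    structure = _validate_structure(structure, P)
    per_phase = [3 * (structure[0] - 1)]
    if P >= 2:
        per_phase.append(7 * structure[1])
    if P >= 3:
        per_phase.append(13 * structure[2])
    return (P - 1) + sum(per_phase)


def param_count_final(structure: Sequence[int], P: int) -> int:
    """Parameter count after the GA, with dynamics fixed: ``(P - 1)`` plus
    ``2 (s_1 - 1)``, ``5 s_2``, ``10 s_3``."""
    structure = _validate_structure(structure, P)
    per_phase = [2 * (structure[0] - 1)]
    if P >= 2:
        per_phase.append(5 * structure[1])
    if P >= 3:
        per_phase.append(10 * structure[2])
    return (P - 1) + sum(per_phase)


# ---------------------------------------------------------------------------
# bounds and flat encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bounds:
    """Admissible ranges per parameter class (clipping bounds).

    ``time_sample_low`` is the lower edge used when *sampling* initial
    durations log-uniformly; the clipping lower bound ``time[0]`` is far
    smaller so optimizers may shrink intervals to effectively zero.
    """

    size: tuple[float, float] = (1e-2, 100.0)
    time: tuple[float, float] = (1e-15, 5.0)
    migration: tuple[float, float] = (0.0, 10.0)
    fraction: tuple[float, float] = (1e-3, 1.0 - 1e-3)
    time_sample_low: float = 1e-2

    def of_kind(self, kind: str) -> tuple[float, float]:
        if kind == "dynamics":
            return (0.0, 2.0)
        return getattr(self, kind)

    def validate(self) -> None:
        for kind in ("size", "time", "migration", "fraction"):
            lo, hi = self.of_kind(kind)
            if lo > hi:
                raise ValueError(f"inverted bounds for {kind}: ({lo}, {hi})")


@dataclass(frozen=True)
class ParamSlot:
    """One position of the flat parameter vector."""

    kind: str  # size | dynamics | migration | time | fraction
    label: str


def vector_spec(
    structure: Sequence[int], P: int | None = None, include_dynamics: bool = True
) -> list[ParamSlot]:
    """Canonical parameter order for a structure.

    Per epoch: end sizes by population index, dynamics by population index
    (GA phase only), migration rates in row-major order excluding the
    diagonal, then the duration; split fractions at their chronological
    position.
    """
    structure = _validate_structure(structure, P)
    slots: list[ParamSlot] = []
    e = 0
    for kind, p in _expected_event_layout(structure):
        if kind == "split":
            slots.append(ParamSlot("fraction", f"s{p}_fraction"))
            continue
        e += 1
        for i in range(p):
            slots.append(ParamSlot("size", f"e{e}_nu{i + 1}"))
        if include_dynamics:
            for i in range(p):
                slots.append(ParamSlot("dynamics", f"e{e}_dyn{i + 1}"))
        for i in range(p):
            for j in range(p):
                if i != j:
                    slots.append(ParamSlot("migration", f"e{e}_m{i + 1}{j + 1}"))
        slots.append(ParamSlot("time", f"e{e}_T"))
    return slots


def encode(model: DemographicModel, include_dynamics: bool = True) -> np.ndarray:
    """Flat parameter vector in the canonical order of :func:`vector_spec`."""
    vec: list[float] = []
    for ev in model.events:
        if isinstance(ev, Split):
            vec.append(ev.fraction)
            continue
        p = ev.num_pops
        vec.extend(ev.end_sizes)
        if include_dynamics:
            vec.extend(_DYN_CODE[d] for d in ev.dynamics)
        if p > 1:
            m = ev.migration_array()
            vec.extend(m[i, j] for i in range(p) for j in range(p) if i != j)
        vec.append(ev.duration)
    return np.asarray(vec, dtype=float)


def decode(
    vector: Sequence[float],
    structure: Sequence[int],
    P: int | None = None,
    dynamics: Sequence[tuple[Dynamics, ...]] | None = None,
) -> DemographicModel:
    """Inverse of :func:`encode`.

    With ``dynamics=None`` the vector is a GA-phase vector containing
    dynamics codes; otherwise ``dynamics`` supplies one tuple per epoch and
    the vector has :func:`param_count_final` entries.
    """
    structure = _validate_structure(structure, P)
    include_dynamics = dynamics is None
    expected = (param_count_ga if include_dynamics else param_count_final)(
        structure, len(structure)
    )
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {vector.shape}")
    events: list[Event] = []
    pos = 0
    e = 0
    for kind, p in _expected_event_layout(structure):
        if kind == "split":
            events.append(Split(float(vector[pos])))
            pos += 1
            continue
        sizes = tuple(float(v) for v in vector[pos : pos + p])
        pos += p
        if include_dynamics:
            codes = vector[pos : pos + p]
            if any(c not in _CODE_DYN for c in codes):
                raise ValueError(f"invalid dynamics code in {codes}")
            dyn = tuple(_CODE_DYN[float(c)] for c in codes)
            pos += p
        else:
            dyn = tuple(dynamics[e])
        migration = None
        if p > 1:
            m = np.zeros((p, p))
            for i in range(p):
                for j in range(p):
                    if i != j:
                        m[i, j] = vector[pos]
                        pos += 1
            migration = tuple(tuple(row) for row in m)
        duration = float(vector[pos])
        pos += 1
        events.append(Epoch(duration, sizes, dyn, migration))
        e += 1
    return DemographicModel(structure, events)


def epoch_dynamics(model: DemographicModel) -> list[tuple[Dynamics, ...]]:
    """Per-epoch dynamics tuples, in chronological order."""
    return [ev.dynamics for ev in model.events if isinstance(ev, Epoch)]


# ---------------------------------------------------------------------------
# structure complexification
# ---------------------------------------------------------------------------

#: duration assigned to the interval carved out of the (stationary)
#: ancestral equilibrium; any value preserves the history exactly.
_FIRST_SPLIT_DURATION = 1.0


def increase_structure(
    model: DemographicModel,
    final: Sequence[int],
    rng: np.random.Generator,
) -> DemographicModel:
    """Split one eligible time interval at its median into two equal halves.

    The first child ends at the parent's mid-trajectory sizes, the second at
    the parent's end sizes; both inherit the dynamics and migration, so the
    size-through-time function — and hence the expected spectrum and the
    likelihood — is unchanged.  Eligible intervals are those in phases where
    the current structure is below ``final``; the implicit ancestral
    equilibrium interval is eligible for phase 1 and, being stationary,
    yields a constant-size interval of default duration.
    """
    final = _validate_structure(final, len(model.structure))
    current = model.structure
    if any(c > f for c, f in zip(current, final)):
        raise ValueError(f"current structure {current} exceeds final {final}")
    if current == final:
        raise ValueError(f"structure already equals final {final}")

    # enumerate candidate intervals as (phase, event_index); -1 = the
    # implicit first interval
    layout = _expected_event_layout(current)
    candidates: list[tuple[int, int]] = []
    if current[0] < final[0]:
        candidates.append((1, -1))
    for idx, (kind, p) in enumerate(layout):
        if kind == "epoch" and current[p - 1] < final[p - 1]:
            candidates.append((p, idx))
    phase, idx = candidates[rng.integers(0, len(candidates))]

    new_structure = tuple(s + 1 if i == phase - 1 else s for i, s in enumerate(current))
    events = list(model.events)
    if idx == -1:
        new_epoch = Epoch(_FIRST_SPLIT_DURATION, (1.0,), (Dynamics.SUDDEN,))
        events.insert(0, new_epoch)
    else:
        parent = events[idx]
        start = model.start_sizes()[idx]
        mid = tuple(
            d.size_at(s0, s1, 0.5)
            for d, s0, s1 in zip(parent.dynamics, start, parent.end_sizes)
        )
        half = parent.duration / 2.0
        first = Epoch(half, mid, parent.dynamics, parent.migration)
        second = Epoch(half, parent.end_sizes, parent.dynamics, parent.migration)
        events[idx : idx + 1] = [first, second]
    return DemographicModel(new_structure, events)


# ---------------------------------------------------------------------------
# random models
# ---------------------------------------------------------------------------

#: probability that a sampled migration rate is exactly zero
_MIGRATION_ZERO_ATOM = 0.3


def _sample_slot(slot: ParamSlot, bounds: Bounds, rng: np.random.Generator) -> float:
    if slot.kind == "size":
        lo, hi = bounds.size
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if slot.kind == "time":
        lo, hi = bounds.time
        lo = max(lo, bounds.time_sample_low)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if slot.kind == "migration":
        if rng.random() < _MIGRATION_ZERO_ATOM:
            return 0.0
        return float(rng.uniform(*bounds.migration))
    if slot.kind == "fraction":
        return float(rng.uniform(*bounds.fraction))
    if slot.kind == "dynamics":
        return float(rng.integers(0, 3))
    raise ValueError(f"unknown parameter kind {slot.kind}")


def random_model(
    structure: Sequence[int],
    bounds: Bounds,
    rng: np.random.Generator,
    fixed_dynamics: Dynamics | None = None,
) -> DemographicModel:
    """Draw a model with parameters inside ``bounds``.

    Sizes and durations are log-uniform, migrations uniform with an atom at
    zero, split fractions uniform and dynamics uniform over the three forms
    (or fixed to ``fixed_dynamics``).
    """
    bounds.validate()
    structure = _validate_structure(structure)
    spec = vector_spec(structure)
    vec = np.array([_sample_slot(s, bounds, rng) for s in spec])
    if fixed_dynamics is not None:
        for i, s in enumerate(spec):
            if s.kind == "dynamics":
                vec[i] = _DYN_CODE[fixed_dynamics]
    return decode(vec, structure)


def clip_vector(vec: np.ndarray, spec: Sequence[ParamSlot], bounds: Bounds) -> np.ndarray:
    """Clip each numeric entry into its class bounds (dynamics untouched)."""
    out = np.array(vec, dtype=float)
    for i, slot in enumerate(spec):
        if slot.kind == "dynamics":
            continue
        lo, hi = bounds.of_kind(slot.kind)
        out[i] = min(max(out[i], lo), hi)
    return out


# ---------------------------------------------------------------------------
# plain-text serialization (for logging / restart)
# ---------------------------------------------------------------------------

def model_to_text(model: DemographicModel) -> str:
    """One event per line: ``epoch T=.. nu=..,.. dyn=..,.. m=..`` / ``split f=..``.

    Header records the structure; parameter order within lines matches the
    canonical flat encoding.
    """
    lines = [f"structure {' '.join(str(s) for s in model.structure)}"]
    for ev in model.events:
        if isinstance(ev, Split):
            lines.append(f"split f={float(ev.fraction)!r}")
        else:
            parts = [
                f"epoch T={float(ev.duration)!r}",
                "nu=" + ",".join(repr(float(s)) for s in ev.end_sizes),
                "dyn=" + ",".join(d.value for d in ev.dynamics),
            ]
            if ev.num_pops > 1:
                m = ev.migration_array()
                p = ev.num_pops
                parts.append(
                    "m=" + ",".join(repr(float(m[i, j])) for i in range(p) for j in range(p) if i != j)
                )
            lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> DemographicModel:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("structure"):
        raise ValueError("model text must start with a 'structure' line")
    structure = tuple(int(tok) for tok in lines[0].split()[1:])
    events: list[Event] = []
    for ln in lines[1:]:
        fields = dict(tok.split("=", 1) for tok in ln.split()[1:])
        if ln.startswith("split"):
            events.append(Split(float(fields["f"])))
        elif ln.startswith("epoch"):
            sizes = tuple(float(v) for v in fields["nu"].split(","))
            dyn = tuple(Dynamics(v) for v in fields["dyn"].split(","))
            migration = None
            if "m" in fields:
                p = len(sizes)
                vals = [float(v) for v in fields["m"].split(",")]
                m = np.zeros((p, p))
                it = iter(vals)
                for i in range(p):
                    for j in range(p):
                        if i != j:
                            m[i, j] = next(it)
                migration = tuple(tuple(row) for row in m)
            events.append(Epoch(float(fields["T"]), sizes, dyn, migration))
        else:
            raise ValueError(f"unrecognized model line: {ln}")
    return DemographicModel(structure, events)
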