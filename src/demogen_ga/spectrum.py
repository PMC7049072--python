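"""Allele frequency spectrum container, text I/O, folding and the Poisson composite likelihood.

The AFS for ``P`` populations is a ``P``-dimensional array whose entry
``[d_1, ..., d_P]`` counts SNVs observed on exactly ``d_i`` of the ``n_i``
sampled chromosomes of population ``i``.  Under free recombination every
entry of an observed spectrum ``S`` is an independent Poisson variable with
mean given by the model's expected spectrum ``M``; the (composite)
log-likelihood summed over unmasked entries is the fitness used throughout
this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "FrequencySpectrum",
    "read_fs",
    "write_fs",
    "fold",
    "poisson_loglik",
    "optimal_scale",
    "bootstrap_resample",
]

#: floor applied to expected entries before taking logs; keeps the
#: optimizer alive when a model predicts (numerically) zero mass in a bin
#: that the data happens to populate.
EXPECTED_FLOOR = 1e-300


class FormatError(ValueError):
    """Raised when an ``fs`` file does not conform to the text dialect."""


@dataclass
class FrequencySpectrum:
    """A P-dimensional allele frequency spectrum with mask and metadata.

    Parameters
    ----------
    counts
        Array of shape ``(n_1 + 1, ..., n_P + 1)``.  Observed spectra hold
        non-negative integers, expected spectra non-negative reals.
    mask
        Boolean array of the same shape; ``True`` marks entries excluded
        from all likelihood computations.  The monomorphic corners
        ``[0,...,0]`` and ``[n_1,...,n_P]`` are always masked.
    folded
        ``True`` if the spectrum is indexed by minor-allele counts.
    population_labels
        Optional identifiers, one per population.
    """

    counts: np.ndarray
    mask: np.ndarray | None = None
    folded: bool = False
    population_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim not in (1, 2, 3):
            raise ValueError(
                f"spectrum must be 1-, 2- or 3-dimensional, got {self.counts.ndim}"
            )
        if np.any(self.counts < 0):
            raise ValueError("spectrum entries must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape does not match counts shape")
            self.mask = self.mask.copy()
        # monomorphic corners carry no polymorphism information
        self.mask[(0,) * self.counts.ndim] = True
        self.mask[tuple(n - 1 for n in self.counts.shape)] = True
        if self.folded:
            tot = _total_derived(self.counts.shape)
            self.mask |= 2 * tot > sum(self.sample_sizes)
        if self.population_labels is not None:
            self.population_labels = tuple(self.population_labels)
            if len(self.population_labels) != self.counts.ndim:
                raise ValueError("need one population label per dimension")

    @property
    def num_populations(self) -> int:
        return self.counts.ndim

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(n - 1 for n in self.counts.shape)

    @property
    def unmasked_sum(self) -> float:
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "FrequencySpectrum":
        return FrequencySpectrum(
            self.counts.copy(), self.mask.copy(), self.folded, self.population_labels
        )

    def scaled(self, factor: float) -> "FrequencySpectrum":
        """Return the spectrum with every entry multiplied by ``factor``."""
        return FrequencySpectrum(
            self.counts * factor, self.mask.copy(), self.folded, self.population_labels
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencySpectrum):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.mask, other.mask)
            and self.folded == other.folded
            and self.population_labels == other.population_labels
        )


def _total_derived(shape: tuple[int, ...]) -> np.ndarray:
    """Array of the same shape whose entry is d_1 + ... + d_P."""
    grids = np.indices(shape)
    return grids.sum(axis=0)


# ---------------------------------------------------------------------------
# fs text dialect
# ---------------------------------------------------------------------------

def read_fs(path: str | Path) -> FrequencySpectrum:
    """Read a spectrum from the whitespace ``fs`` text dialect.

    Line 1: shape integers (``n_i + 1`` per population), a
    ``folded``/``unfolded`` token, then optional quoted population labels.
    Line 2: entries in row-major order.  Line 3 (optional): mask entries,
    ``1`` = masked.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split()
    shape: list[int] = []
    i = 0
    while i < len(header):
        try:
            shape.append(int(header[i]))
        except ValueError:
            break
        i += 1
    if not shape:
        raise FormatError(f"{path}: line 1: header must start with shape integers")
    if i >= len(header) or header[i] not in ("folded", "unfolded"):
        raise FormatError(f"{path}: line 1: expected 'folded' or 'unfolded' token")
    folded = header[i] == "folded"
    labels = tuple(tok.strip('"') for tok in header[i + 1 :]) or None
    if labels is not None and len(labels) != len(shape):
        raise FormatError(f"{path}: line 1: expected {len(shape)} population labels")

    if len(lines) < 2:
        raise FormatError(f"{path}: missing data line")
    values = lines[1].split()
    size = int(np.prod(shape))
    if len(values) != size:
        raise FormatError(
            f"{path}: line 2: expected {size} values for shape {tuple(shape)}, "
            f"got {len(values)}"
        )
    try:
        counts = np.array([float(v) for v in values]).reshape(shape)
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: {exc}") from None
    if np.any(counts < 0):
        col = int(np.argmax(np.asarray([float(v) for v in values]) < 0))
        raise FormatError(f"{path}: line 2, column {col + 1}: negative count")

    mask = None
    if len(lines) >= 3:
        mask_tokens = lines[2].split()
        if len(mask_tokens) != size:
            raise FormatError(
                f"{path}: line 3: expected {size} mask values, got {len(mask_tokens)}"
            )
        if any(tok not in ("0", "1") for tok in mask_tokens):
            raise FormatError(f"{path}: line 3: mask entries must be 0 or 1")
        mask = np.array([tok == "1" for tok in mask_tokens]).reshape(shape)

    return FrequencySpectrum(counts, mask, folded, labels)


def write_fs(fs: FrequencySpectrum, path: str | Path) -> None:
    """Write ``fs`` in the dialect read by :func:`read_fs` (full precision)."""
    path = Path(path)
    header = " ".join(str(n) for n in fs.counts.shape)
    header += " folded" if fs.folded else " unfolded"
    if fs.population_labels is not None:
        header += " " + " ".join(f'"{lab}"' for lab in fs.population_labels)
    data = " ".join(repr(float(v)) for v in fs.counts.ravel())
    mask = " ".join("1" if m else "0" for m in fs.mask.ravel())
    path.write_text(f"{header}\n{data}\n{mask}\n")


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def fold(fs: FrequencySpectrum) -> FrequencySpectrum:
    """Fold an unfolded spectrum onto minor-allele counts.

    Entry ``d`` and its complement ``n - d`` are summed into whichever has
    total derived count <= (sum n_i)/2; majority entries are masked.  The
    central entries (total exactly half) would be double counted by the
    sum with the reversed array and are therefore halved.
    """
    if fs.folded:
        raise ValueError("spectrum is already folded")
    rev = tuple(slice(None, None, -1) for _ in range(fs.counts.ndim))
    total = sum(fs.sample_sizes)
    tot = _total_derived(fs.counts.shape)
    counts = fs.counts + fs.counts[rev]
    counts[2 * tot == total] *= 0.5
    mask = fs.mask | fs.mask[rev]
    out = FrequencySpectrum(counts, mask, folded=True, population_labels=fs.population_labels)
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _joint_unmasked(expected: FrequencySpectrum, observed: FrequencySpectrum) -> np.ndarray:
    if expected.counts.shape != observed.counts.shape:
        raise ValueError(
            f"shape mismatch: expected {expected.counts.shape}, observed {observed.counts.shape}"
        )
    if expected.folded != observed.folded:
        raise ValueError("folded flags of expected and observed spectra differ")
    return ~(expected.mask | observed.mask)


def poisson_loglik(expected: FrequencySpectrum, observed: FrequencySpectrum) -> float:
    """Poisson composite log-likelihood of ``observed`` given ``expected``.

    Returns ``sum(-M + S*log(M) - log(S!))`` over jointly unmasked entries;
    the larger, the better the model fits.  ``log(S!)`` is computed via the
    log-gamma function so projected (non-integer) data are accepted.
    """
    keep = _joint_unmasked(expected, observed)
    m = np.maximum(expected.counts[keep], EXPECTED_FLOOR)
    s = observed.counts[keep]
    return float(np.sum(-m + s * np.log(m) - gammaln(s + 1.0)))


def optimal_scale(expected: FrequencySpectrum, observed: FrequencySpectrum) -> float:
    """Likelihood-maximizing linear scale ``theta-hat = sum(S) / sum(M)``.

    The overall mutation-rate multiplier of an expected spectrum is profiled
    out of the Poisson likelihood by this ratio of unmasked sums.
    """
    keep = _joint_unmasked(expected, observed)
    denom = float(expected.counts[keep].sum())
    if denom == 0.0:
        raise ValueError("expected spectrum sums to zero over unmasked entries")
    return float(observed.counts[keep].sum()) / denom


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_resample(
    regions: Sequence[FrequencySpectrum],
    seed: int | np.random.Generator,
) -> FrequencySpectrum:
    """Entrywise sum of ``len(regions)`` regions drawn with replacement.

    Standard block bootstrap over well-separated genomic regions; the sum
    of region spectra plays the role of a resampled full-genome spectrum.
    """
    if len(regions) == 0:
        raise ValueError("no region spectra supplied")
    first = regions[0]
    for r in regions[1:]:
        if r.counts.shape != first.counts.shape or r.folded != first.folded:
            raise ValueError("region spectra must share shape and folded state")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, len(regions), size=len(regions))
    counts = sum(regions[i].counts for i in idx)
    mask = np.zeros(first.counts.shape, dtype=bool)
    for r in regions:
        mask |= r.mask
    return FrequencySpectrum(counts, mask, first.folded, first.population_labels)
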