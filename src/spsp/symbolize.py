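"""Partitioning of radial-distance series into symbol sequences.

Two partition schemes are provided.  *Uniform* partitioning splits the range
between the minimum and maximum into S equal-width regions.  *Maximum
entropy* (ME) partitioning places the S-1 edges at order statistics of the
data so that every symbol occurs with (near-)equal empirical probability,
which maximizes the Shannon entropy of the resulting sequence.

The alphabet size S is selected by sweeping k = 2, 3, ... under ME
partitioning and stopping at the first k whose entropy increment
h(k) = H(k) - H(k-1) falls strictly below a threshold ``epsilon_h``.

Conventions (fixed so results are deterministic):

* ME edge j (j = 1..S-1) is the ascending-sorted value at 0-based index
  floor(j*N/S).  On tie-free data every symbol's occupancy then differs
  from N/S by at most 1.
* Bins are half-open: a value exactly equal to an edge maps to the higher
  symbol, so symbol(v) = 1 + (number of edges <= v).
* Entropies are in bits (base-2 logarithm) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np

from .errors import (
    DegenerateInputError,
    DegeneratePartitionError,
    DomainError,
    NotConvergedError,
)
from .phase_space import DistanceSeries

ArrayLike = Union[DistanceSeries, np.ndarray, list, tuple]


def _values(d: ArrayLike) -> np.ndarray:
    if isinstance(d, DistanceSeries):
        return d.values
    return np.asarray(d, dtype=float)


def _source(d: ArrayLike) -> tuple[str, str]:
    if isinstance(d, DistanceSeries):
        return d.source
    return ("", "")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PartitionSpec:
    """A fitted partition: scheme, alphabet size S, and S-1 ordered edges."""

    scheme: str  # "uniform" | "max_entropy"
    S: int
    edges: np.ndarray
    fitted_on: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.scheme not in ("uniform", "max_entropy"):
            raise DomainError(f"unknown partition scheme {self.scheme!r}")
        if self.S < 1:
            raise DomainError(f"S must be >= 1, got {self.S}")
        if self.edges.shape[0] != self.S - 1:
            raise DomainError(
                f"expected {self.S - 1} edges for S={self.S}, "
                f"got {self.edges.shape[0]}"
            )
        if self.S > 1 and np.any(np.diff(self.edges) <= 0):
            raise DegeneratePartitionError(
                f"edges not strictly increasing: {self.edges.tolist()}"
            )


@dataclass
class SymbolSequence:
    """Integer sequence over the alphabet 1..S, one symbol per sample."""

    symbols: np.ndarray
    S: int
    subject_id: str = ""
    trial_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        if self.symbols.ndim != 1:
            raise DomainError("symbol sequence must be 1-D")
        if self.symbols.size and (
            self.symbols.min() < 1 or self.symbols.max() > self.S
        ):
            raise DomainError(
                f"symbols outside 1..{self.S}: "
                f"range [{self.symbols.min()}, {self.symbols.max()}]"
            )

    @property
    def source(self) -> tuple[str, str, Optional[str]]:
        return (self.subject_id, self.trial_id, self.label)

    def __len__(self) -> int:
        return self.symbols.shape[0]


@dataclass
class EntropyProfile:
    """H(k) and h(k) = H(k) - H(k-1) for k = 1..k_max, plus the selection.

    ``H[i]`` holds H(k = i + 1) in bits, with H(1) = 0 by definition;
    ``h[i]`` holds h(k = i + 2).  ``selected_S`` is the smallest k with
    h(k) < epsilon_h, or None if no k <= k_max qualified.
    """

    H: np.ndarray
    h: np.ndarray
    epsilon_h: float
    selected_S: Optional[int] = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.H[0] != 0.0:
            raise DomainError("H(1) must be 0")
        if self.h.shape[0] != self.H.shape[0] - 1:
            raise DomainError("h must cover k = 2..k_max")
        if not 0.0 < self.epsilon_h < 1.0:
            raise DomainError(
                f"epsilon_h must lie in (0, 1), got {self.epsilon_h}"
            )

    @property
    def k_max(self) -> int:
        return self.H.shape[0]

    def H_of(self, k: int) -> float:
        return float(self.H[k - 1])

    def h_of(self, k: int) -> float:
        return float(self.h[k - 2])


# ---------------------------------------------------------------------------
# partition fitting
# ---------------------------------------------------------------------------


def uniform_partition(d: ArrayLike, S: int) -> PartitionSpec:
    """Equal-width bins between min(d) and max(d).

    Raises :class:`DegenerateInputError` on a constant series, for which no
    range exists to split (use S = 1 semantics upstream if that is intended).
    """
    values = _values(d)
    if S < 2:
        raise DomainError(f"uniform_partition requires S >= 2, got {S}")
    if values.size == 0:
        raise DomainError("empty distance series")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateInputError(
            f"constant series (min == max == {lo}); no range to partition — "
            f"use S = 1 if a single symbol is intended"
        )
    edges = lo + (hi - lo) * np.arange(1, S) / S
    return PartitionSpec(scheme="uniform", S=S, edges=edges, fitted_on=_source(d))


def max_entropy_partition(d: ArrayLike, S: int) -> PartitionSpec:
    """Equal-occupancy bins: edge j at sorted index floor(j*N/S).

    On tie-free data the resulting symbol occupancies differ from N/S by at
    most 1.  Ties that collapse edges raise
    :class:`DegeneratePartitionError` naming the collapsed edge values.
    """
    values = _values(d)
    n = values.size
    if S < 2:
        raise DomainError(f"max_entropy_partition requires S >= 2, got {S}")
    if n < S:
        raise DomainError(f"need N >= S, got N={n}, S={S}")
    order = np.sort(values)
    ranks = (np.arange(1, S) * n) // S  # floor(j*N/S), used as 0-based index
    edges = order[ranks]
    if np.unique(values).size < S or np.any(np.diff(edges) <= 0):
        collapsed = [
            float(edges[j])
            for j in range(len(edges) - 1)
            if edges[j + 1] <= edges[j]
        ]
        raise DegeneratePartitionError(
            f"fewer than S={S} distinct values; collapsed edges at "
            f"{collapsed if collapsed else edges.tolist()}"
        )
    return PartitionSpec(
        scheme="max_entropy", S=S, edges=edges, fitted_on=_source(d)
    )


def assign_symbols(d: ArrayLike, partition: PartitionSpec) -> SymbolSequence:
    """Map every value to its bin: symbol(v) = 1 + (number of edges <= v)."""
    values = _values(d)
    symbols = 1 + np.searchsorted(partition.edges, values, side="right")
    subject_id, trial_id = _source(d)
    return SymbolSequence(
        symbols=symbols.astype(int),
        S=partition.S,
        subject_id=subject_id,
        trial_id=trial_id,
    )


# ---------------------------------------------------------------------------
# entropy and alphabet-size selection
# ---------------------------------------------------------------------------


def shannon_entropy(seq: Union[SymbolSequence, np.ndarray, list]) -> float:
    """Empirical Shannon entropy of the symbol distribution, in bits."""
    symbols = seq.symbols if isinstance(seq, SymbolSequence) else np.asarray(seq)
    if symbols.size == 0:
        raise DomainError("cannot compute the entropy of an empty sequence")
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / symbols.size
    return float(-np.sum(p * np.log2(p)) + 0.0)  # + 0.0 normalizes -0.0


def _me_entropy(sorted_values: np.ndarray, k: int) -> float:
    """H(k) under ME partitioning, from the pre-sorted series.

    Equivalent to fitting ``max_entropy_partition`` and symbolizing, but
    reuses one sort across the whole k sweep.
    """
    n = sorted_values.size
    ranks = (np.arange(1, k) * n) // k
    edges = sorted_values[ranks]
    if np.any(np.diff(edges) <= 0) or np.unique(sorted_values).size < k:
        raise DegeneratePartitionError(
            f"degenerate ME partition at k={k}: ties collapse edges"
        )
    # occupancy of bin j = number of values in (edge_{j-1}, edge_j] with the
    # edge itself mapping upward; searchsorted(side='right') gives the count
    # of values <= edge, i.e. strictly below the next bin's first member
    below = np.searchsorted(sorted_values, edges, side="left")
    bounds = np.concatenate(([0], below, [n]))
    counts = np.diff(bounds)
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def entropy_profile(
    d: ArrayLike, k_max: int, epsilon_h: float
) -> EntropyProfile:
    """Sweep ME partitioning over k = 2..k_max and record H(k), h(k).

    ``selected_S`` is the smallest k whose increment h(k) falls strictly
    below ``epsilon_h`` (None if the sweep never gets there).
    """
    values = _values(d)
    n = values.size
    if not 0.0 < epsilon_h < 1.0:
        raise DomainError(f"epsilon_h must lie in (0, 1), got {epsilon_h}")
    if k_max < 2:
        raise DomainError(f"k_max must be >= 2, got {k_max}")
    if n < k_max:
        raise DomainError(f"need N >= k_max, got N={n}, k_max={k_max}")
    sorted_values = np.sort(values)
    H = np.zeros(k_max)
    for k in range(2, k_max + 1):
        try:
            H[k - 1] = _me_entropy(sorted_values, k)
        except DegeneratePartitionError as exc:
            raise DegeneratePartitionError(f"{exc} (while profiling k={k})") from exc
    h = np.diff(H)
    selected = None
    for k in range(2, k_max + 1):
        if h[k - 2] < epsilon_h:
            selected = k
            break
    return EntropyProfile(H=H, h=h, epsilon_h=epsilon_h, selected_S=selected)


def select_symbol_count(
    d: ArrayLike, epsilon_h: float, k_max: int = 64
) -> int:
    """Smallest k with h(k) < epsilon_h under ME partitioning.

    Stops as soon as the rule fires; raises :class:`NotConvergedError`
    (reporting the final increment) if no k <= k_max satisfies it.
    """
    values = _values(d)
    if not 0.0 < epsilon_h < 1.0:
        raise DomainError(f"epsilon_h must lie in (0, 1), got {epsilon_h}")
    if k_max < 2:
        raise DomainError(f"k_max must be >= 2, got {k_max}")
    if values.size < k_max:
        raise DomainError(
            f"need N >= k_max, got N={values.size}, k_max={k_max}"
        )
    sorted_values = np.sort(values)
    h_prev = 0.0
    last_h = math.inf
    for k in range(2, k_max + 1):
        H_k = _me_entropy(sorted_values, k)
        last_h = H_k - h_prev
        if last_h < epsilon_h:
            return k
        h_prev = H_k
    raise NotConvergedError(
        f"no k <= {k_max} with h(k) < {epsilon_h}; final h({k_max}) = {last_h:.6g}"
    )


def select_symbol_count_pooled(
    series: Iterable[ArrayLike], epsilon_h: float, k_max: int = 64
) -> int:
    """Global alphabet size: average h(k) across trials, then threshold.

    Each trial contributes its own ME entropy profile; the per-k increments
    are averaged with equal trial weight and the selection rule is applied
    to the average.  Under exact equal-occupancy partitioning this agrees
    with the single-trial rule.
    """
    profiles = [entropy_profile(d, k_max, epsilon_h) for d in series]
    if not profiles:
        raise DomainError("no distance series supplied")
    mean_h = np.mean([p.h for p in profiles], axis=0)
    for k in range(2, k_max + 1):
        if mean_h[k - 2] < epsilon_h:
            return k
    raise NotConvergedError(
        f"no k <= {k_max} with mean h(k) < {epsilon_h}; "
        f"final mean h({k_max}) = {mean_h[-1]:.6g}"
    )


# ---------------------------------------------------------------------------
# word statistics (traditional symbol-sequence analysis)
# ---------------------------------------------------------------------------


def word_histogram(
    seq: SymbolSequence, word_length: int, stride: int = 1
) -> dict[tuple[int, ...], int]:
    """Counts of consecutive ``word_length``-grams taken every ``stride``.

    The counts sum to floor((N - word_length)/stride) + 1.
    """
    n = len(seq)
    if word_length < 1 or word_length > n:
        raise DomainError(
            f"word_length must lie in 1..{n}, got {word_length}"
        )
    if stride < 1:
        raise DomainError(f"stride must be >= 1, got {stride}")
    histogram: dict[tuple[int, ...], int] = {}
    for start in range(0, n - word_length + 1, stride):
        word = tuple(int(s) for s in seq.symbols[start : start + word_length])
        histogram[word] = histogram.get(word, 0) + 1
    return histogram


def export_profile(profile: EntropyProfile, path: str) -> None:
    """Write the entropy profile as CSV columns (k, H, h)."""
    with open(path, "w") as fh:
        fh.write("k,H_bits,h_bits\n")
        for k in range(1, profile.k_max + 1):
            h_str = format(profile.h_of(k), ".17g") if k >= 2 else ""
            fh.write(f"{k},{format(profile.H_of(k), '.17g')},{h_str}\n")
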