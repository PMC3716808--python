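"""Entropy-per-cost pattern selection under storage and bandwidth bounds.

A pattern-filtering stage watches a stream of discrete input configurations
("patterns") and passes through only those belonging to a stored reference
set.  Two resources limit it: it can store at most ``N`` distinct patterns,
and the total rate of accepted input must stay below a bandwidth fraction
``W``.  Each stored pattern *i*, occurring with probability ``p_i``, is an
entropy source of ``-p_i log p_i`` bits per input unit, at a worst-case cost
equal to the larger of the storage cost ``1/N`` and the bandwidth cost
``p_i / W``.  The selection criterion is therefore the entropy yield per
unit cost::

    f(p) = -p log p / max(1/N, p/W)

``f`` is unimodal in ``p`` with a cusp at ``p = W/N`` (provided
``W/N < 1/e``): very common patterns are too expensive in bandwidth, very
rare ones waste storage on almost no information.  Keeping patterns in
decreasing order of ``f`` until either bound would be exceeded maximizes
the transmitted entropy among threshold-form selections.

This module is agnostic about where pattern probabilities come from; the
same machinery serves 3x3 binary image patches (integer ids 0..511) and
multi-layer detector bin combinations (tuples of bin indices).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import numpy as np

__all__ = [
    "GRID_SIDE",
    "N_PATTERNS",
    "ResourceBudget",
    "PatternDistribution",
    "SelectionResult",
    "encode_pattern",
    "decode_pattern",
    "entropy_yield",
    "select_patterns",
    "retained_entropy_fraction",
    "write_pattern_table",
    "read_pattern_table",
]

GRID_SIDE = 3
#: number of distinct binary patches on a 3x3 grid
N_PATTERNS = 2 ** (GRID_SIDE * GRID_SIDE)

# bit i of the code corresponds to cell (row, col) = divmod(i, 3);
# code = sum grid[r, c] * 2**(3*r + c), row 0 at the top.
_CODE_WEIGHTS = (1 << np.arange(GRID_SIDE * GRID_SIDE)).reshape(GRID_SIDE, GRID_SIDE)


def encode_pattern(grid) -> int:
    """Map a 3x3 binary patch to its integer code in ``[0, 512)``.

    The code is ``sum grid[r][c] * 2**(3r + c)`` (row-major, top row first),
    the exact inverse of :func:`decode_pattern`.
    """
    arr = np.asarray(grid)
    if arr.shape != (GRID_SIDE, GRID_SIDE):
        raise ValueError(f"expected a {GRID_SIDE}x{GRID_SIDE} grid, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("grid entries must be 0 or 1")
    return int((arr.astype(np.int64) * _CODE_WEIGHTS).sum())


def decode_pattern(pattern_id: int) -> np.ndarray:
    """Map an integer code back to its 3x3 binary patch (dtype uint8)."""
    pid = int(pattern_id)
    if not 0 <= pid < N_PATTERNS:
        raise ValueError(f"pattern id must be in [0, {N_PATTERNS}), got {pattern_id}")
    bits = (pid >> np.arange(GRID_SIDE * GRID_SIDE)) & 1
    return bits.reshape(GRID_SIDE, GRID_SIDE).astype(np.uint8)


@dataclass(frozen=True)
class ResourceBudget:
    """Resource limits of the filtering stage.

    Parameters
    ----------
    n_patterns:
        ``N``, the maximum number of distinct patterns that can be stored.
    bandwidth:
        ``W``, the maximum total probability (acceptance rate) of the
        selected set, in ``(0, 1]``.
    log_base:
        Base of the logarithm used for entropy; 2 reports bits.  The
        selected set itself does not depend on the base (it rescales
        ``f`` by a positive constant).
    """

    n_patterns: int
    bandwidth: float
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if int(self.n_patterns) != self.n_patterns or self.n_patterns < 1:
            raise ValueError("n_patterns must be a positive integer")
        if not 0.0 < self.bandwidth <= 1.0:
            raise ValueError("bandwidth must lie in (0, 1]")
        if not self.log_base > 1.0:
            raise ValueError("log_base must exceed 1")

    @property
    def cusp(self) -> float:
        """Probability ``W/N`` at which the yield-per-cost curve peaks."""
        return self.bandwidth / self.n_patterns


def entropy_yield(p, budget: ResourceBudget):
    """Entropy yield per unit cost, ``-p log p / max(1/N, p/W)``.

    Accepts a scalar or array of probabilities; returns the same shape.
    The limit value 0 is used at both endpoints ``p = 0`` and ``p = 1``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    cost = np.maximum(1.0 / budget.n_patterns, arr / budget.bandwidth)
    out = np.zeros_like(arr)
    pos = arr > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[pos] = -arr[pos] * np.log(arr[pos]) / math.log(budget.log_base) / cost[pos]
    if np.ndim(p) == 0:
        return float(out)
    return out


@dataclass
class PatternDistribution:
    """Empirical probabilities of patterns in a corpus or event sample.

    ``probs`` maps a hashable pattern key (an integer patch code, or a tuple
    of detector bins) to its probability; probabilities sum to one.  When the
    distribution was built from counts, ``counts`` and ``total_units`` are
    kept so that ``p_i == counts[i] / total_units``.
    """

    probs: dict[Hashable, float]
    counts: dict[Hashable, int] | None = None
    total_units: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("probabilities must be nonnegative")
        total = math.fsum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total!r}")
        if self.counts is not None:
            if self.total_units is None:
                raise ValueError("total_units required when counts are given")
            if any(c < 0 or int(c) != c for c in self.counts.values()):
                raise ValueError("counts must be nonnegative integers")

    @classmethod
    def from_counts(cls, counts: Mapping[Hashable, int], source: str = "") -> "PatternDistribution":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("counts must contain at least one occurrence")
        probs = {k: c / total for k, c in counts.items() if c > 0}
        kept = {k: int(c) for k, c in counts.items() if c > 0}
        return cls(probs=probs, counts=kept, total_units=int(total), source=source)

    def __len__(self) -> int:
        return len(self.probs)

    def entropy(self, log_base: float = 2.0) -> float:
        """Total pattern entropy ``sum -p_i log p_i`` in the given base."""
        p = np.array([v for v in self.probs.values() if v > 0.0])
        if p.size == 0:
            return 0.0
        return float(-(p * np.log(p)).sum() / math.log(log_base))


@dataclass
class SelectionResult:
    """Outcome of entropy-per-cost selection under a :class:`ResourceBudget`.

    ``threshold_c`` is the smallest yield among selected patterns (``inf``
    for an empty selection); ``occupancy`` is the total probability of the
    selected set, whose inverse is the achieved ``compression_factor``.
    """

    selected: frozenset
    threshold_c: float
    f_values: dict[Hashable, float]
    occupancy: float
    compression_factor: float
    retained_entropy_fraction: float
    budget: ResourceBudget
    order: tuple = field(default_factory=tuple, repr=False)

    @property
    def band(self) -> tuple[float, float] | None:
        """Probability band ``[p_lo, p_hi]`` spanned by the selection."""
        if not self.order:
            return None
        ps = [p for _, p in self.order]
        return (min(ps), max(ps))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "budget": {
                "n_patterns": self.budget.n_patterns,
                "bandwidth": self.budget.bandwidth,
                "log_base": self.budget.log_base,
            },
            "selected": sorted(self.selected, key=_sort_key),
            "threshold_c": self.threshold_c if math.isfinite(self.threshold_c) else "inf",
            "occupancy": self.occupancy,
            "compression_factor": (
                self.compression_factor if math.isfinite(self.compression_factor) else "inf"
            ),
            "retained_entropy_fraction": self.retained_entropy_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sort_key(key):
    # ids may be ints or tuples; give a type-stable composite key
    return (0, key, ()) if isinstance(key, int) else (1, 0, tuple(key))


def select_patterns(dist: PatternDistribution, budget: ResourceBudget) -> SelectionResult:
    """Greedy entropy-per-cost selection.

    Patterns are taken in decreasing order of ``f(p_i)`` (ties broken by
    smaller pattern id) while both ``|S| <= N`` and ``sum p <= W`` hold;
    the scan stops at the first candidate whose addition would break a
    bound, or when only zero-yield patterns (``p = 0`` or ``p = 1``) remain.
    Because ``f`` is unimodal in ``p``, the result is a probability band
    straddling the cusp ``W/N``.
    """
    keys = list(dist.probs.keys())
    probs = np.array([dist.probs[k] for k in keys], dtype=float)
    f = entropy_yield(probs, budget) if keys else np.array([])
    f_values = {k: float(v) for k, v in zip(keys, f)}

    order = sorted(range(len(keys)), key=lambda i: (-f[i], _sort_key(keys[i])))
    selected: list[Hashable] = []
    sel_probs: list[float] = []
    occupancy = 0.0
    for i in order:
        if f[i] <= 0.0:
            break
        if len(selected) + 1 > budget.n_patterns:
            break
        if occupancy + probs[i] > budget.bandwidth:
            break
        selected.append(keys[i])
        sel_probs.append(float(probs[i]))
        occupancy += probs[i]

    occupancy = math.fsum(sel_probs)
    threshold = min((f_values[k] for k in selected), default=math.inf)
    compression = 1.0 / occupancy if occupancy > 0 else math.inf
    try:
        retained = retained_entropy_fraction(dist, selected, budget.log_base)
    except ValueError:
        retained = 0.0
    return SelectionResult(
        selected=frozenset(selected),
        threshold_c=threshold,
        f_values=f_values,
        occupancy=occupancy,
        compression_factor=compression,
        retained_entropy_fraction=retained,
        budget=budget,
        order=tuple((k, dist.probs[k]) for k in selected),
    )


def retained_entropy_fraction(
    dist: PatternDistribution,
    selected: Iterable[Hashable],
    log_base: float = 2.0,
    method: str = "entropy",
) -> float:
    """Fraction of the corpus pattern entropy carried by ``selected``.

    The default reading of a selection's "information content" is the
    entropy ratio ``sum_sel -p log p / sum_all -p log p``.  The alternative
    ``method="occupancy"`` reports the plain probability mass of the
    selected set instead.
    """
    sel = set(selected)
    unknown = sel - set(dist.probs)
    if unknown:
        raise KeyError(f"selected patterns missing from distribution: {sorted(unknown, key=_sort_key)[:5]}")
    if method == "occupancy":
        return math.fsum(dist.probs[k] for k in sel)
    if method != "entropy":
        raise ValueError(f"unknown method {method!r}")
    total = dist.entropy(log_base)
    if total <= 0.0:
        raise ValueError("distribution has zero total entropy; fraction undefined")
    p = np.array([dist.probs[k] for k in sel if dist.probs[k] > 0.0])
    if p.size == 0:
        return 0.0
    part = float(-(p * np.log(p)).sum() / math.log(log_base))
    return part / total


def write_pattern_table(
    path: str | Path,
    dist: PatternDistribution,
    result: SelectionResult | None = None,
) -> None:
    """Write the per-pattern table as CSV.

    Columns: ``pattern_id, probability, count, f_value, selected``.  For
    tuple-keyed (detector) distributions the id is a dash-joined bin list.
    """
    sel = result.selected if result is not None else frozenset()
    fvals = result.f_values if result is not None else {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pattern_id", "probability", "count", "f_value", "selected"])
        for key in sorted(dist.probs, key=_sort_key):
            pid = key if isinstance(key, int) else "-".join(map(str, key))
            count = dist.counts.get(key, "") if dist.counts is not None else ""
            writer.writerow(
                [pid, repr(dist.probs[key]), count, repr(fvals.get(key, "")) if key in fvals else "", int(key in sel)]
            )


def read_pattern_table(path: str | Path) -> PatternDistribution:
    """Read a distribution back from the CSV written by :func:`write_pattern_table`."""
    probs: dict[Hashable, float] = {}
    counts: dict[Hashable, int] = {}
    have_counts = True
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row["pattern_id"]
            key: Hashable = tuple(int(b) for b in raw.split("-")) if "-" in raw else int(raw)
            probs[key] = float(row["probability"])
            if row.get("count"):
                counts[key] = int(row["count"])
            else:
                have_counts = False
    if have_counts and counts:
        total = sum(counts.values())
        return PatternDistribution(probs=probs, counts=counts, total_units=total, source=str(path))
    return PatternDistribution(probs=probs, source=str(path))
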