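"""Monte-Carlo of a binned multi-layer tracking detector.

A charged particle crossing a stack of parallel measuring layers leaves one
hit per layer; each layer is read out in discrete position bins, so a track
appears as one bin index per layer — a *pattern*.  Real trigger hardware
(associative memories) pre-loads the bank of all patterns that a physical
trajectory can produce and flags any event combination found in the bank.

This module simulates such a detector sector — circular trajectories
approximated by a quadratic ``x(y) = x0 + slope*y + curvature*y**2`` in bin
units, layer noise, and a few always-on ("dead") channels — measures the
empirical frequency of every bin combination over many events, and checks
that entropy-per-cost selection applied to those frequencies alone recovers
the geometric pattern bank: valid-track patterns occupy an intermediate
probability band, noise combinations the rare tail, dead-channel
combinations the common tail.
"""

from __future__ import annotations

import csv
import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .patterns import PatternDistribution, ResourceBudget, SelectionResult, select_patterns

__all__ = [
    "DetectorConfig",
    "Event",
    "PatternBank",
    "ValidationReport",
    "simulate_event",
    "simulate_events",
    "enumerate_valid_bank",
    "match_patterns",
    "pattern_frequencies",
    "budget_for_bank",
    "validate_selection",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Geometry and running conditions of one detector sector.

    Positions are expressed in units of one readout bin (``bin_width_um``
    records the physical bin pitch only as metadata).  ``mean_tracks`` is
    the mean number of particles per event in the whole detector;
    ``sector_fraction`` is the solid-angle share of the simulated sector,
    so the sector sees ``mean_tracks * sector_fraction`` tracks per event
    on average.  ``slope_range`` is in bins per layer spacing and
    ``curvature_range`` in bins per layer spacing squared.
    """

    n_layers: int = 4
    bins_per_layer: int = 64
    bin_width_um: float = 500.0
    layer_spacing: float = 1.0
    noise_rate: float = 0.01
    n_dead_bins: int = 4
    dead_bins: tuple[tuple[int, int], ...] | None = None
    mean_tracks: float = 50.0
    sector_fraction: float = 1.0 / 18.0
    slope_range: tuple[float, float] = (-0.3, 0.3)
    curvature_range: tuple[float, float] = (-0.03, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins_per_layer < 2 or self.n_layers < 1:
            raise ValueError("need at least 2 bins and 1 layer")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.mean_tracks < 0 or not 0 < self.sector_fraction <= 1:
            raise ValueError("invalid track rate")
        if self.dead_bins is None:
            object.__setattr__(self, "dead_bins", self._draw_dead_bins())
        for layer, b in self.dead_bins:
            if not (0 <= layer < self.n_layers and 0 <= b < self.bins_per_layer):
                raise ValueError(f"dead bin {(layer, b)} out of range")

    def _draw_dead_bins(self) -> tuple[tuple[int, int], ...]:
        # fixed once per config seed, like real defective channels
        rng = np.random.default_rng([int(self.seed), 0xDEAD])
        pairs: set[tuple[int, int]] = set()
        while len(pairs) < self.n_dead_bins:
            layer = int(rng.integers(self.n_layers))
            b = int(rng.integers(self.bins_per_layer))
            pairs.add((layer, b))
        return tuple(sorted(pairs))

    @property
    def layer_y(self) -> np.ndarray:
        return np.arange(self.n_layers) * self.layer_spacing

    def geometry_hash(self) -> str:
        key = json.dumps(
            [
                self.n_layers,
                self.bins_per_layer,
                self.layer_spacing,
                list(self.slope_range),
                list(self.curvature_range),
            ]
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        payload["dead_bins"] = [list(p) for p in self.dead_bins]
        for k in ("slope_range", "curvature_range"):
            payload[k] = list(payload[k])
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectorConfig":
        raw = json.loads(Path(path).read_text())
        raw["dead_bins"] = tuple(tuple(p) for p in raw["dead_bins"])
        for k in ("slope_range", "curvature_range"):
            raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class Event:
    """Hits of one simulated beam crossing: per-layer sorted bin indices."""

    hits: tuple[np.ndarray, ...]
    truth: list[tuple[float, float, float]]  # (x0, slope, curvature) per track

    def n_hits(self) -> int:
        return int(sum(len(h) for h in self.hits))


@dataclass(frozen=True)
class PatternBank:
    """All bin combinations reachable by a valid trajectory.

    ``examples`` keeps one generating ``(x0, slope, curvature)`` per
    pattern so any bank member can be re-simulated.
    """

    patterns: frozenset
    geometry_hash: str
    examples: dict = field(default_factory=dict, compare=False, hash=False)

    def __len__(self) -> int:
        return len(self.patterns)


def _track_bins(cfg: DetectorConfig, x0, slope, curvature) -> np.ndarray:
    """Bin index per layer for track(s); -1 marks out-of-sector crossings."""
    y = cfg.layer_y
    x = (
        np.asarray(x0)[..., None]
        + np.asarray(slope)[..., None] * y
        + np.asarray(curvature)[..., None] * y**2
    )
    bins = np.floor(x).astype(np.int64)
    bins[(bins < 0) | (bins >= cfg.bins_per_layer)] = -1
    return bins


def simulate_event(cfg: DetectorConfig, rng: np.random.Generator) -> Event:
    """Draw one event: Poisson tracks, Bernoulli bin noise, dead channels.

    Tracks whose trajectory leaves the sector deposit only their in-range
    hits (and therefore can never match a full pattern on their own).
    """
    lam = cfg.mean_tracks * cfg.sector_fraction
    n_tracks = int(rng.poisson(lam))
    x0 = rng.uniform(0.0, cfg.bins_per_layer, size=n_tracks)
    slope = rng.uniform(*cfg.slope_range, size=n_tracks)
    curvature = rng.uniform(*cfg.curvature_range, size=n_tracks)
    bins = _track_bins(cfg, x0, slope, curvature) if n_tracks else np.empty((0, cfg.n_layers), int)

    hit_sets: list[set[int]] = [set() for _ in range(cfg.n_layers)]
    for layer in range(cfg.n_layers):
        col = bins[:, layer]
        hit_sets[layer].update(int(b) for b in col[col >= 0])
        noise = np.nonzero(rng.random(cfg.bins_per_layer) < cfg.noise_rate)[0]
        hit_sets[layer].update(int(b) for b in noise)
    for layer, b in cfg.dead_bins:
        hit_sets[layer].add(int(b))
    hits = tuple(np.array(sorted(s), dtype=np.int64) for s in hit_sets)
    truth = [(float(a), float(s), float(k)) for a, s, k in zip(x0, slope, curvature)]
    return Event(hits=hits, truth=truth)


def simulate_events(cfg: DetectorConfig, n_events: int, seed: int | None = None) -> list[Event]:
    """Deterministic event stream: same config and seed, same events."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [simulate_event(cfg, rng) for _ in range(n_events)]


def enumerate_valid_bank(
    cfg: DetectorConfig, density: int = 4, efficiency: float = 0.99
) -> PatternBank:
    """Enumerate the bank of valid-track patterns to a coverage target.

    Track parameters are swept on a dense grid (``density`` is the
    oversampling factor: between neighbouring samples no layer crossing
    moves by more than ``1/(2*density)`` of a bin) and each distinct bin
    combination is credited with the fraction of parameter volume that
    maps to it.  Patterns are then kept in decreasing volume order until
    the bank covers ``efficiency`` of the fully-contained trajectory
    volume — the same trade real trigger banks make, since the map from
    trajectories to bin combinations has an endless tail of patterns
    reachable only from slivers of parameter space near bin boundaries.
    Deterministic for a fixed config.
    """
    if density < 1:
        raise ValueError("density must be >= 1")
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    if cfg.slope_range[0] > cfg.slope_range[1] or cfg.curvature_range[0] > cfg.curvature_range[1]:
        raise ValueError("empty parameter range")
    y_max = float(cfg.layer_y[-1]) if cfg.n_layers > 1 else 1.0
    step = 1.0 / (2 * density)
    # offset the grid by half a step so samples sit at cell centers
    x0s = np.arange(step / 2, cfg.bins_per_layer, step)
    slopes = _grid(cfg.slope_range, step / max(y_max, 1e-12))
    curvs = _grid(cfg.curvature_range, step / max(y_max**2, 1e-12))

    weight: dict[tuple[int, ...], int] = {}
    examples: dict[tuple[int, ...], tuple[float, float, float]] = {}
    # chunk over slope/curvature combos; vectorize over x0
    for s, k in itertools.product(slopes, curvs):
        bins = _track_bins(cfg, x0s, np.full_like(x0s, s), np.full_like(x0s, k))
        ok = (bins >= 0).all(axis=1)
        for row, x0 in zip(bins[ok], x0s[ok]):
            key = tuple(int(b) for b in row)
            weight[key] = weight.get(key, 0) + 1
            examples.setdefault(key, (float(x0), float(s), float(k)))
    if not weight:
        return PatternBank(patterns=frozenset(), geometry_hash=cfg.geometry_hash())
    total = sum(weight.values())
    ranked = sorted(weight, key=lambda p: (-weight[p], p))
    kept: list[tuple[int, ...]] = []
    covered = 0
    for pat in ranked:
        if covered >= efficiency * total:
            break
        kept.append(pat)
        covered += weight[pat]
    return PatternBank(
        patterns=frozenset(kept),
        geometry_hash=cfg.geometry_hash(),
        examples={p: examples[p] for p in kept},
    )


def _grid(rng_: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = rng_
    if hi == lo:
        return np.array([lo])
    n = max(2, int(math.ceil((hi - lo) / step)) + 1)
    return np.linspace(lo, hi, n)


def mask_dead_channels(events: Iterable[Event], cfg: DetectorConfig) -> list[Event]:
    """Drop hits in always-on channels, as trigger hardware masks hot bins.

    A channel stuck on carries no positional information, and every bin
    combination built on it is statistically indistinguishable from a real
    track sharing its other bins, so frequency-based selection cannot
    reject those combinations; production systems therefore mask known hot
    channels before pattern matching.  Patterns that rely on a masked
    channel become unfindable — use :func:`live_bank` for the matching
    reference set.
    """
    dead: dict[int, set[int]] = {}
    for layer, b in cfg.dead_bins:
        dead.setdefault(layer, set()).add(b)
    out = []
    for ev in events:
        hits = tuple(
            np.array([b for b in h.tolist() if b not in dead.get(layer, ())], dtype=np.int64)
            for layer, h in enumerate(ev.hits)
        )
        out.append(Event(hits=hits, truth=ev.truth))
    return out


def live_bank(bank: PatternBank, cfg: DetectorConfig) -> PatternBank:
    """Restrict a bank to patterns that avoid every masked (dead) channel."""
    dead = set(cfg.dead_bins)
    kept = {
        p: bank.examples.get(p)
        for p in bank.patterns
        if not any((layer, b) in dead for layer, b in enumerate(p))
    }
    return PatternBank(
        patterns=frozenset(kept),
        geometry_hash=bank.geometry_hash,
        examples={p: v for p, v in kept.items() if v is not None},
    )


def match_patterns(event: Event) -> set[tuple[int, ...]]:
    """All full bin combinations present in an event.

    The Cartesian product of per-layer hit sets; its size is exactly the
    product of the per-layer hit counts.
    """
    if any(len(h) == 0 for h in event.hits):
        return set()
    return set(itertools.product(*[map(int, h) for h in event.hits]))


def pattern_frequencies(events: Sequence[Event], bins_per_layer: int | None = None) -> PatternDistribution:
    """Empirical pattern distribution over an event sample.

    Each matched combination counts once per event in which it appears;
    probabilities are normalized across patterns so they sum to one.
    """
    events = list(events)
    if not events:
        raise ValueError("need at least one event")
    if bins_per_layer is None:
        bins_per_layer = 1 + max((int(h.max()) for ev in events for h in ev.hits if len(h)), default=0)
    B = int(bins_per_layer)
    n_layers = len(events[0].hits)

    counts: dict[int, int] = {}
    for ev in events:
        if any(len(h) == 0 for h in ev.hits):
            continue
        flat = ev.hits[0].astype(np.int64)
        for layer in range(1, n_layers):
            flat = (flat[..., None] * B + ev.hits[layer]).ravel()
        for code in flat.tolist():
            counts[code] = counts.get(code, 0) + 1

    def unflatten(code: int) -> tuple[int, ...]:
        out = []
        for _ in range(n_layers):
            code, b = divmod(code, B)
            out.append(b)
        return tuple(reversed(out))

    return PatternDistribution.from_counts(
        {unflatten(c): n for c, n in counts.items()},
        source=f"pattern frequencies over {len(events)} events",
    )


def budget_for_bank(
    bank: PatternBank,
    dist: PatternDistribution,
    headroom: float = 1.5,
    log_base: float = 2.0,
) -> ResourceBudget:
    """Resource budget matched to a known bank.

    Storage is set to the bank size; bandwidth to the observed probability
    mass of the bank scaled by ``headroom``, so the yield-per-cost cusp
    ``W/N`` lands inside the bank's probability band.
    """
    bank_mass = math.fsum(dist.probs.get(p, 0.0) for p in bank.patterns)
    if bank_mass <= 0:
        raise ValueError("no bank pattern was ever observed; cannot set a bandwidth")
    return ResourceBudget(
        n_patterns=len(bank),
        bandwidth=min(1.0, headroom * bank_mass),
        log_base=log_base,
    )


@dataclass
class ValidationReport:
    """How well frequency-only selection recovers the geometric bank."""

    recall: float
    precision: float
    selected_band: tuple[float, float] | None
    bank_band: tuple[float, float] | None
    observed_range: tuple[float, float]
    n_selected: int
    n_bank: int
    budget: ResourceBudget
    selection: SelectionResult

    def to_json(self, path: str | Path) -> None:
        payload = {
            "recall": self.recall,
            "precision": self.precision,
            "selected_band": self.selected_band,
            "bank_band": self.bank_band,
            "observed_range": self.observed_range,
            "n_selected": self.n_selected,
            "n_bank": self.n_bank,
            "budget": {
                "n_patterns": self.budget.n_patterns,
                "bandwidth": self.budget.bandwidth,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def validate_selection(
    bank: PatternBank,
    dist: PatternDistribution,
    budget: ResourceBudget,
) -> ValidationReport:
    """Select patterns from frequencies alone and compare with the bank."""
    result = select_patterns(dist, budget)
    selected = result.selected
    in_bank = selected & bank.patterns
    recall = len(in_bank) / len(bank) if len(bank) else float("nan")
    precision = len(in_bank) / len(selected) if selected else float("nan")
    bank_ps = [dist.probs[p] for p in bank.patterns if p in dist.probs]
    bank_band = (min(bank_ps), max(bank_ps)) if bank_ps else None
    all_ps = list(dist.probs.values())
    return ValidationReport(
        recall=recall,
        precision=precision,
        selected_band=result.band,
        bank_band=bank_band,
        observed_range=(min(all_ps), max(all_ps)),
        n_selected=len(selected),
        n_bank=len(bank),
        budget=budget,
        selection=result,
    )


def write_bank(bank: PatternBank, path: str | Path) -> None:
    """Bank as CSV, one row per pattern, one column per layer bin."""
    patterns = sorted(bank.patterns)
    n_layers = len(patterns[0]) if patterns else 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"bin_layer{i}" for i in range(n_layers)] + ["geometry"])
        for i, pat in enumerate(patterns):
            writer.writerow(list(pat) + [bank.geometry_hash if i == 0 else ""])


def read_bank(path: str | Path) -> PatternBank:
    patterns = []
    geometry = ""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        n_layers = len(header) - 1
        for row in reader:
            patterns.append(tuple(int(v) for v in row[:n_layers]))
            if row[n_layers]:
                geometry = row[n_layers]
    return PatternBank(patterns=frozenset(patterns), geometry_hash=geometry)


def write_events(events: Iterable[Event], path: str | Path) -> None:
    """Events as CSV rows ``event_id, layer, bin``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["event_id", "layer", "bin"])
        for i, ev in enumerate(events):
            for layer, hits in enumerate(ev.hits):
                for b in hits:
                    writer.writerow([i, layer, int(b)])


def read_events(path: str | Path, n_layers: int = 4) -> list[Event]:
    rows: dict[int, list[set[int]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ev = rows.setdefault(int(row["event_id"]), [set() for _ in range(n_layers)])
            ev[int(row["layer"])].add(int(row["bin"]))
    return [
        Event(hits=tuple(np.array(sorted(s), dtype=np.int64) for s in rows[i]), truth=[])
        for i in sorted(rows)
    ]
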