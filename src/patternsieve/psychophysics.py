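"""Stimulus arithmetic and psychometric fitting for pattern-detection runs.

Covers the computational side of a two-interval forced-choice (2IFC)
contrast-detection experiment on small binary patterns: Michelson contrast,
rendering a 3x3 pattern at a nominal contrast on a grey background with its
mean pinned to the background, harmonic (Laplace) relaxation to blend
stimulus borders into the surround, simulation of constant-stimuli trial
blocks, maximum-likelihood Weibull fitting with the 75%-correct threshold
convention, and histogram-ratio reweighting of discrimination accuracies.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .patterns import decode_pattern

__all__ = [
    "Stimulus",
    "TrialRecord",
    "PsychometricFit",
    "michelson_contrast",
    "render_pattern_stimulus",
    "smooth_boundary",
    "weibull_2ifc",
    "simulate_2ifc",
    "fit_psychometric",
    "reweight_by_density",
    "read_trials",
    "write_trials",
]


@dataclass
class Stimulus:
    """Luminance patch on a uniform background (cd/m^2 semantics)."""

    luminance: np.ndarray
    background: float
    nominal_contrast: float
    achieved_contrast: float


@dataclass(frozen=True)
class TrialRecord:
    contrast: float
    correct: bool


@dataclass
class PsychometricFit:
    """Two-parameter Weibull fit of 2IFC percent-correct data.

    ``alpha`` is the contrast scale, ``beta`` the slope; the detection
    threshold is the 75%-correct contrast, ``alpha * ln(2)**(1/beta)``,
    and sensitivity its inverse.
    """

    alpha: float
    beta: float
    threshold75: float
    sensitivity: float
    log_likelihood: float
    n_trials: int


def michelson_contrast(l_max: float, l_min: float) -> float:
    """``(L_max - L_min) / (L_max + L_min)`` for positive luminances."""
    if l_min <= 0 or l_max <= 0:
        raise ValueError("luminances must be positive")
    if l_max < l_min:
        raise ValueError("l_max must be >= l_min")
    return (l_max - l_min) / (l_max + l_min)


def render_pattern_stimulus(
    pattern, contrast: float, background: float = 30.0
) -> Stimulus:
    """Render a 3x3 binary pattern at a nominal Michelson contrast.

    White cells start at ``L_bg * (1 + c)`` and black cells at
    ``L_bg * (1 - c)``; a uniform offset then pins the 9-pixel mean to the
    background, as when a stimulus is luminance-normalized to its surround.
    Unless the pattern has equally many black and white cells the offset
    changes the patch's Michelson contrast, so the achieved contrast is
    recomputed on the shifted patch and reported alongside the nominal one.
    """
    if not 0.0 <= contrast < 1.0:
        raise ValueError("contrast must lie in [0, 1)")
    if background <= 0:
        raise ValueError("background luminance must be positive")
    grid = decode_pattern(pattern) if np.isscalar(pattern) else np.asarray(pattern)
    lum = background * (1.0 + contrast * (2.0 * grid.astype(float) - 1.0))
    offset = background - lum.mean()
    lum = lum + offset
    if (lum <= 0).any():
        raise ValueError("mean normalization drove a luminance non-positive")
    achieved = (
        michelson_contrast(float(lum.max()), float(lum.min())) if lum.max() > lum.min() else 0.0
    )
    return Stimulus(
        luminance=lum,
        background=float(background),
        nominal_contrast=float(contrast),
        achieved_contrast=achieved,
    )


def smooth_boundary(
    field: np.ndarray, fixed_mask: np.ndarray, iterations: int = 100
) -> np.ndarray:
    """Relax free pixels toward the discrete Laplace equation.

    Jacobi iteration of 4-neighbour averaging: pixels flagged in
    ``fixed_mask`` (the pattern itself and the outer frame) act as
    Dirichlet boundary values and are never touched; the rest converge
    toward a harmonic interpolation that blends the stimulus into its
    surround.  The default 100 iterations is ample for patch-sized fields.
    """
    field = np.asarray(field, dtype=float).copy()
    fixed = np.asarray(fixed_mask, dtype=bool)
    if field.shape != fixed.shape:
        raise ValueError("field and fixed_mask shapes differ")
    if iterations < 0:
        raise ValueError("iterations must be nonnegative")
    if fixed.all() or iterations == 0:
        return field
    free = ~fixed
    for _ in range(iterations):
        padded = np.pad(field, 1, mode="edge")
        neigh = (padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]) / 4.0
        field[free] = neigh[free]
    return field


def weibull_2ifc(contrast, alpha: float, beta: float):
    """2IFC psychometric model ``0.5 + 0.5 * (1 - exp(-(x/alpha)**beta))``."""
    x = np.asarray(contrast, dtype=float)
    return 0.5 + 0.5 * (1.0 - np.exp(-((x / alpha) ** beta)))


def simulate_2ifc(
    alpha: float,
    beta: float,
    contrast_levels: Sequence[float],
    n_trials: int,
    seed: int = 0,
) -> list[TrialRecord]:
    """Simulate a constant-stimuli 2IFC block from a known observer.

    Each trial draws its contrast uniformly from ``contrast_levels`` and a
    correct/incorrect outcome from the Weibull observer; identical seeds
    give identical blocks.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    levels = np.asarray(contrast_levels, dtype=float)
    if levels.size == 0:
        raise ValueError("need at least one contrast level")
    if ((levels <= 0) | (levels >= 1)).any():
        raise ValueError("contrast levels must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    picks = rng.integers(levels.size, size=n_trials)
    x = levels[picks]
    p = weibull_2ifc(x, alpha, beta)
    correct = rng.random(n_trials) < p
    return [TrialRecord(float(c), bool(ok)) for c, ok in zip(x, correct)]


def fit_psychometric(trials: Iterable[TrialRecord]) -> PsychometricFit:
    """Two-parameter maximum-likelihood Weibull fit of 2IFC trials.

    Maximizes the Bernoulli likelihood of the per-trial outcomes over
    ``(alpha, beta)`` (optimized in log space, multi-start Nelder-Mead).
    Data in which every trial is correct, or none is, do not constrain the
    curve and raise instead of returning a spurious fit.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    x = np.array([t.contrast for t in trials], dtype=float)
    y = np.array([t.correct for t in trials], dtype=bool)
    if y.all() or not y.any():
        raise ValueError(
            "degenerate outcomes (all correct or all incorrect); psychometric fit is not identifiable"
        )
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct contrast levels")

    def nll(theta: np.ndarray) -> float:
        alpha, beta = np.exp(theta)
        p = np.clip(weibull_2ifc(x, alpha, beta), 1e-12, 1 - 1e-12)
        return float(-(np.log(p[y]).sum() + np.log1p(-p[~y]).sum()))

    x_mid = float(np.median(x))
    best = None
    for a0, b0 in [(x_mid, 2.0), (x_mid / 2, 3.0), (x_mid * 2, 1.0)]:
        res = optimize.minimize(
            nll, np.log([a0, b0]), method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000}
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = (float(v) for v in np.exp(best.x))
    threshold = alpha * math.log(2.0) ** (1.0 / beta)
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        threshold75=threshold,
        sensitivity=1.0 / threshold,
        log_likelihood=-float(best.fun),
        n_trials=len(trials),
    )


def reweight_by_density(
    trials: Sequence[tuple[float, bool]],
    hist_ref: np.ndarray,
    hist_target: np.ndarray,
    bin_edges: np.ndarray,
) -> float:
    """Density-matched percent correct.

    Each trial is keyed by a covariate (e.g. the number of visible points
    in the presented sketch); its outcome is weighted by
    ``hist_target(bin) / hist_ref(bin)`` so that the reference condition's
    covariate distribution is forced to match the target's.  Returns the
    weighted fraction correct.
    """
    hist_ref = np.asarray(hist_ref, dtype=float)
    hist_target = np.asarray(hist_target, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if hist_ref.shape != hist_target.shape or edges.size != hist_ref.size + 1:
        raise ValueError("histograms must share a common binning")
    if not trials:
        raise ValueError("need at least one trial")
    values = np.array([t[0] for t in trials], dtype=float)
    correct = np.array([t[1] for t in trials], dtype=float)
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, hist_ref.size - 1)
    inside = (values >= edges[0]) & (values <= edges[-1])
    if not inside.all():
        raise ValueError("a trial's covariate falls outside the histogram range")
    if (hist_ref[idx] <= 0).any():
        raise ValueError("a trial falls in a bin with zero reference mass")
    w = hist_target[idx] / hist_ref[idx]
    if w.sum() <= 0:
        raise ValueError("all weights vanish; target histogram empty over observed bins")
    return float((w * correct).sum() / w.sum())


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["contrast", "correct"])
        for t in trials:
            writer.writerow([repr(t.contrast), int(t.correct)])


def read_trials(path: str | Path) -> list[TrialRecord]:
    with open(path, newline="") as fh:
        return [
            TrialRecord(float(row["contrast"]), bool(int(row["correct"])))
            for row in csv.DictReader(fh)
        ]
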