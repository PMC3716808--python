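# Methods

## The model

`patternsieve` implements an efficient-coding account of early feature
selection as constrained entropy maximization.  A filtering stage watches a
stream of discrete input configurations ("patterns") drawn from a finite
alphabet `Q` and passes through only the patterns in a stored reference
set.  Two resources bound it:

* **storage** — at most `N` distinct patterns can be stored/recognized;
* **bandwidth** — the total acceptance rate of the selected set must stay
  below a fraction `W` of the input, `Σ_{i∈S} p_i ≤ W`.

A stored pattern occurring with probability `p` contributes entropy
`−p log p` per input unit.  Its worst-case cost is the larger of the
storage cost `1/N` and the bandwidth cost `p/W`, giving the selection
criterion — entropy yield per unit cost:

```
f(p) = −p · log p / max(1/N, p/W)
```

On `(0, 1)` the numerator peaks at `p = 1/e`; dividing by the piecewise
cost moves the peak to a cusp at `p = W/N` whenever `W/N < 1/e`.  Patterns
are taken in decreasing `f` until either bound would be exceeded
(`select_patterns`), which — because `f` is unimodal in `p` — always yields
a *probability band* `[p_lo, p_hi]` straddling `W/N`: the most common
patterns are rejected as bandwidth hogs, the rarest as storage waste.  The
occupancy `Σ_{i∈S} p_i` of the selected set is the fraction of input that
survives filtering; its inverse is the achieved compression factor.

Per-pattern entropies are summed independently; correlations between
patterns (overlapping windows share pixels) are deliberately ignored, so
the "retained entropy fraction" is an independence-approximation
bookkeeping quantity, not a channel capacity.

Choices made where the formulation is open:

* Entropy base 2 (bits).  The selected set is base-invariant (the base is
  a positive scale on `f`); only reported entropy values depend on it.
* Ties in `f` break toward the smaller pattern id, for determinism.
* `p = 0` patterns are never selected (`f = 0`); `p = 1` likewise.
* The bandwidth constraint is enforced strictly *before* admission
  (occupancy never exceeds `W`), so realized occupancy is typically a bit
  below the limit.
* An empty selection carries `threshold_c = +inf` and infinite
  compression, as sentinels.
* The "information content" of a selection is reported as the retained
  entropy fraction `Σ_S −p log p / Σ_Q −p log p`.  An alternative reading
  (plain probability mass) is available via
  `retained_entropy_fraction(..., method="occupancy")` but is not the
  default, since mass ignores how informative the retained patterns are.

## Image pipeline

Vision-side patterns are the 512 binary 3×3 patches, coded
`Σ grid[r][c]·2^(3r+c)` (row-major, top row first).  An image is reduced to
one bit per pixel by thresholding at its own median luminance (midpoint of
the central order statistics; pixels strictly above the median become
white, ties fall to black — a deterministic convention for duplicate-heavy
images).  Every fully interior 3×3 window, centered on each pixel and
overlapping its neighbours, contributes one count to the 512-bin histogram;
counts are pooled over the whole corpus before normalizing, so larger
images weigh proportionally to their window count.  Only interior windows
are counted — no padding rule is invented for the one-pixel border.

A *sketch* keeps the binarized value of exactly those pixels whose
neighbourhood matches the selected set and blanks the rest.  Two retention
semantics are provided: `center` (default; a pixel survives iff the window
centered on it matches — sketches are thin contours) and `union` (all nine
pixels of a matching window survive — thicker strokes).  Sketches export as
8-bit rasters with black 0, white 255, blank 128.

Bookkeeping identity used as a cross-check throughout the tests: the
window-weighted fraction of matched windows over a corpus equals, exactly,
the occupancy of the selection computed on that corpus's pooled
distribution — two paths through the same counts.

## Synthetic image corpus

The generator stands in for a photographic corpus so the pipeline is
testable hermetically.  What matters about binarized natural scenes is the
*shape* of the patch distribution: the two uniform patches dominate by a
wide margin, extended edge/bar patches sit at intermediate probability, and
speckle-like patches are rare.  Scene kinds:

* `pink_noise` — Gaussian noise shaped to an isotropic power spectrum
  `∝ f^(−exponent)`, exponent defaulting to 2 (the classic natural-image
  surrogate);
* `edges` — piecewise-constant regions split by random straight
  boundaries over a faint 1/f background;
* `blobs` — random discs on a 1/f background;
* `uniform`, `checker` — degenerate fixtures for exact-value tests.

All stochastic kinds are finished with a Gaussian band-limit
(`blur_sigma`, default 1 px) standing in for optics/sensor low-pass:
without it the synthesized noise keeps full power up to Nyquist and median
binarization produces pixel-scale speckle, ranking isolated-dot patches
*above* straight edges — a structure photographic images do not show.
With the band-limit, corpora reproduce the ranking
`p(uniform) > p(straight edge) > p(single dot)` across seeds.

What the generator does **not** emulate: calibrated luminance, occlusion
and perspective statistics, anisotropies (horizon bias), and the exact
patch probabilities of any photographic database.  Tests passing on these
corpora therefore validate the machinery and its invariants, not the
numerical occupancies or compression factors one would measure on a
specific photographic corpus.

Corpora are written as 16-bit greyscale PNG so median thresholding is not
quantization-limited, plus a newline-delimited manifest.

## Detector simulation

The same selection rule is exercised on a toy multi-layer tracking
detector.  Geometry: four parallel, equally spaced measuring layers, each
read out in `B = 64` position bins (bin pitch 500 µm recorded as
metadata); positions are handled in bin units.  A trajectory is a sagitta
parameterization `x(y) = x0 + slope·y + curvature·y²` with `y` the layer
coordinate — the quadratic term models the circular bending of a charged
particle.  Defaults: slope ∈ ±0.3 bins/spacing, curvature ∈ ±0.03
bins/spacing², intercept uniform across the sector.

`B = 64` is a deliberate desk-scale choice: the full combination space
`B⁴ ≈ 1.7·10⁷` stays enumerable, while per-bin occupancy remains in the
few-percent regime of a real tracker.  Much coarser binning saturates
(every combination fires every event) and destroys the probability-band
structure the model predicts.

Event content: the number of tracks per event is Poisson with mean
`mean_tracks · sector_fraction` (defaults 50 tracks per event detector-wide
× 1/18 solid-angle share ≈ 2.8 per simulated sector — the rate that keeps
the sector at realistic occupancy at this bin count); every bin
independently fires as noise with probability 1% per event; four "always
on" defective channels, drawn once per config seed, are added to every
event.  Tracks that exit the sector leave only their in-range hits and can
never complete a full pattern.

**Pattern bank.**  The reference set of valid-track patterns is enumerated
by sweeping `(x0, slope, curvature)` on a grid fine enough that no layer
crossing moves more than `1/(2·density)` of a bin between samples, crediting
each distinct bin combination with its parameter volume.  The raw image of
the sweep does not converge as the grid refines — the continuum map has an
endless tail of patterns reachable only from slivers of parameter space at
bin boundaries — so the bank is built to a *coverage target*: patterns are
kept in decreasing volume order until 99% (configurable) of the
fully-contained trajectory volume is covered, the same bank-size versus
efficiency trade that production trigger banks make.

**Frequencies and recovery.**  `pattern_frequencies` counts, per event,
every full bin combination present (the Cartesian product of per-layer hit
sets) and normalizes across patterns.  On the raw stream the distribution
has the expected three-band structure: accidental noise combinations in
the rare tail, valid-track patterns in an intermediate band, and
combinations built on always-on channels at the top (the most probable
combination always involves a dead channel).

One structural fact matters for recovery: a combination of three track
bins plus one always-on bin fires whenever the corresponding track family
fires, so its frequency is at least that of the matching valid patterns —
no frequency-only criterion can reject such "shadows".  Production systems
solve this by masking known hot channels before pattern matching, and the
package does the same: `mask_dead_channels` drops those hits and
`live_bank` restricts the reference bank to patterns that avoid masked
channels (patterns through a dead channel are unfindable by construction).
On the masked stream, entropy-per-cost selection with the budget matched
to the bank (`budget_for_bank`: `N` = bank size, `W` = 1.5× the bank's
observed probability mass, placing the cusp inside the bank band) recovers
the live bank with recall = precision ≈ 0.92–0.94 at 5,000 events across
seeds.

Problem sizes: 5,000 events and grid density 4 keep bank enumeration plus
two frequency passes around 15 s on one CPU; these are the sizes the test
suite and the acceptance script use.

## Psychophysics computations

The stimulus/analysis mathematics of a two-interval forced-choice (2IFC)
contrast-detection experiment on single 3×3 patterns:

* **Michelson contrast** `(L_max − L_min)/(L_max + L_min)`.
* **Stimulus rendering**: white cells at `L_bg(1+c)`, black at
  `L_bg(1−c)`, then a uniform offset pinning the 9-pixel mean to the
  background (30 cd/m² default), as when stimuli are luminance-normalized
  to their surround.  Unless the pattern has equally many black and white
  cells the offset changes the patch's Michelson contrast, so the achieved
  contrast is recomputed after the shift and reported beside the nominal
  one.
* **Boundary smoothing**: free pixels relax toward `∇²L = 0` by Jacobi
  iteration of 4-neighbour averages (100 iterations default), with the
  pattern pixels and outer frame as Dirichlet data.  Jacobi rather than
  Gauss–Seidel keeps the result independent of pixel visiting order.  The
  discrete maximum principle (free pixels stay within the fixed-value
  range) is asserted in tests.
* **Observer model and fit**: `P(correct | x) = ½ + ½(1 − exp(−(x/α)^β))`
  — a cumulative Weibull with the guess rate fixed at ½ (2IFC chance) and
  no lapse parameter; α (contrast scale) and β (slope) are the two free
  parameters, estimated by maximizing the per-trial Bernoulli likelihood
  (multi-start Nelder–Mead in log-parameter space).  The detection
  threshold follows the 75%-correct convention, `α·(ln 2)^{1/β}`, and
  sensitivity is its inverse.  Degenerate data (all correct or all wrong)
  raise instead of returning an unidentifiable fit.
* **Density reweighting**: for comparing discrimination accuracies between
  conditions whose stimuli differ in a covariate (e.g. number of visible
  sketch points), each trial is weighted by the ratio of target to
  reference histogram mass in its covariate bin; matching histograms
  reduce the estimate to the plain percent correct, exactly.

Simulated constant-stimuli blocks use the contrast levels 0.01–0.22.  At
the realistic size of 300 trials per block, the median recovered α over 20
blocks lands within a few percent of truth (15% is the acceptance bar).

## Known limitations

* Entropy accounting ignores inter-pattern correlations by design.
* Single pattern scale (3×3, one resolution); no multi-scale sets, no
  grey-level or colour patterns.
* The detector is a statistical toy: no magnetic-field map, efficiency
  model, or multi-sector geometry; conclusions are about pattern
  statistics, not any real apparatus.
* The synthetic corpus approximates the shape, not the values, of
  photographic patch statistics; occupancies/compressions measured on it
  are not comparable to a specific photographic database.
* The Weibull observer is a modelling choice; any two-parameter family
  with a fixed 2IFC guess rate could be substituted behind the same
  interface.
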