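"""Synthetic luminance images with natural-image-like patch statistics.

Binarized natural scenes have a very skewed 3x3 patch distribution: the two
uniform patches dominate, extended edge/bar patches sit at intermediate
probability, and speckle-like patches are rare.  The generators here emulate
that structure — 1/f-spectrum noise for the global luminance landscape,
plus geometric shapes for extended boundaries — so the whole pipeline can
be exercised deterministically without a photographic corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v2 as iio
import numpy as np
from scipy import ndimage

from .images import LuminanceImage

__all__ = ["SceneSpec", "generate_scene", "generate_corpus", "natural_like_specs"]

KINDS = ("uniform", "checker", "pink_noise", "edges", "blobs")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one deterministic synthetic scene.

    ``params`` is kind-specific: ``exponent`` (spectral slope, pink noise),
    ``square`` (checker square side), ``n_edges`` / ``n_blobs`` (shape
    counts), ``noise_amp`` (additive pink-noise amplitude under shapes),
    ``blur_sigma`` (Gaussian band-limit emulating optics/sensor blur,
    applied to the noise and shape kinds; default 1 pixel).  Without the
    band-limit, synthesized noise keeps full power up to the Nyquist
    frequency and median binarization yields pixel-scale speckle that
    photographic images, low-pass filtered by their optics, do not show.
    """

    kind: str
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scene kind {self.kind!r}; expected one of {KINDS}")
        h, w = self.size
        if h < 3 or w < 3:
            raise ValueError("scene must be at least 3x3")


def _pink_noise(shape: tuple[int, int], exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with isotropic power spectrum ~ f**(-exponent)."""
    h, w = shape
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC untouched
    amp = f ** (-exponent / 2.0)
    amp[0, 0] = 0.0
    field_ = np.fft.ifft2(np.fft.fft2(white) * amp).real
    lo, hi = field_.min(), field_.max()
    if hi > lo:
        field_ = (field_ - lo) / (hi - lo)
    return field_


def generate_scene(spec: SceneSpec) -> LuminanceImage:
    """Render a scene; identical specs give identical pixels."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.kind == "uniform":
        pixels = np.full((h, w), float(p.get("level", 0.5)))
    elif spec.kind == "checker":
        sq = int(p.get("square", 1))
        rows = (np.arange(h) // sq)[:, None]
        cols = (np.arange(w) // sq)[None, :]
        pixels = 0.25 + 0.5 * ((rows + cols) % 2).astype(float)
    elif spec.kind == "pink_noise":
        pixels = _pink_noise((h, w), float(p.get("exponent", 2.0)), rng)
    elif spec.kind == "edges":
        # piecewise-constant regions split by random straight boundaries,
        # over a faint 1/f background: extended luminance edges dominate
        pixels = float(rng.uniform(0.3, 0.7)) * np.ones((h, w))
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(int(p.get("n_edges", 6))):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(0, np.hypot(h, w))
            side = (np.cos(theta) * xx + np.sin(theta) * yy) > offset
            pixels[side] = rng.uniform(0.0, 1.0)
        pixels += float(p.get("noise_amp", 0.05)) * _pink_noise((h, w), 2.0, rng)
    elif spec.kind == "blobs":
        pixels = _pink_noise((h, w), 2.0, rng) * float(p.get("noise_amp", 0.3))
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(int(p.get("n_blobs", 8))):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = rng.uniform(min(h, w) / 16, min(h, w) / 4)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            pixels[disc] = rng.uniform(0.0, 1.0)
    else:  # pragma: no cover - guarded by SceneSpec
        raise ValueError(spec.kind)
    if spec.kind in ("pink_noise", "edges", "blobs"):
        sigma = float(p.get("blur_sigma", 1.0))
        if sigma > 0:
            pixels = ndimage.gaussian_filter(pixels, sigma)
    pixels = np.clip(pixels, 0.0, None)
    return LuminanceImage(pixels)


def generate_corpus(specs: Sequence[SceneSpec], out_dir: str | Path) -> Path:
    """Write scenes as 16-bit greyscale PNGs plus a newline-delimited manifest.

    Returns the manifest path.  16 bits keep the continuous luminance field
    intact so later median thresholding is not quantization-limited.
    """
    if not specs:
        raise ValueError("need at least one scene spec")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, spec in enumerate(specs):
        img = generate_scene(spec)
        scale = img.pixels.max()
        norm = img.pixels / scale if scale > 0 else img.pixels
        arr = np.round(norm * 65535).astype(np.uint16)
        path = out_dir / f"scene_{i:04d}_{spec.kind}.png"
        iio.imwrite(path, arr)
        paths.append(path)
    manifest = out_dir / "manifest.txt"
    manifest.write_text("".join(f"{p}\n" for p in paths))
    return manifest


def natural_like_specs(
    n: int, size: tuple[int, int] = (128, 128), seed: int = 0
) -> list[SceneSpec]:
    """A mixed corpus recipe that mimics natural patch statistics.

    Mostly 1/f noise scenes with edge and blob scenes interleaved, all
    deterministically seeded from ``seed``.
    """
    rng = np.random.default_rng(seed)
    kinds = ["pink_noise", "pink_noise", "edges", "blobs"]
    return [
        SceneSpec(kind=kinds[i % len(kinds)], size=size, seed=int(rng.integers(2**31)))
        for i in range(n)
    ]
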