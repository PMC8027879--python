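"""Synthetic infrared-meibography phantoms with exact ground truth.

Real meibography images of patients cannot be redistributed, so this
module generates eyelid-like test images: N vertically oriented,
possibly sinusoidally curved bright gland strips on a dark background,
with configurable imaging artifacts (defocus blur, specular
reflections, non-uniform illumination, sensor noise). Every phantom
ships its exact binary ground-truth mask and analytically known
morphometry (count, arc length, width, tortuosity computed from the
generative parameters by quadrature, never from the rendered mask).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.integrate import quad

from .morphometry import EyelidMorphometry

__all__ = [
    "GlandSpec",
    "PhantomConfig",
    "PhantomSample",
    "PackingError",
    "OverlapError",
    "sample_specs",
    "render_mask",
    "render_image",
    "expected_morphometry",
    "generate_sample",
    "generate_dataset",
]


class PackingError(ValueError):
    """Requested glands cannot fit side by side in the image width."""


class OverlapError(ValueError):
    """Gland specs overlap; the rendered mask would merge glands."""


@dataclass(frozen=True)
class GlandSpec:
    """Generative parameters of one synthetic gland strip.

    The centerline is x(y) = anchor_column
    + amplitude * sin(2*pi*(y - top_row)/wavelength + phase) for
    top_row <= y <= bottom_row; the strip extends half_width pixels to
    each side, so its rendered width is 2*half_width + 1 pixels.
    """

    anchor_column: float
    top_row: int
    bottom_row: int
    half_width: int
    amplitude: float = 0.0
    wavelength: float = 100.0
    phase: float = 0.0

    def __post_init__(self):
        if self.bottom_row <= self.top_row:
            raise ValueError("bottom_row must exceed top_row")
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    def centerline(self, rows: np.ndarray) -> np.ndarray:
        """Centerline column x(y) for the given row indices."""
        return self.anchor_column + self.amplitude * np.sin(
            2 * np.pi * (np.asarray(rows, float) - self.top_row) / self.wavelength + self.phase
        )

    def arc_length(self) -> float:
        """Exact centerline arc length over [top_row, bottom_row]."""
        k = 2 * np.pi / self.wavelength

        def integrand(y):
            return math.sqrt(1 + (self.amplitude * k * math.cos(k * (y - self.top_row) + self.phase)) ** 2)

        val, _ = quad(integrand, self.top_row, self.bottom_row, limit=400)
        return val

    def chord(self) -> float:
        rows = np.array([self.top_row, self.bottom_row])
        x0, x1 = self.centerline(rows)
        return math.hypot(self.bottom_row - self.top_row, x1 - x0)


# Gland length ranges (pixels at 256x256) by eyelid side: upper-eyelid
# glands span most of the tarsal plate, lower-eyelid glands are shorter.
_LENGTH_RANGES = {"upper": (110, 190), "lower": (60, 120)}


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom eyelid image.

    Ranges are inclusive (low, high) tuples sampled uniformly. Artifact
    strengths of 0 (or count 0) disable the artifact. The same seed
    always reproduces the same phantom.
    """

    image_height: int = 256
    image_width: int = 256
    gland_count: int = 10
    eyelid_side: str = "upper"
    length_range: tuple[float, float] | None = None  # defaults per eyelid_side
    half_width_range: tuple[int, int] = (3, 6)
    amplitude_range: tuple[float, float] = (0.0, 4.0)
    wavelength_range: tuple[float, float] = (80.0, 200.0)
    gland_intensity: float = 200.0
    background_intensity: float = 50.0
    blur_sigma: float = 1.0
    specular_spot_count: int = 2
    specular_spot_radius: tuple[float, float] = (3.0, 8.0)
    illumination_gradient_strength: float = 0.25
    noise_sigma: float = 6.0
    min_gap: int = 2
    margin: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.gland_count < 0:
            raise ValueError("gland_count must be >= 0")
        if self.eyelid_side not in _LENGTH_RANGES:
            raise ValueError(f"eyelid_side must be one of {sorted(_LENGTH_RANGES)}")
        if self.length_range is None:
            self.length_range = _LENGTH_RANGES[self.eyelid_side]
        for name in ("length_range", "half_width_range", "amplitude_range", "wavelength_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {(lo, hi)}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


@dataclass
class PhantomSample:
    """One rendered phantom: image, exact mask, specs and analytic truth."""

    image: np.ndarray  # uint8 grayscale
    mask: np.ndarray  # bool
    specs: list[GlandSpec]
    expected: EyelidMorphometry


def sample_specs(config: PhantomConfig, rng: np.random.Generator | None = None) -> list[GlandSpec]:
    """Draw non-overlapping gland specs for one phantom.

    Glands are packed left to right with a horizontal clearance of at
    least ``config.min_gap`` pixels between the envelopes (centerline
    amplitude + half width) of adjacent strips at every shared row.
    Raises :class:`PackingError` when the requested number and widths
    cannot fit.
    """
    if rng is None:
        rng = config.rng(salt=1)
    n = config.gland_count
    if n == 0:
        return []
    half_widths = rng.integers(config.half_width_range[0], config.half_width_range[1] + 1, size=n)
    amplitudes = rng.uniform(*config.amplitude_range, size=n)
    wavelengths = rng.uniform(*config.wavelength_range, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    lengths = rng.uniform(*config.length_range, size=n)

    # horizontal footprint of each gland: centerline swings +-amplitude,
    # strip extends half_width + 0.5 further each side
    envelopes = 2 * (half_widths + np.ceil(amplitudes)) + 2
    usable = config.image_width - 2 * config.margin
    needed = envelopes.sum() + config.min_gap * (n - 1)
    if needed > usable:
        raise PackingError(
            f"{n} glands with total envelope {int(envelopes.sum())} px plus "
            f"{config.min_gap}-px gaps need {int(needed)} px but only {usable} px "
            f"are available in an image of width {config.image_width}"
        )
    # distribute the remaining slack randomly over the n+1 gaps
    slack = usable - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=n + 1)) if slack > 0 else np.zeros(n + 1, int)
    extra = np.diff(np.concatenate([[0], cuts]))  # n+1 non-negative ints, sum <= slack

    specs = []
    x = config.margin
    for i in range(n):
        x += extra[i]
        # integer anchors keep the rendered strip width at 2*half_width+1
        # exactly for straight glands (half-integer centerlines drop a column)
        center = round(x + envelopes[i] / 2)
        length = lengths[i]
        max_top = config.image_height - config.margin - length
        top = int(round(rng.uniform(config.margin, max(config.margin, max_top))))
        bottom = min(int(round(top + length)), config.image_height - 1 - config.margin)
        specs.append(
            GlandSpec(
                anchor_column=float(center),
                top_row=top,
                bottom_row=bottom,
                half_width=int(half_widths[i]),
                amplitude=float(amplitudes[i]),
                wavelength=float(wavelengths[i]),
                phase=float(phases[i]),
            )
        )
        x += envelopes[i] + config.min_gap
    return specs


def render_mask(specs: list[GlandSpec], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize gland specs into an exact binary ground-truth mask.

    Each gland is a strip of physical width 2*half_width + 1 pixels
    centered on its centerline: pixel (y, x) is foreground iff
    |x - centerline(y)| < half_width + 0.5 for some spec with
    top_row <= y <= bottom_row. Every occupied row therefore contains
    exactly 2*half_width + 1 foreground columns regardless of the
    sub-pixel centerline position. Raises :class:`OverlapError` if two
    specs claim the same pixel, and :class:`ValueError` if a spec
    leaves the image bounds.
    """
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    for spec in specs:
        if spec.top_row < 0 or spec.bottom_row >= H:
            raise ValueError(f"spec rows [{spec.top_row}, {spec.bottom_row}] exceed height {H}")
        rows = np.arange(spec.top_row, spec.bottom_row + 1)
        cl = spec.centerline(rows)
        if (cl - spec.half_width).min() < 0 or (cl + spec.half_width).max() > W - 1:
            raise ValueError("gland centerline +- half_width leaves image bounds")
        cols = np.arange(W)
        strip = np.abs(cols[None, :] - cl[:, None]) < spec.half_width + 0.5
        if (mask[rows] & strip).any():
            raise OverlapError("gland specs overlap; mask would merge glands")
        mask[rows] |= strip
    return mask


def render_image(
    mask: np.ndarray, config: PhantomConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render a grayscale phantom image from a ground-truth mask.

    Glands are bright on a dark background (infrared meibography
    convention). Artifacts are applied in a fixed order: illumination
    gradient, gland/background intensity, defocus blur, saturated
    specular spots, additive Gaussian noise; the result is clipped to
    the 8-bit range. Deterministic given the config seed.
    """
    if rng is None:
        rng = config.rng(salt=2)
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    # linear illumination gradient along a random direction, zero-mean
    if config.illumination_gradient_strength > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:H, 0:W]
        ramp = (np.cos(theta) * (yy / H - 0.5) + np.sin(theta) * (xx / W - 0.5)) * 2
        field = 1.0 + config.illumination_gradient_strength * ramp
    else:
        field = np.ones((H, W))
    img = field * np.where(mask, config.gland_intensity, config.background_intensity)
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=config.blur_sigma, mode="nearest")
    for _ in range(config.specular_spot_count):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        r = rng.uniform(*config.specular_spot_radius)
        yy, xx = np.mgrid[0:H, 0:W]
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 255.0
    if config.noise_sigma > 0:
        img = img + rng.normal(0, config.noise_sigma, size=(H, W))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def expected_morphometry(specs: list[GlandSpec]) -> EyelidMorphometry:
    """Analytic morphometry implied by the generative parameters.

    Length is the centerline arc length by numeric quadrature, width is
    the rendered strip width 2*half_width + 1, tortuosity is arc length
    over the chord between the centerline endpoints. Computed from the
    specs only, never from rendered pixels, so it serves as an
    independent oracle for mask-based measurement.
    """
    if not specs:
        return EyelidMorphometry(0, math.nan, math.nan, math.nan, [])
    lengths = [s.arc_length() for s in specs]
    widths = [2 * s.half_width + 1 for s in specs]
    torts = [L / s.chord() for L, s in zip(lengths, specs)]
    return EyelidMorphometry(
        gland_count=len(specs),
        mean_length=float(np.mean(lengths)),
        mean_width=float(np.mean(widths)),
        mean_tortuosity=float(np.mean(torts)),
    )


def generate_sample(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom: specs -> mask -> image -> analytic truth."""
    specs = sample_specs(config)
    mask = render_mask(specs, (config.image_height, config.image_width))
    image = render_image(mask, config)
    return PhantomSample(image=image, mask=mask, specs=specs, expected=expected_morphometry(specs))


def generate_dataset(
    config: PhantomConfig, n: int, seed: int | None = None
) -> list[PhantomSample]:
    """Generate ``n`` phantoms, re-seeding the config per sample."""
    base = config.seed if seed is None else seed
    out = []
    for i in range(n):
        sub = int(np.random.SeedSequence([base, i]).generate_state(1)[0] % (2**31))
        out.append(generate_sample(dataclasses.replace(config, seed=sub)))
    return out


def write_dataset(samples: list[PhantomSample], out_dir: str | Path) -> list[dict]:
    """Write image/mask PNG pairs plus a JSON sidecar of specs and
    analytic morphometry; returns the manifest records."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(samples):
        img_path = out_dir / "images" / f"phantom_{i:04d}.png"
        mask_path = out_dir / "masks" / f"phantom_{i:04d}.png"
        Image.fromarray(s.image).save(img_path)
        Image.fromarray((s.mask.astype(np.uint8)) * 255).save(mask_path)
        records.append(
            {
                "image_path": str(img_path),
                "mask_path": str(mask_path),
                "specs": [dataclasses.asdict(sp) for sp in s.specs],
                "expected": s.expected.to_dict(),
            }
        )
    with open(out_dir / "phantoms.json", "w") as fh:
        json.dump(records, fh, indent=1)
    return records
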