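"""Synthetic CCTA-slice phantoms with exact ground-truth plaque masks.

Each phantom is a bright annular vessel cross-section (contrast-filled
lumen inside a darker wall) on a noisy background, with one or more
eccentric crescent-shaped plaque inclusions straddling the lumen/wall
interface.  The mask is a pure function of the drawn geometry — blur and
noise are applied to the image only, after the mask is rasterized.

Rasterization uses area coverage on a supersampled grid, thresholded at
0.5 for the binary mask.  The generator is an emulation of plaque-in-
vessel-wall appearance, not a claim of radiological realism.

Identical (spec, seed, index) always yields a bit-identical sample; each
sample's random stream is derived from ``(seed, index)`` so datasets are
reproducible and order-independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, DataError

__all__ = ["PhantomSpec", "SyntheticSample", "generate_sample",
           "generate_dataset", "load_manifest"]


@dataclass
class PhantomSpec:
    """Geometry and intensity ranges for phantom generation.

    Lengths are in pixels, arcs in degrees, intensities in [0,1]
    grayscale units (quantized to ``bit_depth`` on disk).
    """

    image_size: int = 64
    vessel_radius_range: tuple = (13.0, 22.0)
    wall_thickness_range: tuple = (3.0, 6.0)
    plaque_arc_range: tuple = (60.0, 240.0)
    plaque_thickness_range: tuple = (3.0, 7.0)
    plaque_count_range: tuple = (1, 3)
    background_intensity: float = 0.15
    wall_intensity: float = 0.40
    plaque_intensity: float = 0.65
    lumen_intensity: float = 0.80
    noise_sigma: float = 0.02
    blur_sigma: float = 0.6
    center_jitter: float = 4.0
    outward_fraction: float = 0.6
    plaque_profile: str = "crescent"  # or "uniform"
    supersample: int = 4
    bit_depth: int = 8
    seed: int = 0
    min_plaque_fraction: float = 0.001
    max_plaque_fraction: float = 0.20

    def __post_init__(self):
        for name in ("vessel_radius_range", "wall_thickness_range",
                     "plaque_arc_range", "plaque_thickness_range",
                     "plaque_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} has low > high: ({lo}, {hi})")
        if (self.vessel_radius_range[1] + self.center_jitter
                >= self.image_size / 2):
            raise ConfigurationError(
                "vessel radius + jitter exceeds half the canvas; shrink "
                "vessel_radius_range or center_jitter"
            )
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if self.plaque_profile not in ("crescent", "uniform"):
            raise ConfigurationError(
                f"unknown plaque_profile {self.plaque_profile!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})


@dataclass
class SyntheticSample:
    image: np.ndarray     # (H, W) uint8/uint16
    mask: np.ndarray      # (H, W) uint8 in {0, 1}
    provenance: dict = field(repr=False)


def _sample_rng(spec: PhantomSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed),
                                                         int(index)]))


def _draw_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    half = spec.image_size / 2.0
    j = spec.center_jitter
    cx = half + rng.uniform(-j, j)
    cy = half + rng.uniform(-j, j)
    r_out = rng.uniform(*spec.vessel_radius_range)
    wall_t = rng.uniform(*spec.wall_thickness_range)
    r_lumen = max(r_out - wall_t, 1.0)
    lo, hi = spec.plaque_count_range
    n_plaques = int(rng.integers(lo, hi + 1))
    plaques = []
    for _ in range(n_plaques):
        plaques.append({
            "theta_deg": float(rng.uniform(0.0, 360.0)),
            "arc_deg": float(rng.uniform(*spec.plaque_arc_range)),
            "thickness": float(rng.uniform(*spec.plaque_thickness_range)),
        })
    return {"cx": cx, "cy": cy, "r_outer": r_out, "r_lumen": r_lumen,
            "plaques": plaques}


def _rasterize(spec: PhantomSpec, geom: dict):
    """Supersampled region masks → (image float [0,1], mask {0,1})."""
    n, s = spec.image_size, spec.supersample
    coords = (np.arange(n * s) + 0.5) / s
    X, Y = np.meshgrid(coords, coords)
    dx, dy = X - geom["cx"], Y - geom["cy"]
    rho = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))

    lumen = rho < geom["r_lumen"]
    wall = (rho >= geom["r_lumen"]) & (rho <= geom["r_outer"])
    plaque = np.zeros_like(lumen)
    for p in geom["plaques"]:
        d = (theta - p["theta_deg"] + 180.0) % 360.0 - 180.0
        in_arc = np.abs(d) <= p["arc_deg"] / 2.0
        if spec.plaque_profile == "crescent":
            t = p["thickness"] * np.cos(np.pi * d / p["arc_deg"])
        else:
            t = np.full_like(d, p["thickness"])
        inner = geom["r_lumen"] - t
        outer = np.minimum(geom["r_lumen"] + spec.outward_fraction * t,
                           geom["r_outer"])
        plaque |= in_arc & (rho >= inner) & (rho <= outer)

    img = np.full((n * s, n * s), spec.background_intensity)
    img[wall] = spec.wall_intensity
    img[lumen] = spec.lumen_intensity
    img[plaque] = spec.plaque_intensity

    block = lambda a: a.reshape(n, s, n, s).mean(axis=(1, 3))
    image = block(img)
    coverage = block(plaque.astype(np.float64))
    mask = (coverage >= 0.5).astype(np.uint8)
    return image, mask


def generate_sample(spec: PhantomSpec, index: int,
                    max_redraws: int = 20) -> SyntheticSample:
    """Render phantom ``index``; deterministic in (spec, seed, index).

    Geometry is redrawn (from the same deterministic stream) until the
    plaque fraction lies in the spec's bounds; plaque-free specs
    (count range (0,0)) skip the lower bound.
    """
    rng = _sample_rng(spec, index)
    allow_empty = spec.plaque_count_range == (0, 0)
    geom, image, mask = None, None, None
    for attempt in range(max_redraws):
        geom = _draw_geometry(spec, rng)
        image, mask = _rasterize(spec, geom)
        frac = mask.mean()
        if allow_empty or (spec.min_plaque_fraction <= frac
                           <= spec.max_plaque_fraction):
            break
    frac = float(mask.mean())

    if spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    if spec.bit_depth == 8:
        image = np.round(image * 255).astype(np.uint8)
    else:
        image = np.round(image * 65535).astype(np.uint16)

    provenance = dict(geom, index=index, plaque_fraction=frac)
    return SyntheticSample(image=image, mask=mask, provenance=provenance)


def _write_png(path: Path, array: np.ndarray) -> None:
    mode = "I;16" if array.dtype == np.uint16 else "L"
    Image.fromarray(array, mode=mode).save(path, format="PNG")


def generate_dataset(spec: PhantomSpec, n_train: int = 519, n_test: int = 223,
                     out_dir=".", overwrite: bool = False) -> Path:
    """Write paired image/mask PNGs plus a CSV manifest; returns the
    manifest path.  Mask PNGs store {0, 255}."""
    out = Path(out_dir)
    manifest = out / "manifest.csv"
    if manifest.exists() and not overwrite:
        raise DataError(
            f"manifest already exists at {manifest}; pass overwrite=True"
        )
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for split, count, offset in (("train", n_train, 0),
                                 ("test", n_test, n_train)):
        for i in range(count):
            index = offset + i
            sample = generate_sample(spec, index)
            sid = f"{split}_{i:04d}"
            img_rel = f"images/{sid}.png"
            mask_rel = f"masks/{sid}.png"
            _write_png(out / img_rel, sample.image)
            _write_png(out / mask_rel, (sample.mask * 255).astype(np.uint8))
            rows.append({
                "id": sid, "split": split, "image": img_rel, "mask": mask_rel,
                "plaque_fraction": f"{sample.provenance['plaque_fraction']:.6f}",
                "n_plaques": len(sample.provenance["plaques"]),
                "provenance": json.dumps(sample.provenance, sort_keys=True),
            })
    header = ["id", "split", "image", "mask", "plaque_fraction", "n_plaques",
              "provenance"]
    with open(manifest, "w", newline="") as fh:
        import csv
        writer = csv.DictWriter(fh, fieldnames=header)
        writer.writeheader()
        writer.writerows(rows)
    (out / "phantom_spec.json").write_text(
        json.dumps(spec.to_dict(), indent=2, sort_keys=True)
    )
    return manifest


def load_manifest(manifest_path) -> list[dict]:
    import csv
    path = Path(manifest_path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
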