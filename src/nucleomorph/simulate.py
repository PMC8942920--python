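"""Synthetic DAPI-stained spread-nucleus generator with exact ground truth.

Emulates 2D fluorescence images of spread interphase *Arabidopsis thaliana*
nuclei: a convex (elliptical) nucleus of roughly uniform euchromatin
intensity, a small number of bright compact chromocenters biased towards the
nuclear periphery, an optional darker nucleolus, a dim extranuclear
background, and additive Gaussian camera noise. Every image is paired with
exact ground truth (area, integrated DNA content, relative heterochromatin
fraction RHF, chromocenter count and centroids) computed from the noiseless
signal, so that downstream segmentation and morphometry can be benchmarked
against known values.

Presets encode the study conditions for the four leaf cell types
(guard cell GC, parenchyma/pavement PC, vascular VC, endopolyploid EC) and
for five natural accessions (Col, Ler, Cvi, C24, Ws) as population
distributions over nucleus specs: target RHF, DNA-content ratio relative to
the 2C guard-cell anchor, nuclear area/shape, and chromocenter number.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, PlacementError

# Extranuclear (slide) background as a fraction of euchromatin intensity.
BACKGROUND_FRACTION = 0.02

# Minimum clearance between rasterized chromocenter discs, in pixels, so
# that 8-connected labelling never merges distinct chromocenters.
_MIN_CC_GAP_PX = 2.0

# One relative DNA-content unit (the 2C guard-cell anchor) in
# intensity · µm². Chosen so that 16-bit presets use a comfortable part of
# the dynamic range (guard-cell euchromatin ≈ 2800 counts).
CONTENT_UNIT = 60_000.0

# Half-width of the uniform jitter applied to sampled chromocenter radii
# relative to their preset mean radius.
_CC_RADIUS_JITTER = 0.10

_PLACEMENT_TRIES_PER_CC = 400


@dataclass(frozen=True)
class NucleusSpec:
    """Full parameterization of one synthetic nucleus.

    Lengths are in µm, intensities in arbitrary camera counts.
    """

    semi_axes: tuple[float, float]          # (a, b) with a >= b > 0
    orientation: float = 0.0                # radians
    eu_intensity: float = 2800.0            # euchromatin counts/pixel
    cc_count: int = 6
    cc_radius_range: tuple[float, float] = (0.22, 0.27)
    cc_intensity_factor: float = 3.0        # CC brightness / euchromatin
    cc_peripheral_bias: float = 0.5         # min radial fraction of placement
    nucleolus_radius: float = 0.0
    nucleolus_intensity_factor: float = 0.3
    noise_sd: float = 0.05                  # fraction of eu_intensity
    pixel_size: float = 0.1                 # µm / pixel
    bit_depth: int = 16

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ConfigurationError(f"semi_axes must satisfy a >= b > 0, got {self.semi_axes}")
        if self.eu_intensity <= 0:
            raise ConfigurationError("eu_intensity must be > 0")
        if self.cc_count < 0:
            raise ConfigurationError("cc_count must be >= 0")
        lo, hi = self.cc_radius_range
        if self.cc_count > 0 and not (0 < lo <= hi):
            raise ConfigurationError("cc_radius_range must be a positive pair (lo <= hi)")
        if self.cc_intensity_factor < 1:
            raise ConfigurationError("cc_intensity_factor must be >= 1")
        if not (0 <= self.cc_peripheral_bias <= 1):
            raise ConfigurationError("cc_peripheral_bias must lie in [0, 1]")
        if self.nucleolus_radius < 0 or not (0 <= self.nucleolus_intensity_factor <= 1):
            raise ConfigurationError("invalid nucleolus parameters")
        if self.noise_sd < 0 or self.pixel_size <= 0:
            raise ConfigurationError("noise_sd must be >= 0 and pixel_size > 0")
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        # total chromocenter area must stay below the nucleus area
        if self.cc_count > 0 and self.cc_count * math.pi * hi**2 >= math.pi * a * b:
            raise ConfigurationError("total chromocenter area exceeds nucleus area")
        if self.nucleolus_radius >= b:
            raise ConfigurationError("nucleolus does not fit inside the nucleus")


@dataclass
class NucleusImage:
    """2D intensity raster plus acquisition metadata."""

    pixels: np.ndarray        # 2D, dtype uint8/uint16 (float accepted downstream)
    pixel_size: float         # µm / pixel
    bit_depth: int
    source_id: str = ""


@dataclass
class SyntheticGroundTruth:
    """Exact values computed from the noiseless signal of one nucleus."""

    true_area: float                 # µm²
    true_content: float              # summed signal above background, counts
    true_rhf: float                  # in [0, 1]
    true_cc_count: int
    true_cc_centroids: list[tuple[float, float]]  # (x, y) µm
    cell_type_label: str = ""
    accession_label: str = ""


@dataclass(frozen=True)
class Preset:
    """Population-level sampling distribution over NucleusSpec fields."""

    name: str
    cell_type_label: str
    accession_label: str = ""
    target_rhf: float = 0.13
    rhf_sd: float = 0.008
    area_mean: float = 46.0          # µm²
    area_cv: float = 0.08
    aspect_range: tuple[float, float] = (1.2, 2.0)
    cc_count_choices: tuple[int, ...] = (7, 8)
    cc_intensity_factor: float = 3.0
    content_mean: float = 2.0        # relative to the 2C guard-cell anchor
    content_cv: float = 0.12
    nucleolus_radius: float = 1.2    # µm; 0 disables the nucleolus
    nucleolus_intensity_factor: float = 0.3
    cc_peripheral_bias: float = 0.5
    noise_sd: float = 0.05
    pixel_size: float = 0.1
    bit_depth: int = 16

    def sample_spec(self, rng: np.random.Generator) -> NucleusSpec:
        """Draw one NucleusSpec realizing this preset's population targets.

        The chromocenter mean radius is solved in closed form so that the
        expected noiseless RHF of the sampled geometry equals the drawn
        per-nucleus RHF target, and the euchromatin intensity is solved so
        that the integrated signal above background equals the drawn
        DNA-content target (in CONTENT_UNIT units).
        """
        area = float(rng.normal(self.area_mean, self.area_cv * self.area_mean))
        area = max(area, 0.4 * self.area_mean)
        aspect = float(rng.uniform(*self.aspect_range))
        b = math.sqrt(area / (math.pi * aspect))
        a = aspect * b
        orientation = float(rng.uniform(0.0, math.pi))
        cc_count = int(rng.choice(self.cc_count_choices))
        t = float(rng.normal(self.target_rhf, self.rhf_sd))
        t = min(max(t, 1e-4), 0.95)
        f = self.cc_intensity_factor

        r_nucl = self.nucleolus_radius
        if r_nucl >= 0.8 * b:          # keep the nucleolus well inside
            r_nucl = 0.5 * b
        n_area = math.pi * r_nucl**2
        g = 1.0 - self.nucleolus_intensity_factor

        # RHF = f*C / (A - g*N - C + f*C)  =>  C = t (A - g N) / (f(1-t) + t)
        cc_total = t * (area - g * n_area) / (f * (1.0 - t) + t)
        j = _CC_RADIUS_JITTER
        r0 = math.sqrt(cc_total / (cc_count * math.pi * (1.0 + j**2 / 3.0)))
        cc_range = (r0 * (1.0 - j), r0 * (1.0 + j))

        content = float(rng.lognormal(
            math.log(self.content_mean * CONTENT_UNIT) - 0.5 * self.content_cv**2,
            self.content_cv,
        ))
        eu = content / (area - g * n_area + (f - 1.0) * cc_total)

        return NucleusSpec(
            semi_axes=(a, b),
            orientation=orientation,
            eu_intensity=eu,
            cc_count=cc_count,
            cc_radius_range=cc_range,
            cc_intensity_factor=f,
            cc_peripheral_bias=self.cc_peripheral_bias,
            nucleolus_radius=r_nucl,
            nucleolus_intensity_factor=self.nucleolus_intensity_factor,
            noise_sd=self.noise_sd,
            pixel_size=self.pixel_size,
            bit_depth=self.bit_depth,
        )


def _gc_area() -> float:
    # round guard-cell nucleus of diameter 4.84 µm
    return math.pi * (4.84 / 2.0) ** 2


#: Study-condition presets. RHF targets: guard cells 0.19 (the study's 2C
#: anchor phenotype), Col/Ler 0.13, Cvi 0.08; Ws 0.10 and EC 0.09 are
#: back-solved from the reported TE-in-euchromatin percentages (77% and 87%
#: at a 211-Mb genome); VC 0.12 places >40% of TEs in chromocenters.
#: Content ratios encode 2C/4C/5C/6.7C for GC/PC/VC/EC.
PRESETS: dict[str, Preset] = {
    "GC": Preset(
        name="GC", cell_type_label="GC", target_rhf=0.19,
        area_mean=_gc_area(), aspect_range=(1.0, 1.15),
        cc_count_choices=(5, 6), cc_intensity_factor=4.0,
        content_mean=1.0, nucleolus_radius=0.0,
    ),
    "PC": Preset(
        name="PC", cell_type_label="PC", target_rhf=0.13,
        area_mean=46.0, aspect_range=(1.2, 2.0),
        content_mean=2.0, nucleolus_radius=1.2,
    ),
    "VC": Preset(
        name="VC", cell_type_label="VC", target_rhf=0.12,
        area_mean=55.0, aspect_range=(3.3, 4.5),
        content_mean=2.5, nucleolus_radius=1.0,
    ),
    "EC": Preset(
        name="EC", cell_type_label="EC", target_rhf=0.09,
        area_mean=140.0, aspect_range=(1.2, 1.8),
        cc_count_choices=(8, 9, 10),
        content_mean=3.35, nucleolus_radius=1.8,
    ),
}
# Accession presets are parenchyma/pavement-type nuclei.
for _name, _rhf, _content, _area in [
    ("Col", 0.13, 2.0, 46.0),
    ("Ler", 0.13, 2.0, 46.0),
    ("Cvi", 0.08, 2.0, 46.0),
    ("C24", 0.12, 2.3, 56.0),
    ("Ws", 0.10, 2.3, 56.0),
]:
    PRESETS[_name] = Preset(
        name=_name, cell_type_label="PC", accession_label=_name,
        target_rhf=_rhf, content_mean=_content, area_mean=_area,
    )


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# rendering


def _pixel_grid(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of pixel centers, µm."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = (cols + 0.5) * pixel_size
    y = (rows + 0.5) * pixel_size
    return x, y


def _inside_ellipse(x, y, cx, cy, a, b, theta):
    dx, dy = x - cx, y - cy
    u = math.cos(theta) * dx + math.sin(theta) * dy
    v = -math.sin(theta) * dx + math.cos(theta) * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disc_inside_ellipse(cx_d, cy_d, r, cx, cy, a, b, theta, n_probe: int = 24) -> bool:
    phis = np.linspace(0.0, 2.0 * math.pi, n_probe, endpoint=False)
    px = cx_d + r * np.cos(phis)
    py = cy_d + r * np.sin(phis)
    return bool(np.all(_inside_ellipse(px, py, cx, cy, a, b, theta)))


def _place_chromocenters(
    spec: NucleusSpec, center: tuple[float, float], rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Sample non-overlapping peripheral disc placements (x, y, r) in µm."""
    a, b = spec.semi_axes
    theta = spec.orientation
    cx, cy = center
    gap = _MIN_CC_GAP_PX * spec.pixel_size
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.cc_count):
        r = float(rng.uniform(*spec.cc_radius_range))
        ok = False
        for _try in range(_PLACEMENT_TRIES_PER_CC):
            phi = float(rng.uniform(0.0, 2.0 * math.pi))
            rho = float(rng.uniform(spec.cc_peripheral_bias, 1.0))
            u = rho * max(a - r, 0.0) * math.cos(phi)
            v = rho * max(b - r, 0.0) * math.sin(phi)
            x = cx + math.cos(theta) * u - math.sin(theta) * v
            y = cy + math.sin(theta) * u + math.cos(theta) * v
            if not _disc_inside_ellipse(x, y, r, cx, cy, a, b, theta):
                continue
            if spec.nucleolus_radius > 0 and math.hypot(x - cx, y - cy) < (
                r + spec.nucleolus_radius + gap
            ):
                continue
            if any(math.hypot(x - px, y - py) < (r + pr + gap) for px, py, pr in placed):
                continue
            placed.append((x, y, r))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place chromocenter {len(placed) + 1}/{spec.cc_count} "
                f"after {_PLACEMENT_TRIES_PER_CC} tries (nucleus too crowded)"
            )
    return placed


def render_noiseless(spec: NucleusSpec, seed: int) -> tuple[np.ndarray, dict]:
    """Render the noiseless float signal raster for (spec, seed).

    Returns the raster (counts, float64) and a geometry dict with the
    boolean nucleus/cc/nucleolus masks, the scalar background level, and the
    chromocenter centers. The same (spec, seed) pair always reproduces the
    same geometry; noise is drawn from an independent stream in
    :func:`generate_nucleus`.
    """
    if seed < 0:
        raise ConfigurationError("seed must be a non-negative integer")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    a, b = spec.semi_axes
    theta = spec.orientation
    px = spec.pixel_size

    hx = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    hy = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    margin = 16  # pixels of clean background around the nucleus
    half_w = int(math.ceil(hx / px)) + margin
    half_h = int(math.ceil(hy / px)) + margin
    shape = (2 * half_h + 1, 2 * half_w + 1)

    # sub-pixel jitter keeps rasterized areas unbiased across a population
    cx = (half_w + 0.5 + float(rng.uniform(-0.5, 0.5))) * px
    cy = (half_h + 0.5 + float(rng.uniform(-0.5, 0.5))) * px

    x, y = _pixel_grid(shape, px)
    nucleus = _inside_ellipse(x, y, cx, cy, a, b, theta)

    nucleolus = np.zeros(shape, dtype=bool)
    if spec.nucleolus_radius > 0:
        nucleolus = ((x - cx) ** 2 + (y - cy) ** 2 <= spec.nucleolus_radius**2) & nucleus

    centers = _place_chromocenters(spec, (cx, cy), rng) if spec.cc_count else []
    cc = np.zeros(shape, dtype=bool)
    for ccx, ccy, r in centers:
        cc |= (x - ccx) ** 2 + (y - ccy) ** 2 <= r**2
    cc &= nucleus

    eu = spec.eu_intensity
    background = BACKGROUND_FRACTION * eu
    raster = np.full(shape, background, dtype=np.float64)
    raster[nucleus] += eu
    raster[nucleolus] = background + eu * spec.nucleolus_intensity_factor
    raster[cc] = background + eu * spec.cc_intensity_factor

    geometry = {
        "nucleus_mask": nucleus,
        "cc_mask": cc,
        "nucleolus_mask": nucleolus,
        "background": background,
        "cc_centers": [(ccx, ccy) for ccx, ccy, _ in centers],
    }
    return raster, geometry


def _ground_truth(
    spec: NucleusSpec, raster: np.ndarray, geom: dict
) -> SyntheticGroundTruth:
    nucleus = geom["nucleus_mask"]
    cc = geom["cc_mask"]
    bg = geom["background"]
    signal = raster - bg
    content = float(signal[nucleus].sum())
    cc_content = float(signal[cc].sum())
    rhf = cc_content / content if content > 0 else 0.0
    return SyntheticGroundTruth(
        true_area=float(nucleus.sum()) * spec.pixel_size**2,
        true_content=content,
        true_rhf=rhf,
        true_cc_count=len(geom["cc_centers"]),
        true_cc_centroids=list(geom["cc_centers"]),
    )


def generate_nucleus(
    spec: NucleusSpec, seed: int
) -> tuple[NucleusImage, SyntheticGroundTruth]:
    """Generate one noisy nucleus image plus its exact ground truth.

    Ground truth is computed from the noiseless signal raster before noise
    and quantization. Identical (spec, seed) pairs yield bit-identical
    images: geometry and noise are drawn from two fixed, independent
    substreams of ``seed``.
    """
    raster, geom = render_noiseless(spec, seed)
    truth = _ground_truth(spec, raster, geom)

    noise_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    noisy = raster
    if spec.noise_sd > 0:
        noisy = raster + noise_rng.normal(
            0.0, spec.noise_sd * spec.eu_intensity, size=raster.shape
        )
    maxval = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(noisy), 0, maxval).astype(dtype)
    img = NucleusImage(pixels=pixels, pixel_size=spec.pixel_size, bit_depth=spec.bit_depth)
    return img, truth


def population_seed(master_seed: int, index: int) -> int:
    """Stable per-nucleus seed derived from a master seed (documented protocol)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_population(
    preset: Preset | str, n: int, seed: int
) -> list[tuple[NucleusImage, SyntheticGroundTruth]]:
    """Generate ``n`` independent nuclei from a preset, reproducibly.

    Per-nucleus seeds are derived from the master seed with
    :func:`population_seed`; spec sampling uses a sibling substream, so the
    whole population is a pure function of (preset, n, seed).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n < 1:
        raise ConfigurationError("population size n must be >= 1")
    out = []
    for i in range(n):
        spec_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i, 1))
        )
        spec = preset.sample_spec(spec_rng)
        img, truth = generate_nucleus(spec, population_seed(seed, i))
        img.source_id = f"{preset.name}_{i:04d}"
        truth.cell_type_label = preset.cell_type_label
        truth.accession_label = preset.accession_label
        out.append((img, truth))
    return out


# ---------------------------------------------------------------------------
# disk output


def write_population(
    pairs: Sequence[tuple[NucleusImage, SyntheticGroundTruth]],
    outdir: str | Path,
    header_comment: str | None = None,
) -> Path:
    """Write TIFFs plus a sidecar ground-truth CSV; returns the CSV path."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "ground_truth.csv"
    tmp = csv_path.with_suffix(".csv.tmp")
    with open(tmp, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["file", "cell_type_label", "accession_label",
             "true_area", "true_content", "true_rhf", "true_cc_count"]
        )
        for img, truth in pairs:
            fname = f"{img.source_id or 'nucleus'}.tif"
            tifffile.imwrite(
                outdir / fname,
                img.pixels,
                metadata={"pixel_size_um": img.pixel_size, "bit_depth": img.bit_depth},
            )
            writer.writerow(
                [fname, truth.cell_type_label, truth.accession_label,
                 repr(truth.true_area), repr(truth.true_content),
                 repr(truth.true_rhf), truth.true_cc_count]
            )
    tmp.replace(csv_path)
    return csv_path
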