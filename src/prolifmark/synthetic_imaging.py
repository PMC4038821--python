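"""Synthetic brightfield microscope fields with exact ground truth.

Nuclei are anti-aliased ellipses. Pixel colors follow Beer-Lambert
transmission: each stain contributes optical density along its RGB
absorbance direction, so channel intensity is ``I0 * 10**(-OD . v)``.
Hematoxylin density scales with DNA content (counterstain on every nucleus);
DAB is added only on nuclei positive for the rendered marker. An H&E mode
renders hematoxylin only — eosin/stroma are deliberately absent, keeping the
DAB channel empty so round-trip tests can assert a null signal.

Every field carries its nucleus records and an integer label mask, so the
counting and IOD algorithms can be scored against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from prolifmark.errors import InvalidParameterError

__all__ = [
    "StainVectors",
    "RenderConfig",
    "NucleusGeometry",
    "NucleusRecord",
    "SyntheticField",
    "place_nuclei",
    "render_field",
    "ground_truth_counts",
    "write_field",
    "read_field",
]

STAIN_MODES = ("MIB1", "PHH3", "HE")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise InvalidParameterError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density directions over (R, G, B) for the three stains.

    Defaults are the standard H-DAB pair with the residual as their
    normalized cross product (signed, so the matrix stays well conditioned).
    The 3x3 matrix must be invertible for color deconvolution to be defined;
    the two physical stain vectors must be non-negative.
    """

    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    dab: tuple[float, float, float] = (0.269, 0.568, 0.777)
    residual: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if np.any(h < 0) or np.any(d < 0):
            raise InvalidParameterError("stain vectors must be non-negative")
        object.__setattr__(self, "hematoxylin", tuple(h))
        object.__setattr__(self, "dab", tuple(d))
        if self.residual is None:
            # orthogonal complement; signed components keep the matrix well conditioned
            r = np.cross(h, d)
            if np.linalg.norm(r) < 1e-12:
                raise InvalidParameterError("hematoxylin and DAB vectors are collinear")
            object.__setattr__(self, "residual", tuple(_unit(r)))
        else:
            object.__setattr__(self, "residual", tuple(_unit(self.residual)))
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise InvalidParameterError("stain matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        """Rows = stains, columns = RGB OD components."""
        return np.array([self.hematoxylin, self.dab, self.residual], dtype=float)


@dataclass(frozen=True)
class RenderConfig:
    """Geometry, stain amplitudes and noise of the renderer.

    The default frame matches a 10x-objective capture of 2560 x 1920 pixels;
    ``hpf_width``/``hpf_height`` describe the 40x high-power-field crop (1/4
    linear size). Amplitudes are peak optical densities at full pixel
    coverage; hematoxylin scales per unit DNA content.
    """

    width: int = 2560
    height: int = 1920
    hpf_width: int = 640
    hpf_height: int = 480
    background_intensity: tuple[float, float, float] = (245.0, 245.0, 245.0)
    radius_range: tuple[float, float] = (7.0, 13.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.6)
    hematoxylin_od_per_dna: float = 0.45
    dab_od: float = 0.8
    noise_sd: float = 2.0
    min_spacing_factor: float = 1.6  # x max radius; allows near-touching, like tissue
    allow_overlap: bool = False
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError("frame dimensions must be positive")
        if self.hematoxylin_od_per_dna < 0 or self.dab_od < 0 or self.noise_sd < 0:
            raise InvalidParameterError("amplitudes and noise sd must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("radius_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class NucleusGeometry:
    """Ellipse: center (x, y) in pixels, semi-axes (a >= b), rotation in radians."""

    cx: float
    cy: float
    a: float
    b: float
    angle: float


@dataclass(frozen=True)
class NucleusRecord:
    """Ground truth for one rendered nucleus."""

    label: int
    geometry: NucleusGeometry
    mib1_pos: bool
    phh3_pos: bool
    mitotically_visible: bool
    dna_content: float
    phase: str


@dataclass
class SyntheticField:
    """One rendered field: RGB raster, label mask, and nucleus records."""

    rgb: np.ndarray            # (H, W, 3) uint8
    labels: np.ndarray         # (H, W) int32, 0 = background
    records: list[NucleusRecord] = field(default_factory=list)
    stain_mode: str = "MIB1"


def place_nuclei(n: int, config: RenderConfig, rng: np.random.Generator) -> list[NucleusGeometry]:
    """Place ``n`` ellipses inside the frame by rejection sampling.

    Unless ``allow_overlap`` is set, pairwise center distances respect
    ``min_spacing_factor * max_radius``. Raises after a bounded number of
    failed attempts per nucleus when the packing is infeasible.
    """
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    lo, hi = config.radius_range
    spacing = config.min_spacing_factor * hi
    placed: list[NucleusGeometry] = []
    centers = np.empty((0, 2))
    for _ in range(n):
        for attempt in range(config.max_place_attempts):
            a = rng.uniform(lo, hi)
            ecc = rng.uniform(*config.eccentricity_range)
            b = a / ecc
            margin = a + 2.0
            cx = rng.uniform(margin, config.width - margin)
            cy = rng.uniform(margin, config.height - margin)
            if config.allow_overlap or len(centers) == 0 or (
                np.min(np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)) >= spacing
            ):
                placed.append(NucleusGeometry(cx, cy, a, b, rng.uniform(0, np.pi)))
                centers = np.vstack([centers, [cx, cy]])
                break
        else:
            raise InvalidParameterError(
                f"could not place nucleus {len(placed) + 1}/{n}: spacing {spacing:.1f}px "
                f"infeasible in {config.width}x{config.height} frame"
            )
    return placed


def _coverage(geom: NucleusGeometry, shape: tuple[int, int],
              supersample: int = 4) -> tuple[slice, slice, np.ndarray]:
    """Anti-aliased area-coverage of an ellipse over its bounding box.

    Returns (row slice, column slice, coverage in [0, 1]); coverage is the
    fraction of each pixel's supersampled subpixel centers inside the ellipse.
    """
    h, w = shape
    r = max(geom.a, geom.b) + 1.5
    x0 = max(int(np.floor(geom.cx - r)), 0)
    x1 = min(int(np.ceil(geom.cx + r)) + 1, w)
    y0 = max(int(np.floor(geom.cy - r)), 0)
    y1 = min(int(np.ceil(geom.cy + r)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5
    ys = (np.arange(y0, y1)[:, None] + offs[None, :]).ravel()
    xs = (np.arange(x0, x1)[:, None] + offs[None, :]).ravel()
    dx = xs[None, :] - geom.cx
    dy = ys[:, None] - geom.cy
    c, sn = np.cos(geom.angle), np.sin(geom.angle)
    u = (dx * c + dy * sn) / geom.a
    v = (-dx * sn + dy * c) / geom.b
    inside = (u * u + v * v) <= 1.0
    cov = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
    return slice(y0, y1), slice(x0, x1), cov


def render_field(
    nuclei: list[NucleusRecord] | list[NucleusGeometry],
    stain_mode: str,
    vectors: StainVectors,
    config: RenderConfig,
    rng: np.random.Generator,
    frame: tuple[int, int] | None = None,
) -> SyntheticField:
    """Render one field for the given stain.

    ``nuclei`` may be bare geometries (treated as marker-negative diploid G1
    nuclei) or full records. Per pixel, OD = hematoxylin amplitude x
    dna_content x coverage plus, for nuclei positive under ``stain_mode``
    (MIB1/PHH3; never HE), the DAB amplitude x coverage. Channel intensities
    are ``I0 * 10**(-OD . v)`` with clipped Gaussian noise. The label mask
    assigns each pixel with >= 0.5 coverage to its nucleus.
    """
    if stain_mode not in STAIN_MODES:
        raise InvalidParameterError(f"stain_mode must be one of {STAIN_MODES}")
    records: list[NucleusRecord] = []
    for i, item in enumerate(nuclei):
        if isinstance(item, NucleusGeometry):
            records.append(NucleusRecord(i + 1, item, False, False, False, 1.0, "G1"))
        else:
            records.append(item)

    h, w = frame if frame is not None else (config.height, config.width)
    od_h = np.zeros((h, w))
    od_d = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    for rec in records:
        ry, rx, cov = _coverage(rec.geometry, (h, w))
        if cov.size == 0:
            continue
        od_h[ry, rx] += config.hematoxylin_od_per_dna * rec.dna_content * cov
        if stain_mode == "MIB1" and rec.mib1_pos:
            od_d[ry, rx] += config.dab_od * cov
        elif stain_mode == "PHH3" and rec.phh3_pos:
            od_d[ry, rx] += config.dab_od * cov
        core = cov >= 0.5
        labels[ry, rx][core] = rec.label

    m = vectors.matrix
    i0 = np.asarray(config.background_intensity)
    od_rgb = (od_h[..., None] * m[0][None, None, :]
              + od_d[..., None] * m[1][None, None, :])
    img = i0[None, None, :] * np.power(10.0, -od_rgb)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticField(rgb=rgb, labels=labels, records=records, stain_mode=stain_mode)


def ground_truth_counts(field: SyntheticField, stain_mode: str) -> int:
    """Number of nucleus records positive for the given stain.

    MIB1/PHH3 count immunopositive nuclei; HE counts detected mitotic figures.
    """
    if stain_mode not in STAIN_MODES:
        raise InvalidParameterError(f"stain_mode must be one of {STAIN_MODES}")
    flag = {"MIB1": "mib1_pos", "PHH3": "phh3_pos", "HE": "mitotically_visible"}[stain_mode]
    return sum(1 for r in field.records if getattr(r, flag))


def write_field(field: SyntheticField, raster_path, sidecar_path=None) -> None:
    """Write raster + mask as a two-series TIFF and records as a JSON sidecar."""
    raster_path = Path(raster_path)
    tifffile.imwrite(raster_path, field.rgb, photometric="rgb")
    tifffile.imwrite(raster_path.with_suffix(".mask.tif"),
                     field.labels.astype(np.uint16))
    sidecar = Path(sidecar_path) if sidecar_path else raster_path.with_suffix(".json")
    payload = {
        "stain_mode": field.stain_mode,
        "records": [
            {**asdict(r), "geometry": asdict(r.geometry)} for r in field.records
        ],
    }
    sidecar.write_text(json.dumps(payload, indent=1))


def read_field(raster_path, sidecar_path=None) -> SyntheticField:
    """Read a field written by :func:`write_field`."""
    raster_path = Path(raster_path)
    rgb = tifffile.imread(raster_path)
    labels = tifffile.imread(raster_path.with_suffix(".mask.tif")).astype(np.int32)
    sidecar = Path(sidecar_path) if sidecar_path else raster_path.with_suffix(".json")
    payload = json.loads(sidecar.read_text())
    records = [
        NucleusRecord(
            label=r["label"],
            geometry=NucleusGeometry(**r["geometry"]),
            mib1_pos=r["mib1_pos"],
            phh3_pos=r["phh3_pos"],
            mitotically_visible=r["mitotically_visible"],
            dna_content=r["dna_content"],
            phase=r["phase"],
        )
        for r in payload["records"]
    ]
    return SyntheticField(rgb=rgb, labels=labels, records=records,
                          stain_mode=payload["stain_mode"])
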