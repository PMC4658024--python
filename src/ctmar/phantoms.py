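"""Digital phantoms: metal-bearing axial slices used as simulation ground truth.

Two anatomies are emulated, matching the implant strata of the study design:

* ``hip_unilateral`` / ``hip_bilateral`` — an elliptical pelvis of soft
  tissue with sacral and iliac bone, iodine-enhanced iliac vessels, and one
  or two dense metal femoral-head discs (disc diameter >= 10% of the grid).
* ``dental`` — a head slice with a mandibular bone arc carrying 2-6 small
  amalgam inserts, a vertebral body, an airway, and enhanced neck vessels.

Every phantom guarantees an artefact-remote soft-tissue patch (>= 20x20 px)
for the noise ROI, and ships a closed polygon ROI encircling the bone and
implant region — the trace along which streak artefacts are quantified.
Geometry is mildly jittered from the seed so cohorts are heterogeneous but
exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .physics import MATERIALS, METAL_NAMES

__all__ = [
    "PHANTOM_MATERIALS",
    "LabeledPhantom",
    "make_phantom",
    "make_cohort",
    "case_seed",
    "save_phantom",
    "load_phantom",
]

#: Label index -> material name for phantom grids.
PHANTOM_MATERIALS: tuple[str, ...] = (
    "air", "soft_tissue", "water", "bone", "iodine_blood",
    "titanium", "steel", "amalgam",
)

_INDEX = {name: i for i, name in enumerate(PHANTOM_MATERIALS)}
_KINDS = ("hip_unilateral", "hip_bilateral", "dental", "custom")


@dataclass
class LabeledPhantom:
    """2D material-label grid plus the ground truth needed downstream."""

    labels: np.ndarray              # int16 grid of PHANTOM_MATERIALS indices
    pixel_size: float               # cm
    kind: str
    seed: int
    metal_tier: str | None          # implant material driving the IMAR cycle count
    roi_vertices: np.ndarray        # (n, 2) float, (x, y) pixel coords, closed implicitly
    noise_center: tuple[float, float]   # (x, y) of the artefact-remote soft-tissue ROI
    noise_radius: float             # px
    materials: tuple[str, ...] = PHANTOM_MATERIALS

    def __post_init__(self) -> None:
        if self.labels.shape[0] != self.labels.shape[1]:
            raise ValueError("phantom grid must be square")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def grid_size(self) -> int:
        return self.labels.shape[0]

    @property
    def metal_mask_truth(self) -> np.ndarray:
        """Boolean grid of pixels whose material is implant metal."""
        metal_idx = [_INDEX[m] for m in METAL_NAMES]
        return np.isin(self.labels, metal_idx)

    def material_mask(self, name: str) -> np.ndarray:
        return self.labels == _INDEX[name]

    def present_materials(self) -> list[str]:
        """Names of materials actually present in the grid."""
        return [PHANTOM_MATERIALS[i] for i in np.unique(self.labels)]

    def mu_map(self, energy_kev: float) -> np.ndarray:
        """Ground-truth attenuation image (cm^-1) at one energy."""
        from .physics import attenuation
        lut = np.array([attenuation(m, energy_kev) for m in PHANTOM_MATERIALS])
        return lut[self.labels]

    def metal_free_copy(self) -> "LabeledPhantom":
        """Identical phantom with implant metal replaced by soft tissue.

        The metal-free control used by artefact-existence checks and as the
        ground-truth prior of the inpainting oracle.
        """
        labels = self.labels.copy()
        labels[self.metal_mask_truth] = _INDEX["soft_tissue"]
        return LabeledPhantom(
            labels=labels, pixel_size=self.pixel_size, kind=self.kind,
            seed=self.seed, metal_tier=None, roi_vertices=self.roi_vertices.copy(),
            noise_center=self.noise_center, noise_radius=self.noise_radius,
        )


def _disk(shape: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:shape, :shape]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def _ellipse(shape: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.ogrid[:shape, :shape]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _roi_ellipse(rng: np.random.Generator, cx: float, cy: float, ax: float,
                 ay: float, n_vertices: int = 24, jitter: float = 0.0) -> np.ndarray:
    """Elliptical polygon through soft tissue around the bone+implant region.

    Mild seeded radial jitter emulates the individually drawn outlines; the
    margins to all structures exceed the jitter so the trace never crosses
    bone, vessels or air in the metal-free anatomy.
    """
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = 1.0 + (rng.uniform(-jitter, jitter, n_vertices) if jitter else 0.0)
    return np.column_stack([cx + ax * r * np.cos(ang), cy + ay * r * np.sin(ang)])


def _hip(labels: np.ndarray, n: int, rng: np.random.Generator,
         bilateral: bool) -> tuple[str, np.ndarray]:
    c = n / 2.0
    j = lambda s: rng.uniform(-s, s) * n  # noqa: E731 - seeded jitter helper

    body = _ellipse(n, c + j(0.005), c + j(0.005), 0.44 * n, 0.34 * n)
    labels[body] = _INDEX["soft_tissue"]
    # sacrum + iliac wings
    labels[_ellipse(n, c, 0.64 * n + j(0.01), 0.09 * n, 0.06 * n)] = _INDEX["bone"]
    for side in (-1.0, 1.0):
        labels[_disk(n, c + side * 0.25 * n + j(0.008), 0.48 * n + j(0.008),
                     0.075 * n)] = _INDEX["bone"]
    # iodine-enhanced iliac vessels
    for side in (-1.0, 1.0):
        labels[_disk(n, c + side * 0.06 * n, 0.40 * n, 0.018 * n)] = _INDEX["iodine_blood"]
    # femoral heads: metal prosthesis, or native bone on the intact side
    tier = "steel" if bilateral else "titanium"
    metal_side = 1.0 if rng.random() < 0.5 else -1.0
    r_head = 0.066 * n * (1.0 + rng.uniform(-0.08, 0.08))
    for side in (-1.0, 1.0):
        cx = c + side * 0.26 * n + j(0.006)
        cy = 0.54 * n + j(0.006)
        if bilateral or side == metal_side:
            labels[_disk(n, cx, cy, r_head)] = _INDEX[tier]
        else:
            labels[_disk(n, cx, cy, 0.05 * n)] = _INDEX["bone"]
    roi = _roi_ellipse(rng, c, 0.52 * n, 0.37 * n, 0.26 * n, jitter=0.015)
    return tier, roi


def _dental(labels: np.ndarray, n: int, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    c = n / 2.0
    labels[_ellipse(n, c, c, 0.36 * n, 0.44 * n)] = _INDEX["soft_tissue"]
    # vertebral body and airway
    labels[_disk(n, c, 0.20 * n, 0.055 * n)] = _INDEX["bone"]
    labels[_ellipse(n, c, 0.33 * n, 0.05 * n, 0.03 * n)] = _INDEX["air"]
    for side in (-1.0, 1.0):
        labels[_disk(n, c + side * 0.16 * n, 0.30 * n, 0.015 * n)] = _INDEX["iodine_blood"]
    # mandibular arc: annulus sector opening toward the posterior
    arc_cy = 0.42 * n
    r_arc = 0.22 * n * (1.0 + rng.uniform(-0.05, 0.05))
    half_th = 0.0225 * n
    yy, xx = np.ogrid[:n, :n]
    rad = np.sqrt((xx - c) ** 2 + (yy - arc_cy) ** 2)
    anterior = yy - arc_cy > 0.3 * np.abs(xx - c)   # ~ 17 deg past horizontal
    arc = (np.abs(rad - r_arc) <= half_th) & anterior
    labels[arc] = _INDEX["bone"]
    # small amalgam inserts along the arc
    n_implants = int(rng.integers(2, 7))
    angles = np.sort(rng.uniform(np.deg2rad(35.0), np.deg2rad(145.0), n_implants))
    for a in angles:
        ix = c + r_arc * np.cos(a)
        iy = arc_cy + r_arc * np.sin(a)
        labels[_disk(n, ix, iy, 0.013 * n)] = _INDEX["amalgam"]
    roi = _roi_ellipse(rng, c, 0.55 * n, 0.30 * n, 0.18 * n, jitter=0.015)
    return "amalgam", roi


def make_phantom(kind: str, grid_size: int = 256, seed: int = 0,
                 pixel_size: float = 0.15) -> LabeledPhantom:
    """Build one labeled phantom of the given ``kind``.

    Parameters
    ----------
    kind:
        One of ``hip_unilateral``, ``hip_bilateral``, ``dental``.
    grid_size:
        Square grid side in pixels; must be >= 128 so implants resolve.
    seed:
        Drives all pseudo-random placement; identical arguments give an
        identical phantom.
    pixel_size:
        Pixel pitch in cm (default 0.15 cm, a ~38 cm field of view at 256).
    """
    if kind not in _KINDS or kind == "custom":
        raise ValueError(f"unknown phantom kind {kind!r}")
    if grid_size < 128:
        raise ValueError("grid_size must be >= 128 to place implants")
    rng = np.random.default_rng(seed)
    n = grid_size
    labels = np.zeros((n, n), dtype=np.int16)  # air background

    if kind in ("hip_unilateral", "hip_bilateral"):
        tier, roi = _hip(labels, n, rng, bilateral=(kind == "hip_bilateral"))
        noise_center = (0.5 * n, 0.30 * n)
    else:
        tier, roi = _dental(labels, n, rng)
        noise_center = (0.5 * n, 0.80 * n)

    noise_radius = max(8.0, round(0.04 * n))
    phantom = LabeledPhantom(
        labels=labels, pixel_size=pixel_size, kind=kind, seed=seed,
        metal_tier=tier, roi_vertices=roi, noise_center=noise_center,
        noise_radius=noise_radius,
    )
    # the noise ROI neighbourhood must be pure soft tissue by construction
    cx, cy = noise_center
    r = int(noise_radius) + 2
    patch = labels[int(cy) - r:int(cy) + r, int(cx) - r:int(cx) + r]
    if not np.all(patch == _INDEX["soft_tissue"]):
        raise RuntimeError(f"noise ROI region not artefact-remote for {kind} seed {seed}")
    return phantom


def case_seed(master_seed: int, case_index: int, stream: int = 0) -> int:
    """Derived per-case seed: SeedSequence((master, case, stream)) -> int < 2^31."""
    ss = np.random.SeedSequence((int(master_seed), int(case_index), int(stream)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_cohort(n_hip: int, n_dental: int, grid_size: int = 256,
                master_seed: int = 0) -> list[LabeledPhantom]:
    """Reproducible cohort of hip and dental phantoms.

    The hip stratum is predominantly unilateral, mirroring the clinical
    mix (one bilateral case per ten hip cases); per-phantom seeds derive
    from ``master_seed`` and the case index via :func:`case_seed`.
    """
    if n_hip < 0 or n_dental < 0:
        raise ValueError("cohort sizes must be >= 0")
    cohort: list[LabeledPhantom] = []
    for i in range(n_hip):
        kind = "hip_bilateral" if i % 10 == 5 else "hip_unilateral"
        cohort.append(make_phantom(kind, grid_size, seed=case_seed(master_seed, i)))
    for i in range(n_dental):
        cohort.append(make_phantom("dental", grid_size,
                                   seed=case_seed(master_seed, n_hip + i)))
    return cohort


def save_phantom(phantom: LabeledPhantom, stem: str | Path) -> None:
    """Write ``<stem>.tiff`` (16-bit label grid) + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tiff"), phantom.labels.astype(np.uint16))
    meta = {
        "pixel_size_cm": phantom.pixel_size,
        "kind": phantom.kind,
        "seed": phantom.seed,
        "metal_tier": phantom.metal_tier,
        "materials": list(phantom.materials),
        "roi_vertices": phantom.roi_vertices.tolist(),
        "noise_center": list(phantom.noise_center),
        "noise_radius": phantom.noise_radius,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_phantom(stem: str | Path) -> LabeledPhantom:
    """Read a phantom written by :func:`save_phantom`."""
    stem = Path(stem)
    labels = tifffile.imread(stem.with_suffix(".tiff")).astype(np.int16)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return LabeledPhantom(
        labels=labels,
        pixel_size=meta["pixel_size_cm"],
        kind=meta["kind"],
        seed=meta["seed"],
        metal_tier=meta["metal_tier"],
        roi_vertices=np.asarray(meta["roi_vertices"], dtype=float),
        noise_center=tuple(meta["noise_center"]),
        noise_radius=meta["noise_radius"],
        materials=tuple(meta["materials"]),
    )
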