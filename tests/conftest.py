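"""Shared fixtures: phantoms, geometries, and one reusable simulated hip case."""

import numpy as np
import pytest

from ctmar import Geometry, LabeledPhantom, Spectrum, acquire, make_phantom
from ctmar.simulate import project


def mono_spectrum(kev: float, label: str = "kv100") -> Spectrum:
    """Single-bin spectrum: monoenergetic acquisition without hardening."""
    return Spectrum(energies=np.array([float(kev)]), weights=np.array([1.0]),
                    kvp_label=label)


def custom_phantom(labels: np.ndarray, pixel_size: float = 0.15) -> LabeledPhantom:
    """Wrap a raw label grid for tests (triangle ROI placeholder)."""
    n = labels.shape[0]
    return LabeledPhantom(
        labels=labels.astype(np.int16), pixel_size=pixel_size, kind="custom",
        seed=0, metal_tier=None,
        roi_vertices=np.array([[n * 0.3, n * 0.3], [n * 0.7, n * 0.3], [n * 0.5, n * 0.7]]),
        noise_center=(n / 2, n / 2), noise_radius=max(4, n // 30),
    )


def water_disk_phantom(grid: int = 256, radius_frac: float = 0.35) -> LabeledPhantom:
    labels = np.zeros((grid, grid), dtype=np.int16)
    yy, xx = np.ogrid[:grid, :grid]
    c = grid / 2
    labels[(xx - c) ** 2 + (yy - c) ** 2 <= (radius_frac * grid) ** 2] = 2  # water
    return custom_phantom(labels)


@pytest.fixture(scope="session")
def hip_phantom() -> LabeledPhantom:
    return make_phantom("hip_unilateral", 256, seed=7)


@pytest.fixture(scope="session")
def geo256(hip_phantom) -> Geometry:
    return Geometry.for_phantom(hip_phantom, n_angles=180)


@pytest.fixture(scope="session")
def hip_case(hip_phantom, geo256):
    """One simulated hip case shared across MAR / dual-energy tests:
    noiseless 70 keV sinogram with and without metal, plus the per-material
    path sinograms."""
    from ctmar.physics import make_spectrum

    paths = project(hip_phantom, geo256)
    sino70 = acquire(hip_phantom, geo256, mono_spectrum(70.0), paths=paths)
    sino_low = acquire(hip_phantom, geo256, make_spectrum("kv100", 30),
                       n0=2e5, seed=101, paths=paths)
    free = hip_phantom.metal_free_copy()
    sino70_free = acquire(free, geo256, mono_spectrum(70.0))
    return {"phantom": hip_phantom, "free": free, "geometry": geo256,
            "paths": paths, "sino70": sino70, "sino70_free": sino70_free,
            "sino_low": sino_low}
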