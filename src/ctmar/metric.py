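"""Polygon-trace Fourier quantification of streak artefacts.

A closed polygon is drawn around the bone/implant region, HU values are
sampled along the polygon line, and the discrete Fourier transform of that
angle-dependent profile is taken.  Streak artefacts radiating from metal
cross the trace as slowly varying bright/dark excursions and therefore show
up as high amplitudes at low frequencies, while ordinary image noise lives
at high frequencies.  The headline streak score is the sum of one-sided
amplitudes over harmonics k = 1..16 (DC excluded); the four constituent
bands {1,2}, {3,4}, {5..8}, {9..16} are always reported alongside.

DFT convention: ``F_k = sum_t x_t exp(-2 pi i k t / N)`` with no 1/N
scaling; amplitudes are ``|F_k|`` for k = 0..N/2.  The trace is resampled
to a fixed ``n_samples`` (default 256) by arc length so band indices are
comparable across differently sized polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon as _ShapelyPolygon

from .simulate import ReconImage

__all__ = [
    "BANDS",
    "PolygonROI",
    "StreakSpectrum",
    "CaseScore",
    "trace_polygon",
    "streak_spectrum",
    "score_case",
    "score_image",
    "noise_roi",
    "percent_reduction",
    "load_polygon",
    "save_polygon",
]

#: Low-frequency band grouping (harmonic indices, inclusive).
BANDS = {"k1_2": (1, 2), "k3_4": (3, 4), "k5_8": (5, 8), "k9_16": (9, 16)}


@dataclass
class PolygonROI:
    """Closed polygon in pixel coordinates (x = column, y = row, 0-based)."""

    vertices: np.ndarray                # (n, 2) float, implicitly closed
    case_id: str = ""
    n_samples: int = 256

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        n = self.n_samples
        if n < 64 or (n & (n - 1)) != 0:
            raise ValueError("n_samples must be a power of two >= 64")
        if not _ShapelyPolygon(self.vertices).is_valid:
            raise ValueError("polygon is self-intersecting")


@dataclass
class StreakSpectrum:
    """One-sided DFT amplitudes of a polygon trace and their band sums."""

    amplitudes: np.ndarray              # |F_k|, k = 0..N/2
    band_sums: dict = field(default_factory=dict)
    total_low: float = 0.0              # sum over k = 1..16


@dataclass
class CaseScore:
    case_id: str
    arm_label: str
    per_slice_scores: list
    mean_score: float


def _resample_closed(vertices: np.ndarray, n_samples: int) -> np.ndarray:
    """Sample the closed polyline at ``n_samples`` equal arc-length steps,
    starting at the first vertex and following vertex order."""
    pts = np.vstack([vertices, vertices[:1]])
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    targets = np.arange(n_samples) * total / n_samples
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return np.column_stack([x, y])


def trace_polygon(image: ReconImage, roi: PolygonROI) -> np.ndarray:
    """HU profile along the closed polygon (length ``roi.n_samples``).

    The polyline is parameterized by arc length and read with bilinear
    interpolation; the first sample sits on the first vertex.
    """
    h, w = image.hu.shape
    v = roi.vertices
    bad = np.where((v[:, 0] < 0) | (v[:, 0] > w - 1) | (v[:, 1] < 0) | (v[:, 1] > h - 1))[0]
    if bad.size:
        raise ValueError(f"polygon exits image bounds at vertices {bad.tolist()}")
    samples = _resample_closed(v, roi.n_samples)
    return map_coordinates(image.hu, [samples[:, 1], samples[:, 0]], order=1, mode="nearest")


def streak_spectrum(sequence: np.ndarray) -> StreakSpectrum:
    """One-sided DFT amplitudes and the low-frequency band sums.

    The DC term (mean HU along the trace) is excluded from every score.
    """
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 1 or x.size < 64 or (x.size & (x.size - 1)) != 0:
        raise ValueError("sequence length must be a power of two >= 64")
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence contains non-finite values")
    amp = np.abs(np.fft.rfft(x))        # k = 0..N/2, no 1/N scaling
    band_sums = {name: float(amp[lo:hi + 1].sum()) for name, (lo, hi) in BANDS.items()}
    total_low = float(amp[1:17].sum())
    return StreakSpectrum(amplitudes=amp, band_sums=band_sums, total_low=total_low)


def score_image(image: ReconImage, roi: PolygonROI) -> float:
    """Streak score (total_low) of one image along one polygon."""
    return streak_spectrum(trace_polygon(image, roi)).total_low


def score_case(images_per_arm: Mapping[str, Sequence[ReconImage]], roi: PolygonROI,
               n_slices: int | None = None, case_id: str = "") -> list[CaseScore]:
    """Score every arm of one case with the *same* propagated polygon.

    ``images_per_arm`` maps arm label to its representative slices (the
    study averages five); the per-arm score is the mean of per-slice
    ``total_low`` values.  The identical ROI object is reused for every arm
    and slice — no per-arm adjustment.
    """
    lengths = {arm: len(slices) for arm, slices in images_per_arm.items()}
    n = n_slices if n_slices is not None else max(lengths.values(), default=0)
    if n < 1:
        raise ValueError("need at least one slice per arm")
    for arm, ln in lengths.items():
        if ln != n:
            raise ValueError(f"arm {arm!r} has {ln} slices, expected {n}")
    out = []
    for arm, slices in images_per_arm.items():
        scores = [score_image(img, roi) for img in slices]
        out.append(CaseScore(case_id=case_id or roi.case_id, arm_label=arm,
                             per_slice_scores=scores,
                             mean_score=float(np.mean(scores))))
    return out


def noise_roi(image: ReconImage, center: tuple[float, float], radius: float) -> float:
    """Population HU standard deviation in a circular soft-tissue ROI."""
    h, w = image.hu.shape
    cx, cy = center
    if cx - radius < 0 or cx + radius > w - 1 or cy - radius < 0 or cy + radius > h - 1:
        raise ValueError("noise ROI circle exits the image")
    yy, xx = np.ogrid[:h, :w]
    sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    return float(np.std(image.hu[sel]))


def percent_reduction(score_arm: float, score_nomar: float) -> float:
    """Signed percent change of an arm's streak score vs the NOMAR baseline."""
    if score_nomar <= 0:
        raise ValueError("baseline score must be > 0")
    return 100.0 * (score_arm - score_nomar) / score_nomar


def save_polygon(roi: PolygonROI, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "case_id": roi.case_id, "n_samples": roi.n_samples,
        "vertices": roi.vertices.tolist(),
    }, indent=1))


def load_polygon(path: str | Path) -> PolygonROI:
    """Read a polygon ROI from JSON ({vertices: [[x, y], ...]}) or CSV (x,y rows)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        verts = np.loadtxt(path, delimiter=",", ndmin=2)
        return PolygonROI(vertices=verts, case_id=path.stem)
    data = json.loads(path.read_text())
    return PolygonROI(vertices=np.asarray(data["vertices"], dtype=float),
                      case_id=data.get("case_id", path.stem),
                      n_samples=int(data.get("n_samples", 256)))
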