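"""Synthetic radiograph phantoms with known soft tissue, rib shadows and contours.

A phantom is the exact additive decomposition

    input = background + bone + noise

where the background is a smooth seeded random field (soft tissue), each rib
is an elongated curved band whose additive shadow is constant along curves
parallel to its boundary contour (the modelling assumption of the physical
suppression algorithm), and the noise is white Gaussian.  Every sample
carries its ground truth, per-rib closed contours and binary masks, so each
pipeline stage can be tested against a known answer and (raw, suppressed)
training pairs can be produced without external data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _fill_polygon

from ribsuppress.st_transform import Contour

__all__ = [
    "PhantomSpec", "PhantomSample", "PhantomLayoutError",
    "generate", "generate_dataset", "train_val_split",
]


class PhantomLayoutError(ValueError):
    """Raised when the requested ribs cannot fit on the canvas."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom; the seed fully determines the output.

    Intensities are unit-range floats.  Defaults emulate a high-SNR
    radiograph detail: a smooth soft-tissue background (base level 0.45,
    fluctuation amplitude 0.10, correlation scale ~H/5) with rib bands of
    thickness 9 px and additive amplitude 0.15, a cosine-taper cross profile
    (flat top, smooth falloff to zero at the boundary), and additive Gaussian
    noise with sigma 0.002.
    """

    size: tuple[int, int] = (256, 256)
    n_ribs: int = 6
    background_amplitude: float = 0.10
    background_blur: float = 50.0
    background_base: float = 0.45
    rib_thickness: float = 9.0
    rib_amplitude: float = 0.15
    cross_profile: str = "cosine-taper"   # or "flat"
    layout: str = "stack"                 # or "ribcage" (two L/R columns)
    noise_sigma: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.rib_amplitude < 0:
            raise ValueError("rib amplitude must be >= 0")
        if self.rib_thickness < 3:
            raise ValueError("rib thickness must be >= 3 px")
        if self.cross_profile not in ("cosine-taper", "flat"):
            raise ValueError("cross_profile must be 'cosine-taper' or 'flat'")
        if self.layout not in ("stack", "ribcage"):
            raise ValueError("layout must be 'stack' or 'ribcage'")


@dataclass
class PhantomSample:
    """One generated phantom with its exact decomposition and annotations."""

    input: np.ndarray
    background: np.ndarray
    bone: np.ndarray
    noise: np.ndarray
    contours: list[Contour]
    masks: list[np.ndarray]
    spec: PhantomSpec = field(repr=False, default=None)


def _cross_profile(r: np.ndarray, kind: str) -> np.ndarray:
    """Profile vs relative depth r = s / c(t) in [0, 1] (0 at the boundary)."""
    r = np.clip(r, 0.0, 1.0)
    if kind == "flat":
        return np.ones_like(r)
    # smooth rise over the outer half, flat top toward the centerline
    return np.where(r < 0.5, np.sin(np.pi * r) ** 2, 1.0)


def _rib_geometry(H: int, W: int, y_center: float, x0: float, x1: float,
                  bow: float, half: float, step: float = 1.25):
    """Centerline polyline and closed offset-band contour of one rib.

    End caps are semicircular, so the band boundary is everywhere at constant
    distance ``half`` from the centerline and the additive shadow is constant
    along contour-parallel curves by construction, caps included.
    """
    n = max(int(np.ceil((x1 - x0) / step)) + 1, 8)
    u = np.linspace(0.0, 1.0, n)
    x = x0 + u * (x1 - x0)
    y = y_center - bow * np.sin(np.pi * u)
    dx = np.gradient(x)
    dy = np.gradient(y)
    norm = np.hypot(dx, dy)
    tx, ty = dx / norm, dy / norm       # unit tangent of the centerline
    nx, ny = -ty, tx                    # unit normal of the centerline
    top = np.column_stack([x + half * nx, y + half * ny])
    bot = np.column_stack([x - half * nx, y - half * ny])

    def _cap(cx, cy, ax, ay, px, py):
        # semicircle around (cx, cy) from +normal through +axis to -normal;
        # finely polygonised: cap curvature is the tightest on the contour
        phi = np.linspace(np.pi / 2, -np.pi / 2, 25)[1:-1]
        return np.column_stack([cx + half * (np.cos(phi) * ax + np.sin(phi) * px),
                                cy + half * (np.cos(phi) * ay + np.sin(phi) * py)])

    end_cap = _cap(x[-1], y[-1], tx[-1], ty[-1], nx[-1], ny[-1])
    start_cap = _cap(x[0], y[0], -tx[0], -ty[0], -nx[0], -ny[0])
    verts = np.vstack([top, end_cap, bot[::-1], start_cap])
    if (verts[:, 0].min() < 1 or verts[:, 0].max() > W - 2
            or verts[:, 1].min() < 1 or verts[:, 1].max() > H - 2):
        raise PhantomLayoutError(
            f"rib at y={y_center:.1f} leaves the {H}x{W} canvas")
    center = np.column_stack([x, y])
    return center, verts


def _distance_to_polyline(pts: np.ndarray, line: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (vectorised over segments)."""
    A = line[:-1]
    B = line[1:]
    AB = B - A
    L2 = (AB ** 2).sum(axis=1)
    V = pts[:, None, :] - A[None, :, :]
    tpar = np.clip(np.einsum("mei,ei->me", V, AB) / L2[None, :], 0.0, 1.0)
    proj = A[None, :, :] + tpar[..., None] * AB[None, :, :]
    d = np.hypot(pts[:, None, 0] - proj[..., 0], pts[:, None, 1] - proj[..., 1])
    return d.min(axis=1)


def _rib_rows(spec: PhantomSpec):
    """Lay ribs out as (y_center, x0, x1, label) rows; raise when they cannot fit."""
    H, W = spec.size
    rows = []
    pad = spec.rib_thickness / 2 + 2        # semicircular caps need clearance
    if spec.layout == "stack":
        counts = [("R", spec.n_ribs, max(0.12 * W, pad), min(0.88 * W, W - pad))]
    else:
        n_left = spec.n_ribs // 2
        counts = [("L", n_left, max(0.06 * W, pad), 0.46 * W),
                  ("R", spec.n_ribs - n_left, 0.54 * W, min(0.94 * W, W - pad))]
    for side, n, x0, x1 in counts:
        if n == 0:
            continue
        top, bottom = 0.10 * H, 0.90 * H
        pitch = (bottom - top) / n
        if pitch < spec.rib_thickness + 3:
            raise PhantomLayoutError(
                f"{n} ribs of thickness {spec.rib_thickness} do not fit in "
                f"{H} rows")
        for i in range(n):
            yc = top + (i + 0.5) * pitch
            rows.append((side + str(i + 1), yc, x0, x1, pitch))
    return rows


def generate(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom deterministically from its spec."""
    H, W = spec.size
    rng = np.random.default_rng(spec.seed)

    field_ = rng.standard_normal((H, W))
    field_ = ndimage.gaussian_filter(field_, spec.background_blur, mode="reflect")
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ *= spec.background_amplitude / (3.0 * sd)   # ~+-amplitude range
    background = spec.background_base + field_

    bone = np.zeros((H, W))
    contours: list[Contour] = []
    masks: list[np.ndarray] = []
    half = spec.rib_thickness / 2.0
    for label, yc, x0, x1, pitch in _rib_rows(spec):
        # gentle arc: curvature radius stays well above the half-thickness
        bow = rng.uniform(0.2, 0.6) * min(pitch - spec.rib_thickness,
                                          0.25 * (x1 - x0))
        bow = min(bow, yc - half - 2.0)     # keep the bowed apex on canvas
        center, verts = _rib_geometry(H, W, yc, x0, x1, bow, half)
        contour = Contour(verts, label=label)
        mask = np.zeros((H, W), dtype=bool)
        rr, cc = _fill_polygon(verts[:, 1], verts[:, 0], shape=(H, W))
        mask[rr, cc] = True
        ys, xs = np.nonzero(mask)
        if len(ys):
            pts = np.column_stack([xs, ys]).astype(float)
            d = _distance_to_polyline(pts, center)
            r = 1.0 - d / half
            bone[ys, xs] += spec.rib_amplitude * _cross_profile(r, spec.cross_profile)
        contours.append(contour)
        masks.append(mask)

    noise = rng.normal(0.0, spec.noise_sigma, size=(H, W)) if spec.noise_sigma > 0 \
        else np.zeros((H, W))
    image = background + bone + noise
    return PhantomSample(input=image, background=background, bone=bone,
                         noise=noise, contours=contours, masks=masks, spec=spec)


def train_val_split(n: int, train_fraction: float = 0.8) -> tuple[int, int]:
    """Deterministic 4:1 split sizes (245 -> 196 train / 49 validation)."""
    n_train = int(round(n * train_fraction))
    return n_train, n - n_train


def contours_to_json(contours: list[Contour]) -> dict:
    return {"ribs": [{"label": c.label, "vertices": c.vertices.tolist()}
                     for c in contours]}


def generate_dataset(template: PhantomSpec, n: int, seed: int, out_dir,
                     split: bool = False) -> list[PhantomSample]:
    """Generate ``n`` phantoms and write supervised training pairs.

    Per sample ``i`` (seed ``seed + i``): 16-bit PNG pair
    ``{id}_input.png`` / ``{id}_gt.png`` (ground-truth soft tissue), the
    float decomposition as ``{id}_float.npz``, and ``{id}_contours.json``.
    A ``manifest.csv`` records ids, seeds, file paths, the affine intensity
    scaling, and (with ``split=True``) a deterministic 4:1 train/validation
    assignment.
    """
    from ribsuppress.io_cli import write_image  # deferred: io depends on phantom types

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_train, _ = train_val_split(n)
    samples = []
    rows = []
    for i in range(n):
        spec = replace(template, seed=seed + i)
        sample = generate(spec)
        sid = f"phantom_{i:04d}"
        lo = float(min(sample.input.min(), sample.background.min(), 0.0))
        hi = float(max(sample.input.max(), sample.background.max(), 1.0))
        scale = lambda a: (a - lo) / (hi - lo)
        write_image(out / f"{sid}_input.png", scale(sample.input), bit_depth=16)
        write_image(out / f"{sid}_gt.png", scale(sample.background), bit_depth=16)
        np.savez_compressed(out / f"{sid}_float.npz", input=sample.input,
                            background=sample.background, bone=sample.bone,
                            noise=sample.noise)
        with open(out / f"{sid}_contours.json", "w") as fh:
            json.dump(contours_to_json(sample.contours), fh)
        rows.append({
            "id": sid, "seed": spec.seed,
            "input": f"{sid}_input.png", "gt": f"{sid}_gt.png",
            "contours": f"{sid}_contours.json", "float": f"{sid}_float.npz",
            "intensity_lo": lo, "intensity_hi": hi,
            "split": ("train" if i < n_train else "val") if split else "",
        })
        samples.append(sample)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return samples
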