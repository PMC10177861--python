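"""Rib removal: subtraction, border blending, full-ribcage iteration, HP search.

One rib is suppressed by subtracting its estimated bone shadow from the
radiograph and smoothing the thin band along the contour where the cut can
leave a visible seam.  A ribcage is handled by repeating the procedure rib by
rib on the running image, so shadows of crossing ribs are removed
sequentially rather than double-counted.  The per-image hyperparameters
(Gaussian width, ratio threshold, neighbour counts, border width) can be
tuned by seeded random grid search against a residual rib-edge energy
objective.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ribsuppress.rib_extraction import (
    BoneImage, ExtractionParams, extract_bone, partial_derivative_s,
)
from ribsuppress.st_transform import Contour, sample_to_st, splat_to_image

__all__ = [
    "RemovalParams", "SuppressionResult",
    "subtract_bone", "blend_border", "suppress_rib", "suppress_ribcage",
    "hp_random_grid_search", "residual_gradient_energy", "rib_sort_key",
]


@dataclass
class RemovalParams:
    """Border-blending tunables.

    sb
        Half-width (in pixels of inward offset ``s``) of the border band that
        gets KNN-blended after subtraction.
    k_border
        Neighbour count of the border KNN mean.
    per_rib_overrides
        Optional map label -> (ExtractionParams, RemovalParams) overriding
        the shared parameters for individual ribs.
    """

    sb: float = 3.0
    k_border: int = 9
    per_rib_overrides: Optional[dict] = None

    def __post_init__(self):
        if self.sb < 0:
            raise ValueError("sb must be >= 0")
        if self.k_border < 1:
            raise ValueError("k_border must be >= 1")


@dataclass
class SuppressionResult:
    """Output of :func:`suppress_ribcage`.

    ``soft + bone_total`` equals the input exactly outside all border bands
    (the blend only touches the bands); ``bone_total >= 0`` everywhere.
    """

    soft: np.ndarray
    bone_total: np.ndarray
    per_rib_bone: dict = field(default_factory=dict)
    params_used: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def subtract_bone(image: np.ndarray, bone: BoneImage) -> np.ndarray:
    """Pixelwise ``image - bone``; the soft image is deliberately not clamped."""
    image = np.asarray(image, dtype=float)
    if image.shape != bone.values.shape:
        raise ValueError("image and bone image shapes differ")
    return image - bone.values


def border_band_mask(contour: Contour, shape: tuple[int, int], sb: float) -> np.ndarray:
    """Rasterise the in-band border strip ``0 <= s <= sb`` of a contour."""
    if sb <= 0:
        return np.zeros(shape, dtype=bool)
    ones = sample_to_st(np.ones(shape), contour, ds=0.5, dt=0.5, s_max=sb)
    rb = splat_to_image(ones, shape)
    return rb > 0


def blend_border(soft: np.ndarray, contour: Contour, params: RemovalParams,
                 rb: Optional[np.ndarray] = None) -> np.ndarray:
    """Replace each border-band pixel by the mean of its k nearest pixels.

    Neighbours are drawn from the band itself plus a 2-px outer margin, so
    context from both sides of the cut pulls the seam together.  Pixels
    outside the band are untouched; ``k_border = 1`` is the identity (every
    band pixel is its own nearest neighbour).
    """
    soft = np.asarray(soft, dtype=float)
    if rb is None:
        rb = border_band_mask(contour, soft.shape, params.sb)
    if not rb.any() or params.k_border == 1:
        return soft.copy()
    margin = ndimage.binary_dilation(rb, iterations=2) & ~rb
    pool = rb | margin
    py, px = np.nonzero(pool)
    ry, rx = np.nonzero(rb)
    tree = cKDTree(np.column_stack([px, py]))
    k = min(params.k_border, len(py))
    _, idx = tree.query(np.column_stack([rx, ry]), k=k)
    idx = np.atleast_2d(idx)
    vals = soft[py, px][idx]
    out = soft.copy()
    out[ry, rx] = vals.mean(axis=1)
    return out


def suppress_rib(image: np.ndarray, contour: Contour, mask: np.ndarray,
                 eparams: Optional[ExtractionParams] = None,
                 rparams: Optional[RemovalParams] = None,
                 ds: float = 1.0, dt: float = 1.0):
    """Suppress one rib: extract its shadow, subtract, blend the border.

    Returns ``(soft, bone)``.
    """
    eparams = eparams or ExtractionParams()
    rparams = rparams or RemovalParams()
    bone = extract_bone(image, contour, mask, params=eparams, ds=ds, dt=dt)
    soft = subtract_bone(image, bone)
    soft = blend_border(soft, contour, rparams)
    return soft, bone


def rib_sort_key(label: str):
    """Deterministic rib processing order: L1..Ln then R1..Rn, then others."""
    m = re.fullmatch(r"([LR])(\d+)", str(label))
    if m:
        return (0 if m.group(1) == "L" else 1, int(m.group(2)), "")
    return (2, 0, str(label))


def suppress_ribcage(image: np.ndarray, contours: list[Contour], masks: list[np.ndarray],
                     eparams: Optional[ExtractionParams] = None,
                     rparams: Optional[RemovalParams] = None,
                     ds: float = 1.0, dt: float = 1.0) -> SuppressionResult:
    """Suppress every rib sequentially on the running soft image.

    Ribs are processed in label order (L1..Ln, R1..Rn) so overlapping
    shadows are subtracted once each; the result is deterministic for a
    fixed ordering.  An empty contour list yields the identity result.
    """
    image = np.asarray(image, dtype=float)
    eparams = eparams or ExtractionParams()
    rparams = rparams or RemovalParams()
    if len(contours) != len(masks):
        raise ValueError("contours and masks must pair up")
    labels = [c.label or f"rib{i}" for i, c in enumerate(contours)]
    if len(set(labels)) != len(labels):
        raise ValueError("rib labels must be unique")
    order = sorted(range(len(contours)), key=lambda i: rib_sort_key(labels[i]))

    soft = image.copy()
    bone_total = np.zeros_like(image)
    per_rib: dict[str, BoneImage] = {}
    log = []
    overrides = rparams.per_rib_overrides or {}
    for i in order:
        contour, mask, label = contours[i], np.asarray(masks[i], dtype=bool), labels[i]
        ep, rp = overrides.get(label, (eparams, rparams))
        bone = extract_bone(soft, contour, mask, params=ep, ds=ds, dt=dt)
        soft = subtract_bone(soft, bone)
        soft = blend_border(soft, contour, rp)
        bone_total += bone.values
        per_rib[label] = bone
        band = int(mask.sum())
        log.append({
            "label": label,
            "band_area": band,
            "clamp_fraction": float((bone.values[mask] == 0).mean()) if band else 0.0,
        })
    return SuppressionResult(
        soft=soft, bone_total=bone_total, per_rib_bone=per_rib,
        params_used={"extraction": eparams, "removal": rparams, "ds": ds, "dt": dt},
        log=log,
    )


def residual_gradient_energy(soft: np.ndarray, contours: list[Contour],
                             masks: list[np.ndarray], ds: float = 1.0,
                             dt: float = 1.0) -> float:
    """Mean squared s-direction gradient of the soft image inside rib bands.

    A rib that survived suppression leaves strong gradients across its
    contour; a well-suppressed band is flat along ``s``.  Used as the default
    objective of the hyperparameter search.
    """
    energies = []
    for contour, mask in zip(contours, masks):
        st = sample_to_st(np.asarray(soft, dtype=float), contour,
                          ds=ds, dt=dt, mask=np.asarray(mask, dtype=bool))
        d = partial_derivative_s(st)
        sel = d.valid.copy()
        sel[0] = False
        if sel.any():
            energies.append(float(np.mean(d.values[sel] ** 2)))
    if not energies:
        raise ValueError("no valid band for the objective")
    return float(np.mean(energies))


_EXTRACTION_KEYS = {"kernel_sigma_t", "tau", "k_center", "keep_if_ratio_gt"}
_REMOVAL_KEYS = {"sb", "k_border"}


def hp_random_grid_search(image: np.ndarray, contours: list[Contour],
                          masks: list[np.ndarray], grid: dict,
                          n_draws: int, seed: int,
                          objective: Optional[Callable[[SuppressionResult], float]] = None,
                          ds: float = 1.0, dt: float = 1.0):
    """Seeded random grid search over suppression hyperparameters.

    ``grid`` maps parameter names (``kernel_sigma_t``, ``tau``, ``k_center``,
    ``sb``, ``k_border``) to candidate lists.  ``n_draws`` combinations are
    drawn uniformly without replacement from the full product grid (a seeded
    permutation), so ``n_draws`` equal to the grid size enumerates it
    exhaustively.  Returns ``(best_params, best_value, records)`` where
    ``best_params`` is a dict of the winning combination and ``records`` the
    evaluated (params, value) pairs in draw order; argmin ties go to the
    earliest draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must have non-empty candidate lists")
    unknown = set(grid) - _EXTRACTION_KEYS - _REMOVAL_KEYS
    if unknown:
        raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")

    names = sorted(grid)
    combos = list(itertools.product(*(grid[n] for n in names)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))[:min(n_draws, len(combos))]

    if objective is None:
        objective = lambda res: residual_gradient_energy(res.soft, contours, masks,
                                                         ds=ds, dt=dt)
    best = None
    records = []
    for pos in order:
        params = dict(zip(names, combos[pos]))
        ep = ExtractionParams(**{k: v for k, v in params.items() if k in _EXTRACTION_KEYS})
        rp = RemovalParams(**{k: v for k, v in params.items() if k in _REMOVAL_KEYS})
        res = suppress_ribcage(image, contours, masks, eparams=ep, rparams=rp,
                               ds=ds, dt=dt)
        val = float(objective(res))
        records.append((params, val))
        if np.isfinite(val) and (best is None or val < best[1]):
            best = (params, val)
    if best is None:
        raise RuntimeError("objective was non-finite for every draw")
    return best[0], best[1], records
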