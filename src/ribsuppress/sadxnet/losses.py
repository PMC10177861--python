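"""Composite training loss: negative PSNR + weighted MS-SSIM and L1 terms.

The total loss is

    L = -alpha * L_PSNR + (1 - alpha) * [beta * L_MS-SSIM + (1 - beta) * L1]

with alpha = 0.75, beta = 0.25.  Conventions, kept deliberately explicit so
tests can be exact:

* ``L_PSNR = log10(MAX_X^2 / MSE)`` — a log10 fidelity term *without* the
  conventional factor 10 (an opt-in ``times_10`` flag restores it); the MSE
  is guarded below by 1e-12 so identical images stay finite.
* ``L_MS-SSIM = 1 - lum * prod_j cs_j``: one luminance term evaluated at the
  coarsest scale times the product of contrast-structure terms over Gaussian
  window scales [0.5, 1, 2, 4, 8] px, each local map spatially averaged, no
  per-scale exponent weights.  Local statistics use zero-padded Gaussian
  windows (self-adjoint, so gradients are exact).
* ``L1``: mean absolute deviation.

All functions accept numpy arrays or autodiff Tensors and return a scalar
Tensor, so the same code path serves evaluation and backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ribsuppress.sadxnet.autodiff import (
    Tensor, absolute, astensor, gaussian_blur, log, maximum_scalar,
)

__all__ = ["LossConfig", "loss_psnr", "loss_msssim", "loss_l1", "composite_loss"]

_LOG10 = float(np.log(10.0))


@dataclass
class LossConfig:
    """Constants of the composite loss.

    max_x is the maximum possible input value (1.0 for unit-normalised
    floats); S is the dynamic range entering the MS-SSIM stability constants
    c1 = (k1*S)^2 and c2 = (k2*S)^2.
    """

    alpha: float = 0.75
    beta: float = 0.25
    max_x: float = 1.0
    ms_scales: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    mse_guard: float = 1e-12
    psnr_times_10: bool = False

    def __post_init__(self):
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if len(self.ms_scales) == 0 or list(self.ms_scales) != sorted(self.ms_scales):
            raise ValueError("ms_scales must be non-empty ascending")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def loss_psnr(x, y, cfg: LossConfig = LossConfig()) -> Tensor:
    """log10(MAX_X^2 / MSE(x, y)), MSE guarded below by ``cfg.mse_guard``."""
    x, y = astensor(x), astensor(y)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    mse = ((x - y) ** 2).mean()
    mse = maximum_scalar(mse, cfg.mse_guard)
    out = log(astensor(cfg.max_x ** 2) / mse) * (1.0 / _LOG10)
    if cfg.psnr_times_10:
        out = out * 10.0
    return out


def loss_l1(x, y) -> Tensor:
    """Mean absolute deviation."""
    x, y = astensor(x), astensor(y)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    return absolute(x - y).mean()


def _local_stats(x: Tensor, y: Tensor, sigma: float):
    mu_x = gaussian_blur(x, sigma)
    mu_y = gaussian_blur(y, sigma)
    var_x = gaussian_blur(x * x, sigma) - mu_x * mu_x
    var_y = gaussian_blur(y * y, sigma) - mu_y * mu_y
    cov = gaussian_blur(x * y, sigma) - mu_x * mu_y
    return mu_x, mu_y, var_x, var_y, cov


def loss_msssim(x, y, cfg: LossConfig = LossConfig()) -> Tensor:
    """1 - [coarsest-scale luminance] * prod over scales of contrast-structure.

    Each term is the spatial mean of its local map.  Requires the image to
    be at least twice the largest window std on each side.
    """
    x, y = astensor(x), astensor(y)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if min(x.shape[-2:]) < 2 * max(cfg.ms_scales):
        raise ValueError("image smaller than the largest Gaussian window")
    c1, c2 = cfg.c1, cfg.c2
    prod = None
    for sigma in cfg.ms_scales:
        mu_x, mu_y, var_x, var_y, cov = _local_stats(x, y, sigma)
        cs = ((cov * 2.0 + c2) / (var_x + var_y + c2)).mean()
        prod = cs if prod is None else prod * cs
    # luminance at the coarsest scale
    mu_x = gaussian_blur(x, cfg.ms_scales[-1])
    mu_y = gaussian_blur(y, cfg.ms_scales[-1])
    lum = ((mu_x * mu_y * 2.0 + c1) / (mu_x * mu_x + mu_y * mu_y + c1)).mean()
    return 1.0 - lum * prod


def composite_loss(x, y, cfg: LossConfig = LossConfig()) -> Tensor:
    """-alpha * PSNR-term + (1-alpha) * [beta * MS-SSIM-term + (1-beta) * L1]."""
    a, b = cfg.alpha, cfg.beta
    out = astensor(0.0)
    if a > 0:
        out = out + (-a) * loss_psnr(x, y, cfg)
    if (1 - a) * b > 0:
        out = out + (1 - a) * b * loss_msssim(x, y, cfg)
    if (1 - a) * (1 - b) > 0:
        out = out + (1 - a) * (1 - b) * loss_l1(x, y)
    return out
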