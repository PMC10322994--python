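"""Analytic first-layer filter banks: difference-of-Gaussians and Gabor kernels.

The first convolution layer of the shallow subcortical-pathway models is not
learned; it is built analytically from two filter families:

* **DoG (difference of Gaussians)** — concentric center-surround kernels,
  ``±A1 exp(-r²/2σ1²) ∓ A2 exp(-r²/2σ2²)``, modelling receptive fields of
  superficial superior-colliculus neurons.  ON kernels have a positive center,
  OFF kernels are their sign-flipped twins.
* **Gabor** — oriented sinusoidal carriers under a Gaussian envelope,
  modelling V1 simple cells.  Even (cosine) and odd (sine) symmetric kernels
  are the real and imaginary parts of the complex Gabor.

Kernels are sampled on a square pixel grid mapped linearly onto the coordinate
square [-0.5, 0.5]², so all σ values and carrier frequencies are expressed in
filter-width units (f = 2 means two carrier cycles across the filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

KERNEL_SIZE = 11  # pixels per side of the standard bank

# Amplitude step shared by every DoG bank member: A1 - A2 = 0.4.
DOG_AMPLITUDE_STEP = 0.4
DOG_A1_VALUES = (0.4, 0.67, 0.8, 1.0)
# Center SDs (filter-width units).  The single-Gaussian members (A2 = 0) use
# the full ladder; genuine center-surround members use the two widest.
DOG_SIGMA1_SINGLE = tuple(1.0 / (k * math.sqrt(2.0)) for k in (2, 4, 8, 16))
DOG_SIGMA1_SURROUND = tuple(1.0 / (k * math.sqrt(2.0)) for k in (2, 4))
DOG_SIGMA_RATIOS = (0.5, 0.25)  # sigma1 / sigma2; surround broader than center

GABOR_AMPLITUDE = 0.4
GABOR_SIGMA = 0.125
GABOR_FREQUENCIES = (2.0, 4.0)  # carrier cycles per filter width
GABOR_ORIENTATIONS = tuple(22.5 * k for k in range(8))  # degrees


@dataclass(frozen=True)
class DoGParams:
    """Parameters of one difference-of-Gaussians kernel.

    ``sigma2`` must be None when ``A2 == 0`` (pure Gaussian member); otherwise
    the surround is broader than the center (``sigma1 < sigma2``).
    """

    A1: float
    A2: float
    sigma1: float
    sigma2: Union[float, None]
    polarity: Literal["ON", "OFF"] = "ON"

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError(f"polarity must be 'ON' or 'OFF', got {self.polarity!r}")
        if self.A2 == 0:
            if self.sigma2 is not None:
                raise ValueError("sigma2 is undefined when A2 = 0")
        else:
            if self.sigma2 is None:
                raise ValueError("sigma2 required when A2 > 0")
            if not self.sigma1 < self.sigma2:
                raise ValueError("surround must be broader than center (sigma1 < sigma2)")


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one Gabor kernel (orientation ``theta`` in degrees)."""

    f: float
    theta: float
    symmetry: Literal["even", "odd"]
    A: float = GABOR_AMPLITUDE
    sigma: float = GABOR_SIGMA

    def __post_init__(self) -> None:
        if self.symmetry not in ("even", "odd"):
            raise ValueError(f"symmetry must be 'even' or 'odd', got {self.symmetry!r}")


@dataclass(frozen=True)
class FilterKernel:
    """A sampled square kernel together with its generating parameters."""

    weights: np.ndarray
    params: Union[DoGParams, GaborParams]
    family: Literal["dog", "gabor"]


def _centered_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates of a size×size grid mapped onto [-0.5, 0.5]²."""
    if size % 2 == 0 or size < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    coords = np.linspace(-0.5, 0.5, size)
    return np.meshgrid(coords, coords, indexing="xy")


def build_dog_kernel(params: DoGParams, size: int = KERNEL_SIZE) -> FilterKernel:
    """Sample a DoG kernel on a centered size×size grid.

    The value at polar radius r is ``s·A1·exp(-r²/2σ1²) - s·A2·exp(-r²/2σ2²)``
    with s = +1 for ON and -1 for OFF polarity.
    """
    xx, yy = _centered_grid(size)
    r2 = xx * xx + yy * yy
    w = params.A1 * np.exp(-r2 / (2.0 * params.sigma1**2))
    if params.A2 != 0:
        w = w - params.A2 * np.exp(-r2 / (2.0 * params.sigma2**2))
    if params.polarity == "OFF":
        w = -w
    return FilterKernel(weights=w.astype(np.float64), params=params, family="dog")


def build_gabor_kernel(params: GaborParams, size: int = KERNEL_SIZE) -> FilterKernel:
    """Sample an even- or odd-symmetric Gabor kernel on the centered grid."""
    xx, yy = _centered_grid(size)
    theta = math.radians(params.theta)
    envelope = params.A * np.exp(-(xx * xx + yy * yy) / (2.0 * params.sigma**2))
    phase = 2.0 * math.pi * params.f * (xx * math.cos(theta) + yy * math.sin(theta))
    carrier = np.cos(phase) if params.symmetry == "even" else np.sin(phase)
    return FilterKernel(weights=envelope * carrier, params=params, family="gabor")


def enumerate_dog_params() -> list[DoGParams]:
    """The 32-member DoG parameter grid, 8 kernels per A1 value.

    Ordering is lexicographic over (A1, sigma1, sigma-ratio, polarity) so that
    channel indices are stable across runs.
    """
    out: list[DoGParams] = []
    for a1 in DOG_A1_VALUES:
        a2 = round(a1 - DOG_AMPLITUDE_STEP, 10)
        if a2 == 0:
            for s1 in DOG_SIGMA1_SINGLE:
                for pol in ("ON", "OFF"):
                    out.append(DoGParams(A1=a1, A2=0.0, sigma1=s1, sigma2=None, polarity=pol))
        else:
            for s1 in DOG_SIGMA1_SURROUND:
                for ratio in DOG_SIGMA_RATIOS:
                    for pol in ("ON", "OFF"):
                        out.append(
                            DoGParams(A1=a1, A2=a2, sigma1=s1, sigma2=s1 / ratio, polarity=pol)
                        )
    return out


def enumerate_dog_bank(size: int = KERNEL_SIZE) -> list[FilterKernel]:
    """All 32 DoG kernels of the fixed first-layer bank."""
    return [build_dog_kernel(p, size) for p in enumerate_dog_params()]


def enumerate_gabor_params() -> list[GaborParams]:
    """The 32-member Gabor grid: 2 frequencies × 8 orientations × 2 symmetries."""
    return [
        GaborParams(f=f, theta=th, symmetry=sym)
        for f in GABOR_FREQUENCIES
        for th in GABOR_ORIENTATIONS
        for sym in ("even", "odd")
    ]


def enumerate_gabor_bank(size: int = KERNEL_SIZE) -> list[FilterKernel]:
    """All 32 Gabor kernels of the cortical-replacement first-layer bank."""
    return [build_gabor_kernel(p, size) for p in enumerate_gabor_params()]


def enumerate_bank(family: str, size: int = KERNEL_SIZE) -> list[FilterKernel]:
    if family == "dog":
        return enumerate_dog_bank(size)
    if family == "gabor":
        return enumerate_gabor_bank(size)
    raise ValueError(f"unknown filter family {family!r}")


def bank_to_conv_weights(bank: list[FilterKernel], in_channels: int = 3) -> np.ndarray:
    """Stack a bank into conv-layer weights of shape (C_out, C_in, k, k).

    Each kernel is replicated identically across the input channels and scaled
    by 1/in_channels, so a grayscale image replicated to 3 channels yields the
    same response as single-channel filtering.
    """
    k = np.stack([f.weights for f in bank]).astype(np.float32)
    w = np.repeat(k[:, None, :, :], in_channels, axis=1) / float(in_channels)
    return w
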