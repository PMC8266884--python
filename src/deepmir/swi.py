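"""Susceptibility-weighted image composition from magnitude and raw phase.

SWI enhances susceptibility contrast by (1) high-pass filtering the raw
phase with a homodyne filter — dividing the complex image m·exp(iφ) by its
low-pass version, obtained by windowing central k-space — then (2) turning
negative filtered phase into a multiplicative mask in [0, 1] (Haacke's
linear negative mask), raising the mask to an integer power and multiplying
it with the magnitude.  Defaults follow the acquisition this package
emulates: a 64 x 64 central k-space window and mask power 4, with only the
shortest echo used downstream.

The k-space window is Hann-tapered by default (a raw rectangular window
rings); the rectangular variant is retained and used as the brute-force
oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_types import ValidationError


@dataclass
class HomodyneConfig:
    window_size: tuple = (64, 64)
    mask_power: int = 4
    taper: str = "hann"  # "hann" | "rect"

    def __post_init__(self) -> None:
        if isinstance(self.window_size, int):
            self.window_size = (self.window_size, self.window_size)
        self.window_size = tuple(int(w) for w in self.window_size)
        if len(self.window_size) != 2 or any(w <= 0 for w in self.window_size):
            raise ValidationError("window_size must be a pair of positive integers")
        if self.mask_power < 1:
            raise ValidationError("mask_power must be >= 1")
        if self.taper not in ("hann", "rect"):
            raise ValidationError("taper must be 'hann' or 'rect'")


def kspace_window(shape, window_size, taper="hann") -> np.ndarray:
    """Centered low-pass window on an fftshifted k-space grid.

    The window is built from the frequency distance to DC, so it is exactly
    Hermitian-symmetric: filtering a real image yields a real low-pass and
    a zero-phase input stays zero-phase through the homodyne filter.
    """
    ny, nx = shape
    wy, wx = window_size
    if wy > ny or wx > nx:
        raise ValidationError(f"window {window_size} larger than image {shape}")

    def _axis(n, w):
        d = np.abs(np.arange(n) - n // 2)  # distance to DC on shifted grid
        half = w / 2.0
        if taper == "rect":
            return (d <= half).astype(float)
        return np.where(d <= half, 0.5 * (1 + np.cos(np.pi * d / half)), 0.0)

    return np.outer(_axis(ny, wy), _axis(nx, wx))


def homodyne_highpass(phase: np.ndarray, magnitude: np.ndarray,
                      config: HomodyneConfig | None = None) -> np.ndarray:
    """High-pass filtered phase of one 2D slice.

    The complex image m·exp(iφ) is divided by its low-pass version (central
    k-space window); the returned array is the phase of that ratio, in
    (-pi, pi].
    """
    config = config or HomodyneConfig()
    phase = np.asarray(phase, dtype=np.float64)
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if phase.shape != magnitude.shape:
        raise ValidationError("phase and magnitude shapes differ")
    if phase.ndim != 2:
        raise ValidationError("homodyne_highpass operates on 2D slices")
    cplx = magnitude * np.exp(1j * phase)
    win = kspace_window(phase.shape, config.window_size, config.taper)
    spec = np.fft.fftshift(np.fft.fft2(cplx))
    lowpass = np.fft.ifft2(np.fft.ifftshift(spec * win))
    eps = np.finfo(np.float64).tiny
    ratio = cplx * np.conj(lowpass) / np.maximum(np.abs(lowpass) ** 2, eps)
    out = np.angle(ratio)
    # np.angle returns [-pi, pi]; fold -pi onto +pi to keep the open interval
    out[out == -np.pi] = np.pi
    return out


def negative_phase_mask(filtered_phase: np.ndarray) -> np.ndarray:
    """Haacke linear negative phase mask: (pi + φ)/pi for φ < 0, else 1."""
    phi = np.asarray(filtered_phase, dtype=np.float64)
    if phi.min() < -np.pi - 1e-9 or phi.max() > np.pi + 1e-9:
        raise ValidationError("phase values must lie in (-pi, pi]")
    mask = np.where(phi < 0, (np.pi + phi) / np.pi, 1.0)
    return np.clip(mask, 0.0, 1.0)


def compose_swi(magnitude: np.ndarray, phase: np.ndarray,
                config: HomodyneConfig | None = None) -> np.ndarray:
    """SWI = magnitude x (negative phase mask)^mask_power, slice-wise for 3D.

    For 3D inputs the slicing axis is the last one (axial slices).
    """
    config = config or HomodyneConfig()
    magnitude = np.asarray(magnitude, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if magnitude.shape != phase.shape:
        raise ValidationError("magnitude and phase shapes differ")
    if magnitude.ndim == 2:
        filt = homodyne_highpass(phase, magnitude, config)
        mask = negative_phase_mask(filt)
        return magnitude * mask**config.mask_power
    if magnitude.ndim == 3:
        out = np.empty_like(magnitude)
        for k in range(magnitude.shape[2]):
            out[:, :, k] = compose_swi(magnitude[:, :, k], phase[:, :, k], config)
        return out
    raise ValidationError("compose_swi expects a 2D slice or 3D volume")
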